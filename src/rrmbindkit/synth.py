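"""Seeded generators for every input class the pipeline consumes.

All randomness in the package lives here.  One integer seed fans out
deterministically into independent per-generator streams (identical
seed + arguments → byte-identical output), and each generator plants a known
ground truth so that recovery can be tested end to end:

* contact tables sampled from a planted propensity model,
* SPR sensorgrams from the 1:1 / bivalent / competition simulators plus
  i.i.d. Gaussian noise and optional linear baseline drift,
* fluorescence-quench titrations of a two-state hairpin,
* RNA strands with consensus motifs planted at known positions.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .hairpin import HairpinBindingSystem, predict_quench
from .kinetics import (
    BridgingParams,
    InjectionSchedule,
    Sensorgram,
    simulate_1to1,
    simulate_bivalent,
    simulate_tandem_competition,
)
from .scoring import RNA_ALPHABET, ContactRecord, PropensityModel

__all__ = [
    "gen_contact_table",
    "gen_sensorgrams",
    "gen_quench_titration",
    "gen_rna",
]

# per-generator stream tags: one global seed fans out deterministically
_STREAMS = {"contacts": 1, "sensorgrams": 2, "titration": 3, "rna": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


def gen_contact_table(
    planted: PropensityModel, n_per_pair: int, seed: int
) -> list[ContactRecord]:
    """Sample contact records from a planted model.

    Draws ``n_per_pair`` nucleotides per (position, residue) entry from the
    planted propensity vector, so retraining on the output converges to the
    planted vectors as n grows.
    """
    if n_per_pair < 0:
        raise InputError("n_per_pair must be >= 0")
    rng = _rng(seed, "contacts")
    nts = list(RNA_ALPHABET)
    records: list[ContactRecord] = []
    counter = 0
    for (pos, res) in sorted(planted.entries):
        p = planted.entries[(pos, res)]
        draws = rng.choice(4, size=n_per_pair, p=p)
        for d in draws:
            records.append(
                ContactRecord(f"cx{counter:06d}", pos, res, 0, nts[int(d)])
            )
            counter += 1
    return records


def gen_sensorgrams(
    kind: str,
    params,
    schedule: InjectionSchedule,
    sigma: float = 0.0,
    drift: float = 0.0,
    seed: int = 0,
) -> list[Sensorgram]:
    """Noisy sensorgrams from one of the kinetic simulators.

    ``kind`` is ``'1to1'``, ``'bivalent'`` or ``'competition'`` (for the last,
    ``params`` is a dict with keys domain1, domain2, bridging, Ltot).
    Gaussian noise of sd ``sigma`` RU and a linear baseline drift
    (``drift`` RU/s) are added on top of the noiseless trace; with
    sigma = drift = 0 the output equals the simulator output exactly.
    """
    if sigma < 0:
        raise InputError("noise sigma must be >= 0")
    if kind == "1to1":
        clean = simulate_1to1(params, schedule)
    elif kind == "bivalent":
        clean = simulate_bivalent(params, schedule)
    elif kind == "competition":
        traces = simulate_tandem_competition(
            params["domain1"], params["domain2"],
            params.get("bridging", BridgingParams()), params["Ltot"], schedule,
        )
        clean = [tr.sensorgram for tr in traces]
    else:
        raise InputError(f"unknown sensorgram kind {kind!r}")
    rng = _rng(seed, "sensorgrams")
    out = []
    for g in clean:
        noise = rng.normal(0.0, sigma, size=g.time.size) if sigma > 0 else 0.0
        r = g.response + noise + drift * g.time
        out.append(Sensorgram(g.time, r, g.concentration, g.t_assoc, g.curve_id))
    return out


def gen_quench_titration(
    system: HairpinBindingSystem,
    p_tots,
    sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(P_tot, normalised fluorescence) pairs with Gaussian noise on F."""
    if sigma < 0:
        raise InputError("noise sigma must be >= 0")
    points = predict_quench(system, p_tots)
    rng = _rng(seed, "titration")
    out = []
    for pt in points:
        noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        out.append((pt.P_tot, pt.fluorescence + noise))
    return out


def gen_rna(
    length: int,
    composition=(0.25, 0.25, 0.25, 0.25),
    motifs: dict[int, str] | None = None,
    seed: int = 0,
) -> str:
    """Random RNA of ``length`` nt with motifs planted verbatim.

    ``composition`` is the background (A, C, G, U) distribution; ``motifs``
    maps 1-based start positions to motif strings.  Overlapping or
    out-of-bounds placements are an error.
    """
    if length < 0:
        raise InputError("length must be >= 0")
    comp = np.asarray(composition, float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
        raise InputError("composition must be a length-4 probability vector")
    motifs = motifs or {}
    occupied = np.zeros(length, bool)
    for start, motif in motifs.items():
        bad = set(motif) - set(RNA_ALPHABET)
        if bad:
            raise InputError(f"motif at {start} contains non-RNA characters {sorted(bad)}")
        i0, i1 = start - 1, start - 1 + len(motif)
        if i0 < 0 or i1 > length:
            raise InputError(f"motif at {start} does not fit a {length}-mer")
        if occupied[i0:i1].any():
            raise InputError(f"motif at {start} overlaps another planted motif")
        occupied[i0:i1] = True
    rng = _rng(seed, "rna")
    seq = list(rng.choice(list(RNA_ALPHABET), size=length, p=comp)) if length else []
    for start, motif in motifs.items():
        seq[start - 1 : start - 1 + len(motif)] = list(motif)
    return "".join(seq)
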