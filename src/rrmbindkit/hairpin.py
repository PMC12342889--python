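"""Coupled RNA hairpin opening and protein binding at equilibrium.

A molecular-beacon style hairpin (fluorophore and quencher held together by
the stem) interconverts between a closed and an open, single-stranded form:

    closed  ⇌  open           K_open = [open]/[closed]
    P + site ⇌ complex        KD_bind (per site, n_sites independent
                              identical sites on the open strand)

Binding is to the open form only, so protein pulls the folding equilibrium
open.  For a free-protein concentration p, the per-strand partition function
is  Z(p) = 1 + K_open·(1 + p/KD)^n,  giving

    fraction closed   = 1 / Z(p)
    bound protein/RNA = K_open · n·(p/KD)·(1 + p/KD)^(n-1) / Z(p)

and p is pinned by protein conservation, solved by bracketed root finding on
[0, P_tot].  Two observable proxies follow: the quencher-release fluorescence
signal (proportional to the RNA *not* in the closed state, normalised to the
zero-protein point of the titration) and the NMR imino-signal proxy (the
fraction of RNA still closed, i.e. still base-paired).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InputError, NumericalError

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal mol^-1 K^-1

__all__ = [
    "HairpinBindingSystem",
    "SpeciesState",
    "TitrationPoint",
    "solve_equilibrium",
    "predict_quench",
    "predict_imino",
]


@dataclass(frozen=True)
class HairpinBindingSystem:
    """Thermodynamic description of one hairpin + protein system.

    K_open is dimensionless (may be ``math.inf`` for an unfoldable strand);
    KD_bind is molar (``math.inf`` switches binding off); RNA_tot is the
    total strand concentration (the assay default is 400 nM).
    """

    K_open: float
    KD_bind: float
    RNA_tot: float = 400e-9
    n_sites: int = 1

    def __post_init__(self) -> None:
        if not self.K_open > 0:
            raise InputError("K_open must be > 0")
        if not self.KD_bind > 0:
            raise InputError("KD_bind must be > 0")
        if self.RNA_tot <= 0:
            raise InputError("RNA_tot must be > 0")
        if self.n_sites < 1:
            raise InputError("n_sites must be >= 1")

    @classmethod
    def from_dg_open(
        cls, dg_open_kcal: float, temperature_K: float = 298.15, **kw
    ) -> "HairpinBindingSystem":
        """Build from an opening free energy ΔG_open (kcal/mol):
        K_open = exp(−ΔG_open / RT)."""
        k_open = math.exp(-dg_open_kcal / (GAS_CONSTANT_KCAL * temperature_K))
        return cls(K_open=k_open, **kw)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium species (molar). ``bound_rna`` counts open strands with at
    least one protein; ``open_rna`` is the unbound open form."""

    closed: float
    open_rna: float
    bound_rna: float
    free_protein: float
    bound_protein: float

    @property
    def not_closed(self) -> float:
        return self.open_rna + self.bound_rna


def _fractions(system: HairpinBindingSystem, p: float):
    """Per-strand fractions (closed, open-unbound, open-bound, protein/strand)
    at free protein p."""
    kop = system.K_open
    occ = 0.0 if math.isinf(system.KD_bind) else p / system.KD_bind
    n = system.n_sites
    if math.isinf(kop):
        # no closed form exists: the strand is a plain n-site lattice
        site = 1.0 + occ
        f_open_unbound = (1.0 / site) ** n
        return 0.0, f_open_unbound, 1.0 - f_open_unbound, n * occ / site
    z = 1.0 + kop * (1.0 + occ) ** n
    f_closed = 1.0 / z
    f_open_unbound = kop / z
    f_bound = kop * ((1.0 + occ) ** n - 1.0) / z
    per_strand = kop * n * occ * (1.0 + occ) ** (n - 1) / z
    return f_closed, f_open_unbound, f_bound, per_strand


def solve_equilibrium(system: HairpinBindingSystem, P_tot: float) -> SpeciesState:
    """Unique physical equilibrium of the coupled system at total protein P_tot.

    The free-protein concentration is the root of
    g(p) = p + RNA_tot·(bound protein per strand)(p) − P_tot,
    which is strictly increasing on [0, P_tot]; it is found by Brent
    bracketing.  Conservation of RNA and protein holds by construction.
    """
    if P_tot < 0:
        raise InputError("P_tot must be >= 0")

    def g(p: float) -> float:
        return p + system.RNA_tot * _fractions(system, p)[3] - P_tot

    if P_tot == 0:
        p = 0.0
    else:
        try:
            p = brentq(g, 0.0, P_tot, xtol=1e-30, rtol=1e-14, maxiter=200)
        except (ValueError, RuntimeError) as exc:
            raise NumericalError(
                f"free-protein bracketing failed on [0, {P_tot}]: {exc}"
            ) from exc
    f_closed, f_open, f_bound, per_strand = _fractions(system, p)
    r = system.RNA_tot
    return SpeciesState(
        closed=f_closed * r,
        open_rna=f_open * r,
        bound_rna=f_bound * r,
        free_protein=p,
        bound_protein=per_strand * r,
    )


@dataclass(frozen=True)
class TitrationPoint:
    P_tot: float
    closed: float
    open_rna: float
    bound_rna: float
    free_protein: float
    fluorescence: float  # normalised


def predict_quench(
    system: HairpinBindingSystem,
    p_tots,
    normalization: str = "zero_point",
) -> list[TitrationPoint]:
    """Predicted fluorescence-quench titration.

    The fluorophore is fully quenched in the closed hairpin and unquenched
    otherwise, so the raw signal is proportional to (open + bound) RNA.
    ``normalization='zero_point'`` divides by the P_tot = 0 signal (the assay
    convention); ``'denatured'`` divides by the all-open denatured-control
    level (RNA_tot), so saturation approaches 1.
    """
    p_tots = np.asarray(list(p_tots), float)
    if np.any(p_tots < 0):
        raise InputError("protein concentrations must be >= 0")
    if normalization == "zero_point":
        ref = solve_equilibrium(system, 0.0).not_closed
        if ref <= 0:
            raise InputError(
                "zero-protein reference signal is 0 (fully closed hairpin); "
                "normalise to the denatured control instead"
            )
    elif normalization == "denatured":
        ref = system.RNA_tot
    else:
        raise InputError(f"unknown normalization {normalization!r}")
    out = []
    for p_tot in p_tots:
        st = solve_equilibrium(system, float(p_tot))
        out.append(
            TitrationPoint(
                P_tot=float(p_tot),
                closed=st.closed,
                open_rna=st.open_rna,
                bound_rna=st.bound_rna,
                free_protein=st.free_protein,
                fluorescence=st.not_closed / ref,
            )
        )
    return out


def predict_imino(system: HairpinBindingSystem, p_tots) -> np.ndarray:
    """Fraction of RNA still closed (base-paired) at each total protein —
    the equilibrium proxy for imino-proton signal intensity.  Monotonically
    nonincreasing in P_tot."""
    p_tots = np.asarray(list(p_tots), float)
    if np.any(p_tots < 0):
        raise InputError("protein concentrations must be >= 0")
    return np.array(
        [solve_equilibrium(system, float(p)).closed / system.RNA_tot for p in p_tots]
    )
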