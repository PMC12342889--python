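"""Readers and writers for the package's tabular and sequence formats.

Conventions: TSV for matrices, profiles and hit tables; CSV for time series;
JSON for fit reports; YAML for configs; UTF-8 throughout.  Floats are
serialised with 17 significant digits so write→read round trips are lossless.
DNA letters (T) in RNA input are converted to U with a warning logged once
per file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ParseError, SchemaError
from .kinetics import FitResult, KineticMapGrid, Sensorgram
from .scoring import (
    AMINO_ACIDS,
    RNA_ALPHABET,
    ContactRecord,
    PropensityModel,
    ScoredMotif,
)

logger = logging.getLogger("rrmbindkit")

_FLOAT = "%.17g"

__all__ = [
    "read_fasta",
    "read_propensity_tsv",
    "write_propensity_tsv",
    "read_contact_tsv",
    "write_contact_tsv",
    "read_profile_tsv",
    "read_slot_map_tsv",
    "read_sensorgram_csv",
    "write_sensorgram_csv",
    "write_hits_tsv",
    "write_scored_motifs_tsv",
    "write_fit_report_json",
    "write_map_tsv",
    "read_titration_csv",
    "write_titration_csv",
    "load_yaml_config",
]


def read_fasta(path, alphabet: str = "rna") -> dict[str, str]:
    """Parse FASTA into {record id: sequence}.

    ``alphabet='rna'`` accepts A/C/G/U plus T (converted to U, logged once
    per file); ``'protein'`` accepts the 20 canonical residues.  Anything
    else raises :class:`ParseError` naming the record.
    """
    path = Path(path)
    if alphabet not in ("rna", "protein"):
        raise SchemaError(f"unknown alphabet {alphabet!r}")
    out: dict[str, str] = {}
    warned = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "rna":
            if "T" in seq and not warned:
                logger.warning("%s: DNA letters found; converting T -> U", path)
                warned = True
            seq = seq.replace("T", "U")
            bad = set(seq) - set(RNA_ALPHABET)
        else:
            bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_propensity_tsv(path, alpha: float = 1.0) -> PropensityModel:
    """Load a propensity matrix (columns: position, residue, pA, pC, pG, pU)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["position", "residue", "pA", "pC", "pG", "pU"], path)
    entries = {}
    for _, row in df.iterrows():
        entries[(int(row["position"]), str(row["residue"]))] = np.array(
            [row["pA"], row["pC"], row["pG"], row["pU"]], float
        )
    return PropensityModel(entries, alpha=alpha)


def write_propensity_tsv(model: PropensityModel, path) -> None:
    rows = [
        {
            "position": pos,
            "residue": res,
            "pA": v[0], "pC": v[1], "pG": v[2], "pU": v[3],
        }
        for (pos, res), v in sorted(model.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def read_contact_tsv(path) -> list[ContactRecord]:
    """Load contact records (columns: complex_id, position, residue, slot, nucleotide)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["complex_id", "position", "residue", "slot", "nucleotide"], path)
    return [
        ContactRecord(
            str(r["complex_id"]), int(r["position"]), str(r["residue"]),
            int(r["slot"]), str(r["nucleotide"]),
        )
        for _, r in df.iterrows()
    ]


def write_contact_tsv(records: list[ContactRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "complex_id": r.complex_id, "position": r.master_position,
                "residue": r.residue, "slot": r.window_slot, "nucleotide": r.nucleotide,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path) -> dict[int, int]:
    """Load a master-position map (columns: position, author_number)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["position", "author_number"], path)
    return {int(r["position"]): int(r["author_number"]) for _, r in df.iterrows()}


def read_slot_map_tsv(path) -> dict[int, int]:
    """Load a position→window-slot map (columns: position, slot)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["position", "slot"], path)
    return {int(r["position"]): int(r["slot"]) for _, r in df.iterrows()}


def write_sensorgram_csv(sensorgrams: list[Sensorgram], path) -> None:
    """Write curves (columns: curve_id, time_s, response_RU, conc_M, phase)."""
    frames = []
    for g in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "curve_id": g.curve_id or f"c{g.concentration:g}",
                    "time_s": g.time,
                    "response_RU": g.response,
                    "conc_M": g.concentration,
                    "phase": g.phase,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT)


def read_sensorgram_csv(path) -> list[Sensorgram]:
    """Read sensorgrams back; one Sensorgram per curve_id, sorted by
    concentration.  Non-monotone time within a curve is a validation error."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["curve_id", "time_s", "response_RU", "conc_M", "phase"], path)
    out = []
    for cid, grp in df.groupby("curve_id", sort=True):
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise SchemaError(f"{path}: curve {cid!r} has non-increasing time")
        concs = grp["conc_M"].unique()
        if concs.size != 1:
            raise SchemaError(f"{path}: curve {cid!r} mixes concentrations")
        assoc = grp["phase"].to_numpy() == "assoc"
        t_assoc = float(t[assoc].max()) if assoc.any() else 0.0
        out.append(
            Sensorgram(t, grp["response_RU"].to_numpy(float), float(concs[0]),
                       t_assoc, curve_id=str(cid))
        )
    out.sort(key=lambda g: g.concentration)
    return out


def write_hits_tsv(hits_by_sequence: dict[str, list], path) -> None:
    """Write motif hits or merged sites (1-based inclusive coordinates)."""
    rows = []
    for seq_id, items in hits_by_sequence.items():
        for h in items:
            if hasattr(h, "pattern_name"):  # MotifHit
                rows.append(
                    {"sequence_id": seq_id, "pattern": h.pattern_name,
                     "start": h.start, "end": h.end, "match": h.matched}
                )
            else:  # Site
                rows.append(
                    {"sequence_id": seq_id, "pattern": "+".join(h.members),
                     "start": h.start, "end": h.end, "match": ""}
                )
    pd.DataFrame(rows, columns=["sequence_id", "pattern", "start", "end", "match"]).to_csv(
        path, sep="\t", index=False
    )


def write_scored_motifs_tsv(motifs: list[ScoredMotif], path) -> None:
    rows = [
        {
            "window": m.window,
            "start": m.start if m.start is not None else "",
            "score": m.score,
            "profile": m.profile_name,
        }
        for m in motifs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def write_fit_report_json(result: FitResult, path) -> None:
    payload = {
        "params": result.params,
        "stderr": result.stderr,
        "ci95": {k: list(v) for k, v in result.ci95.items()},
        "rss": result.rss,
        "n_obs": result.n_obs,
        "converged": result.converged,
        "message": result.message,
        "warnings": list(result.warnings),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_map_tsv(grid: KineticMapGrid, path) -> None:
    """Write the rate-distribution grid (columns: ka, kd, weight)."""
    rows = []
    for i, ka in enumerate(grid.ka_nodes):
        for j, kd in enumerate(grid.kd_nodes):
            rows.append({"ka": ka, "kd": kd, "weight": grid.weights[i, j]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def write_titration_csv(points, path) -> None:
    """Write (P_tot_M, F_norm) rows from TitrationPoints or pairs."""
    rows = []
    for pt in points:
        if hasattr(pt, "fluorescence"):
            rows.append({"P_tot_M": pt.P_tot, "F_norm": pt.fluorescence})
        else:
            p, f = pt
            rows.append({"P_tot_M": p, "F_norm": f})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT)


def read_titration_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["P_tot_M", "F_norm"], path)
    return df


def load_yaml_config(path, allowed_keys: set[str] | None = None) -> dict:
    """Load a YAML config; unknown keys are rejected when a schema is given."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg
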