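"""Published SPR kinetic constants for the MSI-1 constructs (triplicate means).

Monovalent (first-step) rate constants for each protein construct binding
each study oligo: ka1 in M⁻¹s⁻¹, kd1 in s⁻¹, and the reported KD1 in nM with
its replicate spread.  These serve as simulation ground truths (generate →
fit → recover) and as the reference values the recovered KD1 = kd1/ka1 is
compared against.

Protein keys: RRM1 and RRM2 are the isolated domains; RRM2-M1 (E180N) and
RRM2-M2 (K182M) the single-substitution variants; RRM1-2 the wild-type
tandem domain and RRM1-2-DM its E180N/K182M double mutant.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["KineticRow", "REPORTED_KINETICS", "STANDARD_CONCENTRATIONS_M"]


@dataclass(frozen=True)
class KineticRow:
    ka1: float  # M^-1 s^-1
    kd1: float  # s^-1
    KD1_nM: float  # reported
    KD1_err_nM: float  # replicate spread


# the standard dilution series used in the kinetic runs: 7.8-250 nM, twofold
STANDARD_CONCENTRATIONS_M: tuple[float, ...] = tuple(
    7.8125e-9 * 2**i for i in range(6)
)

REPORTED_KINETICS: dict[tuple[str, str], KineticRow] = {
    # isolated domains
    ("RRM1", "oligo-L2"): KineticRow(3.5e6, 0.167, 47.1, 0.7),
    ("RRM1", "oligo-L2.1"): KineticRow(2.6e6, 0.370, 151.0, 16.9),
    ("RRM1", "oligo-L3"): KineticRow(4.5e5, 0.069, 153.0, 8.6),
    ("RRM1", "oligo-L3.2"): KineticRow(1.4e6, 0.120, 85.6, 7.4),
    ("RRM1", "oligo-HP4"): KineticRow(8.3e6, 0.178, 21.9, 2.7),
    ("RRM1", "oligo-HP5"): KineticRow(8.0e6, 0.268, 32.8, 5.2),
    ("RRM2", "oligo-L2"): KineticRow(4.6e6, 0.112, 25.0, 3.6),
    ("RRM2", "oligo-L2.1"): KineticRow(1.8e6, 0.218, 123.0, 7.8),
    ("RRM2", "oligo-L3"): KineticRow(4.7e5, 0.038, 81.6, 2.0),
    ("RRM2", "oligo-L3.2"): KineticRow(2.8e6, 0.121, 44.5, 4.5),
    ("RRM2", "oligo-HP4"): KineticRow(1.1e6, 0.038, 37.2, 2.4),
    ("RRM2", "oligo-HP5"): KineticRow(2.1e6, 0.055, 26.4, 1.6),
    # single-substitution RRM2 variants
    ("RRM2-M1", "oligo-L2"): KineticRow(8.4e6, 0.288, 35.5, 3.6),
    ("RRM2-M1", "oligo-L2.1"): KineticRow(6.7e6, 0.389, 58.6, 3.6),
    ("RRM2-M1", "oligo-L3"): KineticRow(7.0e6, 0.507, 74.8, 9.3),
    ("RRM2-M1", "oligo-L3.2"): KineticRow(4.2e6, 0.187, 49.8, 11.4),
    ("RRM2-M1", "oligo-HP4"): KineticRow(1.4e7, 0.178, 14.1, 2.5),
    ("RRM2-M1", "oligo-HP5"): KineticRow(2.6e7, 0.375, 14.5, 0.8),
    ("RRM2-M2", "oligo-L2"): KineticRow(9.6e5, 0.100, 108.0, 10.2),
    ("RRM2-M2", "oligo-L2.1"): KineticRow(3.5e6, 0.227, 62.9, 11.0),
    ("RRM2-M2", "oligo-L3"): KineticRow(1.5e6, 0.094, 64.5, 4.1),
    ("RRM2-M2", "oligo-L3.2"): KineticRow(1.0e6, 0.187, 88.5, 1.25),
    ("RRM2-M2", "oligo-HP4"): KineticRow(1.1e7, 0.177, 39.1, 15.0),
    ("RRM2-M2", "oligo-HP5"): KineticRow(7.7e6, 0.112, 14.5, 3.0),
    # tandem domain (monovalent step of the bivalent analysis)
    ("RRM1-2", "oligo-L2"): KineticRow(8.8e6, 0.100, 57.6, 12.9),
    ("RRM1-2", "oligo-L2.1"): KineticRow(1.0e6, 0.201, 218.0, 27.5),
    ("RRM1-2", "oligo-L3"): KineticRow(1.6e5, 0.041, 248.0, 8.5),
    ("RRM1-2", "oligo-L3.2"): KineticRow(3.2e5, 0.045, 144.0, 15.0),
    ("RRM1-2", "oligo-HP4"): KineticRow(1.9e6, 0.119, 76.8, 5.9),
    ("RRM1-2", "oligo-HP5"): KineticRow(1.9e6, 0.093, 48.6, 5.6),
    ("RRM1-2-DM", "oligo-L2"): KineticRow(1.0e6, 0.100, 104.0, 9.5),
    ("RRM1-2-DM", "oligo-L2.1"): KineticRow(1.6e6, 0.094, 67.0, 20.4),
    ("RRM1-2-DM", "oligo-L3"): KineticRow(1.4e6, 0.140, 98.5, 4.8),
    ("RRM1-2-DM", "oligo-L3.2"): KineticRow(5.2e5, 0.101, 98.5, 6.9),
}
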