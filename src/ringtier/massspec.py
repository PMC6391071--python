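"""Native-MS arithmetic and stoichiometry assignment.

Everything here works with *average* masses: native electrospray of
multi-hundred-kDa assemblies resolves neither isotopes nor sequence, so the
relevant quantities are sequence-level average masses, differences between
a measured assembly mass and a candidate composition, and the inference of
a neutral mass from a consecutive charge-state peak series.

The residue mass tables are fixed in-package (version tag below) so that
reported expected masses do not drift with third-party library updates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

__all__ = [
    "MASS_TABLE_VERSION",
    "WATER",
    "HPO3",
    "PROTON",
    "AMINO_ACID_RESIDUE_MASSES",
    "DNA_RESIDUE_MASSES",
    "ORI_LAMBDA_DUE_43MER",
    "MassComponent",
    "Composition",
    "PeakSeries",
    "MassEstimate",
    "MassError",
    "protein_average_mass",
    "ssdna_average_mass",
    "complex_mass",
    "mass_error",
    "decompose_mass",
    "infer_mass_from_series",
]

MASS_TABLE_VERSION = "avg-2021-iupac-v1"

WATER = 18.0153  # Da
HPO3 = 79.9799  # Da, metaphosphate (phosphate residue)
PROTON = 1.00728  # Da

# In-chain (residue) average masses: amino acid minus water.
AMINO_ACID_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576, "N": 114.1026,
    "D": 115.0874, "Q": 128.1292, "K": 128.1723, "E": 129.1140, "M": 131.1961,
    "H": 137.1393, "F": 147.1739, "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}

# In-chain deoxynucleoside-monophosphate residue average masses.
DNA_RESIDUE_MASSES: dict[str, float] = {
    "A": 313.2061, "C": 289.1815, "G": 329.2055, "T": 304.1925,
}

# DNA-unwinding-element-derived 43-mer used in the helicase-loader binding
# experiments (5'->3').
ORI_LAMBDA_DUE_43MER = "TGACGAATAATCTTTTCTTTTTTCTTTTGTAATAGTGTCTTTT"


def protein_average_mass(sequence: str, n_terminal_met_loss: bool = False) -> float:
    """Average mass (Da) of a polypeptide from its one-letter sequence.

    ``n_terminal_met_loss`` removes one methionine residue, the common
    in vivo N-terminal processing of bacterial proteins.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(AMINO_ACID_RESIDUE_MASSES)
    if bad:
        raise ValueError(f"non-standard residue code(s): {sorted(bad)}")
    mass = sum(AMINO_ACID_RESIDUE_MASSES[c] for c in seq) + WATER
    if n_terminal_met_loss:
        if seq[0] != "M":
            raise ValueError("met-loss requested but sequence does not start with M")
        mass -= AMINO_ACID_RESIDUE_MASSES["M"]
    return mass


def ssdna_average_mass(
    sequence: str,
    five_prime: Literal["OH", "phosphate"] = "OH",
    three_prime: Literal["OH", "phosphate"] = "OH",
) -> float:
    """Average mass (Da) of single-stranded DNA with explicit termini.

    The residue sum plus water corresponds to a 5'-phosphate / 3'-OH
    oligomer; a 5'-OH terminus (the form of chemically synthesised oligos)
    removes one HPO3, a 3'-phosphate adds one.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty DNA sequence")
    bad = set(seq) - set(DNA_RESIDUE_MASSES)
    if bad:
        raise ValueError(f"non-ACGT character(s): {sorted(bad)}")
    mass = sum(DNA_RESIDUE_MASSES[c] for c in seq) + WATER
    if five_prime == "OH":
        mass -= HPO3
    elif five_prime != "phosphate":
        raise ValueError(f"unknown 5' terminus {five_prime!r}")
    if three_prime == "phosphate":
        mass += HPO3
    elif three_prime != "OH":
        raise ValueError(f"unknown 3' terminus {three_prime!r}")
    return mass


@dataclass(frozen=True)
class MassComponent:
    """A complex building block with an allowed copy-number range."""

    name: str
    monomer_mass: float
    count_min: int = 0
    count_max: int = 0

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise ValueError(f"{self.name}: monomer mass must be positive")
        if not (0 <= self.count_min <= self.count_max):
            raise ValueError(f"{self.name}: invalid count range")


class MassError(NamedTuple):
    delta: float  # measured - expected, Da
    percent: float  # |delta| / expected * 100, two decimals


def mass_error(measured: float, expected: float) -> MassError:
    """Δ mass and percent error of a measurement against an expected mass."""
    if expected <= 0:
        raise ValueError("expected mass must be positive")
    delta = measured - expected
    return MassError(delta=delta, percent=round(abs(delta) / expected * 100.0, 2))


@dataclass(frozen=True)
class Composition:
    """A candidate stoichiometry scored against a measured mass."""

    counts: tuple[tuple[str, int], ...]
    expected_mass: float
    delta: float
    percent_error: float
    ppm: float

    @property
    def total_subunits(self) -> int:
        return sum(n for _, n in self.counts)

    def count(self, name: str) -> int:
        return dict(self.counts).get(name, 0)


def complex_mass(components: Sequence[tuple[MassComponent, int]]) -> float:
    """Expected mass of a complex: Σ count × monomer mass."""
    total = 0.0
    for comp, count in components:
        if count < 0:
            raise ValueError(f"{comp.name}: negative count")
        total += count * comp.monomer_mass
    return total


def decompose_mass(
    measured: float,
    components: Sequence[MassComponent],
    tolerance: float,
    tolerance_unit: Literal["Da", "ppm"] = "Da",
    negative_delta_slack: float = 0.0,
) -> list[Composition]:
    """Exhaustively enumerate compositions matching a measured mass.

    All count combinations within each component's [count_min, count_max]
    range are scored; compositions with |measured - expected| within the
    tolerance are returned, ranked by:

    1. sign plausibility — native-MS measured masses sit *above* the
       sequence mass (salt, solvent and metal adducts only add mass), so a
       composition whose expected mass exceeds the measurement by more than
       ``negative_delta_slack`` is ranked behind every adduct-compatible one;
    2. |Δ| ascending;
    3. fewer total subunits, then component-order counts (parsimony,
       deterministic ties).
    """
    comps = list(components)
    if not comps:
        raise ValueError("no components given")
    tol_da = tolerance if tolerance_unit == "Da" else tolerance * measured / 1e6
    hits: list[Composition] = []
    ranges = [range(c.count_min, c.count_max + 1) for c in comps]
    for counts in itertools.product(*ranges):
        expected = sum(n * c.monomer_mass for c, n in zip(comps, counts))
        if expected <= 0:
            continue
        delta = measured - expected
        if abs(delta) <= tol_da:
            err = mass_error(measured, expected)
            hits.append(
                Composition(
                    counts=tuple((c.name, n) for c, n in zip(comps, counts)),
                    expected_mass=expected,
                    delta=delta,
                    percent_error=err.percent,
                    ppm=abs(delta) / expected * 1e6,
                )
            )
    hits.sort(
        key=lambda h: (
            h.delta < -negative_delta_slack,
            abs(h.delta),
            h.total_subunits,
            [n for _, n in h.counts],
        )
    )
    return hits


@dataclass(frozen=True)
class PeakSeries:
    """An m/z peak list assumed to arise from consecutive charge states."""

    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity)
    adduct_mass: float = PROTON

    def __post_init__(self) -> None:
        if any(mz <= 0 for mz, _ in self.peaks):
            raise ValueError("non-positive m/z")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])


@dataclass(frozen=True)
class MassEstimate:
    mass: float
    sd: float
    charges: tuple[int, ...]
    per_peak_mass: tuple[float, ...]
    per_peak_residual: tuple[float, ...]


def infer_mass_from_series(
    peaks: PeakSeries,
    max_relative_sd: float = 1e-3,
) -> MassEstimate:
    """Neutral mass from a consecutive charge-state series.

    For the adjacent pair with the two largest m/z values (m1 > m2), the
    charge of the second peak is z2 = round((m1 - A)/(m1 - m2)); charges
    then increase by one per peak toward lower m/z.  Each peak yields an
    independent mass z·(m - A); the mean ± SD is returned, and an SD above
    ``max_relative_sd``·mass raises, flagging a series inconsistent with
    any single consecutive-charge assignment.
    """
    A = peaks.adduct_mass
    mz = np.sort(peaks.mz)[::-1]
    if len(mz) < 2:
        raise ValueError("need at least two peaks from consecutive charge states")
    m1, m2 = mz[0], mz[1]
    if m1 - m2 <= 0:
        raise ValueError("duplicate m/z values; charges not assignable")
    z2 = int(round((m1 - A) / (m1 - m2)))
    if z2 < 2:
        raise ValueError("peak spacing inconsistent with consecutive charges")
    charges = np.arange(len(mz)) + (z2 - 1)  # z2 - 1 is the charge of mz[0]
    masses = charges * (mz - A)
    mean = float(masses.mean())
    sd = float(masses.std(ddof=1)) if len(masses) > 1 else 0.0
    if sd > max_relative_sd * mean:
        raise ValueError(
            f"charge-series fit inconsistent: SD {sd:.1f} Da exceeds "
            f"{max_relative_sd:.0e} of the mass ({mean:.1f} Da)"
        )
    return MassEstimate(
        mass=mean,
        sd=sd,
        charges=tuple(int(z) for z in charges),
        per_peak_mass=tuple(float(m) for m in masses),
        per_peak_residual=tuple(float(m - mean) for m in masses),
    )
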