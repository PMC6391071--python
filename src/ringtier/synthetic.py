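"""Synthetic assemblies and spectra with known ground truth.

Every generator is a pure function of its parameter record, including the
seed (NumPy PCG64), and returns the exact planted values alongside the
fixture so tests compare recovered quantities against emitted ground truth
rather than hand-copied numbers.

Defaults mirror the geometry of an open hexameric-helicase spiral as bound
by its loader: six subunits, a per-subunit rise of 4.1 Å and twist of
56.4° about the pseudo-helical axis, domain centers ~35 Å from the axis,
and (optionally) one breached subunit interface.  Pseudo-atoms are all
carbon so surface-area and diameter oracles stay analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .massspec import PROTON, PeakSeries
from .structure_io import AtomRecord, DomainSpec, Structure, TierSpec

__all__ = [
    "RNG_ALGORITHM",
    "HelixParams",
    "AssemblyParams",
    "make_helix_points",
    "make_assembly",
    "make_peak_series",
    "make_crosslink_fixture",
    "InfeasibleFixture",
]

RNG_ALGORITHM = "numpy-PCG64"


class InfeasibleFixture(ValueError):
    """Raised when a requested fixture cannot be built from the structure."""


@dataclass(frozen=True)
class HelixParams:
    """Ideal-helix ground truth: point k sits at angle k·twist and height
    k·rise, a fixed radius from the axis, plus optional isotropic noise."""

    n_subunits: int = 6
    rise: float = 4.1  # Å per subunit
    twist: float = 56.4  # degrees per subunit; sign sets handedness
    radius: float = 35.0  # Å
    axis_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_sd: float = 0.0  # Å, isotropic Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("need at least 3 subunits")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _frame(direction: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, d)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2, d


def make_helix_points(params: HelixParams) -> tuple[np.ndarray, dict]:
    """Ordered helix points plus the planted parameter record."""
    e1, e2, d = _frame(params.axis_direction)
    p0 = np.asarray(params.axis_point, dtype=float)
    k = np.arange(params.n_subunits)
    theta = np.radians(params.twist) * k
    pts = (
        p0[None, :]
        + params.radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
        + (params.rise * k)[:, None] * d
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        pts = pts + rng.normal(0.0, params.noise_sd, size=pts.shape)
    truth = asdict(params)
    truth["rng"] = RNG_ALGORITHM
    return pts, truth


@dataclass(frozen=True)
class AssemblyParams:
    """A pseudo-atomic assembly: one chain per subunit, each a seeded carbon
    cloud centered exactly on its helix point.

    ``breach_gap`` opens the interface between the last and first subunit
    in spiral order to the stated minimum atom-atom distance.  A second
    tier (same chains, residues offset by 100) can be stacked with its own
    rise/twist and an inter-tier tilt.
    """

    helix: HelixParams = field(default_factory=HelixParams)
    atoms_per_domain: int = 40
    domain_radius: float = 6.0  # Å, cloud radius
    breach_gap: float | None = None  # Å, planted opening; None = intact
    breach_after: int | None = None  # open after this 0-based subunit; default last
    second_tier: HelixParams | None = None
    tier_tilt: float = 0.0  # degrees, tilt of the second tier's plane
    tier_offset: float = 30.0  # Å, axial offset of the second tier
    with_nz: bool = False  # add an NZ pseudo-atom near each CA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atoms_per_domain < 1:
            raise ValueError("atoms_per_domain must be >= 1")
        if self.breach_gap is not None and self.breach_gap < 0:
            raise ValueError("breach magnitude must be >= 0")


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _rotate_about(pts: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of points about an axis through the origin."""
    k = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return pts * c + np.cross(k, pts) * s + np.outer(pts @ k, k) * (1 - c)


def _domain_cloud(
    rng: np.random.Generator, center: np.ndarray, n: int, radius: float
) -> np.ndarray:
    """n points in a ball around center, re-centered so the mean is exact."""
    pts = rng.normal(0.0, radius / 2.0, size=(n, 3))
    r = np.linalg.norm(pts, axis=1)
    over = r > radius
    pts[over] *= (radius / r[over])[:, None]
    if n > 1:
        pts -= pts.mean(axis=0)
    else:
        pts[:] = 0.0
    return center + pts


def _apply_breach(
    clouds: list[np.ndarray], gap: float, after: int
) -> tuple[list[np.ndarray], float]:
    """Translate subunits after the breach so the planted opening is exact."""
    a = np.vstack(clouds[: after + 1])
    moved = list(clouds)
    for _ in range(3):  # the closest pair can shift once; iterate to converge
        b = np.vstack(moved[after + 1 :])
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        current = d[i, j]
        if abs(current - gap) < 1e-9:
            break
        u = (b[j] - a[i]) / current
        shift = (gap - current) * u
        moved = moved[: after + 1] + [c + shift for c in moved[after + 1 :]]
    b = np.vstack(moved[after + 1 :])
    final = float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)))
    return moved, final


def make_assembly(params: AssemblyParams) -> tuple[Structure, dict[str, TierSpec], dict]:
    """Build a Structure, its TierSpecs, and the ground-truth record."""
    rng = np.random.default_rng(params.seed)
    truth: dict = {
        "rng": RNG_ALGORITHM,
        "seed": params.seed,
        "tier1": asdict(params.helix),
        "atoms_per_domain": params.atoms_per_domain,
        "domain_radius": params.domain_radius,
    }
    n = params.helix.n_subunits
    chains = _CHAIN_IDS[:n]
    centers1, _ = make_helix_points(params.helix)
    clouds1 = [
        _domain_cloud(rng, centers1[i], params.atoms_per_domain, params.domain_radius)
        for i in range(n)
    ]
    if params.breach_gap is not None:
        after = params.breach_after if params.breach_after is not None else n - 2
        clouds1, achieved = _apply_breach(clouds1, params.breach_gap, after)
        truth["breach_gap"] = achieved
        truth["breach_between"] = (chains[after], chains[after + 1])

    tier_specs: dict[str, TierSpec] = {
        "tier1": TierSpec(
            "tier1",
            [
                DomainSpec(f"tier1_{c}", c, 1, params.atoms_per_domain)
                for c in chains
            ],
        )
    }
    all_clouds: list[tuple[str, int, np.ndarray]] = [
        (chains[i], 0, clouds1[i]) for i in range(n)
    ]

    if params.second_tier is not None:
        from .geometry import fit_plane  # deferred: geometry imports structure_io

        p2 = params.second_tier
        centers2, _ = make_helix_points(p2)
        # plant the tilt relative to tier 1's actual COM plane: first align
        # tier 2's plane normal with tier 1's, then rotate by the requested
        # tilt about an in-plane axis through tier 2's centroid
        centers1_final = np.array([c.mean(axis=0) for c in clouds1])
        n1 = np.asarray(fit_plane(centers1_final).normal)
        n2 = np.asarray(fit_plane(centers2).normal)
        c0 = centers2.mean(axis=0)
        axis_align = np.cross(n2, n1)
        if np.linalg.norm(axis_align) > 1e-12:
            ang_align = np.arccos(np.clip(np.dot(n2, n1), -1, 1))
            centers2 = _rotate_about(centers2 - c0, axis_align, ang_align) + c0
        if params.tier_tilt:
            seed_v = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(seed_v, n1)) > 0.9:
                seed_v = np.array([0.0, 1.0, 0.0])
            in_plane = np.cross(n1, seed_v)
            centers2 = (
                _rotate_about(centers2 - c0, in_plane, np.radians(params.tier_tilt)) + c0
            )
        d = np.asarray(params.helix.axis_direction, dtype=float)
        d /= np.linalg.norm(d)
        centers2 = centers2 + params.tier_offset * d
        truth["tier_tilt_achieved"] = float(
            np.degrees(
                np.arccos(
                    np.clip(abs(np.dot(n1, np.asarray(fit_plane(centers2).normal))), -1, 1)
                )
            )
        )
        clouds2 = [
            _domain_cloud(rng, centers2[i], params.atoms_per_domain, params.domain_radius)
            for i in range(p2.n_subunits)
        ]
        offset = 100
        tier_specs["tier2"] = TierSpec(
            "tier2",
            [
                DomainSpec(
                    f"tier2_{chains[i]}", chains[i],
                    offset + 1, offset + params.atoms_per_domain,
                )
                for i in range(p2.n_subunits)
            ],
        )
        all_clouds += [(chains[i], offset, clouds2[i]) for i in range(p2.n_subunits)]
        truth["tier2"] = asdict(p2)
        truth["tier_tilt"] = params.tier_tilt
        truth["tier_offset"] = params.tier_offset

    atoms: list[AtomRecord] = []
    for chain, res_offset, cloud in all_clouds:
        for r, xyz in enumerate(cloud, start=1):
            atoms.append(
                AtomRecord(
                    chain=chain, residue_number=res_offset + r, residue_name="LYS",
                    atom_name="CA", element="C", position=tuple(xyz),
                )
            )
            if params.with_nz:
                nz = xyz + rng.normal(0.0, 0.1, size=3)
                atoms.append(
                    AtomRecord(
                        chain=chain, residue_number=res_offset + r, residue_name="LYS",
                        atom_name="NZ", element="C", position=tuple(nz),
                    )
                )
    return Structure(atoms=atoms, source="synthetic"), tier_specs, truth


def make_peak_series(
    mass: float,
    charges: Sequence[int],
    adduct: float = PROTON,
    mz_noise_sd: float = 0.0,
    seed: int = 0,
    intensity: float = 100.0,
) -> PeakSeries:
    """Charge-state peak series for a species of known neutral mass."""
    if any(z < 1 for z in charges):
        raise ValueError("charges must be positive")
    rng = np.random.default_rng(seed)
    peaks = []
    for z in charges:
        mz = (mass + z * adduct) / z
        if mz_noise_sd > 0:
            mz += rng.normal(0.0, mz_noise_sd)
        peaks.append((float(mz), intensity))
    return PeakSeries(peaks=tuple(peaks), adduct_mass=adduct)


def make_crosslink_fixture(
    structure: Structure,
    n_satisfied: int,
    n_violated: int,
    cutoff: float = 30.0,
    margin: float = 2.0,
    atom: str = "CA",
    seed: int = 0,
):
    """Sample residue pairs whose distances straddle the cutoff as requested.

    Satisfied pairs are planted at distances ≤ cutoff − margin, violated
    pairs at ≥ cutoff + margin, so classification is unambiguous for any
    nearby measurement atom.  Returns (DataFrame, ground truth); protein
    names are one per chain so chain assignment is exact.

    Raises InfeasibleFixture when the structure lacks enough residue pairs
    in the required distance bands.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    cas = [(a.chain, a.residue_number, a.xyz) for a in structure.atoms if a.atom_name == atom]
    if len(cas) < 2:
        raise InfeasibleFixture("structure has too few residues")
    idx = np.arange(len(cas))
    # sample candidate pairs without materialising the full distance matrix
    max_draw = 200_000
    ii = rng.integers(0, len(cas), size=max_draw)
    jj = rng.integers(0, len(cas), size=max_draw)
    keep = ii < jj
    ii, jj = ii[keep], jj[keep]
    pos = np.array([c[2] for c in cas])
    d = np.linalg.norm(pos[ii] - pos[jj], axis=1)

    def take(mask: np.ndarray, n: int, label: str) -> list[tuple[int, int, float]]:
        cand = list({(int(a), int(b)) for a, b in zip(ii[mask], jj[mask])})
        cand.sort()
        if len(cand) < n:
            raise InfeasibleFixture(
                f"only {len(cand)} candidate {label} pairs available, need {n}"
            )
        picks = rng.choice(len(cand), size=n, replace=False)
        return [
            (cand[p][0], cand[p][1], float(np.linalg.norm(pos[cand[p][0]] - pos[cand[p][1]])))
            for p in picks
        ]

    rows, truth_pairs = [], []
    if n_satisfied:
        for i, j, dist in take(d <= cutoff - margin, n_satisfied, "satisfied"):
            rows.append(_fixture_row(cas, i, j))
            truth_pairs.append({"status": "satisfied", "distance": dist})
    if n_violated:
        for i, j, dist in take(d >= cutoff + margin, n_violated, "violated"):
            rows.append(_fixture_row(cas, i, j))
            truth_pairs.append({"status": "violated", "distance": dist})

    df = pd.DataFrame(
        rows, columns=["Protein1", "Residue1", "Protein2", "Residue2", "Annotation"]
    )
    chain_map = {f"chain_{c}": [c] for c in structure.chains}
    truth = {
        "rng": RNG_ALGORITHM,
        "seed": seed,
        "cutoff": cutoff,
        "margin": margin,
        "n_satisfied": n_satisfied,
        "n_violated": n_violated,
        "pairs": truth_pairs,
        "protein_chain_map": chain_map,
    }
    return df, truth


def _fixture_row(cas, i: int, j: int):
    c1, r1, _ = cas[i]
    c2, r2, _ = cas[j]
    return (f"chain_{c1}", r1, f"chain_{c2}", r2, "planted")
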