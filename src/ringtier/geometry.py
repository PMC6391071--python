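"""Quaternary-structure geometry of ring/spiral assemblies.

The measurements implemented here describe how a stack of protein domains is
arranged in space:

* least-squares plane fits to domain centers of mass and the acute angle
  between two such planes (inter-tier tilt);
* a pseudo-helical description of an ordered domain series — per-step rise
  and signed twist about a fitted axis, with the turn pitch
  ``rise * 360 / twist`` and the total axial extent reported side by side
  (published "pitch" values for open protein spirals do not consistently
  follow either definition, so both are always available);
* the width of the central chamber of a ring (slab-wise, van der Waals
  corrected);
* the gap across a breached subunit interface;
* rigid-body superposition, relative subunit rotations, per-residue Cα
  displacements, and the cis/trans classification of domain orientations
  used for hexameric helicases.

All distances are in Å, all angles in degrees. Every function is
deterministic and invariant under rigid-body motion of its whole input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_io import AtomRecord, center_of_mass

__all__ = [
    "Plane",
    "HelixFit",
    "AxisFit",
    "GapReport",
    "DiameterReport",
    "Transform",
    "fit_plane",
    "plane_angle",
    "fit_helical_axis",
    "helical_parameters",
    "fit_helix",
    "chamber_diameter",
    "interface_gap",
    "superpose",
    "superpose_points",
    "rotation_angle",
    "subunit_rotation",
    "residue_ca_displacement",
    "classify_isomer",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


# --------------------------------------------------------------------------
# planes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    centroid: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"plane normal not unit length (|n|={n})")


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through ≥3 points.

    The normal is the smallest principal component of the centered points;
    its sign is fixed (largest-magnitude component positive) so results are
    deterministic.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane is undefined")
    normal = vt[2]
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    return Plane(centroid=tuple(centroid), normal=tuple(normal))


def plane_angle(a: Plane, b: Plane) -> float:
    """Acute dihedral angle between two planes, degrees in [0, 90]."""
    cosang = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# --------------------------------------------------------------------------
# pseudo-helical parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisFit:
    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radial_rmsd: float
    converged: bool


@dataclass(frozen=True)
class HelixFit:
    """Pseudo-helical description of an ordered point series.

    ``mean_twist`` is signed: positive = right-handed when traversing the
    points in their stated order with the axis oriented along increasing
    rise.  ``pitch`` is the turn pitch ``mean_rise * 360 / |mean_twist|``;
    ``axial_extent`` is the total axial span of the series, the other
    quantity sometimes reported as "pitch" for short open spirals.
    """

    axis_point: tuple[float, float, float]
    axis_direction: tuple[float, float, float]
    rise_per_step: tuple[float, ...]
    twist_per_step: tuple[float, ...]
    mean_rise: float
    mean_twist: float
    pitch: float
    axial_extent: float
    mean_radius: float
    radial_rmsd: float
    handedness: Literal["right", "left", "planar"]

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-9:
            raise ValueError("axis direction must be unit length")
        if np.isfinite(self.pitch) and abs(self.mean_twist) > 1e-12:
            lhs = self.pitch * abs(self.mean_twist) / 360.0
            if abs(lhs - self.mean_rise) > 1e-6 * max(abs(self.mean_rise), 1e-12):
                raise ValueError("pitch/twist/rise identity violated")


def _axis_residuals(params: np.ndarray, pts: np.ndarray, n0: np.ndarray,
                    e1: np.ndarray, e2: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Uniform-helix spread residuals for a candidate axis.

    For the true axis of a uniform helix both the point-to-axis radii and
    the per-step axial climbs are constant, so the residuals are the
    deviations of each from its mean.  (Radial spread alone is ill-posed
    for few, noisy points: spurious tilted cylinders can interpolate the
    radii while scrambling the rises.)

    The direction is the initial estimate tilted by (a, b) along two
    orthonormal complement vectors; the axis point is the centroid offset
    by (u, v) in the same complement.
    """
    a, b, u, v = params
    d = _unit(n0 + a * e1 + b * e2)
    p0 = centroid + u * e1 + v * e2
    rel = pts - p0
    axial = rel @ d
    radial = rel - axial[:, None] * d
    r = np.linalg.norm(radial, axis=1)
    dz = np.diff(axial)
    return np.concatenate([r - r.mean(), dz - dz.mean()])


def _chord_bisector_direction(pts: np.ndarray) -> np.ndarray | None:
    """Axis direction from second differences of an ordered helix.

    For a uniform helix the vectors p[k-1] - 2 p[k] + p[k+1] all point from
    the curve toward the axis; cross products of consecutive ones are
    parallel to the axis.  Exact for ideal helices and planar rings, a good
    starting direction for noisy ones; returns None when degenerate.
    """
    v = pts[:-2] - 2.0 * pts[1:-1] + pts[2:]
    crosses = np.cross(v[:-1], v[1:])
    if len(crosses) == 0:
        return None
    ref = crosses[np.argmax(np.linalg.norm(crosses, axis=1))]
    if np.linalg.norm(ref) < 1e-12:
        return None
    signs = np.sign(crosses @ ref)
    signs[signs == 0] = 1.0
    d = (crosses * signs[:, None]).sum(axis=0)
    n = np.linalg.norm(d)
    return d / n if n > 1e-12 else None


def _circle_center_in_plane(pts: np.ndarray, d: np.ndarray, e1: np.ndarray,
                            e2: np.ndarray, centroid: np.ndarray) -> tuple[float, float]:
    """Algebraic (Kåsa) circle-center fit of the points projected along d."""
    rel = pts - centroid
    x = rel @ e1
    y = rel @ e2
    A = np.column_stack((2 * x, 2 * y, np.ones_like(x)))
    b = x**2 + y**2
    try:
        (u, v, _), *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover
        return 0.0, 0.0
    return float(u), float(v)


def fit_helical_axis(points: np.ndarray, max_nfev: int = 200) -> AxisFit:
    """Fit the axis of an ordered, roughly helical point series.

    Deterministic two-stage scheme: the direction is initialised from the
    chord-bisector construction (exact for ideal helices; total-least-
    squares plane normal as fallback) with the lateral position from an
    algebraic circle fit, then all four axis parameters are refined by
    nonlinear least squares minimising the joint spread of point-to-axis
    radii and per-step axial climbs (both constant for a uniform helix).
    On non-convergence the initial axis is returned with
    ``converged=False``.

    The returned direction is oriented so the mean rise along the point
    order is non-negative.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("axis fit needs at least 4 points")
    if np.allclose(pts, pts[0]):
        raise ValueError("all points coincide; axis undefined")
    plane = fit_plane(pts)
    centroid = np.asarray(plane.centroid)
    n0 = _chord_bisector_direction(pts)
    if n0 is None:
        n0 = np.asarray(plane.normal)
    # orthonormal complement of the initial direction
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n0)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(n0, seed))
    e2 = _unit(np.cross(n0, e1))
    u0, v0 = _circle_center_in_plane(pts, n0, e1, e2, centroid)

    sol = least_squares(
        _axis_residuals,
        x0=np.array([0.0, 0.0, u0, v0]),
        args=(pts, n0, e1, e2, centroid),
        method="lm",
        max_nfev=max_nfev,
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if sol.success:
        a, b, u, v = sol.x
        d = _unit(n0 + a * e1 + b * e2)
        p0 = centroid + u * e1 + v * e2
        converged = True
    else:
        d = n0
        p0 = centroid + u0 * e1 + v0 * e2
        converged = False

    # orient along increasing rise over the ordered series
    axial = (pts - p0) @ d
    if axial[-1] - axial[0] < 0:
        d = -d
    rel = pts - p0
    r = np.linalg.norm(rel - (rel @ d)[:, None] * d, axis=1)
    return AxisFit(
        point=tuple(p0),
        direction=tuple(d),
        radial_rmsd=float(np.sqrt(np.mean((r - r.mean()) ** 2))),
        converged=converged,
    )


def helical_parameters(
    points: np.ndarray,
    axis: AxisFit | tuple[np.ndarray, np.ndarray],
    planar_tolerance: float = 1e-6,
) -> HelixFit:
    """Per-step rise/twist of an ordered point series about a given axis.

    Rise is the difference of axial coordinates of consecutive points;
    twist is the signed angle between their radial vectors in the plane
    normal to the axis (right-hand rule about the axis direction).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValueError("helical parameters need at least 2 points")
    if isinstance(axis, AxisFit):
        p0, d = np.asarray(axis.point), np.asarray(axis.direction)
    else:
        p0, d = (np.asarray(x, dtype=float) for x in axis)
    d = _unit(d)

    rel = pts - p0
    axial = rel @ d
    radial = rel - axial[:, None] * d
    radii = np.linalg.norm(radial, axis=1)
    on_axis = np.where(radii < 1e-9)[0]
    if on_axis.size:
        raise ValueError(f"point {int(on_axis[0])} lies on the axis; twist undefined")
    u = radial / radii[:, None]

    rises = np.diff(axial)
    cross = np.cross(u[:-1], u[1:])
    twists = np.degrees(np.arctan2(cross @ d, np.einsum("ij,ij->i", u[:-1], u[1:])))

    mean_rise = float(rises.mean())
    mean_twist = float(twists.mean())
    if abs(mean_rise) <= planar_tolerance:
        handedness: Literal["right", "left", "planar"] = "planar"
    elif mean_rise * mean_twist > 0:
        handedness = "right"
    else:
        handedness = "left"
    pitch = (
        mean_rise * 360.0 / abs(mean_twist) if abs(mean_twist) > 1e-12 else float("inf")
    )
    return HelixFit(
        axis_point=tuple(p0),
        axis_direction=tuple(d),
        rise_per_step=tuple(float(x) for x in rises),
        twist_per_step=tuple(float(x) for x in twists),
        mean_rise=mean_rise,
        mean_twist=mean_twist,
        pitch=float(pitch),
        axial_extent=float(axial.max() - axial.min()),
        mean_radius=float(radii.mean()),
        radial_rmsd=float(np.sqrt(np.mean((radii - radii.mean()) ** 2))),
        handedness=handedness,
    )


def fit_helix(points: np.ndarray, planar_tolerance: float = 1e-6) -> HelixFit:
    """Convenience: fit the axis, then the helical parameters."""
    return helical_parameters(points, fit_helical_axis(points), planar_tolerance)


# --------------------------------------------------------------------------
# chamber diameter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiameterReport:
    tier: str
    diameter: float
    slab_height: float
    slab_diameters: tuple[tuple[float, float], ...]  # (slab center z, diameter)
    axis_inside: bool


def chamber_diameter(
    atoms: Sequence[AtomRecord],
    axis: AxisFit,
    slab_height: float = 5.0,
    vdw_radii: dict[str, float] | None = None,
    tier: str = "",
) -> DiameterReport:
    """Width of the open channel around a fitted axis.

    Atoms are partitioned into axial slabs; each slab's diameter is twice
    the smallest van-der-Waals-corrected atom-to-axis distance, and the
    reported chamber diameter is the tightest positive slab value.
    """
    from .interfaces import VDW_RADII  # local import avoids a cycle

    if not atoms:
        raise ValueError("chamber_diameter of an empty selection")
    radii_table = vdw_radii or VDW_RADII
    pts = np.array([a.position for a in atoms])
    vdw = np.array([radii_table.get(a.element, radii_table["C"]) for a in atoms])
    p0, d = np.asarray(axis.point), _unit(np.asarray(axis.direction))
    rel = pts - p0
    z = rel @ d
    r = np.linalg.norm(rel - z[:, None] * d, axis=1)

    clearance = r - vdw
    n_slabs = max(1, int(np.ceil((z.max() - z.min()) / slab_height)))
    slabs: list[tuple[float, float]] = []
    for k in range(n_slabs):
        lo = z.min() + k * slab_height
        mask = (z >= lo) & (z <= lo + slab_height) if k == n_slabs - 1 else (
            (z >= lo) & (z < lo + slab_height)
        )
        if not mask.any():
            continue
        slabs.append((float(lo + slab_height / 2), float(2.0 * clearance[mask].min())))
    positive = [dia for _, dia in slabs if dia > 0]
    diameter = min(positive) if positive else 0.0
    # the axis should thread the cloud: it does iff, projected along the
    # axis, the atoms surround it — i.e. the largest angular gap between
    # consecutive atom azimuths is below 180°
    radial_vec = rel - z[:, None] * d
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, d)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, seed))
    e2 = np.cross(d, e1)
    az = np.sort(np.arctan2(radial_vec @ e2, radial_vec @ e1))
    gaps = np.diff(np.concatenate([az, [az[0] + 2 * np.pi]]))
    axis_inside = bool(gaps.max() < np.pi)
    return DiameterReport(
        tier=tier,
        diameter=float(diameter),
        slab_height=slab_height,
        slab_diameters=tuple(slabs),
        axis_inside=axis_inside,
    )


# --------------------------------------------------------------------------
# interface gaps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GapReport:
    interface: tuple[str, str]
    min_distance: float
    atom_pair: tuple[tuple[str, int, str], tuple[str, int, str]]
    mode: str


def interface_gap(
    domain_a: Sequence[AtomRecord],
    domain_b: Sequence[AtomRecord],
    mode: Literal["atom_atom", "ca_ca", "vdw"] = "atom_atom",
    labels: tuple[str, str] = ("a", "b"),
) -> GapReport:
    """Minimum separation between two atom groups.

    ``atom_atom``: all-atom center-to-center minimum (default).
    ``ca_ca``: Cα atoms only.
    ``vdw``: surface-to-surface (centers minus both vdW radii).
    """
    from .interfaces import VDW_RADII

    a, b = list(domain_a), list(domain_b)
    if mode == "ca_ca":
        a = [x for x in a if x.atom_name == "CA"]
        b = [x for x in b if x.atom_name == "CA"]
    if not a or not b:
        raise ValueError("interface_gap: empty selection")
    pa = np.array([x.position for x in a])
    pb = np.array([x.position for x in b])
    dm = cdist(pa, pb)
    if mode == "vdw":
        ra = np.array([VDW_RADII.get(x.element, VDW_RADII["C"]) for x in a])
        rb = np.array([VDW_RADII.get(x.element, VDW_RADII["C"]) for x in b])
        dm = dm - ra[:, None] - rb[None, :]
    i, j = np.unravel_index(np.argmin(dm), dm.shape)
    return GapReport(
        interface=labels,
        min_distance=float(max(dm[i, j], 0.0)),
        atom_pair=(a[i].key(), b[j].key()),
        mode=mode,
    )


# --------------------------------------------------------------------------
# superposition and derived angles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Transform:
    """Rigid transform x -> R @ x + t (proper rotation, det = +1)."""

    rotation: tuple[tuple[float, float, float], ...]
    translation: tuple[float, float, float]
    rmsd: float
    n_atoms: int

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.rotation)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def angle(self) -> float:
        return rotation_angle(self.R)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle in degrees of a 3x3 proper rotation matrix."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def superpose_points(mobile: np.ndarray, reference: np.ndarray) -> Transform:
    """Least-squares rigid superposition of paired points (Kabsch)."""
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if len(mob) != len(ref):
        raise ValueError("superpose: point counts differ")
    if len(mob) < 3:
        raise ValueError("superpose needs at least 3 paired atoms")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    rmsd = float(rssd / np.sqrt(len(mob)))
    return Transform(
        rotation=tuple(map(tuple, R)),
        translation=tuple(t),
        rmsd=rmsd,
        n_atoms=len(mob),
    )


def _pair_by_residue(
    mobile: Sequence[AtomRecord],
    reference: Sequence[AtomRecord],
    correspondence: dict[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair atoms by (residue number, atom name); optional mobile->reference
    residue-number map for cross-species comparisons."""
    ref_index = {(a.residue_number, a.atom_name): a for a in reference}
    mob_pts, ref_pts = [], []
    for a in mobile:
        rnum = correspondence.get(a.residue_number) if correspondence else a.residue_number
        if rnum is None:
            continue
        partner = ref_index.get((rnum, a.atom_name))
        if partner is not None:
            mob_pts.append(a.position)
            ref_pts.append(partner.position)
    return np.array(mob_pts).reshape(-1, 3), np.array(ref_pts).reshape(-1, 3)


def superpose(
    mobile: Sequence[AtomRecord],
    reference: Sequence[AtomRecord],
    correspondence: dict[int, int] | None = None,
) -> Transform:
    """Superpose atom selections paired by residue number and atom name."""
    mob, ref = _pair_by_residue(mobile, reference, correspondence)
    if len(mob) < 3:
        raise ValueError(f"superpose: only {len(mob)} paired atoms (need ≥3)")
    return superpose_points(mob, ref)


def subunit_rotation(
    anchor_a: Sequence[AtomRecord],
    probe_a: Sequence[AtomRecord],
    anchor_b: Sequence[AtomRecord],
    probe_b: Sequence[AtomRecord],
    correspondence: dict[int, int] | None = None,
) -> float:
    """Rotation (degrees) of a probe domain between two assemblies after
    anchoring on a shared reference domain.

    Assembly B is first superposed onto assembly A via the anchor domain;
    the residual rotation that then maps the transformed probe of B onto
    the probe of A is reported as a single angle.
    """
    anchor_tf = superpose(anchor_b, anchor_a, correspondence)
    pb, pa = _pair_by_residue(probe_b, probe_a, correspondence)
    if len(pb) < 3:
        raise ValueError("subunit_rotation: fewer than 3 paired probe atoms")
    residual = superpose_points(anchor_tf.apply(pb), pa)
    return residual.angle()


def residue_ca_displacement(
    complex_a: Sequence[AtomRecord],
    complex_b: Sequence[AtomRecord],
    anchor_a: Sequence[AtomRecord],
    anchor_b: Sequence[AtomRecord],
    residues: Sequence[tuple[str, int]],
    correspondence: dict[int, int] | None = None,
) -> dict[tuple[str, int], float | None]:
    """Cα displacement per residue after anchor superposition.

    ``residues`` lists (chain, residue_number) in complex A numbering;
    ``correspondence`` maps A residue numbers to B numbering where the two
    models use different schemes.  Residues lacking a Cα in either model
    map to None (unmapped).
    """
    tf = superpose(anchor_b, anchor_a, None)
    ca_a = {(x.chain, x.residue_number): x.xyz for x in complex_a if x.atom_name == "CA"}
    ca_b = {(x.chain, x.residue_number): x.xyz for x in complex_b if x.atom_name == "CA"}
    out: dict[tuple[str, int], float | None] = {}
    for chain, rnum in residues:
        rnum_b = correspondence.get(rnum, None) if correspondence else rnum
        pa = ca_a.get((chain, rnum))
        pb = ca_b.get((chain, rnum_b)) if rnum_b is not None else None
        if pa is None or pb is None:
            out[(chain, rnum)] = None
        else:
            out[(chain, rnum)] = float(np.linalg.norm(tf.apply(pb) - pa))
    return out


def classify_isomer(
    ntd_globe: Sequence[AtomRecord],
    ntd_hairpin: Sequence[AtomRecord],
    parent_ctd: Sequence[AtomRecord],
    weighting: Literal["atomic_mass", "uniform"] = "atomic_mass",
) -> Literal["cis", "trans"]:
    """Orientation of a subunit's N-terminal hairpin relative to its own CTD.

    ``cis`` if the hairpin points toward the parent CTD (angle between the
    globe→hairpin and globe→CTD directions below 90°), else ``trans``.
    """
    g = center_of_mass(ntd_globe, weighting)
    h = center_of_mass(ntd_hairpin, weighting)
    c = center_of_mass(parent_ctd, weighting)
    v1, v2 = h - g, c - g
    if np.linalg.norm(v1) < 1e-9 or np.linalg.norm(v2) < 1e-9:
        raise ValueError("coincident centers of mass; isomer undefined")
    cosang = float(np.dot(_unit(v1), _unit(v2)))
    return "cis" if cosang > 0 else "trans"
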