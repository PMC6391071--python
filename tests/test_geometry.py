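import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import ringtier as rt
from ringtier import geometry as geom
from ringtier import structure_io as sio
from ringtier.synthetic import HelixParams, make_helix_points
from conftest import make_ca_atoms


# ---------------------------------------------------------------- planes

def test_fit_plane_flat_points():
    rng = np.random.default_rng(0)
    xy = rng.normal(size=(6, 2)) * 10
    pts = np.column_stack([xy, np.zeros(6)])
    plane = rt.fit_plane(pts)
    assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)
    assert plane.centroid[2] == pytest.approx(0.0, abs=1e-12)


def test_fit_plane_inclined_15_degrees():
    # points on z = x * tan(15 deg): normal is 15 deg from +z
    rng = np.random.default_rng(1)
    xy = rng.normal(size=(6, 2)) * 10
    z = xy[:, 0] * np.tan(np.radians(15))
    plane = rt.fit_plane(np.column_stack([xy, z]))
    ang = np.degrees(np.arccos(abs(plane.normal[2])))
    assert ang == pytest.approx(15.0, abs=1e-9)


def test_fit_plane_alternating_hexagon():
    theta = np.radians(np.arange(6) * 60.0)
    delta = 2.0
    pts = np.column_stack(
        [10 * np.cos(theta), 10 * np.sin(theta), delta * (-1.0) ** np.arange(6)]
    )
    plane = rt.fit_plane(pts)
    assert plane.centroid[2] == pytest.approx(0.0, abs=1e-12)
    assert abs(plane.normal[2]) == pytest.approx(1.0, abs=1e-12)


def test_fit_plane_collinear_rejected():
    pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="collinear"):
        rt.fit_plane(pts)


@pytest.mark.parametrize("deg", [0.0, 10.0, 15.0, 90.0])
def test_plane_angle_analytic(deg):
    a = geom.Plane((0, 0, 0), (0, 0, 1))
    n = (np.sin(np.radians(deg)), 0.0, np.cos(np.radians(deg)))
    b = geom.Plane((5, 5, 5), tuple(np.asarray(n) / np.linalg.norm(n)))
    assert rt.plane_angle(a, b) == pytest.approx(deg, abs=1e-6)
    assert rt.plane_angle(b, a) == pytest.approx(deg, abs=1e-6)


@given(st.floats(0, 180), st.floats(0, 360))
def test_plane_angle_symmetric_and_bounded(polar, azim):
    n = np.array(
        [
            np.sin(np.radians(polar)) * np.cos(np.radians(azim)),
            np.sin(np.radians(polar)) * np.sin(np.radians(azim)),
            np.cos(np.radians(polar)),
        ]
    )
    a = geom.Plane((0, 0, 0), (0, 0, 1))
    b = geom.Plane((0, 0, 0), tuple(n / np.linalg.norm(n)))
    ang = rt.plane_angle(a, b)
    assert 0.0 <= ang <= 90.0
    assert ang == rt.plane_angle(b, a)


# ---------------------------------------------------------------- helices

GRID = [
    (rise, twist, radius)
    for rise in (0.5, 2.6, 4.1, 7.4, 10.0)
    for twist in (30.0, 45.0, 56.4, 60.0, 70.0)
    for radius in (10.0, 30.0, 50.0)
]


@pytest.mark.parametrize("rise,twist,radius", GRID)
def test_helix_parameter_recovery_noise_free(rise, twist, radius):
    pts, _ = make_helix_points(
        HelixParams(n_subunits=6, rise=rise, twist=twist, radius=radius)
    )
    fit = rt.fit_helix(pts)
    assert fit.mean_rise == pytest.approx(rise, rel=1e-6)
    assert fit.mean_twist == pytest.approx(twist, rel=1e-6)
    assert fit.mean_radius == pytest.approx(radius, rel=1e-6)
    assert fit.handedness == "right"
    assert fit.radial_rmsd < 1e-6
    # pitch identity holds by construction
    assert fit.pitch * abs(fit.mean_twist) / 360.0 == pytest.approx(
        fit.mean_rise, rel=1e-9
    )


def test_helix_recovery_under_rigid_motion():
    pts, _ = make_helix_points(HelixParams(rise=7.4, twist=60.0, radius=30.0))
    R = Rotation.from_euler("xyz", [31, -47, 112], degrees=True).as_matrix()
    moved = pts @ R.T + np.array([13.0, -44.0, 7.0])
    a, b = rt.fit_helix(pts), rt.fit_helix(moved)
    assert b.mean_rise == pytest.approx(a.mean_rise, abs=1e-6)
    assert b.mean_twist == pytest.approx(a.mean_twist, abs=1e-6)
    assert b.mean_radius == pytest.approx(a.mean_radius, abs=1e-6)
    assert b.handedness == a.handedness


def test_helix_pitch_and_extent_example():
    # rise 7.4 Å / twist 60° / 6 subunits: turn pitch 44.4 Å, extent 37 Å
    pts, _ = make_helix_points(HelixParams(rise=7.4, twist=60.0, radius=30.0))
    fit = rt.fit_helix(pts)
    assert fit.pitch == pytest.approx(44.4, rel=1e-6)
    assert fit.axial_extent == pytest.approx(5 * 7.4, rel=1e-6)


def test_planar_ring_reports_planar():
    pts, _ = make_helix_points(HelixParams(rise=0.0, twist=60.0, radius=30.0))
    fit = rt.fit_helix(pts)
    assert fit.handedness == "planar"
    assert abs(fit.mean_rise) < 1e-9


def test_left_handed_and_mirrored_helices():
    left, _ = make_helix_points(HelixParams(rise=4.1, twist=-56.4, radius=35.0))
    assert rt.fit_helix(left).handedness == "left"
    right, _ = make_helix_points(HelixParams(rise=4.1, twist=56.4, radius=35.0))
    mirrored = right * np.array([1.0, 1.0, -1.0])
    assert rt.fit_helix(mirrored).handedness == "left"


def test_noisy_helix_recovery_within_statistical_bound():
    sd, n = 0.5, 6
    pts, truth = make_helix_points(
        HelixParams(rise=4.1, twist=56.4, radius=35.0, noise_sd=sd, seed=21)
    )
    fit = rt.fit_helix(pts)
    bound = 3 * sd / np.sqrt(n)
    assert fit.mean_rise == pytest.approx(truth["rise"], abs=bound)
    # twist error bound: lateral noise over the lever arm of the radius
    twist_bound = np.degrees(3 * sd / np.sqrt(n) / truth["radius"]) * 2
    assert fit.mean_twist == pytest.approx(truth["twist"], abs=twist_bound)


def test_point_on_axis_rejected():
    pts, _ = make_helix_points(HelixParams(rise=4.0, twist=60.0, radius=20.0))
    axis = geom.AxisFit((0, 0, 0), (0, 0, 1), 0.0, True)
    bad = np.vstack([pts, [[0.0, 0.0, 50.0]]])
    with pytest.raises(ValueError, match="on the axis"):
        rt.helical_parameters(bad, axis)


def _uniform_helix_spread(pts, point, direction):
    """The fit objective: summed variance of radii and of per-step climbs."""
    rel = pts - np.asarray(point)
    d = np.asarray(direction)
    axial = rel @ d
    r = np.linalg.norm(rel - np.outer(axial, d), axis=1)
    dz = np.diff(axial)
    return float(np.var(r) * len(r) + np.var(dz) * len(dz))


def test_axis_fit_not_worse_than_grid_search_oracle():
    """The refined axis must score at least as well as a brute-force 2°
    direction grid (each grid direction paired with its best lateral center)."""

    def grid_best(pts):
        best = np.inf
        centroid = pts.mean(axis=0)
        for polar in np.arange(0.0, 90.1, 2.0):
            for azim in np.arange(0.0, 360.0, 2.0):
                d = np.array(
                    [
                        np.sin(np.radians(polar)) * np.cos(np.radians(azim)),
                        np.sin(np.radians(polar)) * np.sin(np.radians(azim)),
                        np.cos(np.radians(polar)),
                    ]
                )
                rel = pts - centroid
                proj = rel - np.outer(rel @ d, d)
                # best lateral center for this direction: algebraic circle fit
                seed = np.array([1.0, 0.0, 0.0])
                if abs(seed @ d) > 0.9:
                    seed = np.array([0.0, 1.0, 0.0])
                e1 = np.cross(d, seed)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(d, e1)
                x, y = proj @ e1, proj @ e2
                A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
                sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
                center = centroid + sol[0] * e1 + sol[1] * e2
                best = min(best, _uniform_helix_spread(pts, center, d))
        return best

    pts, _ = make_helix_points(
        HelixParams(n_subunits=8, rise=3.0, twist=50.0, radius=25.0, noise_sd=1.0, seed=5)
    )
    fit_axis = rt.fit_helical_axis(pts)
    fit_score = _uniform_helix_spread(pts, fit_axis.point, fit_axis.direction)
    assert fit_score <= grid_best(pts) + 1e-9


# ------------------------------------------------------- diameter and gaps

def test_chamber_diameter_cylinder_and_ring(single_carbon):
    axis = geom.AxisFit((0, 0, 0), (0, 0, 1), 0.0, True)
    theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    ring = make_ca_atoms(
        np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros(16)])
    )
    rep = rt.chamber_diameter(ring, axis)
    assert rep.diameter == pytest.approx(2 * (10 - 1.7), abs=1e-9)
    assert rep.axis_inside

    cyl_pts = [
        (10 * np.cos(t), 10 * np.sin(t), z)
        for t in theta
        for z in np.arange(0.0, 30.0, 2.0)
    ]
    rep = rt.chamber_diameter(make_ca_atoms(cyl_pts), axis)
    assert rep.diameter == pytest.approx(16.6, abs=1e-9)
    assert len(rep.slab_diameters) >= 6

    off_axis = geom.AxisFit((50, 0, 0), (0, 0, 1), 0.0, True)
    assert not rt.chamber_diameter(ring, off_axis).axis_inside


def test_interface_gap_two_atoms_and_modes():
    a = make_ca_atoms([[0, 0, 0]], chain="A")
    b = make_ca_atoms([[15, 0, 0]], chain="B")
    rep = rt.interface_gap(a, b)
    assert rep.min_distance == pytest.approx(15.0)
    assert rep.atom_pair == (("A", 1, "CA"), ("B", 1, "CA"))
    vdw = rt.interface_gap(a, b, mode="vdw")
    assert vdw.min_distance == pytest.approx(15.0 - 2 * 1.7)
    with pytest.raises(ValueError, match="empty"):
        rt.interface_gap(a, [])


def test_planted_breach_gap_recovered(breached_assembly):
    structure, tier_specs, truth = breached_assembly
    domains = {d.chain: d for d in tier_specs["tier1"].domains}
    ca, cb = truth["breach_between"]
    rep = rt.interface_gap(
        rt.select_domain(structure, domains[ca]),
        rt.select_domain(structure, domains[cb]),
    )
    assert rep.min_distance == pytest.approx(20.0, abs=0.5)
    assert rep.min_distance == pytest.approx(truth["breach_gap"], abs=1e-6)


def test_two_tier_tilt_recovered(two_tier_assembly):
    structure, tier_specs, truth = two_tier_assembly
    coms1 = rt.tier_coms(structure, tier_specs["tier1"])
    coms2 = rt.tier_coms(structure, tier_specs["tier2"])
    ang = rt.plane_angle(rt.fit_plane(coms1), rt.fit_plane(coms2))
    assert ang == pytest.approx(15.0, abs=0.5)
    assert ang == pytest.approx(truth["tier_tilt_achieved"], abs=1e-6)


# ------------------------------------------------- superposition & isomers

def test_superpose_identity_and_constructed_rotation():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(15, 3)) * 8
    atoms = make_ca_atoms(pts)
    tf = rt.superpose(atoms, atoms)
    assert tf.rmsd == pytest.approx(0.0, abs=1e-6)
    assert tf.angle() == pytest.approx(0.0, abs=1e-6)

    R = Rotation.from_euler("z", 25, degrees=True).as_matrix()
    rotated = make_ca_atoms(pts @ R.T + [4.0, -2.0, 9.0])
    tf = rt.superpose(atoms, rotated)
    assert tf.rmsd == pytest.approx(0.0, abs=1e-6)
    assert tf.angle() == pytest.approx(25.0, abs=1e-6)


def test_superpose_needs_three_pairs():
    atoms = make_ca_atoms([[0, 0, 0], [1, 0, 0]])
    with pytest.raises(ValueError):
        rt.superpose(atoms, atoms)


def test_subunit_rotation_constructed_20_degrees():
    rng = np.random.default_rng(4)
    anchor = rng.normal(size=(20, 3)) * 8
    probe = rng.normal(size=(20, 3)) * 8 + [30.0, 0.0, 0.0]
    R = Rotation.from_rotvec(np.radians(20) * np.array([0, 1, 0])).as_matrix()
    whole_motion = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    # complex B = rigidly moved copy of A with the probe additionally rotated
    anchor_b = anchor @ whole_motion.T + [5.0, 5.0, 5.0]
    probe_b = (probe @ R.T) @ whole_motion.T + [5.0, 5.0, 5.0]
    ang = rt.subunit_rotation(
        make_ca_atoms(anchor, "A"),
        make_ca_atoms(probe, "B"),
        make_ca_atoms(anchor_b, "A"),
        make_ca_atoms(probe_b, "B"),
    )
    assert ang == pytest.approx(20.0, abs=1e-6)
    same = rt.subunit_rotation(
        make_ca_atoms(anchor, "A"), make_ca_atoms(probe, "B"),
        make_ca_atoms(anchor, "A"), make_ca_atoms(probe, "B"),
    )
    assert same == pytest.approx(0.0, abs=1e-6)


def test_residue_ca_displacement_translated_loop():
    rng = np.random.default_rng(6)
    anchor = rng.normal(size=(12, 3)) * 6
    loop = rng.normal(size=(5, 3)) * 6 + [25.0, 0.0, 0.0]
    a_atoms = make_ca_atoms(anchor, "A") + make_ca_atoms(loop, "B")
    b_atoms = make_ca_atoms(anchor, "A") + make_ca_atoms(loop + [0, 0, 5.0], "B")
    disp = rt.residue_ca_displacement(
        a_atoms, b_atoms,
        make_ca_atoms(anchor, "A"), make_ca_atoms(anchor, "A"),
        residues=[("B", 1), ("B", 3), ("B", 99)],
    )
    assert disp[("B", 1)] == pytest.approx(5.0, abs=1e-9)
    assert disp[("B", 3)] == pytest.approx(5.0, abs=1e-9)
    assert disp[("B", 99)] is None  # no Cα -> unmapped
    ident = rt.residue_ca_displacement(
        a_atoms, a_atoms,
        make_ca_atoms(anchor, "A"), make_ca_atoms(anchor, "A"),
        residues=[("B", 2)],
    )
    assert ident[("B", 2)] == pytest.approx(0.0, abs=1e-9)


def test_classify_isomer_extremes_and_degenerate():
    globe = make_ca_atoms([[0, 0, 0]] * 3)
    hairpin = make_ca_atoms([[5, 0, 0]] * 3, start=10)
    toward = make_ca_atoms([[9, 0.5, 0]] * 3, start=20)
    away = make_ca_atoms([[-9, 0, 0]] * 3, start=30)
    assert rt.classify_isomer(globe, hairpin, toward) == "cis"
    assert rt.classify_isomer(globe, hairpin, away) == "trans"
    with pytest.raises(ValueError, match="coincident"):
        rt.classify_isomer(globe, globe, away)
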