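"""Geometry descriptors: oracles, closed forms and invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import fpgtraj as F
from fpgtraj.geometry import torsion_values
from fpgtraj.topology import AtomRecord, Topology, Trajectory


def _traj_from_points(points):
    """n_snapshots x n_atoms x 3 array -> minimal trajectory of C atoms."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 2:
        points = points[None]
    recs = [AtomRecord(i + 1, f"C{i}", "C", "", "UNK", 1, "A", points[0, i])
            for i in range(points.shape[1])]
    return Trajectory(Topology(recs), points)


def _random_rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    trans = rng.normal(0, 10, 3)
    return rot, trans


# -- distances / angles / torsions -----------------------------------------

def test_distance_basic_and_oracle(rng):
    t = _traj_from_points([[[0, 0, 0], [0, 0, 2]]])
    assert F.distance_series(t, 0, 1).values[0] == pytest.approx(2.0)
    assert F.distance_series(t, 0, 0).values[0] == 0.0
    pts = rng.normal(0, 5, (20, 2, 3))
    t = _traj_from_points(pts)
    expect = np.sqrt(((pts[:, 0] - pts[:, 1]) ** 2).sum(1))
    assert np.allclose(F.distance_series(t, 0, 1).values, expect, atol=1e-12)


def test_angle_right_angle_and_symmetry(rng):
    t = _traj_from_points([[[1, 0, 0], [0, 0, 0], [0, 1, 0]]])
    assert F.angle_series(t, 0, 1, 2).values[0] == pytest.approx(90.0)
    pts = rng.normal(0, 3, (10, 3, 3))
    t = _traj_from_points(pts)
    fwd = F.angle_series(t, 0, 1, 2).values
    rev = F.angle_series(t, 2, 1, 0).values
    assert np.allclose(fwd, rev)
    assert np.all((fwd >= 0) & (fwd <= 180))


def test_torsion_cis_trans_and_rotation_oracle(rng):
    cis = [[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]]
    # reorder as chain a-b-c-d planar: cis (same side) -> 0, trans -> 180
    t = _traj_from_points([cis])
    assert F.torsion_series(t, 0, 1, 2, 3).values[0] == pytest.approx(0.0,
                                                                      abs=1e-9)
    trans = [[1, 1, 0], [0, 1, 0], [0, 0, 0], [-1, 0, 0]]
    t = _traj_from_points([trans])
    assert abs(F.torsion_series(t, 0, 1, 2, 3).values[0]) == pytest.approx(180.0)
    # butane-like: build a chain with a known dihedral by explicit rotation
    for target in (-150.0, -60.0, 25.0, 90.0, 179.0):
        b = np.array([0, 0, 0.0])
        c = np.array([0, 0, 1.5])
        a = b + np.array([1.4, 0, -0.4])
        d0 = c + np.array([1.4, 0, 0.4])
        rot = Rotation.from_rotvec(np.radians(target) * np.array([0, 0, 1.0]))
        d = c + rot.apply(d0 - c)
        t = _traj_from_points([[a, b, c, d]])
        got = F.torsion_series(t, 0, 1, 2, 3).values[0]
        assert got == pytest.approx(target, abs=1e-8)
        # IUPAC: the torsion has the same sign viewed from either end
        rev = F.torsion_series(t, 3, 2, 1, 0).values[0]
        assert rev == pytest.approx(got, abs=1e-8)


def test_torsion_degenerate_axis_is_masked():
    pts = [[1, 0, 0], [0, 0, 0], [0, 0, 0], [0, 1, 0]]
    s = F.torsion_series(_traj_from_points([pts]), 0, 1, 2, 3)
    assert not s.mask[0]


# -- glycosidic chi ---------------------------------------------------------

def test_chi_by_construction_and_toy_lesion(toy):
    from fpgtraj.synth import _base_atoms_3d, _set_chi, _sugar_atoms_3d
    glyco = np.array([2.0, 1.0, -0.5])
    base, anchor = _base_atoms_3d("DG", glyco, [1, 0, 0], [0, 0, 1])
    sugar = _sugar_atoms_3d(glyco, [-1, 0, 0], [0, 0, 1])
    base = _set_chi(base, sugar, anchor, 30.0)
    recs = []
    for i, (name, pos) in enumerate({**sugar, **base}.items()):
        recs.append(AtomRecord(i + 1, name, name[0], "", "DG", 1, "D", pos))
    top = Topology(recs)
    traj = Trajectory(top, np.array([[r.coordinates for r in recs]]))
    chi = F.glycosidic_chi(traj, top.residues[0])
    assert chi.values[0] == pytest.approx(30.0, abs=1e-6)
    # the toy lesion is built at the requested chi
    t = Trajectory(toy.topology, toy.coords[None])
    assert F.glycosidic_chi(t, toy.lesion).values[0] == pytest.approx(-120.0,
                                                                      abs=1e-6)


def test_chi_missing_atoms_is_hard_error():
    recs = [AtomRecord(1, "C1'", "C", "", "DG", 1, "D", np.zeros(3))]
    top = Topology(recs)
    traj = Trajectory(top, np.zeros((1, 1, 3)))
    with pytest.raises(ValueError, match="DG"):
        F.glycosidic_chi(traj, top.residues[0])


@pytest.mark.parametrize("chi,label,sub", [
    (27.0, "syn", None),          # unambiguously syn
    (101.0, "anti", "high_syn"),  # anti domain, high-syn border range
    (-64.0, "syn", "high_anti"),  # syn domain, high-anti border range
    (-55.0, "syn", "high_anti"),
    (90.0, "anti", "high_syn"),   # boundary: half-open convention
    (-90.0, "anti", None),
    (180.0, "anti", None),
])
def test_classify_chi_domains(chi, label, sub):
    d = F.ConformerDomains()
    assert F.classify_chi(chi) == label
    assert d.sublabel(chi) == sub


def test_classify_chi_total_over_circle():
    vals = np.linspace(-180.0, 180.0, 721)
    labels = F.classify_chi(vals)
    assert set(labels) == {"syn", "anti"}


# -- superposition ----------------------------------------------------------

def test_kabsch_identity_and_rigid_copy(rng):
    pts = rng.normal(0, 4, (30, 3))
    _, _, r0 = F.superpose_kabsch(pts, pts)
    assert r0 == pytest.approx(0.0, abs=1e-12)
    rot, trans = _random_rigid(rng)
    moved = pts @ rot.T + trans
    r, t, rmsd = F.superpose_kabsch(pts, moved)
    assert rmsd <= 1e-9
    assert np.linalg.det(r) == pytest.approx(1.0)


def test_kabsch_single_displaced_atom_bound_and_scipy_crosscheck(rng):
    n, d = 50, 2.0
    pts = rng.normal(0, 4, (n, 3))
    mob = pts.copy()
    mob[7] += [0, 0, d]
    r, t, rmsd = F.superpose_kabsch(pts, mob)
    assert rmsd <= d / np.sqrt(n) + 1e-9
    rot_sp, rssd = Rotation.align_vectors(pts - pts.mean(0),
                                          mob - mob.mean(0))
    assert rmsd == pytest.approx(rssd / np.sqrt(n), rel=1e-6)


def test_kabsch_errors():
    with pytest.raises(ValueError):
        F.superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.outer(np.arange(5.0), [1, 0, 0])
    with pytest.raises(ValueError, match="collinear"):
        F.superpose_kabsch(line, line)


def test_rmsd_series_constant_noise_and_invariance(rng):
    n_atoms = 1000
    ref = rng.normal(0, 8, (n_atoms, 3))
    ident = _traj_from_points(np.repeat(ref[None], 3, axis=0))
    sel = np.arange(n_atoms)
    s = F.rmsd_series(ident, ref, sel, sel)
    assert np.allclose(s.values, 0.0, atol=1e-9)
    # Gaussian noise sigma per coordinate -> rmsd ~ sigma*sqrt(3) within 5%
    sigma = 0.3
    noisy = ref[None] + rng.normal(0, sigma, (5, n_atoms, 3))
    s = F.rmsd_series(_traj_from_points(noisy), ref, sel, sel)
    assert np.mean(s.values) == pytest.approx(sigma * np.sqrt(3), rel=0.05)
    # global rigid motion of every snapshot leaves the series unchanged
    rot, trans = _random_rigid(rng)
    s2 = F.rmsd_series(_traj_from_points(noisy @ rot.T + trans), ref, sel, sel)
    assert np.allclose(s2.values, s.values, atol=1e-6)
    # fitted rmsd never exceeds the unfitted one
    unfitted = np.sqrt(((noisy - ref) ** 2).sum(2).mean(1))
    assert np.all(s.values <= unfitted + 1e-12)


# -- radius of gyration -----------------------------------------------------

def test_radius_of_gyration_cases(rng):
    t = _traj_from_points([[[0, 0, 0], [2, 0, 0]]])
    assert F.radius_of_gyration(t, np.array([0, 1])).values[0] == \
        pytest.approx(1.0)
    assert F.radius_of_gyration(t, np.array([0])).values[0] == 0.0
    pts = rng.normal(0, 5, (4, 100, 3))
    t = _traj_from_points(pts)
    got = F.radius_of_gyration(t, np.arange(100)).values
    com = pts.mean(1, keepdims=True)
    expect = np.sqrt(((pts - com) ** 2).sum(2).mean(1))
    assert np.allclose(got, expect, atol=1e-12)


# -- DNA kink ---------------------------------------------------------------

def test_kink_collinear_and_constructed_angles():
    z = np.arange(6.0)
    straight = np.concatenate([
        np.column_stack([z, 0 * z, 0 * z]),
        np.column_stack([6 + z, 0 * z, 0 * z])])
    t = _traj_from_points([straight])
    k = F.dna_kink_angle(t, np.arange(6), np.arange(6, 12))
    assert k.values[0] == pytest.approx(0.0, abs=1e-6)
    # strand-continuous arms whose lines are 120 degrees apart: the
    # direction of travel changes by 60 degrees at the vertex -> 60 kink
    d2 = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0.0])
    bent = np.concatenate([
        np.column_stack([z, 0 * z, 0 * z]),
        6 * np.array([1.0, 0, 0]) + np.outer(z, d2)])
    t = _traj_from_points([bent])
    k = F.dna_kink_angle(t, np.arange(6), np.arange(6, 12))
    assert k.values[0] == pytest.approx(60.0, abs=1e-6)


def test_kink_of_toy_duplex_matches_built_angle(toy):
    top = toy.topology
    t = Trajectory(top, toy.coords[None])
    arm1, arm2 = [], []
    for num in range(-7, 7):
        if not (-7 <= num <= -2 or 2 <= num <= 6):
            continue
        for chain in ("D", "E"):
            try:
                p = top.atom_index(chain, num, "P")
            except KeyError:
                continue
            (arm1 if num < 0 else arm2).append(p)
    k = F.dna_kink_angle(t, np.array(arm1), np.array(arm2))
    assert k.values[0] == pytest.approx(60.0, abs=8.0)


# -- propeller twist --------------------------------------------------------

def _base_pair_traj(omega):
    from fpgtraj.synth import _base_atoms_3d, _rotate_about
    g1 = np.array([5.2, 0, 0.0])
    g2 = np.array([-5.2, 0, 0.0])
    base1, _ = _base_atoms_3d("DA", g1, [-1, 0, 0], [0, 0, 1])
    base2, _ = _base_atoms_3d("DT", g2, [1, 0, 0], [0, 0, -1])
    if omega:
        # counter-rotate about the pair long axis (C8 purine -> C6 pyrimidine)
        axis = base2["C6"] - base1["C8"]
        base1 = _rotate_about(base1, g1, axis, +omega / 2.0)
        base2 = _rotate_about(base2, g2, axis, -omega / 2.0)
    recs = []
    serial = 0
    for resname, resnum, atoms in (("DA", 1, base1), ("DT", 2, base2)):
        for name, pos in atoms.items():
            serial += 1
            recs.append(AtomRecord(serial, name, name[0], "", resname,
                                   resnum, "D", pos))
    top = Topology(recs)
    return top, Trajectory(top, np.array([[r.coordinates for r in recs]]))


def test_propeller_coplanar_is_zero():
    top, traj = _base_pair_traj(0.0)
    w = F.propeller_twist(traj, (top.residues[0], top.residues[1]))
    assert w.values[0] == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("omega", [15.0, -15.0, 7.0])
def test_propeller_counter_rotation_recovered(omega):
    top, traj = _base_pair_traj(omega)
    w = F.propeller_twist(traj, (top.residues[0], top.residues[1]))
    assert abs(w.values[0]) == pytest.approx(abs(omega), abs=0.5)
    # opposite rotations give opposite signs
    top2, traj2 = _base_pair_traj(-omega)
    w2 = F.propeller_twist(traj2, (top2.residues[0], top2.residues[1]))
    assert np.sign(w2.values[0]) == -np.sign(w.values[0])


def test_propeller_rigid_invariance(rng):
    top, traj = _base_pair_traj(11.0)
    w = F.propeller_twist(traj, (top.residues[0], top.residues[1]))
    rot, trans = _random_rigid(rng)
    traj2 = Trajectory(top, traj.coords @ rot.T + trans)
    w2 = F.propeller_twist(traj2, (top.residues[0], top.residues[1]))
    assert w2.values[0] == pytest.approx(w.values[0], abs=1e-6)


# -- eversion ---------------------------------------------------------------

def test_eversion_default_definition_and_invariance(toy, rng):
    t = Trajectory(toy.topology, toy.coords[None])
    e = F.eversion_angle(t, toy.lesion)
    assert e.mask[0]
    rot, trans = _random_rigid(rng)
    t2 = Trajectory(toy.topology, t.coords @ rot.T + trans)
    e2 = F.eversion_angle(t2, toy.lesion)
    assert e2.values[0] == pytest.approx(e.values[0], abs=1e-6)


def test_eversion_equals_torsion_oracle_and_swap(toy):
    t = Trajectory(toy.topology, toy.coords[None])
    d = F.EversionDefinition.default_for(toy.topology, toy.lesion)
    ring, c1, p, p3 = d.points
    pts = [toy.coords[np.asarray(ring)].mean(0), toy.coords[c1],
           toy.coords[p], toy.coords[p3]]
    expect, _ = torsion_values(*[x[None] for x in pts])
    assert F.eversion_angle(t, toy.lesion, d).values[0] == \
        pytest.approx(expect[0], abs=1e-9)
    swapped = F.EversionDefinition(points=(ring, c1, p3, p))
    expect_sw, _ = torsion_values(pts[0][None], pts[1][None],
                                  pts[3][None], pts[2][None])
    assert F.eversion_angle(t, toy.lesion, swapped).values[0] == \
        pytest.approx(expect_sw[0], abs=1e-9)


# -- moving averages --------------------------------------------------------

def test_moving_average_constant_window1_and_masking():
    s = F.GeometrySeries("x", "angstrom", np.full(100, 3.7))
    out = F.moving_average(s, 50)
    assert np.allclose(out.values, 3.7)
    s2 = F.GeometrySeries("x", "angstrom", np.arange(10.0))
    assert np.allclose(F.moving_average(s2, 1).values, s2.values)
    with pytest.warns(UserWarning):
        out = F.moving_average(s2, 11)
    assert not out.mask.any()


def test_moving_average_circular_wraparound():
    vals = np.where(np.arange(100) % 2 == 0, 179.0, -179.0)
    s = F.GeometrySeries("tor", "degree", vals)
    out = F.moving_average(s, 50)
    assert np.all(np.abs(np.abs(out.values[25:75]) - 180.0) < 1.5)


def test_descriptor_rigid_invariance_sweep(toy, rng):
    """Distances, angles, torsions and Rg are rigid-motion invariant."""
    t = Trajectory(toy.topology, toy.coords[None])
    rot, trans = _random_rigid(rng)
    t2 = Trajectory(toy.topology, t.coords @ rot.T + trans)
    assert F.distance_series(t2, 0, 50).values[0] == \
        pytest.approx(F.distance_series(t, 0, 50).values[0], abs=1e-9)
    assert F.angle_series(t2, 0, 25, 50).values[0] == \
        pytest.approx(F.angle_series(t, 0, 25, 50).values[0], abs=1e-8)
    assert F.torsion_series(t2, 0, 25, 50, 75).values[0] == \
        pytest.approx(F.torsion_series(t, 0, 25, 50, 75).values[0], abs=1e-7)
    sel = np.arange(200)
    assert F.radius_of_gyration(t2, sel).values[0] == \
        pytest.approx(F.radius_of_gyration(t, sel).values[0], abs=1e-9)
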