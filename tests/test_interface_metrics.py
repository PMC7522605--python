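import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ifacedyn import synthetic_data as synth
from ifacedyn.interface_metrics import (
    COULOMB_K,
    GeometryError,
    MetricsError,
    ParamEntry,
    ParameterError,
    aligned_segment_rmsd,
    buried_sasa,
    count_waters_within,
    interaction_energy,
    read_param_table,
    sasa,
    superpose_kabsch,
    switching_function,
    write_param_table,
)
from ifacedyn.structure_io import ResidueRange, SelectionSpec, Trajectory

from conftest import make_atom, make_frame, random_rigid_transform, transform_frame


def _entry(chain, seq, name, charge=0.0, eps=0.0, rmin_half=1.0, radius=1.7):
    return ParamEntry(chain, seq, name, charge, eps, rmin_half, radius)


def _param_table(entries):
    return {e.key: e for e in entries}


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def test_isolated_sphere_analytic():
    frame = make_frame([make_atom("P", 1, "CA", (0, 0, 0))])
    result = sasa(frame, SelectionSpec.chains("P"), probe_A=1.4, n_points=960)
    expected = 4 * math.pi * (1.7 + 1.4) ** 2  # default C radius
    assert result.total == pytest.approx(expected, rel=0.01)
    assert result.total == pytest.approx(sum(result.per_atom.values()))


def test_two_distant_atoms_additive():
    frame = make_frame(
        [make_atom("P", 1, "CA", (0, 0, 0)), make_atom("P", 2, "CA", (100, 0, 0))]
    )
    result = sasa(frame, SelectionSpec.chains("P"), n_points=960)
    expected = 2 * 4 * math.pi * (1.7 + 1.4) ** 2
    assert result.total == pytest.approx(expected, rel=0.01)


def _two_sphere_analytic(r1, r2, d, probe):
    """Closed-form exposed area of two overlapping probe-expanded spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * (R1**2 + R2**2)
    h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
    h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
    a1 = 4 * math.pi * R1**2 - 2 * math.pi * R1 * h1
    a2 = 4 * math.pi * R2**2 - 2 * math.pi * R2 * h2
    return a1 + a2


def test_two_overlapping_spheres_analytic_oracle():
    params = _param_table(
        [_entry("P", 1, "CA", radius=1.9), _entry("P", 2, "CA", radius=1.7)]
    )
    frame = make_frame(
        [make_atom("P", 1, "CA", (0, 0, 0)), make_atom("P", 2, "CA", (3.0, 0, 0))]
    )
    result = sasa(frame, SelectionSpec.chains("P"), probe_A=1.4, n_points=960,
                  params=params)
    expected = _two_sphere_analytic(1.9, 1.7, 3.0, 1.4)
    assert result.total == pytest.approx(expected, rel=0.01)


def test_quadrature_error_shrinks_with_more_points():
    params = _param_table(
        [_entry("P", 1, "CA", radius=1.9), _entry("P", 2, "CA", radius=1.7)]
    )
    frame = make_frame(
        [make_atom("P", 1, "CA", (0, 0, 0)), make_atom("P", 2, "CA", (3.0, 0, 0))]
    )
    expected = _two_sphere_analytic(1.9, 1.7, 3.0, 1.4)
    errors = [
        abs(sasa(frame, SelectionSpec.chains("P"), n_points=n, params=params).total - expected)
        for n in (60, 240, 3840)
    ]
    assert errors[2] < errors[0]
    assert errors[2] < errors[1] + 1e-9


def test_sasa_missing_radius_error():
    frame = make_frame([make_atom("P", 1, "CA", (0, 0, 0))])
    with pytest.raises(ParameterError, match="CA"):
        sasa(frame, SelectionSpec.chains("P"), params={})


def test_sasa_excludes_hydrogens():
    frame = make_frame(
        [make_atom("P", 1, "CA", (0, 0, 0)), make_atom("P", 1, "H", (1.0, 0, 0))]
    )
    result = sasa(frame, SelectionSpec.chains("P"), n_points=960)
    assert result.total == pytest.approx(4 * math.pi * 3.1**2, rel=0.01)


# ---------------------------------------------------------------------------
# buried SASA
# ---------------------------------------------------------------------------

def test_far_separated_bodies_bury_nothing():
    frame = make_frame(
        [make_atom("P", 1, "CA", (0, 0, 0)), make_atom("H", 1, "CA", (50, 0, 0))]
    )
    b = buried_sasa(frame, SelectionSpec.chains("P"), SelectionSpec.chains("H"),
                    n_points=960)
    assert b == pytest.approx(0.0, abs=1e-6)


def test_buried_sasa_symmetric(toy_traj, toy_params, side_p, side_h):
    frame = toy_traj.frames[0]
    ab = buried_sasa(frame, side_p, side_h, n_points=240, params=toy_params)
    ba = buried_sasa(frame, side_h, side_p, n_points=240, params=toy_params)
    assert ab == pytest.approx(ba)
    assert ab >= -1e-6


def test_buried_sasa_compositional_oracle(toy_traj, toy_params, side_p, side_h):
    frame = toy_traj.frames[0]
    got = buried_sasa(frame, side_p, side_h, n_points=240, params=toy_params)
    s_a = sasa(frame, side_p, n_points=240, params=toy_params).total
    s_b = sasa(frame, side_h, n_points=240, params=toy_params).total
    union = SelectionSpec((ResidueRange("P"), ResidueRange("H")))
    s_ab = sasa(frame, union, n_points=240, params=toy_params).total
    assert got == pytest.approx(s_a + s_b - s_ab)
    assert got <= s_a + s_b


def test_buried_sasa_invariant_under_rigid_transform(toy_traj, toy_params, side_p, side_h):
    frame = toy_traj.frames[0]
    R, t = random_rigid_transform(np.random.default_rng(4))
    a = buried_sasa(frame, side_p, side_h, n_points=960, params=toy_params)
    b = buried_sasa(transform_frame(frame, R, t), side_p, side_h, n_points=960,
                    params=toy_params)
    # sphere-point grids do not rotate with the frame: quadrature-level match
    assert b == pytest.approx(a, abs=2.0)


# ---------------------------------------------------------------------------
# interaction energy
# ---------------------------------------------------------------------------

def test_coulomb_hand_oracle():
    """+1e and -1e at 5 Å with no LJ -> 332.0636/5 attractive kcal/mol."""
    params = _param_table(
        [_entry("P", 1, "N", charge=1.0), _entry("H", 1, "O", charge=-1.0)]
    )
    frame = make_frame(
        [make_atom("P", 1, "N", (0, 0, 0)), make_atom("H", 1, "O", (5.0, 0, 0))]
    )
    e = interaction_energy(frame, SelectionSpec.chains("P"), SelectionSpec.chains("H"),
                           params)
    assert e.electrostatic == pytest.approx(-66.41272, abs=1e-4)
    assert e.vdw == 0.0
    assert e.total == pytest.approx(e.electrostatic)


def test_pair_beyond_cutoff_contributes_nothing():
    params = _param_table(
        [_entry("P", 1, "N", charge=1.0, eps=0.2),
         _entry("H", 1, "O", charge=-1.0, eps=0.2)]
    )
    frame = make_frame(
        [make_atom("P", 1, "N", (0, 0, 0)), make_atom("H", 1, "O", (13.0, 0, 0))]
    )
    e = interaction_energy(frame, SelectionSpec.chains("P"), SelectionSpec.chains("H"),
                           params)
    assert e.total == 0.0


def test_switching_function_shape():
    assert switching_function(np.array([5.0]), 10, 12)[0] == 1.0
    assert switching_function(np.array([12.0]), 10, 12)[0] == 0.0
    mid = switching_function(np.array([11.0]), 10, 12)[0]
    assert 0.0 < mid < 1.0


def _brute_force_energy(frame, chain_a, chain_b, params, cutoff=12.0, r_on=10.0):
    """Independent double loop with the same physics."""
    elec = vdw = 0.0
    for x in frame.atoms:
        if x.chain_id != chain_a:
            continue
        for y in frame.atoms:
            if y.chain_id != chain_b:
                continue
            r = math.dist(x.position, y.position)
            if r >= cutoff:
                continue
            if r <= r_on:
                sw = 1.0
            else:
                c2, o2, r2 = cutoff**2, r_on**2, r**2
                sw = (c2 - r2) ** 2 * (c2 + 2 * r2 - 3 * o2) / (c2 - o2) ** 3
            px, py = params[x.key], params[y.key]
            elec += COULOMB_K * px.charge * py.charge / r * sw
            eps = math.sqrt(px.epsilon * py.epsilon)
            rmin = px.rmin_half + py.rmin_half
            vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6) * sw
    return elec, vdw


def test_energy_equals_brute_force_reference():
    rng = np.random.default_rng(42)
    atoms, entries = [], []
    for i in range(5):
        atoms.append(make_atom("P", i + 1, "N", rng.uniform(0, 8, 3)))
        entries.append(_entry("P", i + 1, "N", charge=rng.uniform(-1, 1),
                              eps=rng.uniform(0, 0.3), rmin_half=rng.uniform(1.2, 2)))
    for i in range(5):
        atoms.append(make_atom("H", i + 1, "O", rng.uniform(4, 14, 3)))
        entries.append(_entry("H", i + 1, "O", charge=rng.uniform(-1, 1),
                              eps=rng.uniform(0, 0.3), rmin_half=rng.uniform(1.2, 2)))
    frame = make_frame(atoms)
    params = _param_table(entries)
    e = interaction_energy(frame, SelectionSpec.chains("P"), SelectionSpec.chains("H"),
                           params)
    ref_elec, ref_vdw = _brute_force_energy(frame, "P", "H", params)
    assert e.electrostatic == pytest.approx(ref_elec, rel=1e-9, abs=1e-9)
    assert e.vdw == pytest.approx(ref_vdw, rel=1e-9, abs=1e-9)


def test_energy_symmetry_and_additivity(toy_traj, toy_params, side_p):
    frame = toy_traj.frames[0]
    side_h = SelectionSpec.chains("H")
    e_ab = interaction_energy(frame, side_p, side_h, toy_params)
    e_ba = interaction_energy(frame, side_h, side_p, toy_params)
    assert e_ab.total == pytest.approx(e_ba.total)
    # partition side_b by residue parity
    h_res = sorted({a.residue_seq for a in frame.atoms if a.chain_id == "H"})
    part1 = SelectionSpec(tuple(ResidueRange("H", r, r) for r in h_res[::2]))
    part2 = SelectionSpec(tuple(ResidueRange("H", r, r) for r in h_res[1::2]))
    e1 = interaction_energy(frame, side_p, part1, toy_params)
    e2 = interaction_energy(frame, side_p, part2, toy_params)
    assert e_ab.total == pytest.approx(e1.total + e2.total)


def test_energy_missing_params_error(toy_traj, side_p, side_h):
    with pytest.raises(ParameterError):
        interaction_energy(toy_traj.frames[0], side_p, side_h, {})


def test_param_table_round_trip(tmp_path, toy_params):
    p = tmp_path / "params.tsv"
    write_param_table(toy_params, p)
    back = read_param_table(p)
    assert back == toy_params


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def _cloud_frame(coords, chain="P"):
    return make_frame(
        [make_atom(chain, i + 1, "CA", c) for i, c in enumerate(coords)]
    )


def test_kabsch_identity():
    rng = np.random.default_rng(1)
    coords = rng.uniform(-5, 5, (10, 3))
    frame = _cloud_frame(coords)
    tf = superpose_kabsch(frame, frame, SelectionSpec.chains("P"))
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(tf.translation, np.zeros(3), atol=1e-9)


def test_kabsch_recovers_known_rotation():
    rng = np.random.default_rng(2)
    coords = rng.uniform(-5, 5, (20, 3))
    R_true = Rotation.from_euler("xyz", [30, 0, 0], degrees=True).as_matrix()
    t_true = np.array([1.0, -2.0, 3.0])
    ref = _cloud_frame(coords @ R_true.T + t_true)
    mob = _cloud_frame(coords)
    tf = superpose_kabsch(mob, ref, SelectionSpec.chains("P"))
    np.testing.assert_allclose(tf.rotation, R_true, atol=1e-6)
    np.testing.assert_allclose(tf.apply(coords), ref.coords, atol=1e-6)
    assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)


def test_kabsch_beats_coarse_grid_search():
    rng = np.random.default_rng(3)
    coords = rng.uniform(-5, 5, (20, 3))
    R_true = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
    noisy = coords @ R_true.T + rng.normal(0, 0.1, coords.shape)
    ref = _cloud_frame(noisy)
    mob = _cloud_frame(coords)
    tf = superpose_kabsch(mob, ref, SelectionSpec.chains("P"))
    fit_rmsd = np.sqrt(np.mean(np.sum((tf.apply(coords) - noisy) ** 2, axis=1)))

    # independent coarse grid search over Euler angles (centered clouds)
    pc, qc = coords.mean(axis=0), noisy.mean(axis=0)
    P0, Q0 = coords - pc, noisy - qc
    best = np.inf
    angles = np.arange(0, 360, 24)
    for a in angles:
        for b in np.arange(-90, 91, 24):
            for c in angles:
                R = Rotation.from_euler("zyx", [a, b, c], degrees=True).as_matrix()
                r = np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))
                best = min(best, r)
    assert fit_rmsd <= best + 1e-9


def test_kabsch_too_few_or_collinear():
    a = _cloud_frame([(0, 0, 0), (1, 0, 0)])
    with pytest.raises(GeometryError):
        superpose_kabsch(a, a, SelectionSpec.chains("P"))
    line = _cloud_frame([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
    with pytest.raises(GeometryError, match="collinear"):
        superpose_kabsch(line, line, SelectionSpec.chains("P"))


# ---------------------------------------------------------------------------
# aligned segment RMSD
# ---------------------------------------------------------------------------

def test_rmsd_zero_for_repeated_reference(toy_traj, side_h):
    ref = toy_traj.frames[0]
    reps = Trajectory([ref.with_coords(ref.coords, frame_index=i, time_ps=float(i))
                       for i in range(4)])
    loop = SelectionSpec((ResidueRange("P", 25, 33),))
    out = aligned_segment_rmsd(reps, ref, side_h, loop)
    np.testing.assert_allclose(out, 0.0, atol=1e-9)


def test_rmsd_matches_closed_form_rigid_rotation(side_h):
    theta = 60.0
    spec = synth.ToySpec(n_frames=3, seed=0)
    spec.rotation = synth.RotationScenario(
        ResidueRange("P", 25, 33), np.array([0.0, theta, theta])
    )
    traj, _ = synth.generate_rotation_trajectory(spec)
    ref = traj.frames[0]  # unrotated
    loop = SelectionSpec((ResidueRange("P", 25, 33),))
    out = aligned_segment_rmsd(traj, ref, side_h, loop)
    assert out[0] == pytest.approx(0.0, abs=1e-9)

    # closed form: rmsd = 2 sin(theta/2) * sqrt(mean |v_perp|^2) about the axis
    from ifacedyn.complex_builder import plan_rotation

    plan = plan_rotation(ref, ResidueRange("P", 25, 33), side_h, 90.0)
    seg = [a for a in ref.atoms
           if a.chain_id == "P" and 25 <= a.residue_seq <= 33 and not a.is_hydrogen]
    v = np.array([a.position for a in seg]) - plan.pivot
    v_perp = v - np.outer(v @ plan.axis_unit, plan.axis_unit)
    expected = 2 * abs(math.sin(math.radians(theta) / 2)) * math.sqrt(
        np.mean(np.sum(v_perp**2, axis=1))
    )
    assert out[1] == pytest.approx(expected, rel=1e-9)
    assert out[2] == pytest.approx(expected, rel=1e-9)


def test_rmsd_invariant_under_global_motion(toy_traj, side_h):
    ref = toy_traj.frames[0]
    moved = transform_frame(
        toy_traj.frames[1], *random_rigid_transform(np.random.default_rng(9))
    )
    loop = SelectionSpec((ResidueRange("P", 25, 33),))
    base = aligned_segment_rmsd(
        Trajectory([toy_traj.frames[1]]), ref, side_h, loop
    )[0]
    shifted = aligned_segment_rmsd(Trajectory([moved]), ref, side_h, loop)[0]
    assert shifted == pytest.approx(base, abs=1e-9)


def test_rmsd_atom_mismatch_names_missing(toy_traj, side_h):
    ref = toy_traj.frames[0]
    from ifacedyn.complex_builder import truncate_segment

    chopped = truncate_segment(toy_traj.frames[1], ResidueRange("P", 25, 26))
    loop = SelectionSpec((ResidueRange("P", 25, 33),))
    with pytest.raises(MetricsError, match="missing"):
        aligned_segment_rmsd(Trajectory([chopped]), ref, side_h, loop)


# ---------------------------------------------------------------------------
# water counts
# ---------------------------------------------------------------------------

def test_no_waters_counts_zero(toy_traj, side_p):
    assert count_waters_within(toy_traj.frames[0], side_p) == 0


def test_boundary_water_is_inclusive():
    atoms = [
        make_atom("P", 1, "CA", (0, 0, 0)),
        make_atom("W", 1, "O", (3.9, 0, 0), water=True),
        make_atom("W", 2, "O", (4.1, 0, 0), water=True),
        make_atom("W", 3, "O", (4.0, 0, 0), water=True),  # exactly at 4: counted
    ]
    frame = make_frame(atoms)
    assert count_waters_within(frame, SelectionSpec.chains("P"), 4.0) == 2


def test_water_count_matches_exhaustive_oracle():
    spec = synth.ToySpec(
        n_frames=4, seed=11, water_shell=synth.WaterShellSpec(12, 3.0, 6.0)
    )
    traj, _, truth = synth.generate_toy_complex(spec)
    loop = SelectionSpec((ResidueRange("P", 25, 33),))
    for frame, expected in zip(traj.frames, truth.expected_water_counts):
        got = count_waters_within(frame, loop, 4.0)
        # independent brute force
        brute = 0
        for a in frame.atoms:
            if not (a.is_water and a.atom_name == "O"):
                continue
            for b in frame.atoms:
                if b.is_water or b.is_hydrogen:
                    continue
                if not (b.chain_id == "P" and 25 <= b.residue_seq <= 33):
                    continue
                if math.dist(a.position, b.position) <= 4.0:
                    brute += 1
                    break
        assert got == expected == brute
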