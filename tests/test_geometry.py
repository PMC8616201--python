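import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ipdtplan as ip
from ipdtplan.errors import GeometryError, OutOfGridError, PlanNotValidatedError
from oracles import sampled_segment_distance

coord = st.floats(-50.0, 50.0, allow_nan=False)
point = st.tuples(coord, coord, coord)


def _parallel_pair(separation_mm, length=20.0):
    f1 = ip.FiberTrajectory(entry=(0, 0, -30), target=(0, 0, 30), diffuser_length_mm=length)
    f2 = ip.FiberTrajectory(entry=(separation_mm, 0, -30), target=(separation_mm, 0, 30),
                            diffuser_length_mm=length)
    return ip.Plan(fibers=[f1, f2])


# ---------------------------------------------------------- diffuser segment


def test_diffuser_segment_distal_at_target():
    traj = ip.FiberTrajectory(entry=(0, 0, 0), target=(100, 0, 0), diffuser_length_mm=30.0)
    proximal, distal = ip.diffuser_segment(traj)
    np.testing.assert_allclose(proximal, (70, 0, 0), atol=1e-9)
    np.testing.assert_allclose(distal, (100, 0, 0), atol=1e-9)


def test_track_shorter_than_diffuser_rejected():
    with pytest.raises(GeometryError):
        ip.FiberTrajectory(entry=(0, 0, 0), target=(25, 0, 0), diffuser_length_mm=30.0)


def test_diffuser_segment_length_matches_declared():
    rng = np.random.default_rng(9)
    for _ in range(100):
        entry = rng.uniform(-80, 80, 3)
        direction = ip.sample_isotropic_directions(1, rng)[0]
        L = float(rng.choice(ip.ALLOWED_DIFFUSER_LENGTHS_MM))
        target = entry + direction * (L + rng.uniform(5, 60))
        traj = ip.FiberTrajectory(entry=tuple(entry), target=tuple(target),
                                  diffuser_length_mm=L)
        proximal, distal = ip.diffuser_segment(traj)
        assert np.linalg.norm(distal - proximal) == pytest.approx(L, abs=1e-9)


# --------------------------------------------------------- segment distance


def test_segment_distance_parallel_offset():
    assert ip.segment_min_distance((0, 0, 0), (0, 0, 10), (10, 0, 0), (10, 0, 10)) == 10.0


def test_segment_distance_intersecting_is_zero():
    assert ip.segment_min_distance((-5, 0, 0), (5, 0, 0), (0, -5, 0), (0, 5, 0)) == 0.0


def test_segment_distance_345_triangle():
    d = ip.segment_min_distance((0, 0, 0), (10, 0, 0), (0, 3, 4), (10, 3, 4))
    assert d == pytest.approx(5.0, abs=1e-12)
    assert sampled_segment_distance((0, 0, 0), (10, 0, 0), (0, 3, 4), (10, 3, 4)) == \
        pytest.approx(5.0, abs=1e-6)


def test_segment_distance_matches_sampling_oracle():
    rng = np.random.default_rng(17)
    for _ in range(30):
        a0, a1, b0, b1 = rng.uniform(-30, 30, (4, 3))
        closed = ip.segment_min_distance(a0, a1, b0, b1)
        sampled = sampled_segment_distance(a0, a1, b0, b1)
        assert closed == pytest.approx(sampled, abs=1e-6)
        assert closed <= sampled + 1e-12  # the oracle can only overestimate


@given(a0=point, a1=point, b0=point, b1=point)
def test_segment_distance_symmetric_and_nonnegative(a0, a1, b0, b1):
    d_ab = ip.segment_min_distance(a0, a1, b0, b1)
    d_ba = ip.segment_min_distance(b0, b1, a0, a1)
    assert d_ab >= 0.0
    assert d_ab == pytest.approx(d_ba, abs=1e-9)
    # never larger than an endpoint pair distance
    assert d_ab <= np.linalg.norm(np.subtract(a0, b0)) + 1e-9


# ------------------------------------------------------------- validate_plan


def test_spacing_violation_below_9mm():
    alerts = ip.validate_plan(_parallel_pair(8.0))
    assert [a.kind for a in alerts] == ["spacing-violation"]
    assert alerts[0].value == pytest.approx(8.0)


def test_spacing_exactly_9mm_passes():
    assert ip.validate_plan(_parallel_pair(9.0)) == []


def test_single_fiber_plan_has_no_pairwise_alerts():
    traj = ip.FiberTrajectory(entry=(0, 0, 0), target=(0, 0, 50), diffuser_length_mm=20.0)
    assert ip.validate_plan(ip.Plan(fibers=[traj])) == []


def test_invalid_length_alert():
    traj = ip.FiberTrajectory(entry=(0, 0, 0), target=(0, 0, 50), diffuser_length_mm=35.0)
    alerts = ip.validate_plan(ip.Plan(fibers=[traj]))
    assert [a.kind for a in alerts] == ["invalid-length"]
    assert alerts[0].value == 35.0


def test_crossing_trajectories_alert():
    f1 = ip.FiberTrajectory(entry=(-20, 0, 0), target=(20, 0, 20), diffuser_length_mm=20.0)
    f2 = ip.FiberTrajectory(entry=(0, -20, 10), target=(0, 20, 10), diffuser_length_mm=20.0)
    kinds = {a.kind for a in ip.validate_plan(ip.Plan(fibers=[f1, f2]))}
    assert "trajectory-crossing" in kinds


def test_out_of_grid_alert():
    grid = ip.homogeneous_phantom(ip.TissueLabel.WHITE_MATTER, (30, 30, 30), 1.0)
    traj = ip.FiberTrajectory(entry=(14.5, 14.5, -20.0), target=(14.5, 14.5, 25.0),
                              diffuser_length_mm=20.0)
    kinds = {a.kind for a in ip.validate_plan(ip.Plan(fibers=[traj]), grid)}
    assert "out-of-grid" in kinds


def test_alerts_invariant_under_fiber_permutation():
    f1 = ip.FiberTrajectory(entry=(0, 0, -30), target=(0, 0, 30), diffuser_length_mm=20.0)
    f2 = ip.FiberTrajectory(entry=(5, 0, -30), target=(5, 0, 30), diffuser_length_mm=20.0)
    f3 = ip.FiberTrajectory(entry=(40, 0, -30), target=(40, 0, 30), diffuser_length_mm=35.0)
    a_fwd = ip.validate_plan(ip.Plan(fibers=[f1, f2, f3]))
    a_rev = ip.validate_plan(ip.Plan(fibers=[f3, f2, f1]))
    assert sorted((a.kind, round(a.value, 9)) for a in a_fwd) == \
        sorted((a.kind, round(a.value, 9)) for a in a_rev)


def test_bisection_localizes_min_spacing():
    """The smallest accepted parallel separation equals the configured 9 mm."""
    lo, hi = 5.0, 15.0  # lo violates, hi passes
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        alerts = ip.validate_plan(_parallel_pair(mid))
        if alerts:
            lo = mid
        else:
            hi = mid
    assert hi == pytest.approx(9.0, abs=1e-9)


# ---------------------------------------------------- coordinate transforms


def test_world_to_voxel_identity_affine():
    grid = ip.homogeneous_phantom(ip.TissueLabel.WHITE_MATTER, (10, 10, 10), 1.0)
    assert grid.world_to_voxel((5.0, 5.0, 5.0)) == (5, 5, 5)
    with pytest.raises(OutOfGridError, match="outside"):
        grid.world_to_voxel((50.0, 5.0, 5.0))


def test_coordinate_roundtrips():
    grid = ip.VoxelGrid.from_spacing(
        np.zeros((12, 14, 16), dtype=np.int16), (0.5, 1.0, 2.0), origin_mm=(-3.0, 4.0, 7.0)
    )
    rng = np.random.default_rng(2)
    for _ in range(1000):
        idx = tuple(int(i) for i in rng.integers(0, (12, 14, 16)))
        assert grid.world_to_voxel(grid.voxel_to_world(idx)) == idx
    lo, hi = grid.world_bounds
    pts = lo + rng.random((1000, 3)) * (hi - lo)
    for p in pts:
        back = grid.voxel_to_world(grid.world_to_continuous(p))
        np.testing.assert_allclose(back, p, atol=1e-9)


# ------------------------------------------------------------- plan I/O


def test_plan_file_roundtrip(tmp_path):
    plan = _parallel_pair(12.0)
    path = tmp_path / "plan.json"
    ip.write_plan(plan, path)
    back = ip.read_plan(path)
    assert len(back.fibers) == 2
    for orig, rt in zip(plan.fibers, back.fibers):
        np.testing.assert_allclose(rt.entry, orig.entry, atol=1e-6)
        np.testing.assert_allclose(rt.target, orig.target, atol=1e-6)
        assert rt.diffuser_length_mm == orig.diffuser_length_mm


def test_report_refused_with_alerts():
    plan = _parallel_pair(8.0)
    alerts = ip.validate_plan(plan)
    with pytest.raises(PlanNotValidatedError, match="spacing-violation"):
        ip.export_plan_report(plan, alerts)


def test_report_roundtrip_coordinates(tmp_path):
    import json

    plan = _parallel_pair(12.0)
    sources = [ip.build_line_source(t) for t in plan.fibers]
    path = tmp_path / "report.json"
    report = ip.export_plan_report(plan, [], sources=sources, path=path)
    back = json.loads(path.read_text())
    assert back == json.loads(json.dumps(report))
    for i, traj in enumerate(plan.fibers):
        rec = back["fibers"][i]
        assert abs(rec["entry_mm"]["x"] - traj.entry[0]) < 1e-6
        assert abs(rec["target_mm"]["z"] - traj.target[2]) < 1e-6
        assert rec["linear_power_mw_per_cm"] == 200.0
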