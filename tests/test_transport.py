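import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ipdtplan as ip
from ipdtplan.errors import GeometryError, OutOfGridError, UnknownTissueError
from ipdtplan.tissue_optics import OpticalProperties, TissueTable


# ----------------------------------------------------- phase-function sampling


def test_hg_cosine_isotropic_limit():
    assert ip.henyey_greenstein_cosine(0.0, 0.75) == pytest.approx(0.5)


def test_hg_cosine_closed_form_value():
    assert ip.henyey_greenstein_cosine(0.9, 0.5) == pytest.approx(0.98550, abs=1e-5)


def test_hg_cosine_first_moment():
    """The mean sampled cosine equals g (the defining property of the family)."""
    rng = np.random.default_rng(77)
    u = rng.random(1_000_000)
    c = ip.henyey_greenstein_cosine(0.85, u)
    se = c.std(ddof=1) / np.sqrt(c.size)
    assert abs(c.mean() - 0.85) < 3.0 * se


@given(g=st.floats(-1.0, 1.0), u=st.floats(0.0, 1.0, exclude_max=True))
def test_hg_cosine_in_range(g, u):
    assert -1.0 <= float(ip.henyey_greenstein_cosine(g, u)) <= 1.0


# ------------------------------------------------------------- ray traversal


def test_traverse_axis_aligned_unit_chords():
    grid = ip.homogeneous_phantom(ip.TissueLabel.WHITE_MATTER, (10, 5, 5), 1.0)
    chords = ip.traverse_voxels((-0.49, 2.0, 2.0), (1.0, 0.0, 0.0), grid, max_length_mm=4.99)
    assert [c[0] for c in chords] == [(i, 2, 2) for i in range(5)]
    lengths = np.array([c[1] for c in chords])
    assert lengths[1:-1] == pytest.approx(1.0)
    assert lengths.sum() == pytest.approx(4.99)


def test_traverse_diagonal_single_cube():
    grid = ip.homogeneous_phantom(ip.TissueLabel.WHITE_MATTER, (1, 1, 1), 1.0)
    d = np.ones(3) / np.sqrt(3.0)
    chords = ip.traverse_voxels((-0.499, -0.499, -0.499), d, grid)
    assert len(chords) == 1
    assert chords[0][1] == pytest.approx(np.sqrt(3.0), rel=1e-2)


def test_traverse_chord_sums_equal_ray_length():
    """Chord lengths must sum to the exact in-grid path length (box-clip oracle)."""
    grid = ip.homogeneous_phantom(ip.TissueLabel.WHITE_MATTER, (20, 17, 23), 1.0)
    lo, hi = grid.world_bounds
    rng = np.random.default_rng(5)
    for _ in range(200):
        origin = lo + rng.random(3) * (hi - lo)
        direction = ip.sample_isotropic_directions(1, rng)[0]
        # independent oracle: distance from origin to the grid box along direction
        with np.errstate(divide="ignore"):
            t_hi = (hi - origin) / direction
            t_lo = (lo - origin) / direction
        t_exit = np.min(np.maximum(t_hi, t_lo))
        chords = ip.traverse_voxels(origin, direction, grid)
        assert sum(c[1] for c in chords) == pytest.approx(t_exit, abs=1e-9)
    with pytest.raises(OutOfGridError):
        ip.traverse_voxels(hi + 1.0, (1.0, 0.0, 0.0), grid)


# --------------------------------------------------------------- conservation


def test_weight_conservation_exact_without_roulette(table, enhancing_grid_small):
    res = ip.run_point_source(
        enhancing_grid_small, table, (19.5, 19.5, 19.5),
        n_packets=20_000, seed=3, use_roulette=False,
    )
    assert res.conservation_defect < 1e-9


def test_weight_conservation_near_exact_with_roulette(table, enhancing_grid_small):
    """Roulette is unbiased: the defect stays at the scale of the threshold weight."""
    res = ip.run_point_source(
        enhancing_grid_small, table, (19.5, 19.5, 19.5), n_packets=20_000, seed=3
    )
    assert res.conservation_defect < 1e-3


# ------------------------------------------------------------ reproducibility


def test_bit_reproducibility_under_fixed_seed(table, enhancing_grid_small):
    traj = ip.FiberTrajectory(entry=(19.5, 19.5, 2.0), target=(19.5, 19.5, 32.0),
                              diffuser_length_mm=20.0)
    src = ip.build_line_source(traj)
    r1 = ip.run_transport(enhancing_grid_small, table, src, n_packets=5000, seed=11)
    r2 = ip.run_transport(enhancing_grid_small, table, src, n_packets=5000, seed=11)
    assert np.array_equal(r1.fluence_rate, r2.fluence_rate)
    assert np.array_equal(r1.deposited_weight, r2.deposited_weight)
    assert r1.escaped_weight == r2.escaped_weight
    r3 = ip.run_transport(enhancing_grid_small, table, src, n_packets=5000, seed=12)
    assert not np.array_equal(r1.fluence_rate, r3.fluence_rate)


# ------------------------------------------------------------------ symmetry


def test_mirror_symmetry_about_source_plane(table):
    """A centered point source illuminates mirrored half-grids equally."""
    grid = ip.homogeneous_phantom(ip.TissueLabel.ENHANCING, (41, 41, 41), 1.0)
    totals = []
    for seed in (1, 2, 3):
        res = ip.run_point_source(grid, table, (20.0, 20.0, 20.0),
                                  n_packets=30_000, seed=seed)
        totals.append((res.fluence_rate[:20].sum(), res.fluence_rate[21:].sum()))
    totals = np.array(totals)
    diffs = totals[:, 0] - totals[:, 1]
    scale = totals.mean()
    sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < max(3.0 * sem, 0.01 * scale)


# --------------------------------------------------------- estimator details


def test_absorption_tally_zero_where_no_absorber(absorber_table):
    """mu_t = 0 voxels transmit packets freely and collect no deposition."""
    labels = np.ones((41, 41, 41), dtype=np.int16)
    labels[:, :, 25:28] = 2  # vacuum slab
    vac_table = TissueTable(
        {0: OpticalProperties(0, 0, 0, 1.0), 1: OpticalProperties(0.5, 0.0, 0.0),
         2: OpticalProperties(0.0, 0.0, 0.0)},
        version="test-vacuum",
    )
    grid = ip.VoxelGrid.from_spacing(labels, 1.0)
    res = ip.run_point_source(grid, vac_table, (20.0, 20.0, 20.0),
                              n_packets=20_000, seed=2, use_roulette=False)
    assert res.deposited_weight[:, :, 25:28].sum() == 0.0
    assert res.fluence_rate[:, :, 25:28].max() > 0.0  # light still crosses
    assert res.fluence_rate[:, :, 30].max() > 0.0  # and reaches the far side
    assert res.conservation_defect < 1e-9


def test_fluence_scales_linearly_with_power(table, enhancing_grid_small):
    traj = ip.FiberTrajectory(entry=(19.5, 19.5, 2.0), target=(19.5, 19.5, 32.0),
                              diffuser_length_mm=20.0)
    lo = ip.build_line_source(traj, linear_power_mw_per_cm=100.0)
    hi = ip.build_line_source(traj, linear_power_mw_per_cm=200.0)
    r_lo = ip.run_transport(enhancing_grid_small, table, lo, n_packets=3000, seed=4)
    r_hi = ip.run_transport(enhancing_grid_small, table, hi, n_packets=3000, seed=4)
    np.testing.assert_allclose(r_hi.fluence_rate, 2.0 * r_lo.fluence_rate, rtol=1e-12)


# ------------------------------------------------------------ error handling


def test_source_outside_grid_rejected(table):
    grid = ip.homogeneous_phantom(ip.TissueLabel.ENHANCING, (30, 30, 30), 1.0)
    traj = ip.FiberTrajectory(entry=(14.5, 14.5, -40.0), target=(14.5, 14.5, 20.0),
                              diffuser_length_mm=50.0)
    src = ip.build_line_source(traj)
    with pytest.raises(GeometryError):
        ip.run_transport(grid, table, src, n_packets=10, seed=0)
    with pytest.raises(GeometryError):
        ip.run_point_source(grid, table, (100.0, 0.0, 0.0), n_packets=10, seed=0)


def test_unregistered_label_rejected(table):
    labels = np.full((10, 10, 10), 42, dtype=np.int16)
    grid = ip.VoxelGrid.from_spacing(labels, 1.0)
    with pytest.raises(UnknownTissueError):
        ip.run_point_source(grid, table, (4.5, 4.5, 4.5), n_packets=10, seed=0)
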