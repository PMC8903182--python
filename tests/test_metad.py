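"""Metadynamics post-processing: HILLS I/O, bias, FES, barriers, binding."""

import math

import numpy as np
import pytest
from scipy.ndimage import label

from csarpipe import fixtures
from csarpipe.constants import C_STANDARD_PER_NM3, R_KJ
from csarpipe.metad import (
    FreeEnergySurface,
    FunnelSpec,
    HillsFile,
    HillsFormatError,
    barrier_height,
    bias_potential,
    binding_free_energy,
    fes_from_hills,
    read_hills,
    write_hills,
)
from csarpipe.synthetic import gen_hills

RT = R_KJ * 277.0


def _hills(centers, heights, sigma=0.1, bias_factor=5.0, period=None):
    n = len(centers)
    return HillsFile(
        cv_names=["cv"],
        times=np.arange(n, dtype=float) * 0.5,
        centers=np.asarray(centers, dtype=float)[:, None],
        sigmas=np.full((n, 1), sigma),
        heights=np.asarray(heights, dtype=float),
        bias_factor=bias_factor,
        periods=[period],
    )


# ---------------------------------------------------------------------------
# HILLS I/O
# ---------------------------------------------------------------------------


def test_write_read_round_trip(tmp_path):
    hills = _hills([0.1, 0.5, -0.3], [1.0, 0.8, 0.6], period=2 * math.pi)
    path = tmp_path / "HILLS"
    write_hills(hills, path)
    back = read_hills(path)
    np.testing.assert_allclose(back.centers, hills.centers, atol=1e-6)
    np.testing.assert_allclose(back.heights, hills.heights, atol=1e-6)
    assert back.bias_factor == 5.0
    assert back.periods[0] == pytest.approx(2 * math.pi)


def test_empty_body_gives_zero_records(tmp_path):
    path = tmp_path / "HILLS"
    path.write_text("#! FIELDS time cv sigma_cv height biasf\n")
    assert read_hills(path).n_hills == 0


def test_multi_walker_files_merge_time_sorted(tmp_path):
    paths = []
    for w in range(10):
        hills = _hills([0.1 * w, 0.1 * w + 0.05], [1.0, 0.9])
        p = tmp_path / f"HILLS.{w}"
        write_hills(hills, p)
        paths.append(p)
    merged = read_hills(paths)
    assert merged.n_hills == 20  # sum over walkers
    assert np.all(np.diff(merged.times) >= 0)
    assert set(merged.walkers.tolist()) == set(range(10))


def test_decreasing_times_within_walker_rejected(tmp_path):
    path = tmp_path / "HILLS"
    path.write_text(
        "#! FIELDS time cv sigma_cv height biasf\n"
        "1.0 0.0 0.1 1.0 5\n"
        "0.5 0.1 0.1 1.0 5\n"
    )
    with pytest.raises(HillsFormatError, match="non-decreasing"):
        read_hills(path)


def test_inconsistent_column_count_names_line(tmp_path):
    path = tmp_path / "HILLS"
    path.write_text(
        "#! FIELDS time cv sigma_cv height biasf\n"
        "0.5 0.0 0.1 1.0 5\n"
        "1.0 0.1 0.1 1.0\n"
    )
    with pytest.raises(HillsFormatError, match="line 3"):
        read_hills(path)


# ---------------------------------------------------------------------------
# bias potential
# ---------------------------------------------------------------------------


def test_single_hill_evaluates_to_height_at_center():
    hills = _hills([0.3], [2.5])
    assert bias_potential(hills, 0.3) == pytest.approx(2.5)
    assert bias_potential(hills, 5.0) < 1e-10  # far away


def test_two_overlapping_hills_sum_checked_by_hand():
    hills = _hills([0.0, 0.1], [1.0, 2.0], sigma=0.1)
    expected = 1.0 * math.exp(-0.05**2 / 0.02) + 2.0 * math.exp(-0.05**2 / 0.02)
    assert bias_potential(hills, 0.05) == pytest.approx(expected, rel=1e-12)


def test_bias_is_additive_in_hills():
    a = _hills([0.0], [1.0])
    b = _hills([0.4], [0.7])
    both = _hills([0.0, 0.4], [1.0, 0.7])
    for s in (-0.2, 0.0, 0.3, 0.8):
        assert bias_potential(both, s) == pytest.approx(
            bias_potential(a, s) + bias_potential(b, s), rel=1e-12
        )


def test_periodic_wrapping():
    hills = _hills([math.pi - 0.05], [1.0], sigma=0.1, period=2 * math.pi)
    near = bias_potential(hills, -math.pi + 0.05)  # 0.1 away through the seam
    assert near == pytest.approx(math.exp(-0.1**2 / 0.02), rel=1e-9)


# ---------------------------------------------------------------------------
# FES reconstruction
# ---------------------------------------------------------------------------


def test_rescale_factor_is_g_over_g_minus_one():
    hills = _hills([0.0], [1.0], bias_factor=5.0)
    grid = np.linspace(-1, 1, 201)
    fes = fes_from_hills(hills, [grid])
    # single negative-definite bias: F range = 1.25 x hill height
    assert fes.F.max() - fes.F.min() == pytest.approx(1.25, rel=1e-6)
    assert fes.F.min() == 0.0


def test_zero_hills_give_flat_zero_surface():
    hills = _hills([], [])
    fes = fes_from_hills(hills, [np.linspace(-1, 1, 11)])
    np.testing.assert_array_equal(fes.F, np.zeros(11))


def test_round_trip_recovers_model_within_tolerance():
    # short deposition: coarse agreement; the long-run acceptance test
    # tightens this to 1 kJ/mol RMS
    spec = fixtures.torsion_double_well_hills_spec(duration_ns=3.0)
    hills, _ = gen_hills(spec, seed=1)
    fes = fes_from_hills(hills, [spec.cv_grid])
    model = spec.fes_values - spec.fes_values.min()
    err = fes.F - model
    rms = float(np.sqrt(np.mean((err - err.mean()) ** 2)))
    assert rms < 4.0


def test_convergence_series_emitted_each_interval():
    spec = fixtures.torsion_double_well_hills_spec(duration_ns=0.2)
    hills, _ = gen_hills(spec, seed=1)
    fes, series = fes_from_hills(hills, [spec.cv_grid], convergence_interval_ps=50.0)
    assert len(series) == 3  # checkpoints at 50, 100, 150 ps within 200 ps
    assert all(f.shape == fes.F.shape for _, f in series)


# ---------------------------------------------------------------------------
# barriers
# ---------------------------------------------------------------------------


def test_symmetric_double_well_barrier_exact():
    grid = np.linspace(-math.pi, math.pi, 721)
    f = 40.0 * (1 - np.cos(2 * grid))
    fes = FreeEnergySurface([grid], f, [True])
    assert barrier_height(fes, (-0.3, 0.3), (2.8, math.pi)) == pytest.approx(80.0)


def test_window_without_local_minimum_rejected():
    grid = np.linspace(0.0, 1.0, 101)
    fes = FreeEnergySurface([grid], 10.0 * grid, [False])  # monotone ramp
    with pytest.raises(ValueError, match="no local minimum"):
        barrier_height(fes, (0.4, 0.6), (0.0, 0.05))


def _brute_force_saddle(F, a_idx, b_idx):
    """Threshold flood-fill oracle: lowest level connecting the two minima."""
    levels = np.unique(F)
    for lev in levels:
        mask = F <= lev
        lab, _ = label(mask)  # 4-connectivity
        if lab[a_idx] and lab[a_idx] == lab[b_idx]:
            return lev
    raise AssertionError("never connected")


def test_2d_saddle_matches_flood_fill_oracle():
    rng = np.random.default_rng(77)
    x = np.linspace(-2, 2, 41)
    y = np.linspace(-2, 2, 41)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    # two basins at (+-1, 0) with a saddle ridge along x=0 plus rough noise
    F = 10 * (xx**2 - 1) ** 2 + 8 * yy**2 + rng.normal(0, 0.4, xx.shape)
    F -= F.min()
    fes = FreeEnergySurface([x, y], F, [False, False])
    a = np.unravel_index(np.argmin(np.where(xx < 0, F, np.inf)), F.shape)
    b = np.unravel_index(np.argmin(np.where(xx > 0, F, np.inf)), F.shape)
    expected = _brute_force_saddle(F, a, b) - F[a]
    got = barrier_height(
        fes,
        ((x[a[0]] - 0.01, x[a[0]] + 0.01), (y[a[1]] - 0.01, y[a[1]] + 0.01)),
        ((x[b[0]] - 0.01, x[b[0]] + 0.01), (y[b[1]] - 0.01, y[b[1]] + 0.01)),
    )
    assert got == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# binding free energy
# ---------------------------------------------------------------------------


def test_flat_profile_gives_pure_volume_term():
    z = np.linspace(0.0, 4.0, 801)
    fes = FreeEnergySurface([z], np.zeros_like(z), [False])
    funnel = FunnelSpec(radius=0.5, bound_window=(0.1, 0.5))
    res = binding_free_energy(fes, funnel, 277.0)
    # K = L_b/L_u; dG = -RT ln(K * pi r^2 L_u c0 NA) = -RT ln(L_b pi r^2 c0 NA)
    z_b = z[(z >= 0.1) & (z <= 0.5)]
    l_b = z_b[-1] - z_b[0]
    expected = -RT * math.log(l_b * math.pi * 0.25 * C_STANDARD_PER_NM3)
    assert res.dG_bind == pytest.approx(expected, rel=1e-9)
    assert res.plateau_flat


def test_release_rotamer_fixture_recovers_target():
    fes, funnel = fixtures.binding_profile_fixture(14.5, desorption_barrier=3.0)
    res = binding_free_energy(fes, funnel, 277.0)
    assert res.dG_bind == pytest.approx(14.5, abs=0.5)
    assert res.desorption_barrier == pytest.approx(3.0, abs=0.1)


def test_cfr_fixture_recovers_minus_20_5():
    fes, funnel = fixtures.binding_profile_fixture(-20.5)
    res = binding_free_energy(fes, funnel, 277.0)
    assert res.dG_bind == pytest.approx(-20.5, abs=0.5)


def test_result_invariant_to_fes_zero_offset():
    fes, funnel = fixtures.binding_profile_fixture(14.5)
    shifted = FreeEnergySurface([fes.grids[0]], fes.F + 37.0, fes.periodic)
    a = binding_free_energy(fes, funnel, 277.0)
    b = binding_free_energy(shifted, funnel, 277.0)
    assert b.dG_bind == pytest.approx(a.dG_bind, abs=1e-9)


def test_deepening_the_well_shifts_binding_additively():
    fes, funnel = fixtures.binding_profile_fixture(14.5)
    z = fes.grids[0]
    delta = 35.0
    f2 = fes.F.copy()
    bound = (z >= funnel.bound_window[0] - 0.02) & (z <= funnel.bound_window[1] + 0.02)
    f2[bound] -= delta
    res2 = binding_free_energy(FreeEnergySurface([z], f2 - f2.min(), fes.periodic),
                               funnel, 277.0)
    assert res2.dG_bind == pytest.approx(14.5 - delta, abs=0.5)


def test_barrier_at_least_bound_depth_when_attractive():
    fes, funnel = fixtures.binding_profile_fixture(-20.5, desorption_barrier=3.0)
    res = binding_free_energy(fes, funnel, 277.0)
    assert res.desorption_barrier >= -res.dG_bind - 5.0  # depth-dominated exit
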