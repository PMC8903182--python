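"""Generators: stationary laws, switching rates, closed-form recoveries."""

import numpy as np
import pytest

from csarpipe import fixtures
from csarpipe.constants import R_KJ
from csarpipe.rotamers import N_STATES
from csarpipe.synthetic import (
    CNTCurveSpec,
    RegimeSpec,
    TorsionPES,
    distribution_with_background,
    double_well_pes,
    gen_cnt_curve,
    gen_hills,
    gen_langevin_torsion,
    gen_rotamer_chain,
    gen_velocities,
)
from csarpipe.trajectory import classify_trajectory


# ---------------------------------------------------------------------------
# regime spec / Markov chain
# ---------------------------------------------------------------------------


def test_unknown_rotamer_name_rejected_with_offender():
    with pytest.raises(ValueError, match="TTQTT"):
        distribution_with_background({"TTQTT": 0.3})


def test_background_distribution_sums_to_one():
    dist = distribution_with_background({"TTPTT": 0.337, "NTPTN": 0.0045})
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
    assert len(dist) == N_STATES


def test_cis_spike_weight_validation():
    dist = distribution_with_background({})
    with pytest.raises(ValueError, match="cis_spike_weight"):
        RegimeSpec("surface", dist, 1.0, cis_spike_weight=1.0)


def test_chain_is_bit_reproducible():
    spec = fixtures.surface_regime_spec()
    a = gen_rotamer_chain(spec, 5000, 0.01, seed=7)
    b = gen_rotamer_chain(spec, 5000, 0.01, seed=7)
    np.testing.assert_array_equal(a.angles, b.angles)


def test_uniform_stationary_law_max_population():
    uniform = {w: 1.0 / N_STATES for w in distribution_with_background({})}
    spec = RegimeSpec("bulk", uniform, mean_switch_rate=2.0, temperature=277.0)
    traj = gen_rotamer_chain(spec, 200_000, 0.1, seed=3)
    rt = classify_trajectory(traj)
    counts = np.bincount(rt.states - 1, minlength=N_STATES) / rt.n_frames
    # per-state SE with the effective sample size set by the per-frame
    # resample probability (~0.2 at rate 2/ps, dt 0.1 ps); the max over 243
    # estimates sits ~sqrt(2 ln 243) ~ 3.3 SE above the mean
    n_eff = rt.n_frames * 0.2
    se = np.sqrt((1 / N_STATES) * (1 - 1 / N_STATES) / n_eff)
    assert counts.max() < 1.0 / N_STATES + 5 * se
    assert abs(counts.mean() - 1.0 / N_STATES) < 1e-12


def test_two_state_switch_rate_matches_request():
    dist = dict.fromkeys(distribution_with_background({}), 0.0)
    dist["TTTTT"] = 0.5
    dist["NNNNN"] = 0.5
    spec = RegimeSpec("bulk", dist, mean_switch_rate=0.5, temperature=277.0)
    traj = gen_rotamer_chain(spec, 200_000, 0.1, seed=5)
    rt = classify_trajectory(traj)
    n_trans = int(np.sum(rt.states[1:] != rt.states[:-1]))
    rate = n_trans / (rt.times[-1] - rt.times[0])
    assert rate == pytest.approx(0.5, rel=0.05)


def test_bulk_chain_converges_to_stationary_law(bulk_chain):
    # TV noise floor: 243 states, effective sample size n*q with per-frame
    # leave probability q ~ 0.11 -> expected TV ~ 0.035 at 2e5 frames; the
    # bound below is ~2x that floor, and the shorter run must be worse
    rt = classify_trajectory(bulk_chain)
    pi = fixtures.bulk_regime_spec().stationary_vector()
    emp = np.bincount(rt.states - 1, minlength=N_STATES) / rt.n_frames
    tv = 0.5 * np.abs(emp - pi).sum()
    assert tv < 0.07
    short = np.bincount(rt.states[:20_000] - 1, minlength=N_STATES) / 20_000
    tv_short = 0.5 * np.abs(short - pi).sum()
    assert tv < tv_short


def test_surface_cis_spikes_present_but_classification_preserved(surface_chain):
    ang = surface_chain.angles
    # gauche torsions: a clear excess of emissions within 10 degrees of cis
    gauche = np.abs(ang) < 120.0
    near_cis = np.abs(ang) < 10.0
    frac = near_cis[gauche].mean()
    assert frac > 0.05  # spike mass clearly visible
    # spikes never flip the letter: P-side emissions stay positive
    rt = classify_trajectory(surface_chain)
    pi = fixtures.surface_regime_spec().stationary_vector()
    emp = np.bincount(rt.states - 1, minlength=N_STATES) / rt.n_frames
    assert 0.5 * np.abs(emp - pi).sum() < 0.07


def test_unresolvable_switch_rate_rejected():
    spec = fixtures.surface_regime_spec()
    with pytest.raises(ValueError, match="smaller dt"):
        gen_rotamer_chain(spec, 100, dt=1.0, seed=0)  # 10/ps at 1 ps frames


# ---------------------------------------------------------------------------
# Langevin torsional dynamics
# ---------------------------------------------------------------------------


def test_langevin_flat_potential_uniform_histogram():
    pes = TorsionPES(terms=[], barrier_height=0.0)
    traj = gen_langevin_torsion(pes, 277.0, 200_000, 0.05, seed=2, diffusion=2000.0)
    hist, _ = np.histogram(traj.angles[:, 0], bins=12, range=(-180, 180))
    frac = hist / hist.sum()
    assert np.all(np.abs(frac - 1 / 12) < 0.02)


def test_langevin_well_matches_boltzmann_variance():
    # V = A(1 - cos 2theta): harmonic with k = 4A rad^-2 near 0, with an
    # anharmonic widening the exact Boltzmann oracle accounts for
    amp = 40.0
    pes = double_well_pes(2 * amp)
    # dt must resolve the well's relaxation rate a = D*beta*k ~ 42/ps:
    # Euler-Maruyama inflates the stationary variance by 1/(1 - a*dt/2)
    traj = gen_langevin_torsion(pes, 277.0, 400_000, 0.0005, seed=3, diffusion=2000.0)
    theta_rad = np.radians(traj.angles[:, 0])
    grid = np.linspace(-np.pi / 2, np.pi / 2, 4001)
    weight = np.exp(-pes.energy(np.degrees(grid)) / (R_KJ * 277.0))
    exact = np.trapezoid(grid**2 * weight, grid) / np.trapezoid(weight, grid)
    assert theta_rad.var() == pytest.approx(exact, rel=0.05)
    # the harmonic (equipartition) value RT/k is the small-noise limit
    assert exact == pytest.approx(R_KJ * 277.0 / (4.0 * amp), rel=0.2)


def test_langevin_80kJ_barrier_has_no_crossings():
    # Kramers rate ~ exp(-80/RT) ~ 1e-15/ps: no well-to-well events at this scale
    traj = gen_langevin_torsion(
        double_well_pes(80.0), 277.0, 1_000_000, 0.005, seed=4, diffusion=2000.0
    )
    assert np.all(np.abs(traj.angles[:, 0]) < 90.0)  # never reaches the saddle


def test_langevin_step_size_guard():
    with pytest.raises(ValueError, match="RMS angular step"):
        gen_langevin_torsion(double_well_pes(10.0), 277.0, 100, 1.0, seed=0)


# ---------------------------------------------------------------------------
# CNT curves
# ---------------------------------------------------------------------------


def test_cnt_curve_noise_free_matches_closed_form_pointwise():
    spec = CNTCurveSpec(delta_mu=1.0, b=6.0, noise_sd=0.0, n_min=2, n_max=50)
    curve = gen_cnt_curve(spec, seed=0)
    n = curve.N.astype(float)
    np.testing.assert_allclose(curve.dG, -1.0 * n + 6.0 * n ** (2 / 3), rtol=1e-12)


def test_cnt_curve_same_seed_identical():
    spec = CNTCurveSpec(noise_sd=1.5)
    a = gen_cnt_curve(spec, seed=9)
    b = gen_cnt_curve(spec, seed=9)
    np.testing.assert_array_equal(a.dG, b.dG)


def test_saturating_curve_monotonically_approaches_plateau():
    spec = CNTCurveSpec(form="saturating", g_slab=-100.0, plateau_onset=20.0,
                        noise_sd=0.0)
    curve = gen_cnt_curve(spec, seed=0)
    gaps = np.abs(curve.dG - (-100.0))
    assert np.all(np.diff(gaps) < 0)
    assert curve.slab_reference == -100.0


def test_cnt_range_validation():
    with pytest.raises(ValueError, match="N range"):
        CNTCurveSpec(n_min=1, n_max=50)


# ---------------------------------------------------------------------------
# hills
# ---------------------------------------------------------------------------


def test_zero_duration_run_gives_empty_hill_list():
    spec = fixtures.torsion_double_well_hills_spec(duration_ns=0.0)
    hills, cv = gen_hills(spec, seed=0)
    assert hills.n_hills == 0
    assert cv.shape[0] == 0


def test_first_hill_height_follows_protocol_rule():
    # initial height (277/T) x 1.0 kcal/mol: at 277 K the first deposits are
    # exactly 1 kcal/mol = 4.184 kJ/mol
    spec = fixtures.torsion_double_well_hills_spec(duration_ns=0.01)
    hills, _ = gen_hills(spec, seed=1)
    assert hills.heights[0] == pytest.approx(4.184, abs=1e-12)
    # at 554 K the rule halves the height
    spec2 = fixtures.torsion_double_well_hills_spec(duration_ns=0.01)
    spec2.temperature = 554.0
    hills2, _ = gen_hills(spec2, seed=1)
    assert hills2.heights[0] == pytest.approx(2.092, abs=1e-12)


def test_hills_reproducible_and_heights_decay():
    spec = fixtures.torsion_double_well_hills_spec(duration_ns=1.0)
    h1, _ = gen_hills(spec, seed=2)
    h2, _ = gen_hills(spec, seed=2)
    np.testing.assert_array_equal(h1.centers, h2.centers)
    # well-tempered decay: late hills much smaller than early ones
    assert h1.heights[-200:].mean() < 0.5 * h1.heights[:200].mean()


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------


def test_kinetic_temperature_within_one_percent():
    vt = gen_velocities("free_diffusive", 24, 277.0, seed=6, n_frames=100_000,
                        dt=0.004, tau=0.1)
    kt_mech = R_KJ * 277.0 / 0.01
    ke_ratio = float((vt.velocities**2).mean() * vt.masses[0] / kt_mech)
    assert ke_ratio == pytest.approx(1.0, abs=0.01)


def test_torsion_pes_barrier_consistency_check():
    with pytest.raises(ValueError, match="inconsistent"):
        TorsionPES(terms=[(40.0, 2, 180.0)], barrier_height=100.0)
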