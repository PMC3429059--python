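"""Stochastic engine: exact SSA validation, QSSA, hybrid drive, ensembles."""

import numpy as np
import pytest
from scipy import stats

from yeastgates.cells import InputSignal, ReporterCell
from yeastgates.deterministic import Trajectory, steady_state
from yeastgates.stochastic import (
    FullReporterModel,
    GFP_THRESHOLD_COUNT,
    Reaction,
    StochasticModel,
    coefficient_of_variation,
    gillespie_direct,
    hybrid_drive,
    run_ensemble,
    ste2_qssa,
)
from yeastgates.units import NM, concentration_to_count


def test_zero_propensity_freezes_state():
    model = StochasticModel(["x"], [Reaction(0.0, ("x",), ())],
                            initial_counts={"x": 7})
    out = gillespie_direct(model, 600.0, seed=1)
    assert np.all(out[:, 0] == 7)


def test_pure_birth_is_poisson():
    lam, t_end = 5.0, 200.0
    model = StochasticModel(["x"], [Reaction(lam, (), ("x",))])
    ens = run_ensemble(model, 10_000, t_end / 3600.0, seed=11,
                       report_dt_s=t_end)
    x = ens.counts[:, -1, 0]
    assert x.mean() == pytest.approx(lam * t_end, rel=0.05)
    assert x.var(ddof=1) == pytest.approx(lam * t_end, rel=0.05)


def test_pure_death_mean_decays_exponentially():
    k, n0, t_end = 0.01, 500, 100.0
    model = StochasticModel(["x"], [Reaction(k, ("x",), ())],
                            initial_counts={"x": n0})
    ens = run_ensemble(model, 4000, t_end / 3600.0, seed=12, report_dt_s=t_end)
    assert ens.counts[:, -1, 0].mean() == pytest.approx(
        n0 * np.exp(-k * t_end), rel=0.02)


def test_birth_death_stationary_distribution_is_poisson():
    """Chi-square goodness of fit at the 1 % level, 1e4 samples."""
    lam, k = 50.0, 1.0
    model = StochasticModel(
        ["x"],
        [Reaction(lam, (), ("x",)), Reaction(k, ("x",), ())],
        initial_counts={"x": 50},
    )
    ens = run_ensemble(model, 10_000, 10.0 / 3600.0, seed=13, report_dt_s=10.0)
    x = ens.counts[:, -1, 0].astype(int)
    lo, hi = 30, 70  # ~3 sd window; tails pooled into the end bins
    values = np.arange(lo, hi + 1)
    obs = np.array([np.sum(x == v) for v in values], dtype=float)
    obs[0] += np.sum(x < lo)
    obs[-1] += np.sum(x > hi)
    pois = stats.poisson(lam)
    exp = pois.pmf(values)
    exp[0] = pois.cdf(lo)
    exp[-1] = pois.sf(hi - 1)
    exp *= len(x)
    chi2, p = stats.chisquare(obs, exp)
    assert p > 0.01


def test_ste2_qssa_limits_and_oracle():
    assert ste2_qssa(0.0) == 0
    # saturation plateau: synthesis/degradation-limited
    p = ReporterCell().params
    plateau = concentration_to_count(
        p["v_Ste2_production"] / p["k5"] / NM, 29.0)
    assert ste2_qssa(1e-3) == pytest.approx(plateau, rel=1e-3)
    # independent oracle: deterministic steady state at 5 nM alpha
    ss = steady_state(ReporterCell(), InputSignal(alpha=5.0 * NM))
    want = concentration_to_count(ss["Ste2_Ph"] / NM, 29.0)
    assert abs(ste2_qssa(5.0 * NM) - want) <= 1
    with pytest.raises(ValueError):
        ste2_qssa(-1.0)


def _toy_trajectory(times, counts_nuclear):
    # concentrations (mmol/ml) that convert back to the given nuclear counts
    per_count_nm = 1.0 / (4.06 * 0.6022)
    vals = np.asarray(counts_nuclear, float)[:, None] * per_count_nm * NM
    return Trajectory(times, ["reporter.Fus3ppn"], vals)


def test_hybrid_drive_constant_input_gives_zero_propensity():
    t = np.arange(0.0, 601.0, 60.0)
    d = hybrid_drive(_toy_trajectory(t, np.full(len(t), 500.0)))
    assert all(d.propensity(x) == pytest.approx(0.0, abs=1e-9) for x in t)


def test_hybrid_drive_linear_ramp_recovers_slope():
    t = np.arange(0.0, 1201.0, 60.0)
    slope = 0.8  # molecules/s
    d = hybrid_drive(_toy_trajectory(t, 10.0 + slope * t))
    mid = [d.propensity(x) for x in np.linspace(50, 1100, 20)]
    np.testing.assert_allclose(mid, slope, rtol=1e-6)


def test_hybrid_drive_identity_dead_time(identity_drive):
    """Nuclear Fus3-PP appears only after a few hundred seconds."""
    assert 250.0 <= identity_drive.t0_s <= 550.0
    for t in (0.0, 100.0, identity_drive.t0_s - 1.0):
        assert identity_drive.propensity(t) == 0.0
    assert identity_drive.propensity(identity_drive.t0_s + 600.0) > 0.0


def test_hybrid_drive_warns_when_clamping_is_substantial():
    t = np.arange(0.0, 1201.0, 60.0)
    wav = 200.0 + 150.0 * np.sin(t / 120.0)
    with pytest.warns(UserWarning, match="non-monotone"):
        hybrid_drive(_toy_trajectory(t, wav))


def test_hybrid_ensemble_mean_tracks_deterministic(
        identity_result, identity_hybrid_ensemble):
    ens = identity_hybrid_ensemble
    det = identity_result.trajectory.series_nm("reporter.mature_GFP") * 29 * 0.6022
    mean = ens.mean("mature_GFP")
    sem = ens.sd("mature_GFP") / np.sqrt(ens.n)
    sl = slice(30, 241)  # from 30 min on (earlier counts are ~zero for both)
    assert np.all(np.abs(mean[sl] - det[sl]) <= 3 * sem[sl] + 1.0)


def test_hybrid_fus3_is_poisson_counting_process(identity_hybrid_ensemble):
    ens = identity_hybrid_ensemble
    for h in (1.0, 2.0, 4.0):
        i = ens._tidx(h * 3600.0)
        mean = ens.mean("Fus3ppn")[i]
        cv = coefficient_of_variation(ens, "Fus3ppn", h)
        assert cv == pytest.approx(100.0 / np.sqrt(mean), rel=0.15)


def test_gfp_noise_decreases_with_time(identity_hybrid_ensemble):
    cvs = [coefficient_of_variation(identity_hybrid_ensemble, "mature_GFP", h)
           for h in (1.0, 2.0, 4.0)]
    assert cvs[0] > cvs[1] > cvs[2]


def test_full_model_mean_matches_deterministic_reporter():
    """Quasi-equilibrium full model stays on the deterministic trajectory."""
    alpha_nm = 2.5
    ens = run_ensemble(FullReporterModel(alpha_nm), 40, 1.0, seed=3)
    ss = steady_state(ReporterCell(), InputSignal(alpha=alpha_nm * NM))
    det_ppn = concentration_to_count(ss["Fus3ppn"] / NM, 4.06)
    i = ens._tidx(3600.0)
    # Fus3 pathway equilibrates within minutes; compare at 1 h
    assert ens.mean("Fus3ppn")[i] == pytest.approx(det_ppn, rel=0.05)
    assert coefficient_of_variation(ens, "mature_GFP", 1.0) > 0


def test_cv_definition_zero_mean_and_reproducibility():
    model = StochasticModel(["x"], [Reaction(0.0, (), ("x",))])
    ens = run_ensemble(model, 10, 0.01, seed=5, report_dt_s=36.0)
    assert coefficient_of_variation(ens, "x", 0.01) == 0.0
    with pytest.raises(ValueError):
        run_ensemble(model, 1, 0.01, seed=5)
    lam_model = StochasticModel(["x"], [Reaction(1.0, (), ("x",))])
    e1 = run_ensemble(lam_model, 5, 0.05, seed=42, report_dt_s=60.0)
    e2 = run_ensemble(lam_model, 5, 0.05, seed=42, report_dt_s=60.0)
    np.testing.assert_array_equal(e1.counts, e2.counts)


def test_frac_above_threshold(identity_hybrid_ensemble):
    ens = identity_hybrid_ensemble
    f = ens.frac_above("mature_GFP", GFP_THRESHOLD_COUNT)
    assert f[0] == 0.0
    assert np.all((0.0 <= f) & (f <= 1.0))
    # mature GFP never decreases, so positives can never revert
    assert np.all(np.diff(f) >= 0.0)
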