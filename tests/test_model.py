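"""Piecewise psychometric function, likelihood, hierarchical fit, predictions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import vascat as vc
from vascat.model import DegenerateDataError, PARAM_NAMES


@pytest.mark.parametrize("params,step,expected", [
    (dict(lower=0, upper=100, crossover=5, slope=25), 5, 50.0),
    (dict(lower=0, upper=100, crossover=5, slope=25), 9, 100.0),
    (dict(lower=10, upper=90, crossover=5, slope=10), 7, 70.0),
    (dict(lower=10, upper=90, crossover=5, slope=10), 1, 10.0),
])
def test_piecewise_mean_closed_form_points(params, step, expected):
    p = vc.PiecewiseParams(noise_sd=5.0, **params)
    assert vc.piecewise_mean(p, step) == pytest.approx(expected)


@settings(max_examples=200, derandomize=True)
@given(
    lower=st.floats(0, 49),
    spread=st.floats(1, 50),
    crossover=st.floats(1, 9),
    slope=st.floats(0.1, 100),
    step=st.floats(-5, 15),
)
def test_piecewise_mean_properties(lower, spread, crossover, slope, step):
    upper = lower + spread
    p = vc.PiecewiseParams(lower=lower, upper=upper, crossover=crossover,
                           slope=slope, noise_sd=1.0)
    val = float(vc.piecewise_mean(p, step))
    # matches the clip closed form
    expected = min(max((lower + upper) / 2 + slope * (step - crossover),
                       lower), upper)
    assert val == pytest.approx(expected, abs=1e-12)
    assert lower <= val <= upper
    # monotone non-decreasing
    assert float(vc.piecewise_mean(p, step + 0.5)) >= val - 1e-12
    # crossover midpoint
    assert float(vc.piecewise_mean(p, crossover)) == pytest.approx(
        (lower + upper) / 2)


def test_piecewise_mean_step_function_limit():
    """Once the slope exceeds (U-L)/2 per step, the values one step either
    side of the crossover saturate at the asymptotes."""
    lower, upper = 10.0, 90.0
    critical = (upper - lower) / 2
    p = vc.PiecewiseParams(lower=lower, upper=upper, crossover=5,
                           slope=critical + 1e-9, noise_sd=1.0)
    assert float(vc.piecewise_mean(p, 4)) == lower
    assert float(vc.piecewise_mean(p, 6)) == upper
    shallow = vc.PiecewiseParams(lower=lower, upper=upper, crossover=5,
                                 slope=critical * 0.9, noise_sd=1.0)
    assert float(vc.piecewise_mean(shallow, 4)) > lower


def test_params_validation_and_latent_round_trip():
    with pytest.raises(ValueError):
        vc.PiecewiseParams(lower=50, upper=40, crossover=5, slope=1,
                           noise_sd=1)
    with pytest.raises(ValueError):
        vc.PiecewiseParams(lower=0, upper=100, crossover=5, slope=-1,
                           noise_sd=1)
    with pytest.raises(ValueError):
        vc.PiecewiseParams(lower=0, upper=100, crossover=5, slope=1,
                           noise_sd=0)
    p = vc.PiecewiseParams(lower=5, upper=95, crossover=4.5, slope=12,
                           noise_sd=9)
    q = vc.PiecewiseParams.from_latent(p.to_latent())
    assert q.upper == pytest.approx(p.upper)
    assert q.junctures[0] == pytest.approx(4.5 - 90 / 24)


def test_log_likelihood_gaussian_mode_far_from_bounds():
    p = vc.PiecewiseParams(lower=20, upper=80, crossover=5, slope=5,
                           noise_sd=3.0)
    m = float(vc.piecewise_mean(p, 5))  # 50, bounds 16+ SDs away
    ll = vc.log_likelihood(p, [m], [5])
    assert ll == pytest.approx(-math.log(3.0 * math.sqrt(2 * math.pi)),
                               abs=1e-6)


def test_log_likelihood_penalizes_inflated_noise():
    p1 = vc.PiecewiseParams(lower=20, upper=80, crossover=5, slope=5,
                            noise_sd=4.0)
    p2 = vc.PiecewiseParams(lower=20, upper=80, crossover=5, slope=5,
                            noise_sd=8.0)
    m = float(vc.piecewise_mean(p1, 5))
    assert vc.log_likelihood(p2, [m], [5]) < vc.log_likelihood(p1, [m], [5])


def test_log_likelihood_matches_quadrature_oracle():
    rng = np.random.default_rng(0)
    p = vc.PiecewiseParams(lower=8, upper=92, crossover=4.6, slope=11,
                           noise_sd=9.0)
    steps = rng.integers(1, 10, 100).astype(float)
    m = np.asarray(vc.piecewise_mean(p, steps))
    ratings = np.clip(m + 9 * rng.standard_normal(100), 0, 100)
    ll = vc.log_likelihood(p, ratings, steps)
    oracle = 0.0
    for r, mm in zip(ratings, m):
        dens = lambda x, mm=mm: (math.exp(-0.5 * ((x - mm) / 9) ** 2)
                                 / (9 * math.sqrt(2 * math.pi)))
        norm, _ = integrate.quad(dens, 0, 100)
        oracle += math.log(dens(r) / norm)
    assert ll == pytest.approx(oracle, abs=1e-8)


def test_plain_normal_likelihood_agrees_away_from_bounds():
    p = vc.PiecewiseParams(lower=30, upper=70, crossover=5, slope=4,
                           noise_sd=2.0)
    steps = np.arange(1, 10, dtype=float)
    ratings = np.asarray(vc.piecewise_mean(p, steps)) + 1.0
    trunc = vc.log_likelihood(p, ratings, steps, likelihood="truncated")
    plain = vc.log_likelihood(p, ratings, steps, likelihood="normal")
    assert trunc == pytest.approx(plain, abs=1e-10)


def _manual_trials(rng, params_by_subject, n_reps=6):
    rows = []
    for sid, p in params_by_subject.items():
        for step in range(1, 10):
            m = float(vc.piecewise_mean(p, step))
            for rep in range(n_reps):
                r = float(np.clip(m + p.noise_sd * rng.standard_normal(),
                                  0, 100))
                rows.append({"subject_id": sid, "continuum_id": "c1",
                             "step": step, "session": 1, "rep": rep,
                             "endpoint_reversed": 0, "rating": r,
                             "rating_aligned": r})
    return pd.DataFrame(rows)


def test_fit_orders_subjects_by_true_noise():
    """Subjects simulated with trial SD 5 vs 25 around the same mean curve
    must come out ordered on the variability index."""
    rng = np.random.default_rng(12)
    base = dict(lower=5, upper=95, crossover=5, slope=12)
    params = {}
    for i in range(4):
        params[f"low{i}"] = vc.PiecewiseParams(noise_sd=5.0, **base)
        params[f"high{i}"] = vc.PiecewiseParams(noise_sd=25.0, **base)
    trials = _manual_trials(rng, params)
    spec = vc.HierarchicalSpec(chains=2, warmup=300, draws=300, seed=4)
    post = vc.fit_continuum(trials, spec)
    nu = post.subject_param_means()["nu"]
    low = nu[[s for s in nu.index if s.startswith("low")]]
    high = nu[[s for s in nu.index if s.startswith("high")]]
    assert low.max() < high.min()


def test_fit_rejects_degenerate_inputs():
    rng = np.random.default_rng(0)
    p = vc.PiecewiseParams(lower=5, upper=95, crossover=5, slope=12,
                           noise_sd=8)
    one = _manual_trials(rng, {"only": p})
    spec = vc.HierarchicalSpec(chains=1, warmup=10, draws=10, seed=0)
    with pytest.raises(DegenerateDataError, match="2 subjects"):
        vc.fit_continuum(one, spec)

    two = _manual_trials(rng, {"a": p, "b": p})
    flat = two.copy()
    flat["rating_aligned"] = 50.0
    with pytest.raises(DegenerateDataError, match="identical"):
        vc.fit_continuum(flat, spec)

    sparse = two[two["step"] <= 2]
    with pytest.raises(DegenerateDataError, match="distinct steps"):
        vc.fit_continuum(sparse, spec)

    multi = pd.concat([two, two.assign(continuum_id="c2")])
    with pytest.raises(ValueError, match="single continuum"):
        vc.fit_continuum(multi, spec)


def test_crossover_recovered_from_clean_data(small_graded_fit):
    """With informative graded data the population crossover posterior mean
    lands within a quarter step of the generating value."""
    pop, profiles, _, post = small_graded_fit
    cid = pop.continuum_ids()[0]
    true_c = np.mean([p.params[cid].crossover for p in profiles])
    est_c = float(post.fixed_effect_means()["c"])
    assert est_c == pytest.approx(true_c, abs=0.25)


def test_diagnostics_report_shapes_and_failure_modes(small_graded_fit,
                                                     small_graded_cohort):
    _, _, trials, post = small_graded_fit
    report = post.diagnostics()
    n_scalars = len(report.table)
    assert n_scalars == 10 + 15 * 5  # mu, tau, subject_theta
    assert report.rhat_available

    # threshold 1.0 fails everything
    strict = vc.diagnostics(post, rhat_threshold=1.0)
    assert not strict.passed

    # single chain: R-hat unavailable, reported as such
    spec1 = vc.HierarchicalSpec(chains=1, warmup=50, draws=50, seed=1)
    post1 = vc.fit_continuum(trials, spec1)
    rep1 = post1.diagnostics()
    assert not rep1.rhat_available
    assert np.isnan(rep1.max_rhat)


def test_diagnostics_flag_constant_chains():
    from conftest import make_fake_posterior
    theta = np.tile(np.array([5.0, 4.5, 5.0, 2.5, 2.3]), (6, 1))
    post = make_fake_posterior([f"S{i}" for i in range(6)], theta,
                               jitter=0.0)
    report = vc.diagnostics(post)
    assert not report.passed


def test_diagnostics_pass_on_well_identified_fit():
    """A cohort whose data pin all five parameters (steep slopes, low
    noise) mixes well enough to clear the strict R-hat/ESS bar."""
    pop = vc.PopulationConfig(
        n_subjects=12, n_continua=1, seed=3,
        pop_means={"L": 8.0, "U": 92.0, "c": 5.0, "eta": math.log(25.0),
                   "nu": math.log(5.0)},
        subject_sd=dict(L=3.0, delta=0.08, c=0.3, eta=0.3, nu=0.4),
        archetype_mix={"graded": 1.0})
    trials = vc.align_ratings(vc.generate_trials(vc.sample_population(pop),
                                                 pop))
    spec = vc.HierarchicalSpec(chains=4, warmup=600, draws=500, thin=4,
                               seed=9)
    report = vc.fit_continuum(trials, spec).diagnostics()
    assert report.passed, str(report)


def test_posterior_predict_contract(small_graded_fit):
    _, _, _, post = small_graded_fit
    sid = post.subject_ids[0]
    with pytest.raises(KeyError):
        vc.posterior_predict(post, "nobody", [1, 5, 9])
    pp = vc.posterior_predict(post, sid, np.linspace(1, 9, 17), seed=0)
    assert (np.diff(pp["mean_curve"]) >= -1e-9).all()  # monotone mean curve
    assert (pp["lower"] <= pp["predictive_mean"]).all()
    assert (pp["predictive_mean"] <= pp["upper"]).all()
    # interior predictive spread at least reflects the trial noise
    sigma = float(np.exp(post.fixed_effect_means()["nu"]))
    mid = pp.iloc[(pp["step"] - 5).abs().argsort().index[0]]
    assert mid["predictive_sd"] >= 0.8 * sigma


def test_posterior_predict_coverage(small_graded_fit):
    """Empirical coverage of the 90% predictive interval on held-out trials
    from the same generating parameters is close to nominal."""
    pop, profiles, _, post = small_graded_fit
    held_cfg = vc.PopulationConfig(**{**pop.__dict__,
                                      "n_reps_per_session": 10})
    held = vc.align_ratings(vc.generate_trials(profiles, held_cfg))
    hits, n = 0, 0
    for sid, g in held.groupby("subject_id"):
        pp = vc.posterior_predict(post, sid, np.arange(1, 10), seed=1)
        lo = dict(zip(pp["step"], pp["lower"]))
        hi = dict(zip(pp["step"], pp["upper"]))
        for s, r in zip(g["step"], g["rating_aligned"]):
            hits += int(lo[s] <= r <= hi[s])
            n += 1
    assert hits / n == pytest.approx(0.90, abs=0.03)


def test_pooled_fit_carries_item_intercepts():
    pop = vc.PopulationConfig(n_subjects=8, n_continua=3, seed=5,
                              archetype_mix={"graded": 1.0})
    trials = vc.align_ratings(vc.generate_trials(vc.sample_population(pop),
                                                 pop))
    spec = vc.HierarchicalSpec(chains=2, warmup=150, draws=150, seed=2)
    post = vc.fit_pooled(trials, spec)
    assert len(post.item_ids) == 3
    assert "item_theta" in post.idata.posterior
    assert post.idata.posterior["item_theta"].shape[-2:] == (3, 5)
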