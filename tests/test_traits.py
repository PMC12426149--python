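"""Index extraction, trait-consistency correlations, scoring, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vascat as vc
from conftest import make_fake_posterior


# ---------------------------------------------------------------------------
# critical_r and Fisher-z averaging
# ---------------------------------------------------------------------------

def test_critical_r_reference_values():
    assert round(vc.critical_r(68, 0.05), 3) == 0.239
    assert round(vc.critical_r(5, 0.05), 3) == 0.878
    assert vc.critical_r(10 ** 6) < 0.01


def test_critical_r_monotone_and_guarded():
    values = [vc.critical_r(n) for n in (5, 10, 30, 68, 200)]
    assert values == sorted(values, reverse=True)
    with pytest.raises(ValueError):
        vc.critical_r(2)


def test_critical_r_agrees_with_permutation_null():
    """The analytic two-tailed threshold matches the 95th percentile of
    |r| under a permutation null at n = 68."""
    rng = np.random.default_rng(0)
    n, n_perm = 68, 10 ** 5
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    xz = (x - x.mean()) / x.std(ddof=1)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perms]
    yz = (yp - yp.mean(axis=1, keepdims=True)) / yp.std(ddof=1, axis=1,
                                                        keepdims=True)
    rs = (yz @ xz) / (n - 1)
    threshold = np.quantile(np.abs(rs), 0.95)
    assert threshold == pytest.approx(vc.critical_r(68, 0.05), abs=0.01)


def test_fisher_z_mean_hand_value():
    # z = atanh: (0 + atanh(0.8))/2 = 0.5493 -> tanh = 0.5
    assert vc.fisher_z_mean([0.0, 0.8]) == pytest.approx(0.5, abs=5e-5)


# ---------------------------------------------------------------------------
# Index extraction
# ---------------------------------------------------------------------------

def _posteriors_for(n_subjects, n_continua, seed=0):
    rng = np.random.default_rng(seed)
    sids = [f"S{i:02d}" for i in range(n_subjects)]
    out = {}
    for k in range(n_continua):
        theta = np.column_stack([
            np.full(n_subjects, 5.0),
            np.full(n_subjects, np.log(90.0)),
            np.full(n_subjects, 5.0),
            rng.normal(2.5, 0.3, n_subjects),
            rng.normal(2.3, 0.5, n_subjects),
        ])
        out[f"c{k}"] = make_fake_posterior(sids, theta, seed=seed + k,
                                           continuum_id=f"c{k}")
    return sids, out


def test_extract_indices_bookkeeping_and_scales():
    sids, posteriors = _posteriors_for(68, 8)
    idx = vc.extract_indices(posteriors)
    assert len(idx) == 68 * 8  # 544 rows carrying both index columns
    assert set(idx.columns) >= {"subject_id", "continuum_id", "slope_index",
                                "variability_index"}
    nat = vc.extract_indices(posteriors, scale="natural")
    merged = idx.merge(nat, on=["subject_id", "continuum_id"])
    np.testing.assert_allclose(np.exp(merged["slope_index_x"]),
                               merged["slope_index_y"])


def test_extract_indices_combined_effect_equals_posterior_mean():
    sids, posteriors = _posteriors_for(6, 1, seed=3)
    post = posteriors["c0"]
    idx = vc.extract_indices({"c0": post}).set_index("subject_id")
    expected = post.subject_param_means()
    np.testing.assert_allclose(idx["variability_index"],
                               expected["nu"].loc[idx.index])


def test_extract_indices_rejects_excluded_subject():
    sids, posteriors = _posteriors_for(5, 2)
    with pytest.raises(KeyError, match="ghost"):
        vc.extract_indices(posteriors, retained_subjects=sids + ["ghost"])


# ---------------------------------------------------------------------------
# Pairwise correlations
# ---------------------------------------------------------------------------

def test_pairwise_correlations_structure():
    rng = np.random.default_rng(1)
    sids = [f"S{i}" for i in range(30)]
    frames = []
    shared = rng.standard_normal(30)
    for k in range(8):
        frames.append(pd.DataFrame({
            "subject_id": sids, "continuum_id": f"c{k}",
            "slope_index": rng.standard_normal(30),
            "variability_index": shared + 0.5 * rng.standard_normal(30),
        }))
    idx = pd.concat(frames, ignore_index=True)
    summary = vc.pairwise_correlations(idx, "variability_index")
    assert len(summary.coefficients) == 28  # C(8, 2)
    mat = summary.matrix.to_numpy()
    np.testing.assert_allclose(mat, mat.T)
    np.testing.assert_allclose(np.diag(mat), 1.0)
    assert np.all(np.abs(summary.coefficients) <= 1.0)
    assert (min(summary.coefficients) <= summary.fisher_z_mean_r
            <= max(summary.coefficients))
    assert summary.n == 30


def test_pairwise_correlations_identical_vectors_give_unit_r():
    sids = [f"S{i}" for i in range(10)]
    vals = np.arange(10.0)
    idx = pd.concat([
        pd.DataFrame({"subject_id": sids, "continuum_id": c,
                      "slope_index": vals, "variability_index": vals})
        for c in ("a", "b")], ignore_index=True)
    summary = vc.pairwise_correlations(idx, "slope_index")
    assert summary.coefficients[0] == pytest.approx(1.0)


def test_pairwise_correlations_zero_variance_reported_undefined():
    sids = [f"S{i}" for i in range(10)]
    idx = pd.concat([
        pd.DataFrame({"subject_id": sids, "continuum_id": "a",
                      "slope_index": np.arange(10.0),
                      "variability_index": np.arange(10.0)}),
        pd.DataFrame({"subject_id": sids, "continuum_id": "b",
                      "slope_index": np.ones(10),
                      "variability_index": np.arange(10.0) ** 2}),
        pd.DataFrame({"subject_id": sids, "continuum_id": "c",
                      "slope_index": np.arange(10.0) * 2,
                      "variability_index": np.arange(10.0) * 3}),
    ], ignore_index=True)
    with pytest.warns(UserWarning, match="zero-variance"):
        summary = vc.pairwise_correlations(idx, "slope_index")
    assert summary.undefined_pairs == [("a", "b"), ("b", "c")]
    assert len(summary.coefficients) == 1
    assert np.isnan(summary.matrix.loc["a", "b"])


# ---------------------------------------------------------------------------
# Questionnaire scoring
# ---------------------------------------------------------------------------

def _responses(scale, n_items, value, sid="S1"):
    return pd.DataFrame({"subject_id": sid, "scale": scale,
                         "item": np.arange(1, n_items + 1),
                         "response": value})


def test_scoring_totals_and_reverse_keys():
    no_rev = vc.QuestionnaireScheme(name="PSWQ", n_items=16, min_response=1,
                                    max_response=5)
    scored = vc.score_questionnaire(_responses("PSWQ", 16, 1), no_rev)
    assert scored["total"].iloc[0] == 16  # 16 items at scale minimum

    k = 5
    rev = vc.QuestionnaireScheme(name="PSWQ", n_items=16, min_response=1,
                                 max_response=5,
                                 reverse_items=frozenset(range(1, k + 1)))
    scored = vc.score_questionnaire(_responses("PSWQ", 16, 1), rev)
    assert scored["total"].iloc[0] == 16 + 4 * k  # reverse-keyed arithmetic

    aq = vc.QuestionnaireScheme(name="AQ", n_items=50, min_response=1,
                                max_response=4)
    assert vc.score_questionnaire(_responses("AQ", 50, 4),
                                  aq)["total"].iloc[0] == 200


def test_scoring_subscales_and_default_ranges():
    schemes = vc.default_schemes()
    assert schemes["PSWQ"].total_range == (16, 80)
    assert schemes["AQ"].total_range == (50, 200)
    assert schemes["UPPS"].total_range == (59, 236)
    aq = schemes["AQ"]
    assert sorted(i for sub in aq.subscales.values() for i in sub) \
        == list(range(1, 51))
    upps = schemes["UPPS"]
    assert sorted(len(v) for v in upps.subscales.values()) \
        == [10, 11, 12, 12, 14]


def test_scoring_rejects_bad_input():
    scheme = vc.QuestionnaireScheme(name="PSWQ", n_items=16, min_response=1,
                                    max_response=5)
    bad = _responses("PSWQ", 16, 1)
    bad.loc[3, "response"] = 9
    with pytest.raises(ValueError, match="out of range"):
        vc.score_questionnaire(bad, scheme)
    incomplete = _responses("PSWQ", 16, 2).iloc[:-1]
    with pytest.raises(ValueError, match="missing"):
        vc.score_questionnaire(incomplete, scheme)


# ---------------------------------------------------------------------------
# Averaging and regression
# ---------------------------------------------------------------------------

def test_average_index_bookkeeping():
    idx = pd.DataFrame({
        "subject_id": ["a", "a", "b", "b", "c"],
        "continuum_id": ["x", "y", "x", "y", "x"],
        "variability_index": [1.0, 3.0, 2.0, 2.0, 5.0],
        "slope_index": 0.0,
    })
    avg = vc.average_index(idx, "variability_index").set_index("subject_id")
    assert avg.loc["a", "mean_index"] == 2.0
    assert avg.loc["b", "mean_index"] == 2.0
    assert avg.loc["c", "n_continua"] == 1
    assert not avg.loc["c", "complete"]
    assert avg.loc["a", "complete"]


def test_regression_reference_geometry():
    # y = (1, 2, 2) on x = (1, 2, 3): R^2 = Sxy^2/(Sxx*Syy) = 0.75 and the
    # standardized slope is r = sqrt(0.75)
    y = pd.Series([1.0, 2.0, 2.0])
    x = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    res = vc.regress_indices(y, x)
    assert res.r_squared == pytest.approx(0.75)
    slope_z = res.coef_table.set_index("term").loc["x", "estimate"]
    assert slope_z == pytest.approx(np.sqrt(0.75))
    # raw-scale slope recovered by un-standardizing: b = b_z * sy / sx
    assert slope_z * y.std(ddof=1) / x["x"].std(ddof=1) \
        == pytest.approx(0.5)


def test_regression_degrees_of_freedom_at_study_size():
    rng = np.random.default_rng(5)
    y = pd.Series(rng.standard_normal(68))
    X = pd.DataFrame(rng.standard_normal((68, 3)),
                     columns=["PSWQ", "UPPS", "AQ"])
    res = vc.regress_indices(y, X)
    assert (res.df1, res.df2) == (3, 64)
    assert res.adj_r_squared <= res.r_squared
    assert res.predictor_correlations.shape == (3, 3)


def test_regression_exact_fit_and_errors():
    rng = np.random.default_rng(6)
    X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
    y = pd.Series(2 * X["a"] - X["b"])
    res = vc.regress_indices(y, X)
    assert res.r_squared == pytest.approx(1.0)

    with pytest.raises(ValueError, match="constant"):
        vc.regress_indices(y, X.assign(c=1.0))
    with pytest.raises(ValueError, match="rank"):
        vc.regress_indices(y, X.assign(c=X["a"] * 2))
    with pytest.raises(ValueError, match="N > p"):
        vc.regress_indices(y.iloc[:3], X.iloc[:3])


def test_regression_matches_normal_equations_oracle():
    """statsmodels-backed fit reproduces the closed-form least squares
    solution (X'X)^-1 X'y to near machine precision on random inputs."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        n, p = 50, 3
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=list("abc")[:p])
        y = pd.Series(rng.standard_normal(n))
        res = vc.regress_indices(y, X)
        Xz = np.column_stack([np.ones(n)] + [
            (X[c] - X[c].mean()) / X[c].std(ddof=1) for c in X.columns])
        yz = (y - y.mean()) / y.std(ddof=1)
        beta = np.linalg.solve(Xz.T @ Xz, Xz.T @ yz)
        np.testing.assert_allclose(res.coef_table["estimate"].to_numpy(),
                                   beta, atol=1e-10)
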