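"""Individual-difference analysis of the fitted psychometric indices.

From each hierarchical fit we take, per subject and continuum, the
posterior mean of the subject-level log-slope (``slope_index``) and
log trial-SD (``variability_index``): fixed effect plus subject intercept
combined, on the latent scale where the random effects are Normal (a
natural-scale option exponentiates).  Trait-likeness of an index is the
pattern of its pairwise Pearson correlations across continua; the
questionnaire analysis regresses the per-subject average index on z-scored
AQ / PSWQ / UPPS-P totals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .model import HierarchicalPosterior

INDEX_COLUMNS = ("slope_index", "variability_index")


# ---------------------------------------------------------------------------
# Index extraction
# ---------------------------------------------------------------------------

def extract_indices(
    posteriors: Mapping[object, HierarchicalPosterior],
    retained_subjects: Sequence | None = None,
    scale: str = "latent",
) -> pd.DataFrame:
    """Per-subject, per-continuum slope and variability indices.

    ``posteriors`` maps continuum id to its fit.  When
    ``retained_subjects`` is given, every requested subject must be present
    in every fit (subjects excluded upstream must not be requested);
    subjects genuinely missing from a fit are simply absent from its rows,
    never imputed.  ``scale='natural'`` returns ``exp`` of the latent
    indices (slope in rating units/step, trial SD in rating units).
    """
    if scale not in ("latent", "natural"):
        raise ValueError("scale must be 'latent' or 'natural'")
    frames = []
    for cid, post in posteriors.items():
        means = post.subject_param_means()
        if retained_subjects is not None:
            missing = [s for s in retained_subjects if s not in means.index]
            if missing:
                raise KeyError(
                    f"subjects {missing} requested but absent from the fit "
                    f"for continuum {cid!r} (excluded upstream?)")
            means = means.loc[list(retained_subjects)]
        eta = means["eta"]
        nu = means["nu"]
        if scale == "natural":
            eta, nu = np.exp(eta), np.exp(nu)
        frames.append(pd.DataFrame({
            "subject_id": means.index,
            "continuum_id": cid,
            "slope_index": eta.to_numpy(),
            "variability_index": nu.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cross-continuum trait consistency
# ---------------------------------------------------------------------------

def fisher_z_mean(rs: Sequence[float]) -> float:
    """Back-transformed mean of correlations on the Fisher-z scale."""
    rs = np.asarray(rs, dtype=float)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson correlation at sample size ``n``.

    ``r* = t* / sqrt(t*^2 + n - 2)`` with ``t*`` the two-tailed t critical
    value on ``n - 2`` degrees of freedom; decreasing in ``n``.
    """
    if n < 3:
        raise ValueError(f"critical_r requires n >= 3, got {n}")
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_star / math.sqrt(t_star ** 2 + n - 2))


@dataclass
class TraitSummary:
    index_type: str
    matrix: pd.DataFrame  # continua x continua, unit diagonal
    coefficients: np.ndarray  # the C(n, 2) off-diagonal values (defined ones)
    pair_labels: list
    mean_r: float  # raw arithmetic mean
    fisher_z_mean_r: float
    critical_r: float
    n: int  # subjects entering the critical value
    alpha: float
    undefined_pairs: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair": ["|".join(map(str, p)) for p in self.pair_labels],
            "r": self.coefficients,
        })


def pairwise_correlations(
    indices: pd.DataFrame,
    index_type: str = "variability_index",
    method: str = "pearson",
    alpha: float = 0.05,
) -> TraitSummary:
    """Pairwise cross-continuum correlation structure of one index.

    Each unordered continuum pair contributes one coefficient computed over
    the subjects present on both continua (pairwise complete, minimum 3).
    Pairs with a zero-variance index vector are reported as undefined and
    excluded from the averages with a warning.  The critical value uses the
    median pairwise-complete sample size.
    """
    if index_type not in indices.columns:
        raise KeyError(f"no column {index_type!r} in the index table")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    wide = indices.pivot(index="subject_id", columns="continuum_id",
                         values=index_type)
    continua = list(wide.columns)
    mat = pd.DataFrame(np.eye(len(continua)), index=continua, columns=continua)
    coefficients, labels, undefined, ns = [], [], [], []
    for a, b in combinations(continua, 2):
        both = wide[[a, b]].dropna()
        if len(both) < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 complete "
                             "subjects")
        x, y = both[a].to_numpy(), both[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            undefined.append((a, b))
            mat.loc[a, b] = mat.loc[b, a] = np.nan
            continue
        if method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        else:
            r = float(stats.spearmanr(x, y).statistic)
        mat.loc[a, b] = mat.loc[b, a] = r
        coefficients.append(r)
        labels.append((a, b))
        ns.append(len(both))
    if undefined:
        warnings.warn(f"{len(undefined)} pair(s) with zero-variance index "
                      f"excluded from averages: {undefined}", stacklevel=2)
    coefficients = np.asarray(coefficients, dtype=float)
    n_used = int(np.median(ns)) if ns else 0
    return TraitSummary(
        index_type=index_type,
        matrix=mat,
        coefficients=coefficients,
        pair_labels=labels,
        mean_r=float(np.mean(coefficients)) if len(coefficients) else np.nan,
        fisher_z_mean_r=(fisher_z_mean(coefficients)
                         if len(coefficients) else np.nan),
        critical_r=critical_r(n_used, alpha) if n_used >= 3 else np.nan,
        n=n_used,
        alpha=alpha,
        undefined_pairs=undefined,
    )


def average_index(indices: pd.DataFrame, index_type: str) -> pd.DataFrame:
    """Unweighted per-subject mean of an index over available continua.

    Returns one row per subject with the mean and the count of contributing
    continua (flagging subjects averaged over fewer than the full set).
    """
    if index_type not in indices.columns:
        raise KeyError(f"no column {index_type!r} in the index table")
    g = indices.groupby("subject_id")[index_type]
    out = g.mean().rename("mean_index").reset_index()
    out["n_continua"] = g.count().to_numpy()
    out["complete"] = out["n_continua"] == indices["continuum_id"].nunique()
    return out


# ---------------------------------------------------------------------------
# Questionnaire scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuestionnaireScheme:
    """Scoring definition: item count, response bounds, reverse keys,
    subscale membership.  Fully config-driven — the defaults below are
    conventions for the synthetic data, not an authority on any published
    instrument."""

    name: str
    n_items: int
    min_response: int
    max_response: int
    reverse_items: frozenset[int] = frozenset()
    subscales: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_response <= self.min_response:
            raise ValueError("max_response must exceed min_response")
        bad = [i for i in self.reverse_items
               if not (1 <= i <= self.n_items)]
        if bad:
            raise ValueError(f"reverse items out of range: {bad}")

    @property
    def total_range(self) -> tuple[int, int]:
        return (self.n_items * self.min_response,
                self.n_items * self.max_response)


# AQ items where agreement indicates autistic traits, under the common
# Likert scoring convention; the remaining 26 items are reverse-keyed.
_AQ_FORWARD = frozenset({2, 4, 5, 6, 7, 9, 12, 13, 16, 18, 19, 20, 21, 22,
                         23, 26, 33, 35, 39, 41, 42, 43, 45, 46})
_AQ_SUBSCALES = {
    "social_skill": (1, 11, 13, 15, 22, 36, 44, 45, 47, 48),
    "attention_switching": (2, 4, 10, 16, 25, 32, 34, 37, 43, 46),
    "attention_to_detail": (5, 6, 9, 12, 19, 23, 28, 29, 30, 49),
    "communication": (7, 17, 18, 26, 27, 31, 33, 35, 38, 39),
    "imagination": (3, 8, 14, 20, 21, 24, 40, 41, 42, 50),
}
# UPPS-P subscales as contiguous structural blocks (12/11/10/12/14 items);
# the published 59-item key is not bundled — supply it via config for real
# data.
_UPPS_SUBSCALES = {
    "negative_urgency": tuple(range(1, 13)),
    "premeditation": tuple(range(13, 24)),
    "perseverance": tuple(range(24, 34)),
    "sensation_seeking": tuple(range(34, 46)),
    "positive_urgency": tuple(range(46, 60)),
}


def default_schemes() -> dict[str, QuestionnaireScheme]:
    """Default scoring schemes for PSWQ (16 items, 1-5), AQ (50 items, 1-4)
    and UPPS-P (59 items, 1-4)."""
    return {
        "PSWQ": QuestionnaireScheme(
            name="PSWQ", n_items=16, min_response=1, max_response=5,
            reverse_items=frozenset({1, 3, 8, 10, 11})),
        "AQ": QuestionnaireScheme(
            name="AQ", n_items=50, min_response=1, max_response=4,
            reverse_items=frozenset(range(1, 51)) - _AQ_FORWARD,
            subscales=_AQ_SUBSCALES),
        "UPPS": QuestionnaireScheme(
            name="UPPS", n_items=59, min_response=1, max_response=4,
            subscales=_UPPS_SUBSCALES),
    }


def score_questionnaire(responses: pd.DataFrame,
                        scheme: QuestionnaireScheme) -> pd.DataFrame:
    """Score one scale: reverse-key, then sum total and declared subscales.

    ``responses`` needs columns ``subject_id, item, response`` (a ``scale``
    column, if present, is filtered to ``scheme.name``).  Reverse-keyed
    items are mapped through ``min + max - response`` before summation.
    Out-of-range responses and incomplete item sets raise, naming the
    subject and item; there is no imputation.
    """
    df = responses
    if "scale" in df.columns:
        df = df.loc[df["scale"] == scheme.name]
    df = df[["subject_id", "item", "response"]].copy()
    lo, hi = scheme.min_response, scheme.max_response
    oob = ~df["response"].between(lo, hi)
    if oob.any():
        first = df.loc[oob].iloc[0]
        raise ValueError(
            f"{scheme.name}: response {first['response']} out of range "
            f"[{lo}, {hi}] for subject {first['subject_id']!r} "
            f"item {int(first['item'])}")
    wide = df.pivot(index="subject_id", columns="item", values="response")
    expected = set(range(1, scheme.n_items + 1))
    missing_cols = expected - set(wide.columns)
    if missing_cols or wide.isna().any().any():
        if missing_cols:
            raise ValueError(f"{scheme.name}: items {sorted(missing_cols)} "
                             "missing for all subjects")
        sid = wide.index[wide.isna().any(axis=1)][0]
        items = [int(c) for c in wide.columns[wide.loc[sid].isna()]]
        raise ValueError(f"{scheme.name}: subject {sid!r} missing items "
                         f"{items}; no imputation is performed")
    keyed = wide.copy()
    for item in scheme.reverse_items:
        keyed[item] = lo + hi - keyed[item]
    out = pd.DataFrame(index=keyed.index)
    out["total"] = keyed.sum(axis=1)
    for sub, items in scheme.subscales.items():
        out[sub] = keyed[list(items)].sum(axis=1)
    return out.reset_index()


def score_all(responses: pd.DataFrame,
              schemes: Mapping[str, QuestionnaireScheme] | None = None
              ) -> pd.DataFrame:
    """Wide per-subject score table over all scales (totals + subscales),
    with z-scored total columns (``<scale>_total_z``) appended."""
    schemes = schemes or default_schemes()
    out = None
    for name, scheme in schemes.items():
        scored = score_questionnaire(responses, scheme)
        scored = scored.rename(columns={
            c: (f"{name}_{c}") for c in scored.columns if c != "subject_id"})
        out = scored if out is None else out.merge(scored, on="subject_id")
    for name in schemes:
        out[f"{name}_total_z"] = zscore(out[f"{name}_total"])
    return out


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def zscore(x) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, denominator N-1)."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - np.mean(x)) / sd


@dataclass
class RegressionResult:
    coef_table: pd.DataFrame  # estimate, se, t, p per term (incl. intercept)
    f_stat: float
    df1: int
    df2: int
    f_pvalue: float
    r_squared: float
    adj_r_squared: float
    n: int
    predictor_correlations: pd.DataFrame


def regress_indices(outcome: pd.Series,
                    predictors: pd.DataFrame) -> RegressionResult:
    """OLS of a z-scored index on z-scored questionnaire totals.

    Outcome and every predictor are standardized (sample SD) before the
    fit, mirroring ``lm(index_z ~ pswq_z + upps_z + aq_z)``; the overall F
    has ``(p, N - p - 1)`` degrees of freedom.  A collinearity pre-check
    reports the predictor correlation matrix; constant predictors and
    rank-deficient designs raise.
    """
    y = np.asarray(outcome, dtype=float)
    X = predictors.astype(float)
    n, p = X.shape
    if n != len(y):
        raise ValueError("outcome and predictors must align")
    if n <= p + 1:
        raise ValueError(f"need N > p + 1, got N={n}, p={p}")
    for col in X.columns:
        if np.std(X[col], ddof=1) == 0:
            raise ValueError(f"constant predictor {col!r}")
    Xz = pd.DataFrame({c: zscore(X[c]) for c in X.columns}, index=X.index)
    if np.linalg.matrix_rank(Xz.to_numpy()) < p:
        raise ValueError("rank-deficient predictor matrix")
    yz = zscore(y)
    design = sm.add_constant(Xz)
    fit = sm.OLS(yz, design).fit()
    coef = pd.DataFrame({
        "term": design.columns,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "t": fit.tvalues.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    return RegressionResult(
        coef_table=coef,
        f_stat=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        f_pvalue=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        n=n,
        predictor_correlations=Xz.corr(),
    )
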