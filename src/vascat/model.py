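"""Hierarchical Bayesian piecewise-linear psychometric model for VAS ratings.

The mean rating along a 9-step speech continuum is modelled as a
piecewise-linear approximation of the four-parameter logistic: two flat
asymptotes ``L`` (lower) and ``U`` (upper) joined by a diagonal of slope
``s`` crossing the midpoint ``(L+U)/2`` at the crossover step ``c``::

    m(x) = clip( (L + U)/2 + s * (x - c),  L,  U )

Trial ratings scatter around ``m(x)`` with subject-specific SD ``sigma``
(response variability), truncated to the rating scale [0, 100].  All five
quantities live on a latent scale where subject (and optionally item)
random intercepts are additive Normals::

    theta = (L, delta, c, eta, nu)
    U = L + exp(delta),  s = exp(eta),  sigma = max(exp(nu), SIGMA_FLOOR)

Fitting is by adaptive random-walk Metropolis-within-Gibbs on the
non-centered parameterization, with convergence diagnostics (split-R-hat,
bulk ESS) computed through arviz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr

# latent parameter order used everywhere in this module
PARAM_NAMES: tuple[str, ...] = ("L", "delta", "c", "eta", "nu")
N_PARAMS = len(PARAM_NAMES)

SCALE_LO: float = 0.0
SCALE_HI: float = 100.0
SIGMA_FLOOR: float = 0.1  # rating units; regularizes zero-variance subjects

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateDataError(ValueError):
    """Raised when the data carry no information for the model (e.g. all
    ratings identical, or too few subjects/steps)."""


# ---------------------------------------------------------------------------
# Psychometric function and likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiecewiseParams:
    """Four curve parameters plus trial noise for one subject x continuum.

    Parameters are stored on the natural scale; :meth:`to_latent` /
    :meth:`from_latent` convert to the unconstrained parameterization
    ``(L, delta, c, eta, nu)`` used by the sampler.
    """

    lower: float  # L, rating units in [0, 100)
    upper: float  # U, rating units in (L, 100]
    crossover: float  # c, step units
    slope: float  # s, rating units per step, > 0
    noise_sd: float  # sigma, rating units, > 0

    def __post_init__(self) -> None:
        if not (SCALE_LO <= self.lower < self.upper <= SCALE_HI):
            raise ValueError(
                f"asymptotes must satisfy 0 <= L < U <= 100, got "
                f"L={self.lower}, U={self.upper}"
            )
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not np.isfinite(self.crossover):
            raise ValueError("crossover must be finite")

    def to_latent(self) -> np.ndarray:
        return np.array(
            [
                self.lower,
                np.log(self.upper - self.lower),
                self.crossover,
                np.log(self.slope),
                np.log(self.noise_sd),
            ]
        )

    @classmethod
    def from_latent(cls, theta: Sequence[float]) -> "PiecewiseParams":
        lo, delta, c, eta, nu = (float(v) for v in theta)
        return cls(
            lower=lo,
            upper=lo + np.exp(delta),
            crossover=c,
            slope=np.exp(eta),
            noise_sd=max(np.exp(nu), SIGMA_FLOOR),
        )

    @property
    def junctures(self) -> tuple[float, float]:
        """Steps where the diagonal meets the lower/upper asymptote."""
        half = (self.upper - self.lower) / (2.0 * self.slope)
        return (self.crossover - half, self.crossover + half)


def piecewise_mean(params: PiecewiseParams, step) -> np.ndarray | float:
    """Expected rating at ``step`` under the piecewise-linear function."""
    return _piecewise_mean(
        np.asarray(step, dtype=float),
        params.lower,
        params.upper,
        params.crossover,
        params.slope,
    )


def _piecewise_mean(step, lower, upper, crossover, slope):
    mid = 0.5 * (lower + upper)
    return np.clip(mid + slope * (step - crossover), lower, upper)


def _truncnorm_logpdf(x, mean, sd, lo=SCALE_LO, hi=SCALE_HI):
    """Log-density of Normal(mean, sd) truncated to [lo, hi], elementwise."""
    z = (x - mean) / sd
    # normalizer Phi((hi-m)/sd) - Phi((lo-m)/sd); guard against underflow
    norm = ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd)
    log_norm = np.log(np.maximum(norm, 1e-300))
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI - log_norm


def _normal_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def log_likelihood(
    params: PiecewiseParams,
    ratings,
    steps,
    likelihood: str = "truncated",
) -> float:
    """Total log-likelihood of one subject-x-continuum block of trials.

    ``likelihood`` selects the truncated-Normal density on [0, 100]
    (default, matching the generator) or a plain Normal for sensitivity
    analysis.
    """
    ratings = np.asarray(ratings, dtype=float)
    steps = np.asarray(steps, dtype=float)
    if params.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    m = piecewise_mean(params, steps)
    if likelihood == "truncated":
        return float(np.sum(_truncnorm_logpdf(ratings, m, params.noise_sd)))
    if likelihood == "normal":
        return float(np.sum(_normal_logpdf(ratings, m, params.noise_sd)))
    raise ValueError(f"unknown likelihood {likelihood!r}")


# ---------------------------------------------------------------------------
# Hierarchical specification
# ---------------------------------------------------------------------------


def _default_prior_mean() -> dict[str, float]:
    return {
        "L": 5.0,
        "delta": float(np.log(90.0)),
        "c": 5.0,
        "eta": float(np.log(12.0)),
        "nu": float(np.log(10.0)),
    }


def _default_prior_sd() -> dict[str, float]:
    return {"L": 10.0, "delta": 0.5, "c": 2.0, "eta": 1.0, "nu": 1.0}


def _default_re_sd_scale() -> dict[str, float]:
    # half-Normal scales for subject random-intercept SDs; L on rating scale
    return {"L": 10.0, "delta": 0.5, "c": 0.5, "eta": 0.5, "nu": 0.5}


@dataclass
class HierarchicalSpec:
    """Priors and sampler settings for the hierarchical fit.

    Fixed-effect priors are Normal (``L`` truncated to [0, 100], crossover
    to [1, 9]); random-intercept SDs get half-Normal priors with the scales
    in ``re_sd_scale``.  Weakly informative defaults centered on the
    observable rating scale.
    """

    prior_mean: dict[str, float] = field(default_factory=_default_prior_mean)
    prior_sd: dict[str, float] = field(default_factory=_default_prior_sd)
    re_sd_scale: dict[str, float] = field(default_factory=_default_re_sd_scale)
    item_sd_scale: dict[str, float] = field(default_factory=_default_re_sd_scale)
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    thin: int = 1  # sweeps per stored draw; RW kernels profit from > 1
    seed: int = 0
    likelihood: str = "truncated"  # or "normal"
    rhat_threshold: float = 1.01
    ess_threshold: float = 400.0

    def __post_init__(self) -> None:
        for name, d in (
            ("prior_sd", self.prior_sd),
            ("re_sd_scale", self.re_sd_scale),
            ("item_sd_scale", self.item_sd_scale),
        ):
            for p, v in d.items():
                if not v > 0:
                    raise ValueError(f"{name}[{p}] must be > 0, got {v}")
        if self.draws < 1 or self.warmup < 0 or self.chains < 1 \
                or self.thin < 1:
            raise ValueError("chains >= 1, warmup >= 0, draws >= 1, "
                             "thin >= 1 required")
        if self.likelihood not in ("truncated", "normal"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")

    def _vec(self, d: dict[str, float]) -> np.ndarray:
        return np.array([d[p] for p in PARAM_NAMES], dtype=float)


# bounds applied to the fixed-effect vector mu
_MU_LO = np.array([SCALE_LO, -np.inf, 1.0, -np.inf, -np.inf])
_MU_HI = np.array([SCALE_HI, np.inf, 9.0, np.inf, np.inf])


# ---------------------------------------------------------------------------
# Posterior container and diagnostics
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalPosterior:
    """MCMC draws for one hierarchical fit, wrapped around arviz.

    ``idata.posterior`` holds ``mu`` and ``tau`` (per latent parameter),
    ``subject_theta`` (fixed effect + subject intercept, per subject and
    parameter) and, for pooled fits, ``item_theta``/``omega``.
    """

    idata: az.InferenceData
    subject_ids: list
    item_ids: list
    spec: HierarchicalSpec
    continuum_id: object = None

    def subject_param_draws(self, param: str) -> np.ndarray:
        """Draws of a subject-level latent parameter, shape (chain, draw, subject)."""
        i = PARAM_NAMES.index(param)
        return self.idata.posterior["subject_theta"].values[..., i]

    def subject_param_means(self) -> pd.DataFrame:
        """Posterior mean of each subject-level latent parameter."""
        theta = self.idata.posterior["subject_theta"].values  # (ch, dr, S, P)
        means = theta.mean(axis=(0, 1))
        return pd.DataFrame(means, index=pd.Index(self.subject_ids, name="subject_id"),
                            columns=list(PARAM_NAMES))

    def fixed_effect_means(self) -> pd.Series:
        mu = self.idata.posterior["mu"].values.mean(axis=(0, 1))
        return pd.Series(mu, index=list(PARAM_NAMES))

    def diagnostics(self, rhat_threshold: float | None = None,
                    ess_threshold: float | None = None) -> "DiagnosticsReport":
        return diagnostics(
            self,
            rhat_threshold=rhat_threshold if rhat_threshold is not None else self.spec.rhat_threshold,
            ess_threshold=ess_threshold if ess_threshold is not None else self.spec.ess_threshold,
        )


@dataclass
class DiagnosticsReport:
    table: pd.DataFrame  # per scalar parameter: rhat, ess_bulk
    max_rhat: float
    min_ess: float
    rhat_threshold: float
    ess_threshold: float
    rhat_available: bool
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        rhat = f"{self.max_rhat:.4f}" if self.rhat_available else "n/a (single chain)"
        return (f"diagnostics {status}: max split-Rhat = {rhat} "
                f"(<= {self.rhat_threshold}), min bulk ESS = {self.min_ess:.0f} "
                f"(>= {self.ess_threshold})")


def diagnostics(
    posterior: HierarchicalPosterior,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 400.0,
) -> DiagnosticsReport:
    """Split-R-hat and bulk effective sample size for every stored parameter.

    With a single chain R-hat is unavailable and reported as such (the ESS
    criterion still applies).  Chains of constant draws yield NaN R-hat /
    zero-information ESS and are flagged as failing.
    """
    idata = posterior.idata
    n_chains = idata.posterior.sizes["chain"]
    ess = az.ess(idata, method="bulk")
    rows = []
    rhat_ds = az.rhat(idata) if n_chains >= 2 else None
    for var in idata.posterior.data_vars:
        ess_vals = np.ravel(ess[var].values)
        rhat_vals = (np.ravel(rhat_ds[var].values) if rhat_ds is not None
                     else np.full(ess_vals.shape, np.nan))
        for k, (e, r) in enumerate(zip(ess_vals, rhat_vals)):
            rows.append({"parameter": f"{var}[{k}]", "rhat": r, "ess_bulk": e})
    table = pd.DataFrame(rows)
    rhat_available = n_chains >= 2
    max_rhat = float(np.nanmax(table["rhat"])) if rhat_available else np.nan
    # constant chains produce NaN rhat: treat as failure, not success
    degenerate = rhat_available and table["rhat"].isna().any()
    min_ess = float(np.nanmin(table["ess_bulk"]))
    passed = (min_ess >= ess_threshold) and not degenerate
    if rhat_available:
        passed = passed and (max_rhat <= rhat_threshold)
    return DiagnosticsReport(
        table=table,
        max_rhat=max_rhat,
        min_ess=min_ess,
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
        rhat_available=rhat_available,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------


class _FitData:
    """Long-format trial arrays with subject/item index maps."""

    def __init__(self, records: pd.DataFrame, rating_col: str):
        if rating_col not in records.columns:
            raise ValueError(f"records must carry a {rating_col!r} column; "
                             "run align_ratings first")
        self.subject_ids = sorted(records["subject_id"].unique().tolist())
        self.item_ids = sorted(records["continuum_id"].unique().tolist())
        subj_map = {s: i for i, s in enumerate(self.subject_ids)}
        item_map = {s: i for i, s in enumerate(self.item_ids)}
        self.ratings = records[rating_col].to_numpy(dtype=float)
        self.steps = records["step"].to_numpy(dtype=float)
        self.subj_idx = records["subject_id"].map(subj_map).to_numpy(dtype=np.intp)
        self.item_idx = records["continuum_id"].map(item_map).to_numpy(dtype=np.intp)
        self.n_subjects = len(self.subject_ids)
        self.n_items = len(self.item_ids)
        self.n_trials = len(records)


def _validate_fit_inputs(data: _FitData) -> None:
    if data.n_subjects < 2:
        raise DegenerateDataError(
            f"hierarchical fit needs >= 2 subjects, got {data.n_subjects}")
    steps_per_subj = pd.DataFrame(
        {"s": data.subj_idx, "x": data.steps}).groupby("s")["x"].nunique()
    if (steps_per_subj < 3).any():
        bad = steps_per_subj[steps_per_subj < 3].index.tolist()
        raise DegenerateDataError(
            f"every subject needs trials on >= 3 distinct steps; "
            f"subject indices {bad} do not")
    if np.ptp(data.ratings) == 0:
        raise DegenerateDataError(
            "all ratings are identical; the psychometric function is "
            "unidentifiable")


def _subject_support_penalty(theta: np.ndarray) -> np.ndarray:
    """-inf-like penalty for subject parameter vectors outside [0,100] support."""
    L = theta[:, 0]
    U = L + np.exp(theta[:, 1])
    bad = (L < SCALE_LO) | (U > SCALE_HI)
    return np.where(bad, -1e12, 0.0)


class _Model:
    """Log-density pieces for the Metropolis-within-Gibbs sampler."""

    def __init__(self, data: _FitData, spec: HierarchicalSpec, pooled: bool):
        self.data = data
        self.spec = spec
        self.pooled = pooled
        self.m0 = spec._vec(spec.prior_mean)
        self.s0 = spec._vec(spec.prior_sd)
        self.tau_scale = spec._vec(spec.re_sd_scale)
        self.omega_scale = spec._vec(spec.item_sd_scale)
        self._logpdf = (_truncnorm_logpdf if spec.likelihood == "truncated"
                        else _normal_logpdf)

    def subject_theta(self, mu, tau, Z, B):
        theta = mu[None, :] + tau[None, :] * Z
        return theta

    def elementwise_ll(self, mu, tau, Z, B):
        """Per-trial log-density, (N,) — item effects enter via the trial's item."""
        d = self.data
        theta_s = mu[None, :] + tau[None, :] * Z  # (S, P)
        if self.pooled:
            theta_n = theta_s[d.subj_idx] + B[d.item_idx]
        else:
            theta_n = theta_s[d.subj_idx]
        L = theta_n[:, 0]
        U = L + np.exp(theta_n[:, 1])
        c = theta_n[:, 2]
        s = np.exp(theta_n[:, 3])
        sd = np.maximum(np.exp(theta_n[:, 4]), SIGMA_FLOOR)
        m = np.clip(0.5 * (L + U) + s * (d.steps - c), L, U)
        # keep density finite even off-support; the support penalty dominates
        m = np.clip(m, SCALE_LO, SCALE_HI)
        return self._logpdf(d.ratings, m, sd)

    def trial_theta_penalty(self, mu, tau, Z, B):
        """Support penalty per subject (and per item for pooled fits)."""
        d = self.data
        theta_s = mu[None, :] + tau[None, :] * Z
        if not self.pooled:
            return _subject_support_penalty(theta_s), np.zeros(d.n_items)
        # pooled: a subject x item combination can be off-support; charge the
        # penalty to both margins so either update can repair it
        theta_si = theta_s[:, None, :] + B[None, :, :]  # (S, K, P)
        L = theta_si[..., 0]
        U = L + np.exp(theta_si[..., 1])
        bad = (L < SCALE_LO) | (U > SCALE_HI)
        subj_pen = np.where(bad.any(axis=1), -1e12, 0.0)
        item_pen = np.where(bad.any(axis=0), -1e12, 0.0)
        return subj_pen, item_pen

    def subject_sums(self, ll_elem):
        return np.bincount(self.data.subj_idx, weights=ll_elem,
                           minlength=self.data.n_subjects)

    def item_sums(self, ll_elem):
        return np.bincount(self.data.item_idx, weights=ll_elem,
                           minlength=self.data.n_items)

    def log_prior_mu(self, mu):
        if np.any(mu < _MU_LO) or np.any(mu > _MU_HI):
            return -np.inf
        z = (mu - self.m0) / self.s0
        return float(-0.5 * np.sum(z * z))

    def log_prior_logtau(self, log_tau, scale):
        # half-Normal on tau, sampled on log scale (Jacobian = +log_tau each)
        tau = np.exp(log_tau)
        return float(-0.5 * np.sum((tau / scale) ** 2) + np.sum(log_tau))

    def log_prior_Z(self, Z):
        return -0.5 * np.sum(Z * Z, axis=1)  # per subject

    def log_prior_B(self, B, omega):
        z = B / omega[None, :]
        return -0.5 * np.sum(z * z, axis=1)  # per item


def _moment_estimates(data: _FitData) -> np.ndarray:
    """Crude per-subject latent parameter estimates from step-wise moments.

    Used only to initialize chains inside the typical set (the hierarchy's
    funnel makes random-walk recovery from a collapsed subject-SD slow, so
    warmup should start near the data-supported subject spread).
    """
    theta0 = np.empty((data.n_subjects, N_PARAMS))
    df = pd.DataFrame({"s": data.subj_idx, "x": data.steps, "y": data.ratings})
    for s, g in df.groupby("s"):
        step_means = g.groupby("x")["y"].mean()
        lo = float(np.clip(step_means.min(), 0.0, 45.0))
        hi = float(np.clip(step_means.max(), 55.0, 100.0))
        mid = 0.5 * (lo + hi)
        xs = step_means.index.to_numpy(dtype=float)
        ys = step_means.to_numpy()
        above = xs[ys >= mid]
        c0 = float(np.clip(above.min() - 0.5 if len(above) else 5.0, 1.0, 9.0))
        # slope from the transition region, fall back to a global fit
        trans = (ys > lo + 0.2 * (hi - lo)) & (ys < lo + 0.8 * (hi - lo))
        if trans.sum() >= 2:
            s0 = float(np.polyfit(xs[trans], ys[trans], 1)[0])
        else:
            s0 = float(np.polyfit(xs, ys, 1)[0])
        s0 = float(np.clip(s0, 1.0, 60.0))
        resid_sd = float(g.groupby("x")["y"].std(ddof=1).mean())
        if not np.isfinite(resid_sd):
            resid_sd = 5.0
        sig0 = float(np.clip(resid_sd, 0.5, 40.0))
        theta0[s] = (lo, np.log(max(hi - lo, 10.0)), c0,
                     np.log(s0), np.log(sig0))
    return theta0


_GRID_LO, _GRID_HI, _GRID_N = -7.0, 3.5, 512


def _grid_gibbs_logtau(rng: np.random.Generator, n_groups: int,
                       resid2: float, scale: float) -> float:
    """Exact draw of log(tau) | group effects via inverse-CDF on a grid.

    Target: tau ~ half-Normal(scale) prior with n_groups Normal(0, tau)
    observations carrying summed squares ``resid2``; an independent draw
    each sweep removes the random-walk autocorrelation of the
    centered-direction SD update.
    """
    lt = np.linspace(_GRID_LO + np.log(scale), _GRID_HI + np.log(scale),
                     _GRID_N)
    t = np.exp(lt)
    logp = (-n_groups * lt - resid2 / (2.0 * t * t)
            - 0.5 * (t / scale) ** 2 + lt)
    logp -= logp.max()
    cdf = np.cumsum(np.exp(logp))
    u = rng.random() * cdf[-1]
    return float(lt[np.searchsorted(cdf, u)])


def _run_chain(model: _Model, rng: np.random.Generator,
               warmup: int, draws: int, thin: int = 1) -> dict[str, np.ndarray]:
    d = model.data
    S, K, P = d.n_subjects, d.n_items, N_PARAMS
    pooled = model.pooled

    # --- initial state: per-subject moment estimates, jittered per chain
    theta0 = _moment_estimates(d)
    theta0 = theta0 + 0.05 * np.abs(theta0).mean(axis=0) \
        * rng.standard_normal((S, P))
    mu = theta0.mean(axis=0)
    mu = np.clip(mu, _MU_LO + 1e-3, _MU_HI - 1e-3)
    tau0 = np.clip(theta0.std(axis=0), 0.05 * model.tau_scale,
                   3.0 * model.tau_scale)
    log_tau = np.log(tau0)
    Z = (theta0 - mu[None, :]) / tau0[None, :]
    B = np.zeros((K, P))
    log_omega = np.log(0.5 * model.omega_scale) + 0.1 * rng.standard_normal(P)

    tau = np.exp(log_tau)
    omega = np.exp(log_omega)

    ll_elem = model.elementwise_ll(mu, tau, Z, B)

    # --- adaptive proposal scales
    step_z = np.full((S, P), 0.3)
    step_slide = np.full((S, 3), 2.0)  # rating units: L-, U-slide, vertical
    step_gslide = np.full(2, 1.0)  # rating units, global L-/U-slides
    step_mu = np.array([1.0, 0.1, 0.2, 0.1, 0.1])
    step_tau = np.full(P, 0.3)
    step_b = np.full(K, 0.1)
    step_omega = np.full(P, 0.3)
    target_block, target_scalar = 0.25, 0.44

    out_mu = np.empty((draws, P))
    out_tau = np.empty((draws, P))
    out_theta = np.empty((draws, S, P))
    out_item = np.empty((draws, K, P)) if pooled else None
    out_omega = np.empty((draws, P)) if pooled else None

    total = warmup + draws * thin
    for t in range(total):
        adapting = t < warmup
        gamma = (t + 1) ** -0.6 if adapting else 0.0

        # ---- subject intercepts: per-parameter updates, vectorized over
        # subjects (per-(subject, parameter) adaptive scales — the five
        # latent dimensions have very different posterior widths)
        for p in range(P):
            Z_prop = Z.copy()
            Z_prop[:, p] = Z[:, p] + step_z[:, p] * rng.standard_normal(S)
            ll_prop = model.elementwise_ll(mu, tau, Z_prop, B)
            subj_cur = model.subject_sums(ll_elem) + model.log_prior_Z(Z)
            subj_prop = (model.subject_sums(ll_prop)
                         + model.log_prior_Z(Z_prop))
            pen_cur, _ = model.trial_theta_penalty(mu, tau, Z, B)
            pen_prop, _ = model.trial_theta_penalty(mu, tau, Z_prop, B)
            log_alpha = (subj_prop + pen_prop) - (subj_cur + pen_cur)
            accept = np.log(rng.random(S)) < log_alpha
            if accept.any():
                Z = np.where(accept[:, None], Z_prop, Z)
                keep = accept[d.subj_idx]
                ll_elem = np.where(keep, ll_prop, ll_elem)
            if adapting:
                step_z[:, p] *= np.exp(gamma * (accept.astype(float)
                                                - target_scalar))

        # ---- ridge/slide moves.  The clipped piecewise mean makes three
        # directions in (L, U, c) nearly likelihood-flat and therefore slow
        # for axis-aligned walks: sliding L with U fixed, sliding U with L
        # fixed (each with the shear c' = c + eps/(2s) that keeps the
        # diagonal line unchanged), and shifting the whole curve vertically
        # (c' = c + eps/s).  Random walks in (L, U, c) coordinates; the
        # change of variables from the latent delta = log(U - L)
        # contributes log((U-L)/(U'-L')) for the one-sided slides and
        # nothing for the volume-preserving vertical shift.
        def propose_slide(which: str, eps: np.ndarray):
            theta = mu[None, :] + tau[None, :] * Z
            L_s = theta[:, 0]
            U_s = L_s + np.exp(theta[:, 1])
            s_s = np.exp(theta[:, 3])
            Z_prop = Z.copy()
            if which == "L":
                L_new = L_s + eps
                valid = (L_new >= SCALE_LO) & (L_new < U_s - 1e-6)
                L_new = np.where(valid, L_new, L_s)
                eff = L_new - L_s
                Z_prop[:, 0] = (L_new - mu[0]) / max(tau[0], 1e-12)
                Z_prop[:, 1] = (np.log(U_s - L_new) - mu[1]) \
                    / max(tau[1], 1e-12)
                Z_prop[:, 2] = (theta[:, 2] + eff / (2.0 * s_s)
                                - mu[2]) / max(tau[2], 1e-12)
                jac = np.log(U_s - L_s) - np.log(U_s - L_new)
            elif which == "U":
                U_new = U_s + eps
                valid = (U_new <= SCALE_HI) & (U_new > L_s + 1e-6)
                U_new = np.where(valid, U_new, U_s)
                eff = U_new - U_s
                Z_prop[:, 1] = (np.log(U_new - L_s) - mu[1]) \
                    / max(tau[1], 1e-12)
                Z_prop[:, 2] = (theta[:, 2] + eff / (2.0 * s_s)
                                - mu[2]) / max(tau[2], 1e-12)
                jac = np.log(U_s - L_s) - np.log(U_new - L_s)
            else:  # vertical shift
                valid = ((L_s + eps >= SCALE_LO)
                         & (U_s + eps <= SCALE_HI))
                eff = np.where(valid, eps, 0.0)
                Z_prop[:, 0] = (L_s + eff - mu[0]) / max(tau[0], 1e-12)
                Z_prop[:, 2] = (theta[:, 2] + eff / s_s
                                - mu[2]) / max(tau[2], 1e-12)
                jac = np.zeros(S)
            return Z_prop, valid, jac

        for which, idx in (("L", 0), ("U", 1), ("V", 2)):
            Z_prop, valid, jac = propose_slide(
                which, step_slide[:, idx] * rng.standard_normal(S))
            ll_prop = model.elementwise_ll(mu, tau, Z_prop, B)
            subj_cur = model.subject_sums(ll_elem) + model.log_prior_Z(Z)
            subj_prop = (model.subject_sums(ll_prop)
                         + model.log_prior_Z(Z_prop))
            pen_cur, _ = model.trial_theta_penalty(mu, tau, Z, B)
            pen_prop, _ = model.trial_theta_penalty(mu, tau, Z_prop, B)
            log_alpha = np.where(
                valid, (subj_prop + pen_prop) - (subj_cur + pen_cur) + jac,
                -np.inf)
            accept = np.log(rng.random(S)) < log_alpha
            if accept.any():
                Z = np.where(accept[:, None], Z_prop, Z)
                keep = accept[d.subj_idx]
                ll_elem = np.where(keep, ll_prop, ll_elem)
            if adapting:
                step_slide[:, idx] *= np.exp(gamma * (accept.astype(float)
                                                      - target_scalar))

        # ---- global slides: the same moves with one common epsilon for
        # the whole cohort (cohort-wide asymptote shifts are a slow mode
        # that per-subject moves cannot travel).  The fixed effect absorbs
        # the common shift so the subject deviations stay centered.
        for which, idx in (("L", 0), ("U", 1)):
            eps_g = float(step_gslide[idx] * rng.standard_normal())
            Z_prop, valid, jac = propose_slide(which, np.full(S, eps_g))
            if not bool(valid.all()):
                acc_g = False
            else:
                theta_prop = mu[None, :] + tau[None, :] * Z_prop
                mu_prop = mu.copy()
                shift_p = 0 if which == "L" else 1
                mu_prop[shift_p] += float(
                    np.mean(theta_prop[:, shift_p] - (mu[shift_p]
                            + tau[shift_p] * Z[:, shift_p])))
                lp_mu = model.log_prior_mu(mu_prop)
                if not np.isfinite(lp_mu):
                    acc_g = False
                else:
                    Z_new = (theta_prop - mu_prop[None, :]) \
                        / np.maximum(tau, 1e-12)[None, :]
                    ll_prop = model.elementwise_ll(mu_prop, tau, Z_new, B)
                    pen_prop, _ = model.trial_theta_penalty(
                        mu_prop, tau, Z_new, B)
                    pen_cur, _ = model.trial_theta_penalty(mu, tau, Z, B)
                    cur = (float(np.sum(ll_elem))
                           + float(np.sum(model.log_prior_Z(Z)))
                           + model.log_prior_mu(mu) + float(np.sum(pen_cur)))
                    prop_lp = (float(np.sum(ll_prop))
                               + float(np.sum(model.log_prior_Z(Z_new)))
                               + lp_mu + float(np.sum(pen_prop)))
                    acc_g = bool(np.log(rng.random())
                                 < (prop_lp - cur + float(np.sum(jac))))
                    if acc_g:
                        mu = mu_prop
                        Z = Z_new
                        ll_elem = ll_prop
            if adapting:
                step_gslide[idx] *= np.exp(gamma * (float(acc_g)
                                                    - target_scalar))

        # ---- item blocks (pooled variant only)
        if pooled and K > 1:
            B_prop = B + step_b[:, None] * rng.standard_normal((K, P))
            ll_prop = model.elementwise_ll(mu, tau, Z, B_prop)
            item_cur = model.item_sums(ll_elem) + model.log_prior_B(B, omega)
            item_prop = model.item_sums(ll_prop) + model.log_prior_B(B_prop, omega)
            _, ipen_cur = model.trial_theta_penalty(mu, tau, Z, B)
            _, ipen_prop = model.trial_theta_penalty(mu, tau, Z, B_prop)
            log_alpha = (item_prop + ipen_prop) - (item_cur + ipen_cur)
            accept = np.log(rng.random(K)) < log_alpha
            if accept.any():
                B = np.where(accept[:, None], B_prop, B)
                keep = accept[d.item_idx]
                ll_elem = np.where(keep, ll_prop, ll_elem)
            if adapting:
                step_b *= np.exp(gamma * (accept.astype(float) - target_block))

            # omega (item-SD) scalars — prior-only interaction with B? no:
            # omega enters the B prior, B fixed -> conjugate-like scalar MH
            for p in range(P):
                prop = log_omega.copy()
                prop[p] += step_omega[p] * rng.standard_normal()
                cur_lp = (model.log_prior_logtau(log_omega, model.omega_scale)
                          + float(np.sum(model.log_prior_B(B, np.exp(log_omega)))))
                prop_lp = (model.log_prior_logtau(prop, model.omega_scale)
                           + float(np.sum(model.log_prior_B(B, np.exp(prop)))))
                acc_p = np.log(rng.random()) < (prop_lp - cur_lp)
                if acc_p:
                    log_omega = prop
                    omega = np.exp(log_omega)
                if adapting:
                    step_omega[p] *= np.exp(gamma * (float(acc_p) - target_scalar))

        # ---- fixed effects (scalar random-walk per parameter)
        cur_total = None
        for p in range(P):
            mu_prop = mu.copy()
            mu_prop[p] += step_mu[p] * rng.standard_normal()
            lp_mu_prop = model.log_prior_mu(mu_prop)
            if np.isfinite(lp_mu_prop):
                if cur_total is None:
                    pen_s, pen_i = model.trial_theta_penalty(mu, tau, Z, B)
                    cur_total = (float(np.sum(ll_elem)) + model.log_prior_mu(mu)
                                 + float(np.sum(pen_s)) + float(np.sum(pen_i)))
                ll_prop = model.elementwise_ll(mu_prop, tau, Z, B)
                pen_s, pen_i = model.trial_theta_penalty(mu_prop, tau, Z, B)
                prop_total = (float(np.sum(ll_prop)) + lp_mu_prop
                              + float(np.sum(pen_s)) + float(np.sum(pen_i)))
                acc_p = np.log(rng.random()) < (prop_total - cur_total)
            else:
                acc_p = False
            if acc_p:
                mu = mu_prop
                ll_elem = ll_prop
                cur_total = prop_total
            if adapting:
                step_mu[p] *= np.exp(gamma * (float(acc_p) - target_scalar))

        # ---- random-intercept SDs (log scale)
        cur_total = None
        for p in range(P):
            prop = log_tau.copy()
            prop[p] += step_tau[p] * rng.standard_normal()
            tau_prop = np.exp(prop)
            if cur_total is None:
                pen_s, pen_i = model.trial_theta_penalty(mu, tau, Z, B)
                cur_total = (float(np.sum(ll_elem))
                             + model.log_prior_logtau(log_tau, model.tau_scale)
                             + float(np.sum(pen_s)) + float(np.sum(pen_i)))
            ll_prop = model.elementwise_ll(mu, tau_prop, Z, B)
            pen_s, pen_i = model.trial_theta_penalty(mu, tau_prop, Z, B)
            prop_total = (float(np.sum(ll_prop))
                          + model.log_prior_logtau(prop, model.tau_scale)
                          + float(np.sum(pen_s)) + float(np.sum(pen_i)))
            acc_p = np.log(rng.random()) < (prop_total - cur_total)
            if acc_p:
                log_tau = prop
                tau = tau_prop
                ll_elem = ll_prop
                cur_total = prop_total
            if adapting:
                step_tau[p] *= np.exp(gamma * (float(acc_p) - target_scalar))

        # ---- interweaving (ancillarity-sufficiency): centered updates of
        # mu and tau given subject_theta fixed.  The likelihood depends on
        # theta only, so these moves are free of data evaluations and break
        # the strong mu/Z and tau/Z coupling of the non-centered walk.
        theta = mu[None, :] + tau[None, :] * Z  # (S, P), held fixed
        prec = S / np.maximum(tau, 1e-12) ** 2 + 1.0 / model.s0 ** 2
        cond_mean = (theta.sum(axis=0) / np.maximum(tau, 1e-12) ** 2
                     + model.m0 / model.s0 ** 2) / prec
        cond_sd = 1.0 / np.sqrt(prec)
        for p in range(P):
            mu[p] = _draw_truncnorm_scalar(rng, cond_mean[p], cond_sd[p],
                                           _MU_LO[p], _MU_HI[p])
        resid2 = ((theta - mu[None, :]) ** 2).sum(axis=0)
        for p in range(P):
            log_tau[p] = _grid_gibbs_logtau(rng, S, resid2[p],
                                            model.tau_scale[p])
        tau = np.exp(log_tau)
        Z = (theta - mu[None, :]) / tau[None, :]

        if not adapting and (t - warmup) % thin == thin - 1:
            i = (t - warmup) // thin
            out_mu[i] = mu
            out_tau[i] = tau
            out_theta[i] = mu[None, :] + tau[None, :] * Z
            if pooled:
                out_item[i] = B
                out_omega[i] = omega

    result = {"mu": out_mu, "tau": out_tau, "subject_theta": out_theta}
    if pooled:
        result["item_theta"] = out_item
        result["omega"] = out_omega
    return result


def _fit(records: pd.DataFrame, spec: HierarchicalSpec, pooled: bool,
         rating_col: str, continuum_id) -> HierarchicalPosterior:
    data = _FitData(records, rating_col)
    _validate_fit_inputs(data)
    model = _Model(data, spec, pooled)
    seed_seq = np.random.SeedSequence(spec.seed)
    chain_out: list[dict[str, np.ndarray]] = []
    for child in seed_seq.spawn(spec.chains):
        rng = np.random.default_rng(child)
        chain_out.append(_run_chain(model, rng, spec.warmup, spec.draws,
                                    spec.thin))
    posterior = {k: np.stack([c[k] for c in chain_out]) for k in chain_out[0]}
    dims = {"mu": ["param"], "tau": ["param"],
            "subject_theta": ["subject", "param"]}
    coords = {"param": list(PARAM_NAMES), "subject": data.subject_ids}
    if pooled:
        dims["item_theta"] = ["item", "param"]
        dims["omega"] = ["param"]
        coords["item"] = data.item_ids
    idata = az.from_dict(posterior=posterior, dims=dims, coords=coords)
    return HierarchicalPosterior(
        idata=idata,
        subject_ids=data.subject_ids,
        item_ids=data.item_ids,
        spec=spec,
        continuum_id=continuum_id,
    )


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def fit_continuum(
    records: pd.DataFrame,
    spec: HierarchicalSpec,
    rating_col: str = "rating_aligned",
) -> HierarchicalPosterior:
    """Fit the hierarchical piecewise model to one continuum.

    ``records`` is a long trial table (one continuum) with columns
    ``subject_id``, ``continuum_id``, ``step`` and the aligned rating.
    Subject random intercepts are placed on all five latent parameters
    (non-centered); the posterior carries split-R-hat/ESS diagnostics via
    :meth:`HierarchicalPosterior.diagnostics`.
    """
    continua = records["continuum_id"].unique()
    if len(continua) != 1:
        raise ValueError(
            f"fit_continuum expects a single continuum, got {len(continua)}; "
            "use fit_pooled for a joint fit")
    return _fit(records, spec, pooled=False, rating_col=rating_col,
                continuum_id=continua[0])


def fit_pooled(
    records: pd.DataFrame,
    spec: HierarchicalSpec,
    rating_col: str = "rating_aligned",
) -> HierarchicalPosterior:
    """Joint fit over all continua with item (continuum) random intercepts.

    The subject intercept is shared across continua; each continuum gets its
    own additive intercept on every latent parameter, with half-Normal priors
    on the item-SD vector ``omega``.
    """
    return _fit(records, spec, pooled=True, rating_col=rating_col,
                continuum_id=None)


def posterior_predict(
    posterior: HierarchicalPosterior,
    subject_id,
    steps,
    interval: float = 0.9,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Predictive rating distribution per step for one fitted subject.

    Returns one row per step with the posterior-mean latent curve
    (``mean_curve``, monotone in step for every draw), the predictive mean
    of new trials, and equal-tailed predictive interval bounds obtained by
    simulating one truncated-Normal trial per posterior draw.
    """
    if subject_id not in posterior.subject_ids:
        raise KeyError(f"subject {subject_id!r} not present in this fit")
    s = posterior.subject_ids.index(subject_id)
    theta = posterior.idata.posterior["subject_theta"].values[:, :, s, :]
    theta = theta.reshape(-1, N_PARAMS)  # (n_draws, P)
    steps = np.asarray(steps, dtype=float)
    L = theta[:, 0][:, None]
    U = L + np.exp(theta[:, 1])[:, None]
    c = theta[:, 2][:, None]
    sl = np.exp(theta[:, 3])[:, None]
    sd = np.maximum(np.exp(theta[:, 4]), SIGMA_FLOOR)[:, None]
    m = np.clip(0.5 * (L + U) + sl * (steps[None, :] - c), L, U)  # (D, n_steps)
    rng = np.random.default_rng(seed)
    draws = _sample_truncnorm(rng, m, np.broadcast_to(sd, m.shape))
    alpha = (1.0 - interval) / 2.0
    lo_q, hi_q = np.quantile(draws, [alpha, 1.0 - alpha], axis=0)
    return pd.DataFrame({
        "step": steps,
        "mean_curve": m.mean(axis=0),
        "predictive_mean": draws.mean(axis=0),
        "predictive_sd": draws.std(axis=0, ddof=1),
        "lower": lo_q,
        "upper": hi_q,
    })


def _sample_truncnorm(rng: np.random.Generator, mean, sd,
                      lo=SCALE_LO, hi=SCALE_HI) -> np.ndarray:
    """Inverse-CDF sampling of Normal(mean, sd) truncated to [lo, hi]."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + (b - a) * rng.random(mean.shape)
    from scipy.special import ndtri
    x = mean + sd * ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    return np.clip(x, lo, hi)


def _draw_truncnorm_scalar(rng: np.random.Generator, mean: float, sd: float,
                           lo: float, hi: float) -> float:
    if not np.isfinite(lo) and not np.isfinite(hi):
        return float(mean + sd * rng.standard_normal())
    from scipy.special import ndtri
    a = ndtr((lo - mean) / sd) if np.isfinite(lo) else 0.0
    b = ndtr((hi - mean) / sd) if np.isfinite(hi) else 1.0
    u = a + (b - a) * rng.random()
    x = mean + sd * ndtri(min(max(u, 1e-15), 1 - 1e-15))
    return float(min(max(x, lo), hi)) if np.isfinite(lo) else float(x)
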