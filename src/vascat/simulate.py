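"""Synthetic VAS cohorts with the statistical structure the analysis assumes.

Generates long-format trial tables for a design of ``n_subjects`` listeners
x ``n_continua`` speech continua x ``n_steps`` steps x repetitions x
sessions (default 9 x 8 x 3 x 2 = 432 trials per listener), from
subject-specific piecewise-linear psychometric functions plus
subject-specific trial noise.

Three listener archetypes dissociate the mean slope from trial-to-trial
consistency:

* ``graded`` — ratings are truncated-Normal around the subject's piecewise
  mean (the generative model the fitter assumes);
* ``endpoint_bimodal`` — ratings come from a two-component mixture hugging
  the scale endpoints, with a step-dependent mixture weight: a shallow mean
  slope despite categorical single-trial behavior;
* ``flat`` — ratings are truncated-Normal around midscale regardless of
  step (random/unreliable responders, the kind the exclusion filter is
  meant to remove).

Cross-continuum trait structure uses an equicorrelated shared-trait
construction: a subject's log-noise values across continua share a latent
consistency trait with correlation ``trait_rho_consistency`` (analogously
``trait_rho_slope`` for log slope).

Questionnaire item responses (AQ, PSWQ, UPPS-P) are simulated from a
discretized latent Gaussian with a configurable association to the latent
traits (default zero) and a configurable AQ-PSWQ total-score correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .model import PiecewiseParams, _piecewise_mean, _sample_truncnorm

ARCHETYPES = ("graded", "endpoint_bimodal", "flat")

# the study's eight continua, used as default continuum ids
DEFAULT_CONTINUA = (
    "beach-peach", "dime-time", "pen-pan", "bet-bat",
    "beet-boot", "hat-hot", "net-nut", "sip-ship",
)

LATENT_NAMES = ("L", "delta", "c", "eta", "nu")

TRIAL_COLUMNS = ("subject_id", "continuum_id", "step", "session", "rep",
                 "endpoint_reversed", "rating")


def _default_pop_means() -> dict[str, float]:
    return {"L": 5.0, "U": 95.0, "c": 5.0,
            "eta": math.log(12.0), "nu": math.log(10.0)}


def _default_subject_sd() -> dict[str, float]:
    return {"L": 3.0, "delta": 0.10, "c": 0.4, "eta": 0.35, "nu": 0.5}


def _default_continuum_sd() -> dict[str, float]:
    return {"L": 1.5, "delta": 0.05, "c": 0.3, "eta": 0.20, "nu": 0.15}


def _default_mix() -> dict[str, float]:
    # flat fraction chosen so the default 78-listener cohort contains the
    # 10 unreliable responders the exclusion filter should catch
    return {"graded": 1.0 - 0.25 - 10.0 / 78.0,
            "endpoint_bimodal": 0.25,
            "flat": 10.0 / 78.0}


@dataclass
class PopulationConfig:
    """Design and population-level parameters of a synthetic cohort.

    ``pop_means`` holds population means for the natural-scale asymptotes
    ``L``/``U`` (rating units), crossover ``c`` (step units), log-slope
    ``eta`` and log-noise ``nu``.  ``subject_sd`` / ``continuum_sd`` are
    between-subject and between-continuum SDs on the latent scale
    ``(L, delta, c, eta, nu)`` where ``delta = log(U - L)``.
    """

    n_subjects: int = 78
    n_continua: int = 8
    n_steps: int = 9
    n_reps_per_session: int = 3
    n_sessions: int = 2
    pop_means: dict[str, float] = field(default_factory=_default_pop_means)
    subject_sd: dict[str, float] = field(default_factory=_default_subject_sd)
    continuum_sd: dict[str, float] = field(default_factory=_default_continuum_sd)
    trait_rho_consistency: float = 0.7
    trait_rho_slope: float = 0.35
    archetype_mix: dict[str, float] = field(default_factory=_default_mix)
    bimodal_weight_mode: str = "logistic"  # or "matched"
    bimodal_weight_steepness: float = 0.8  # logistic growth per step
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_continua", "n_steps",
                     "n_reps_per_session", "n_sessions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        L, U = self.pop_means["L"], self.pop_means["U"]
        if not (0.0 <= L < U <= 100.0):
            raise ValueError(f"need 0 <= L_mean < U_mean <= 100, got {L}, {U}")
        for name, rho in (("trait_rho_consistency", self.trait_rho_consistency),
                          ("trait_rho_slope", self.trait_rho_slope)):
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"{name} must lie in (-1, 1), got {rho}")
        if set(self.archetype_mix) - set(ARCHETYPES):
            raise ValueError(f"unknown archetypes in mix: "
                             f"{set(self.archetype_mix) - set(ARCHETYPES)}")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix must sum to 1, sums to {total}")
        if self.bimodal_weight_mode not in ("logistic", "matched"):
            raise ValueError("bimodal_weight_mode must be 'logistic' or 'matched'")

    @property
    def trials_per_subject(self) -> int:
        return (self.n_steps * self.n_continua
                * self.n_reps_per_session * self.n_sessions)

    def continuum_ids(self) -> list[str]:
        if self.n_continua <= len(DEFAULT_CONTINUA):
            return list(DEFAULT_CONTINUA[: self.n_continua])
        return [f"continuum_{k + 1:02d}" for k in range(self.n_continua)]


@dataclass
class ListenerProfile:
    """True generating quantities for one synthetic listener."""

    subject_id: str
    archetype: str
    params: dict[str, PiecewiseParams]  # per continuum
    consistency_trait: float  # shared latent component of nu (standardized)
    slope_trait: float  # shared latent component of eta (standardized)

    def true_nu(self, continuum_id: str) -> float:
        return math.log(self.params[continuum_id].noise_sd)

    def true_eta(self, continuum_id: str) -> float:
        return math.log(self.params[continuum_id].slope)


def _largest_remainder_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Deterministic apportionment of n subjects to archetypes."""
    quotas = {a: mix.get(a, 0.0) * n for a in ARCHETYPES}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    short = n - sum(counts.values())
    by_remainder = sorted(ARCHETYPES,
                          key=lambda a: (-(quotas[a] - counts[a]), a))
    for a in by_remainder[:short]:
        counts[a] += 1
    return counts


def sample_population(config: PopulationConfig) -> list[ListenerProfile]:
    """Draw true per-subject, per-continuum psychometric parameters.

    Continuum offsets on every latent parameter are drawn once and shared
    across subjects.  A subject's ``nu`` across continua decomposes as
    ``sd * (sqrt(rho) * trait + sqrt(1 - rho) * idiosyncratic)`` so the
    population correlation of ``nu`` between any two continua equals
    ``trait_rho_consistency`` (analogously for ``eta``); subject effects on
    ``L``, ``delta``, ``c`` are shared across continua.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_continua
    continua = config.continuum_ids()
    means = {
        "L": config.pop_means["L"],
        "delta": math.log(config.pop_means["U"] - config.pop_means["L"]),
        "c": config.pop_means["c"],
        "eta": config.pop_means["eta"],
        "nu": config.pop_means["nu"],
    }
    cont_offsets = {p: rng.normal(0.0, config.continuum_sd[p], size=K)
                    for p in LATENT_NAMES}

    counts = _largest_remainder_counts(config.archetype_mix, config.n_subjects)
    archetype_pool = [a for a in ARCHETYPES for _ in range(counts[a])]
    order = rng.permutation(config.n_subjects)
    archetypes = [archetype_pool[i] for i in order]

    rho_nu = config.trait_rho_consistency
    rho_eta = config.trait_rho_slope
    # a single shared trait cannot represent negative equicorrelation
    if rho_nu < 0 or rho_eta < 0:
        raise ValueError("equicorrelated construction requires rho >= 0")

    profiles: list[ListenerProfile] = []
    width = len(str(config.n_subjects))
    for i in range(config.n_subjects):
        sid = f"S{i + 1:0{width}d}"
        t_cons = rng.standard_normal()
        t_slope = rng.standard_normal()
        shared = {p: rng.standard_normal() for p in ("L", "delta", "c")}
        idio_nu = rng.standard_normal(K)
        idio_eta = rng.standard_normal(K)
        params: dict[str, PiecewiseParams] = {}
        for k, cid in enumerate(continua):
            lat = {}
            for p in ("L", "delta", "c"):
                lat[p] = (means[p] + cont_offsets[p][k]
                          + config.subject_sd[p] * shared[p])
            lat["nu"] = (means["nu"] + cont_offsets["nu"][k]
                         + config.subject_sd["nu"]
                         * (math.sqrt(rho_nu) * t_cons
                            + math.sqrt(1.0 - rho_nu) * idio_nu[k]))
            lat["eta"] = (means["eta"] + cont_offsets["eta"][k]
                          + config.subject_sd["eta"]
                          * (math.sqrt(rho_eta) * t_slope
                             + math.sqrt(1.0 - rho_eta) * idio_eta[k]))
            lower = min(max(lat["L"], 0.0), 40.0)
            upper = min(lower + math.exp(lat["delta"]), 100.0)
            if archetypes[i] == "flat":
                # constant-at-midscale true function
                params[cid] = PiecewiseParams(
                    lower=0.0, upper=100.0, crossover=lat["c"],
                    slope=1e-6, noise_sd=math.exp(lat["nu"]))
            else:
                params[cid] = PiecewiseParams(
                    lower=lower, upper=upper, crossover=lat["c"],
                    slope=math.exp(lat["eta"]), noise_sd=math.exp(lat["nu"]))
        profiles.append(ListenerProfile(
            subject_id=sid, archetype=archetypes[i], params=params,
            consistency_trait=t_cons, slope_trait=t_slope))
    return profiles


def _truncnorm_mean(loc: float, sd: np.ndarray | float,
                    lo: float = 0.0, hi: float = 100.0):
    """Analytic mean of Normal(loc, sd) truncated to [lo, hi]."""
    sd = np.asarray(sd, dtype=float)
    a = (lo - loc) / sd
    b = (hi - loc) / sd
    z = ndtr(b) - ndtr(a)
    phi = lambda x: np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return loc + sd * (phi(a) - phi(b)) / np.maximum(z, 1e-300)


def generate_trials(profiles: Sequence[ListenerProfile],
                    config: PopulationConfig) -> pd.DataFrame:
    """Simulate the full trial table for a cohort.

    Ratings are generated on the aligned scale (function rising with step)
    and stored raw: the endpoint assignment is reversed in even-numbered
    sessions, mirroring the session-wise endpoint swap of the task, so
    ``rating = 100 - aligned`` there and ``endpoint_reversed = 1``.

    For the ``endpoint_bimodal`` archetype the two mixture components sit at
    the scale endpoints with within-component SD ``exp(nu)``; the mixture
    weight is either a logistic in step (own steepness) or, in ``matched``
    mode, derived from the subject's piecewise mean and the analytic
    truncated component means so that the step-wise mean exactly equals the
    graded archetype's.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    continua = config.continuum_ids()
    steps = np.arange(1, config.n_steps + 1)
    reps = np.arange(1, config.n_reps_per_session + 1)
    frames = []
    for prof in profiles:
        for session in range(1, config.n_sessions + 1):
            reversed_flag = int(session % 2 == 0)
            for cid in continua:
                p = prof.params[cid]
                step_grid = np.repeat(steps, len(reps))
                rep_grid = np.tile(reps, len(steps))
                n = len(step_grid)
                if prof.archetype == "flat":
                    aligned = _sample_truncnorm(
                        rng, np.full(n, 50.0), np.full(n, p.noise_sd))
                elif prof.archetype == "endpoint_bimodal":
                    aligned = _bimodal_ratings(rng, p, step_grid, config)
                else:
                    m = _piecewise_mean(step_grid.astype(float), p.lower,
                                        p.upper, p.crossover, p.slope)
                    aligned = _sample_truncnorm(rng, m, np.full(n, p.noise_sd))
                rating = 100.0 - aligned if reversed_flag else aligned
                frames.append(pd.DataFrame({
                    "subject_id": prof.subject_id,
                    "continuum_id": cid,
                    "step": step_grid,
                    "session": session,
                    "rep": rep_grid,
                    "endpoint_reversed": reversed_flag,
                    "rating": rating,
                }))
    out = pd.concat(frames, ignore_index=True)
    return out[list(TRIAL_COLUMNS)]


def _bimodal_ratings(rng: np.random.Generator, p: PiecewiseParams,
                     step_grid: np.ndarray,
                     config: PopulationConfig) -> np.ndarray:
    sd = p.noise_sd
    lo_mean = float(_truncnorm_mean(0.0, sd))
    hi_mean = float(_truncnorm_mean(100.0, sd))
    if config.bimodal_weight_mode == "matched":
        target = _piecewise_mean(step_grid.astype(float), p.lower, p.upper,
                                 p.crossover, p.slope)
        w = np.clip((target - lo_mean) / (hi_mean - lo_mean), 0.0, 1.0)
    else:
        w = expit(config.bimodal_weight_steepness
                  * (step_grid.astype(float) - p.crossover))
    hi = rng.random(len(step_grid)) < w
    centers = np.where(hi, 100.0, 0.0)
    return _sample_truncnorm(rng, centers, np.full(len(step_grid), sd))


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

_ITEM_LOADING = 0.7  # latent loading of each item on the scale factor


def _discretize(latent: np.ndarray, k: int) -> np.ndarray:
    """Map standard-normal latents to 1..k with equal category probabilities."""
    thresholds = ndtri(np.arange(1, k) / k)
    return 1 + np.sum(latent[..., None] > thresholds[None, :], axis=-1)


def _score_attenuation(n_items: int, k: int, rng: np.random.Generator,
                       n_phantom: int = 8000) -> float:
    """corr(total score, scale latent) under the item-generation model.

    Used to disattenuate requested score-level correlations so the
    *observed* total-score correlations hit their targets.
    """
    z = rng.standard_normal(n_phantom)
    lam = _ITEM_LOADING
    items = (lam * z[:, None]
             + math.sqrt(1 - lam * lam) * rng.standard_normal((n_phantom, n_items)))
    total = _discretize(items, k).sum(axis=1)
    return float(np.corrcoef(total, z)[0, 1])


def generate_questionnaires(
    profiles: Sequence[ListenerProfile],
    assoc: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    aq_pswq_rho: float = 0.55,
    schemes: Mapping[str, "object"] | None = None,
) -> pd.DataFrame:
    """Simulate item-level questionnaire responses for a cohort.

    ``assoc`` maps a scale name to target correlations
    ``(with_consistency_trait, with_slope_trait)`` of the *total score*;
    the default (None) makes every score independent of the latent traits.
    ``aq_pswq_rho`` is the target correlation between AQ and PSWQ totals.
    Requested correlations are disattenuated internally for item-level
    discretization noise, so the empirical score-level correlations match
    the targets; a request too strong to be representable after
    disattenuation raises a configuration error.

    Returns a long table (subject_id, scale, item, response); reverse-keyed
    items (per the scoring schemes) are emitted pre-flipped so that scoring
    restores the intended direction.
    """
    from .traits import default_schemes  # local import: traits has no dep on us

    schemes = dict(schemes) if schemes is not None else default_schemes()
    assoc = dict(assoc) if assoc else {}
    for name in assoc:
        if name not in schemes:
            raise ValueError(f"assoc given for unknown scale {name!r}")

    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    n = len(profiles)
    t_cons = np.array([p.consistency_trait for p in profiles])
    t_slope = np.array([p.slope_trait for p in profiles])

    atten = {name: _score_attenuation(s.n_items,
                                      s.max_response - s.min_response + 1, rng)
             for name, s in schemes.items()}

    # latent AQ/PSWQ cores share a factor to reproduce their correlation
    wanted = aq_pswq_rho
    if not (-1.0 < wanted < 1.0):
        raise ValueError("aq_pswq_rho must lie in (-1, 1)")
    if "AQ" in schemes and "PSWQ" in schemes and wanted != 0.0:
        r_lat = wanted / (atten["AQ"] * atten["PSWQ"])
        if not abs(r_lat) < 1.0:
            raise ValueError("aq_pswq_rho too strong to represent after "
                             "item-level attenuation")
    else:
        r_lat = 0.0
    g = rng.standard_normal(n)
    cores = {}
    for name in schemes:
        e = rng.standard_normal(n)
        if name in ("AQ", "PSWQ") and r_lat != 0.0:
            sign = 1.0 if (r_lat > 0 or name == "AQ") else -1.0
            cores[name] = (sign * math.sqrt(abs(r_lat)) * g
                           + math.sqrt(1 - abs(r_lat)) * e)
        else:
            cores[name] = e

    frames = []
    for name, scheme in schemes.items():
        a_c, a_s = assoc.get(name, (0.0, 0.0))
        # disattenuate so the total-score correlation hits the request
        b_c = a_c / atten[name]
        b_s = a_s / atten[name]
        if b_c * b_c + b_s * b_s > 1.0:
            raise ValueError(
                f"assoc for {name!r} too strong after disattenuation "
                f"(needs b_c^2 + b_s^2 <= 1, got {b_c:.3f}, {b_s:.3f})")
        resid = math.sqrt(1.0 - b_c * b_c - b_s * b_s)
        z = b_c * t_cons + b_s * t_slope + resid * cores[name]
        lam = _ITEM_LOADING
        item_latent = (lam * z[:, None] + math.sqrt(1 - lam * lam)
                       * rng.standard_normal((n, scheme.n_items)))
        k = scheme.max_response - scheme.min_response + 1
        responses = _discretize(item_latent, k)
        responses = responses + (scheme.min_response - 1)
        # pre-flip reverse-keyed items so scoring recovers the direction
        for item in scheme.reverse_items:
            col = item - 1
            responses[:, col] = (scheme.min_response + scheme.max_response
                                 - responses[:, col])
        frames.append(pd.DataFrame({
            "subject_id": np.repeat([p.subject_id for p in profiles],
                                    scheme.n_items),
            "scale": name,
            "item": np.tile(np.arange(1, scheme.n_items + 1), n),
            "response": responses.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)
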