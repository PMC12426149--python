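"""End-to-end reproducible runs: simulate/read -> align -> exclude -> fit ->
indices -> trait correlations -> questionnaire regressions.

One global seed deterministically derives per-stage seeds (SeedSequence
spawn keys), every stage writes its artifact under the run directory
without touching upstream artifacts, and the MCMC stage is cached by a
content hash of its inputs.  The run report is a pydantic model, so it
validates against a published JSON schema and round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__ as _pkg_version
from . import model as _model
from . import simulate as _simulate
from . import traits as _traits
from . import vas_io as _vas_io

# machine-readable error codes, mapped to CLI exit codes
CODE_VALIDATION = "validation_error"
CODE_CONVERGENCE = "convergence_error"
CODE_IO = "io_error"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}] {code}: {message}")
        self.stage = stage
        self.code = code


@dataclasses.dataclass
class RunConfig:
    """Everything one run needs; loadable from a YAML mapping."""

    outdir: str = "vascat_run"
    seed: int = 1  # mandatory single knob; all stage seeds derive from it
    trials_path: str | None = None  # None -> synthetic cohort
    questionnaires_path: str | None = None
    population: dict[str, Any] = dataclasses.field(default_factory=dict)
    exclusion: dict[str, Any] = dataclasses.field(default_factory=dict)
    fit: dict[str, Any] = dataclasses.field(default_factory=dict)
    pooled: bool = False
    allow_nonconverged: bool = False
    scale: str = "latent"  # or "natural"
    correlation_method: str = "pearson"
    alpha: float = 0.05
    questionnaire_assoc: dict[str, Any] = dataclasses.field(default_factory=dict)
    aq_pswq_rho: float = 0.55
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", CODE_VALIDATION,
                                f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineError("config", CODE_VALIDATION, "seed is mandatory")
        for key in ("trials_path", "questionnaires_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise PipelineError("config", CODE_VALIDATION,
                                    f"{key} does not exist: {p}")
        if self.scale not in ("latent", "natural"):
            raise PipelineError("config", CODE_VALIDATION,
                                f"bad scale {self.scale!r}")

    def stage_seed(self, stage_index: int) -> int:
        ss = np.random.SeedSequence(entropy=int(self.seed),
                                    spawn_key=(stage_index,))
        return int(ss.generate_state(1)[0] % (2 ** 31))


class StageCounts(BaseModel):
    generated: int = 0
    read: int = 0
    retained: int = 0
    excluded: int = 0
    fitted_continua: int = 0
    index_rows: int = 0

    @model_validator(mode="after")
    def _reconciled(self) -> "StageCounts":
        if self.read and self.read != self.retained + self.excluded:
            raise ValueError(
                f"count mismatch: read={self.read} != retained="
                f"{self.retained} + excluded={self.excluded}")
        return self


class RunReport(BaseModel):
    config: dict[str, Any]
    versions: dict[str, str]
    counts: StageCounts
    diagnostics: dict[str, dict[str, float | bool]] = Field(default_factory=dict)
    artifacts: dict[str, str] = Field(default_factory=dict)
    wall_clock_s: dict[str, float] = Field(default_factory=dict)
    seeds: dict[str, int] = Field(default_factory=dict)


def make_report(config: RunConfig, counts: StageCounts,
                diagnostics: dict, artifacts: dict[str, str],
                wall_clock: dict[str, float],
                seeds: dict[str, int]) -> RunReport:
    """Assemble and validate the run report (hard error on count mismatch)."""
    import arviz
    import scipy
    import statsmodels
    try:
        report = RunReport(
            config=dataclasses.asdict(config),
            versions={
                "vascat": _pkg_version,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "arviz": arviz.__version__,
                "statsmodels": statsmodels.__version__,
            },
            counts=counts,
            diagnostics=diagnostics,
            artifacts=artifacts,
            wall_clock_s=wall_clock,
            seeds=seeds,
        )
    except Exception as exc:  # count reconciliation failures land here
        raise PipelineError("report", CODE_VALIDATION, str(exc)) from exc
    return report


def _hash_fit_inputs(trials: pd.DataFrame, spec: _model.HierarchicalSpec,
                     pooled: bool) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(trials, index=False).to_numpy().tobytes())
    h.update(json.dumps(dataclasses.asdict(spec), sort_keys=True).encode())
    h.update(b"pooled" if pooled else b"per-continuum")
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage, writing artifacts under ``config.outdir``.

    Identical config + seed reproduces identical index tables and
    correlation summaries.  Any stage failure aborts with the stage name
    and a machine-readable code; non-converged fits abort unless
    ``allow_nonconverged``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = dict(generated=0, read=0, retained=0, excluded=0,
                  fitted_continua=0, index_rows=0)
    artifacts: dict[str, str] = {}
    wall: dict[str, float] = {}
    seeds: dict[str, int] = {}
    diag_summary: dict[str, dict] = {}

    # ---- stage 1: simulate or read -------------------------------------
    t0 = time.perf_counter()
    if config.trials_path is None:
        seeds["simulate"] = config.stage_seed(1)
        pop = _simulate.PopulationConfig(**{**config.population,
                                            "seed": seeds["simulate"]})
        profiles = _simulate.sample_population(pop)
        trials = _simulate.generate_trials(profiles, pop)
        counts["generated"] = len(trials)
        trials_path = outdir / "trials.csv"
        _vas_io.write_trials(trials, trials_path)
        artifacts["trials"] = str(trials_path)
        q_seed = config.stage_seed(2)
        seeds["questionnaires"] = q_seed
        assoc = {k: tuple(v) for k, v in config.questionnaire_assoc.items()}
        questionnaires = _simulate.generate_questionnaires(
            profiles, assoc=assoc or None, seed=q_seed,
            aq_pswq_rho=config.aq_pswq_rho)
        q_path = outdir / "questionnaires.csv"
        questionnaires.to_csv(q_path, index=False)
        artifacts["questionnaires"] = str(q_path)
        trials = _vas_io.read_trials(trials_path)
    else:
        try:
            trials = _vas_io.read_trials(config.trials_path)
        except _vas_io.TrialValidationError as exc:
            raise PipelineError("read", CODE_VALIDATION, str(exc)) from exc
        questionnaires = None
        if config.questionnaires_path is not None:
            questionnaires = pd.read_csv(config.questionnaires_path)
    counts["read"] = len(trials["subject_id"].unique())
    wall["simulate_or_read"] = time.perf_counter() - t0

    # ---- stage 2: align + exclusion ------------------------------------
    t0 = time.perf_counter()
    aligned = _vas_io.align_ratings(trials)
    pre_path = outdir / "trials_preprocessed.csv"
    _vas_io.write_trials(aligned, pre_path)
    artifacts["preprocessed"] = str(pre_path)
    excl = _vas_io.apply_exclusion(aligned, **config.exclusion)
    counts["retained"] = len(excl.retained)
    counts["excluded"] = len(excl.excluded)
    excl_path = outdir / "exclusion_report.csv"
    excl.report.to_csv(excl_path, index=False)
    artifacts["exclusion_report"] = str(excl_path)
    retained = aligned[aligned["subject_id"].isin(excl.retained)]
    design = _vas_io.validate_design(
        trials,
        n_steps=int(trials["step"].max()),
        n_continua=trials["continuum_id"].nunique(),
        n_reps_per_session=int(trials["rep"].max()),
        n_sessions=int(trials["session"].max()),
    )
    (outdir / "design_report.json").write_text(json.dumps({
        "expected_per_subject": design.expected_per_subject,
        "mismatching_subjects": [str(s) for s in design.mismatches],
    }, indent=2))
    artifacts["design_report"] = str(outdir / "design_report.json")
    wall["preprocess"] = time.perf_counter() - t0

    # ---- stage 3: hierarchical fits ------------------------------------
    t0 = time.perf_counter()
    seeds["fit"] = config.stage_seed(3)
    spec = _model.HierarchicalSpec(**{**config.fit, "seed": seeds["fit"]})
    posteriors: dict[object, _model.HierarchicalPosterior] = {}
    fit_dir = outdir / "posteriors"
    fit_dir.mkdir(exist_ok=True)
    if config.pooled:
        groups = [(None, retained)]
    else:
        groups = list(retained.groupby("continuum_id", sort=True))
    for cid, sub in groups:
        key = "pooled" if cid is None else str(cid)
        cache_file = fit_dir / f"{key}.nc"
        digest = _hash_fit_inputs(sub.reset_index(drop=True), spec,
                                  config.pooled)
        manifest = fit_dir / f"{key}.hash"
        if cache_file.exists() and manifest.exists() \
                and manifest.read_text() == digest:
            import arviz as az
            idata = az.from_netcdf(cache_file)
            post = _model.HierarchicalPosterior(
                idata=idata,
                subject_ids=list(idata.posterior.coords["subject"].values),
                item_ids=(list(idata.posterior.coords["item"].values)
                          if "item" in idata.posterior.coords else []),
                spec=spec, continuum_id=cid)
        else:
            try:
                if config.pooled:
                    post = _model.fit_pooled(sub, spec)
                else:
                    post = _model.fit_continuum(sub, spec)
            except _model.DegenerateDataError as exc:
                raise PipelineError("fit", CODE_VALIDATION, str(exc)) from exc
            post.idata.to_netcdf(cache_file)
            manifest.write_text(digest)
        report = post.diagnostics()
        diag_summary[key] = {
            "max_rhat": (None if not report.rhat_available
                         else float(report.max_rhat)),
            "min_ess": float(report.min_ess),
            "passed": bool(report.passed),
        }
        if not report.passed and not config.allow_nonconverged:
            raise PipelineError(
                "fit", CODE_CONVERGENCE,
                f"fit for {key} failed convergence checks ({report}); "
                "re-run with allow_nonconverged to proceed anyway")
        posteriors[cid if cid is not None else "pooled"] = post
        counts["fitted_continua"] += (len(post.item_ids) if config.pooled
                                      else 1)
    artifacts["posteriors"] = str(fit_dir)
    wall["fit"] = time.perf_counter() - t0

    # ---- stage 4: indices ----------------------------------------------
    t0 = time.perf_counter()
    if config.pooled:
        # subject theta in the pooled fit is the fixed+subject part shared
        # across continua; add item intercepts to index per continuum
        post = posteriors["pooled"]
        theta = post.idata.posterior["subject_theta"].values
        item = post.idata.posterior["item_theta"].values
        rows = []
        p_eta = _model.PARAM_NAMES.index("eta")
        p_nu = _model.PARAM_NAMES.index("nu")
        for k, cid in enumerate(post.item_ids):
            eta = (theta[..., p_eta] + item[..., k, p_eta][..., None]).mean((0, 1))
            nu = (theta[..., p_nu] + item[..., k, p_nu][..., None]).mean((0, 1))
            if config.scale == "natural":
                eta, nu = np.exp(eta), np.exp(nu)
            rows.append(pd.DataFrame({
                "subject_id": post.subject_ids, "continuum_id": cid,
                "slope_index": eta, "variability_index": nu}))
        indices = pd.concat(rows, ignore_index=True)
    else:
        indices = _traits.extract_indices(posteriors, scale=config.scale)
    counts["index_rows"] = len(indices)
    idx_path = outdir / "indices.csv"
    indices.to_csv(idx_path, index=False)
    artifacts["indices"] = str(idx_path)
    wall["indices"] = time.perf_counter() - t0

    # ---- stage 5: trait correlations -----------------------------------
    t0 = time.perf_counter()
    corr_out = {}
    for index_type in _traits.INDEX_COLUMNS:
        summary = _traits.pairwise_correlations(
            indices, index_type=index_type,
            method=config.correlation_method, alpha=config.alpha)
        corr_out[index_type] = {
            "mean_r": summary.mean_r,
            "fisher_z_mean_r": summary.fisher_z_mean_r,
            "critical_r": summary.critical_r,
            "n": summary.n,
            "n_pairs": len(summary.coefficients),
            "coefficients": summary.coefficients.tolist(),
            "pairs": ["|".join(map(str, p)) for p in summary.pair_labels],
        }
        summary.matrix.to_csv(outdir / f"correlations_{index_type}.csv")
    (outdir / "correlations.json").write_text(
        json.dumps(corr_out, indent=2))
    artifacts["correlations"] = str(outdir / "correlations.json")
    wall["traits"] = time.perf_counter() - t0

    # ---- stage 6: questionnaire regressions ----------------------------
    t0 = time.perf_counter()
    if questionnaires is not None:
        scores = _traits.score_all(questionnaires)
        scores = scores[scores["subject_id"].isin(excl.retained)]
        reg_out = {}
        for index_type in _traits.INDEX_COLUMNS:
            avg = _traits.average_index(indices, index_type)
            merged = avg.merge(scores, on="subject_id")
            result = _traits.regress_indices(
                merged["mean_index"],
                merged[["PSWQ_total", "UPPS_total", "AQ_total"]])
            reg_out[index_type] = {
                "coefficients": result.coef_table.to_dict(orient="records"),
                "F": result.f_stat, "df1": result.df1, "df2": result.df2,
                "p": result.f_pvalue, "adj_r_squared": result.adj_r_squared,
                "n": result.n,
            }
        (outdir / "regressions.json").write_text(json.dumps(reg_out, indent=2))
        artifacts["regressions"] = str(outdir / "regressions.json")
    wall["regress"] = time.perf_counter() - t0

    report = make_report(
        config,
        StageCounts(**counts),
        diag_summary,
        artifacts,
        wall,
        seeds,
    )
    (outdir / "report.json").write_text(report.model_dump_json(indent=2))
    return report
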