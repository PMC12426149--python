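"""Trial-table IO, rating alignment, exclusion filtering, design validation.

Trial tables are long-format CSVs with one row per VAS trial:
``subject_id, continuum_id, step (1-9), session, rep, endpoint_reversed
(0/1), rating (float 0-100)``.  Ratings are stored raw; the polarity flag
records which endpoint sat on which side of the scale so that
:func:`align_ratings` can put every psychometric function on a rising
scale (``aligned = 100 - raw`` when reversed).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject_id", "continuum_id", "step", "session", "rep",
                    "endpoint_reversed", "rating")

_NUMERIC = {"step": "Int64", "session": "Int64", "rep": "Int64",
            "endpoint_reversed": "Int64", "rating": "float64"}


class TrialValidationError(ValueError):
    """Malformed or out-of-range trial rows; carries offending row numbers."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


def read_trials(path) -> pd.DataFrame:
    """Read and validate a long-format trial CSV.

    Raises :class:`TrialValidationError` listing the offending data-row
    numbers (1-based, excluding the header) for non-numeric fields, ratings
    outside [0, 100], or steps below 1.  Unknown columns produce a warning
    and are kept.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(
            f"missing required columns: {missing}", rows=[])
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS
             and c != "rating_aligned"]
    if extra:
        warnings.warn(f"unknown columns kept as-is: {extra}", stacklevel=2)

    bad_rows: dict[int, str] = {}
    out = df.copy()
    for col, dtype in _NUMERIC.items():
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna()
        for idx in out.index[bad]:
            bad_rows.setdefault(int(idx) + 1, f"non-numeric {col}")
        out[col] = converted
    if bad_rows:
        rows = sorted(bad_rows)
        detail = "; ".join(f"row {r}: {bad_rows[r]}" for r in rows[:10])
        raise TrialValidationError(
            f"{len(rows)} malformed row(s): {detail}", rows=rows)

    oob = ~out["rating"].between(0.0, 100.0)
    if oob.any():
        rows = [int(i) + 1 for i in out.index[oob]]
        raise TrialValidationError(
            f"rating outside [0, 100] in row(s) {rows[:20]}", rows=rows)
    bad_step = out["step"] < 1
    if bad_step.any():
        rows = [int(i) + 1 for i in out.index[bad_step]]
        raise TrialValidationError(
            f"step below 1 in row(s) {rows[:20]}", rows=rows)

    for col in ("step", "session", "rep", "endpoint_reversed"):
        out[col] = out[col].astype(int)
    return out


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table; full float precision so round-trips are exact."""
    df.to_csv(path, index=False)


def align_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``rating_aligned`` so every psychometric function rises with step.

    ``rating_aligned = rating`` where ``endpoint_reversed == 0`` and
    ``100 - rating`` where it is 1.  Always recomputed from the raw rating,
    hence idempotent.
    """
    if "endpoint_reversed" not in df.columns:
        raise ValueError("endpoint_reversed column required to align ratings")
    flag = df["endpoint_reversed"]
    if flag.isna().any():
        rows = [int(i) + 1 for i in df.index[flag.isna()]]
        raise ValueError(f"endpoint_reversed missing in row(s) {rows[:20]}")
    out = df.copy()
    out["rating_aligned"] = np.where(flag.astype(int) == 1,
                                     100.0 - out["rating"], out["rating"])
    return out


@dataclass
class ExclusionResult:
    retained: list
    excluded: list
    report: pd.DataFrame  # subject_id, step1_mean, step9_mean, excluded, reason


def apply_exclusion(
    df: pd.DataFrame,
    lower_threshold: float = 25.0,
    upper_threshold: float = 75.0,
    combine: str = "and",
    mode: str = "mean",
    n_steps: int | None = None,
) -> ExclusionResult:
    """Data-quality filter removing listeners who cannot place the endpoints.

    Default (``mode='mean'``, ``combine='and'``): a subject is excluded iff
    their mean aligned rating over all Step-1 trials exceeds
    ``lower_threshold`` AND their mean over all Step-9 (last step) trials
    falls below ``upper_threshold`` — failure at *both* unambiguous
    endpoints, i.e. an inability to discriminate even the clear tokens.
    ``combine='or'`` excludes on failure at either end.

    ``mode='proportion'`` is the alternative trial-share reading: a subject
    fails the lower end iff more than ``lower_threshold`` percent of their
    Step-1 trials are rated above midscale (50), and the upper end iff more
    than ``100 - upper_threshold`` percent of Step-9 trials fall below
    midscale.
    """
    if "rating_aligned" not in df.columns:
        raise ValueError("aligned ratings required; run align_ratings first")
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    if mode not in ("mean", "proportion"):
        raise ValueError("mode must be 'mean' or 'proportion'")
    last = int(n_steps) if n_steps is not None else int(df["step"].max())

    rows = []
    for sid, g in df.groupby("subject_id", sort=True):
        s1 = g.loc[g["step"] == 1, "rating_aligned"]
        s9 = g.loc[g["step"] == last, "rating_aligned"]
        if len(s1) == 0 or len(s9) == 0:
            raise ValueError(
                f"subject {sid!r} has no trials at step 1 or step {last}; "
                "the exclusion rule is undefined")
        if mode == "mean":
            m1, m9 = float(s1.mean()), float(s9.mean())
            fail_low = m1 > lower_threshold
            fail_high = m9 < upper_threshold
        else:
            m1 = float((s1 > 50.0).mean() * 100.0)
            m9 = float((s9 < 50.0).mean() * 100.0)
            fail_low = m1 > lower_threshold
            fail_high = m9 > (100.0 - upper_threshold)
        excluded = (fail_low and fail_high) if combine == "and" \
            else (fail_low or fail_high)
        if excluded:
            ends = []
            if fail_low:
                ends.append("step-1")
            if fail_high:
                ends.append(f"step-{last}")
            reason = "failed " + " and ".join(ends)
        else:
            reason = ""
        rows.append({"subject_id": sid, "step1_mean": m1, "step9_mean": m9,
                     "excluded": excluded, "reason": reason})
    report = pd.DataFrame(rows)
    retained = report.loc[~report["excluded"], "subject_id"].tolist()
    excluded = report.loc[report["excluded"], "subject_id"].tolist()
    return ExclusionResult(retained=retained, excluded=excluded, report=report)


@dataclass
class DesignReport:
    expected_per_subject: int
    counts: pd.DataFrame  # subject_id, n_trials, matches
    mismatches: list

    @property
    def ok(self) -> bool:
        return not self.mismatches


def validate_design(
    df: pd.DataFrame,
    n_steps: int = 9,
    n_continua: int = 8,
    n_reps_per_session: int = 3,
    n_sessions: int = 2,
) -> DesignReport:
    """Check that every subject carries the full crossed design.

    Expected per-subject trial count is the product of the design factors
    (9 x 8 x 3 x 2 = 432 for the default design); the report lists any
    subject whose count deviates.  Report-only, never raises.
    """
    expected = n_steps * n_continua * n_reps_per_session * n_sessions
    counts = (df.groupby("subject_id", sort=True).size()
              .rename("n_trials").reset_index())
    counts["matches"] = counts["n_trials"] == expected
    mismatches = counts.loc[~counts["matches"], "subject_id"].tolist()
    return DesignReport(expected_per_subject=expected, counts=counts,
                        mismatches=mismatches)


# ---------------------------------------------------------------------------
# Stimulus acoustic metadata
# ---------------------------------------------------------------------------

def load_stimulus_table() -> pd.DataFrame:
    """Acoustic endpoint measurements bundled with the package.

    One row per continuum endpoint token; which acoustic columns are
    populated depends on the contrast class (formants/duration for vowels,
    VOT and vowel duration for stop voicing, spectral moments for the
    fricative place pair).
    """
    ref = importlib.resources.files("vascat.data") / "stimulus_acoustics.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)


def cue_difference(table: pd.DataFrame, continuum_id: str, cue: str) -> float:
    """Absolute acoustic difference between the two endpoints of a continuum.

    ``cue`` is a column of the stimulus table (e.g. ``"VOT_ms"``); raises if
    the continuum is unknown, does not have exactly two endpoints, or the
    cue is not measured for its contrast class.
    """
    if cue not in table.columns:
        raise KeyError(f"unknown cue column {cue!r}")
    rows = table.loc[table["continuum_id"] == continuum_id]
    if len(rows) == 0:
        raise KeyError(f"unknown continuum {continuum_id!r}")
    if len(rows) != 2:
        raise ValueError(f"continuum {continuum_id!r} must have exactly two "
                         f"endpoint rows, found {len(rows)}")
    vals = rows[cue].astype(float)
    if vals.isna().any():
        raise ValueError(
            f"cue {cue!r} is not measured for continuum {continuum_id!r}")
    return float(abs(vals.iloc[0] - vals.iloc[1]))
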