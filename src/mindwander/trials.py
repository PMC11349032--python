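"""Thought-probe trial tables: recoding, filtering, and behavioral summaries.

Raw probe responses are on a 1-8 task-focus Likert scale (1 = fully focused
endpoints as presented to the participant) with "9" signalling distraction
that is not mind-wandering. All analyses use the reverse-coded rating
(9 - raw), so higher ratings mean more mind-wandering, and a trial is a
mind-wandering trial when the reverse-coded rating is 5 or higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import spearman_corr, CorrelationResult

__all__ = [
    "DISTRACTED_RESPONSE",
    "MW_THRESHOLD",
    "reverse_code",
    "filter_and_flag",
    "ContentCountVector",
    "content_counts",
    "content_distance",
    "nuisance_correlations",
    "summarize",
]

DISTRACTED_RESPONSE = 9
MW_THRESHOLD = 5  # reverse-coded rating >= 5 => mind-wandering


def reverse_code(response_raw: int):
    """Reverse-code one raw response: 9 - raw for 1-8, ``None`` for the
    distracted "9" response. Raises on out-of-range values."""
    r = int(response_raw)
    if not 1 <= r <= 9:
        raise ValueError(f"response_raw must be in 1..9, got {response_raw}")
    if r == DISTRACTED_RESPONSE:
        return None
    return 9 - r


def filter_and_flag(records: pd.DataFrame) -> pd.DataFrame:
    """Recode and annotate a raw events table.

    Adds columns: ``rating`` (reverse-coded, NaN when distracted),
    ``is_distracted``, ``is_mw`` (rating >= 5), ``trial_index_in_session``
    (order of the probe within its session, counting all probes), and a
    per-run ``run_excluded_constant`` flag for runs whose non-distracted
    ratings show no variation (such runs are excluded from GLM fitting and
    cannot contribute within-run selection contrast).

    Distracted trials are retained in the table with their flag; analysis
    views filter on ``is_distracted``.
    """
    if len(records) == 0:
        raise ValueError("empty trial table")
    df = records.copy()
    raw = df["response_raw"].astype(int)
    bad = ~raw.between(1, 9)
    if bad.any():
        rows = df.index[bad].tolist()
        raise ValueError(f"response_raw out of range 1..9 at rows {rows}")
    df["is_distracted"] = raw == DISTRACTED_RESPONSE
    df["rating"] = np.where(df["is_distracted"], np.nan, 9 - raw)
    df["is_mw"] = (~df["is_distracted"]) & (df["rating"] >= MW_THRESHOLD)
    if "session_id" not in df.columns:
        df["session_id"] = "ses-01"
    if "run_id" not in df.columns:
        df["run_id"] = "run-00"
    df["trial_index_in_session"] = (
        df.sort_values(["session_id", "run_id", "onset"])
        .groupby("session_id")
        .cumcount()
        .reindex(df.index)
    )
    run_const = (
        df[~df["is_distracted"]]
        .groupby("run_id")["rating"]
        .agg(lambda r: len(r) == 0 or r.nunique() <= 1)
    )
    df["run_excluded_constant"] = df["run_id"].map(run_const).fillna(True).astype(bool)
    return df


@dataclass(frozen=True)
class ContentCountVector:
    """Per-option response counts for one categorical probe question,
    tallied over mind-wandering trials only."""

    question_id: str
    option_labels: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != len(self.option_labels):
            raise ValueError("counts and option_labels must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")


def content_counts(table: pd.DataFrame, flag_columns, question_id: str = "content") -> ContentCountVector:
    """Tally content-flag responses over mind-wandering trials."""
    mw = table[table["is_mw"]]
    counts = tuple(int(mw[c].sum()) for c in flag_columns)
    return ContentCountVector(question_id, tuple(flag_columns), counts)


def content_distance(v1: ContentCountVector, v2: ContentCountVector) -> float:
    """Euclidean distance between two subjects' count vectors."""
    if v1.question_id != v2.question_id or v1.option_labels != v2.option_labels:
        raise ValueError("count vectors refer to different questions or options")
    a = np.asarray(v1.counts, dtype=float)
    b = np.asarray(v2.counts, dtype=float)
    return float(np.sqrt(((a - b) ** 2).sum()))


def nuisance_correlations(table: pd.DataFrame) -> dict[str, CorrelationResult]:
    """Spearman correlation of the rating with each nuisance covariate.

    Covariates: mean framewise displacement over the pre-probe window
    (``fd_mean``), onset within run (``onset``), and trial order within
    session (``trial_index_in_session``). Pooled across the subject's runs and
    sessions; distracted trials excluded. Constant covariates are reported as
    undefined (NaN) rather than dropped.
    """
    ok = table[~table["is_distracted"]]
    if len(ok) < 3:
        raise ValueError("need at least 3 non-distracted trials")
    out: dict[str, CorrelationResult] = {}
    for cov in ("fd_mean", "onset", "trial_index_in_session"):
        x = ok[cov].to_numpy(dtype=float)
        y = ok["rating"].to_numpy(dtype=float)
        out[cov] = spearman_corr(x, y)
    return out


def summarize(table: pd.DataFrame) -> dict:
    """Counts and proportions of the trial partition (mind-wandering /
    on-task / distracted) plus the rating histogram."""
    n = len(table)
    n_distracted = int(table["is_distracted"].sum())
    n_mw = int(table["is_mw"].sum())
    n_on = n - n_distracted - n_mw
    ok = table[~table["is_distracted"]]
    hist = ok["rating"].value_counts().sort_index()
    return {
        "n_probes": n,
        "n_mw": n_mw,
        "n_on_task": n_on,
        "n_distracted": n_distracted,
        "prop_mw": n_mw / max(1, n - n_distracted),
        "rating_histogram": {int(k): int(v) for k, v in hist.items()},
    }
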