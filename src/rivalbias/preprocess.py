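"""Trial-level preprocessing: exclusions, priming scores, dominance curves.

The raw outcome of a rivalry trial is categorical (manipulated / fixed /
mixed / none).  To obtain a graded dominance measure per contrast, trials of
one subject and condition are sorted by the contrast of the manipulated
grating and a sliding window of 11 consecutive contrast values is moved along
them; within each window the dominance is the fraction of trials on which the
manipulated grating was reported dominant, with mixed reports counted as 0.5.
The window's value is assigned to the midpoint of its contrast range.  Trials
with no logged response are dropped before windowing, so each window still
spans 11 consecutive remaining contrast values.

Subject exclusions follow the catch-trial response-bias rule: a subject whose
mock-rivalry priming score exceeds the cohort mean by more than two standard
deviations is removed, as is any subject with no logged responses at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (EmptyInputError, InsufficientDataError, PreconditionError,
                     UndefinedStatisticError)

__all__ = [
    "DominanceCurve",
    "ExclusionReport",
    "apply_exclusions",
    "derive_dominance",
    "derive_all_curves",
    "priming_proportion",
    "mock_priming",
]

DEFAULT_WINDOW = 11


@dataclass
class DominanceCurve:
    """Windowed dominance estimates for one subject x condition."""

    subject_id: str
    condition: str
    midpoints: np.ndarray
    dominance: np.ndarray
    window_size: int = DEFAULT_WINDOW

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id, "condition": self.condition,
            "midpoint": self.midpoints, "dominance": self.dominance,
            "window_size": self.window_size,
        })


@dataclass
class ExclusionReport:
    """Which subjects were removed and why, plus the cohort bias statistics."""

    excluded: dict = field(default_factory=dict)  # subject_id -> (reason, value)
    mock_priming_mean: float = float("nan")
    mock_priming_sd: float = float("nan")
    threshold: float = float("nan")


def apply_exclusions(dataset: pd.DataFrame):
    """Remove response-bias outliers and silent subjects.

    Returns the filtered dataset and an :class:`ExclusionReport`.  The
    response-bias metric is the mock-rivalry priming score (cue-matching
    catch responses, mixed counted as 0.5); subjects above the cohort mean
    plus two standard deviations are excluded.
    """
    if len(dataset) == 0:
        raise EmptyInputError("cannot apply exclusions to an empty dataset")
    report = ExclusionReport()

    responded = dataset["response"] != "none"
    n_resp = responded.groupby(dataset["subject_id"]).sum()
    silent = set(n_resp.index[n_resp == 0])
    for sid in sorted(silent):
        report.excluded[sid] = ("no_responses", 0.0)

    alive = dataset[~dataset["subject_id"].isin(silent)]
    catch = alive[alive["is_catch"]]
    if len(catch) == 0:
        raise PreconditionError("dataset has no catch trials; response-bias "
                                "exclusion requires them")
    scores = catch.groupby("subject_id").apply(mock_priming, include_groups=False)
    mean, sd = float(scores.mean()), float(scores.std(ddof=1))
    threshold = mean + 2.0 * sd
    report.mock_priming_mean, report.mock_priming_sd = mean, sd
    report.threshold = threshold
    if sd > 0:
        for sid, val in scores.items():
            if val > threshold:
                report.excluded[sid] = ("response_bias", float(val))

    keep = ~dataset["subject_id"].isin(report.excluded)
    return dataset[keep].reset_index(drop=True), report


def derive_dominance(trials: pd.DataFrame, window_size: int = DEFAULT_WINDOW) -> DominanceCurve:
    """Sliding-window dominance curve for one subject x condition.

    ``trials`` must be rivalry (non-catch) trials of a single subject and
    condition with responses in {manipulated, fixed, mixed}; "none" responses
    must be filtered out upstream.  Trials are sorted by manipulated contrast;
    each window of ``window_size`` consecutive trials yields one point::

        dominance = (#manipulated + 0.5 * #mixed) / window_size

    at the midpoint (min + max) / 2 of the window's contrast range.
    """
    if trials["is_catch"].any():
        raise PreconditionError("catch trials must be removed before windowing")
    if (trials["response"] == "none").any():
        raise PreconditionError('"none" responses must be filtered out first')
    for col in ("subject_id", "condition"):
        if trials[col].nunique() > 1:
            raise PreconditionError(f"trials must come from a single {col}")
    n = len(trials)
    if n < window_size:
        raise InsufficientDataError(
            f"{n} trials < window size {window_size}")

    srt = trials.sort_values("manipulated_contrast", kind="mergesort")
    x = srt["manipulated_contrast"].to_numpy(float)
    score = np.select(
        [srt["response"] == "manipulated", srt["response"] == "mixed"],
        [1.0, 0.5], default=0.0)

    kernel = np.ones(window_size)
    dominance = np.convolve(score, kernel, mode="valid") / window_size
    midpoints = (x[: n - window_size + 1] + x[window_size - 1:]) / 2.0
    return DominanceCurve(
        subject_id=str(trials["subject_id"].iloc[0]),
        condition=str(trials["condition"].iloc[0]),
        midpoints=midpoints, dominance=dominance, window_size=window_size)


def derive_all_curves(dataset: pd.DataFrame, window_size: int = DEFAULT_WINDOW) -> list:
    """Dominance curves for every subject x condition in the dataset."""
    rivalry = dataset[~dataset["is_catch"] & (dataset["response"] != "none")]
    curves = []
    for (sid, cond), grp in rivalry.groupby(["subject_id", "condition"], sort=True):
        curves.append(derive_dominance(grp, window_size=window_size))
    return curves


def priming_proportion(trials: pd.DataFrame) -> float:
    """Fraction of decided rivalry reports that match the imagined stimulus.

    Mixed and "none" trials are removed first; among the rest, a trial counts
    as primed when the reported percept equals the cue.
    """
    decided = trials[~trials["is_catch"]
                     & trials["response"].isin(["manipulated", "fixed"])]
    if len(decided) == 0:
        raise UndefinedStatisticError("no decided (non-mixed) rivalry trials")
    return float((decided["response"] == decided["cue"]).mean())


def mock_priming(catch_trials: pd.DataFrame) -> float:
    """Response-bias score from mock-rivalry catch trials.

    ``(#cue-matching + 0.5 * #mixed) / #responded`` — 0.5 means no bias, 1.0
    means the subject always reported the imagined percept on trials that
    contained no perceptual information.
    """
    if "is_catch" in catch_trials.columns and not catch_trials["is_catch"].all():
        raise PreconditionError("mock_priming expects catch trials only")
    responded = catch_trials[catch_trials["response"] != "none"]
    if len(responded) == 0:
        raise UndefinedStatisticError("no responded catch trials")
    match = (responded["response"] == responded["cue"]).sum()
    mixed = (responded["response"] == "mixed").sum()
    return float((match + 0.5 * mixed) / len(responded))
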