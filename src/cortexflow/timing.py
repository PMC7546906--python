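"""Cytokinesis stage timing and cohort summaries.

Stage intervals are defined by four landmark events: anaphase onset,
shallow equatorial deformation, back-to-back membrane configuration, and
full furrow ingression.  Ring assembly spans anaphase onset to shallow
deformation, furrow initiation spans shallow deformation to back-to-back,
and ring constriction spans back-to-back to full ingression.  Event
annotations are inputs (JSON), not detected from images.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CytokinesisTimeline",
    "stage_intervals",
    "fold_delay",
    "completion_rate",
    "summarize_cohort",
]

_EVENT_ORDER = (
    "anaphase_onset_s",
    "shallow_deformation_s",
    "back_to_back_s",
    "full_ingression_s",
)


@dataclass
class CytokinesisTimeline:
    """Landmark event times (s) for one embryo; any event may be absent."""

    embryo_id: str
    anaphase_onset_s: float | None = None
    shallow_deformation_s: float | None = None
    back_to_back_s: float | None = None
    full_ingression_s: float | None = None
    completed: bool | None = None

    def __post_init__(self) -> None:
        present = [
            (name, getattr(self, name))
            for name in _EVENT_ORDER
            if getattr(self, name) is not None
        ]
        times = [t for _, t in present]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"embryo {self.embryo_id!r}: events out of order: {present}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CytokinesisTimeline":
        return cls(**json.loads(Path(path).read_text()))


def stage_intervals(timeline: CytokinesisTimeline) -> dict[str, float]:
    """Stage durations in seconds; absent event pairs give NaN.

    Intervals are additive: when all four events are present, the three
    stages sum to the anaphase-onset-to-full-ingression span.
    """

    def diff(a: float | None, b: float | None) -> float:
        return b - a if a is not None and b is not None else math.nan

    return {
        "ring_assembly_s": diff(
            timeline.anaphase_onset_s, timeline.shallow_deformation_s
        ),
        "furrow_initiation_s": diff(
            timeline.shallow_deformation_s, timeline.back_to_back_s
        ),
        "ring_constriction_s": diff(
            timeline.back_to_back_s, timeline.full_ingression_s
        ),
    }


def fold_delay(t_perturbed_s: float, t_reference_s: float) -> dict[str, float]:
    """Delay of a perturbed interval relative to a reference.

    Returns the raw ratio and its round-half-up integer fold: medians of
    155, 110 and 298 s against a 53 s reference give three-, two- and
    six-fold delays.
    """
    if t_reference_s <= 0:
        raise ValueError("reference interval must be positive")
    ratio = t_perturbed_s / t_reference_s
    return {"ratio": ratio, "fold": int(math.floor(ratio + 0.5))}


def completion_rate(outcomes: list[bool]) -> int:
    """Percentage of embryos that completed cytokinesis, nearest integer."""
    if not outcomes:
        raise ValueError("no outcomes given")
    return int(math.floor(100.0 * sum(map(bool, outcomes)) / len(outcomes) + 0.5))


def summarize_cohort(
    intervals_by_condition: dict[str, list[float]],
    reference: str,
    outcomes_by_condition: dict[str, list[bool]] | None = None,
) -> pd.DataFrame:
    """Per-condition summary table with fold-delays of medians.

    Reports n, mean, SD, SEM, median and quartiles (linear interpolation)
    per condition, the fold-delay of each condition's median against the
    reference condition, and — when outcomes are given — the completion
    percentage.  SD/SEM are NaN for single-embryo conditions.
    """
    if reference not in intervals_by_condition:
        raise ValueError(f"unknown reference condition {reference!r}")
    ref_median = float(np.median(intervals_by_condition[reference]))
    rows = []
    for cond, vals in intervals_by_condition.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 1:
            raise ValueError(f"condition {cond!r} has no embryos")
        med = float(np.median(arr))
        fd = fold_delay(med, ref_median)
        row = {
            "condition": cond,
            "n": int(arr.size),
            "mean_s": float(arr.mean()),
            "sd_s": float(arr.std(ddof=1)) if arr.size > 1 else math.nan,
            "sem_s": float(arr.std(ddof=1) / math.sqrt(arr.size))
            if arr.size > 1
            else math.nan,
            "median_s": med,
            "q25_s": float(np.percentile(arr, 25)),
            "q75_s": float(np.percentile(arr, 75)),
            "fold_delay_ratio": fd["ratio"],
            "fold_delay": fd["fold"],
        }
        if outcomes_by_condition and cond in outcomes_by_condition:
            row["completion_pct"] = completion_rate(outcomes_by_condition[cond])
        rows.append(row)
    return pd.DataFrame(rows)
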