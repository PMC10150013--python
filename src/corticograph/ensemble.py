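"""Time-based ensemble: from per-segment sub-action predictions to a
whole-movement label and a movement-quality score.

A trial's six predicted (movement, position) labels M[0..5] are compared
against a reference sequence G with a per-segment similarity

    similarity(a, b) = 0                      if a, b from different movements
                       1 - |pos_a - pos_b|/n  otherwise  (n = segments/trial)

and the movement score is the mean similarity over segments.  To classify
the trial, the score against each movement's canonical in-order sequence
[(m,0)..(m,5)] is computed and the best-scoring movement wins.  Scores are
reported on a 0-100 scale for clinical readability.

For assessment, per-segment predictions are additionally bucketed into
close (same movement, position off by <= 3), far (same movement, off by
> 3) and wrong (other movement), and group-level score differences
(e.g. patients vs healthy controls) are tested with an independent-samples
t-test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import MOVEMENTS

__all__ = [
    "MovementScore",
    "similarity",
    "movement_score",
    "classify_movement",
    "canonical_sequence",
    "categorize_predictions",
    "compare_groups",
    "assess",
]

logger = logging.getLogger(__name__)

Label = tuple[str, int]
CLOSE_DISTANCE = 3  # max |position error| still counted as "close"


@dataclass(frozen=True)
class MovementScore:
    """Movement quality in [0, 1]; ``scaled`` is the 0-100 report value."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"score must be in [0, 1], got {self.value}")

    @property
    def scaled(self) -> int:
        return int(round(100 * self.value))


def _check_label(label: Label, n_seg: int) -> None:
    movement, pos = label
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement {movement!r}")
    if not 0 <= pos < n_seg:
        raise ValueError(f"position {pos} out of range for n_seg={n_seg}")


def similarity(a: Label, b: Label, n_seg: int = 6) -> float:
    """Per-segment similarity of two sub-action labels; in [0, 1]."""
    if n_seg < 1:
        raise ValueError("n_seg must be >= 1")
    _check_label(a, n_seg)
    _check_label(b, n_seg)
    if a[0] != b[0]:
        return 0.0
    return 1.0 - abs(a[1] - b[1]) / n_seg


def movement_score(G: list[Label], M: list[Label]) -> MovementScore:
    """Mean per-segment similarity between reference G and prediction M."""
    if len(G) != len(M):
        raise ValueError(f"sequence length mismatch: {len(G)} vs {len(M)}")
    if not G:
        raise ValueError("empty sequences")
    n_seg = len(G)
    return MovementScore(
        float(np.mean([similarity(g, m, n_seg) for g, m in zip(G, M)]))
    )


def canonical_sequence(movement: str, n_seg: int = 6) -> list[Label]:
    """The in-order reference sequence [(m, 0), ..., (m, n_seg-1)]."""
    return [(movement, i) for i in range(n_seg)]


def classify_movement(
    M: list[Label],
    movements: tuple[str, ...] = MOVEMENTS,
    n_seg: int | None = None,
) -> tuple[str, MovementScore]:
    """Pick the movement whose canonical sequence best matches M.

    Ties are broken by the fixed ordering of ``movements`` (push before
    pull) and logged.
    """
    if not movements:
        raise ValueError("empty candidate movement set")
    n_seg = n_seg if n_seg is not None else len(M)
    scores = [
        (m, movement_score(canonical_sequence(m, n_seg), M)) for m in movements
    ]
    best_value = max(s.value for _, s in scores)
    winners = [(m, s) for m, s in scores if s.value == best_value]
    if len(winners) > 1:
        logger.info(
            "movement-score tie between %s at %.4f; keeping %s",
            [m for m, _ in winners], best_value, winners[0][0],
        )
    return winners[0]


def categorize_predictions(G: list[Label], M: list[Label]
                           ) -> tuple[float, float, float]:
    """Proportions of (close, far, wrong) per-segment predictions.

    wrong: predicted movement differs; close: same movement and
    |position error| <= 3; far: same movement, |position error| > 3.
    The three proportions sum to 1.
    """
    if len(G) != len(M):
        raise ValueError(f"sequence length mismatch: {len(G)} vs {len(M)}")
    if not G:
        raise ValueError("empty sequences")
    close = far = wrong = 0
    for g, m in zip(G, M):
        if g[0] != m[0]:
            wrong += 1
        elif abs(g[1] - m[1]) <= CLOSE_DISTANCE:
            close += 1
        else:
            far += 1
    n = len(G)
    return close / n, far / n, wrong / n


def compare_groups(scores_a, scores_b, welch: bool = False
                   ) -> tuple[float, float]:
    """Two-sided independent-samples t-test between two score groups.

    Student's pooled-variance test by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two scores")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("degenerate: zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def assess(
    records: list[dict],
    csv_path=None,
    json_path=None,
    welch: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject assessment report plus group comparison.

    ``records`` holds one dict per trial with keys: subject, group, score
    (in [0, 1]), close, far, wrong.  Returns a per-subject DataFrame
    (mean/sd of scores, mean category proportions) and a summary dict with
    the healthy-vs-patient t statistic and p-value (None if only one group
    is present).  Optionally writes the CSV and JSON artifacts.
    """
    df = pd.DataFrame.from_records(records)
    required = {"subject", "group", "score", "close", "far", "wrong"}
    if not required.issubset(df.columns):
        raise ValueError(f"records must contain columns {sorted(required)}")
    per_subject = (
        df.groupby(["subject", "group"], as_index=False)
        .agg(n_trials=("score", "size"), mean_score=("score", "mean"),
             sd=("score", "std"), close=("close", "mean"),
             far=("far", "mean"), wrong=("wrong", "mean"))
    )
    per_subject["sd"] = per_subject["sd"].fillna(0.0)
    summary: dict = {
        "n_trials": int(len(df)),
        "mean_score_by_group": {
            g: float(v) for g, v in df.groupby("group")["score"].mean().items()
        },
    }
    groups = sorted(df["group"].unique())
    if len(groups) == 2:
        a = df.loc[df["group"] == groups[0], "score"]
        b = df.loc[df["group"] == groups[1], "score"]
        t, p = compare_groups(a, b, welch=welch)
        summary.update({"group_a": groups[0], "group_b": groups[1],
                        "t": t, "p": p})
    if csv_path is not None:
        per_subject.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary, indent=2))
    return per_subject, summary
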