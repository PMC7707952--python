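"""Case-level (per-patient) classification from per-nucleus predictions.

A slide's nuclei are classified individually by the RBF network; the case
classifier then calls the patient benign when the number (numeric mode) or
percentage (percent mode) of benign-classified nuclei strictly exceeds a
threshold, and malignant otherwise.  The threshold is chosen on the training
cases only, by sweeping a fixed grid (counts 1..100 step 1; percentages
1.0..100.0 step 0.1) and picking the candidate that best balances case-level
sensitivity and specificity (malignant = positive class).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .rbf import BENIGN, MALIGNANT, NucleusPrediction

__all__ = [
    "CaseTally",
    "CaseThreshold",
    "tally_case",
    "classify_case",
    "optimize_threshold",
    "case_score",
    "threshold_grid",
]


@dataclass(frozen=True)
class CaseTally:
    """Benign-prediction tally for one patient's structures."""

    case_id: str
    n_structures: int
    n_benign_pred: int

    def __post_init__(self) -> None:
        if self.n_structures < 1:
            raise ValueError(f"case {self.case_id}: inadequate specimen (no structures)")
        if not 0 <= self.n_benign_pred <= self.n_structures:
            raise ValueError(f"case {self.case_id}: benign count out of range")

    @property
    def pct_benign_pred(self) -> float:
        return 100.0 * self.n_benign_pred / self.n_structures


@dataclass
class CaseThreshold:
    """Optimized decision threshold plus the full sweep it was selected from."""

    mode: str  # "numeric" | "percent"
    value: float
    sweep_record: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"mode": self.mode, "value": self.value, "sweep_record": self.sweep_record},
            indent=1,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CaseThreshold":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            source = Path(source).read_text()
        doc = json.loads(source)
        return cls(mode=doc["mode"], value=doc["value"], sweep_record=doc["sweep_record"])


def tally_case(case_id: str, predictions: Iterable[NucleusPrediction | str]) -> CaseTally:
    """Count benign-classified structures for one case.

    Accepts NucleusPrediction objects or bare label strings.
    """
    labels = [p.label if isinstance(p, NucleusPrediction) else p for p in predictions]
    if not labels:
        raise ValueError(f"case {case_id}: inadequate specimen (no structures)")
    bad = set(labels) - {BENIGN, MALIGNANT}
    if bad:
        raise ValueError(f"case {case_id}: unknown labels {sorted(bad)}")
    return CaseTally(
        case_id=case_id,
        n_structures=len(labels),
        n_benign_pred=sum(1 for lab in labels if lab == BENIGN),
    )


def _stat(tally: CaseTally, mode: str) -> float:
    if mode == "numeric":
        return float(tally.n_benign_pred)
    if mode == "percent":
        return tally.pct_benign_pred
    raise ValueError(f"unknown mode {mode!r}")


def classify_case(tally: CaseTally, threshold: CaseThreshold) -> str:
    """Benign iff the tally statistic STRICTLY exceeds the threshold."""
    return BENIGN if _stat(tally, threshold.mode) > threshold.value else MALIGNANT


def case_score(tally: CaseTally, mode: str) -> float:
    """ROC score: negated benign statistic, so larger = more malignant."""
    return -_stat(tally, mode)


def threshold_grid(mode: str) -> np.ndarray:
    """Candidate grid: counts 1..100 step 1, or percentages 1.0..100.0 step 0.1."""
    if mode == "numeric":
        return np.arange(1, 101, dtype=float)
    if mode == "percent":
        return np.round(np.arange(10, 1001) / 10.0, 1)
    raise ValueError(f"unknown mode {mode!r}")


def optimize_threshold(
    tallies: Sequence[CaseTally],
    truth: Sequence[str],
    mode: str,
) -> CaseThreshold:
    """Sweep the full threshold grid on training cases and pick the balance point.

    For every candidate t the rule "benign iff statistic > t" is scored by
    case-level sensitivity and specificity; the winner minimizes
    |sensitivity − specificity|, ties broken by higher overall accuracy and
    then by the smaller threshold.  The complete sweep is retained.
    """
    if len(tallies) != len(truth):
        raise ValueError("tallies and truth must be aligned")
    truth_arr = np.asarray(truth)
    if not ((truth_arr == BENIGN).any() and (truth_arr == MALIGNANT).any()):
        raise ValueError("both classes must be present to optimize a threshold")
    stats = np.array([_stat(t, mode) for t in tallies])
    is_mal = truth_arr == MALIGNANT
    n_mal, n_ben = int(is_mal.sum()), int((~is_mal).sum())

    grid = threshold_grid(mode)
    # predicted malignant iff statistic <= t
    pred_mal = stats[None, :] <= grid[:, None]  # (n_thresholds, n_cases)
    tp = (pred_mal & is_mal).sum(axis=1)
    tn = (~pred_mal & ~is_mal).sum(axis=1)
    sens = tp / n_mal
    spec = tn / n_ben
    acc = (tp + tn) / len(stats)

    order = np.lexsort((grid, -acc, np.abs(sens - spec)))
    best = order[0]
    sweep = [
        {
            "threshold": float(g),
            "sensitivity": float(se),
            "specificity": float(sp),
            "accuracy": float(a),
        }
        for g, se, sp, a in zip(grid, sens, spec, acc)
    ]
    return CaseThreshold(mode=mode, value=float(grid[best]), sweep_record=sweep)
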