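"""Comparison of forum signals against reference signals.

Over an evaluation universe of drug-event pairs (typically the pairs
attested in both sources), forum signal flags are scored against reference
flags (or ground-truth labels) via the 2x2 confusion table, the five
classical performance indicators, and ROC/AUC obtained by sweeping a
threshold over a continuous forum metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dispro import DEFINITIONS


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def m1(self) -> int:  # forum-positive row total
        return self.tp + self.fp

    @property
    def m2(self) -> int:
        return self.fn + self.tn

    @property
    def n1(self) -> int:  # reference-positive column total
        return self.tp + self.fn

    @property
    def n2(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(flags_forum, flags_reference, universe) -> ConfusionCounts:
    """Tally forum vs reference flags over *universe*.

    *flags_forum* / *flags_reference* are mappings (or Series) pair ->
    bool; every pair of the universe must be present in both.
    """
    tp = fp = fn = tn = 0
    for pair in universe:
        try:
            f = bool(flags_forum[pair])
        except KeyError:
            raise KeyError(f"pair {pair} missing a forum flag") from None
        try:
            r = bool(flags_reference[pair])
        except KeyError:
            raise KeyError(f"pair {pair} missing a reference flag") from None
        if f and r:
            tp += 1
        elif f:
            fp += 1
        elif r:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def performance(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV, accuracy.

    An indicator whose denominator is zero is reported as NaN (undefined),
    never as 0.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": ratio(counts.tp, counts.n1),
        "specificity": ratio(counts.tn, counts.n2),
        "ppv": ratio(counts.tp, counts.m1),
        "npv": ratio(counts.tn, counts.m2),
        "accuracy": ratio(counts.tp + counts.tn, counts.n),
    }


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc(scores, labels, universe) -> ROCResult:
    """ROC curve and AUC of a forum score against reference labels.

    Thresholds sweep the distinct score values (ties share one point);
    undefined (NaN) scores rank below every defined score.  AUC is the
    trapezoidal integral, equal to the Mann-Whitney ordering probability.
    """
    pairs = sorted(universe)
    y = np.array([bool(labels[p]) for p in pairs])
    s = np.array([float(scores[p]) for p in pairs])
    if y.all() or not y.any():
        raise ValueError("AUC undefined: labels are all one class")
    finite_min = np.nanmin(s[np.isfinite(s)]) if np.isfinite(s).any() else 0.0
    s = np.where(np.isnan(s), finite_min - 1.0, s)
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr, tpr, thresholds, auc)


def compare_definitions(
    flags_forum: pd.DataFrame,
    flags_reference: pd.DataFrame,
    universe,
    definitions=DEFINITIONS,
) -> pd.DataFrame:
    """Per-definition performance table (rows = definitions).

    Both flag frames are indexed by (drug_id, pt_code) with one boolean
    column per definition, as produced by ``dispro.score_source``.
    """
    rows = {}
    for d in definitions:
        counts = confusion(flags_forum[d], flags_reference[d], universe)
        perf = performance(counts)
        perf.update(tp=counts.tp, fp=counts.fp, fn=counts.fn, tn=counts.tn)
        rows[d] = perf
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "definition"
    return out


def plot_roc(result: ROCResult, path, title: str = "ROC") -> None:
    """Write a ROC plot to *path* (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(result.fpr, result.tpr, lw=1.5, label=f"AUC = {result.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
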