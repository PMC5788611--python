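"""Binary-classification metrics in the N+/N− bookkeeping convention.

The six metrics — sensitivity (Sn), specificity (Sp), accuracy (ACC),
Matthews correlation coefficient (MCC), product of Sn and Sp (Pt) and
property excess (Py = Sn + Sp − 1) — are computed from four counts:
N+ and N− (class sizes) plus the two error counts N−+ (positives called
negative) and N+− (negatives called positive). Pt and Py were proposed
for settings where negatives heavily outnumber positives, as they do for
DHS benchmarks. The MCC here uses the rearranged error-rate form

    MCC = (1 − (N−+/N+ + N+−/N−)) /
          sqrt((1 + (N+− − N−+)/N+) · (1 + (N−+ − N+−)/N−)),

which is algebraically identical to the classical TP/FP/TN/FN formula;
a degenerate denominator (one-class predictor or one-class truth) yields
0 with a flag, the usual convention. AUC follows the Mann-Whitney
formulation (ties count half).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics_report",
    "roc_auc",
    "roc_curve_table",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Confusion counts: class totals and the two error counts.

    ``fn`` is N−+ (positives predicted negative); ``fp`` is N+−
    (negatives predicted positive).
    """

    n_pos: int
    n_neg: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "fn", "fp"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.fn > self.n_pos:
            raise ValueError("false negatives exceed positive total")
        if self.fp > self.n_neg:
            raise ValueError("false positives exceed negative total")

    @property
    def tp(self) -> int:
        return self.n_pos - self.fn

    @property
    def tn(self) -> int:
        return self.n_neg - self.fp


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Count confusion entries from parallel binary (0/1) label vectors."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0:
        raise ValueError("empty input")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for name, arr in (("y_true", yt), ("y_pred", yp)):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        n_pos=int((yt == 1).sum()),
        n_neg=int((yt == 0).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
    )


@dataclasses.dataclass
class MetricsReport:
    """The six threshold metrics, optionally with AUC.

    ``degenerate`` flags an MCC whose rearranged form had a zero
    denominator (value reported as 0 by convention). The identities
    Pt = Sn·Sp and Py = Sn + Sp − 1 hold exactly.
    """

    sn: float
    sp: float
    acc: float
    mcc: float
    pt: float
    py: float
    auc: float | None = None
    degenerate: bool = False

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        """Display values at table precision (full precision kept in fields)."""
        out = {
            k: round(getattr(self, k), ndigits)
            for k in ("sn", "sp", "acc", "mcc", "pt", "py")
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, ndigits)
        return out

    def to_json(self) -> str:
        full = {k: getattr(self, k) for k in ("sn", "sp", "acc", "mcc", "pt", "py", "auc")}
        return json.dumps(
            {"full": full, "rounded": self.rounded(), "degenerate": self.degenerate},
            indent=2,
        )


def metrics_report(c: ConfusionCounts) -> MetricsReport:
    """Compute Sn, Sp, ACC, MCC, Pt and Py from confusion counts."""
    if c.n_pos < 1 or c.n_neg < 1:
        raise ValueError("both classes must be non-empty")
    sn = 1.0 - c.fn / c.n_pos
    sp = 1.0 - c.fp / c.n_neg
    acc = 1.0 - (c.fn + c.fp) / (c.n_pos + c.n_neg)
    num = 1.0 - (c.fn / c.n_pos + c.fp / c.n_neg)
    den_sq = (1.0 + (c.fp - c.fn) / c.n_pos) * (1.0 + (c.fn - c.fp) / c.n_neg)
    degenerate = den_sq <= 0.0
    mcc = 0.0 if degenerate else num / math.sqrt(den_sq)
    return MetricsReport(
        sn=sn, sp=sp, acc=acc, mcc=mcc, pt=sn * sp, py=sn + sp - 1.0,
        degenerate=degenerate,
    )


def roc_auc(scores: Sequence[float], y_true: Sequence[int]) -> float:
    """AUC as the probability a random positive outscores a random negative.

    Mann-Whitney formulation with ties counted half; requires both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_true)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be parallel")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # average ranks handle ties-half automatically
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_table(scores: Sequence[float], y_true: Sequence[int]) -> pd.DataFrame:
    """ROC curve as a (threshold, fpr, tpr) table for export/plotting."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y_true)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # one point per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s_sorted[distinct]],
            "fpr": np.r_[0.0, fps / n_neg],
            "tpr": np.r_[0.0, tps / n_pos],
        }
    )
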