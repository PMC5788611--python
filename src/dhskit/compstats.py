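"""Compositional statistics: per-k-mer class comparisons by Welch's t-test.

For each k-mer, the per-sequence compositions of the two classes are
compared with the unequal-variance t-test (Welch-Satterthwaite degrees of
freedom, two-sided p). The statistic is computed from its formula
directly; only the t-distribution tail probability is delegated to scipy.
Results are reported as mean ± standard error per class with the absolute
between-class difference, sorted by that difference (descending, ties
broken lexicographically by k-mer), and flagged significant at alpha
(default 0.01, no multiple-testing correction by default — an optional
Benjamini-Hochberg flag is provided). Composition values can be reported
on the percent scale (default), which is the natural scale for display
filters like "absolute difference > 0.20" on higher-order k-mers.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .encoders import kmer_composition
from .seqio import LabeledDataset

__all__ = ["welch_t", "CompositionComparison", "compositional_comparison"]


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with t = (mean_a − mean_b) / sqrt(s²_a/n_a +
    s²_b/n_b), Welch-Satterthwaite df, and the two-sided p-value. Requires
    at least two observations per group and nonzero variance in at least
    one group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    if va + vb == 0.0:
        raise ValueError("both groups have zero variance")
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), p


@dataclasses.dataclass
class CompositionComparison:
    """Per-k-mer class comparison table plus the settings that produced it."""

    k: int
    alpha: float
    scale: str  # "percent" or "fraction"
    table: pd.DataFrame  # kmer, mean_pos, se_pos, mean_neg, se_neg, abs_diff, t, df, p, significant

    def display(self, min_diff: float | None = None) -> pd.DataFrame:
        """Reporting view: rows with abs_diff > min_diff (all rows if None)."""
        if min_diff is None:
            return self.table
        return self.table[self.table["abs_diff"] > min_diff].reset_index(drop=True)


def compositional_comparison(
    dataset: LabeledDataset,
    k: int,
    alpha: float = 0.01,
    scale: str = "percent",
    bh_correct: bool = False,
) -> CompositionComparison:
    """Compare per-k-mer compositions between the positive and negative class.

    Per-sequence compositions come from :func:`~dhskit.encoders.kmer_composition`;
    each of the 4^k k-mers is tested with Welch's t. K-mers with zero
    variance in both classes (absent everywhere, typical for large k) get
    t=0, p=1 when the means agree — they carry no signal. Rows are sorted
    by ``abs_diff`` descending with lexicographic tie-break.
    """
    if dataset.n_pos == 0 or dataset.n_neg == 0:
        raise ValueError("both classes must be non-empty")
    if scale not in ("percent", "fraction"):
        raise ValueError("scale must be 'percent' or 'fraction'")
    factor = 100.0 if scale == "percent" else 1.0
    comp = np.vstack([kmer_composition(r, k).to_numpy() for r in dataset.records])
    comp *= factor
    names = list(kmer_composition(dataset.records[0], k).index)
    pos = comp[dataset.labels == 1]
    neg = comp[dataset.labels == 0]
    rows = []
    for j, name in enumerate(names):
        a, b = pos[:, j], neg[:, j]
        if a.var(ddof=1) + b.var(ddof=1) == 0.0:
            equal = a.mean() == b.mean()
            t, df, p = (0.0, float("nan"), 1.0) if equal else (math.inf, float("nan"), 0.0)
            t = math.copysign(t, a.mean() - b.mean()) if not equal else 0.0
        else:
            t, df, p = welch_t(a, b)
        rows.append({
            "kmer": name.split(":", 1)[1],
            "mean_pos": a.mean(),
            "se_pos": a.std(ddof=1) / math.sqrt(a.size),
            "mean_neg": b.mean(),
            "se_neg": b.std(ddof=1) / math.sqrt(b.size),
            "abs_diff": abs(a.mean() - b.mean()),
            "t": t, "df": df, "p": p,
        })
    table = pd.DataFrame(rows)
    if bh_correct:
        table["p_adj"] = _benjamini_hochberg(table["p"].to_numpy())
        table["significant"] = table["p_adj"] <= alpha
    else:
        table["significant"] = table["p"] <= alpha
    table = table.sort_values(
        ["abs_diff", "kmer"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return CompositionComparison(k=k, alpha=alpha, scale=scale, table=table)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj
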