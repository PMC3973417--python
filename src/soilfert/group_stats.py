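"""Group summaries, one-way ANOVA, compact letter display, weight spread.

Reproduces the reporting structure of a land-use / chronosequence study:
per-group means with sample SD (n-1 denominator) and CV, a classical
one-way ANOVA per index across groups, pairwise-LSD compact letters, and
the between-index *weight spread* statistic used to describe how entropy
weights converge along a restoration chronosequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .entropy_weight import WeightVector
from .standards import INDEX_NAMES, ParameterError, ValidationError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "WeightSpread",
    "summarize",
    "summary_table",
    "oneway_anova",
    "letter_display",
    "weight_spread",
]

SPREAD_METHODS = ("range_over_min", "range_over_mean")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group, per-index mean / SD / CV over n replicates."""

    group: str
    n: int
    mean: pd.Series
    sd: pd.Series
    cv: pd.Series


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way F test for one index across groups."""

    index: str
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class WeightSpread:
    """Largest relative difference among a group's index weights, in percent."""

    group: str
    spread_pct: float
    method: str


def _index_columns(st: pd.DataFrame) -> list[str]:
    cols = [c for c in st.columns if c not in ("sample_id", "group", "age_years")]
    if not cols:
        raise ValidationError("sample table has no index columns")
    return cols


def summarize(st: pd.DataFrame) -> list[GroupSummary]:
    """Mean, sample SD (n-1) and CV per group and index."""
    cols = _index_columns(st)
    out = []
    for label, sub in st.groupby("group", sort=True):
        if len(sub) < 2:
            raise ValidationError(f"group {label!r} has n < 2; cannot compute SD/CV")
        x = sub[cols].astype(float)
        mean = x.mean()
        sd = x.std(ddof=1)
        out.append(
            GroupSummary(
                group=str(label),
                n=len(sub),
                mean=mean,
                sd=sd,
                cv=sd / mean,
            )
        )
    return out


def summary_table(
    summaries: list[GroupSummary], letters: dict[str, dict[str, str]] | None = None
) -> pd.DataFrame:
    """Tidy table ``group,index,mean,sd,cv,n[,letters]``."""
    rows = []
    for s in summaries:
        for name in s.mean.index:
            row = {
                "group": s.group,
                "index": name,
                "mean": s.mean[name],
                "sd": s.sd[name],
                "cv": s.cv[name],
                "n": s.n,
            }
            if letters is not None:
                row["letters"] = letters.get(name, {}).get(s.group, "")
            rows.append(row)
    return pd.DataFrame(rows)


def _group_arrays(st: pd.DataFrame, index: str) -> tuple[list[str], list[np.ndarray]]:
    if index not in st.columns:
        raise ValidationError(f"no such index column: {index!r}")
    labels, arrays = [], []
    for label, sub in st.groupby("group", sort=True):
        if len(sub) < 2:
            raise ValidationError(f"group {label!r} has n < 2")
        labels.append(str(label))
        arrays.append(sub[index].to_numpy(dtype=float))
    if len(labels) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    return labels, arrays


def oneway_anova(st: pd.DataFrame, index: str) -> AnovaResult:
    """One-way fixed-effects ANOVA of one index across the table's groups.

    Computed from sums of squares so the degenerate zero-within-variance
    case has a defined outcome: p = 0 if group means differ (infinite F),
    p = 1 if all observations are identical (F = 0).
    """
    labels, arrays = _group_arrays(st, index)
    g = len(arrays)
    ns = np.array([a.size for a in arrays])
    total_n = int(ns.sum())
    grand = np.concatenate(arrays).mean()
    means = np.array([a.mean() for a in arrays])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b, df_w = g - 1, total_n - g
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(index, 0.0, df_b, df_w, 1.0)
        return AnovaResult(index, float("inf"), df_b, df_w, 0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(index, float(f), df_b, df_w, p)


def _pairwise_lsd_p(st: pd.DataFrame, index: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Group labels, group means, and the pairwise LSD p-value matrix."""
    labels, arrays = _group_arrays(st, index)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_w = int(ns.sum()) - len(arrays)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
    g = len(labels)
    p = np.ones((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            if mse == 0.0:
                pij = 0.0 if means[i] != means[j] else 1.0
            else:
                se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
                t = abs(means[i] - means[j]) / se
                pij = 2.0 * float(stats.t.sf(t, df_w))
            p[i, j] = p[j, i] = pij
    return labels, means, p


def letter_display(st: pd.DataFrame, index: str, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from pairwise LSD tests (insert-and-absorb).

    Groups sharing a letter are pairwise non-significant at ``alpha``.
    Letters are assigned in descending-mean order; the construction is
    deterministic.
    """
    if not (0.0 < alpha < 1.0):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    labels, means, pmat = _pairwise_lsd_p(st, index)
    order = np.argsort(-means, kind="stable")  # best mean first
    g = len(labels)
    # columns are candidate letters: sets of group positions (in `order` space)
    cols: list[set[int]] = [set(range(g))]
    for a in range(g):
        for b in range(a + 1, g):
            i, j = order[a], order[b]
            if pmat[i, j] < alpha:  # significant pair must not share a letter
                new_cols: list[set[int]] = []
                for col in cols:
                    if a in col and b in col:
                        new_cols.append(col - {a})
                        new_cols.append(col - {b})
                    else:
                        new_cols.append(col)
                # absorb: drop columns contained in another
                cols = [
                    c
                    for idx, c in enumerate(new_cols)
                    if c
                    and not any(
                        c < other or (c == other and idx > jdx)
                        for jdx, other in enumerate(new_cols)
                        if jdx != idx
                    )
                ]
    # deterministic letter order: by smallest member (best mean) then size
    cols.sort(key=lambda c: (min(c), -len(c), sorted(c)))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for li, col in enumerate(cols):
        ch = chr(ord("a") + li) if li < 26 else f"z{li - 25}"
        for pos in sorted(col):
            letters[labels[order[pos]]].append(ch)
    return {lab: "".join(v) for lab, v in letters.items()}


def weight_spread(w: WeightVector, method: str = "range_over_min") -> WeightSpread:
    """Largest relative difference D among one group's index weights.

    ``range_over_min`` (default): D = (max w - min w) / min w * 100.
    ``range_over_mean``:          D = (max w - min w) / mean w * 100.
    Zero iff all weights are equal.
    """
    wts = np.asarray(w.weights, dtype=float)
    lo, hi = float(wts.min()), float(wts.max())
    if method == "range_over_min":
        if lo <= 0.0:
            raise ValidationError(
                f"group {w.group!r}: zero minimum weight; use method='range_over_mean'"
            )
        d = (hi - lo) / lo * 100.0
    elif method == "range_over_mean":
        d = (hi - lo) / wts.mean() * 100.0
    else:
        raise ParameterError(f"method must be one of {SPREAD_METHODS}, got {method!r}")
    return WeightSpread(w.group, d, method)
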