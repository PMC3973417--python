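"""Single-index attribute measures.

The attribute measure mu_ijk in [0, 1] quantifies the degree to which
sample *i*'s value of index *j* belongs to fertility grade *k*.  For each
(sample, index) pair the measure vector over the K grades is a proper
distribution: it sums to one and its support is a single grade or two
adjacent grades.

Construction (``anchor="midpoint"``, the default): each grade receives
full membership (mu = 1) at an *anchor* point — the midpoint of the
grade's interval for interior grades, an extension beyond the outermost
boundary for the edge grades — and membership 0.5 exactly at the grade
boundaries, falling linearly to 0 at the neighbouring anchors.  Values
beyond the outermost anchors belong entirely to the edge grade
(saturation).  ``anchor="boundary"`` instead ramps linearly between
consecutive boundary values, with full membership attained at the
boundaries themselves.

``lower_is_better`` indexes are handled by the mirror identity: evaluate
the reversed boundary list as ``higher_is_better`` and reverse the grade
axis of the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .standards import ParameterError, StandardMatrix, ValidationError

__all__ = ["MeasureTensor", "single_index_measure", "measure_table", "tensor_to_long"]

ANCHORS = ("midpoint", "boundary")


@dataclass(frozen=True)
class MeasureTensor:
    """Samples x indexes x grades array of attribute measures mu_ijk."""

    values: np.ndarray  # shape (n_samples, n_indexes, K)
    sample_ids: tuple
    index_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3:
            raise ValidationError("measure tensor must be 3-dimensional")
        if v.shape[0] != len(self.sample_ids) or v.shape[1] != len(self.index_names):
            raise ValidationError("measure tensor shape does not match labels")

    @property
    def n_grades(self) -> int:
        return self.values.shape[2]


def _knots(boundaries: np.ndarray, anchor: str) -> tuple[np.ndarray, np.ndarray]:
    """Knot positions (ascending) and per-grade membership values at the knots.

    ``boundaries`` must be strictly decreasing (higher_is_better).  Returns
    ``(xp, fp)`` with ``xp`` ascending and ``fp`` of shape (K, len(xp)) so
    that grade k's membership is the linear interpolant of ``fp[k]`` over
    ``xp``, clamped outside the knot range.
    """
    b = np.asarray(boundaries, dtype=float)
    k = b.size + 1
    if anchor == "midpoint":
        # anchors: edge extension above b1, interval midpoints, midpoint of [0, b_{K-1}]
        if k >= 3:
            top = b[0] + (b[0] - b[1]) / 2.0
        else:
            top = 1.5 * b[0]
        mids = (b[:-1] + b[1:]) / 2.0
        anchors = np.concatenate([[top], mids, [b[-1] / 2.0]])  # length K, decreasing
        # interleave: t_1 > b_1 > t_2 > b_2 > ... > b_{K-1} > t_K
        pos = np.empty(2 * k - 1)
        pos[0::2] = anchors
        pos[1::2] = b
        fp = np.zeros((k, pos.size))
        for g in range(k):
            fp[g, 2 * g] = 1.0  # own anchor
            if g > 0:
                fp[g, 2 * g - 1] = 0.5  # boundary above
            if g < k - 1:
                fp[g, 2 * g + 1] = 0.5  # boundary below
    elif anchor == "boundary":
        # ramps between consecutive boundaries; bottom grade ramps to 0
        pos = np.concatenate([b, [0.0]])  # length K, decreasing
        fp = np.eye(k)
    else:
        raise ParameterError(f"anchor must be one of {ANCHORS}, got {anchor!r}")
    if np.any(np.diff(pos) >= 0):
        raise ValidationError(f"degenerate (non-distinct) anchors for boundaries {b.tolist()}")
    return pos[::-1], fp[:, ::-1]


def single_index_measure(
    x: float | np.ndarray,
    boundaries: Sequence[float],
    orientation: str = "higher_is_better",
    anchor: str = "midpoint",
) -> np.ndarray:
    """Attribute-measure vector(s) of value(s) ``x`` against one index's boundaries.

    Parameters
    ----------
    x
        Scalar or 1-d array of non-negative index values.
    boundaries
        The K-1 grade boundaries, strictly decreasing for
        ``higher_is_better`` (increasing for ``lower_is_better``).
    orientation
        Whether larger values mean better fertility.
    anchor
        ``"midpoint"`` (default) or ``"boundary"``; see module docstring.

    Returns
    -------
    numpy.ndarray
        Shape ``(K,)`` for scalar input, ``(len(x), K)`` otherwise.  Each
        measure vector is non-negative, sums to 1 and is supported on at
        most two adjacent grades.
    """
    xa = np.asarray(x, dtype=float)
    scalar = xa.ndim == 0
    xa = np.atleast_1d(xa)
    if not np.all(np.isfinite(xa)) or np.any(xa < 0):
        raise ValidationError("index values must be finite and >= 0")
    b = np.asarray(boundaries, dtype=float)
    if orientation == "lower_is_better":
        out = single_index_measure(xa, b[::-1], "higher_is_better", anchor)
        out = out[:, ::-1]
        return out[0] if scalar else out
    if orientation != "higher_is_better":
        raise ParameterError(f"unknown orientation {orientation!r}")
    xp, fp = _knots(b, anchor)
    mu = np.empty((xa.size, fp.shape[0]))
    for g in range(fp.shape[0]):
        mu[:, g] = np.interp(xa, xp, fp[g])
    return mu[0] if scalar else mu


def measure_table(
    st: pd.DataFrame,
    sm: StandardMatrix,
    anchor: str = "midpoint",
    missing: str = "error",
) -> MeasureTensor:
    """Elementwise attribute measures for a sample table.

    ``st`` must carry a ``sample_id`` column and one column per index of
    the standard matrix; extra non-index columns (``group``,
    ``age_years``) are ignored.  Sample order is preserved.

    ``missing`` controls NaN policy: ``"error"`` (default — silent
    imputation would corrupt downstream entropy weights) or ``"drop"``
    (remove samples with any missing index value).
    """
    if "sample_id" not in st.columns:
        raise ValidationError("sample table must have a sample_id column")
    names = [n for n in sm.index_names if n in st.columns]
    missing_cols = [n for n in sm.index_names if n not in st.columns]
    if missing_cols:
        raise ValidationError(f"sample table lacks index columns: {missing_cols}")
    sub = st[["sample_id", *names]]
    if sub[names].isna().any().any():
        if missing == "drop":
            sub = sub.dropna(subset=names)
        elif missing == "error":
            bad = sub.loc[sub[names].isna().any(axis=1), "sample_id"].tolist()
            raise ValidationError(f"missing index values for samples {bad}")
        else:
            raise ParameterError(f"missing policy must be 'error' or 'drop', got {missing!r}")
    k = sm.n_grades
    vals = np.empty((len(sub), len(names), k))
    for j, name in enumerate(names):
        spec = sm.spec(name)
        vals[:, j, :] = single_index_measure(
            sub[name].to_numpy(dtype=float),
            sm.boundaries[name],
            spec.orientation,
            anchor,
        )
    return MeasureTensor(vals, tuple(sub["sample_id"]), tuple(names))


def tensor_to_long(mt: MeasureTensor) -> pd.DataFrame:
    """Long-format export ``sample_id,index,grade,measure`` for inspection."""
    n, m, k = mt.values.shape
    return pd.DataFrame(
        {
            "sample_id": np.repeat(list(mt.sample_ids), m * k),
            "index": list(np.tile(np.repeat(mt.index_names, k), n)),
            "grade": list(np.tile(np.arange(1, k + 1), n * m)),
            "measure": mt.values.reshape(-1),
        }
    )
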