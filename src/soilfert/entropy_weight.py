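"""Entropy weights for nutrient indexes, computed per sample group.

The entropy weight method assigns objective weights from the dispersion
of the data itself: for each index j the Shannon entropy of the
column-normalised shares p_ij is

    H_j = -(1 / ln n) * sum_i p_ij ln p_ij      (0 * ln 0 == 0),

the divergence d_j = 1 - H_j measures how strongly the index
discriminates among the n samples, and the weight is the normalised
divergence w_j = d_j / sum_j d_j.  An index whose values are identical
across samples carries no information and receives weight 0; if *every*
index is constant the method is uninformative and falls back to equal
weights with a warning.

Weights are computed within each land-use / restoration-age group over
its replicates, one weight vector per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribute_measure import measure_table
from .standards import ParameterError, StandardMatrix, ValidationError

__all__ = ["WeightVector", "normalize_columns", "entropy_weights", "group_weights", "weights_table"]

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("proportional", "minmax")
WEIGHT_MODES = ("raw", "measure")


@dataclass(frozen=True)
class WeightVector:
    """Per-group index weights w_j (sum to 1); ``percent`` mirrors reporting."""

    group: str
    index_names: tuple[str, ...]
    weights: np.ndarray
    mode: str = "raw"
    normalization: str = "proportional"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != len(self.index_names):
            raise ValidationError("weight vector shape does not match index names")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be >= 0 and sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.weights

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.index_names), name=self.group)


def normalize_columns(
    x: np.ndarray, method: str = "proportional"
) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise shares p_ij plus a constant-column flag vector.

    ``proportional``: p_ij = x_ij / sum_i x_ij.  ``minmax``: min-max range
    scaling followed by the proportional step.  A constant column cannot
    be range-scaled; it is returned as uniform shares and flagged so the
    entropy step can assign it zero divergence instead of dividing by
    zero.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need an n x m matrix with n >= 2 samples")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValidationError("entries must be finite and >= 0")
    n, m = x.shape
    constant = x.max(axis=0) == x.min(axis=0)
    if method == "proportional":
        colsum = x.sum(axis=0)
        if np.any(colsum <= 0):
            bad = np.nonzero(colsum <= 0)[0].tolist()
            raise ValidationError(f"zero column sum in proportional normalization: columns {bad}")
        p = x / colsum
    elif method == "minmax":
        rng = x.max(axis=0) - x.min(axis=0)
        r = np.where(constant, 1.0 / n, (x - x.min(axis=0)) / np.where(constant, 1.0, rng))
        p = r / r.sum(axis=0)
    else:
        raise ParameterError(f"normalization must be one of {NORMALIZATIONS}, got {method!r}")
    return p, constant


def entropy_weights(
    p: np.ndarray,
    constant_flags: np.ndarray | None = None,
    *,
    group: str = "",
    index_names: tuple[str, ...] | None = None,
    mode: str = "raw",
    normalization: str = "proportional",
) -> WeightVector:
    """Entropy weights from a share matrix (columns of non-constant indexes sum to 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValidationError("cannot compute entropy with fewer than 2 samples")
    n, m = p.shape
    if constant_flags is None:
        constant_flags = np.zeros(m, dtype=bool)
    constant_flags = np.asarray(constant_flags, dtype=bool)
    if index_names is None:
        index_names = tuple(f"x{j + 1}" for j in range(m))

    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    h = -plogp.sum(axis=0) / np.log(n)
    d = np.where(constant_flags, 0.0, 1.0 - h)
    d = np.maximum(d, 0.0)  # guard fp noise at the uniform limit
    total = d.sum()
    if total <= 1e-12:
        logger.warning(
            "group %r: all indexes uninformative (uniform data); falling back to equal weights",
            group,
        )
        w = np.full(m, 1.0 / m)
    else:
        w = d / total
    return WeightVector(group, tuple(index_names), w, mode, normalization)


def group_weights(
    st: pd.DataFrame,
    sm: StandardMatrix,
    mode: str = "raw",
    normalization: str = "proportional",
    anchor: str = "midpoint",
    grade_values: np.ndarray | None = None,
) -> dict[str, WeightVector]:
    """One entropy :class:`WeightVector` per group of the sample table.

    ``mode="raw"`` takes entropy over the normalised raw values x_ij.
    ``mode="measure"`` first maps each value to its per-index grade score
    q_ij = sum_k c_k mu_ijk (c_k = K+1-k by default) so that weighting
    happens inside the attribute-measure framework, then normalises.
    """
    if mode not in WEIGHT_MODES:
        raise ParameterError(f"weight mode must be one of {WEIGHT_MODES}, got {mode!r}")
    if "group" not in st.columns:
        raise ValidationError("sample table must have a group column")
    names = list(sm.index_names)
    sm.check_sample_columns([c for c in names if c in st.columns])
    out: dict[str, WeightVector] = {}
    for label, sub in st.groupby("group", sort=True):
        if len(sub) < 2:
            raise ValidationError(
                f"group {label!r} has a single sample; entropy weights need n >= 2"
            )
        if mode == "raw":
            x = sub[names].to_numpy(dtype=float)
        else:
            mt = measure_table(sub, sm, anchor=anchor)
            k = mt.n_grades
            c = (
                np.arange(k, 0, -1, dtype=float)
                if grade_values is None
                else np.asarray(grade_values, dtype=float)
            )
            x = mt.values @ c  # (n, m) per-sample per-index grade scores
        p, const = normalize_columns(x, normalization)
        out[str(label)] = entropy_weights(
            p,
            const,
            group=str(label),
            index_names=tuple(names),
            mode=mode,
            normalization=normalization,
        )
    return out


def weights_table(weights: dict[str, WeightVector], percent: bool = True) -> pd.DataFrame:
    """Weights as a group x index table (percents, 2 decimals, by default)."""
    rows = {}
    for label, wv in weights.items():
        vals = wv.percent if percent else wv.weights
        rows[label] = pd.Series(vals, index=list(wv.index_names))
    df = pd.DataFrame(rows).T
    df.index.name = "group"
    return df.round(2) if percent else df
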