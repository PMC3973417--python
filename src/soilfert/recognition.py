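"""Grade synthesis, confidence-criterion classification and scoring.

The multi-index (comprehensive) attribute measure of sample *i* is the
weight-averaged mixture of its single-index measures,

    mu_ik = sum_j w_j mu_ijk,

a convex combination of distributions and hence itself a distribution
over the K grades.  The *confidence criterion* assigns the grade

    k* = min { k : sum_{l<=k} mu_il >= lambda },      lambda in (0.5, 1],

scanning grades from best (1) to worst (K): the first grade at which the
accumulated confidence reaches lambda.  Samples are ranked by the score
q_i = sum_k c_k mu_ik with grade values c_k = K + 1 - k by default, so a
larger score means higher fertility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attribute_measure import ANCHORS, MeasureTensor, measure_table
from .entropy_weight import NORMALIZATIONS, WEIGHT_MODES, WeightVector, group_weights
from .standards import ParameterError, StandardMatrix, ValidationError

__all__ = ["AssessConfig", "GradeResult", "synthesize", "classify", "score", "assess", "results_table"]


@dataclass(frozen=True)
class AssessConfig:
    """Tunable parameters of an assessment run.

    confidence
        The lambda of the confidence criterion, in (0.5, 1].  0.7 by
        default (conventional choices are 0.6-0.7).
    anchor
        Attribute-measure anchoring, ``midpoint`` or ``boundary``.
    weight_mode / normalization
        Entropy-weighting options (see :mod:`soilfert.entropy_weight`).
    grade_values
        Scoring values c_k; ``None`` means K+1-k (grade 1 scores highest).
    """

    confidence: float = 0.7
    anchor: str = "midpoint"
    weight_mode: str = "raw"
    normalization: str = "proportional"
    grade_values: tuple[float, ...] | None = None
    missing: str = "error"

    def __post_init__(self) -> None:
        if not (0.5 < self.confidence <= 1.0):
            raise ParameterError(
                f"confidence level must be in (0.5, 1], got {self.confidence} "
                "(the criterion is ill-posed at or below 0.5)"
            )
        if self.anchor not in ANCHORS:
            raise ParameterError(f"anchor must be one of {ANCHORS}, got {self.anchor!r}")
        if self.weight_mode not in WEIGHT_MODES:
            raise ParameterError(
                f"weight_mode must be one of {WEIGHT_MODES}, got {self.weight_mode!r}"
            )
        if self.normalization not in NORMALIZATIONS:
            raise ParameterError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )


@dataclass(frozen=True)
class GradeResult:
    """Per-sample outcome: comprehensive measure, grade, confidence, score."""

    sample_id: object
    group: str
    mu: np.ndarray
    grade: int
    confidence: float
    score: float
    grade_values: tuple[float, ...]


def synthesize(mt: MeasureTensor, w: WeightVector) -> np.ndarray:
    """Comprehensive measures mu_ik = sum_j w_j mu_ijk, shape (n, K)."""
    if tuple(w.index_names) != tuple(mt.index_names):
        raise ValidationError(
            f"weight indexes {w.index_names} do not match tensor indexes {mt.index_names}"
        )
    return np.einsum("ijk,j->ik", mt.values, w.weights)


def classify(mu: np.ndarray, confidence: float) -> int:
    """Grade k* by the confidence criterion (min k with cum measure >= lambda)."""
    if not (0.5 < confidence <= 1.0):
        raise ParameterError(f"confidence level must be in (0.5, 1], got {confidence}")
    mu = np.asarray(mu, dtype=float)
    cum = np.cumsum(mu)
    hits = np.nonzero(cum >= confidence)[0]
    # cum always reaches 1 analytically; guard the <1-ulp float shortfall
    return int(hits[0]) + 1 if hits.size else mu.size


def score(mu: np.ndarray, grade_values: np.ndarray | None = None) -> float:
    """Expected grade value q_i = sum_k c_k mu_ik (default c_k = K+1-k)."""
    mu = np.asarray(mu, dtype=float)
    k = mu.size
    c = (
        np.arange(k, 0, -1, dtype=float)
        if grade_values is None
        else np.asarray(grade_values, dtype=float)
    )
    if c.size != k:
        raise ValidationError("grade_values length must equal the number of grades")
    return float(mu @ c)


def assess(
    st: pd.DataFrame,
    sm: StandardMatrix,
    config: AssessConfig | None = None,
) -> tuple[list[GradeResult], dict[str, WeightVector]]:
    """Full pipeline: measures -> group entropy weights -> grades and scores.

    Deterministic (no randomness); one :class:`GradeResult` per sample in
    input order, plus the per-group weight vectors used.
    """
    cfg = config or AssessConfig()
    if "group" not in st.columns:
        raise ValidationError("sample table must have a group column")
    weights = group_weights(
        st,
        sm,
        mode=cfg.weight_mode,
        normalization=cfg.normalization,
        anchor=cfg.anchor,
        grade_values=None if cfg.grade_values is None else np.asarray(cfg.grade_values),
    )
    mt = measure_table(st, sm, anchor=cfg.anchor, missing=cfg.missing)
    k = mt.n_grades
    cvals = (
        tuple(float(v) for v in np.arange(k, 0, -1))
        if cfg.grade_values is None
        else tuple(cfg.grade_values)
    )
    groups = st["group"].astype(str).tolist()
    results = []
    for i, sid in enumerate(mt.sample_ids):
        wv = weights[groups[i]]
        mu = np.einsum("jk,j->k", mt.values[i], wv.weights)
        results.append(
            GradeResult(
                sample_id=sid,
                group=groups[i],
                mu=mu,
                grade=classify(mu, cfg.confidence),
                confidence=cfg.confidence,
                score=score(mu, np.asarray(cvals)),
                grade_values=cvals,
            )
        )
    return results, weights


def results_table(results: list[GradeResult]) -> pd.DataFrame:
    """Results as a flat table ``sample_id,group,mu_1..mu_K,grade,score``."""
    if not results:
        return pd.DataFrame(columns=["sample_id", "group", "grade", "score"])
    k = results[0].mu.size
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "group": r.group}
        row.update({f"mu_{g + 1}": r.mu[g] for g in range(k)})
        row["grade"] = r.grade
        row["score"] = r.score
        rows.append(row)
    return pd.DataFrame(rows)
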