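"""Grade standard matrices for soil-nutrient classification.

A *standard matrix* holds, for every nutrient index, the ordered boundary
values that separate ``K`` fertility grades.  Grades are numbered
``1..K`` with grade 1 the most fertile; for a ``higher_is_better`` index
the ``K - 1`` boundaries are therefore strictly decreasing
(``b1 > b2 > ... > b_{K-1}``), and strictly increasing for a
``lower_is_better`` index.  The matrix is the evaluation criterion against
which single-index attribute measures are computed.

The boundary values shipped with the package
(:func:`default_standard`) follow the six-level soil-nutrient
classification tradition used in Chinese national soil surveys; they are
an editable fixture (``data/nutrient_grades.csv``), never hard-coded in
logic, so alternative standards can be swapped in without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "IndexSpec",
    "StandardMatrix",
    "SchemaError",
    "ValidationError",
    "ParameterError",
    "load_standard",
    "write_standard",
    "default_standard",
]

#: Canonical order of the six nutrient indexes used throughout the package.
INDEX_NAMES = ("SOM", "N_total", "P_total", "N_hydro", "P_avail", "K_avail")

ORIENTATIONS = ("higher_is_better", "lower_is_better")


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A file or table does not have the expected columns/fields."""


class ParameterError(ValueError):
    """A configuration parameter is outside its admissible range."""


@dataclass(frozen=True)
class IndexSpec:
    """One nutrient index: its name, units and grading orientation."""

    name: str
    units: str
    orientation: str = "higher_is_better"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("index name must be non-empty")
        if not self.units:
            raise ValidationError(f"index {self.name!r}: units must be non-empty")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"index {self.name!r}: orientation must be one of {ORIENTATIONS}, "
                f"got {self.orientation!r}"
            )


@dataclass(frozen=True)
class StandardMatrix:
    """Per-index grade boundaries for ``K`` fertility grades (1 = best).

    ``boundaries[name]`` holds the ``K - 1`` finite values separating the
    grades, strictly decreasing for ``higher_is_better`` indexes and
    strictly increasing for ``lower_is_better`` ones.
    """

    indexes: tuple[IndexSpec, ...]
    boundaries: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.indexes:
            raise ValidationError("standard matrix needs at least one index")
        names = [ix.name for ix in self.indexes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate index names in standard matrix")
        if set(self.boundaries) != set(names):
            raise SchemaError(
                "boundaries must be given for exactly the declared indexes; "
                f"declared {names}, got {sorted(self.boundaries)}"
            )
        k = None
        for ix in self.indexes:
            b = np.asarray(self.boundaries[ix.name], dtype=float)
            if b.ndim != 1 or b.size < 1:
                raise ValidationError(
                    f"index {ix.name!r}: need at least one boundary (K >= 2)"
                )
            if k is None:
                k = b.size + 1
            elif b.size + 1 != k:
                raise ValidationError(
                    f"index {ix.name!r}: inconsistent grade count "
                    f"({b.size + 1} vs {k})"
                )
            if not np.all(np.isfinite(b)) or np.any(b <= 0):
                raise ValidationError(
                    f"index {ix.name!r}: boundaries must be finite and > 0"
                )
            diffs = np.diff(b)
            if ix.orientation == "higher_is_better":
                ok = np.all(diffs < 0)
            else:
                ok = np.all(diffs > 0)
            if not ok:
                raise ValidationError(
                    f"index {ix.name!r}: boundaries must be strictly "
                    f"{'decreasing' if ix.orientation == 'higher_is_better' else 'increasing'}, "
                    f"got {b.tolist()}"
                )
        # normalise storage to plain float tuples (hash/eq friendly)
        object.__setattr__(
            self,
            "boundaries",
            {n: tuple(float(v) for v in self.boundaries[n]) for n in names},
        )

    @property
    def n_grades(self) -> int:
        """Number of fertility grades ``K``."""
        first = self.indexes[0].name
        return len(self.boundaries[first]) + 1

    @property
    def index_names(self) -> tuple[str, ...]:
        return tuple(ix.name for ix in self.indexes)

    def spec(self, name: str) -> IndexSpec:
        for ix in self.indexes:
            if ix.name == name:
                return ix
        raise KeyError(name)

    def check_sample_columns(self, columns: Iterable[str]) -> None:
        """Raise :class:`SchemaError` unless every column exists in the matrix."""
        missing = [c for c in columns if c not in self.boundaries]
        if missing:
            raise SchemaError(f"sample indexes not in standard matrix: {missing}")


def _frame_to_matrix(df: pd.DataFrame) -> StandardMatrix:
    required = {"index", "units", "orientation"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"standard file must have columns {sorted(required)} plus b1..b(K-1); "
            f"got {list(df.columns)}"
        )
    bcols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not bcols:
        raise SchemaError("standard file has no boundary columns b1..b(K-1)")
    specs = []
    bounds = {}
    for _, row in df.iterrows():
        specs.append(
            IndexSpec(str(row["index"]), str(row["units"]), str(row["orientation"]))
        )
        bounds[str(row["index"])] = tuple(float(row[c]) for c in bcols)
    return StandardMatrix(tuple(specs), bounds)


def load_standard(path: str | Path, format: str | None = None) -> StandardMatrix:
    """Read and validate a grade standard matrix from CSV or JSON.

    CSV dialect: UTF-8, header ``index,units,orientation,b1,...,b{K-1}``,
    one row per index.  JSON: a list with one object per index carrying
    the same fields plus a ``boundaries`` array.  ``format`` defaults to
    the file suffix.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path, comment="#")
        return _frame_to_matrix(df)
    if fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise SchemaError("JSON standard must be a list of index objects")
        specs, bounds = [], {}
        for rec in records:
            try:
                specs.append(
                    IndexSpec(rec["index"], rec["units"], rec["orientation"])
                )
                bounds[rec["index"]] = tuple(float(v) for v in rec["boundaries"])
            except KeyError as exc:
                raise SchemaError(f"index object missing field {exc}") from exc
        return StandardMatrix(tuple(specs), bounds)
    raise ParameterError(f"unknown standard format {fmt!r} (csv or json)")


def write_standard(sm: StandardMatrix, path: str | Path, format: str | None = None) -> None:
    """Serialize a validated standard matrix; inverse of :func:`load_standard`.

    Output is bit-stable for a fixed input (fixed column/key order).
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    k = sm.n_grades
    if fmt == "csv":
        rows = []
        for ix in sm.indexes:
            row = {"index": ix.name, "units": ix.units, "orientation": ix.orientation}
            row.update({f"b{i + 1}": v for i, v in enumerate(sm.boundaries[ix.name])})
            rows.append(row)
        cols = ["index", "units", "orientation"] + [f"b{i + 1}" for i in range(k - 1)]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return
    if fmt == "json":
        records = [
            {
                "index": ix.name,
                "units": ix.units,
                "orientation": ix.orientation,
                "boundaries": list(sm.boundaries[ix.name]),
            }
            for ix in sm.indexes
        ]
        path.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
        return
    raise ParameterError(f"unknown standard format {fmt!r} (csv or json)")


def default_standard() -> StandardMatrix:
    """The packaged six-grade nutrient standard (editable CSV fixture)."""
    with resources.as_file(
        resources.files("soilfert").joinpath("data/nutrient_grades.csv")
    ) as p:
        return load_standard(p, format="csv")
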