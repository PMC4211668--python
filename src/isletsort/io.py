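"""Cell tables and the in-memory islet model.

An islet is a point cloud: one row per endocrine cell with its 3D nuclear
coordinates (µm) and its hormone-defined type (``alpha``, ``beta`` or
``delta``).  The canonical on-disk form is a delimited table with header
columns ``islet_id, cell_id, x_um, y_um, z_um, cell_type``; tab-separated
input is accepted via :class:`TableDialect`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import TableFormatError, ValidationError

CELL_TYPES = ("alpha", "beta", "delta")
TYPE_CODES = {"alpha": 0, "beta": 1, "delta": 2}

#: canonical unordered type pairs, paper order (binary first, then delta pairs)
BINARY_PAIRS = (("beta", "beta"), ("alpha", "beta"), ("alpha", "alpha"))
TERNARY_PAIRS = BINARY_PAIRS + (
    ("delta", "delta"),
    ("alpha", "delta"),
    ("beta", "delta"),
)


def canonical_pair(pair):
    """Normalize an unordered type pair to its canonical key.

    Canonical keys are those of :data:`TERNARY_PAIRS` (e.g. ``("alpha","beta")``,
    never ``("beta","alpha")``).
    """
    a, b = pair
    if a not in CELL_TYPES or b not in CELL_TYPES:
        raise ValidationError(f"unknown cell type in pair {pair!r}")
    return (a, b) if TYPE_CODES[a] <= TYPE_CODES[b] else (b, a)


class CellRecord(NamedTuple):
    cell_id: str
    x: float
    y: float
    z: float
    cell_type: str


@dataclass
class TableDialect:
    """Column naming and separator for cell tables."""

    sep: str = ","
    islet_id: str = "islet_id"
    cell_id: str = "cell_id"
    x: str = "x_um"
    y: str = "y_um"
    z: str = "z_um"
    cell_type: str = "cell_type"

    @classmethod
    def tsv(cls) -> "TableDialect":
        return cls(sep="\t")


@dataclass
class IsletPointCloud:
    """Per-cell 3D coordinates and types for one islet.

    ``coords`` is an (n, 3) float array; ``cell_types`` an (n,) array of the
    strings in :data:`CELL_TYPES`; ``cell_ids`` an (n,) array of unique ids.
    Row order is meaningful and preserved through I/O round trips.
    """

    islet_id: str
    cell_ids: np.ndarray
    coords: np.ndarray
    cell_types: np.ndarray
    species_label: str = ""

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        n = len(self.cell_ids)
        if n < 2:
            raise ValidationError("an islet needs at least 2 cells")
        if self.coords.shape != (n, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match {n} cells"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        bad = [t for t in self.cell_types if t not in CELL_TYPES]
        if bad:
            raise TableFormatError(f"unsupported cell type(s): {sorted(set(bad))}")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids must be unique within an islet")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def type_codes(self) -> np.ndarray:
        """Integer codes (alpha=0, beta=1, delta=2), int8."""
        return np.array([TYPE_CODES[t] for t in self.cell_types], dtype=np.int8)

    @property
    def cells(self) -> Iterator[CellRecord]:
        for cid, (x, y, z), t in zip(self.cell_ids, self.coords, self.cell_types):
            yield CellRecord(cid, float(x), float(y), float(z), t)

    def type_counts(self) -> dict:
        return {t: int(np.sum(self.cell_types == t)) for t in CELL_TYPES}

    def with_types(self, cell_types) -> "IsletPointCloud":
        return replace(self, cell_types=np.asarray(cell_types, dtype=object))


@dataclass(frozen=True)
class Composition:
    """Type fractions of an islet; sums to 1 (p_delta may be 0)."""

    p_alpha: float
    p_beta: float
    p_delta: float = 0.0

    def __post_init__(self):
        ps = (self.p_alpha, self.p_beta, self.p_delta)
        if any(p < 0 or p > 1 for p in ps):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(sum(ps) - 1.0) > 1e-9:
            raise ValidationError(f"fractions must sum to 1, got {sum(ps)}")

    def as_dict(self) -> dict:
        return {"alpha": self.p_alpha, "beta": self.p_beta, "delta": self.p_delta}

    @property
    def is_binary(self) -> bool:
        return self.p_delta == 0.0


def composition_of(cloud: IsletPointCloud) -> Composition:
    """Type fractions of a cloud: counts / total."""
    counts = cloud.type_counts()
    n = cloud.n_cells
    return Composition(counts["alpha"] / n, counts["beta"] / n, counts["delta"] / n)


def read_cell_table(path, dialect: TableDialect | None = None) -> IsletPointCloud:
    """Read one islet from a delimited cell table.

    Raises :class:`TableFormatError` for a missing column, a non-numeric
    coordinate (reported with its row number) or an unknown cell type, and
    :class:`ValidationError` for duplicate cell ids.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    needed = [dialect.cell_id, dialect.x, dialect.y, dialect.z, dialect.cell_type]
    for col in needed:
        if col not in df.columns:
            raise TableFormatError(f"missing required column {col!r}")
    coords = np.empty((len(df), 3), dtype=float)
    for j, col in enumerate((dialect.x, dialect.y, dialect.z)):
        try:
            coords[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() | ~np.isfinite(bad))[0])
            raise TableFormatError(
                f"non-numeric coordinate in column {col!r}, row {row}"
            ) from None
    types = df[dialect.cell_type].str.strip().to_numpy(dtype=object)
    islet_id = ""
    if dialect.islet_id in df.columns and len(df):
        islet_id = str(df[dialect.islet_id].iloc[0])
    return IsletPointCloud(
        islet_id=islet_id,
        cell_ids=df[dialect.cell_id].to_numpy(dtype=object),
        coords=coords,
        cell_types=types,
    )


def write_cell_table(cloud: IsletPointCloud, path, dialect: TableDialect | None = None) -> None:
    """Write a cloud as a delimited table re-readable by :func:`read_cell_table`."""
    dialect = dialect or TableDialect()
    df = pd.DataFrame(
        {
            dialect.islet_id: [cloud.islet_id] * cloud.n_cells,
            dialect.cell_id: cloud.cell_ids,
            dialect.x: cloud.coords[:, 0],
            dialect.y: cloud.coords[:, 1],
            dialect.z: cloud.coords[:, 2],
            dialect.cell_type: cloud.cell_types,
        }
    )
    df.to_csv(path, sep=dialect.sep, index=False)


#: islet-size classes used in census summaries
SIZE_CLASSES = (("small", 0, 1000), ("medium", 1000, 2000), ("large", 2000, None))


def size_class(n_cells: int) -> str:
    """Classify an islet as small (<1000 cells), medium (1000-2000) or large (>2000)."""
    if n_cells < 1000:
        return "small"
    if n_cells <= 2000:
        return "medium"
    return "large"
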