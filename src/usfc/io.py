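"""On-disk formats: region atlas tables, connectivity matrices, route tables, reports.

Conventions
-----------
* Atlas: CSV with columns ``region_id,label,x_mm,y_mm,z_mm,network``.
  External region ids are 1-based; all in-memory indices are 0-based positions
  in atlas order (ascending ``region_id``), which fixes the row/column order of
  every matrix in a run.
* Matrices: TSV, ``N+1`` rows x ``N+1`` columns — header row of region labels,
  row labels in the first column.  Files whose labels are a permutation of the
  atlas are reordered on read; any other label set is rejected.
* Route tables: CSV, one row per routed region pair, node sequence
  hyphen-joined (``A-B-C``).
* Reports: plain JSON.

Malformed data fails loudly: asymmetry beyond ``SYMMETRY_TOL`` or out-of-range
entries for the declared matrix kind raise instead of being silently repaired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-9

MATRIX_KINDS = ("SC", "FC", "USFC", "DIST")

ATLAS_COLUMNS = ["region_id", "label", "x_mm", "y_mm", "z_mm", "network"]
ROUTE_COLUMNS = ["subject_id", "source", "target", "route", "n_steps", "total_cost", "fc"]


class ValidationError(ValueError):
    """Input violates a structural invariant (range, symmetry, uniqueness)."""


class LabelMismatchError(ValidationError):
    """Matrix labels do not form the atlas label set."""


class FormatError(ValidationError):
    """File cannot be parsed as the expected table/matrix layout."""


# ---------------------------------------------------------------------------
# Region atlas
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class RegionAtlas:
    """Node set of the parcellation: ids, labels, centroids (mm), networks.

    Region order here defines row/column order for every matrix in the run.
    """

    region_ids: tuple[int, ...]
    labels: tuple[str, ...]
    centroids: np.ndarray  # (N, 3) float, mm
    networks: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        if n < 2:
            raise ValidationError(f"atlas needs at least 2 regions, got {n}")
        if len(set(self.region_ids)) != n:
            raise ValidationError("duplicate region_ids in atlas")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in atlas")
        centroids = np.asarray(self.centroids, dtype=float)
        if centroids.shape != (n, 3):
            raise ValidationError(f"centroids must be ({n}, 3), got {centroids.shape}")
        if not np.all(np.isfinite(centroids)):
            raise ValidationError("non-finite centroid coordinates")
        if len(self.networks) != n:
            raise ValidationError("networks length mismatch")
        if list(self.region_ids) != sorted(self.region_ids):
            raise ValidationError("atlas must be sorted by region_id")
        object.__setattr__(self, "centroids", centroids)
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.labels)})

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionAtlas):
            return NotImplemented
        return (
            self.region_ids == other.region_ids
            and self.labels == other.labels
            and np.array_equal(self.centroids, other.centroids)
            and self.networks == other.networks
        )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self._index[label]

    @property
    def network_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for net in self.networks:
            seen.setdefault(net, None)
        return tuple(seen)

    def regions_in_network(self, network: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.networks) == network)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "label": self.labels,
                "x_mm": self.centroids[:, 0],
                "y_mm": self.centroids[:, 1],
                "z_mm": self.centroids[:, 2],
                "network": self.networks,
            }
        )


def read_atlas(path: str | Path) -> RegionAtlas:
    """Read a region atlas CSV, returning regions sorted by ``region_id``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse atlas table {path}: {exc}") from exc
    missing = set(ATLAS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"atlas table missing columns: {sorted(missing)}")
    for col in ("x_mm", "y_mm", "z_mm"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric coordinates in column {col!r}")
    df = df.sort_values("region_id", kind="stable").reset_index(drop=True)
    return RegionAtlas(
        region_ids=tuple(int(i) for i in df["region_id"]),
        labels=tuple(str(s) for s in df["label"]),
        centroids=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        networks=tuple(str(s) for s in df["network"]),
    )


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnMatrix:
    """A symmetric region-by-region matrix of a declared kind.

    Kinds and their admissible ranges:
    ``SC`` >= 0 (FA-weighted structural strength), ``FC`` in [-1, 1] (Pearson
    correlation; negative values arise after global signal regression),
    ``USFC`` >= 0 (accumulated functional load), ``DIST`` off-diagonal > 0
    (Euclidean centroid distance, mm).
    """

    values: np.ndarray
    kind: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        validate_matrix(values, self.kind)
        if values.shape[0] != len(self.labels):
            raise ValidationError("label count does not match matrix dimension")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def validate_matrix(values: np.ndarray, kind: str) -> None:
    """Check symmetry, diagonal and the range rules for ``kind``; raise on failure."""
    if kind not in MATRIX_KINDS:
        raise ValidationError(f"unknown matrix kind {kind!r}")
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise FormatError(f"matrix must be square, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValidationError("matrix contains non-finite entries")
    if np.max(np.abs(values - values.T), initial=0.0) > SYMMETRY_TOL:
        raise FormatError(f"matrix asymmetric beyond tolerance {SYMMETRY_TOL}")
    if np.max(np.abs(np.diagonal(values)), initial=0.0) > SYMMETRY_TOL:
        raise ValidationError("matrix diagonal must be zero")
    off = ~np.eye(values.shape[0], dtype=bool)
    if kind in ("SC", "USFC") and np.any(values < 0):
        raise ValidationError(f"{kind} entries must be nonnegative")
    if kind == "FC" and (np.any(values < -1) or np.any(values > 1)):
        raise ValidationError("FC entries must lie in [-1, 1]")
    if kind == "DIST" and np.any(values[off] <= 0):
        raise ValidationError("DIST off-diagonal entries must be positive")


def read_matrix(path: str | Path, atlas: RegionAtlas, kind: str) -> ConnMatrix:
    """Read a labeled TSV matrix and reorder it to atlas order.

    The file's labels must be exactly the atlas labels (any order); the
    returned matrix rows/columns follow the atlas.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse matrix file {path}: {exc}") from exc
    file_labels = [str(c) for c in df.columns]
    if [str(r) for r in df.index] != file_labels:
        raise FormatError(f"row labels differ from column labels in {path}")
    if set(file_labels) != set(atlas.labels):
        extra = sorted(set(file_labels) - set(atlas.labels))
        missing = sorted(set(atlas.labels) - set(file_labels))
        raise LabelMismatchError(
            f"matrix labels do not match atlas (missing={missing}, extra={extra})"
        )
    if len(file_labels) != len(set(file_labels)):
        raise LabelMismatchError("duplicate labels in matrix file")
    df.index = file_labels
    df.columns = file_labels
    ordered = df.loc[list(atlas.labels), list(atlas.labels)].to_numpy(dtype=float)
    return ConnMatrix(values=ordered, kind=kind, labels=atlas.labels)


def write_matrix(matrix: ConnMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.labels), columns=list(matrix.labels))
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_raw_matrix(values: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Write an arbitrary labeled square matrix (no kind validation).

    Used for signed edge-load matrices and statistic maps (t/q values) that do
    not fit a declared ConnMatrix kind.
    """
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# Route tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RouteRecord:
    """One serialized route: who, between which regions, along which nodes."""

    subject_id: str
    source: str
    target: str
    nodes: tuple[str, ...]
    n_steps: int
    total_cost: float
    fc: float

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise ValidationError("route needs at least two nodes")
        if self.nodes[0] != self.source or self.nodes[-1] != self.target:
            raise ValidationError(
                f"route {self.nodes} does not run from {self.source} to {self.target}"
            )
        if self.n_steps != len(self.nodes) - 1:
            raise ValidationError("n_steps inconsistent with node sequence")


def write_route_table(records: Iterable[RouteRecord], path: str | Path) -> None:
    """Write routes as CSV; an empty record set yields a header-only file."""
    rows = [
        {
            "subject_id": r.subject_id,
            "source": r.source,
            "target": r.target,
            "route": "-".join(r.nodes),
            "n_steps": r.n_steps,
            "total_cost": repr(float(r.total_cost)),
            "fc": repr(float(r.fc)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ROUTE_COLUMNS).to_csv(path, index=False)


def read_route_table(path: str | Path) -> list[RouteRecord]:
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "source": str, "target": str, "route": str},
        float_precision="round_trip",
    )
    missing = set(ROUTE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"route table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            RouteRecord(
                subject_id=str(row.subject_id),
                source=str(row.source),
                target=str(row.target),
                nodes=tuple(str(row.route).split("-")),
                n_steps=int(row.n_steps),
                total_cost=float(row.total_cost),
                fc=float(row.fc),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Write a JSON report (run config, per-stage summaries, seed)."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
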