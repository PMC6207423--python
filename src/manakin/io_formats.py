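"""Readers/writers for the standard formats the pipeline touches.

Everything downstream consumes the validated domain types built here
(:class:`Phylogeny`, :class:`RangePolygon`, :class:`DataTable`); no other
module opens files.  Interchange formats are deliberately plain text:
newick for trees, GeoJSON (lon/lat, WGS84) for range polygons, and
tab-separated tables with a header row for measurement data (the TSV
dialect of the study's ``.txt`` source-data files).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.validation import explain_validity, make_valid

__all__ = [
    "FormatError",
    "SchemaError",
    "ValidationError",
    "GeometryError",
    "Phylogeny",
    "RangePolygon",
    "DataTable",
    "TableSchema",
    "ACOUSTICS_SCHEMA",
    "FATIGUE_SCHEMA",
    "TWITCHSPEED_SCHEMA",
    "read_tree",
    "read_range_polygon",
    "write_range_polygon",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """The file could not be parsed as the expected format."""


class SchemaError(ValueError):
    """A table is missing required columns or fails type validation."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class GeometryError(ValueError):
    """A polygon is degenerate or otherwise unusable."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in (relative) time units.

    Nodes are indexed 0..n-1 in preorder (root first).  ``parent[i]`` is -1
    for the root.  Tips carry taxon labels; unlabeled internal nodes are
    auto-numbered "1", "2", ... in preorder so ancestors can be referred to
    by a stable name.
    """

    labels: list[str]
    parent: np.ndarray          # int, -1 at root
    branch_length: np.ndarray   # float, 0.0 at root
    is_tip: np.ndarray          # bool
    ultrametric: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def tip_labels(self) -> list[str]:
        return [l for l, t in zip(self.labels, self.is_tip) if t]

    @property
    def internal_labels(self) -> list[str]:
        return [l for l, t in zip(self.labels, self.is_tip) if not t]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.branch_length[i]
        return d

    def edges(self) -> list[tuple[int, int, float]]:
        """(parent index, child index, branch length) for every non-root node."""
        return [
            (int(self.parent[i]), i, float(self.branch_length[i]))
            for i in range(self.n_nodes)
            if self.parent[i] >= 0
        ]


def _phylogeny_from_dendropy(tree: dendropy.Tree) -> Phylogeny:
    labels: list[str] = []
    parents: list[int] = []
    blens: list[float] = []
    tips: list[bool] = []
    index_of: dict[int, int] = {}
    n_internal = 0
    for node in tree.preorder_node_iter():
        idx = len(labels)
        index_of[id(node)] = idx
        if node.is_leaf():
            name = node.taxon.label if node.taxon else f"tip{idx}"
            tips.append(True)
        else:
            n_internal += 1
            name = node.label or str(n_internal)
            tips.append(False)
        labels.append(name)
        if node.parent_node is None:
            parents.append(-1)
            blens.append(0.0)
        else:
            parents.append(index_of[id(node.parent_node)])
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl < 0:
                raise ValidationError(f"negative branch length ({bl}) on node {name!r}")
            blens.append(float(bl))
    return Phylogeny(
        labels=labels,
        parent=np.asarray(parents, dtype=int),
        branch_length=np.asarray(blens, dtype=float),
        is_tip=np.asarray(tips, dtype=bool),
    )


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted newick tree with branch lengths.

    Ultrametricity (all tip depths equal) is checked within a relative
    tolerance of 1e-6 of tree depth; violations raise a warning and flag
    the tree, they do not abort.
    """
    path = Path(path)
    try:
        dt = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        raise FormatError(f"could not parse {path} as newick: {exc}") from exc
    return _check_ultrametric(_phylogeny_from_dendropy(dt), path.name)


def parse_tree_string(newick: str) -> Phylogeny:
    """Like :func:`read_tree` but from an in-memory newick string."""
    try:
        dt = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"could not parse newick string: {exc}") from exc
    return _check_ultrametric(_phylogeny_from_dendropy(dt), "<string>")


def _check_ultrametric(phy: Phylogeny, source: str) -> Phylogeny:
    depths = phy.depths()[phy.is_tip]
    depth = float(depths.max())
    if depth <= 0:
        raise ValidationError("tree has zero depth")
    if not np.allclose(depths, depth, rtol=ULTRAMETRIC_RTOL,
                       atol=ULTRAMETRIC_RTOL * depth):
        warnings.warn(
            f"tree in {source} is not ultrametric "
            f"(tip depths range {depths.min():.6g}-{depths.max():.6g})",
            stacklevel=3,
        )
        phy.ultrametric = False
    return phy


# ---------------------------------------------------------------------------
# Range polygons
# ---------------------------------------------------------------------------


@dataclass
class RangePolygon:
    """A species range as one or more lon/lat rings (planar degree² areas).

    All study ranges sit comfortably inside the Americas, so geometry is
    treated as planar in degrees; polygons spanning more than 180° of
    longitude (antimeridian ambiguity) are rejected outright.
    """

    geom: Polygon | MultiPolygon
    name: str = ""

    @property
    def area(self) -> float:
        return float(self.geom.area)

    @property
    def parts(self) -> list[Polygon]:
        if isinstance(self.geom, MultiPolygon):
            return list(self.geom.geoms)
        return [self.geom]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.geom.bounds


def _validate_range_geom(geom, name: str) -> RangePolygon:
    if geom.is_empty:
        raise GeometryError(f"range {name!r}: empty geometry")
    if not isinstance(geom, (Polygon, MultiPolygon)):
        raise GeometryError(f"range {name!r}: expected Polygon/MultiPolygon, got {geom.geom_type}")
    minx, miny, maxx, maxy = geom.bounds
    if minx < -180 or maxx > 180 or miny < -90 or maxy > 90:
        raise ValidationError(
            f"range {name!r}: coordinates outside lon [-180,180] / lat [-90,90]"
        )
    if maxx - minx > 180:
        raise ValidationError(
            f"range {name!r}: spans more than 180° of longitude; "
            "antimeridian-crossing ranges are unsupported"
        )
    if not geom.is_valid:
        reason = explain_validity(geom)
        fixed = make_valid(geom)
        if isinstance(fixed, MultiPolygon) and len(fixed.geoms) == 1:
            fixed = fixed.geoms[0]
        if not isinstance(fixed, (Polygon, MultiPolygon)) or fixed.is_empty:
            raise GeometryError(f"range {name!r}: invalid geometry ({reason})")
        warnings.warn(f"range {name!r}: repaired invalid geometry ({reason})", stacklevel=3)
        geom = fixed
    if geom.area <= 0:
        raise GeometryError(f"range {name!r}: zero area")
    return RangePolygon(geom=geom, name=name)


def read_range_polygon(path: str | Path, name: str | None = None) -> RangePolygon:
    """Read a GeoJSON Polygon/MultiPolygon (optionally Feature-wrapped)."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"could not parse {path} as JSON: {exc}") from exc
    props: Mapping = {}
    if obj.get("type") == "FeatureCollection":
        feats = obj.get("features", [])
        if len(feats) != 1:
            raise FormatError(f"{path}: expected exactly one feature, got {len(feats)}")
        obj = feats[0]
    if obj.get("type") == "Feature":
        props = obj.get("properties") or {}
        obj = obj.get("geometry") or {}
    try:
        geom = shape(obj)
    except Exception as exc:
        raise FormatError(f"{path}: not a GeoJSON geometry: {exc}") from exc
    if name is None:
        name = str(props.get("name", path.stem))
    return _validate_range_geom(geom, name)


def range_polygon_from_geojson(obj: Mapping, name: str = "") -> RangePolygon:
    """Build a validated :class:`RangePolygon` from an in-memory GeoJSON mapping."""
    if obj.get("type") == "Feature":
        name = name or str((obj.get("properties") or {}).get("name", ""))
        obj = obj["geometry"]
    return _validate_range_geom(shape(obj), name)


def write_range_polygon(rp: RangePolygon, path: str | Path) -> None:
    """Write a range as a GeoJSON Feature with its name in the properties."""
    feature = {
        "type": "Feature",
        "properties": {"name": rp.name},
        "geometry": mapping(rp.geom),
    }
    Path(path).write_text(json.dumps(feature, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Tabular data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableSchema:
    """Required columns of a measurement table and which must be numeric."""

    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...]


#: per-display roll-snap measurements (one row per display)
ACOUSTICS_SCHEMA = TableSchema(
    name="acoustics",
    required=("species", "individual", "snaps", "duration_s"),
    numeric=("snaps", "duration_s"),
)

#: per-pulse percent relaxation in stimulation trains
FATIGUE_SCHEMA = TableSchema(
    name="fatigue",
    required=("species", "individual", "frequency_hz", "replicate",
              "pulse", "percent_relaxation"),
    numeric=("frequency_hz", "replicate", "pulse", "percent_relaxation"),
)

#: per-pulse contraction/relaxation phase durations
TWITCHSPEED_SCHEMA = TableSchema(
    name="twitchspeed",
    required=("species", "individual", "frequency_hz", "replicate",
              "pulse", "shortening_ms", "lengthening_ms"),
    numeric=("frequency_hz", "replicate", "pulse", "shortening_ms", "lengthening_ms"),
)


@dataclass
class DataTable:
    """A validated measurement table plus its provenance."""

    df: pd.DataFrame
    schema: TableSchema
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.df)


def _validate_table(df: pd.DataFrame, schema: TableSchema, provenance: str) -> DataTable:
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{provenance or schema.name}: missing required column(s) {missing}"
        )
    df = df.copy()
    for col in schema.numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(df[col].to_numpy(dtype=float))
        if bad.any():
            rows = list(np.flatnonzero(bad)[:5])
            raise SchemaError(
                f"{provenance or schema.name}: non-finite values in column "
                f"{col!r} at rows {rows}"
            )
    for col in ("species", "individual"):
        if col in df.columns:
            df[col] = df[col].astype(str)
            if (df[col].str.len() == 0).any():
                raise SchemaError(f"{provenance or schema.name}: empty {col} label")
    return DataTable(df=df, schema=schema, provenance=provenance)


def read_table(path: str | Path, schema: TableSchema) -> DataTable:
    """Read a tab-delimited table with a header row and validate it.

    Unknown columns are preserved untouched.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as TSV: {exc}") from exc
    return _validate_table(df, schema, provenance=path.name)


def table_from_frame(df: pd.DataFrame, schema: TableSchema,
                     provenance: str = "<memory>") -> DataTable:
    """Validate an in-memory DataFrame against a schema."""
    return _validate_table(df, schema, provenance)


def write_table(table: DataTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, lineterminator="\n")
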