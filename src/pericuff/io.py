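"""Readers and writers for cell tables, polygon collections and expression matrices.

Cell tables are delimited text with a header (required columns ``x``, ``y``,
``phenotype``; optional ``cell_id``, ``sample_id``, ``roi_id``).  Polygon
collections are GeoJSON FeatureCollections in the dialect produced by
slide-analysis exports (QuPath-style): Polygon or MultiPolygon geometries
with a marker label in the feature properties.  Expression matrices are
either dense TSV (genes as rows) or MatrixMarket triplets with gene/unit
sidecar lists.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .core import CellMap, ExpressionMatrix, FormatError, MembraneHull

log = logging.getLogger("pericuff")

_REQUIRED_CELL_COLUMNS = ("x", "y", "phenotype")
_OPTIONAL_CELL_COLUMNS = ("cell_id", "sample_id", "roi_id")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_cell_table(
    path,
    column_map: Mapping[str, str] | None = None,
    coord_scale: float = 1.0,
    vocabulary: Sequence[str] | None = None,
) -> CellMap:
    """Read a phenotyped cell table into a :class:`CellMap`.

    Parameters
    ----------
    path
        TSV/CSV file with a header row.
    column_map
        Mapping from canonical names (``x``, ``y``, ``phenotype``, ...) to
        the column names used in the file.
    coord_scale
        Micrometres per input coordinate unit; e.g. ``0.5`` for exports in
        pixels at 0.5 µm/px.  Applied exactly once and recorded in
        provenance.
    vocabulary
        Optional declared phenotype vocabulary; labels outside it are
        coerced to ``Other`` with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if column_map:
        rename = {src: canon for canon, src in column_map.items() if src in df.columns}
        missing_src = [src for src in column_map.values() if src not in df.columns]
        if missing_src:
            raise FormatError(f"mapped column(s) {missing_src} not present in {path.name}")
        df = df.rename(columns=rename)
    for col in _REQUIRED_CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path.name}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise FormatError(f"non-numeric {col} coordinate at row {bad} of {path.name}")
        df[col] = coerced * coord_scale
    keep = [c for c in CellMap.COLUMNS if c in df.columns]
    df = df[keep]
    if vocabulary is not None:
        vocab = set(vocabulary)
        unknown = ~df["phenotype"].astype(str).isin(vocab)
        if unknown.any():
            labels = sorted(df.loc[unknown, "phenotype"].astype(str).unique())
            log.warning("%d cells with unknown phenotype(s) %s mapped to Other", int(unknown.sum()), labels)
            df.loc[unknown, "phenotype"] = "Other"
    return CellMap(df, provenance={"source": str(path), "coord_scale": coord_scale})


def write_cell_table(cell_map: CellMap, path) -> None:
    """Write a CellMap back to delimited text (full float precision)."""
    path = Path(path)
    cell_map.df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")


def read_polygon_collection(
    path,
    marker: str | None = None,
    marker_property: str = "marker",
) -> list[MembraneHull]:
    """Read a GeoJSON FeatureCollection into a list of membrane hulls.

    MultiPolygon features are split into one hull per part; holes are
    preserved.  Non-polygon geometries are skipped with a counted warning
    (real exports contain point/line detection artifacts).  The marker label
    is read from ``properties[marker_property]`` (a QuPath-style
    ``classification: {name: ...}`` dict is also understood) unless an
    explicit ``marker`` overrides it.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    features = doc.get("features", [doc] if doc.get("type") != "FeatureCollection" else [])
    hulls: list[MembraneHull] = []
    skipped = 0
    for i, feat in enumerate(features):
        geom = feat.get("geometry", feat)
        gtype = geom.get("type")
        if gtype not in ("Polygon", "MultiPolygon"):
            skipped += 1
            continue
        props = feat.get("properties") or {}
        label = marker
        if label is None:
            raw = props.get(marker_property, props.get("classification"))
            if isinstance(raw, dict):
                raw = raw.get("name")
            label = str(raw) if raw is not None else "unknown"
        g = shape(geom)
        if not g.is_valid:
            raise FormatError(f"invalid polygon ring in feature {i} of {path.name}")
        parts = list(g.geoms) if isinstance(g, MultiPolygon) else [g]
        for j, part in enumerate(parts):
            hulls.append(MembraneHull(part, marker=label, hull_id=f"{path.stem}_{i}_{j}"))
    if skipped:
        log.warning("%d non-polygon geometries skipped in %s", skipped, path.name)
    return hulls


def write_polygon_collection(hulls: Sequence[MembraneHull], path) -> None:
    """Write hulls as a GeoJSON FeatureCollection with a ``marker`` property."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(h.polygon),
            "properties": {"marker": h.marker, "hull_id": h.hull_id},
        }
        for h in hulls
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_expression(
    path,
    layout: str = "dense",
    genes_path=None,
    units_path=None,
    value_kind: str = "raw_count",
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``layout='dense'``: delimited text, genes as rows, first column gene ids,
    header row of unit ids.  ``layout='triplet'``: MatrixMarket coordinate
    file plus sidecar text files listing gene and unit ids (one per line).
    Both layouts with the same content yield identical matrices.
    """
    path = Path(path)
    if layout == "dense":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicated gene row name {dup!r}")
        return ExpressionMatrix(df.to_numpy(dtype=float), df.index, df.columns, value_kind)
    if layout == "triplet":
        if genes_path is None or units_path is None:
            raise ValueError("triplet layout requires genes_path and units_path sidecars")
        from scipy.io import mmread

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = mmread(path)
        genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
        units = [ln.strip() for ln in open(units_path) if ln.strip()]
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if dense.shape != (len(genes), len(units)):
            raise FormatError(
                f"triplet dimensions {dense.shape} do not match sidecars ({len(genes)} genes, {len(units)} units)"
            )
        return ExpressionMatrix(dense, genes, units, value_kind)
    raise ValueError(f"unknown layout {layout!r}")


def write_expression(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), float_format="%.12g")
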