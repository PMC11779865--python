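"""Domain types for phenotyped-cell spatial analysis.

The central containers are :class:`CellMap` (a phenotyped 2-D point set in
micrometres), :class:`MembraneHull` (a closed polygon, possibly with holes,
delimiting a membrane region or vessel), :class:`ExpressionMatrix`
(genes x units), and small value types for ROI frames and gemistocytic
tumor-cell (GTC) abundance scores.

All public spatial quantities are in micrometres; a coordinate scale is
applied exactly once at read time and recorded in provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

#: Default phenotype vocabulary.  Unknown labels are coerced to ``Other``
#: with a warning when a vocabulary is enforced.
DEFAULT_PHENOTYPES = (
    "TumorCell",
    "GTC",
    "TAM",
    "CD4T",
    "CD8T",
    "BCell",
    "Other",
)

#: Phenotypes counted as T cells throughout the pipeline.
T_CELL_LABELS = frozenset({"CD4T", "CD8T"})

#: ROI frame dimensions of the imaging protocol, in micrometres.
ROI_WIDTH_UM = 670.0
ROI_HEIGHT_UM = 502.0


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular/geometry format."""


@dataclass(frozen=True)
class Cell:
    """A single phenotyped cell centroid."""

    cell_id: str
    x: float
    y: float
    phenotype: str
    sample_id: str = ""
    roi_id: str | None = None


class CellMap:
    """Ordered collection of phenotyped cells with sample/ROI identifiers.

    Backed by a :class:`pandas.DataFrame` with columns
    ``cell_id, x, y, phenotype, sample_id, roi_id``; coordinates are always
    micrometres.  Row order is the ingestion order and is preserved.
    """

    COLUMNS = ("cell_id", "x", "y", "phenotype", "sample_id", "roi_id")

    def __init__(self, df: pd.DataFrame, provenance: Mapping | None = None):
        df = df.copy()
        for col, default in (("cell_id", None), ("sample_id", ""), ("roi_id", None)):
            if col not in df.columns:
                df[col] = default
        if df["cell_id"].isna().any():
            df["cell_id"] = [f"cell_{i}" for i in range(len(df))]
        df["cell_id"] = df["cell_id"].astype(str)
        df["phenotype"] = df["phenotype"].astype(str)
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise FormatError("non-finite cell coordinates")
        if df["cell_id"].duplicated().any():
            dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate cell_id {dup!r} within one CellMap")
        self._df = df[list(self.COLUMNS)].reset_index(drop=True)
        self.provenance = dict(provenance or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterable[Cell]:
        for row in self._df.itertuples(index=False):
            yield Cell(row.cell_id, row.x, row.y, row.phenotype, row.sample_id, row.roi_id)

    @property
    def df(self) -> pd.DataFrame:
        """The underlying table (copy-safe view; do not mutate)."""
        return self._df

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in micrometres."""
        return self._df[["x", "y"]].to_numpy(dtype=float)

    @property
    def phenotypes(self) -> np.ndarray:
        return self._df["phenotype"].to_numpy()

    def subset(self, mask) -> "CellMap":
        return CellMap(self._df[np.asarray(mask)], self.provenance)

    def of_type(self, labels: str | Iterable[str]) -> "CellMap":
        if isinstance(labels, str):
            labels = {labels}
        return self.subset(self._df["phenotype"].isin(set(labels)).to_numpy())

    def counts(self) -> pd.Series:
        return self._df["phenotype"].value_counts()

    @classmethod
    def from_cells(cls, cells: Sequence[Cell], provenance: Mapping | None = None) -> "CellMap":
        df = pd.DataFrame([c.__dict__ for c in cells], columns=list(cls.COLUMNS))
        return cls(df, provenance)

    @classmethod
    def empty(cls) -> "CellMap":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))


@dataclass(frozen=True)
class GtcScore:
    """Gemistocytic tumor-cell abundance score for an ROI or sample.

    ``category`` follows the four-bin histology convention
    (``-`` 0%, ``+`` 0-20%, ``++`` 20-40%, ``+++`` >40%); ``binary_class``
    dichotomizes at the WHO ~20% threshold.  Bin boundaries are right-closed
    and the binary threshold is a strict inequality; see
    :func:`pericuff.scoring.gtc_category`.
    """

    category: str
    fraction: float
    binary_class: str

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"GTC fraction {self.fraction} outside [0, 1]")
        if self.category not in ("-", "+", "++", "+++"):
            raise ValueError(f"unknown GTC category {self.category!r}")
        if self.binary_class not in ("high", "low"):
            raise ValueError(f"unknown GTC class {self.binary_class!r}")


@dataclass
class ROIFrame:
    """A rectangular region-of-interest frame in slide coordinates (µm)."""

    origin_x: float
    origin_y: float
    width: float = ROI_WIDTH_UM
    height: float = ROI_HEIGHT_UM
    tissue_phenotype: str = "unassigned"
    gtc_score: GtcScore | None = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI frame width and height must be positive")

    def polygon(self) -> Polygon:
        x0, y0 = self.origin_x, self.origin_y
        return Polygon(
            [(x0, y0), (x0 + self.width, y0), (x0 + self.width, y0 + self.height), (x0, y0 + self.height)]
        )

    def contains(self, x: float, y: float) -> bool:
        return (
            self.origin_x <= x <= self.origin_x + self.width
            and self.origin_y <= y <= self.origin_y + self.height
        )


class MembraneHull:
    """A closed polygon (possibly with holes) delimiting a membrane region.

    ``marker`` records the stain/compartment the polygon was derived from
    (e.g. ``LAMA2`` parenchymal membrane, ``CD31`` vessel, ``tissue-outline``).
    """

    def __init__(self, polygon: Polygon, marker: str = "LAMA2", hull_id: str | None = None):
        if not isinstance(polygon, Polygon):
            raise TypeError("MembraneHull requires a shapely Polygon")
        if not polygon.is_valid:
            raise ValueError("invalid polygon ring (self-intersecting or malformed)")
        if polygon.area <= 0:
            raise ValueError("polygon has zero area")
        self.polygon = polygon
        self.marker = marker
        self.hull_id = hull_id

    @property
    def area(self) -> float:
        """Enclosed area in µm² (holes subtracted)."""
        return self.polygon.area

    @property
    def exterior(self) -> np.ndarray:
        return np.asarray(self.polygon.exterior.coords)

    @property
    def holes(self) -> list[np.ndarray]:
        return [np.asarray(r.coords) for r in self.polygon.interiors]

    def contains_point(self, x: float, y: float) -> bool:
        """Even-odd containment of a point; boundary counts as contained."""
        from shapely.geometry import Point

        return self.polygon.covers(Point(x, y))

    def __repr__(self) -> str:
        return f"MembraneHull(marker={self.marker!r}, area={self.area:.1f} µm², holes={len(self.polygon.interiors)})"


class ExpressionMatrix:
    """Dense genes x units expression matrix.

    ``units`` are cells, nuclei or samples depending on the assay;
    ``value_kind`` records whether values are raw counts or normalized
    expression (the enrichment score assumes normalized input).
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        unit_ids: Sequence[str],
        value_kind: str = "raw_count",
    ):
        values = np.asarray(values, dtype=float)
        gene_ids = list(map(str, gene_ids))
        unit_ids = list(map(str, unit_ids))
        if values.ndim != 2 or values.shape != (len(gene_ids), len(unit_ids)):
            raise FormatError(
                f"matrix shape {values.shape} inconsistent with {len(gene_ids)} genes x {len(unit_ids)} units"
            )
        if len(set(gene_ids)) != len(gene_ids):
            dup = next(g for g in gene_ids if gene_ids.count(g) > 1)
            raise FormatError(f"duplicate gene id {dup!r}")
        if len(set(unit_ids)) != len(unit_ids):
            raise FormatError("duplicate unit id")
        if value_kind not in ("raw_count", "normalized"):
            raise ValueError(f"unknown value_kind {value_kind!r}")
        if value_kind == "raw_count" and (values < 0).any():
            raise FormatError("negative values in a raw_count matrix")
        self.values = values
        self.gene_ids = gene_ids
        self.unit_ids = unit_ids
        self.value_kind = value_kind
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_rows(self, genes: Sequence[str]) -> np.ndarray:
        idx = []
        for g in genes:
            if g not in self._gene_index:
                raise KeyError(f"gene {g!r} absent from matrix")
            idx.append(self._gene_index[g])
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)


def equivalent_radius(area: float) -> float:
    """Radius of the disk with the given area (µm² -> µm)."""
    return math.sqrt(area / math.pi)
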