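"""Section ingestion and the squares method.

A tissue section is represented by a table of detected cells (one row per
cell, planar coordinates in mm) plus optional necrosis polygons.  The squares
method overlays non-overlapping 1 cm^2 grids of one hundred 1 mm squares on
viable tumour and scores the tumour proportion score (TPS) — the percentage
of viable tumour cells that are marker-positive — in every square.

Coordinate convention: origin at the section lower-left, units mm, and
half-open square membership [x, x+1) x [y, y+1), so each cell belongs to
exactly one square and block boundaries never double-count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box as _box
from shapely.geometry import mapping as _mapping
from shapely.geometry import shape as _shape

from .errors import (
    EmptySectionError,
    FormatError,
    ParameterError,
    UndefinedScoreError,
)

#: Required columns of the cell CSV dialect, in canonical order.
CELL_COLUMNS = ("x_mm", "y_mm", "is_tumour", "viable", "marker_positive")

#: Side of one scoring grid block, mm ("1 cm squares").
GRID_SIDE_MM = 10.0

#: Side of one scoring square, mm.
SQUARE_SIDE_MM = 1.0

#: Default minimum viable tumour cells for a square to be scored.
DEFAULT_MIN_CELLS = 100

#: Default maximum fraction of a square/block that may overlap necrosis.
DEFAULT_MAX_NECROSIS_FRACTION = 0.5

_FLAG_COLUMNS = ("is_tumour", "viable", "marker_positive")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class SectionMap:
    """One tissue section: cell records, necrosis polygons, identity.

    Parameters
    ----------
    section_id
        Unique identifier of the section within a cohort.
    cells
        DataFrame with columns ``x_mm, y_mm, is_tumour, viable,
        marker_positive``; flags are stored as booleans.
    necrosis
        Shapely polygons (mm coordinates) marking necrotic/fibrotic zones.
    extent
        Bounding rectangle ``(xmin, ymin, xmax, ymax)`` in mm; computed from
        the data when not supplied.
    site
        ``"primary"`` or ``"node"``; nodal sections carry a ``station``
        label (``"N1"``, ``"N2"`` ...).
    """

    section_id: str
    cells: pd.DataFrame
    necrosis: list = field(default_factory=list)
    extent: tuple[float, float, float, float] | None = None
    patient_id: str = ""
    site: str = "primary"
    station: str | None = None
    block_id: str = ""
    meta: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise FormatError(f"cell table missing columns: {', '.join(missing)}")
        cells = self.cells.copy()
        for col in ("x_mm", "y_mm"):
            cells[col] = cells[col].astype(float)
        for col in _FLAG_COLUMNS:
            cells[col] = cells[col].astype(bool)
        self.cells = cells.reset_index(drop=True)
        if self.site not in ("primary", "node"):
            raise ParameterError(f"site must be 'primary' or 'node', got {self.site!r}")
        if len(self.cells):
            x = self.cells["x_mm"].to_numpy()
            y = self.cells["y_mm"].to_numpy()
            if not (np.isfinite(x).all() and np.isfinite(y).all()):
                raise ParameterError("non-finite cell coordinates")
            data_extent = (x.min(), y.min(), x.max(), y.max())
        else:
            data_extent = (0.0, 0.0, 0.0, 0.0)
        if self.extent is None:
            self.extent = data_extent
        else:
            xmin, ymin, xmax, ymax = map(float, self.extent)
            if len(self.cells) and (
                data_extent[0] < xmin
                or data_extent[1] < ymin
                or data_extent[2] > xmax
                or data_extent[3] > ymax
            ):
                raise ParameterError("cells fall outside the supplied extent")
            self.extent = (xmin, ymin, xmax, ymax)

    @property
    def viable_tumour(self) -> pd.DataFrame:
        """Cells that are both tumour and viable — the scoring population."""
        c = self.cells
        return c[c["is_tumour"] & c["viable"]]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class GridBlock:
    """One 1 cm^2 scoring block: lower-left origin (mm) and side length."""

    origin: tuple[float, float]
    side: float = GRID_SIDE_MM
    grid_id: str = ""

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        ox, oy = self.origin
        return (ox, oy, ox + self.side, oy + self.side)


@dataclass(frozen=True)
class SquareScore:
    """Score of one 1 mm square within a block, in row-major block order."""

    row: int
    col: int
    n_tumour_cells: int
    n_positive: int
    tps: float  # percent; NaN when the square holds no viable tumour cells
    included: bool
    exclusion_reason: str | None  # None | "too_few_cells" | "necrosis"


@dataclass
class TumourCase:
    """A primary tumour with its nodal metastases (one SectionMap per block)."""

    case_id: str
    primary: list[SectionMap] = field(default_factory=list)
    nodes: list[SectionMap] = field(default_factory=list)

    @property
    def sections(self) -> list[SectionMap]:
        return list(self.primary) + list(self.nodes)


# ---------------------------------------------------------------------------
# Ingestion and serialisation
# ---------------------------------------------------------------------------

def read_necrosis(path: str | Path) -> list:
    """Read necrosis polygons from a GeoJSON FeatureCollection (mm coords)."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    polys = []
    for feat in payload.get("features", []):
        geom = _shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        elif geom.geom_type == "Polygon":
            polys.append(geom)
        else:
            raise FormatError(f"{path}: unsupported geometry {geom.geom_type}")
    return polys


def write_necrosis(polygons: Iterable, path: str | Path) -> None:
    """Write necrosis polygons as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "properties": {}, "geometry": _mapping(p)}
        for p in polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_cells(
    path: str | Path,
    necrosis_path: str | Path | None = None,
    *,
    section_id: str | None = None,
    patient_id: str = "",
    site: str = "primary",
    station: str | None = None,
    block_id: str = "",
    extent: tuple[float, float, float, float] | None = None,
) -> SectionMap:
    """Read a per-cell annotation CSV (plus optional necrosis GeoJSON).

    The dialect is the one written by :func:`write_cells`: UTF-8, header
    required, columns ``x_mm,y_mm,is_tumour,viable,marker_positive`` with
    booleans coded 0/1.  Malformed rows are reported with their file line
    numbers (header = line 1).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptySectionError(f"{path}: empty file") from None
    missing = [c for c in CELL_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    if len(raw) == 0:
        raise EmptySectionError(f"{path}: no cell records")

    bad = pd.Series(False, index=raw.index)
    coerced = {}
    for col in ("x_mm", "y_mm"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad |= ~np.isfinite(vals)
        coerced[col] = vals
    for col in _FLAG_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad |= ~vals.isin([0, 1])
        coerced[col] = vals
    if bad.any():
        lines = [int(i) + 2 for i in raw.index[bad][:20]]  # header is line 1
        raise FormatError(f"{path}: malformed rows at lines {lines}")

    cells = pd.DataFrame({c: coerced[c] for c in CELL_COLUMNS})
    necrosis = read_necrosis(necrosis_path) if necrosis_path else []
    return SectionMap(
        section_id=section_id or path.stem,
        cells=cells,
        necrosis=necrosis,
        extent=extent,
        patient_id=patient_id,
        site=site,
        station=station,
        block_id=block_id,
    )


def write_cells(
    section: SectionMap,
    path: str | Path,
    necrosis_path: str | Path | None = None,
) -> None:
    """Write a section's cells as CSV (and necrosis as GeoJSON if requested)."""
    out = section.cells[list(CELL_COLUMNS)].copy()
    for col in _FLAG_COLUMNS:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    if necrosis_path is not None:
        write_necrosis(section.necrosis, necrosis_path)


# ---------------------------------------------------------------------------
# Grid placement
# ---------------------------------------------------------------------------

def _necrosis_union(section: SectionMap):
    if not section.necrosis:
        return None
    return shapely.union_all(section.necrosis)


def _necrosis_fraction(union, bounds: tuple[float, float, float, float]) -> float:
    if union is None or union.is_empty:
        return 0.0
    cell = _box(*bounds)
    return union.intersection(cell).area / cell.area


def place_grids(
    section: SectionMap,
    max_blocks: int = 3,
    *,
    max_necrosis_fraction: float = DEFAULT_MAX_NECROSIS_FRACTION,
    min_block_cells: int = 1,
) -> list[GridBlock]:
    """Place up to ``max_blocks`` non-overlapping 1 cm^2 blocks on a section.

    Candidate origins lie on the 1 mm integer lattice inside the section
    extent.  Candidates are ranked by contained viable tumour cells
    (descending, ties broken by origin y then x), candidates whose necrosis
    overlap exceeds ``max_necrosis_fraction`` are skipped, and blocks are
    accepted greedily subject to pairwise non-overlap.  Deterministic and
    invariant to cell row order.  An empty list is a valid outcome.
    """
    if max_blocks < 1:
        raise ParameterError("max_blocks must be >= 1")
    vt = section.viable_tumour
    if len(vt) == 0:
        return []
    xmin, ymin, xmax, ymax = section.extent
    side = int(GRID_SIDE_MM)
    x0 = math.ceil(xmin - 1e-9)
    y0 = math.ceil(ymin - 1e-9)
    nx = math.floor(xmax + 1e-9) - x0
    ny = math.floor(ymax + 1e-9) - y0
    if nx < side or ny < side:
        return []

    x = vt["x_mm"].to_numpy()
    y = vt["y_mm"].to_numpy()
    hist, _, _ = np.histogram2d(
        x, y, bins=[np.arange(x0, x0 + nx + 1), np.arange(y0, y0 + ny + 1)]
    )
    # 10x10 box sums over the 1 mm histogram via a 2-D cumulative sum.
    c = np.zeros((nx + 1, ny + 1))
    c[1:, 1:] = hist.cumsum(axis=0).cumsum(axis=1)
    sums = (
        c[side:, side:] - c[:-side, side:] - c[side:, :-side] + c[:-side, :-side]
    )

    candidates = [
        (int(sums[i, j]), x0 + i, y0 + j)
        for i in range(sums.shape[0])
        for j in range(sums.shape[1])
        if sums[i, j] >= min_block_cells
    ]
    candidates.sort(key=lambda t: (-t[0], t[2], t[1]))

    union = _necrosis_union(section)
    chosen: list[GridBlock] = []
    for count, ox, oy in candidates:
        if any(
            abs(ox - b.origin[0]) < side and abs(oy - b.origin[1]) < side
            for b in chosen
        ):
            continue
        if _necrosis_fraction(union, (ox, oy, ox + side, oy + side)) > max_necrosis_fraction:
            continue
        chosen.append(
            GridBlock(
                origin=(float(ox), float(oy)),
                grid_id=f"{section.section_id}:g{len(chosen) + 1}",
            )
        )
        if len(chosen) == max_blocks:
            break
    return chosen


# ---------------------------------------------------------------------------
# Square scoring
# ---------------------------------------------------------------------------

def score_block(
    section: SectionMap,
    block: GridBlock,
    *,
    min_cells: int = DEFAULT_MIN_CELLS,
    max_necrosis_fraction: float = DEFAULT_MAX_NECROSIS_FRACTION,
) -> list[SquareScore]:
    """Score every 1 mm square of a block, returned in row-major order.

    Each square counts viable tumour cells by half-open membership
    ``[x, x+1) x [y, y+1)``.  Squares overlapping necrosis beyond
    ``max_necrosis_fraction`` are excluded with reason ``"necrosis"``;
    otherwise squares with fewer than ``min_cells`` viable tumour cells are
    excluded with reason ``"too_few_cells"``.
    """
    ox, oy = block.origin
    n = int(block.side)  # squares per edge
    vt = section.viable_tumour
    x = vt["x_mm"].to_numpy()
    y = vt["y_mm"].to_numpy()
    pos = vt["marker_positive"].to_numpy()
    inside = (x >= ox) & (x < ox + block.side) & (y >= oy) & (y < oy + block.side)
    col_idx = np.floor(x[inside] - ox).astype(int)
    row_idx = np.floor(y[inside] - oy).astype(int)
    counts = np.zeros((n, n), dtype=int)
    positives = np.zeros((n, n), dtype=int)
    np.add.at(counts, (row_idx, col_idx), 1)
    np.add.at(positives, (row_idx, col_idx), pos[inside].astype(int))

    union = _necrosis_union(section)
    scores: list[SquareScore] = []
    for r in range(n):
        for c_ in range(n):
            nc = int(counts[r, c_])
            np_ = int(positives[r, c_])
            tps = 100.0 * np_ / nc if nc > 0 else float("nan")
            necro = _necrosis_fraction(
                union, (ox + c_, oy + r, ox + c_ + 1, oy + r + 1)
            )
            if necro > max_necrosis_fraction:
                reason = "necrosis"
            elif nc < min_cells:
                reason = "too_few_cells"
            else:
                reason = None
            scores.append(
                SquareScore(
                    row=r,
                    col=c_,
                    n_tumour_cells=nc,
                    n_positive=np_,
                    tps=tps,
                    included=reason is None,
                    exclusion_reason=reason,
                )
            )
    return scores


# ---------------------------------------------------------------------------
# Pooled TPS
# ---------------------------------------------------------------------------

def positivity_counts(
    section: SectionMap, block: GridBlock | None = None
) -> tuple[int, int]:
    """(positive, total) viable tumour cells in a section or block footprint."""
    vt = section.viable_tumour
    if block is not None:
        ox, oy = block.origin
        x = vt["x_mm"].to_numpy()
        y = vt["y_mm"].to_numpy()
        inside = (
            (x >= ox) & (x < ox + block.side) & (y >= oy) & (y < oy + block.side)
        )
        vt = vt[inside]
    return int(vt["marker_positive"].sum()), int(len(vt))


def pooled_tps(
    scope: SectionMap | Sequence[SectionMap],
    block: GridBlock | None = None,
) -> float:
    """Cell-count-weighted TPS over a scope, in percent.

    The scope is one section, a list of sections, or — with ``block`` — the
    footprint of one grid block.  This is the ratio of totals, never an
    average of sub-scores, so pooling over a partition equals the
    cell-weighted combination of the parts.
    """
    if isinstance(scope, SectionMap):
        sections = [scope]
    else:
        sections = list(scope)
        if block is not None:
            raise ParameterError("block restriction requires a single section")
    npos = ntot = 0
    for sec in sections:
        p, t = positivity_counts(sec, block if len(sections) == 1 else None)
        npos += p
        ntot += t
    if ntot == 0:
        raise UndefinedScoreError("no viable tumour cells in scope")
    return 100.0 * npos / ntot
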