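"""Shared fixtures: deterministic hand-built sections with known square counts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tpsgrid import CELL_COLUMNS, SectionMap


def make_cells(x, y, positive, tumour=None, viable=None) -> pd.DataFrame:
    x = np.asarray(x, dtype=float)
    n = len(x)
    return pd.DataFrame(
        {
            "x_mm": x,
            "y_mm": np.asarray(y, dtype=float),
            "is_tumour": np.ones(n, bool) if tumour is None else np.asarray(tumour, bool),
            "viable": np.ones(n, bool) if viable is None else np.asarray(viable, bool),
            "marker_positive": np.asarray(positive, bool),
        },
        columns=list(CELL_COLUMNS),
    )


def section_from_squares(
    square_counts: dict[tuple[int, int], tuple[int, int]],
    *,
    extent=(0.0, 0.0, 10.0, 10.0),
    section_id: str = "fixture",
    **meta,
) -> SectionMap:
    """Build a section whose 1 mm squares hold exactly the given counts.

    ``square_counts`` maps (row, col) — y index, x index from the extent
    origin — to (n_cells, n_positive).  Cells are laid out deterministically
    on a sub-millimetre lattice inside each square.
    """
    xs, ys, pos = [], [], []
    x0, y0 = extent[0], extent[1]
    rng = np.random.default_rng(12345)  # fixed: positives spread, not clustered
    for (row, col), (n, npos) in sorted(square_counts.items()):
        side = int(np.ceil(np.sqrt(n)))
        coords = (np.arange(side) + 0.5) / side
        gx, gy = np.meshgrid(coords, coords)
        px = (x0 + col + gx.ravel()[:n]).tolist()
        py = (y0 + row + gy.ravel()[:n]).tolist()
        xs.extend(px)
        ys.extend(py)
        flags = np.zeros(n, bool)
        flags[rng.choice(n, size=npos, replace=False)] = True
        pos.extend(flags.tolist())
    return SectionMap(
        section_id=section_id,
        cells=make_cells(xs, ys, pos),
        extent=extent,
        **meta,
    )


@pytest.fixture
def homogeneous_section() -> SectionMap:
    """10x10 mm section, 150 cells per square, 30 positive each (TPS 20)."""
    counts = {(r, c): (150, 30) for r in range(10) for c in range(10)}
    return section_from_squares(counts, section_id="homog")
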