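"""Heterogeneity scales, pairwise comparisons and clinical cut-off crossing.

Three scales of intra-tumoural heterogeneity are distinguished: *small*
(variation among the 1 mm squares of one 1 cm^2 grid), *medium* (variation
between grids within one section) and *large* (variation between tissue
blocks, i.e. whole-section pooled scores).  Inter-tumoural comparisons set
the primary tumour against its nodal metastases, and nodal stations against
each other.

Any two TPS values are compared by their absolute difference (the *delta*),
a magnitude category, and the set of clinical guidance cut-offs (>=1%,
>=25%, >=50%) the pair straddles.  A cut-off ``c`` is crossed when
``min(a, b) < c <= max(a, b)``, so 0 vs 1 crosses the >=1% cut-off while
25 vs 25 crosses nothing.  Deltas are categorised after rounding to the
nearest integer percentage point (scores are conventionally reported as
integers); crossing uses the unrounded values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .errors import InsufficientDataError, ParameterError, StructuralError
from .grid import SquareScore, TumourCase, pooled_tps
from .stats import DispersionSummary, dispersion_summary

#: TPS cut-offs (percent) used to guide immunotherapy prescription.
CLINICAL_CUTOFFS = (1.0, 25.0, 50.0)

CAT_NO_CHANGE = "0%"
CAT_LE10 = "<=10%"
CAT_GT10 = ">10%"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (57/107 -> 53%)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class CutoffCrossing:
    """Which clinical cut-offs a pair of TPS values straddles."""

    tps_a: float
    tps_b: float
    delta: float
    crossed: frozenset
    highest_crossed: float | None


def crossed_cutoffs(
    tps_a: float,
    tps_b: float,
    cutoffs: Sequence[float] = CLINICAL_CUTOFFS,
) -> CutoffCrossing:
    """Cut-offs crossed between two scores: ``min < c <= max``; symmetric."""
    for v in (tps_a, tps_b):
        if not (0 <= v <= 100):
            raise ParameterError(f"TPS must lie in [0, 100], got {v}")
    lo, hi = min(tps_a, tps_b), max(tps_a, tps_b)
    crossed = frozenset(float(c) for c in cutoffs if lo < c <= hi)
    return CutoffCrossing(
        tps_a=float(tps_a),
        tps_b=float(tps_b),
        delta=abs(tps_a - tps_b),
        crossed=crossed,
        highest_crossed=max(crossed) if crossed else None,
    )


def magnitude_category(delta: float) -> str:
    """Categorise an absolute TPS difference as 0% / <=10% / >10%."""
    d = round_half_away(abs(delta))
    if d == 0:
        return CAT_NO_CHANGE
    return CAT_LE10 if d <= 10 else CAT_GT10


@dataclass(frozen=True)
class PairComparison:
    """Comparison of pooled TPS between two scopes (e.g. primary vs N2)."""

    label_a: str
    label_b: str
    tps_a: float
    tps_b: float
    delta: float
    delta_rounded: int
    category: str
    crossing: CutoffCrossing


def compare_pair(
    label_a: str, tps_a: float, label_b: str, tps_b: float,
    cutoffs: Sequence[float] = CLINICAL_CUTOFFS,
) -> PairComparison:
    crossing = crossed_cutoffs(tps_a, tps_b, cutoffs)
    delta = abs(tps_a - tps_b)
    return PairComparison(
        label_a=label_a,
        label_b=label_b,
        tps_a=float(tps_a),
        tps_b=float(tps_b),
        delta=delta,
        delta_rounded=round_half_away(delta),
        category=magnitude_category(delta),
        crossing=crossing,
    )


@dataclass
class ScaleResult:
    """Result at one heterogeneity scale.

    ``summaries`` is populated at the small scale (one dispersion summary
    per grid); ``values`` and ``comparison`` at the medium and large scales
    (per-unit pooled TPS and the min-vs-max comparison).
    """

    scale: str
    summaries: list[DispersionSummary] = field(default_factory=list)
    values: dict[str, float] = field(default_factory=dict)
    comparison: PairComparison | None = None


def small_scale(
    scored_grids: Sequence[tuple[str, Sequence[SquareScore]]],
) -> ScaleResult:
    """Dispersion summary per grid, over included squares only.

    Grids with fewer than two included squares are silently dropped; at
    least one qualifying grid is required.
    """
    summaries = []
    for grid_id, squares in scored_grids:
        values = [s.tps for s in squares if s.included]
        if len(values) >= 2:
            summaries.append(dispersion_summary(values, grid_id=grid_id))
    if not summaries:
        raise InsufficientDataError("no grid has >= 2 included squares")
    return ScaleResult(scale="small", summaries=summaries)


def _min_max_comparison(values: Mapping[str, float], scale: str) -> ScaleResult:
    if len(values) < 2:
        raise InsufficientDataError(f"{scale} scale needs >= 2 units, got {len(values)}")
    # Ties broken by label so the comparison is deterministic.
    lo = min(values, key=lambda k: (values[k], k))
    hi = max(values, key=lambda k: (values[k], k))
    return ScaleResult(
        scale=scale,
        values=dict(values),
        comparison=compare_pair(lo, values[lo], hi, values[hi]),
    )


def medium_scale(grid_tps: Mapping[str, float]) -> ScaleResult:
    """Between-grid heterogeneity within one section (min vs max grid TPS)."""
    return _min_max_comparison(grid_tps, "medium")


def large_scale(block_tps: Mapping[str, float]) -> ScaleResult:
    """Between-block heterogeneity of one tumour (whole-section pooled TPS)."""
    return _min_max_comparison(block_tps, "large")


def intertumoural_compare(case: TumourCase) -> list[PairComparison]:
    """Primary-vs-nodes and station-vs-station pooled TPS comparisons.

    The first comparison always pools the primary blocks against all nodal
    tissue.  When two or more stations are present, each station pair is
    compared with cell-weighted pooling per station; when a single station
    holds several nodes, the lowest- and highest-scoring nodes of that
    station are compared (both sides carrying the station label).
    """
    if not case.primary:
        raise StructuralError(f"case {case.case_id}: no primary section")
    if not case.nodes:
        raise StructuralError(f"case {case.case_id}: no nodal section")
    out = [
        compare_pair(
            "primary", pooled_tps(case.primary), "nodes", pooled_tps(case.nodes)
        )
    ]
    by_station: dict[str, list] = {}
    for sec in case.nodes:
        by_station.setdefault(sec.station or "N?", []).append(sec)
    stations = sorted(by_station)
    if len(stations) >= 2:
        for s1, s2 in combinations(stations, 2):
            out.append(
                compare_pair(
                    s1, pooled_tps(by_station[s1]), s2, pooled_tps(by_station[s2])
                )
            )
    elif len(by_station[stations[0]]) >= 2:
        s = stations[0]
        tps = {sec.section_id: pooled_tps(sec) for sec in by_station[s]}
        lo = min(tps, key=lambda k: (tps[k], k))
        hi = max(tps, key=lambda k: (tps[k], k))
        out.append(compare_pair(s, tps[lo], s, tps[hi]))
    return out
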