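"""Worked-example cohort built from published category counts.

The study this package models printed only category counts, not per-case
scores.  These helpers construct a cohort of case results whose pairwise
comparisons and dispersion summaries land exactly in the printed categories,
so the cohort summary's counting and rounding rules can be checked against
the printed percentages end to end.
"""

from __future__ import annotations

from tpsgrid import CaseResult, compare_pair, dispersion_summary, medium_scale
from tpsgrid.scales import ScaleResult, large_scale

# Grid value series engineered to hit each dispersion class exactly:
#   A: mean >= 1, IOD > 1, SD > mean     ([0,0,0,30]: mean 7.5, sd 15, IOD 30)
#   B: mean >= 1, IOD > 1, SD <= mean    ([40,60]: mean 50, sd ~14, IOD 4)
#   C: mean >= 1, IOD < 1                ([50,51]: IOD ~0.01)
#   D: all-zero (mean < 1), IOD = 0
#   Dp: mean < 1 but IOD > 1             (19 zeros + one 9: mean 0.45, IOD 9)
#   E: IOD exactly 1                     ([1,3]: mean 2, variance 2)
SERIES = {
    "A": [0.0, 0.0, 0.0, 30.0],
    "B": [40.0, 60.0],
    "C": [50.0, 51.0],
    "D": [0.0, 0.0],
    "Dp": [0.0] * 19 + [9.0],
    "E": [1.0, 3.0],
}


def _grids(spec: list[tuple[str, int]]):
    out = []
    i = 0
    for kind, count in spec:
        for _ in range(count):
            out.append(dispersion_summary(SERIES[kind], grid_id=f"{kind}{i}"))
            i += 1
    return out


def small_scale_results() -> list[CaseResult]:
    """87 primary and 26 nodal grids: IOD>1 68/19, =1 0/1, <1 19/6;
    SD>mean 32 of 66 primary and 6 of 26 nodal TPS>=1% grids."""
    primary = _grids([("A", 32), ("B", 34), ("Dp", 2), ("D", 19)])
    node = _grids([("A", 6), ("B", 13), ("E", 1), ("C", 6)])
    return [CaseResult(case_id="small", small_primary=primary, small_node=node)]


def medium_scale_results() -> list[CaseResult]:
    """16 sections: 7 no change; 9 changed >=1% of which 3 >=10%;
    2 crossing the >=50% cut-off."""
    sections = (
        [{"g1": 10.0, "g2": 10.0}] * 7
        + [{"g1": 10.0, "g2": 15.0}] * 6
        + [{"g1": 2.0, "g2": 13.0}]
        + [{"g1": 45.0, "g2": 56.0}] * 2
    )
    return [
        CaseResult(case_id=f"m{i}", medium=[medium_scale(s)])
        for i, s in enumerate(sections)
    ]


def large_scale_results() -> list[CaseResult]:
    """61 two-block cases: 33 no change; 28 changed (17 >=10%, 10 >10%);
    5 crossing a cut-off (1 at >=25%, 4 at >=50%)."""
    pairs = (
        [(20.0, 20.0)] * 33
        + [(10.0, 15.0)] * 11  # changed, < 10
        + [(5.0, 15.0), (2.0, 12.0)]  # delta exactly 10, no crossing
        + [(24.0, 34.0)]  # delta 10, crosses 25
        + [(45.0, 55.0)] * 4  # delta 10, crosses 50
        + [(2.0, 24.0)] * 10  # delta 22, crosses nothing
    )
    return [
        CaseResult(case_id=f"l{i}", large=large_scale({"b1": a, "b2": b}))
        for i, (a, b) in enumerate(pairs)
    ]


def primary_vs_nodes_results() -> list[CaseResult]:
    """107 primary-vs-pooled-nodes pairs: 50 no change, 31 <=10%, 26 >10%;
    25 clinical crossings partitioned 12 (>=1%) / 3 (>=25%) / 10 (>=50%)."""
    pairs = (
        [(10.0, 10.0)] * 50
        + [(10.0, 15.0)] * 6  # changed, no crossing
        + [(0.0, 2.0)] * 12  # crosses 1 only
        + [(24.0, 26.0)] * 3  # crosses 25 only
        + [(49.0, 51.0)] * 10  # crosses 50 only
        + [(2.0, 24.0)] * 26  # delta 22, crosses nothing
    )
    return [
        CaseResult(
            case_id=f"p{i}",
            intertumoural=[compare_pair("primary", a, "nodes", b)],
        )
        for i, (a, b) in enumerate(pairs)
    ]


def station_results() -> list[CaseResult]:
    """35 station pairs (4 same-station): 29 no change; 6 changed >=10%, all
    crossing a cut-off (3 at >=1%, 3 at >=50%); clinical denominator is the
    31 cross-station pairs."""
    specs = (
        [("N1", 10.0, "N1", 10.0)] * 4
        + [("N1", 10.0, "N2", 10.0)] * 25
        + [("N1", 0.0, "N2", 10.0)] * 3  # delta 10, crosses 1
        + [("N1", 44.0, "N2", 56.0)] * 3  # delta 12, crosses 50
    )
    out = []
    for i, (la, a, lb, b) in enumerate(specs):
        # station pairs sit after the primary-vs-nodes pair in case results
        out.append(
            CaseResult(
                case_id=f"st{i}",
                intertumoural=[
                    compare_pair("primary", 10.0, "nodes", 10.0),
                    compare_pair(la, a, lb, b),
                ],
            )
        )
    return out
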