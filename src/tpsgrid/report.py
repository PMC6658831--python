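"""Case analysis, cohort summaries and the virtual-biopsy simulation.

``analyze_case`` runs the squares method end to end on one tumour case and
``summarize_cohort`` aggregates case results into the tabular summaries a
pathology study reports: dispersion-flag counts at the small scale, change
categories (0% / <=10% / >10%) with clinical cut-off crossings at the
medium, large and inter-tumoural levels, all with percentages recomputed
from counts and rounded half away from zero to integers.

``simulate_biopsy`` estimates, by Monte Carlo, how often a small specimen
(a 1 mm square or a disc) mis-classifies a section against each clinical
cut-off relative to the whole-section score — the sampling-error question
that motivates quantifying heterogeneity in the first place.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    InsufficientDataError,
    ParameterError,
    StructuralError,
    TpsGridError,
    UndefinedScoreError,
)
from .grid import (
    DEFAULT_MAX_NECROSIS_FRACTION,
    DEFAULT_MIN_CELLS,
    SectionMap,
    TumourCase,
    place_grids,
    pooled_tps,
    read_cells,
    score_block,
)
from .scales import (
    CAT_GT10,
    CAT_LE10,
    CAT_NO_CHANGE,
    CLINICAL_CUTOFFS,
    PairComparison,
    ScaleResult,
    intertumoural_compare,
    large_scale,
    medium_scale,
    small_scale,
)
from .stats import DispersionSummary

logger = logging.getLogger("tpsgrid")

#: Tolerance for classifying an IOD as exactly 1.
_IOD_EQ1_TOL = 1e-9


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the scoring pipeline.

    ``min_cells`` applies the >=100 viable-tumour-cell square rule
    uniformly to primary and nodal grids; ``max_necrosis_fraction`` bounds
    the necrosis overlap tolerated per square and per block candidate.
    """

    max_blocks: int = 3
    min_cells: int = DEFAULT_MIN_CELLS
    max_necrosis_fraction: float = DEFAULT_MAX_NECROSIS_FRACTION
    min_block_cells: int = 1
    cutoffs: tuple[float, ...] = CLINICAL_CUTOFFS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "cutoffs" in raw:
            raw["cutoffs"] = tuple(float(c) for c in raw["cutoffs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        return d


@dataclass
class CaseResult:
    """Everything the pipeline computed for one tumour case."""

    case_id: str
    small_primary: list[DispersionSummary] = field(default_factory=list)
    small_node: list[DispersionSummary] = field(default_factory=list)
    medium: list[ScaleResult] = field(default_factory=list)
    large: ScaleResult | None = None
    intertumoural: list[PairComparison] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def percentage(count: int, denom: int) -> int:
    """Integer percentage, rounded half away from zero (e.g. 57/107 -> 53)."""
    if denom <= 0:
        raise ParameterError("denominator must be positive")
    return int(math.floor(100.0 * count / denom + 0.5))


def _counted(count: int, denom: int) -> dict:
    return {"count": int(count), "pct": percentage(count, denom) if denom else None}


# ---------------------------------------------------------------------------
# Case analysis
# ---------------------------------------------------------------------------

def analyze_case(case: TumourCase, config: PipelineConfig | None = None) -> CaseResult:
    """Run grids, scoring, dispersion and all comparisons for one case.

    Small-scale summaries cover every placeable grid on both primary and
    nodal sections; medium scale needs >= 2 grids in one primary section;
    large scale needs >= 2 primary blocks; the inter-tumoural comparisons
    pool all scored tissue per scope.
    """
    config = config or PipelineConfig()
    result = CaseResult(case_id=case.case_id)

    grids_by_section: dict[str, list] = {}
    for sec in case.sections:
        blocks = place_grids(
            sec,
            config.max_blocks,
            max_necrosis_fraction=config.max_necrosis_fraction,
            min_block_cells=config.min_block_cells,
        )
        scored = [
            (b.grid_id, score_block(
                sec, b,
                min_cells=config.min_cells,
                max_necrosis_fraction=config.max_necrosis_fraction,
            ))
            for b in blocks
        ]
        grids_by_section[sec.section_id] = [(sec, b, sq) for b, (_, sq) in zip(blocks, scored)]
        target = result.small_primary if sec.site == "primary" else result.small_node
        try:
            target.extend(small_scale([(gid, sq) for gid, sq in scored]).summaries)
        except InsufficientDataError:
            pass

    for sec in case.primary:
        placed = grids_by_section.get(sec.section_id, [])
        if len(placed) >= 2:
            grid_tps = {}
            for s, b, _sq in placed:
                try:
                    grid_tps[b.grid_id] = pooled_tps(s, b)
                except UndefinedScoreError:
                    continue
            if len(grid_tps) >= 2:
                result.medium.append(medium_scale(grid_tps))

    if len(case.primary) >= 2:
        block_tps = {}
        for sec in case.primary:
            try:
                block_tps[sec.section_id] = pooled_tps(sec)
            except UndefinedScoreError:
                result.errors.append(f"{sec.section_id}: no viable tumour cells")
        if len(block_tps) >= 2:
            result.large = large_scale(block_tps)

    try:
        result.intertumoural = intertumoural_compare(case)
    except (StructuralError, UndefinedScoreError) as exc:
        result.errors.append(str(exc))
    return result


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Nested count/percentage blocks over a case collection."""

    small_scale: dict
    medium_scale: dict | None
    large_scale: dict | None
    primary_vs_nodes: dict | None
    stations: dict | None
    n_cases: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _summarize_small(summaries: Sequence[DispersionSummary]) -> dict | None:
    if not summaries:
        return None
    n = len(summaries)
    gt1 = sum(1 for s in summaries if s.iod > 1 + _IOD_EQ1_TOL)
    eq1 = sum(1 for s in summaries if abs(s.iod - 1) <= _IOD_EQ1_TOL)
    lt1 = n - gt1 - eq1
    eligible = [s for s in summaries if s.flag_sd_gt_mean is not None]
    sd_gt = sum(1 for s in eligible if s.flag_sd_gt_mean)
    return {
        "n_grids": n,
        "iod_gt1": _counted(gt1, n),
        "iod_eq1": _counted(eq1, n),
        "iod_lt1": _counted(lt1, n),
        "n_tps_ge1": len(eligible),
        "sd_gt_mean": _counted(sd_gt, len(eligible)) if eligible else None,
        "avg_cov": float(np.mean([s.cov for s in summaries])),
    }


def _summarize_comparisons(
    pairs: Sequence[PairComparison],
    cutoffs: Sequence[float] = CLINICAL_CUTOFFS,
    clinical_pairs: Sequence[PairComparison] | None = None,
) -> dict | None:
    """Change-magnitude and cut-off-crossing counts over pair comparisons.

    ``clinical_pairs`` restricts the clinical-change denominator (used for
    station comparisons, where same-station pairs are not judged against
    the cut-offs); it defaults to all pairs.
    """
    if not pairs:
        return None
    n = len(pairs)
    cats = {CAT_NO_CHANGE: 0, CAT_LE10: 0, CAT_GT10: 0}
    for p in pairs:
        cats[p.category] += 1
    changed = [p for p in pairs if p.delta_rounded >= 1]
    ge10 = sum(1 for p in pairs if p.delta_rounded >= 10)
    clin = list(pairs) if clinical_pairs is None else list(clinical_pairs)
    nc = len(clin)
    crossed_any = [p for p in clin if p.crossing.crossed]
    by_cutoff = {
        str(int(c)): _counted(
            sum(1 for p in clin if c in p.crossing.crossed), nc
        )
        for c in cutoffs
    }
    highest = {
        str(int(c)): _counted(
            sum(1 for p in clin if p.crossing.highest_crossed == c), nc
        )
        for c in cutoffs
    }
    deltas = [p.delta_rounded for p in changed]
    return {
        "n": n,
        "no_change": _counted(cats[CAT_NO_CHANGE], n),
        "le10": _counted(cats[CAT_LE10], n),
        "gt10": _counted(cats[CAT_GT10], n),
        "changed_ge1": _counted(len(changed), n),
        "changed_ge10": _counted(ge10, n),
        "delta_range": [min(deltas), max(deltas)] if deltas else None,
        "n_clinical_eligible": nc,
        "clinical_change": _counted(len(crossed_any), nc),
        "clinical_no_change": _counted(nc - len(crossed_any), nc),
        "crossed_by_cutoff": by_cutoff,
        "highest_crossed": highest,
    }


def summarize_cohort(
    results: Sequence[CaseResult],
    cutoffs: Sequence[float] = CLINICAL_CUTOFFS,
) -> CohortSummary:
    """Aggregate case results into cohort-level count tables.

    The unit of small-scale counting is the grid; medium-scale units are
    sections, large-scale units are cases with >= 2 blocks, and the
    inter-tumoural blocks count one primary-vs-nodes pair per case plus all
    station comparisons.  Counting is order-invariant and percentages are
    recomputed from counts.
    """
    if not results:
        raise InsufficientDataError("no case results to summarise")
    small_primary = [s for r in results for s in r.small_primary]
    small_node = [s for r in results for s in r.small_node]
    medium = [m.comparison for r in results for m in r.medium if m.comparison]
    large = [r.large.comparison for r in results if r.large and r.large.comparison]
    pvn = [r.intertumoural[0] for r in results if r.intertumoural]
    station_pairs = [p for r in results for p in r.intertumoural[1:]]
    cross_station = [p for p in station_pairs if p.label_a != p.label_b]
    return CohortSummary(
        small_scale={
            "primary": _summarize_small(small_primary),
            "node": _summarize_small(small_node),
        },
        medium_scale=_summarize_comparisons(medium, cutoffs),
        large_scale=_summarize_comparisons(large, cutoffs),
        primary_vs_nodes=_summarize_comparisons(pvn, cutoffs),
        stations=_summarize_comparisons(
            station_pairs, cutoffs, clinical_pairs=cross_station
        ),
        n_cases=len(results),
    )


# ---------------------------------------------------------------------------
# Virtual-biopsy sampling simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingSimResult:
    """Discordance of specimen-based vs whole-section cut-off classification."""

    k: int
    geometry: tuple[str, float]
    reps: int
    seed: int
    section_tps: float
    discordance: dict
    redraws: int


def simulate_biopsy(
    section: SectionMap,
    k: int,
    *,
    geometry: tuple[str, float] = ("square", 1.0),
    reps: int = 500,
    seed: int = 0,
    cutoffs: Sequence[float] = CLINICAL_CUTOFFS,
) -> SamplingSimResult:
    """Monte-Carlo virtual biopsy: k specimens pooled per replicate.

    Specimen centres are uniform over the section extent, clamped so the
    specimen lies fully inside it (a biopsy samples tissue, not the slide
    margin); a specimen containing zero viable tumour cells is redrawn
    (redraw count reported).
    ``geometry`` is ``("square", side_mm)`` or ``("disc", radius_mm)``.
    Discordance at a cut-off is the fraction of replicates whose pooled
    specimen classification differs from the whole-section classification.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    shape_, size = geometry
    if shape_ not in ("square", "disc") or size <= 0:
        raise ParameterError(f"bad geometry {geometry!r}")
    vt = section.viable_tumour
    if len(vt) == 0:
        raise UndefinedScoreError("section has no viable tumour cells")
    x = vt["x_mm"].to_numpy()
    y = vt["y_mm"].to_numpy()
    pos = vt["marker_positive"].to_numpy()
    xmin, ymin, xmax, ymax = section.extent
    sec_tps = pooled_tps(section)
    sec_class = {c: sec_tps >= c for c in cutoffs}

    rng = np.random.default_rng(seed)
    margin = size / 2.0 if shape_ == "square" else size
    cxmin, cxmax = xmin + margin, xmax - margin
    cymin, cymax = ymin + margin, ymax - margin
    if cxmin > cxmax:
        cxmin = cxmax = (xmin + xmax) / 2.0
    if cymin > cymax:
        cymin = cymax = (ymin + ymax) / 2.0
    redraws = 0
    disagree = {c: 0 for c in cutoffs}
    max_attempts = 1000
    for _ in range(reps):
        npos = ntot = 0
        for _j in range(k):
            for _attempt in range(max_attempts):
                cx = rng.uniform(cxmin, cxmax)
                cy = rng.uniform(cymin, cymax)
                if shape_ == "square":
                    half = size / 2.0
                    mask = (np.abs(x - cx) <= half) & (np.abs(y - cy) <= half)
                else:
                    mask = (x - cx) ** 2 + (y - cy) ** 2 <= size**2
                nc = int(mask.sum())
                if nc > 0:
                    break
                redraws += 1
            else:
                raise TpsGridError(
                    "could not place a specimen containing tumour cells"
                )
            npos += int(pos[mask].sum())
            ntot += nc
        tps = 100.0 * npos / ntot
        for c in cutoffs:
            if (tps >= c) != sec_class[c]:
                disagree[c] += 1
    return SamplingSimResult(
        k=k,
        geometry=(shape_, float(size)),
        reps=reps,
        seed=seed,
        section_tps=sec_tps,
        discordance={str(int(c)): disagree[c] / reps for c in cutoffs},
        redraws=redraws,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _json_ready(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _json_ready(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (frozenset, set)):
        return sorted(_json_ready(v) for v in obj)
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(obj) else float(obj)
    return obj


def _case_result_dict(result: CaseResult) -> dict:
    return _json_ready(result)


def _comparison_rows(results: Sequence[CaseResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        pairs = list(r.intertumoural)
        pairs += [m.comparison for m in r.medium if m.comparison]
        if r.large and r.large.comparison:
            pairs.append(r.large.comparison)
        for p in pairs:
            rows.append(
                {
                    "case_id": r.case_id,
                    "label_a": p.label_a,
                    "label_b": p.label_b,
                    "tps_a": p.tps_a,
                    "tps_b": p.tps_b,
                    "delta": p.delta,
                    "delta_rounded": p.delta_rounded,
                    "category": p.category,
                    "crossed": ";".join(
                        str(int(c)) for c in sorted(p.crossing.crossed)
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "label_a", "label_b", "tps_a", "tps_b",
            "delta", "delta_rounded", "category", "crossed",
        ],
    )


def _dispersion_rows(results: Sequence[CaseResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for site, summaries in (
            ("primary", r.small_primary),
            ("node", r.small_node),
        ):
            for s in summaries:
                rows.append(
                    {
                        "case_id": r.case_id,
                        "site": site,
                        "grid_id": s.grid_id,
                        "n": s.n,
                        "mean_tps": s.mean_tps,
                        "sd_tps": s.sd_tps,
                        "iod": s.iod,
                        "cov": s.cov,
                        "flag_iod_gt1": s.flag_iod_gt1,
                        "flag_sd_gt_mean": s.flag_sd_gt_mean,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "site", "grid_id", "n", "mean_tps", "sd_tps",
            "iod", "cov", "flag_iod_gt1", "flag_sd_gt_mean",
        ],
    )


def cases_from_manifest(manifest_path: str | Path) -> tuple[list[TumourCase], list[str]]:
    """Assemble TumourCases from a cohort manifest CSV.

    Required columns: ``section_id,patient_id,site,station,block_id,path``
    (``necrosis_path`` optional).  Paths are resolved relative to the
    manifest.  Sections that fail to load are skipped and reported; a
    patient with no loadable primary still yields a case so the failure is
    visible downstream.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = ["section_id", "patient_id", "site", "station", "block_id", "path"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ParameterError(f"manifest missing columns: {', '.join(missing)}")
    errors: list[str] = []
    cases: dict[str, TumourCase] = {}
    for _, row in manifest.iterrows():
        patient = str(row["patient_id"])
        case = cases.setdefault(patient, TumourCase(case_id=patient))
        path = manifest_path.parent / str(row["path"])
        nec = row.get("necrosis_path")
        nec_path = (
            manifest_path.parent / str(nec)
            if isinstance(nec, str) and nec
            else None
        )
        station = row["station"] if isinstance(row["station"], str) else None
        try:
            sec = read_cells(
                path,
                nec_path,
                section_id=str(row["section_id"]),
                patient_id=patient,
                site=str(row["site"]),
                station=station,
                block_id=str(row["block_id"]),
            )
        except (OSError, TpsGridError) as exc:
            errors.append(f"{row['section_id']}: {exc}")
            continue
        (case.primary if sec.site == "primary" else case.nodes).append(sec)
    return list(cases.values()), errors


def run_pipeline(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Ingest a manifest, run every stage, and write the cohort report.

    Writes ``cohort_summary.json``, tidy ``comparisons.csv`` and
    ``dispersion.csv``, and one JSON per case under ``cases/``.  Failures of
    individual sections or cases are collected in the report, not fatal.
    Output is deterministic (sorted keys, no timestamps).
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "cases").mkdir(exist_ok=True)

    cases, errors = cases_from_manifest(manifest_path)
    results: list[CaseResult] = []
    for case in cases:
        logger.info("analysing case %s (%d sections)", case.case_id, len(case.sections))
        try:
            results.append(analyze_case(case, config))
        except TpsGridError as exc:
            errors.append(f"{case.case_id}: {exc}")
    if not results:
        raise StructuralError("no case could be analysed")
    summary = summarize_cohort(results, config.cutoffs)

    payload = {
        "config": config.to_dict(),
        "n_cases": summary.n_cases,
        "summary": _json_ready(summary.to_dict()),
        "errors": sorted(errors),
    }
    with open(out_dir / "cohort_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    _comparison_rows(results).to_csv(out_dir / "comparisons.csv", index=False)
    _dispersion_rows(results).to_csv(out_dir / "dispersion.csv", index=False)
    for r in results:
        with open(out_dir / "cases" / f"{r.case_id}.json", "w") as fh:
            json.dump(_case_result_dict(r), fh, indent=2, sort_keys=True)
    return payload
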