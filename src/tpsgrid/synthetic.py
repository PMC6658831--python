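"""Synthetic tumour sections with known ground-truth TPS.

No per-cell data are publicly available for resected tumour cohorts of this
kind, so the package ships a generator that emulates what cell-detection
software exports from a stained section: tumour cells as a homogeneous
planar Poisson process over a rectangular region, marker positivity driven
by a spatially correlated latent Gaussian field passed through a logistic
link, and necrosis as random discs from which cells are removed.

The latent field gives direct control over the two knobs that matter for
heterogeneity experiments: the marginal positive fraction (``target_tps``,
calibrated exactly through the link by solving for the mean offset) and the
spatial scale of patchiness (``correlation_length_mm`` with marginal SD
``field_sd`` on the logit scale).  With ``field_sd = 0`` positivity is iid
Bernoulli and per-square TPS is a scaled binomial proportion — the
analytically tractable limit used to validate the dispersion statistics.

Everything is deterministic given a seed; cohorts derive per-section
substreams from one master seed via ``numpy`` seed sequences.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from numpy.polynomial.hermite import hermgauss
from scipy.fft import next_fast_len
from scipy.optimize import brentq
from scipy.special import expit, logit
from shapely.geometry import Point
from shapely.geometry import box as _box

from .errors import ParameterError, StructuralError
from .grid import CELL_COLUMNS, SectionMap, TumourCase

_GH_NODES, _GH_WEIGHTS = hermgauss(80)
_SQRT2 = math.sqrt(2.0)
_SQRT_PI = math.sqrt(math.pi)

# Lattice resolution bounds for sampling the latent field (mm).
_MIN_LATTICE_SPACING = 0.05
_MAX_LATTICE_SPACING = 1.0
# Correlation lengths below this are indistinguishable from iid noise at
# typical inter-cell spacings.
_IID_CORR_LENGTH = 0.05


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one synthetic section.

    Defaults emulate a resected tumour section: a 10 x 10 mm region at
    500 tumour cells per mm^2 (so a 1 mm square holds ~500 cells, comfortably
    above the 100-cell scoring rule), a whole-section TPS of 30%, and strong
    millimetre-scale patchiness (``correlation_length_mm = 1.5``,
    ``field_sd = 2`` on the logit scale).
    """

    extent_mm: tuple[float, float] = (10.0, 10.0)
    cell_density: float = 500.0
    target_tps: float = 30.0
    correlation_length_mm: float = 1.5
    field_sd: float = 2.0
    necrosis_count: int = 0
    necrosis_radius_mm: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        ext = self.extent_mm
        if np.isscalar(ext):
            ext = (float(ext), float(ext))
        else:
            ext = (float(ext[0]), float(ext[1]))
        object.__setattr__(self, "extent_mm", ext)
        self.validate()

    def validate(self) -> None:
        w, h = self.extent_mm
        checks = [
            (math.isfinite(w) and w > 0 and math.isfinite(h) and h > 0,
             f"extent_mm must be positive, got {self.extent_mm}"),
            (math.isfinite(self.cell_density) and self.cell_density >= 0,
             f"cell_density must be >= 0, got {self.cell_density}"),
            (math.isfinite(self.target_tps) and 0 <= self.target_tps <= 100,
             f"target_tps must lie in [0, 100], got {self.target_tps}"),
            (math.isfinite(self.correlation_length_mm)
             and self.correlation_length_mm >= 0,
             f"correlation_length_mm must be >= 0, got {self.correlation_length_mm}"),
            (math.isfinite(self.field_sd) and self.field_sd >= 0,
             f"field_sd must be >= 0, got {self.field_sd}"),
            (self.necrosis_count >= 0, "necrosis_count must be >= 0"),
            (math.isfinite(self.necrosis_radius_mm) and self.necrosis_radius_mm >= 0,
             "necrosis_radius_mm must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(msg)


@dataclass(frozen=True)
class CaseParams:
    """Parameters of one primary tumour plus its nodal metastases.

    Each node inherits the primary's generative law unless overridden, with
    its ``target_tps`` shifted by ``intersite_shift`` percentage points and
    clipped to [0, 100].
    """

    primary_params: GeneratorParams
    node_specs: tuple[tuple[str, GeneratorParams], ...]
    intersite_shift: float = 0.0
    n_primary_blocks: int = 1
    case_id: str = "case"

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_specs", tuple(
            (str(label), gp) for label, gp in self.node_specs
        ))
        self.validate()

    def validate(self) -> None:
        if len(self.node_specs) == 0:
            raise StructuralError("at least one node spec is required")
        if self.n_primary_blocks < 1:
            raise ParameterError("n_primary_blocks must be >= 1")
        if not math.isfinite(self.intersite_shift):
            raise ParameterError("intersite_shift must be finite")


# ---------------------------------------------------------------------------
# Latent field machinery
# ---------------------------------------------------------------------------

def marginal_positive_fraction(offset: float, field_sd: float) -> float:
    """E[expit(offset + field_sd * Z)] for Z ~ N(0, 1), by Gauss-Hermite."""
    if field_sd == 0:
        return float(expit(offset))
    vals = expit(offset + field_sd * _SQRT2 * _GH_NODES)
    return float(_GH_WEIGHTS @ vals / _SQRT_PI)


def solve_link_offset(p: float, field_sd: float) -> float:
    """Mean offset mu such that the marginal positive fraction equals p."""
    if not 0 < p < 1:
        raise ParameterError("p must lie strictly in (0, 1)")
    if field_sd == 0:
        return float(logit(p))
    return brentq(
        lambda mu: marginal_positive_fraction(mu, field_sd) - p,
        -80.0, 80.0, xtol=1e-12,
    )


def _sample_latent_field(
    rng: np.random.Generator,
    points: np.ndarray,
    extent: tuple[float, float],
    corr_length: float,
    field_sd: float,
) -> np.ndarray:
    """Stationary Gaussian field with squared-exponential correlation.

    Sampled exactly by circulant embedding (FFT) on a lattice that resolves
    the correlation length; cells take the value of their nearest lattice
    node, which preserves the exact marginal N(0, field_sd^2) law that the
    link-offset calibration relies on.  A correlation length at or below the
    lattice floor degenerates to iid noise per cell.
    """
    if field_sd == 0 or len(points) == 0:
        return np.zeros(len(points))
    if corr_length <= _IID_CORR_LENGTH:
        return rng.normal(0.0, field_sd, size=len(points))
    w, h = extent
    spacing = min(
        max(corr_length / 3.0, _MIN_LATTICE_SPACING), _MAX_LATTICE_SPACING
    )
    nx = int(math.floor(w / spacing)) + 2
    ny = int(math.floor(h / spacing)) + 2
    # Pad the embedding torus so wrap-around correlation is negligible.
    pad = int(math.ceil(5.0 * corr_length / spacing))
    mx = next_fast_len(nx + pad)
    my = next_fast_len(ny + pad)
    dx = np.minimum(np.arange(mx), mx - np.arange(mx)) * spacing
    dy = np.minimum(np.arange(my), my - np.arange(my)) * spacing
    d2 = dx[:, None] ** 2 + dy[None, :] ** 2
    kernel = field_sd**2 * np.exp(-d2 / (2.0 * corr_length**2))
    lam = np.clip(np.fft.fft2(kernel).real, 0.0, None)
    z = rng.standard_normal((mx, my)) + 1j * rng.standard_normal((mx, my))
    sample = np.fft.ifft2(np.sqrt(lam) * z) * math.sqrt(mx * my)
    field = sample.real[:nx, :ny]
    xi = np.clip(np.round(points[:, 0] / spacing).astype(int), 0, nx - 1)
    yi = np.clip(np.round(points[:, 1] / spacing).astype(int), 0, ny - 1)
    return field[xi, yi]


# ---------------------------------------------------------------------------
# Section / case / cohort generation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if seed is None:
        raise ParameterError("a seed is required (argument or params.seed)")
    return np.random.default_rng(seed)


def generate_section(
    params: GeneratorParams,
    seed: int | np.random.SeedSequence | None = None,
    *,
    section_id: str = "synthetic",
    patient_id: str = "",
    site: str = "primary",
    station: str | None = None,
    block_id: str = "",
) -> SectionMap:
    """Generate one synthetic section; deterministic given (params, seed).

    Cells are a homogeneous Poisson process at ``cell_density`` over the
    extent, cells inside necrosis discs are removed entirely, and each
    remaining cell is marker-positive with probability
    ``expit(mu + field(x, y))`` where ``mu`` is solved so the marginal
    positive fraction equals ``target_tps / 100``.
    """
    params.validate()
    rng = _as_rng(seed if seed is not None else params.seed)
    w, h = params.extent_mm

    necrosis = []
    for _ in range(params.necrosis_count):
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        r = params.necrosis_radius_mm * rng.uniform(0.6, 1.4)
        if r > 0:
            disc = Point(cx, cy).buffer(r, quad_segs=16)
            necrosis.append(disc.intersection(_box(0, 0, w, h)))

    n = rng.poisson(params.cell_density * w * h)
    xy = rng.random((n, 2)) * np.array([w, h])
    if necrosis and n:
        union = shapely.union_all(necrosis)
        keep = ~shapely.contains_xy(union, xy[:, 0], xy[:, 1])
        xy = xy[keep]

    p = params.target_tps / 100.0
    m = len(xy)
    if p <= 0:
        positive = np.zeros(m, dtype=bool)
    elif p >= 1:
        positive = np.ones(m, dtype=bool)
    elif params.field_sd == 0:
        positive = rng.random(m) < p
    else:
        mu = solve_link_offset(p, params.field_sd)
        fld = _sample_latent_field(
            rng, xy, (w, h), params.correlation_length_mm, params.field_sd
        )
        positive = rng.random(m) < expit(mu + fld)

    cells = pd.DataFrame(
        {
            "x_mm": xy[:, 0],
            "y_mm": xy[:, 1],
            "is_tumour": np.ones(m, dtype=bool),
            "viable": np.ones(m, dtype=bool),
            "marker_positive": positive,
        },
        columns=list(CELL_COLUMNS),
    )
    return SectionMap(
        section_id=section_id,
        cells=cells,
        necrosis=necrosis,
        extent=(0.0, 0.0, w, h),
        patient_id=patient_id,
        site=site,
        station=station,
        block_id=block_id,
        meta={"generator": dataclasses.asdict(params)},
    )


def generate_case(
    params: CaseParams,
    seed: int | np.random.SeedSequence | None = None,
) -> TumourCase:
    """Generate a primary tumour (>= 1 blocks) and its nodal metastases.

    Every node's target TPS is the primary's shifted by
    ``params.intersite_shift`` and clipped to [0, 100]; section substreams
    are spawned from the master seed in a fixed order (primary blocks first,
    then nodes), so cases are reproducible end to end.
    """
    params.validate()
    if seed is None:
        seed = params.primary_params.seed
    if seed is None:
        raise ParameterError("a seed is required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(params.n_primary_blocks + len(params.node_specs))

    primaries = []
    for b in range(params.n_primary_blocks):
        primaries.append(
            generate_section(
                params.primary_params,
                streams[b],
                section_id=f"{params.case_id}-P{b + 1}",
                patient_id=params.case_id,
                site="primary",
                block_id=f"P{b + 1}",
            )
        )
    nodes = []
    for i, (station, node_params) in enumerate(params.node_specs):
        shifted = float(
            np.clip(
                params.primary_params.target_tps + params.intersite_shift, 0.0, 100.0
            )
        )
        gp = dataclasses.replace(node_params, target_tps=shifted)
        nodes.append(
            generate_section(
                gp,
                streams[params.n_primary_blocks + i],
                section_id=f"{params.case_id}-{station}-{i + 1}",
                patient_id=params.case_id,
                site="node",
                station=station,
                block_id=f"{station}-{i + 1}",
            )
        )
    return TumourCase(case_id=params.case_id, primary=primaries, nodes=nodes)


def generate_cohort(
    case_param_list: list[CaseParams],
    seed: int | np.random.SeedSequence,
) -> list[TumourCase]:
    """Generate one case per parameter set, substreamed from a master seed."""
    if len(case_param_list) == 0:
        raise ParameterError("case_param_list must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(case_param_list))
    return [generate_case(cp, st) for cp, st in zip(case_param_list, streams)]


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def generator_params_from_dict(d: dict) -> GeneratorParams:
    allowed = {f.name for f in dataclasses.fields(GeneratorParams)}
    unknown = set(d) - allowed
    if unknown:
        raise ParameterError(f"unknown generator parameters: {sorted(unknown)}")
    if "extent_mm" in d and isinstance(d["extent_mm"], list):
        d = {**d, "extent_mm": tuple(d["extent_mm"])}
    return GeneratorParams(**d)


def case_params_from_dict(d: dict) -> CaseParams:
    """Build CaseParams from a config mapping; nodes inherit primary params."""
    if "primary" not in d or "nodes" not in d:
        raise ParameterError("case config requires 'primary' and 'nodes'")
    primary = generator_params_from_dict(d["primary"])
    node_specs = []
    for spec in d["nodes"]:
        spec = dict(spec)
        station = spec.pop("station", "N1")
        merged = {**dataclasses.asdict(primary), **spec}
        merged.pop("seed", None)
        node_specs.append((station, generator_params_from_dict(merged)))
    return CaseParams(
        primary_params=primary,
        node_specs=tuple(node_specs),
        intersite_shift=float(d.get("intersite_shift", 0.0)),
        n_primary_blocks=int(d.get("n_primary_blocks", 1)),
        case_id=str(d.get("case_id", "case")),
    )


def cohort_params_from_config(config: dict) -> list[CaseParams]:
    cases = config.get("cases")
    if not cases:
        raise ParameterError("cohort config requires a non-empty 'cases' list")
    return [case_params_from_dict(c) for c in cases]
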