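# Methods

## Scoring model

The unit of measurement is the tumour proportion score (TPS): the
percentage of viable tumour cells that are marker-positive. All scoring is
cell-count-weighted — a pooled TPS over any scope (square, grid, section,
group of sections) is the ratio of total positive to total viable tumour
cells, never an average of sub-scores — so pooling over a partition equals
the cell-weighted combination of the parts, and a primary-vs-pooled-nodes
difference can never exceed the most extreme primary-vs-single-node
difference.

The squares method places axis-aligned 10 mm blocks on the 1 mm integer
lattice. The original procedure placed grids by eye; here placement is a
deterministic greedy search: candidates are ranked by contained viable
tumour cells (ties broken by origin y then x), candidates whose
necrosis-polygon overlap exceeds `max_necrosis_fraction` (default 0.5) are
skipped, and blocks are accepted subject to pairwise non-overlap, up to
`max_blocks` (default 3, the observed per-section maximum). Each block's
hundred 1 mm squares bin cells half-open, `[x, x+1) × [y, y+1)`, so
boundary cells count exactly once. Squares are excluded for necrosis
overlap (checked first) or for holding fewer than `min_cells` viable
tumour cells. The ≥100-cell rule was stated only for nodal metastases in
the source procedure; it is applied uniformly to primary grids as well
(configurable), which is the conservative symmetric choice.

## Dispersion statistics

Per-grid square TPS values are summarised by the sample mean, sample SD
(n−1 denominator; the convention is not dictated by the procedure, the
small-sample default is used), the index of dispersion IOD = s²/x̄ and the
coefficient of variation COV = 100·s/x̄ (percent). An all-zero grid has
IOD = COV = 0 by definition so every scored grid is classifiable. The
SD > mean flag is evaluated only for grids with mean TPS ≥ 1%; grids below
that floor are excluded from the flag's denominator.

Two COVs are compared with the size-corrected F-statistic for equality of
coefficients of variation in normal samples,

    F = [ĉ₁²/(1 + ĉ₁²(n₁−1)/n₁)] / [ĉ₂²/(1 + ĉ₂²(n₂−1)/n₂)],

referred to F(n₁−1, n₂−1), two-sided by doubling the smaller tail (capped
at 1). A zero COV in either group is a degenerate comparison: the
statistic collapses to a boundary value (0 or ∞; 1 when both are zero) and
the p-value is reported as its limit with a flag. Simulated type-I error at
nominal 0.05 over 2,000 null pairs (normal samples, n = 30, true COV 0.3)
is checked to lie in [0.03, 0.07] by the acceptance suite.

## Scales and comparisons

Small scale: one dispersion summary per grid over its included squares
(≥ 2 required). Medium scale: per-grid pooled TPS within one section with
≥ 2 grids; the section's delta is max − min. Large scale: whole-section
pooled TPS across ≥ 2 blocks of one tumour, again min vs max. The source
procedure only ever compared two units; with more than two, the (min, max)
pair is the natural generalisation and is what the summary categorises.

Differences are categorised 0 / ≤10% / >10% after rounding the delta half
away from zero to an integer percentage point (scores are conventionally
reported as integers); cut-off crossing uses the unrounded scores with the
rule c ∈ crossed iff min < c ≤ max over c ∈ {1, 25, 50}. Inter-tumoural
comparisons report primary vs all nodal tissue pooled, then station vs
station (cell-weighted pooling per station); a case whose nodes all sit at
one station compares that station's extreme nodes instead. In cohort
summaries the clinical-change denominator for station comparisons is the
cross-station pairs only (same-station pairs are not judged against the
cut-offs), which is how the reference tabulation's denominators reconcile.
Both the per-cut-off crossing counts and the highest-crossed partition are
reported, since published tabulations of this kind are ambiguous between
the two.

Displayed percentages are recomputed from counts and rounded half away
from zero to integers.

## Synthetic sections

The generator emulates a cell-detection export from one stained section:

- cell positions: homogeneous planar Poisson process at `cell_density`
  (default 500 /mm², typical carcinoma cellularity at 20× detection; a
  1 mm square then holds ~500 cells, comfortably above the 100-cell rule)
  over `extent_mm` (default 10 × 10 mm);
- necrosis: `necrosis_count` random discs with mean radius
  `necrosis_radius_mm` (radii jittered ±40%); cells inside are removed
  entirely, mimicking a detection run that skips necrotic zones — the
  viable-flag column is still honoured when ingesting real exports;
- positivity: a stationary Gaussian random field with squared-exponential
  correlation (length `correlation_length_mm`, default 1.5 mm; marginal SD
  `field_sd`, default 2.0 on the logit scale) is passed through a logistic
  link; the mean offset is solved numerically (Gauss–Hermite quadrature +
  Brent root-finding) so the *marginal* positive fraction equals
  `target_tps`/100 exactly.

The field is sampled exactly by FFT circulant embedding on a lattice with
spacing ≈ one third of the correlation length (floor 0.05 mm, torus padded
by 5 correlation lengths; negative embedding eigenvalues, which are
negligible for this kernel, are clipped). Cells take the value of their
nearest lattice node rather than an interpolated value: interpolation
would shrink the marginal variance between nodes and bias the calibration,
whereas nearest-node assignment preserves the exact N(0, field_sd²)
marginal the link-offset solve relies on, at the cost of sub-lattice
blockiness well below the 1 mm scoring scale. Correlation lengths at or
below 0.05 mm degenerate to iid noise per cell. One master seed drives
everything; cases and cohorts spawn per-section substreams in a fixed
enumeration order, so outputs are bit-reproducible.

With `field_sd = 0` positivity is iid and per-square TPS is a scaled
binomial proportion, giving the closed form E[IOD] = 100(1−p)/n for
squares of n cells — the analytic anchor the test suite checks by
simulation. Mean per-grid IOD increases with correlation length while the
length is below the grid scale (patches differentiate the 1 mm squares),
but it is **not** globally monotone: as the correlation length approaches
the 10 mm block, the field is nearly constant within a grid and
square-to-square variation collapses back toward the binomial floor
(measured: mean IOD 15.0 at 1.0 mm vs 14.0 at 3.0 mm). The monotonicity
property is therefore asserted in the sub-grid regime (0.2 / 0.6 / 1.5 mm).

Default generator parameters are a plausible emulation, not an estimate:
no quantitative spatial model of real PD-L1 patchiness was available to
fit. The generator reproduces the *mechanisms* (patchy positivity,
necrosis, density variation across sites) but not tissue anisotropy,
stromal architecture, or detection artefacts, so passing tests demonstrate
correctness of the computations, not biological realism.

## Virtual biopsy

`simulate_biopsy` draws k specimens (1 mm squares by default, or discs)
with centres uniform over the section extent, clamped so specimens lie
fully inside it; specimens containing no viable tumour cells are redrawn
(count reported). The k specimens' cells are pooled into one TPS and
classified against each cut-off; discordance is the fraction of replicates
whose classification differs from the whole-section one. Averaging over
more specimens weakly reduces discordance, which the suite checks with
Monte-Carlo slack.

## Numerical and degenerate-input choices

- Link-offset solve: Brent on [−80, 80], 80-node Gauss–Hermite; exact
  endpoints `target_tps` ∈ {0, 100} bypass the field entirely.
- IOD classified as exactly 1 within 1e−9 (the value arises exactly for
  integer series such as [1, 3]).
- Zero viable tumour cells in a scope raises an undefined-score error;
  fewer than two values raises an insufficient-data error; empty grid
  placements are a valid, logged outcome.
- Pipeline outputs are deterministic: sorted JSON keys, no timestamps.

## Problem sizes

The test and acceptance runs use 5–10 × 5–10 mm sections at 250–500
cells/mm², 20–50 replicates per calibration check, 2,000 null replicates
for the Forkman calibration and 300–400 Monte-Carlo replicates elsewhere —
sizes at which every Monte-Carlo band in the suite is stable across seeds
while the whole suite runs in well under a minute.

## Known limitations

- Grid placement optimises cell count, not "continuous viable tumour" as a
  pathologist would judge it; a qualifying section is simply one with ≥ 1
  placeable grid.
- The per-case COV distributions underlying published cohort-level average
  COVs (and hence their exact Forkman comparison) cannot be reconstructed
  from category counts; the acceptance script reports the test at the
  published grid counts instead.
- Immune-cell scoring, combined positive score, assay cross-comparison and
  pixel-level image analysis are out of scope; the input is a per-cell
  table.
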