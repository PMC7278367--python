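# Methods

## Height extraction model

A crop surface model (CSM) is a single-band elevation raster containing
both canopy and visible soil. For one plot, extraction operates on the
pixels whose centers fall inside the plot boundary — the rectangle covering
the plot's middle two rows over the planted length (3.6576 m × 1.524 m
under the default 15 ft pitch / 30 in row-spacing geometry). Pixel
inclusion is half-open: centers on the minimum-x/minimum-y edges are in,
centers on the maximum edges are out, so adjacent plots never share pixels.

The window is sliced into `n_bins = 20` contiguous pixel-column bins along
the row; when the column count is not divisible by 20, the extra columns go
to the leading bins (widths differ by at most one). Per bin the 3rd and
97th percentile elevations are computed over valid pixels by linear
interpolation between order statistics (index `(n−1)·p/100`, the numpy
default). The percentile pair is configurable (1st/5th etc.), as is the
bin count.

The plot ground elevation is the minimum 3rd-percentile across bins. This
works only if some soil is visible inside each boundary — in real fields
supplied by alleys and row gaps; the method is inapplicable under full
canopy closure or heavy weed cover. Bin heights are `p97 − ground`, floored
at zero (heights are physical lengths; barren bins can dip below the ground
estimate by noise). The plot mean height PH_UAV is the trimmed mean of the
middle 12 bins: bins 5–16 of 20, dropping exactly one maximum and one
minimum bin (ties broken by first occurrence along the row) and averaging
the remaining 10. The 20-bin/middle-12 split is symmetric — four bins
excluded at each end — chosen because the point of the restriction is to
keep alley-adjacent plants out of the average; the exact split is not
otherwise constrained. The comparison estimator PH_95 is the 95th
percentile of all plot pixels minus the same ground elevation.

Days after sowing are computed per plot from its own planting date, since
plantings are staggered.

Boundaries may be generated at a single rotation angle, but binned
extraction requires axis-aligned boundaries (bins are pixel-column slices);
a boundary whose along-row axis is not parallel to a raster axis is
rejected.

## Outlier screening

Within each flight date, a plot height is flagged when it falls strictly
outside mean ± √2·sd (sample sd, n−1). The filter is single-pass by design:
it is *not* idempotent, and applying it twice removes more points. Values
are pooled across treatments within a date. On clean Gaussian data the
expected flag rate is 2(1−Φ(√2)) ≈ 15.7% — on real CSM data the filter
removes far fewer points because genuine extraction artifacts dominate the
tails, whereas on the simulator's clean data it trims the distribution
tails themselves (including tall genotypes). Passing QC-rate checks on
synthetic data therefore says nothing about artifact rejection on real
reconstructions.

## Growth curves and slopes

Each plot's (days, height) series is fit with a least-squares B-spline on
`n_pieces = 20` equal-width pieces of polynomial order 4 (cubic), mirroring
the deliberately over-parameterized piecewise fit this pipeline is built
around; both piece count and order are configurable, so a single-piece
high-order polynomial fit is also expressible. With 8–12 observations the
23-coefficient cubic basis is under-determined; the fit is then regularized
by a second-divided-difference penalty on the coefficients with respect to
the Greville abscissae, at a tiny fixed relative weight (1e−9). The penalty
null space is exactly the straight lines, so the fit is a deterministic
smooth interpolant that reproduces linear (and, over-determined, any
polynomial) trends; a plain minimum-norm coefficient solution was rejected
because it does not reproduce even linear data between observations.
Over-determined systems use ordinary least squares.

The growth-rate curve is the exact piecewise-polynomial derivative.
Extrapolation outside a plot's observed domain is refused (slope features
feed prediction). Slopes are sampled at 100 equidistant times on the grid
spanning the *intersection* of all plot domains, identical across plots.
Heights are meters and slopes m/day internally; the CLI adds cm/day.

In the pipeline, plots whose QC'd series no longer spans the common flight
window are excluded from growth modelling: a single missing terminal
observation would otherwise shrink the shared slope grid into the early
season for every plot.

## Terminal-height prediction

For each of the 100 slope timepoints, the fraction of terminal-height
variance explained alone is the simple-regression R² (computed as
cov²/(var·var), avoiding square roots so exact-threshold ties are
deterministic); timepoints with R² strictly greater than 0.40 are kept.
Screening uses the training quarter only by default — the leakage-free
choice — with `screen_on="all"` available. Adjacent selected timepoints are
not merged. The predictor is OLS on the selected slopes; if selection
exceeds the training size (likely on smooth synthetic slope curves, which
are heavily collinear across adjacent timepoints), the minimum-norm
least-squares solution is used with a warning. Train/test is a uniform
random split, train size `round(0.25·n)`. Held-out performance is reported
as the adjusted R² of predicted vs observed (single-predictor convention),
RMSE, and NRMSE normalized by the observed mean.

## Metrics, resampling, ANOVA

`compute_metrics` reports Pearson r, adjusted R² `1−(1−r²)(n−1)/(n−2)`,
RMSE, and NRMSE (RMSE over the mean of the designated reference series —
deliberately asymmetric). The ruler resampling analysis draws two disjoint
k-plant subsets per plot from full single-row measurements, compares the
two plot-mean vectors across plots, and averages metrics over 100
replicates; for i.i.d. within-row heights with sd σ and k = 2 the expected
squared difference of the two means is σ², the closed form the Monte-Carlo
RMSE is tested against.

The ANOVA is an OLS fixed-effects fit with sequential (type-I) sums of
squares in the order genotype, planting date, density, replicate,
genotype×date, genotype×density, date×density. On the balanced 144-plot
design the degrees of freedom are 11/1/2/1/11/22/2 with 93 residual, and
the type choice is immaterial; on unbalanced data the sequential SS depend
on term order. Replicate is coded crossed with date (1 DF) by default, with
a nested-within-date coding (2 DF) available, and the date×density
interaction can be dropped — the two codings reflect a genuine ambiguity
between the model formula and the printed table this design follows, so
both are implemented rather than one guessed. Missing factorial cells raise
an aliasing error naming the cells.

## Synthetic field simulator

Per-plant true height follows a logistic curve `A/(1+exp(−r(t−t0)))` with
the asymptote per genotype (defaults drawn once in 2.0–2.7 m), rate per
genotype (0.14–0.18 /day) times a density multiplier (higher density
slightly faster), inflection ≈ 42 days after sowing, and per-plant
asymptote spread (sd 0.05 m, truncated positive). A lodging event at a
fixed calendar day multiplies height by (1−severity) instantly, relaxing
linearly to the pre-event trajectory over a recovery period; severity
increases with density (defaults 0.10/0.20/0.30) and by default only the
earliest planting is affected. The severities are free parameters — no
quantitative lodging magnitudes exist to calibrate against.

Rasters are rendered as a planar terrain (default tilt 0.5 cm/m) plus, per
plant, a radially tapered disc: a plateau at the plant's height out to 60%
of the disc radius, then a linear taper to the ground. The radius grows
with height, `r = min(0.06 + 0.4·h, 0.45·row_spacing)`; the 0.45 cap keeps
a thin inter-row soil strip (~10% of plot pixels) visible all season, the
simulator's stand-in for the row-gap/alley ground visibility the ground
estimate requires. I.i.d. Gaussian pixel noise (default sd 1 cm) and a NaN
border ring complete the scene. Within-row plant spacing is
`10000/(density·row_spacing)`, so plot plant counts conserve the nominal
density to within rounding.

What the simulator does **not** emulate: leaf geometry, photogrammetric
artifacts (doming, spatially correlated noise, outlier spikes), weeds,
inter-plot canopy overlap, or full canopy closure. Consequently, passing
truth-recovery tests here validates the percentile/binning logic and its
noise behavior, not robustness to real reconstruction pathology; the
synthetic terminal-prediction R² (~0.99) is far above what heterogeneous
real fields yield, because the simulated slope–terminal relationship is
essentially noiseless.

## Problem sizes and numerical choices

Default simulations run the full 144-plot trial at 2 cm ground sampling
distance with eight flights — small enough for a full season in well under
a minute — with the native 0.82 cm GSD exercised on a four-plot scene; the
extraction code is resolution-independent and validates that every bin
receives at least 25 pixels. Percentiles pin the linear-interpolation
convention in tests; all world coordinates are planar meters in a projected
CRS (EPSG carried through, never reprojected); imperial conversions are
fixed at 1 ft = 0.3048 m, 1 in = 0.0254 m. Every stochastic operation takes
an explicit seed; the pipeline derives per-stage seeds as
`hash(master_seed, stage_name)` so adding a stage never perturbs earlier
stages. Tabular outputs are bit-reproducible under a fixed master seed.
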