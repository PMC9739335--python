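# Methods

## Scope and data model

`ricascade` measures reproductive isolation (RI) between species in a
complex along an ordered sequence of barriers and composes them into total
isolation per directed pair (acceptor × donor). Four inputs drive the
analysis: occurrence points on a multi-layer environmental raster,
flowering-onset records (day within a common season calendar, from a common
garden or from wild observations — never pooled), pollination-cross outcome
counts, and a phylogeny with branch lengths. All four are produced by the
synthetic generator in `ricascade.synth`; all are read and written as plain
text (CSV, ESRI ASCII grid, Newick, JSON).

Conventions: unprojected decimal degrees, lon/lat order, cell-center
coordinates, row 0 = northernmost row, half-open extents
(`n_cols = floor(lon_span / resolution)`), season days 1-based.

## The synthetic study system

The generator emulates a small allopatric/parapatric species complex strung
along a regional climate gradient.

**Environment.** Two monotone gradient layers (`temp_north`: south→north,
0–100; `precip_east`: west→east, 0–100) with smooth low-frequency noise
(default amplitude 2 gradient units), a `seasonality` layer defined as
`(temp_north − 50)² / 25`, and an uninformative smooth `elevation` field.
The quadratic layer is deliberate: a logistic model with linear terms only
cannot express a suitability *band* in the interior of a monotone gradient,
but over {gradient, gradient²} its log-odds span all quadratics — exactly
the log of a Gaussian niche. This plays the role that a rich, partly
non-monotone predictor set (multiple bioclim summaries, elevation, soil)
plays in real landscapes; with only monotone layers, interior species would
be structurally unseparable and SDM skill would be an artifact of niche
position rather than data quality.

**Niches and occurrences.** Each species' true suitability is a product of
per-layer Gaussian kernels, rescaled to max 1. The default scenario places
8 species evenly along `temp_north` (spacing 12.5 units) with breadth =
spacing/4, giving ordered, well-separated latitudinal bands; adjacent true
overlaps are D ≈ 0.05. Presences (default 300/species) are cells drawn
without replacement with probability proportional to suitability, then
jittered uniformly within the cell — cell-level sampling keeps the
pseudo-absence buffer well defined.

**Phenology.** Onset days are Normal(mean, sd) rounded and truncated to
[1, season]. Defaults: a 150-day season, species means evenly spaced
40–110, sd 10 days — most neighbours overlap while the seasonal extremes
barely do. Garden records carry round-robin spatial block labels; year
effects enter as additive mean shifts. The generator does not emulate
within-season censoring, observation effort, or the correlation of onset
with climate.

**Crosses.** Fruits ~ Binomial(pollinations, p_fruit); seeds ~
Poisson(20 × fruits); viable seeds ~ Binomial(seeds, p_viab); pollen
germination ~ Binomial over 50 grains per pollination. Within/between
parameters are chosen by whether acceptor = donor; defaults carry a mild
heterospecific deficit (e.g. fruit 0.55 vs 0.45) so late barriers are weak
but present, mirroring a system isolated mainly by early barriers.

**Tree.** Successive random pairwise joins with exponential waiting times:
an ultrametric, bifurcating tree with positive branch lengths, independent
of the niches — so the RI–distance association is null by construction.

## Species distribution modelling

Pseudo-absences are sampled uniformly without replacement from valid cells
whose center is farther than `buffer_deg` (default 0.05°, planar degrees)
from every presence point and which contain no presence, at `ratio` = 4×
the presences; a shortfall is an error, not a silent truncation. The SDM is
an unpenalized logistic regression (linear terms, no interactions) on all
environment layers, fitted on a class-stratified 70% split; AUC
(Mann–Whitney, ties ½) and the maximum TSS over score-midpoint thresholds
are computed on the held-out 30%. Predictors are standardized internally
and coefficients mapped back to layer units. Complete separation is allowed
to run to the solver's iteration cap: rankings (hence AUC/TSS) are correct
even when coefficient magnitudes diverge.

**Overlap scale.** `predict_surface` returns the inverse-logit probability
map. For niche overlap, however, the pipeline normalizes the *relative
occurrence intensity* `exp(linear predictor)` (`relative_intensity`). In a
presence/background design the intercept absorbs the arbitrary
presence:absence ratio, and the sigmoid flattens high-suitability bands
into plateaus; the normalized probability surface therefore systematically
overstates overlap (measured bias ≈ +0.2 at the default configuration) and
does not converge to the generating overlap as sampling grows. The
exponential of the linear predictor is proportional to the sampling
intensity (the point-process view of presence/background regression), and
the normalized intensity surface recovers the true-suitability overlap to
≈ 0.04 at 500 presences per species. `eco_overlap_scale="probability"`
switches the pipeline to the probability surface for comparison.

**Known limitation.** When niches are broad enough that presences blanket
the landscape section they occupy, nearly every band cell falls inside the
exclusion buffer, the two classes become spatially separable, and the
unpenalized fit overestimates niche narrowness; overlap recovery degrades
(error ≈ 0.15 for breadth ≈ 5 gradient units at 500 presences). The
recovery guarantee is therefore stated for the default, well-separated
scenario, not for arbitrarily broad niches.

## Overlap and barriers

Schoener's D is computed over the full shared valid grid (both surfaces
normalized over the same cells) or over a common week grid; weekly bins are
7 days aligned to season day 1, a final partial week is its own bin, and an
optional symmetric quantile trim (default off) handles outlier wild onset
dates. Results are clamped to [0, 1] against floating-point drift.

Cross summaries are ratios of pooled counts, never means of per-flower
ratios. A treatment × pair cell with fewer than `min_n` = 5 pollination
records is treated as unobserved; by default the "between" fraction pools
all of an acceptor's donors that individually meet `min_n` (the experiment
measures a treatment effect, not donor-specific effects), with a
donor-resolved mode available. A pair whose own between-cross count fails
`min_n` gets MISSING asymmetric barriers even in pooled mode. Both-zero
success yields MISSING with a warning (the barrier is unobservable, not
complete).

Missing barriers propagate as explicit markers: in the cascade they
contribute AC = 0 without consuming remaining gene flow, so partially
tested pairs compose exactly their tested barriers, and output tables carry
a `missing_flag` distinguishing "not tested" from "RI = 0". Negative RI
values propagate unchanged; a heterospecific advantage can lower the total.
Display rounding is half-up to 2 decimals; machine outputs keep full
precision.

## Association

Patristic distances are path sums of branch lengths (via dendropy). The
Mantel statistic is Pearson r on strictly-lower-triangle entries, with the
null from jointly permuting rows and columns of the second matrix and the
add-one p-value (1 + hits)/(1 + permutations); default 9999 seeded
permutations. Because total RI is directional while the test needs one
value per unordered pair, the directed matrix is symmetrized by the
arithmetic mean of the two directions (max/min selectable); the choice is
recorded in the report metadata.

## Determinism and problem sizes

Every generator and every stochastic stage is a pure function of a root
seed; independent streams are derived from the seed plus stable operation
tags, so adding a stage never shifts another stage's draws. The default
problem sizes — a 40 × 78 cell grid, 8 species × 300 presences, 40 garden
and 60 wild flowering records per species, 30 within- and 12
between-pollinations per pair — run the full pipeline in about a second and
were chosen as the smallest configuration at which SDM skill, overlap
recovery and Mantel calibration are all comfortably measurable.

## What passing tests do and do not show

The suite verifies the algebra of the indices and the cascade exactly, and
verifies statistical behavior (SDM skill, overlap recovery, permutation
calibration, null-treatment crosses) on the synthetic system whose
assumptions — independent Gaussian niches on known layers, Normal onset
days, binomial cross outcomes, a tree independent of ecology — are the
analysis' own assumptions. Passing therefore demonstrates correctness of
the machinery, not robustness to field realities such as spatially biased
sampling, non-equilibrium ranges, overdispersed seed counts, or phylogenetic
signal in niches.
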