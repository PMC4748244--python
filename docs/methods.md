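# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic validation does and does not
establish about real data.

## The synthetic experiment

The generator emulates the cryopreserved-PBMC arm of a multi-center
standardization study: `n_centers = 9` sites each stain `n_replicates = 3`
replicates of `n_samples = 3` biological samples with up to four 8-color
panels (T-cell, Treg, B-cell, DC/Mono/NK; the Th1/2/17 panel is excluded
as unusable). Each file carries three scatter channels (FSC-A, FSC-H,
SSC-A), a viability channel (FITC) and seven antibody channels.

**Proportions.** Every panel defines a set of mutually exclusive leaf cell
types with baseline abundances chosen to resemble healthy adult PBMC
(e.g. total CD3+ ≈ 55%, total Treg ≈ 2.6% of cells, plasmablasts ≈ 0.3%).
Each leaf's proportion varies on the logit scale by the crossed model
`y = logit(p) = μ + α_i + β_j + ε_rij` with default SDs
`(σ_sample, σ_center, σ_residual) = (0.5, 0.3, 0.2)` — the same model the
variance module fits, run forwards. Sample effects are redrawn per
dataset; replicates of one (sample, center) share them. Leaves are
renormalized per file to keep at least 1% of events in an unnamed
all-negative remainder, so internal populations are exact sums of leaves
and gated counts are conserved. Reported (population-level) proportions
are ratios of leaf sums under each population's declared denominator;
these ratios are no longer exactly logit-normal, which is why the
parameter-recovery studies draw at the observation level directly.

**Intensities.** Marker intensities live in asinh-transformed space:
negative modes at −2, positive at +2, `high` at +3.5, with per-marker SD
0.5 (4σ separation between modes). Raw intensities are
`sinh(x) · cofactor` with cofactor 150. A per-marker SD of 1.0 was
considered and rejected: with 2σ separation a five-marker phenotype
cannot exceed ~0.9 event-level F1 for any threshold rule, which would make
gating-accuracy validation uninformative; 0.5 is also the more realistic
figure for bright, well-compensated markers on this display scale. The
`marker_sd` knob restores harder mixtures when overlap robustness is the
question.

**Technical effects.** Center-specific distortions are affine maps on raw
fluorescence (gain ~ lognormal(0, 0.08), offset ~ N(0, 3) in raw units),
applied before spillover — mimicking PMT/voltage differences between
instruments. The statistical model constrains center effects only on
proportions; how those effects arise at the intensity level is not
identified by proportion data, so the affine law is this package's
choice. Spillover
mixes raw fluorescence as `observed = true · S`; the default S has 4%
nearest-neighbour and 1% next-neighbour terms. Doublets (3%) are two cells
acquired as one event: areas and fluorescence add, FSC-H takes the
maximum, which puts them far below the FSC-H ~ FSC-A singlet line. Dead
cells (5%) move to a viability mode at +3.5; debris (5%) sits at low
scatter. Defaults of 20,000 events per file keep a full 324-file run in
the minutes range; the validation studies use 30,000 where subset sizes
matter (real files run 50k–480k events).

**What passing does not show.** The mixture is Gaussian in transformed
space with diagonal covariance and no acquisition-time drift, no
cross-marker correlation within a cell type, no center-specific staining
chemistry (e.g. poorly resolving IgD lots), and no mislabeled channels.
Results here validate the machinery — not the claim that any particular
real panel will gate at F1 ≈ 0.99.

## Preprocessing

Compensation solves `true = observed · S⁻¹` (linear solve, not explicit
inverse) and refuses matrices with condition number above 1e8. The default
display transform is asinh with cofactor 150 per fluorescence/viability
channel; a logicle family (T = 262144, W = 0.5, M = 4.5, A = 0) is
provided for real-instrument fidelity, implemented through its closed-form
inverse with a vectorized bisection for the forward map (resolution far
below 1e-10 display units).

Pre-gating is three nested masks. *Cells*: Gaussian-mixture clustering of
(FSC-A, SSC-A) — three components for lymphoid panels, four for the
mononuclear panel, one of which absorbs the doublet cloud so it cannot
steal the debris component — keeping every component whose FSC-A mean is
at least 0.55× that of the heaviest component. This drops debris, keeps
both lymphocyte and monocyte clusters, and keeps everything when the
input is a single cluster. The fit uses five deterministic k-means++
restarts (best likelihood wins); with a single start, one in roughly ten
initializations merged debris into the lymphocyte component. *Singlets*: residuals within 4 MADs of a Theil–Sen fit of
FSC-H on FSC-A (the slope is fitted on a deterministic 2,000-event
subsample; the exhaustive pairwise fit is quadratic in n). *Viable*:
below the density cut-point on the transformed viability channel.

## Gating engine

1-D cut-points come from a Gaussian KDE on a 512-point grid over the data
range padded 5%, Silverman bandwidth × a configurable factor. Local maxima
with height ≥ 5% of the global maximum are candidate modes; peaks closer
than 2.5 bandwidths are ripples of one mode and are merged (tallest
representative wins). With ≥ 2 modes the threshold is the leftmost grid
minimizer between the two tallest; a perfectly symmetric sample therefore
cuts exactly at the center when the grid contains it (odd grid sizes).
With one mode the threshold is mode ± k·(MAD-based SD), k = 3 by default,
on the side with the longer tail unless the template says otherwise.
Below 200 events the cut falls back to the median with a warning —
deliberately conservative, mirroring how rare parents (e.g. CD8-activated
cells) defeat density estimation in practice. Tail gates for `high`
phenotypes use mode + k·robust SD (k = 3), widening to the 0.99 quantile
below 50 events. Quadrant gates use the closed-on-positive convention
(value ≥ cut is "+"); all four quadrants share cuts computed once per
(parent, marker), so they partition the parent exactly.

Templates are CSV rows (alias, parent, dims, method, args, signs,
denominator, report) evaluated in order; parents must precede children,
denominators must be ancestors. The four built-in templates are
reconstructions of the panels' standard phenotype definitions, with two
resolved ambiguities: "Transitional" B cells are gated CD24high/CD38high
within CD19+CD20+ (a bare CD19+/CD20+ definition would duplicate the CD20
gate), and the Treg hierarchy omits the CD8 dimension its panel does not
stain. Plasmablasts are gated CD20−/CD24high/CD38high.

## Statistics

Proportions from counts are corrected to `(k + 0.5)/(n + 1)` before the
logit, so empty subsets stay finite. REML maximizes the restricted
log-likelihood over log-variances (L-BFGS-B, moment-estimator start,
bounds keeping components ≥ 1e-10); estimates at the lower bound are
reported as exactly 0 and flagged. On balanced designs with interior
moments, REML and the ANOVA estimator agree to ~1e-6, which the tests
assert. With only 3 samples the sample component has 2 degrees of freedom:
its REML estimate is mean-unbiased but median-biased low by ~30% on the
variance scale (~16% on the SD scale) — a property of the design, not the
estimator, visible in the recovery studies.

Sample-level estimates refit with fixed per-sample means and random center
effects, and report GLS estimates with t-intervals at `n_centers − 1`
degrees of freedom. A plain z-interval was measured at 92.6% true coverage
here (the center variance is estimated from 8 df), at the edge of the
92–98% target band; the t-interval sits at ~95.8%. Bias between methods is
the logit-scale difference of sample-level estimates with a
summed-variance interval (independent-estimate approximation);
significance means that interval excludes 0, with the more conservative
CI-overlap rule also reported. Power formulas use normal quantiles
(classical closed form); sizing a t-test analysis with z quantiles costs
~1–3 points of power at n = 16, which the Monte-Carlo self-check shows.

CV summaries report within-site CV (across replicates, averaged over
centers) and between-site CV (across per-center means), per sample and
pooled. Note that when σ_center = 0 the between-site CV of r-replicate
center means concentrates at 1/√r of the within-site CV; the two are not
exchangeable estimates of the same number.

The local-gating power scenario needs the excess variance of site-specific
over central gating; with no human analysts here, the comparator is a
second automated pass with KDE bandwidth widened 1.6×, and the excess
(center + residual) variance of that pass is used, clipped at zero.

## Known limitations

- Populations are modelled and analyzed independently; correlations
  between subsets of one panel are ignored (as in the source analysis).
- The FCS reader covers only the float list-mode subset this package
  writes; it is not a general FCS parser.
- 2-D data-driven gate shapes (ellipses, polygons) are out of scope; all
  gates reduce to per-axis thresholds.
- Truth proportions for populations whose predicate no generated cell type
  satisfies are 0 and their logits are clamped; such populations (all
  flagged unreliable) carry no information in the variance stage.
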