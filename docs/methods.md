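# Methods

## Bliss scoring of combination screens

Viability is carried as a fraction of vehicle control; readers accept a
`percent` flag and divide by 100 once, at I/O, so the core never
double-converts. Fractional activity is Fa = 1 − viability, clamped to
[0, 1]. Values above control (viability > 1) therefore clamp to Fa = 0 —
the assay admits super-control growth and the data model deliberately
flags rather than clamps at I/O, leaving the decision to the scoring
layer where it is logged. Clamping keeps Excess over Bliss inside
[−100, 100] points.

Replicates are averaged **on the viability scale** before the Fa
conversion (matching how replicate plate readings are normally combined);
`score_matrix(..., average="fa")` switches to Fa-scale averaging for
sensitivity analysis. Every combination well must have both monotherapy
margins at exactly matching concentrations in the same matrix — a missing
margin is a validation error, not an NaN.

Two designs are supported. The *diagonal* (fixed-ratio ray) design pairs
the k-th dilution of drug A with the k-th dilution of drug B; series of
unequal length are an error, never truncated. The *full* design scores
every grid cell. A cell line's combination score is the maximal EoB over
its dose pairs; the dose pair reported for the maximum breaks ties toward
the lowest total concentration (the value is unaffected). Panel ranking
averages per-line maxima; pairs missing from some lines are averaged over
the lines they have and flagged, and rank ties share the smaller rank.

Taking a maximum over noisy wells is upward-biased: on Bliss-null
matrices with 5 % multiplicative noise and triplicates the *mean* EoB
stays within a fraction of a point of zero (slightly negative, because
noisy viabilities above 1 clamp to Fa = 0), while the *maximum* sits
several points above zero. Ranking is therefore validated on recovery of
an injected ordering, not on absolute maxima.

## Interaction transcriptomics

The analysis runs at a single timepoint (default label "24h"; the
timepoint is a config field of the experiment, not hard-coded). The
classifier is two-stage:

1. **DE stage.** Per gene, a pooled within-condition variance (residual
   df = N − 4) is shrunk toward a common prior by empirical Bayes: a
   scaled inverse-chi-square prior (d0, s0²) is fitted to the variance
   distribution by matching moments of log s² (Newton inversion of the
   trigamma function), and the posterior variance
   (d0·s0² + d·s²)/(d0 + d) feeds two-sample t statistics of each
   treatment arm against vehicle with d + d0 degrees of freedom.
   P-values are BH-adjusted jointly across genes × 3 contrasts; a gene is
   DE if any contrast has q ≤ α (default α = 0.05).
2. **Interaction stage.** Restricted to DE genes, the contrast
   `combination − drug_a − drug_b + vehicle` (deviation from the additive
   log2 expectation) is tested two-sided with the same moderated
   variance, BH-adjusted among DE genes. The sign of a significant
   deviation gives the positive/negative interaction call.

This two-stage scheme is an explicit interpretation: the upstream study
this pipeline emulates delegated DE detection and its profile taxonomy to
an unpublished in-house algorithm, so the additive log2 null and the
moderated-t framework here are our stand-in, with α, the variance
moderation and the tie tolerance all configurable.

Profile labels rank the four condition means with an ε tolerance equal to
the pooled standard error of a difference of two condition means;
means within ε share a rank, members of a tied group are listed in fixed
V, A, B, C order (e.g. `C<V=A=B` for combination-specific repression).
This yields a finite label set comparable across runs.

A known property of any select-then-test cascade: genes that enter stage
2 through a *false* stage-1 discovery were selected for extreme noise,
so their interaction p-values are not uniform and the realized
false-discovery proportion among interaction *calls* can exceed α even
though the miscall rate measured over all truly non-interacting genes
stays well below α (~1.5 % at α = 0.05 in the bundled study). The
classifier's guarantees are therefore stated on the null-gene miscall
rate.

## In-vivo RTV

Volume from perpendicular caliper diameters uses the standard
`V = (min(d1,d2)² × max(d1,d2))/2`; an ellipsoid variant is available and
recorded in output metadata when used. Baseline is the last measurement
at or before the first dosing day (configurable to an earlier
randomization day); RTV exactly 1.0 counts as response, per the
"RTV ≤ 1" stabilization definition. Group growth curves report per-day
mean ± SD (ddof = 1) of per-mouse relative volumes; missing days are
reported absent, never interpolated, and single-animal groups get SD 0
with a flag.

The Mann–Whitney test is two-sided with
`p = P(|R − E[R]| ≥ |r_obs − E[R]|)` under random group assignment,
computed by exact dynamic-programming enumeration of the rank-sum
distribution (midranks, so ties are handled) for combined n ≤ 16 —
which covers the emulated study's 8–9 animals per arm — and by the
tie-corrected normal approximation above that. Significance tiers are
* p<0.05, ** p<0.005, *** p<0.0005.

## Synthetic data

The generators define the study conditions the analyses are validated
under:

- **Screens** follow the emulated assay's geometry: 10 concentrations per
  drug including vehicle, serial 1:4 dilutions, diagonal design,
  triplicates; the default top dose is 16× the EC50 (Hill emax 0.9,
  slope 1) so activity saturates within the first half of the series.
  Full 6×6 grids use the same machinery with `n_doses=6`. Per line and
  drug the EC50 is jittered lognormally (sd 0.3 on the log scale) to
  emulate panel heterogeneity. Synergy is injected *on the Fa scale* as
  an additive delta to the Bliss expectation (uniform or dose-peaked),
  so ground truth is in the analysis's own units; the combination Fa is
  clamped to [0, 1], and clamped wells cannot carry the full delta.
  Noise is multiplicative Gaussian on viability (CV-like, matching plate
  assays), truncated at −100 % so viability stays non-negative.
- **Expression** experiments plant single-agent log2 shifts of magnitude
  U(1, 2) with random signs on the DE genes and a ±`effect` deviation
  from additivity on the interaction genes; remaining genes are flat.
  Truth labels depend only on the gene index, so changing the seed
  changes the noise but never the labels. Defaults (2000 genes, duplicate
  arms, σ = 0.25) mirror a small targeted array experiment; recovery
  studies use triplicates.
- **Growth** studies are exponential, v(t) = v0·exp(rate·effect·t), with
  lognormal measurement noise and twice-weekly measurements over 4 weeks,
  8 mice per arm; arm effects default to control 1.0, single agents 0.6
  and 0.4, combination 0.1 (a synergistic combination slows growth more
  than either monotherapy). Volumes are emitted as two equal caliper
  diameters d = (2V)^(1/3), exercising the volume formula on the way
  back in.

What the generators do **not** emulate: dose-response shapes other than
Hill curves, plate-position or batch effects, correlated gene modules and
heavy-tailed expression noise, tumor-growth deceleration or regressing
tumors, and dropout/death of animals. Passing recovery tests therefore
demonstrates correctness and calibration of the computations, not
robustness to every artifact of real data.

## Problem sizes and numerical choices

Calibration and recovery studies run at: 1000 Bliss-null matrices
(triplicates, σ = 0.05) for null calibration; 200 panels × 10 lines with
injected deltas 5/10/20/40 points (σ = 0.02) for rank recovery; 100
simulated experiments of 2000 genes (500 interaction, 300 additive-DE,
1200 null; |effect| = 2, σ = 0.25, n = 3) for classifier recovery. These
sizes give Monte-Carlo error comfortably below the margins being checked
while keeping a full run under a minute each.

Floats are written with `%.12g` so CSV round trips are stable to 1e-9 and
pipeline reruns are byte-identical; manifests carry no timestamps. Exact
Mann–Whitney uses doubled midranks (always integers) for the DP. The
trigamma inversion in variance moderation falls back to complete
shrinkage (d0 = ∞) when the observed log-variance spread is no larger
than expected under a single common variance; genes with zero residual
variance are flagged `degenerate`, their tests resolved by the shrunk
variance (t = 0 where the contrast is also zero).
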