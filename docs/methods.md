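# Methods

This note documents the models and procedures implemented in `metabofuse`,
the assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic test bed can show.

## Problem setting

A seasonal plant-metabolomics study measures the same leaf extracts on two
platforms: 2D J-resolved NMR (reduced to its 1D chemical-shift projection)
and untargeted LC-MS in both ionization polarities (reduced, by MZmine-style
processing upstream of this package, to an aligned feature table of peak
areas). The scientific question is which chemical variables — δ buckets on
the NMR side, m/z features on the MS side — discriminate the harvest
seasons, and what compounds they correspond to. The package implements the
full mid-level-fusion route: each platform is reduced to a feature matrix,
the matrices are scaled as blocks and concatenated, and one supervised
latent-variable model is fit on the fused matrix.

## Preprocessing

**NMR binning.** Each projection is bucketed over 0.0–9.0 ppm at 0.04 ppm,
giving 225 variables. A bucket's value is the arithmetic mean of the
intensities of the axis points falling inside it; bins are half-open on the
right with a right-closed final bin, empty bins emit 0 (not missing, so the
matrix stays complete), and points outside the range are ignored. The mean
(rather than the sum) makes bucket values comparable across acquisition
grids of different densities; the summed-intensity convention is available
via `statistic="sum"`. Descending (instrument-order) axes are canonicalized
to ascending order first so both orientations give bit-identical output.

**MS curation.** Every feature with any signal above a configurable
threshold (default 0) in a solvent blank is deleted, and blank columns are
dropped. A retention-time/mass window check on the external standard
(reserpine, 11.38 ± 0.2 min, m/z 609.2794 [M+H]+, 3 ppm) reports whether
the run passed QC; the expected m/z is a parameter, not derived from a
formula. Accurate-mass utilities use reference monoisotopic atomic masses
(C = 12 exact; H, N, O, S to ≥ 7 decimals) and proton-mass adduct
arithmetic — [M+H]+ = M + 1.00727646, [M−H]− = M − 1.00727646 — which is
what reproduces positive-mode literature values to 4 decimals. Molecular
formula prediction enumerates CHNOS compositions inside explicit element
bounds and keeps candidates within the ppm tolerance that also pass the
standard plausibility heuristics: H/C in [0.2, 3.1], O/C ≤ 1.2, RDBE ≥ 0
and integral for even-electron neutrals. These heuristics are a documented,
configurable subset of the rule sets used by formula-assignment tools, not
an exhaustive reimplementation of any of them. Dereplication computes, for
every feature, the theoretical m/z of every library compound under the
default adduct of the feature's polarity ([M+H]+ for positive, [M−H]− for
negative) and emits all matches within tolerance (default 3 ppm),
optionally restricted to library entries sharing a taxon tag. Matches rest
on accurate mass alone and are therefore labelled confidence Level 3.

## Block-wise fusion

Before concatenation each block is scaled as a unit:

x̂ = x / Σσ_block,  where Σσ_block is the sum of the block's per-variable
sample standard deviations (ddof = 1).

After this scaling the per-variable SDs of each block sum to 1, so the two
platforms enter the fused matrix with balanced total variation despite
their very different raw scales (NMR bucket means vs MS peak areas) and
variable counts (225 vs ~90). The alternative reading of the same formula —
multiplying by the dataset size — only rescales each block by a constant
and cannot balance the blocks, so it was rejected. Block scaling happens at
fusion time; centering and Pareto scaling happen inside the modelling step,
i.e. Pareto is applied to the already block-scaled fused matrix (the order
is a documented choice; the source workflow does not pin it down). Variables
with zero variance are scaled like the rest but flagged.

## Latent-variable models

All models are fit natively (NIPALS-family algorithms); scikit-learn's PLS
appears only as an independent cross-check in the test suite.

**Pareto scaling.** Column-wise (x − mean)/√SD, ddof = 1; zero-variance
columns are centered and left undivided. Pareto is the chemometrics middle
ground between no scaling and unit variance: it shrinks the dominance of
intense signals without blowing up baseline noise.

**PLS-DA.** NIPALS PLS2 against the centered class dummy matrix (one 0/1
column per season). Per component: alternate w ← Xᵀu/uᵀu (normalized),
t ← Xw, c ← Yᵀt/tᵀt, u ← Yc/cᵀc until the relative change of t falls below
1e-10, then deflate X and Y by the rank-one fits. The inner loop converges
linearly at the eigen-gap rate of XᵀYYᵀX; label-permuted refits routinely
produce nearly degenerate component pairs for which no iteration budget
reaches 1e-10, so at the cap (5000 iterations) a component whose relative
score change is below 1e-4 is accepted — within a near-degenerate
eigenspace any such vector explains the same variance to far better than
the precision at which R²/Q² are read — and only genuine non-contraction
raises an error. Each weight vector is signed so its largest-magnitude
entry is positive, making plots reproducible. The default component count
is 2 (score/loading plots are two-dimensional); it is configuration, not an
auto-selection rule.

**OPLS-DA.** For a binary or one-vs-rest contrast response: iteratively,
the orthogonal weight is the part of the X-loading not along the predictive
weight; its component t_o p_oᵀ is removed from X (default one orthogonal
component), after which a single predictive component is fit. Reported are
R2X(pred) = ‖t pᵀ‖²/‖X‖² (between-group variation) and
R2X(ortho) = Σ‖t_o p_oᵀ‖²/‖X‖² (within-group variation). The multiclass
season design is handled as one-vs-rest against the most distinct season,
chosen automatically as the class whose PLS-DA score centroid lies farthest
from the overall centroid.

**Inner relation.** OLS of the first Y-scores u₁ on the first X-scores t₁;
its R² (squared Pearson correlation) summarizes how faithfully the X-side
projection tracks the class structure.

**VIP.** VIP_j = √(p · Σ_a (w_ja/‖w_a‖)² SSY_a / Σ_a SSY_a) with p the
number of variables and SSY_a the Y sum of squares explained by component
a. The mean of squared VIPs is exactly 1, so VIP > 1 marks above-average
contributors.

**Q².** 1 − PRESS/SS with venetian-blind assignment of samples to 7 folds
after a seeded shuffle; each fold is predicted by a PLS model refit on the
rest (centering from the training fold). Seven folds is the de-facto
default of commercial chemometrics software; every class must remain
represented in every training fold or the call errors with a suggestion to
lower the fold count.

**Permutation validation.** Class labels are permuted n = 100 times, the
model refit, and R²/Q² regressed on the absolute correlation between the
permuted and original class assignments (the unpermuted model enters as the
correlation-1 point). The model is flagged valid when the R² line lies
above the Q² line, the Q² intercept is negative, and the original Q²
exceeds every permuted Q². The last condition is needed for the flag to
mean anything: a pure-noise model has uniformly poor permuted Q² values and
hence a negative Q² intercept, so the intercept conditions alone would
declare it valid.

## Discriminant selection

Variables are ranked by VIP and the top k = 15 taken as candidates
(descending VIP, ties broken lexicographically for determinism). Each
candidate's seasonal effect is tested by one-way ANOVA across the four
seasons on the unscaled (pre-Pareto) intensities — ANOVA p-values are
invariant to the per-block constant of the fusion scaling. Candidates with
p ≤ 0.05 are ranked from smallest to largest p and each is assigned the
Benjamini–Hochberg critical value FDR_i = (i/m) × Q with Q = 0.05 and m the
number of ranked candidates, reported to 3 decimals.

Because (i/m) × Q never exceeds Q, the rule "retain when FDR ≤ Q" keeps
every p ≤ 0.05 candidate: the FDR column of this classical workflow is
descriptive, not a further filter, and it does not control the false
discovery rate (simulated null studies yield at least one "discriminant"
over 90% of the time under it). The pipeline therefore defaults to the
standard BH step-up procedure applied over all tested variables
(`fdr_method="bh"`), which in the same null simulations leaves roughly the
nominal fraction of studies with any discovery; the verbatim rank rule
(`fdr_method="paper"`, `fdr_rank`) is kept both for reproducing published
discriminant tables and because its arithmetic is a fixed, testable
transform. Selected discriminants are the intersection of the top-k VIP set
with the FDR-retained set, ordered by p.

Group summaries report per-season mean ± SD and n, box-plot five-number
summaries, the ANOVA F and p, and Tukey HSD adjusted pairwise p-values
(studentized range, via statsmodels).

## Synthetic seasonal studies

The generator emulates the target study design: 4 seasons (SPR/SUM/AUT/WIN)
× 3 independent harvests × 3 replicate extracts = 36 samples, 0.0–9.0 ppm
projections (2048 points by default), and a 90-feature curated MS block,
plus 2 solvent blanks, 3 blank-borne contaminant features and a planted
QC-standard feature. Six discriminants are planted per block: half follow a
triterpene-like pattern (aliphatic shifts 0.5–3.1 ppm, late-eluting apolar
m/z features, intensity rising monotonically SPR → WIN), half a
flavone-like pattern (aromatic shifts 6.5–8.0 ppm, glycoside m/z features,
rising WIN → SPR). The seasonal effect is multiplicative on the mean —
multipliers follow a geometric ladder between 1 and the effect size
(default 4) across the season order — and all intensities carry log-normal
multiplicative noise at a default CV of 0.2 plus a mild per-sample dilution
factor (CV 0.05). NMR peaks are Lorentzian (half-width 5–8 mδ, centered in
their bins) on a small non-negative (half-normal) baseline; planted MS
features sit at the theoretical adduct m/z of real compound formulas with
±1.5 ppm jitter, so dereplication against the built-in library annotates
them. Within-season biological variance is not reported by typical field
studies; it is exposed as `noise_cv` rather than guessed, and 0.2 is a
conventional peak-area CV. All randomness derives deterministically from
the design seed (a structure stream plus one stream per sample), so a fixed
design is bit-reproducible.

What the generator does *not* emulate: chromatographic peak shapes, isotope
patterns and in-source fragments, correlated metabolite co-regulation,
peak-position drift between samples, solvent/water NMR artifacts, missing
values from gap-filling failures. Tests passing on this bed therefore
demonstrate the statistical machinery (recovery of planted monotone
seasonal effects at realistic noise, null calibration, validation
behaviour), not robustness to those instrumental artifacts.

## Numerical choices and degenerate inputs

- Sample (ddof = 1) standard deviations everywhere a SD enters (block
  scaling, Pareto, group summaries).
- Binning bucket count uses an integer-snap guard (ratios within 1e-9 of an
  integer are taken exactly) so 9.0/0.04 gives 225 bins despite float
  representation.
- Empty bins, zero-variance variables and all-constant features are kept
  (as 0 / flagged) so matrix shapes never silently change; an all-constant
  *block* is an error because its scaling divisor would be 0.
- ANOVA with zero between- and within-group variation reports p = 1 (F = 0
  convention); zero within-group variance with real separation reports
  p = 0.
- The FDR column is rounded to 3 decimals for reporting only; retention
  decisions use full precision.
- Fold assignment, permutations and the generator are all driven by
  explicit seeds; two runs with the same configuration produce identical
  output bundles (checksummed manifests).

## Problem sizes used in the shipped checks

The repository's verification runs use the default study conditions
(36 samples, 225 + 91 variables after curation): 20 seeded effect-size-4
studies for recovery and permutation validity (n = 100 permutations each)
and 50 seeded effect-size-1 studies for null calibration. Desk-scale checks
(mass arithmetic, binning grid, the rank-FDR transform of published
p-value lists) are exact and instantaneous.

## Known limitations

- OPLS-DA supports one predictive component against a binary/one-contrast
  response (the standard O-PLS formulation); full multiclass O2-PLS is out
  of scope.
- At most two blocks are fused; there are no block weights beyond the
  sum-of-SD scaling.
- Dereplication is accurate-mass-only (Level 3); no MS/MS spectral
  matching, isotope-pattern scoring or retention-time prediction.
- The permutation validity flag is a heuristic reading of the permutation
  plot, not a hypothesis test with a stated error rate.
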