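# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Array model and geometry

A slide is an array of `n_subarrays = 3` identical copies of the peptide
set, printed consecutively and stacked vertically. Each subarray holds a
4×4 grid of blocks, each block is deposited by a single print tip
("needle") and holds 20×20 spots — 19200 spots per slide. The GPR `Block`
field numbers blocks row-major across the whole slide, so block *b* maps to
subarray ⌈b/16⌉ and needle ((b−1) mod 16)+1; global row and column are the
physical positions (240 row levels, 80 column levels). This stacking
convention is what makes the degrees of freedom of the control-model ANOVA
come out as Subarray 2, Needle 15, Row 234 and Column 76: the row factor
loses the six dimensions already spanned by the intercept, the subarray
contrasts and the block-row margins of the needle factor, and the column
factor loses the four block-column margins.

10% of spots are dedicated controls: 5% positive (react when sample is
present), 2.5% secondary-antibody (react with the detection antibody on
every slide, including empty ones), 1% negative, 1.5% process. Thirteen
distinct control peptide identities are used, so the control-only fit
carries a 12-df peptide factor. Controls are placed by a per-needle seeded
permutation: every block row carries controls, every global row and column
level is represented, every needle×subarray cell contains every class, and
the placement pattern differs between needles. The last point is essential:
a placement pattern repeated identically in every block creates accidental
linear dependencies on the sparse control support (the row–column support
graph disconnects) and silently costs the model estimable row/column
levels.

## Variance stabilization

Raw mean-foreground intensities are transformed as log2(max(x, 1)); the
floor of one count maps zero intensities to zero and is configurable. On
the raw scale the replicate spread grows roughly proportionally with the
mean; after the binary log the residual spread is level-independent, which
is what justifies a homoscedastic linear model and Gaussian mixture
downstream.

## Control-peptide effects model

The log2 intensity of a control spot is decomposed additively into
peptide + array + subarray + needle + row + column + ε, all factors
categorical, no interactions (interactions would consume more degrees of
freedom than the control replication can support). Fitting uses a greedy
column-orthogonalization (incremental QR): candidate dummy columns enter in
the fixed order Peptide, Array, Subarray, Needle, Row, Column, and a column
that adds no rank (relative tolerance 1e-8) is dropped and recorded as
aliased rather than failing the fit. The same sweep yields the sequential
(Type I) ANOVA: each term's sum of squares is the drop in residual sum of
squares when its retained columns enter. Per-array fits are the default
(one model per slide, no Array term); a joint fit across slides adds the
Array factor.

Correction subtracts, from every spot on the slide, the estimated
subarray + needle + row + column (+ array) effects, each factor re-centered
to zero weighted by its control observation counts — so the array-wide mean
of control log intensities is preserved exactly, and the identifiability of
the additive decomposition does not leak into the corrected values. The
peptide term is fitted (it absorbs the thirteen control identities'
baselines) but never subtracted, because no peptide effect can be estimated
for the experimental peptides. Spots at aliased levels are corrected with
the retained effects; a level the fit has never seen is an error.

Two properties of this design are worth stating because they are easy to
get wrong when testing it:

- *The per-spot correction surface is well determined; the per-factor
  coefficient split is not.* On a 10% control support, the row, column and
  needle factors are strongly collinear, so individual level coefficients
  have standard errors far larger than the naive σ/√n — a +1.0 effect
  injected on one needle comes back as a coefficient anywhere in roughly
  ±0.35 of the truth on a single slide. The summed correction surface,
  however, is a projection and is accurate: the same injected effect is
  flattened to within ±0.05 by correction, and the surface averaged over
  six slides correlates ≥ 0.98 with the injected truth. Recovery is
  therefore always assessed on the correction surface (including the
  subarray term, which legitimately absorbs the block margins of any smooth
  spatial gradient), not on single coefficients.
- *Variance reduction* is reported as SS(subarray+needle+row+column(+array))
  divided by that quantity plus the residual SS, from the sequential
  decomposition with Peptide fitted first. The peptide term is excluded
  from both numerator and denominator: it measures biology, not nuisance.

## Spot quality control

Historic slides with the same layout provide automatic labels: for each
subarray *a* and each partner subarray *b*, the values of *a* are regressed
on those of *b* over all shared experimental peptides, and a spot is
labeled unreliable when it falls outside the 95% band in **every** partner
regression. Two deliberate choices here:

- *Band type*: the default band is the prediction band for a new
  observation, `t·s·sqrt(1 + 1/n + (x−x̄)²/Sxx)`; a mean-response confidence
  band shrinks like 1/√n and would flag the majority of spots at any
  realistic n (it remains available as an option).
- *Scale and partner rule*: the residual scale `s` is the normalized median
  absolute deviation by default, because the corrupt spots being hunted
  otherwise widen their own detection band; and the all-partners rule is
  used because a corrupt value in the *predictor* subarray throws a large
  residual in that single regression — flagging on any one regression
  (also available, `partner_rule="any"`) would mark the two healthy
  replicates of a corrupted peptide as unreliable and roughly triples the
  false-label rate, which measurably poisons the downstream classifier.

A random forest (500 trees, √p feature subsampling, fixed seed) is trained
on these labels after downsampling the majority class to balance, using
every numeric column of the incubation result file plus every column of the
scatterlight quality-control scan (identifier and sequence columns
excluded, constant columns dropped, missing values median-imputed).
Out-of-bag accuracy is recorded. At application time replicates labeled
unreliable are discarded and the remainder averaged weighted by their
predicted probability of being reliable; a peptide whose replicates are all
unreliable is excluded. The whole stage is optional and the pipeline runs
identically without it.

Inter-batch reproducibility (R² between the per-peptide values of the two
print batches) is the QC stage's summary statistic. It must be compared on
the **common surviving peptide set**: QC preferentially excludes
high-intensity peptides, so comparing R² across different peptide universes
confounds the cleaning effect with range restriction.

## Mixture models and calling

Both the secondary-binder step and the signal call use the same
two-component Gaussian EM: E-step responsibilities, M-step weighted
moments, a variance floor of 1e-6 (log2 scale) against component collapse,
convergence at relative log-likelihood change < 1e-8 or 1000 iterations,
components relabeled at exit so μ₁ ≤ μ₂. Initialization comes from control
groups — negative vs secondary-antibody controls on empty slides, negative
vs positive controls on sample slides — using the per-spot normalized
control values (hundreds of observations) rather than the handful of
per-peptide aggregates, and mixing weights start at (0.9, 0.1) because most
peptides are expected inert.

Calls use only the fitted noise component: p̂(y) = 1 − Φ((y − μ₁)/σ₁), call
iff p̂ strictly < α (default 0.05; boundary values are non-calls; α is
user-adjustable to trade sensitivity against specificity, and α = 1 is the
degenerate call-everything limit). Leaning on the noise component alone
makes the cutoff adaptive and keeps the harder-to-estimate signal component
out of the decision; an alternative mode computes the posterior local fdr
π₁φ₁/(π₁φ₁+π₂φ₂) and a call-set FDR, at the price of trusting the signal
component's normality.

One structural consequence worth knowing: the p̂ < α rule excludes ≈ α of
the *null* peptides by construction (the fitted noise component matches the
clean-peptide distribution, whose upper α-tail always exceeds q̂). Expect
~5% of clean peptides in a secondary-binder exclusion set at the default α;
this is the price of the adaptive cutoff, not a defect.

Mixtures are fitted on per-peptide aggregated values (after replicate
averaging), excluded peptides removed before fitting. Secondary-binder
exclusion is scoped per print batch from that batch's empty slide; with no
empty slide the step is skipped with a warning and an increased
false-positive risk. Excluded peptides are omitted from evaluation
denominators by default; a `noncall` policy counts them as negative calls
instead (this is the policy under which exclusion provably never changes
the truth-class denominators).

## Evaluation

Confusion counts come from the expected-reactive (spiked) and
expected-nonreactive panels; sensitivity, specificity and accuracy with 95%
percentile bootstrap intervals from 1000 resamples of the peptide
intensities within each truth class, re-thresholded against the fixed
fitted cutoff (re-running EM per resample is available behind a flag but is
an order of magnitude slower and answers a subtly different question).

## Synthetic data generator

The generator is the package's study-design double: six slides (two print
batches × empty / low / high spike-in), per-spot log2 intensity =
baseline + array + subarray + needle + row + column + peptide + reaction +
artifact + ε, raw intensity 2^log2 (so raw-scale heteroscedasticity emerges
automatically), deterministic under a single seed. Defaults, in log2 units:

| parameter | default | rationale |
|---|---|---|
| baseline | 8.0 | ~256 raw counts for an inert spot |
| noise sd ε | 0.45 | residual variance ≈ 0.2, matching a typical control-model residual mean square |
| peptide effect sd | 0.5 | sequence-specific baseline spread of experimental peptides |
| needle sd / subarray sd | 0.15 / 0.10 | print-tip and subarray offsets, smaller than spatial effects |
| row/col gradient (peak-to-peak) | 1.5 | spatial incubation decline as the dominant systematic effect |
| row/col per-level jitter | 0.15 | roughness on top of the smooth gradient |
| array sd / batch offset sd | 0.15 / 0.30 | slide-to-slide and batch-to-batch shifts |
| spike effect low / high | 1.5 / 3.1 | differ by log2(3) ≈ 1.6, mirroring the 1 vs 3 ng/ml concentration ratio |
| reactive peptides | 222 | a contiguous tiled-protein block (666 spots in triplicate) |
| expected-nonreactive panel | 171 | a disjoint contiguous block (513 spots) serving as specificity truth |
| secondary binders | 150 | random experimental peptides, +3.0 on every slide including empty |
| positive / process control effect | 4.0 / 2.0 | strong expected reactions |
| artifact fraction (batch 1 / 2) | 4% / 6% | batches deliberately differ; ±4 noise-sd independent perturbations |

Artifact spots also receive correlated aberrant features in both scans
(inflated pixel variation, shifted diameter, reduced circularity), which is
what makes them learnable by the QC forest. The scatterlight feature set
(diameter, pixel-intensity variation, circularity) is a small synthetic
stand-in for a real quality-control result file whose exact columns vary by
scanner software.

What the generator does **not** emulate: sequence-specific artifact modes
(peptide decay that affects all replicates of one sequence equally —
exactly the failure mode automatic band labels cannot see), spatially
correlated artifact clusters (dust smears), non-Gaussian heavy-tailed
noise, saturation at the scanner's dynamic-range ceiling, and empty-slide
peptide effects that differ from sample-slide ones. Green tests on this
generator therefore demonstrate that the machinery is correct and behaves
as designed under the assumed noise model — not that real slides meet those
assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run full-scale slides (19200
spots; six-slide experiments) for everything except repeated-seed
directional checks, which are still run at full slide scale across ten
seeds; the QC forest in the shared test fixture uses 200 trees (500 in the
acceptance script). Every random draw in the package flows from an explicit
seed: the generator spawns per-slide substreams from one master seed, the
forest and the bootstrap take their own seeds, and re-running any entry
point with the same configuration is bit-identical.

## Known limitations

- Band labels inherit an irreducible error: a spot is flagged relative to
  its partners, so two corrupted replicates can out-vote a healthy one.
- The classifier's false-flag rate on clean spots (~15–20% at the default
  conditions) is dominated by label noise that correlates with intensity;
  automatic band labels bound the forest's quality, and no amount of
  training data removes that ceiling.
- With 10% controls, per-level row/column coefficients are noisy by design;
  only the summed correction surface should be interpreted.
- The exceedance rule's null exclusion rate equals α; lower α if excluding
  5% of clean peptides on empty slides is unacceptable for a given screen.
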