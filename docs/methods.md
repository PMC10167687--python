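# Methods

This note documents the models and procedures implemented in `secdiff`,
the defaults and why they were chosen, the numerical decisions, what the
synthetic-data generator does and does not emulate, and known limitations.

## Data model

Peptide traces form a dense peptide × sample × fraction tensor.  Fraction
indices are 1-based and the grid is made contiguous up to a configurable
maximum (default 49; very late SEC fractions contain only low-MW material
and are cut).  Missingness is explicit: zero or absent intensities are
NaN, never 0, because downstream rules treat "not detected" differently
from measured signal (spline imputation eligibility, sibling-correlation
fill-in, uniform below-minimum imputation).  Every peptide maps to exactly
one protein (proteotypic peptides only); violations are hard errors.

The fraction↔MW calibration is an unweighted OLS fit of log10(MW in kDa)
on fraction index from external standards.  The fit method is a package
choice — any log-linear calibration source works.  Slope must be negative
(larger particles elute earlier); the map is closed-form invertible, and
`mw_to_fraction` may return fractional, even off-grid, positions: clamping
to [1, max_fraction] happens where a cutoff is actually used.

## Preprocessing

* **Imputation.**  Only internal single gaps — missing cells whose left
  and right neighbors are measured — are filled, from a cubic
  interpolating spline over the measured fractions of that
  peptide/sample, floored at 0.  Cubic is the standard smooth interpolant;
  the source method states the eligibility rule but not the spline order.
  Traces with fewer than 4 measured points fall back to linear
  interpolation.  Measured cells are never modified.
* **Cyclic loess normalization** operates on log2 intensities of the
  cells measured in both samples of a pair: per ordered pair, a loess
  curve of M = x_i − x_j on A = (x_i + x_j)/2 is fitted (statsmodels
  `lowess`, span 0.7, with `delta` linear interpolation for speed) and
  half the fitted M is moved from one sample to the other; three full
  cycles by default, after which pairwise offsets are far below
  quantitation noise.  Samples sharing fewer than 100 measured cells with
  every other sample pass through unnormalized with a warning — a loess
  fit on fewer points is not trustworthy.  The procedure preserves the
  grand mean of log2 intensities to well under 0.1%.
* **Peptide filtering** applies, in order: (1) at least three consecutive
  detections within some single sample; (2) maximum sibling-peptide
  correlation ≥ 0.5; (3) mean sibling correlation ≥ 0.2; proteins left
  with fewer than two peptides are dropped.  Correlations are Pearson on
  the concatenation of full-grid traces across all samples, with missing
  as 0 inside the correlation only — filtering is applied once to the
  whole experiment, not per sample.  Filtering is idempotent on its own
  output; correlations are computed after normalization.
* **Protein quantification** sums the top two peptides by total intensity
  (over all samples and fractions), the same peptides for every sample.
  Rank ties break lexicographically on peptide id so runs are
  reproducible.

## Coelution feature detection

The feature finder is one deterministic realization of sliding-window
coelution scoring.  Member traces (peptides of a protein, or subunit
protein traces of a complex query) are first integrated across samples,
so every condition shares one set of boundaries.  Steps: centered moving
average smoothing (length 7); mean pairwise Pearson correlation in a
sliding 7-fraction window; runs of window centers with correlation ≥ 0.9
become candidate regions (extended by half a window each side); local
maxima of the summed smoothed trace inside a region are apexes, maxima
closer than `rt_height` (default 1) fractions to a higher one merge into
it; boundaries run to the nearest local minima (or region edge).  The
coelution score is then recomputed over the boundaries on *unsmoothed*
traces, greedily dropping the member least correlated with the rest until
the score reaches the cutoff or fewer than two members remain, in which
case no feature is emitted.  Peaks whose boundaries span fewer than three
fractions are discarded: Pearson correlation over two points is ±1 by
construction and carries no evidence.  `perturb_cutoff` is accepted and
recorded for provenance but has no effect; its semantics in the original
tooling are not defined by our sources.

Features are translation-equivariant and invariant to global intensity
scaling (correlation is scale-free).

**Error control.**  Decoy owners are built by random reassignment: for
protein-level features, one decoy per protein with the same peptide count,
peptides drawn from distinct proteins; for complex queries, one decoy
hypothesis per target of equal size whose members are pairwise at least
`min_edge_distance` (default 3) apart in the supplied PPI graph (without a
graph: no shared complex membership), rejection-sampled under a bounded
retry budget with flagged relaxation on exhaustion.  For a score
threshold s, FDR(s) = (#decoys ≥ s)/(#targets ≥ s); a feature's q-value is
the minimum FDR over thresholds at or below its score, and its p-value is
the empirical decoy exceedance (#decoys ≥ s + 1)/(#decoys + 1).  Complex
primaries are ranked by the composite (completeness, coelution score):
the most complete feature per query enters FDR estimation; queries passing
q ≤ 0.05 are appended with secondary features at coelution score ≥ 0.7.
Complex features must elute above twice the largest subunit MMW —
apparent MWs at or below that are indistinguishable from comigrating
monomers.  Redundant features across queries collapse by single linkage
(apex distance ≤ 1.25 fractions and overlapping subunit sets, Jaccard > 0
as the minimal reading of "same composition and position"); the
representative is the largest subunit set, ties to the higher score.
Collapsing is idempotent.

## Differential statistics

**Bounded proportions (AMF, FMF).**  The assembled range is *strictly*
earlier than the (possibly fractional) 2·MMW cutoff fraction; signal at
the cutoff counts as monomeric (the tie rule is a package convention).
Proportions are shrunk by y′ = (y(n−1) + 0.5)/n (n = total samples in the
comparison) and tested by beta regression: logit mean link, constant
precision φ, maximum likelihood via L-BFGS-B with analytic gradients,
logit-scale OLS starts and a method-of-moments precision start; log φ is
bounded at 25 so degenerate (zero-variance) fits stay finite.  The LRT
statistic 2(ℓ_full − ℓ_null) is referred to χ² with (groups − 1) degrees
of freedom.  All-equal responses and non-convergent fits report p = 1 — a
degenerate fit is evidence of nothing, and the pipeline stays total.  The
fits agree with `statsmodels` `BetaModel` log-likelihoods to < 1e−4 (a
dual-route test); the test itself is ours because the LRT comparison of
nested beta models is the package's statistic.

*Small-sample behavior.*  At three replicates per condition the χ²
reference is notably liberal: on Beta(5,5) null draws the measured
rejection rate at α = 0.05 is ≈ 0.14 (the acceptance script reports the
value it measures).  This is a property of the asymptotic LRT itself at
n = 6, reproduced exactly by the independent statsmodels route, and is
retained deliberately — the method specifies the default LRT, and the
practical effect-size gate (|diff| ≥ 0.3) dominates the false-call rate
in realistic cohorts (measured false-call rates on 1000-protein null
backgrounds are ≈ 0).  Users wanting calibrated nulls at tiny n should
increase replication or apply a permutation reference.

**Fold changes.**  Per feature and member: missing cells are imputed
uniformly on (0, minimum detected signal of that member) with a recorded
seed; member intensity is the sum over the closed boundary interval;
log2FC = log2(mean_A/mean_B) of replicate means; the p-value is a
two-sided Welch t test on per-replicate sums (the source states only
"nonpaired t test"; Welch avoids the equal-variance assumption), or a
paired per-fraction t test when a condition lacks replicates.  Zero
variance in both groups reports p = 1.  Global analysis is the same with
the full grid as the range — equivalent to conventional abundance-level
proteomics.

**Aggregation.**  Parent log2FC is the member median.  For the parent
p-value, members whose fold-change sign opposes the parent median have
p replaced by 1 − p (sign ties stay concordant, resolving toward the
parent); the j-th smallest adjusted p (j = ⌈m/2⌉, the lower median for
even m) is referred to Beta(j, m − j + 1), the exact null of the j-th
order statistic of m uniforms.  Under independence of member p-values and
signs the aggregate is exactly uniform under the null (verified by
simulation).  Aggregation is permutation-invariant and monotone in
concordant member p-values.  Complex-level results aggregate
protein-level results with the same rule.  BH correction runs across
entities at each level; significance requires both the effect-size gate
(|log2FC| ≥ 1, or |diff| ≥ 0.3 for mass fractions) and adjusted p ≤ 0.05.

## Synthetic data

The generator draws each protein's noiseless profile as a sum of Gaussian
peaks (σ = 1.5 fractions) positioned by the calibration: a monomer peak at
the MMW and one peak per assembly state at the state's MW, scaled by the
state's per-condition abundance.  Peptide traces are the protein profile
times a per-peptide lognormal response factor (σ = 0.5, constant across
fractions — this is what makes sibling correlations high, as the filters
assume) times cell-level multiplicative lognormal noise (CV 0.1 by
default), with a detection floor (1.0 intensity unit) and optional
intensity-dependent dropout, P(missing) logistic in −log2(intensity) with
configurable midpoint, scale and steepness.  Defaults describe a
three-condition, three-replicate design over 49 fractions with a
calibration spanning ≈1.4 MDa to ≈6 kDa; pairwise comparisons therefore
involve six samples.  Ground truth records per-condition true AMF
(computed from the discretized noiseless profile), state apex positions,
and state/protein log2 fold changes; regeneration under the same seed is
bit-identical.

What it does **not** emulate: retention-time drift between runs,
interference/co-fragmentation, saturation, heteroscedastic
fraction-dependent noise, shared (non-proteotypic) peptides, or
stoichiometry other than 1:1.  Passing tests on this generator show the
statistical machinery recovers planted effects under the model's own
assumptions; they do not certify performance on real chromatograms whose
artifacts fall outside that model.

Cohort builders fix the study conditions used by tests and the acceptance
script: AMF-shift cohorts (baseline assembled share uniform on
[0.15, 0.45], shifted proteins +0.4 in one condition at constant total),
fold-change cohorts (single assembled state, 4-fold abundance change),
a planted-complex benchmark (3-subunit complexes at 1.2× the summed
subunit MMW, with 0.4× monomeric shares, plus null queries over free
monomer-only proteins), and a rewiring fixture (80%/20% mass split
flipping between a 800 kDa and a 120 kDa state at constant total).

## Problem sizes

The shipped tests and the acceptance script run: 1000-null-protein LRT
calibration; twenty 30-protein fold-change cohorts; 1000-protein AMF
cohorts (50 shifted) over ten seeds; 50 planted + 450 null complex
queries per seed over ten seeds (four in the script).  These sizes give
stable estimates of the reported rates while keeping a full run in the
minutes range on a single core.

## Known limitations

* The beta-regression LRT is anti-conservative at very small n (above).
* Feature-finder internals (smoothing kernel, merge rule, boundary rule,
  greedy member pruning) are one reconstruction of sliding-window
  coelution scoring; other realizations will place boundaries slightly
  differently.
* Complex hypothesis construction (STRING filtering, ClusterONE
  partitioning) is out of scope; hypotheses and PPI edges arrive as
  files.
* Only pairwise condition contrasts are provided; multi-way omnibus
  testing is not.
* No moderated/shrinkage variance estimation for the t tests.
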