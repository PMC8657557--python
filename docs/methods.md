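# Methods

This package implements the computational chain of a partial-EMT (p-EMT)
prostate cancer study: an inducible Zeb1 knockdown in mesenchymal PC-3
cells is profiled on an Illumina EPIC-style methylation array under four
conditions — control cells with DMSO (C0) or 5-azacytidine (C5), and
knockdown cells with DMSO (Z0) or 5-aza (Z5), four replicates each — and
the analysis asks which CpG sites gain methylation upon knockdown and
lose it again under the demethylating drug ("rescue sites").  Alongside
the chip analysis, the package quantifies the study's phenotype readouts:
cell-shape roundness classification and mask-based wound-healing,
spheroid-invasion, transwell and BrdU assays.

## Synthetic data model

No distributional description of the real data is available, so the
generator's distributions are stand-ins chosen for testability, not
estimates of PC-3 biology.  What passing tests show is that the pipeline
recovers known truth under a plausible noise model; they do not certify
performance on real arrays (no genomic autocorrelation, no batch or
position effects, no realistic detection-p physics).

**Methylation.**  Baseline per-probe means are bimodal,
0.5·Beta(2,10) + 0.5·Beta(10,2), the unmethylated/methylated peaks of
real arrays; this exercises the three-state assumption of BMIQ.
Differential probes add `delta_beta` (default 0.3) to the Z0 mean;
non-rescue differential probes carry the gain into Z5 while rescue probes
return to the C0 baseline, so in the noiseless limit
mean(Z5) − mean(Z0) = −(mean(Z0) − mean(C0)) exactly.  C5 is distributed
identically to C0 (the design contains it, the analysis never contrasts
it).  Replicate noise is Gaussian with SD `within_sd` (default 0.03) and
betas are clipped to [0, 1].  Type II probes (default 84% of the array)
have their group means compressed toward 0.5 by
β_obs = 0.5 + c·(β − 0.5) with c = 0.8 before noise — the simplest bias
BMIQ must undo.  Detection p-values are ~0 (Uniform(0, 10⁻³)) for passing
cells and Uniform(0.01, 1) for failing cells; bead counts are
3 + Poisson(9) for passing cells and Uniform{0, 1, 2} for failures; no
intensity model is simulated because none is described for the study.

Default scale is 20,000 probes with 200 planted differential and 100
rescue probes — a desk-scale rendition of the ~866k-probe chip chosen so
the full chain runs in seconds.  The annotation-flag fractions
(SNP 0.114, non-CpG 0.0035, multi-mapping 10⁻⁴, X/Y 0.02) and the
per-cell failure rates (detection-p 2.5·10⁻⁴, beads 2·10⁻³) are
back-solved so that each QC stage removes, in expectation, the same
*fraction* of probes as the corresponding stage of the published cascade
removed from the real array under the same rules (any-sample for
detection p; ≥5%-of-samples for beads, n = 16).

Planted differential probes are drawn only from probes that pass the
annotation flags and whose baseline satisfies β ≤ 1 − delta_beta.  The
rationale: planted truth is meant to be recoverable, so it is placed
where the effect is expressible without clipping and where only the
*stochastic* QC stages (detection-p/bead failures) can remove it.  Those
stochastic losses are real and retained — they are the main cost to
sensitivity (≈3–5% of planted probes per run under the defaults).

**Cell shapes.**  Cells are polygonized ellipses (the roundness score of
an ellipse is analytically its axis ratio b/a, giving exact oracles).
Class axis-ratio distributions are truncated normals: epithelial
(0.85 ± 0.03), mixed (0.50 ± 0.06), mesenchymal (0.18 ± 0.03).  The
control cell lines used for cutoff derivation (an epithelial breast
cancer line, mesenchymal lung fibroblasts) are modelled with the same
means but broader dispersion (SD 0.08): real control lines are
morphologically heterogeneous, and the mean ± SD cutoffs they produce
then clear each assay class by more than two within-class SDs — the
"well-separated cutoffs" regime in which three-class recovery is
meaningful.  The default population mix (25% epithelial, 45% mixed, 30%
mesenchymal) depicts a p-EMT-like population dominated by mixed
morphology.

**Assay masks.**  Integer-pixel geometry (rectangular scratch, circular
spheroid halo, 3×3-pixel nuclei on a disjoint lattice), with ground truth
computed from the masks themselves, so quantifiers must reproduce it
exactly rather than approximately.  No textures or imaging artifacts are
rendered.

## Probe QC

Cascade order is fixed: detection p → bead count → non-CpG → SNP →
multi-mapping → X/Y.  A removed probe is attributed to the *first* stage
at which it fails; per-stage counts are therefore disjoint and
order-dependent, while the survivor set is not.  Rules: a probe fails
detection p if its fraction of samples with p > 0.01 exceeds
`max_fail_fraction` (default 0, the any-sample dialect — the source
pipeline states only "above 0.01", so the fraction is configurable); it
fails beads if bead count < 3 in at least 5% of samples (boundary
inclusive).  Presets: `raw` (none), `partial` (detection p, beads,
non-CpG), `full` (all six).

## BMIQ

Per sample, three-state beta mixtures are fitted by EM to the type I and
type II betas separately.  Initialisation is deterministic (thresholds
0.25/0.75 assign U/H/M, then per-state method-of-moments); betas are
clipped to [10⁻⁶, 1 − 10⁻⁶] before likelihoods to avoid boundary
singularities; the M-step maximises each component's weighted beta
log-likelihood through its sufficient statistics (L-BFGS-B on (log a,
log b), bounded to [10⁻², 10⁴]), so the log-likelihood trace is
non-decreasing up to optimiser tolerance; convergence at Δlog L < 10⁻⁴
or 100 iterations with a warning.  Components are relabelled by
ascending mean; probes take their max-posterior state with exact ties
broken toward H.  Type II U-state betas map through their own U-CDF and
the inverse type I U-CDF (M analogously via upper tails); H-state betas
are shifted and dilated linearly onto the interval between the
transformed U maximum and M minimum, preserving the input-scale gaps.
Degenerate cases (no U or M probes, inverted or collapsed H interval)
fall back to the raw H span; outputs are clipped to [0, 1].  Type I
probes are returned bit-identical.

## Differential testing and rescue calling

Per probe, a two-tailed unpaired equal-variance (pooled) t-test with
n_A + n_B − 2 degrees of freedom, run on beta values (an M-value option
exists but is off by default, matching the beta-scale analysis of the
study).  The t statistic follows the A-vs-B direction while `delta_beta`
reports B − A; two-tailed p-values are direction-free.  Zero pooled
variance is detected as exact within-group constancy: equal means give
t = 0, p = 1; unequal means give an infinite t, p = 0, flagged
degenerate.  Benjamini–Hochberg q-values are computed per contrast
across all surviving probes (the two contrasts are filtered separately,
matching the study's two tests).

A rescue site must be significant in both contrasts (q ≤ 0.05) with
delta(Z0 − C0) > 0 and delta(Z5 − Z0) < 0.  The study's wording "the
gain equals the loss" is operationalized two ways, neither asserted as
the authors' intent: `sign` mode (default) uses direction only — on
noisy replicate data literal equality of deltas selects ~nothing —
while `strict` mode additionally requires
|delta_Z5Z0 + delta_Z0C0| ≤ 0.5·|delta_Z0C0|.  The strict set is always
a subset of the sign set.

## Problem sizes and numerical choices

Tests and the acceptance script run the methylation chain at 20,000
probes × 16 samples, the null control over 20 seeded replicates, and
morphology over 250-cell populations with 750-cell controls — sizes at
which every stage's statistical behaviour (BH thresholds, multinomial
recovery bands) is already in its asymptotic regime while the whole
suite completes in well under a minute per stage.  All generators are
driven by `numpy.random.default_rng` seeded from explicit
`SeedSequence([seed, stream])` pairs, so a single seed determines every
artifact byte-for-byte.  The EM fit needs ≥100 values and rejects
constant input; `fit_beta_mixture` accepts a `seed` argument for
interface symmetry but is fully deterministic.

## Known limitations

- BMIQ quality degrades when the type I pool is small (a few hundred
  probes): the mixture fit's sampling noise enters the quantile maps.
  At realistic array fractions (16% type I of ≥20k probes) the c = 1
  transform is near-identity (mean |Δβ| < 0.02).
- The rescue filter tests each contrast marginally; no joint model of
  the three group means is fitted, and region-level (DMR) structure is
  out of scope.
- The roundness score uses the maximum Feret diameter as "the longest
  axis"; for non-convex outlines a manually traced long axis could
  differ, though the two coincide for convex cells.
- Wound tracking assumes the scratch is the largest cell-free connected
  component at t0 and measures later timepoints inside that fixed
  window; partial closure entering from outside the window is not
  credited.
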