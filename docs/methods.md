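# Methods

This note documents the statistical procedures implemented in `csfmark`,
the synthetic-cohort model used to validate them, the defaults and why they
were chosen, and what the validation does and does not demonstrate.

## Cohort and data model

A cohort is a set of patients sampled at scheduled months (default
0, 2, 10, 18, 26, 34, 42) with monotone dropout: the default per-timepoint
patient counts are 24, 24, 24, 20, 17, 14, 11 (134 CSF samples per
platform). Each visit yields one TMT and one LFQ protein quantification
plus clinical measurements: the HFMSE motor score (integer 0–66), qAlb,
lactate, glucose, total protein, the total CSF cell count per 100 µl and a
cytology differential in percent. Absolute cell counts are
`percent / 100 × total cells per 100 µl`; cytology percentages must sum to
100 ± 0.5. Intensity matrices are proteins × samples with NaN as the only
missing-value representation (empty cells on disk), because imputation must
distinguish "not observed" from zero. Clinical units are carried as
metadata and never converted; all change–change correlations are
unit-invariant.

## Preprocessing

**Sample QC.** Samples whose summed raw intensity falls below a threshold
(default 225, in the intensity table's arbitrary units) are removed. The
filter applies to TMT only by default, where failed labeling produces
near-empty channels; the threshold is configuration, not science — its
units depend on the upstream quantification software.

**Detection filter.** A protein is kept iff some patient has ≥ 2
non-missing samples for it *and* ≥ 2 distinct patients have at least one
non-missing sample. "Detected" means non-missing after sample QC; the two
platforms are filtered independently, as they are processed as separate
datasets throughout.

**Variance stabilization.** Each sample is affinely calibrated so its
median and MAD over proteins match the median sample's (median/MAD are
robust to the minority of truly changing proteins), then
`glog2(x) = log2((x + sqrt(x² + λ²)) / 2)` is applied with a single global
λ ≥ 0. `glog2` → `log2` for `x ≫ λ` and stays finite at and below zero, so
the transformed data are log2-fold-change compatible for abundant proteins
while low intensities are compressed rather than exploded. λ is selected to
minimize |Spearman ρ| between per-protein mean and SD, on a 25-point
geometric quantile grid of the calibrated intensities followed by a 41-point
refinement around the coarse minimum — the |ρ|(λ) minimum is a narrow dip
(the sign of ρ flips as λ crosses the additive-noise scale), and a single
coarse grid can straddle it. λ = 0 is admitted only when all calibrated
values are positive. Ties prefer the smaller λ. The transform is monotone
per sample, so it preserves within-sample value orderings and the sign of
every within-patient change.

**kNN imputation.** For a missing entry (protein *p*, sample *s*): among
the proteins observed at *s*, the k = 10 nearest to *p* — Euclidean
distance over the samples observed in both rows, rescaled by
`sqrt(n_samples / n_shared)` so pairs with different overlap are comparable
— contribute an inverse-distance-weighted mean of their values at *s*.
Zero-distance neighbours are averaged unweighted; distance ties are broken
by protein ID lexicographic order, making the imputation deterministic.
If fewer than k candidate neighbours exist the protein's own observed mean
is used; a protein with no observed values is an error. Observed entries
are never altered. Neighbours live in protein space (rows), the standard
convention for expression-matrix kNN imputation; MNAR-specific
(left-censored) imputation is deliberately out of scope since the pipeline
models missingness as MAR.

## Patient adjustment and sample correlation

Inter-patient level differences dominate CSF proteomes. Per protein, OLS is
fit on `[timepoint indicators | patient indicators]` (no intercept; one
patient level dropped) and only the fitted patient block is subtracted,
mean-centered across patients. Retaining timepoint indicators during the
fit is the defining contract: timepoint contrasts recomputed on adjusted
data equal the original estimates to numerical precision, and applying the
adjustment twice equals applying it once. A design in which patient and
timepoint indicators are collinear (every patient seen at exactly one
timepoint) is rejected. Adjusted proteins are z-scored (sample SD, n−1;
constant proteins dropped with a warning), sample–sample Pearson
correlations computed, and samples clustered by average linkage on
`1 − r`. Average linkage is a default, not a claim — the linkage is
configurable. TMT and LFQ are clustered separately by default.

## Differential expression

Per protein, OLS on `~ 0 + timepoint + patient` over the complete
(imputed) matrix gives the coefficient vector, residual variance `s²` and
residual df `d`. The variance prior is estimated by moment matching on
`log s²`: with `e = log s² − ψ(d/2) + log(d/2)`,

    trigamma(d₀/2) = var(e) − trigamma(d/2)        (solved by Newton)
    s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))

and the posterior variance is `s²_post = (d₀s₀² + d·s²)/(d₀ + d)`. When the
observed spread of `log s²` does not exceed its sampling noise the d₀ = ∞
branch sets `s²_post` to the pooled mean variance; forcing d₀ = 0
reproduces the classical per-protein *t* exactly. Moderated
`t = c'β̂ / sqrt(s²_post · c'(X'X)⁻¹c)` is referred to a t distribution
with `d₀ + d` df, two-sided. All pairwise timepoint contrasts are tested;
the sign convention is later-minus-earlier, so upregulation under therapy
is positive. Benjamini–Hochberg adjustment runs across proteins within each
contrast (a global mode is available). DEPs are `FDR < 0.05` **and**
`|log2FC| > 0.5`, both strict, as the thresholds are printed.

## Cross-platform intersection

A protein is a shared direction-consistent DEP if it is flagged with the
same direction in both platforms for at least one *common* contrast (the
strict default; an any-contrast mode is available). Proteins that are DEPs
in both platforms only with opposing directions are reported as conflicts.
Abundance ranks use mean non-missing normalized intensity, descending, ties
broken by protein ID.

## Response markers

**Consistency scores.** For each candidate protein (reference signs come
from the direction-consistent DEP intersection) and post-baseline timepoint
*t*: the fraction, over patients with data at baseline and *t*, whose
change has the reference sign. A change of exactly zero counts as
non-concordant (the conservative choice).

**Change–change screen.** Δ values are computed against the month-0 visit
only. Baseline Δ-pairs are identically zero and carry no information, so
they are excluded by default (an inclusive mode exists for replication of
analyses that pooled them). Pearson r with `t = r√(n−2)/√(1−r²)` on n−2 df,
two-sided; BH across proteins. Raw and adjusted p-values are both emitted,
since screens of this kind are variously reported unadjusted.

**Cutoff rules.** A threshold θ > 0 classifies a visit as
improved-or-stable if Δprotein ≥ θ, not-improved-or-worse if Δprotein ≤ −θ,
abstaining in between. Clinical truth is ΔHFMSE ≥ 0 ⇒ improved-or-stable:
a change of exactly zero satisfies both clinical phrasings ("stability" and
"lack of improvement"); it is assigned to improved-or-stable — consistent
with pairing intensity increases with "improvement or stability" — and the
number of such ties is reported so the choice is auditable. Concordance is
the agreement fraction over non-abstained visits; only the *sign* of the
HFMSE change is used, so concordance is invariant to any sign-preserving
transform of the clinical scale. `scan_cutoffs` maximizes concordance over
a θ grid subject to a minimum non-abstained fraction (pipeline default
0.5), ties toward smaller θ. For negatively coupled proteins the pipeline
fits the rule on the negated change and records the orientation.

**Enrichment.** One-sided hypergeometric upper tail per annotation term
against a user-supplied term → protein table; BH across terms. No ontology
semantics are implied — terms are opaque labels.

## The synthetic-cohort generator

The generator exists so that every stage can be validated by parameter
recovery without the original deposit. On the raw scale,

    intensity = 2^(μ_p + patient_ip + batch_bp + Σ_k w_pk f_kv + effect_pv) · e^ε + δ

with per-protein baseline `μ_p ~ Uniform(4, 24)` log2 units (≈20 log2 units
of dynamic range; one dominant albumin-like protein is planted ~4× above
everything else), patient effects N(0, 0.5²) per (protein, patient), TMT
plex effects N(0, 0.3²) with one plex per patient series (so plex is
deliberately confounded with patient, as in the multiplexed design it
emulates), three latent per-visit factors with N(0, 0.15²) loadings that
induce protein–protein correlation (the signal kNN imputation exploits),
multiplicative noise `ε ~ N(0, 0.15²)` (natural log) and additive noise
`δ ~ N(0, 50²)` clipped at zero. The additive component makes raw
per-protein SD grow with the mean (Spearman ρ ≈ 1), the structure the VST
must remove; the λ that decouples mean and SD lands near the additive-noise
scale. Missingness is MAR by default (rate 0.08, exact cell count);
an intensity-dependent mechanism (logistic weights in log2 intensity,
weighted sampling without replacement) is available. Two low-total TMT
samples are planted by default to exercise the sample filter.

The LFQ protein set is the top-429 most abundant TMT proteins plus 12
LFQ-only proteins drawn from the high-abundance range, reproducing the
platform-depth relationship (1,674 TMT / 441 LFQ / 429 shared by default).

Planted effects: 40 treatment-responsive proteins with |log2FC| = 1.5,
random sign, full effect from the first post-baseline visit (configurable
onset ramp) — 60 % drawn from the LFQ-covered stratum so cross-platform
intersection has targets; planting is restricted to proteins with baseline
≥ 2⁹ raw units because below the additive-noise floor a fold change is
unquantifiable by construction. A further 25 % of proteins receive a
persistent N(0, 0.3) log2 "broad shift" at treated visits — the general
proteome composition shift under therapy that separates pre-treatment
samples in the correlation heatmap without reaching the DEP thresholds.
Ten clinically coupled proteins follow
`Δintensity = slope × ΔHFMSE + N(0, 0.15)` with slope ±0.2 log2 per HFMSE
point (70 % positive); the slope was sized from the variance budget so the
planted couplings are clearly detectable at the cohort's size, matching a
study setting in which top correlates are unambiguous.

HFMSE trajectories: integer baseline from N(23, 15²) truncated to [0, 66]
(the cohort-mean baseline with a generous inter-patient SD, as severity
ranges from 0 to near-normal), mean drift (+1.1, +2.2, +1.6, +1.4, +2.6,
+2.1 points at months 2–42) scaled per patient by a N(1, 0.8²) responder
factor, visit noise SD 2, rounded and clipped. Routine parameters couple
negatively to ΔHFMSE (qAlb −0.08, lactate −0.015, glucose −0.5 per point);
total protein is left uncoupled as a null control; the cytology
differential shifts toward macrophages over time and lymphocytes couple
negatively to improvement. Dropout is monotone — patients leave and never
return. Everything is deterministic given (config, seed).

**What the generator does not emulate:** peptide/PSM-level effects,
reporter-ion interference, fractionation artifacts, protein-inference
discordance between platforms, left-censored (intensity-dependent)
missingness as the default, non-Gaussian clinical noise, and correlated
dropout (patients leave at random order, not by severity). Passing
recovery tests therefore demonstrates the pipeline's correctness under a
plausible noise model with the study's dimensions — not performance on any
particular real instrument's data.

## Validation design and problem sizes

The test suite validates every elementary statistic against an independent
brute-force implementation (detection rule, BH step-up, Pearson r/p against
`scipy.stats.pearsonr` and a permutation test, consistency scores, cutoff
scans, hypergeometric tails by direct combinatorial summation), checks the
moderated-t limits (d₀ = 0 and equal-variance reduce to the classical t)
and recovers the variance prior from simulated variances (d₀ = 4,
s₀² = 2, 2,000 proteins, 10 seeds). Calibration and power use simulated
cohorts: false-discovery control on 20 null cohorts (500 proteins, 12
patients, 5 timepoints) measured as V/max(R,1) per (seed, contrast) family
— the family BH actually controls; planted-DEP recovery, screen ranking
and cutoff concordance on 5 cohorts of 600 TMT proteins, 12 patients,
7 timepoints; VST and imputation efficacy at the full default size. The
scaled sizes keep a complete validation run around a minute on one CPU
while preserving the cohort's statistical structure; `scripts/acceptance.py`
re-runs all of it from a single seed.

Oracle cutoff evaluation scans θ ∈ {0.1, …, 1.5} (step 0.1) requiring
≥ 30 % non-abstained visits — a rule that applies to almost no visits is
not a usable biomarker rule, but the pipeline's stricter 50 % default is a
reporting choice, not part of the oracle definition.

## Numerical choices and degenerate inputs

- Rank checks use pivoted QR; a rank-deficient design beyond the standard
  single dropped patient indicator raises an error listing the aliased
  columns.
- `trigamma⁻¹` uses the standard Newton iteration with asymptotic
  initialization; inputs ≤ 0 map to d₀ = ∞.
- Proteins with exactly zero residual variance are excluded from prior
  moment estimation; a zero contrast estimate with zero standard error
  yields t = 0, p = 1.
- BH adjustment validates p ∈ [0, 1]; empty inputs pass through.
- Correlation matrices are symmetrized, clipped to [−1, 1] and checked for
  unit diagonal before clustering; clustering of n samples needs ≥ 3
  proteins.
- All tie-breaks (kNN neighbours, abundance ranks, cutoff grid, λ grid)
  are deterministic and documented at the operation.

## Known limitations

- The VST's single global λ assumes one additive-noise scale per platform;
  per-sample λ or spline-based stabilizers are not implemented.
- The DEP model tests pairwise contrasts only; no spline or random-slope
  longitudinal trend models.
- The enrichment test treats annotation terms independently (no term
  hierarchy, no semantic reduction).
- Cutoff-rule concordance is an in-sample quantity; the package does not
  cross-validate thresholds, mirroring the exploratory character of
  cutoff biomarkers at this cohort size.
- With one TMT plex per patient, plex effects are statistically
  inseparable from patient effects; the pipeline removes them jointly and
  cannot attribute variance between the two.
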