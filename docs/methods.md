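# Methods

`hypometa` implements a pipeline that links a coordinate-based
meta-analysis of FDG-PET hypometabolism to spatially-resolved brain
transcriptomes. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Activation likelihood estimation (ALE)

Each experiment in the meta-analysis reports peak coordinates ("foci") of
hypometabolism in MNI mm. The modeled-activation (MA) map of experiment
*i* assigns voxel *v* the probability that at least one of that
experiment's peaks lies at *v*, modeled as an isotropic 3-D Gaussian
kernel centred on each focus:

    MA_i(v) = max_f  p0 · exp(−‖v − f‖² / 2σ²),   σ = FWHM / (2√(2 ln 2))

where `p0` is the kernel's probability mass inside one voxel centred on
the focus (the product of per-axis Gaussian masses over the voxel edge
lengths), so `0 < MA ≤ 1`. The maximum — not the sum — over foci means
repeated peaks within one study do not inflate evidence. Across
experiments the ALE value is the probabilistic union of independent
events:

    ALE(v) = 1 − ∏_i (1 − MA_i(v))

computed through `log1p`/`expm1` for numerical stability. ALE is
permutation-invariant and monotone in every MA input, bounded below by
`max_i MA_i` and above by `Σ_i MA_i`.

**Kernel width.** The default FWHM is 10 mm, a fixed self-contained
choice. A sample-size-dependent kernel is available by passing a
`fwhm_by_n` table mapping subject counts to FWHM values; each experiment
then uses the nearest table entry.

**Null calibration.** The voxelwise significance threshold is estimated
by permutation: each permutation relocates every experiment's foci
uniformly at random among in-mask voxel centers (focus counts and kernels
preserved) and recomputes the ALE map. By default all in-mask null values
are pooled into one histogram and each observed voxel receives the
add-one exceedance p value `(c + 1) / (M + 1)` where `c` counts null
values at or above it; pooling trades per-voxel exactness for far fewer
permutations at desk scale, and a per-voxel variant is available
(`pooled=False`). The add-one form keeps p strictly positive, which the
subsequent multiple-testing step requires. Benjamini–Hochberg across
in-mask voxels at level *q* (default 0.05) then yields the threshold: the
smallest observed ALE value among significant voxels (`inf` when none
pass). Fewer than 100 permutations are refused because the pooled tail is
unstable there.

**Clusters.** Supra-threshold voxels are grouped into connected
components under 6-, 18- or 26-connectivity (default 26, via
`scipy.ndimage.label`); components smaller than `min_extent_mm3`
(default 500 mm³, i.e. 63 voxels at 2 mm ceiling division) are discarded.
Labels are assigned in decreasing extent order, ties broken by higher
peak value and then lexicographic peak index, so labeling is
deterministic across platforms.

**Grid.** The default grid is axis-aligned, 2 mm isotropic, with the
origin at the grid center (MNI-like). mm→voxel conversion is
inverse-affine followed by rounding half away from zero; voxel centers
round-trip exactly.

## Spatial labeling of expression samples

Samples carry MNI coordinates and per-sample flags. The analysis is
restricted to cerebral-cortex samples with allocortex (hippocampal
formation, piriform cortex) excluded; the flags are input data rather
than an ontology lookup, keeping the package atlas-agnostic. Each
retained sample is assigned the mask value at its nearest voxel. Samples
whose coordinates fall outside the grid are labeled *outside* (with a
logged count) rather than dropped, preserving sample totals. Probe-level
matrices are collapsed to genes by the arithmetic mean of surviving
probes per sample, optionally after a QC keep-list.

## Differential expression

For each donor and gene, expression is compared between inside and
outside samples with the Mann–Whitney U test. The effect size is
`AUC = U / (n_in · n_out)`, the probability that a random inside sample
exceeds a random outside one. Ties receive midranks; when
`n_in + n_out ≤ 12` the exact conditional null (enumeration over all
labelings of the pooled midranks, point mass included) is used, otherwise
the tie-corrected, continuity-corrected normal approximation. The two
branches agree within 0.01 absolute p at the crossover size on continuous
data. Degenerate all-equal inputs return AUC 0.5 and p 1 in both
directions.

One-sided p values per direction (over-/under-expressed inside) are
combined across donors with Fisher's method, `X = −2 Σ ln p` against
χ²(2k); zero p values are clamped to the smallest positive normal with a
warning. Benjamini–Hochberg is applied within each direction separately
over the tested genes — the pipeline reports separate up/down counts, and
within-direction correction matches that reporting. Donors with fewer
than two inside or two outside samples are excluded from the
meta-combination (only for the affected genes' donor set), not globally.
No spatial-autocorrelation correction is applied; samples within a donor
are spatially correlated and the resulting p values should be read as
descriptive rankings rather than exact error rates.

## Gene-set enrichment

Genes are ranked from most over- to most under-expressed (ties broken by
gene symbol for determinism). For each set, the AUC of in-set vs
out-of-set rank positions scores the set's placement: AUC > 0.5 means
enrichment at the overexpressed end. Significance is the two-sided
Mann–Whitney p with BH across tested sets. Sets are tested only when
their intersection with the ranking universe holds 10–200 genes; the size
filter is waived for cell-type marker sets, which are small by
construction.

## Monotone progression across ordered states

Given per-gene mean expression across k ≥ 2 ordered states, a gene is
flagged when its means *strictly* increase in the given order; ties break
monotonicity (the conservative reading of "monotonically increase").
Genes with any missing state value are excluded from numerator and
denominator and tallied. Under an exchangeable null the flagged fraction
is 1/k! (1/6 for three states), which the tests verify. For a gene set,
the hypergeometric upper tail `P(X ≥ set_hits)` against the universe's
flagged fraction is computed by `logsumexp` over log pmf terms, so tails
far beyond double underflow (e.g. 10⁻⁵⁵) are exact. The universe is the
genes with complete data in the state matrix, not the genome.
Cross-species sets are translated through a homolog map first: one-to-many
homologs expand to one row per target gene, untranslated genes are
dropped, and the translated set is de-duplicated at the target-species
level before counting.

## Marker-gene profiles (MGP)

The relative proportion of a cell type across samples is the first
principal component of its marker genes: markers are z-scored across the
in-scope samples (constant markers dropped), the leading PC of the
samples × markers matrix is the score, and the sign is oriented so the
score correlates positively with the mean marker z-score — the PC sign is
otherwise arbitrary. Scores are standardized (mean 0, sd 1) per cell type
and scope, and the captured variance fraction is reported. Estimation
runs separately per donor by default, matching how atlas expression is
normalized per brain. Markers shared between cell types are dropped from
both.

The region × donor interaction is tested by pooling the per-donor scores
into one ordinary-least-squares fit

    score ~ inside + donor + inside : donor

with the donor of interest as a binary contrast against all others
pooled; the interaction coefficient's t and two-sided p are reported
(one-sided on request). This is the simplest model consistent with
reporting a single t statistic; alternatives (mixed models, donor-wise
summaries) were not pursued. Collinear designs are rejected with the
degenerate term named.

## Synthetic data

The generators produce every input with the statistical structure the
analysis assumes, each alongside its ground truth:

- **Foci**: region centers placed with a minimum separation, foci
  jittered around a uniformly chosen center with isotropic Gaussian noise
  (default sd 4 mm), optional uniform decoys; 33 experiments by default
  with 10–50 subjects each.
- **Expression**: i.i.d. Gaussian noise (sd 1) around per-gene means;
  planted genes (default 200 of 5000) are shifted by `delta·sd`
  (default 2) only in the aberrant donor's inside-mask samples, so
  exactly one of the six donors carries the spatial signal. Roughly 8% of
  each donor's samples fall inside the mask — the overlap regime of
  cortical atlas samples with a hypometabolism mask — with at least two
  inside samples per donor guaranteed; set
  `inside_sample_fraction=None` for uniform placement. About 10% of
  samples are flagged allocortical to exercise the exclusion rule.
- **State matrices**: background genes have exchangeable state means;
  planted genes climb 5 noise-sd per state, so they are flagged monotone
  essentially always.
- **Markers**: six cell types × 21 markers; latent proportions from a
  symmetric Dirichlet, markers linear in the standardized latent
  proportion plus noise; an optional interaction effect raises the last
  cell type's latent score inside-mask in the aberrant donor only.

A single seed is expanded into independent substreams per generator, so
changing one generator's parameters does not perturb the others' draws.
Identical configurations reproduce identical outputs.

The generators use Gaussian noise throughout; the downstream statistics
are rank-based, so the noise family is not load-bearing. They do **not**
model spatial autocorrelation of expression, microarray probe effects, or
donor-level batch structure; passing tests therefore demonstrate the
correctness and calibration of the machinery under the assumed design,
not robustness to those real-data features.

## Problem sizes and numerical defaults

The bundled analyses run on a 20×24×20 voxel grid at 2 mm, 200
permutations for the ALE null, 5000 genes × 6 donors × 100 samples for
differential expression, 200 decoy sets for the enrichment scans, and
200 samples for the marker analyses — sizes chosen so the full pipeline
and its calibration suites complete in minutes on one CPU while keeping
every statistic in its asymptotically valid regime. Null-calibration
suites use 10,000 genes (monotone fraction), 2000–3000 random sets (AUC),
20 replicates of m = 2000 (BH), and 200 replicate OLS fits at 60 samples
(interaction p uniformity).

## Known limitations

- The ALE null relocates foci independently and uniformly within the
  brain mask; real foci cluster by anatomy, so the calibrated threshold
  is conservative near cortex boundaries.
- The pooled null histogram slightly smooths voxelwise p values relative
  to the per-voxel variant; both are provided.
- The per-donor Mann–Whitney treats samples as exchangeable units; no
  correction for within-donor spatial correlation is attempted.
- The interaction model assumes homoscedastic scores across donors.
- GO-style annotations are taken as flat sets; no DAG propagation or
  semantic summarization is performed.
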