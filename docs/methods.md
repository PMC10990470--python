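# Methods

This note documents the models, estimators, numerical choices and known
limitations behind sweepscan. Everything stated here is computed by the
package itself (the test suite and `scripts/acceptance.py` exercise every
claim); nothing is quoted from external analyses.

## Data model and conventions

Genotypes are diploid alt-allele dosages in {0, 1, 2} with missing encoded
as −1, keyed by sample ID and the SNP ID string `chrom:pos` (1-based
physical position; BED output converts to 0-based half-open at the
boundary). Haplotypes are a binary matrix with two rows per sample; phased
input is required for the haplotype statistics — sites with any unphased or
missing call are dropped with a logged count, and unphased mode is
deliberately unsupported. When no genetic map is supplied, genetic
positions default to a flat 1 cM/Mb map (cm = bp × 10⁻⁶), logged
prominently because iHH integrates over cM.

Site filters (defaults): folded MAF < 0.01 removed (MAF exactly 0.01
kept), missing-genotype rate > 0.1 removed (exactly 0.1 kept), and
multi-allelic sites dropped rather than split. MAF is computed over
non-missing genotypes with all retained samples pooled. Per-filter removal
counts are logged and returned (`FilterReport`).

## Constituent statistics

**Weir–Cockerham F_ST.** Per SNP, the two-population variance components
a (among populations), b (among individuals within populations) and c
(within individuals) give θ̂ = a/(a+b+c). The interface takes allele
counts, not genotypes, so the observed heterozygosity entering b and c is
replaced by its random-union-of-gametes expectation
h_i = 2p̂ᵢ(1−p̂ᵢ)·n_al/(n_al−1). Consequences: a fixed difference returns
exactly 1; sites monomorphic across both populations are undefined (NaN);
negative estimates are retained so that downstream ranks are unaffected by
clipping. Genome-wide summaries use the ratio-of-sums form Σa/Σ(a+b+c).

**EHH, iHH, XP-EHH.** EHH(d) at a core SNP is the probability that two
haplotypes drawn without replacement are identical over the interval from
the core to the flanking SNP at distance d:
EHH(d) = Σ_h C(n_h,2)/C(n,2) over identity classes. Following the
cross-population convention, all haplotypes of a population enter (no
partition by core allele). EHH(0) ≡ 1 by convention (empty interval); for
d ≥ 1 the core allele is part of the identity requirement. The outward walk
stops at the first SNP where EHH < `ehh_cutoff` (default 0.05); that
terminal sub-cutoff point is kept so the integral decays through it. iHH is
the trapezoidal integral of EHH over cM, summed over both sides; a physical
gap > `max_gap_bp` (default 200 kb) terminates integration on that side.
XP-EHH is computed as ln(iHH_target) − ln(iHH_reference) — the subtraction
form makes the antisymmetry xpehh(A,B) = −xpehh(B,A) bit-exact — and is
undefined where either iHH is 0. The genome-wide scan runs in a compiled
(numba) kernel that maintains haplotype identity classes incrementally per
core; a pure-Python per-core path (`ehh_at_core` + `ihh`) exists for
inspection and is cross-checked against the kernel in the tests.

**ΔSAF.** The signed alt-allele frequency difference, target minus
reference; positive values mark alleles at higher frequency in the target.
Whether an ancestral/derived polarization would be preferable is an open
question for real data; the alt-allele convention is the documented
assumption here, and because CSS uses ranks, any monotone re-polarization
changes only the sign bookkeeping.

**Standardization.** Genome-wide z-scores with the sample standard
deviation (denominator n−1), recorded in each track's provenance. XP-EHH
uses a single genome-wide normalization without frequency bins. Undefined
values stay undefined.

## The composite score

Tracks are merged on the intersection of SNP IDs, in genome order; SNPs
undefined in any constituent are excluded. Each constituent is converted to
fractional ranks rᵢ/(n+1) (ties share mean ranks) and mapped through Φ⁻¹.
The per-SNP mean z̄ of the k rank-z tracks is scaled by σ̄ and converted to
CSS = −log₁₀(1 − Φ(z̄/σ̄)), evaluated in log space (`norm.logsf`) so
extreme scores keep precision. σ̄ defaults to the **empirical** sample sd
of z̄ — self-calibrating, because the three constituents are correlated on
real signals — with the analytic 1/√k available as `variance_mode=
"analytic"` for independent constituents (the null-calibration tests
verify sd(z̄) = 1/√3 ± 0.01 on independent tracks).

**Smoothing.** Default is a centered sliding window: each SNP receives the
mean CSS over SNPs within ±10 kb on its chromosome (window 20 kb). A
disjoint (tumbling) mode is available. Smoothing is shift-equivariant and
respects chromosome boundaries.

**Cluster calling.** The top sets are the ⌈0.001·n⌉ and ⌈0.01·n⌉ highest
smoothed scores (stable argsort; ties broken by genome order). The recorded
thresholds are the k-th largest values. A top-0.1% SNP is significant iff
at least `min_flankers` = 5 *other* top-1% SNPs lie within ±`flank_span_bp`
on its chromosome; significant SNPs within `flank_span_bp` of each other
merge into one region spanning the member SNP positions. The flanking span
is not pinned down by the methodology this follows; the default of 500 kb
mirrors the gene-annotation flank and is configurable — it is the main
sensitivity of the cluster count and is echoed into every output header.
Note on ties: with very dense markers (spacing ≪ window), adjacent SNPs can
share an identical window and tie exactly in the smoothed score, so the
count of SNPs at/above the recorded threshold can exceed ⌈0.001·n⌉ even
though the member *set* always has exactly ⌈0.001·n⌉ SNPs; at array-like
spacing the scores are tie-free and the count is exact.

**Annotation.** Genes (BED or GFF3 `gene` features) overlapping each
cluster extended by ±500 kb (clamped at position 1, boundary inclusive:
a gene ending exactly 500,000 bp away is included, 500,001 bp is not) are
attached via an interval tree; shared-gene intersections across
populations are reported with per-chromosome tallies.

## Ancestry

**PCA.** Sites are mean-centered, scaled by √(p(1−p)), missing dosages
mean-imputed, and the sample covariance eigendecomposed via SVD. Variance
fractions are normalized over the first 20 components (or all, if fewer).
A rank-1 configuration (two internally homogeneous groups) is legal and
returns the single informative axis; only a zero-variance matrix errors.

**f3.** Per site, f3 = (c−a)(c−b) − c(1−c)/(n_c−1), the unbiased
frequency-based estimator with the finite-sample heterozygosity correction
for the target only (reference sampling is already unbiased). Sites
monomorphic across all three populations are dropped. The genome-wide
estimate is the plain mean; uncertainty comes from a weighted block
jackknife over contiguous physical blocks (default 5 Mb, per-chromosome,
SNP-count weights, ≥ 10 blocks required), z = estimate/SE. The
admixture flag uses z < −3 — the significance convention is configurable
since no canonical threshold exists. Interpretation caveat built into the
tests: strong drift in the target *after* admixture adds +F_C·p(1−p) to
f3 and can mask a real admixture signal; the drift-only simulation
reproduces the positive-f3 regime.

## The simulator

The simulator emulates the study conditions the scan is meant for, not a
full coalescent. Defaults: 50 + 50 diploids, 10,000 SNPs uniformly placed
on one 30 Mb chromosome (≈3 kb spacing — a scaled-down whole-genome
density), ancestral frequencies from Beta(0.5, 0.5) truncated to
[0.02, 0.98] (U-shaped spectrum without immediate post-filter loss), and
independent Balding–Nichols drift Beta(p(1−F)/F, (1−p)(1−F)/F) on each
branch with F = `divergence_fst` (default 0.1): for two populations each
drifted by F from a common ancestor, the large-sample expectation of the
ratio-of-sums Weir–Cockerham estimator is F, so the requested background
differentiation is realized directly (verified empirically over
F ∈ {0.01, 0.05, 0.1, 0.2}).

The hard sweep copies one founder haplotype into round(freq · 2n) target
haplotypes at sites within ±`sweep_halo_bp` (default 200 kb) of the core,
with per-site copy probability exp(−|pos−core|/halo); the founder's core
allele is forced to ALT so the planted sweep always acts on the alternate
allele. This produces the two signals the scan needs — a frequency
differential across the halo and extended haplotype homozygosity — while
leaving everything outside the halo untouched: the background and sweep
use separate RNG streams, so a no-sweep run with the same seed is
bit-identical outside the halo. Fixed seeds reproduce all outputs exactly,
including VCF bytes.

The admixture trio draws refA/refB by drift (F_A = F_B = 0.1, roughly the
differentiation between divergent cattle lineages) from a shared ancestral
frequency, forms the target as α·p_A′ + (1−α)·p_B′ (default α = 0.5) or by
pure drift from the refA branch (α = None), drifts it by F_C (default 0.01
for recent admixture; 0.3 models a severely bottlenecked unadmixed breed),
and samples 20 diploids per population over 50k SNPs at 1 kb spacing
(50 Mb ⇒ 10 jackknife blocks).

**What the simulator does not model** — and hence what passing tests do
not show about real data: there is no linkage disequilibrium in the
neutral background (sites are independent), so the null XP-EHH
distribution is sharper than in real genomes; there is no recombination
gradient, no mutation-rate heterogeneity, no genotyping error, and no
realistic demography (bottlenecks, migration, Ne trajectories). Because
CSS normalization and thresholds are empirical genome-wide quantiles,
detection and calibration results transfer qualitatively, but absolute
cluster counts on real data depend on the real LD structure.

## Numerical and design notes

- EHH is computed as an integer pair count divided once by n(n−1), so
  brute-force enumeration reproduces it bit-exactly.
- The null XP-EHH z-distribution is mildly heavy-tailed (excess kurtosis
  ≈ 0.4 under the site-independent background); the |z| > 3 rate is the
  same order as the Gaussian 0.27% but not equal to it, and the property
  test bounds it to [0.09%, 0.9%] rather than asserting an exact binomial
  rate.
- Problem sizes in tests and the acceptance script (10k-SNP sweep panels,
  100k-SNP null tracks at 100k-array spacing, 50k-SNP trios, 10–50 seed
  batches) are scaled-down study conditions chosen to keep each
  statistical check well-powered at desk scale.
- Degenerate inputs are errors, not silent results: empty populations,
  constant tracks under standardization, fewer SNPs than 1/top_frac for
  cluster calling, < 10 jackknife blocks, chromosome-name mismatches in
  annotation. A constant jackknife input reports SE 0 with z undefined.
- Pipeline stages run in a fixed order, fail with stage-named errors, and
  write outputs once, each with a provenance header echoing every tunable;
  reruns with an identical configuration are byte-identical (no
  timestamps anywhere in outputs).
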