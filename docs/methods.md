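# Methods

This note documents the statistical models, the defaults, and the design
decisions behind `egscreen`, and what the simulation-based validation does
and does not establish.

## Genotype representation

Genotypes are diploid, biallelic alt-allele dosages: 0 (hom ref), 1 (het),
2 (hom alt), −1 (missing). AA/AB/BB array labels map to 0/1/2 with AA = hom
ref; every metric below depends only on hom/het distinctions and hom
orientation, so the choice of which allele is "alt" is immaterial. Phased
VCF genotypes are accepted and treated as unphased; multiallelic records
are rejected rather than split, since the intended panels are biallelic
SNPs. Depth bins use 0-based half-open coordinates (BED dialect); loci use
1-based positions (VCF dialect).

## WGA error model and concordance metrics

The generator corrupts each called locus independently: with probability
`missing` the call is dropped; otherwise a true het is emitted as a random
homozygote with probability `ado` (dropout is symmetric — either allele can
drop, so AA and BB are equally likely), and a true homozygote is emitted as
het with probability `het_gain` or as the opposite homozygote with
probability `hom_reversal`. Missing truth stays missing. Errors carry no
linkage structure; all the estimators that consume them are per-locus
proportions, for which LD is irrelevant.

The metrics invert this model. **Denominator convention:** concordance and
all three error rates are computed over *comparable* loci — called in both
the amplified and reference sample. A genotype "appearing as" another
requires both calls to exist; missingness is captured separately by the
original call rate (called / all loci) and relative call rate (called in
amp among called in ref). A rate whose denominator is empty is reported as
absent (None), never as 0, so tiny panels cannot produce silently
optimistic summaries. Two exact accounting identities follow and are
property-tested: on the ref-het stratum concordant + ADO = 1, and on the
ref-hom stratum concordant + het-gain + hom-reversal = 1; overall
concordance is the comparable-count-weighted mean of the stratum
concordances.

## Binned depth, copy number, and aneuploidy

Simulated per-bin depth is a gamma–Poisson mixture with mean
`depth_mean · (CN/2) · bias` and variance/mean = `depth_dispersion`
(dispersion 1 is pure Poisson) — the standard overdispersed-coverage model,
parameterized directly by mean and dispersion. The bias factor is a
unit-mean sinusoid (20 Mb wavelength, random phase per chromosome) scaled
by `gc_bias_amplitude`; it emulates smooth GC/mappability waves but is not
tied to any real sequence composition.

Copy number per bin is 2 × depth / median(bin depths). The median is taken
over autosomal bins whenever an autosome is present, so a male X cannot
bias the normalizer. The estimator assumes a majority-euploid genome: if
more than half of all bins are altered the median itself shifts and CN is
systematically mis-scaled. The per-chromosome summary is the **median** of
its bin CNs — the aggregation is a deliberate choice for robustness to
segmental noise; the fraction of individually abnormal bins is reported
alongside so segmental events remain visible. Calls use strict
inequalities (CN > 2.6 trisomy, CN < 1.4 monosomy; ties are euploid). CV curves use the sample SD (n−1 denominator, because
window counts are small at 100 Mb) divided by the mean, after rebinning to
each window size; rebinning requires the window to be an integer multiple
of the source bin and keeps trailing partial windows. No GC-correction
regression or segmentation is performed; the bin-ratio method is applied
uniformly, which averages out sub-chromosomal mosaicism.

At the validated operating point (mean depth ≥ 5×, dispersion ≤ 2, 1 Mb
bins, 100 Mb chromosomes) whole-chromosome CN 1 and CN 3 events are
detected with ≥ 95% sensitivity at ≤ 1% per-chromosome false calls; the
test suite measures this over 100 replicates.

## SNP QC

A locus is retained iff call rate ≥ 0.9 AND MAF > 0.01 AND (when the HWE
filter is enabled) HWE p > 1e-5. The filters are evaluated jointly, which
makes the retained set independent of filter order. The HWE test is the
1-df chi-square goodness of fit of genotype counts against p²/2pq/q²
among called genotypes — a deterministic choice that is adequate at the
sample sizes simulated here; monomorphic loci trivially "fit" HWE and are
removed by the MAF filter instead. Note the retained-iff-pass-both reading
of the exclusion rule: a locus failing either threshold is excluded.

Missing genotypes are filled by per-locus mean dosage before building G.
This is deliberately naive — it shrinks an individual's centered dosage to
zero at missing loci, slightly shrinking relationships — and is used only
for G construction; it is not a haplotype-based imputation and is not
claimed to substitute for one. At ≤ 1% missingness the effect on G entries
is below 0.05 (perturbation-tested).

## G matrix, GBLUP and REML

G follows the VanRaden construction: dosage columns centered by 2pᵢ
(codes 0, 1, 2 → −2p, 1−2p, 2−2p) and G = ZZ′ / 2Σpᵢ(1−pᵢ), with pᵢ
estimated from all supplied individuals — reference animals and embryos
together — unless frequencies are passed explicitly. Fixed loci are
dropped with a warning. On HWE-simulated unrelated individuals the mean
diagonal is 1 within ±0.05 at m ≥ 2000.

The animal model y = 1μ + Wg + e (W the incidence of phenotyped
individuals, g ~ N(0, Gσ²g)) is solved in prediction form:

    μ̂ = (1′V⁻¹1)⁻¹ 1′V⁻¹y,   ĝ = G W′ (W G W′ + λI)⁻¹ (y − 1μ̂),

with λ = σ²e/σ²g = (1−h²)/h². This is algebraically identical to the joint
mixed-model equations over all individuals but never inverts G (which is
singular whenever individuals outnumber informative markers); embryos
receive predictions through their G-covariances with the reference set.
Correctness is anchored by the GBLUP/ridge-SNP-BLUP duality: ĝ must equal
Z·â from the equivalent ridge regression on marker effects to 1e-6 on
every random fixture, and does. A singular system (duplicated individuals
with λ → 0) raises a diagnostic error.

The variance ratio may be supplied (as λ or h²) or estimated by REML:
eigendecompose the phenotyped submatrix of G (with a 1e-8 diagonal
jitter), rotate, and profile the restricted likelihood over h² ∈ (0,1) as
a bounded 1-D optimization. The estimate is scale-invariant in y. Its
sampling SD at n = 500 phenotyped animals with the default cohort
structure is roughly 0.08–0.1, so single-replicate estimates of h² = 0.3
typically land in 0.2–0.4.

## Breeding-cohort generator

The cohort mirrors a dairy genomic-selection design rather than an
exchangeable sample: the reference population is built of paternal
half-sib families (default ~25 offspring per sire, unrelated dams), and
embryos arrive in full-sib groups (default 5 per mating) from reference
dams mated to the sire pool. This matters: with completely unrelated
individuals at n_ref = 500 and m = 2000 independent markers, the expected
GBLUP accuracy is only ≈ √(nh²/(nh²+m)) ≈ 0.26, and REML has little
relationship variance to work with; with progeny-structured embryos the
embryo-DGV accuracy is ≈ 0.5–0.6, which is what an eGS program relies on.
Offspring genotypes are per-locus Mendelian samples from the parents — loci
are independent, so there is no recombination map and no LD; consequences:
marker-effect-based traits are exactly additive, and nothing here tests
imputation or haplotype methods.

Traits are polygenic: marker effects iid normal, scaled so var(true g) =
h² on a unit-variance phenotype scale; the reference phenotype ("DRP-like")
is true g plus N(0, 1−h²) noise. A real de-regressed proof has
reliability-dependent error variance; that heterogeneity is not simulated,
and DRP de-regression itself is out of scope — the phenotype is consumed
as given.

## X chromosome and sexing

Outside the PAR (default: the first 5% of loci, a terminal block), males
carry one X allele which the genotyper emits as a homozygous diploid call —
never het before error injection — matching how genotyping pipelines call
hemizygous sites and making the heterozygosity rule workable at all.
Females are diploid HWE; PAR loci are diploid HWE in both sexes. WGA
errors are then injected with the same corruption model, so male
heterozygosity on clean non-PAR loci is exactly 0 and rises to ≈ het_gain
under noise.

Panel filters (call rate ≥ 0.9, MAF > 0.015, male het ≤ 0.01) remove PAR
loci via the known-male heterozygosity criterion. When no known males
exist, a two-pass bootstrap is provided: pass 1 classifies all embryos on
the unfiltered (call-rate-only) locus set, pass 2 rebuilds the panel using
pass-1 males. This works because females sit far above the 0.02 threshold
(HWE heterozygosity ≈ 0.3 on the simulated MAF spectrum) even with PAR
loci included. The male call is het rate ≤ 0.02, deliberately inclusive at
the boundary; embryos with fewer than 50 called panel loci (configurable) get
`no_call`. Sexing is robust to ADO (which only removes hets from males'
already-hom calls and deflates female rates that have huge margin) and
degrades only when het_gain approaches the 0.02 threshold.

## Pipeline and reproducibility

The demo pipeline simulates a bovine-scale genome (25 autosomes × 100 Mb ≈
2500 one-Mb bins), 50,000 loci for 3 truth samples, amplified replicates
under three error settings (clean; MDA-like ado 0.05 / gain 0.01 /
reversal 0.002 / missing 0.05; MALBAC-like ado 0.25 / gain 0.05 /
reversal 0.01 / missing 0.25), and a 500-animal cohort with 10 embryos —
sizes chosen so a full run completes in seconds while every estimator
operates in its validated regime. A single global seed fans out through
`numpy.random.SeedSequence` to per-stage child seeds, so toggling stages
does not perturb the others; identical config + seed reproduces
byte-identical outputs, verified via the SHA-256 manifest.

## Numerical conventions and edge cases

- Floats in reports are serialized to 6 significant digits.
- Threshold strictness is intentional and consistent: QC call rate is
  ≥ (exclusion is <), MAF and HWE are strict >, CN thresholds are strict,
  the male het threshold is inclusive ≤.
- Zero-denominator rates are absent, not zero; an all-missing reference
  sample, an all-zero depth track, and an empty post-filter sex panel each
  raise explicit errors.
- Depth tracks must be sorted, non-overlapping, non-negative; violations
  are rejected at read time with the offending bin named.

## What the validation shows — and does not

All validation is against the package's own generative models: the error
taxonomy is recovered because the corruption process matches the estimator's
assumptions exactly; depth is overdispersed but free of real GC structure,
mappability holes, and segmental mosaicism; cohort LD is absent. Passing
tests therefore demonstrate internal correctness (estimators recover what
was injected, identities hold, solvers match independent algebra), not
field performance on real WGA chemistry, whose error rates depend on
chemistry, input cell count and sequencing depth in ways this package
measures but does not model.
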