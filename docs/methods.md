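# Methods

This note documents the statistical procedures purgekit implements, the
choices made where the underlying methods are conventionally
under-specified, what the synthetic-data generator does and does not
emulate, and known limitations.

## Variant filtering

Sites are 1-based; all intervals (sites, ROH segments, windows) are fully
closed, following VCF/PLINK/vcftools conventions.  Genotypes are unphased
throughout; phase separators are ignored on input.

Three filters are provided, each a pure subset operation preserving site
order, and mutually commuting:

1. biallelic-SNP restriction (single-base ref and alt, ref ≠ alt);
2. the hard filter `QD < 2.0 || FS > 60.0 || MQ < 40.0 || MQRankSum < −12.5
   || ReadPosRankSum < −8.0` — a site is removed iff any clause fires on a
   *present* annotation.  Absent INFO fields never trigger removal (GATK
   convention); removal-on-absence would silently empty annotation-poor
   inputs such as simulated VCFs;
3. missingness: a site is dropped when the fraction of missing genotypes
   exceeds 0.20 (strict) in **any** population.  Missingness is evaluated
   per population but failing sites are dropped globally so that every
   downstream statistic shares one site matrix.

## ROH detection

The caller reproduces PLINK 1.9 `--homozyg` semantics.  Parameters and
defaults (PLINK v1.90 defaults unless noted):

| parameter | default | meaning |
|---|---|---|
| `window_snp` | 20 | SNPs per sliding window |
| `window_het` | 1 | max het calls in a homozygous window |
| `window_missing` | 5 | max missing calls in a homozygous window |
| `window_threshold` | 0.05 | min fraction of spanning windows that are homozygous |
| `min_snp` | 100 | min SNPs per segment |
| `min_kb` | 10 | min segment length (kb) |
| `density_kb_per_snp` | 50 | max kb per SNP within a segment |
| `max_gap_kb` | 1000 | inter-SNP gap that splits a run |
| `final_min_length_kb` | 100 | downstream exclusion threshold |

Each SNP's homozygous-window fraction uses the count of windows actually
spanning it as denominator, so SNPs near chromosome ends (covered by fewer
than `window_snp` windows) are handled as PLINK does.  Runs of eligible
SNPs are split at gaps > `max_gap_kb` *before* the length/SNP-count/density
tests.  Chromosomes with fewer SNPs than `window_snp` yield no calls.
Segments shorter than 100 kb are removed by a separate downstream filter so
the caller itself stays parameter-faithful.

F_ROH = Σ segment lengths / Σ autosome lengths; only autosomes (from the
genome layout) enter both numerator and denominator.  Length-class
summaries use [100 kb, 1 Mb), [1 Mb, 5 Mb), ≥ 5 Mb plus a cumulative
"≥ 1 Mb" restricted F_ROH, and population means ± sd use the n−1 sample
standard deviation.

## Diversity

Windowed π follows vcftools `--window-pi`: per site, the unbiased
heterozygosity 2j(n−j)/[n(n−1)] with j the alt-allele count among the
population's called alleles and n the called-allele count (missing
genotypes shrink n; they are never imputed); per window, the per-site sum
divided by the window span.  A terminal window shorter than the window size
uses its true length as denominator when the chromosome length is known;
with no length table, whole windows up to the last variant are assumed.
Genome-wide π is reported as the length-weighted mean over windows — the
neutral aggregation when a single per-population value is wanted.

Observed heterozygosity is (het genotypes)/(called genotypes) per
individual; an individual with no called genotypes reports NaN rather than
raising.

## Effect classes, Grantham distances, polarization

Effect classes: LoF = {stop_gained, splice_acceptor_variant,
splice_donor_variant}; missense, synonymous and intergenic map from the
standard effect vocabulary; anything unrecognized maps to `other` with a
warning, never a silent drop.  Multi-transcript annotations collapse to the
most severe class (LoF > missense > synonymous > intergenic > other).

Grantham distances are computed from the 1974 physicochemical formula
D = ρ·[α(Δc)² + β(Δp)² + γ(Δv)²]^{1/2} with α = 1.833, β = 0.1018,
γ = 0.000399 over side-chain composition, polarity and molecular volume,
with ρ fixed so the mean over the 190 amino-acid pairs is 100.  The
recomputed matrix agrees with the published integer table within ±1 after
rounding for 189 of 190 pairs; the printed Asp–Trp entry (181) is
inconsistent with the printed property values (the formula gives 190.8,
and every other Asp–* and Trp–* pair reproduces to ≤ 1), so it is treated
as a defect of the printed table and the formula value is served.  The
dnsSNP class (missense with D ≥ 150, inclusive) is unaffected — both
values clear the threshold.

Polarization: at each site the ancestral allele must (i) equal the
per-site outgroup allele and (ii) be the major allele — frequency strictly
above 0.5 — in the focal population.  Sites failing either condition
(including outgroup matching neither allele, or absent) are UNRESOLVED and
excluded from all derived-allele statistics.  One consequence worth
flagging: a derived allele *fixed in the focal population* leaves the
ancestral allele at frequency 0 there, so such sites are always UNRESOLVED
— fixed bins of the SFS therefore populate only for non-focal populations.
Load counting is polarity-aware: where the derived allele is the reference,
hom-ref genotypes count as derived homozygotes.

## Purging statistics

**ROHf / non-ROHf.**  Per individual and category, a site counts when the
individual carries ≥ 1 derived allele there; it belongs to ROH iff its
position lies in any of that individual's segments (closed intervals).
ROHf = deleterious count / synonymous count within ROH; non-ROHf the same
outside.  An individual with zero synonymous sites in a region has an
undefined ratio and is excluded from the population test.  Populations are
tested with a two-sided paired Wilcoxon signed-rank across individuals —
a conventional distribution-free choice for paired ratios; the test is
configurable in principle since nothing downstream depends on it.

**Rxy.**  L_X = Σ_{i∈C}(m_X/s_X)(1 − m_Y/s_Y) / Σ_{i∈I}(m_X/s_X)(1 −
m_Y/s_Y), L_Y with labels swapped, R = L_X/L_Y.  Sites with zero called
alleles in either population are skipped in both sums.  R(X,X) = 1
identically and R(X,Y)·R(Y,X) = 1 on shared site sets.  The standard error
is a delete-one-block jackknife: category and intergenic sites are
partitioned jointly into 20 contiguous blocks (genomic order; configurable)
and R is recomputed leaving each block out — a block jackknife respects
local linkage, and 20 blocks is the conventional compromise between bias
and variance of the variance estimate.  The jackknife *unit* (site, block
or chromosome) is a design choice of this package, not a claim about any
particular published analysis.

**Conservation-weighted relative load.**  The top-quantile mask marks the
⌈q·n⌉ highest-scoring sites (default q = 0.001, ties broken by site order,
threshold reproducible from the scores).  Per individual: Σ over top sites
of derived dose (het = 1, hom = 2) × score, divided by the individual's
total derived dose over **all** polarized sites — the implemented reading
of "over the total number of derived alleles"; restricting the denominator
to top-quantile sites is the plausible alternative and would rescale all
individuals by a common population-level factor without changing rankings.
The statistic is linear in the scores and invariant to permuting scores
strictly below the threshold.

**SFS.**  For each class (damaging = LoF ∪ missense, neutral = intergenic)
and population, each resolved site with s ≥ 2n′ called alleles contributes
its exact hypergeometric pmf over derived counts 0..2n′ (deterministic
projection); `mode="mc"` instead takes a single seeded hypergeometric draw
per site, matching the expected spectrum in mean.  Bins 0 (absent) and 2n′
(fixed) are retained.  The fixed proportion is the spectrum mass in the
fixed bin, which for fully-projected sites equals the fraction of fixed
sites.  An odd subsample size is rejected (alleles come in diploid pairs).

## Synthetic-data generator

The generator produces the statistical structure the analyses assume, not
an evolutionary simulation:

- **Genome**: 2 chromosomes × 20 Mb by default; ~19,800 sites (300 LoF,
  1,500 missense, 2,000 synonymous, 16,000 intergenic) placed uniformly —
  about 1 SNP / 2 kb.  There is no linkage model beyond shared ROH tracts;
  the statistics under test need ROH structure and frequency spectra, not
  realistic LD.
- **Frequencies**: per population and class, per-site derived frequencies
  are Beta draws — LoF Beta(0.4, 3.6) (mean 0.10, strongly deleterious and
  rare), missense Beta(0.6, 2.4) (mean 0.20), synonymous and intergenic
  Beta(0.8, 1.9) (mean ≈ 0.30) — plus a point mass at 1 (8–9% by class)
  emulating drift-driven fixed differences.
- **Autozygosity**: per individual, non-overlapping tracts (0.2–3 Mb,
  uniform) are placed until the target genome fraction is met (bookkeeping
  within ±0.02; the last tract is trimmed).  Genotypes are Hardy–Weinberg
  binomial draws outside tracts and a single doubled Bernoulli draw inside
  (forced homozygous, zero heterozygosity inside tracts).
- **Purging**: with probability ρ, a deleterious (default LoF) derived
  homozygote inside a planted tract is reverted to the ancestral
  homozygote — a parametric distortion standing in for selection having
  removed exposed recessives, not an evolved process.
- **Outgroup and scores**: the outgroup allele equals the true ancestral
  allele with a 1% flip rate; conservation scores are Normal(0, 1) with an
  Exponential(2) bump added at deleterious sites, giving the heavy upper
  tail and deleterious-class enrichment the top-quantile analysis expects.

Because sites are exchangeable given their class and there is no linkage,
demography, or genotype-calling error model, passing calibration tests here
demonstrates correctness of the statistics under their own assumptions —
not robustness to LD structure, batch effects or reference bias in real
resequencing data.

## Problem sizes and determinism

Calibration and recovery tests run at desk scale — 40 Mb genomes,
~20k sites, 1–10 individuals per population, 50 replicates — chosen so the
full suite completes in a few minutes while keeping binomial/Poisson
sampling error well inside the asserted tolerances.  Every stochastic step
(simulation, Monte-Carlo SFS) takes an explicit seed; the pipeline derives
per-stage seeds deterministically from the single config seed, and repeated
runs with the same seed are bit-identical.

## Known limitations

- No genotype-likelihood ROH calling (bcftools roh-style HMM) and no
  phased-IBD methods; calls are hard-genotype based.
- No annotation engine: effect classes and amino-acid changes are inputs
  (SnpEff-style ANN or TSV), not derived from transcript models.
- Polarization takes a per-site outgroup-allele table as input; deriving it
  from a whole-genome alignment is upstream of this package.
- Conservation scores are consumed, never computed, from multi-species
  alignments.
- The Rxy jackknife assumes blocks of roughly exchangeable sites; with very
  few informative sites the SE is reported as NaN rather than fabricated.
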