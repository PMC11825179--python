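# purgekit

Population-genomic analysis of inbreeding, mutational load and genetic
purging in resequenced diploid populations — the kind of analysis run for
conservation genomics of endangered species (small populations, runs of
homozygosity, deleterious-variant burdens), packaged as a tested Python
library with a thin CLI and a built-in synthetic-population generator so
every stage can be exercised without external data.

## What it computes

Given a multi-sample VCF of biallelic SNPs, a sample→population map, effect
annotations, per-site outgroup alleles and a conservation-score track:

- **Site filtering** — removal of indels/multiallelics, the GATK-style hard
  filter `QD < 2.0 || FS > 60.0 || MQ < 40.0 || MQRankSum < −12.5 ||
  ReadPosRankSum < −8.0`, and a per-population missingness cut (> 20%).
- **Runs of homozygosity (ROH)** — PLINK 1.9 `--homozyg` windowed semantics
  (window of 20 SNPs, ≤ 1 het and ≤ 5 missing calls per homozygous window,
  hit fraction ≥ 0.05, gap/length/density tests), segments < 100 kb excluded
  downstream, and the inbreeding coefficient
  *F*<sub>ROH</sub> = *L*<sub>ROH</sub>/*L*<sub>autosome</sub> with length-class
  summaries ([100 kb, 1 Mb), [1 Mb, 5 Mb), ≥ 5 Mb).
- **Diversity** — vcftools-style windowed nucleotide diversity
  π = Σ<sub>sites</sub> 2*j*(*n*−*j*)/[*n*(*n*−1)] per 500 kb window and per-base,
  and observed heterozygosity per individual.
- **Load annotation** — LoF (stop gained, splice acceptor/donor), missense,
  synonymous, intergenic classes; Grantham physicochemical distances
  *D* = ρ·[α(Δc)² + β(Δp)² + γ(Δv)²]<sup>1/2</sup> with missense changes at
  *D* ≥ 150 flagged deleterious (dnsSNP); derived-allele polarization
  (ancestral = outgroup allele that is also the > 50% major allele in the
  focal population); per-individual het / derived-hom load counts and the
  homozygous-load ratio 2·hom/(2·hom + het).
- **Purging statistics** —
  ROH*f* = *N*<sub>m</sub>/*S*<sub>ROH</sub> vs non-ROH*f* = *N*<sub>m</sub>/*S*<sub>nonROH</sub>
  (deleterious / synonymous counts inside vs outside each individual's ROH,
  compared by paired Wilcoxon signed-rank);
  *R*<sub>X/Y</sub> = *L*<sub>X</sub>/*L*<sub>Y</sub> with
  *L*<sub>X</sub> = Σ<sub>i∈C</sub>(m<sub>X</sub>/s<sub>X</sub>)(1 − m<sub>Y</sub>/s<sub>Y</sub>) /
  Σ<sub>i∈I</sub>(m<sub>X</sub>/s<sub>X</sub>)(1 − m<sub>Y</sub>/s<sub>Y</sub>)
  and a delete-one-block jackknife SE; conservation-weighted (GERP-style)
  relative load over the top 0.1% scored sites (het = 1, hom = 2 alleles);
  derived-allele site-frequency spectra on a fixed subsample size via exact
  hypergeometric projection (fixed and absent bins included), with the
  proportion of fixed damaging vs neutral alleles.
- **Synthetic data** — seeded generator of ≥ 2 diploid populations with
  planted autozygous tracts (controllable genome fraction and tract
  lengths), class-specific derived-allele frequency distributions with
  fixed-difference point mass, an optional purging distortion (deleterious
  derived homozygotes inside ROH reverted with probability ρ), outgroup
  alleles with error, missingness, and heavy-tailed conservation scores —
  plus ground-truth tables for calibration tests.

## Worked example

```bash
python examples/01_simulate_and_detect_roh.py
```

prints (seeded, reproducible):

```
sample   F_ROH(est)  F_ROH(true)  n_segments
inbred_00       0.261        0.255           6
inbred_01       0.261        0.255           6
inbred_02       0.258        0.255           7
```

Three simulated individuals carry planted autozygous tracts covering 25.5%
of a 40 Mb genome; the windowed caller recovers an *F*<sub>ROH</sub> within
~0.01 of the truth (the small excess comes from run-eligible SNPs flanking
tract edges).  The other examples cover diversity (`02`), load counts and
Grantham classification (`03`), purging statistics (`04` — with full purging
the LoF ROH*f* drops to 0 against a non-ROH*f* of ~0.11, paired *p* ≈ 0.002),
the site-frequency spectrum (`05` — ~7.2% of damaging vs ~10.6% of neutral
spectrum mass in the fixed bin on the default generator settings), and the
end-to-end pipeline (`06`).

The full pipeline is also exposed as a CLI:

```bash
purgekit run -c config.yaml --seed 1 --out results_dir
purgekit simulate -c config.yaml --out bundle_dir
```

with `roh`, `pi`, `load`, `rxy` and `sfs` subcommands producing the
corresponding slice of the full report.

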