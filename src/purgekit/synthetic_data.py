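"""Synthetic diploid populations with planted autozygosity, deleterious
variant classes, outgroup alleles and conservation scores.

The generator emulates the statistical structure the analysis stack
assumes rather than a full evolutionary model: sites are laid down
uniformly along synthetic autosomes (no linkage beyond shared ROH tracts),
per-site derived-allele frequencies are drawn per population from
class-specific Beta distributions with an optional point mass at 1 (fixed
differences), genotypes are Hardy-Weinberg draws outside planted ROH
tracts and forced homozygous inside them, and genetic purging is imposed
as a parametric distortion: a deleterious derived homozygote inside a
planted tract is reverted to the ancestral homozygote with probability
``purging_strength``.

Every run is fully determined by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .load_annotation import classify_effects
from .purging_stats import ConservationTrack
from .roh import ROHSegment
from .variants_io import MISSING, GenomeLayout, SamplePanel, VariantTable

_TERM_BY_CLASS = {
    "LoF": "stop_gained",
    "missense": "missense_variant",
    "synonymous": "synonymous_variant",
    "intergenic": "intergenic_region",
}

#: amino-acid pairs below / at-or-above the deleteriousness threshold,
#: used to give missense sites a realistic mix of benign and radical changes
_MILD_AA_PAIRS = [("L", "I"), ("F", "Y"), ("H", "Q"), ("D", "E"), ("R", "K")]
_RADICAL_AA_PAIRS = [("C", "W"), ("C", "F"), ("L", "C"), ("D", "W"), ("S", "W")]


@dataclass
class PopulationConfig:
    n_individuals: int = 10
    autozygous_fraction: float = 0.0     # target F_ROH from planted tracts
    roh_tract_min_bp: int = 200_000
    roh_tract_max_bp: int = 3_000_000
    #: per-class Beta(a, b) parameters of the derived-allele frequency
    derived_freq_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "LoF": (0.4, 3.6),          # mean 0.10: strongly deleterious, rare
            "missense": (0.6, 2.4),     # mean 0.20
            "synonymous": (0.8, 1.9),   # mean ~0.30
            "intergenic": (0.8, 1.9),   # neutral, matches synonymous
        }
    )
    #: per-class probability that a site is fixed derived (frequency 1)
    fixed_prob: dict[str, float] = field(
        default_factory=lambda: {
            "LoF": 0.08,
            "missense": 0.08,
            "synonymous": 0.085,
            "intergenic": 0.09,
        }
    )


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 20_000_000, "chr2": 20_000_000}
    )
    populations: dict[str, PopulationConfig] = field(
        default_factory=lambda: {"popA": PopulationConfig(), "popB": PopulationConfig()}
    )
    site_counts: dict[str, int] = field(
        default_factory=lambda: {
            "LoF": 300,
            "missense": 1500,
            "synonymous": 2000,
            "intergenic": 16_000,
        }
    )
    radical_missense_prob: float = 0.2   # fraction of missense with Grantham >= 150
    purging_strength: float = 0.0        # rho: P(remove deleterious derived hom in ROH)
    purged_classes: tuple[str, ...] = ("LoF",)
    missingness: float = 0.02
    outgroup_error: float = 0.01
    #: conservation score: Normal(0, conservation_sd) baseline plus an
    #: Exponential(conservation_bump) upper tail added to deleterious classes
    conservation_sd: float = 1.0
    conservation_bump: float = 2.0

    def validate(self) -> None:
        for name, p in self.populations.items():
            if not (0 <= p.autozygous_fraction <= 1):
                raise ValueError(f"{name}: autozygous fraction outside [0, 1]")
            if p.roh_tract_min_bp > p.roh_tract_max_bp:
                raise ValueError(f"{name}: tract min exceeds max")
            if p.roh_tract_max_bp > max(self.chrom_lengths.values()):
                raise ValueError(f"{name}: tract length exceeds every chromosome")
            if p.n_individuals < 1:
                raise ValueError(f"{name}: need at least one individual")
        if not (0 <= self.purging_strength <= 1):
            raise ValueError("purging_strength outside [0, 1]")
        if any(c < 0 for c in self.site_counts.values()):
            raise ValueError("negative site count")


@dataclass
class TruthTable:
    segments: dict[str, list[ROHSegment]]
    autozygous_fraction: dict[str, float]
    ancestral_is_ref: np.ndarray
    effect_class: np.ndarray
    scores: np.ndarray
    derived_freq: dict[str, np.ndarray]      # population -> per-site frequency
    load_ratio: dict[str, dict[tuple[str, str], float]]  # class -> (X, Y) -> ratio


@dataclass
class SimResult:
    variants: VariantTable
    panel: SamplePanel
    effects: pd.DataFrame
    outgroup: pd.DataFrame
    track: ConservationTrack
    layout: GenomeLayout
    truth: TruthTable

    def write(self, outdir) -> None:
        """Emit all inputs in the pipeline's on-disk formats."""
        import os
        from . import variants_io as vio

        os.makedirs(outdir, exist_ok=True)
        vio.write_vcf(self.variants, os.path.join(outdir, "variants.vcf"), self.layout)
        vio.write_panel(self.panel, os.path.join(outdir, "panel.tsv"))
        vio.write_layout(self.layout, os.path.join(outdir, "layout.tsv"))
        self.effects[["chrom", "pos", "term", "aa_ref", "aa_alt"]].to_csv(
            os.path.join(outdir, "effects.tsv"), sep="\t", header=False, index=False
        )
        self.outgroup.to_csv(
            os.path.join(outdir, "outgroup.tsv"), sep="\t", header=False, index=False
        )
        pd.DataFrame(
            {
                "chrom": self.variants.sites["chrom"],
                "pos": self.variants.sites["pos"],
                "score": self.track.scores,
            }
        ).to_csv(os.path.join(outdir, "scores.tsv"), sep="\t", header=False, index=False)


def _plant_tracts(
    rng: np.random.Generator,
    sample: str,
    cfg: SimConfig,
    pop: PopulationConfig,
) -> list[ROHSegment]:
    """Place non-overlapping tracts totalling ~fraction*L of the autosomes."""
    target = pop.autozygous_fraction * sum(cfg.chrom_lengths.values())
    if target <= 0:
        return []
    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    total = 0.0
    tries = 0
    segs: list[ROHSegment] = []
    while total < target and tries < 10_000:
        tries += 1
        length = int(rng.integers(pop.roh_tract_min_bp, pop.roh_tract_max_bp + 1))
        length = min(length, int(target - total) + pop.roh_tract_min_bp)
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        clen = cfg.chrom_lengths[chrom]
        if length >= clen:
            continue
        start = int(rng.integers(1, clen - length + 1))
        end = start + length - 1
        if any(start <= e and end >= s for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        segs.append(ROHSegment(sample, chrom, start, end, n_snps=1))
        total += length
    return segs


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a full input bundle plus ground truth; bit-reproducible per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = GenomeLayout(dict(cfg.chrom_lengths), list(cfg.chrom_lengths))

    # -- site positions and classes
    n_sites = sum(cfg.site_counts.values())
    chroms = list(cfg.chrom_lengths)
    weights = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(chroms), size=n_sites, p=weights)
    pos = np.empty(n_sites, dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        sel = chrom_idx == ci
        k = int(sel.sum())
        # distinct positions per chromosome; rejection keeps memory flat
        clen = cfg.chrom_lengths[chrom]
        uniq = np.unique(rng.integers(1, clen + 1, size=2 * k + 16))
        while uniq.size < k:
            uniq = np.unique(
                np.concatenate([uniq, rng.integers(1, clen + 1, size=k)])
            )
        pos[sel] = rng.permutation(uniq)[:k]
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    site_chrom = np.array([chroms[i] for i in chrom_idx])

    classes = np.concatenate(
        [np.repeat(cls, n) for cls, n in cfg.site_counts.items()]
    )
    rng.shuffle(classes)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, n_sites)) % 4
    ref = bases[ref_idx]
    alt = bases[alt_idx]
    ancestral_is_ref = rng.random(n_sites) < 0.7

    # -- per-population derived frequencies and genotypes
    pop_names = list(cfg.populations)
    assignments: dict[str, str] = {}
    samples: list[str] = []
    for pop in pop_names:
        for k in range(cfg.populations[pop].n_individuals):
            name = f"{pop}_{k:02d}"
            samples.append(name)
            assignments[name] = pop
    panel = SamplePanel(assignments)

    derived_freq: dict[str, np.ndarray] = {}
    for pop in pop_names:
        pc = cfg.populations[pop]
        q = np.empty(n_sites)
        for cls in cfg.site_counts:
            sel = classes == cls
            a, b = pc.derived_freq_beta[cls]
            q[sel] = rng.beta(a, b, int(sel.sum()))
            fixed = rng.random(int(sel.sum())) < pc.fixed_prob[cls]
            qs = q[sel]
            qs[fixed] = 1.0
            q[sel] = qs
        derived_freq[pop] = q

    segments: dict[str, list[ROHSegment]] = {}
    true_frac: dict[str, float] = {}
    L = sum(cfg.chrom_lengths.values())
    geno = np.empty((n_sites, len(samples)), dtype=np.int8)
    purged_mask = np.isin(classes, cfg.purged_classes)
    for col, sample in enumerate(samples):
        pop = assignments[sample]
        q = derived_freq[pop]
        segs = _plant_tracts(rng, sample, cfg, cfg.populations[pop])
        segments[sample] = segs
        true_frac[sample] = sum(sg.length for sg in segs) / L
        in_tract = np.zeros(n_sites, dtype=bool)
        for sg in segs:
            in_tract |= (site_chrom == sg.chrom) & (pos >= sg.start) & (pos <= sg.end)
        # derived-allele dose
        dose = rng.binomial(2, q).astype(np.int8)
        hom_draw = (rng.random(n_sites) < q).astype(np.int8) * 2
        dose = np.where(in_tract, hom_draw, dose)
        # purging: revert deleterious derived homozygotes inside tracts
        if cfg.purging_strength > 0:
            purge = (
                in_tract
                & purged_mask
                & (dose == 2)
                & (rng.random(n_sites) < cfg.purging_strength)
            )
            dose[purge] = 0
        # translate derived dose to ref/alt genotype codes
        gt = np.where(ancestral_is_ref, dose, 2 - dose).astype(np.int8)
        if cfg.missingness > 0:
            gt[rng.random(n_sites) < cfg.missingness] = MISSING
        geno[:, col] = gt

    sites = pd.DataFrame({"chrom": site_chrom, "pos": pos, "ref": ref, "alt": alt})
    vt = VariantTable(sites, geno, samples)

    # -- effect annotations (with amino-acid changes for missense)
    aa_ref = np.full(n_sites, None, dtype=object)
    aa_alt = np.full(n_sites, None, dtype=object)
    mis = np.flatnonzero(classes == "missense")
    for i in mis:
        pool = (
            _RADICAL_AA_PAIRS
            if rng.random() < cfg.radical_missense_prob
            else _MILD_AA_PAIRS
        )
        a1, a2 = pool[rng.integers(0, len(pool))]
        aa_ref[i], aa_alt[i] = a1, a2
    raw = pd.DataFrame(
        {
            "chrom": site_chrom,
            "pos": pos,
            "term": [_TERM_BY_CLASS[c] for c in classes],
            "aa_ref": aa_ref,
            "aa_alt": aa_alt,
        }
    )
    effects = classify_effects(raw)

    # -- outgroup alleles with error
    anc_base = np.where(ancestral_is_ref, ref, alt)
    der_base = np.where(ancestral_is_ref, alt, ref)
    flip = rng.random(n_sites) < cfg.outgroup_error
    out_base = np.where(flip, der_base, anc_base)
    outgroup = pd.DataFrame({"chrom": site_chrom, "pos": pos, "base": out_base})

    # -- conservation scores: heavy upper tail, enriched at deleterious sites
    scores = rng.normal(0.0, cfg.conservation_sd, n_sites)
    del_mask = np.isin(classes, ("LoF", "missense"))
    scores[del_mask] += rng.exponential(cfg.conservation_bump, int(del_mask.sum()))
    track = ConservationTrack(scores)

    # -- truth: realized per-pair category load ratios (total derived dose)
    load_ratio: dict[str, dict[tuple[str, str], float]] = {}
    for cls in cfg.site_counts:
        sel = classes == cls
        totals = {
            pop: float(derived_freq[pop][sel].sum()) for pop in pop_names
        }
        load_ratio[cls] = {
            (x, y): totals[x] / totals[y] if totals[y] > 0 else np.nan
            for x in pop_names
            for y in pop_names
            if x != y
        }

    truth = TruthTable(
        segments=segments,
        autozygous_fraction=true_frac,
        ancestral_is_ref=ancestral_is_ref,
        effect_class=classes,
        scores=scores,
        derived_freq=derived_freq,
        load_ratio=load_ratio,
    )
    return SimResult(vt, panel, effects, outgroup, track, layout, truth)


# ---------------------------------------------------------------------------
# Hand-checkable worked toys
# ---------------------------------------------------------------------------

def make_worked_toy() -> dict:
    """Tiny fixtures with hand-computed expected outputs.

    Returns a dict with three entries:

    ``rxy``
        A 4-site example (2 category + 2 intergenic sites, s = 20 alleles
        everywhere).  Hand evaluation of the ratio-of-sums formulas gives
        L_X = 0.125/0.4375, L_Y = 0.275/0.4375, R = 0.125/0.275 = 5/11.
    ``roh``
        One sample, 200 hom-alt SNPs at 750 bp spacing from position
        10,000: a single run of 200 SNPs spanning [10000, 159250].
    ``sfs``
        25 one-class sites with s = 4 called alleles; 2 sites fixed derived
        (m = 4), the rest m = 2.  At subsample size 2 the single-site
        spectrum for m = 2 is (1/6, 2/3, 1/6) by enumeration of the six
        allele pairs; at subsample size 4 (the full sample) exactly the two
        fixed sites put mass in the fixed bin, so the fixed proportion is
        2/25 = 0.08.
    """
    from .load_annotation import ANCESTRAL_REF, PolarizedTable

    # Rxy toy
    m_x = np.array([2, 1, 5, 10])
    m_y = np.array([4, 2, 5, 10])
    s = np.full(4, 20)
    polar = PolarizedTable(
        ancestral=np.full(4, ANCESTRAL_REF, dtype=np.int8),
        m={"X": m_x, "Y": m_y},
        s={"X": s.copy(), "Y": s.copy()},
        focal_population="X",
    )
    rxy_toy = {
        "polar": polar,
        "category_sites": np.array([True, True, False, False]),
        "intergenic_sites": np.array([False, False, True, True]),
        "expected_l_x": 0.125 / 0.4375,
        "expected_l_y": 0.275 / 0.4375,
        "expected_r": 5.0 / 11.0,
    }

    # ROH toy
    n = 200
    pos = 10_000 + 750 * np.arange(n)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "G"}
    )
    geno = np.full((n, 1), 2, dtype=np.int8)
    vt = VariantTable(sites, geno, ["ind1"])
    roh_toy = {
        "variants": vt,
        "sample": "ind1",
        "expected_segment": {"chrom": "chr1", "start": 10_000,
                             "end": int(pos[-1]), "n_snps": n},
    }

    # SFS toy
    n_sites = 25
    m = np.full(n_sites, 2)
    m[:2] = 4
    sfs_toy = {
        "m": m,
        "s": np.full(n_sites, 4),
        "subsample_2n": 2,
        "expected_single_site_pmf": (1 / 6, 2 / 3, 1 / 6),
        "fixed_subsample_2n": 4,
        "expected_fixed_fraction": 2 / 25,
    }
    return {"rxy": rxy_toy, "roh": roh_toy, "sfs": sfs_toy}
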