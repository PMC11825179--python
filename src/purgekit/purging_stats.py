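"""Purging and load statistics: ROHf / non-ROHf, Rxy with block jackknife,
conservation-weighted relative load, and the site-frequency spectrum.

ROHf is, per individual, the count of derived deleterious mutations inside
that individual's ROH regions divided by the count of synonymous mutations
in the same regions (non-ROHf analogously outside ROH).  Genetic purging —
selection removing recessive deleterious alleles exposed as homozygotes
inside autozygous tracts — depresses ROHf relative to non-ROHf.

Rxy compares the relative excess of derived alleles of a category C in
population X versus Y, normalized by intergenic sites I:

    L_X = sum_{i in C} (m_X/s_X)(1 - m_Y/s_Y) / sum_{i in I} (m_X/s_X)(1 - m_Y/s_Y)
    R_X/Y = L_X / L_Y

R = 1 means equal load; R < 1 means Y carries the greater derived load.
The standard error comes from a delete-one-block jackknife over contiguous
site blocks (C and I partitioned jointly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom

from .load_annotation import PolarizedTable, derived_dose
from .roh import ROHSegment
from .variants_io import MISSING, SamplePanel, VariantTable


# ---------------------------------------------------------------------------
# ROHf / non-ROHf
# ---------------------------------------------------------------------------

@dataclass
class ROHfResult:
    per_individual: pd.DataFrame   # sample, population, category, counts + ratios
    per_population: pd.DataFrame   # means, sds, paired-test p-value


def sites_in_roh(
    chroms: np.ndarray, pos: np.ndarray, segs: list[ROHSegment]
) -> np.ndarray:
    """Boolean mask of sites lying inside any segment (closed intervals)."""
    mask = np.zeros(pos.size, dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    for chrom, spans in by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        p = pos[sel]
        spans.sort()
        starts = np.array([a for a, _ in spans])
        ends = np.array([b for _, b in spans])
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p <= ends[np.clip(idx, 0, None)])
        mask[sel[ok]] = True
    return mask


def rohf_statistics(
    vt: VariantTable,
    effects: pd.DataFrame,
    polar: PolarizedTable,
    panel: SamplePanel,
    segs_by_sample: dict[str, list[ROHSegment]],
    categories: tuple[str, ...] = ("LoF", "missense", "dnsSNP"),
) -> ROHfResult:
    """Per-individual ROHf and non-ROHf with a paired population test.

    A site counts for an individual when that individual carries at least one
    derived allele there; it is assigned to ROH / non-ROH by whether its
    position falls inside any of the individual's segments.  Populations are
    compared with a two-sided Wilcoxon signed-rank test of ROHf vs non-ROHf
    across individuals; individuals with an undefined ratio (zero synonymous
    count in a region) are excluded from the test.
    """
    from .load_annotation import category_masks

    masks = category_masks(effects)
    syn_mask = masks["synonymous"]
    chroms = vt.sites["chrom"].astype(str).to_numpy()
    pos = vt.sites["pos"].to_numpy()
    rows = []
    for sample in vt.samples:
        dose = derived_dose(vt, polar, sample)
        carrier = dose > 0
        in_roh = sites_in_roh(chroms, pos, segs_by_sample.get(sample, []))
        s_in = int((carrier & syn_mask & in_roh).sum())
        s_out = int((carrier & syn_mask & ~in_roh).sum())
        for cat in categories:
            n_in = int((carrier & masks[cat] & in_roh).sum())
            n_out = int((carrier & masks[cat] & ~in_roh).sum())
            rohf = n_in / s_in if s_in > 0 else np.nan
            nonrohf = n_out / s_out if s_out > 0 else np.nan
            ratio = rohf / nonrohf if s_in > 0 and s_out > 0 and nonrohf > 0 else np.nan
            rows.append(
                {
                    "sample": sample,
                    "population": panel.population_of(sample),
                    "category": cat,
                    "n_del_in_roh": n_in,
                    "n_syn_in_roh": s_in,
                    "n_del_out_roh": n_out,
                    "n_syn_out_roh": s_out,
                    "rohf": rohf,
                    "nonrohf": nonrohf,
                    "ratio": ratio,
                }
            )
    per_ind = pd.DataFrame(rows)
    pop_rows = []
    for (pop, cat), grp in per_ind.groupby(["population", "category"]):
        ok = grp.dropna(subset=["rohf", "nonrohf"])
        if len(ok) >= 2 and not np.allclose(ok["rohf"], ok["nonrohf"]):
            try:
                pval = float(
                    stats.wilcoxon(ok["rohf"], ok["nonrohf"],
                                   alternative="two-sided").pvalue
                )
            except ValueError:
                pval = np.nan
        else:
            pval = np.nan
        pop_rows.append(
            {
                "population": pop,
                "category": cat,
                "rohf_mean": float(ok["rohf"].mean()) if len(ok) else np.nan,
                "rohf_sd": float(ok["rohf"].std()) if len(ok) > 1 else np.nan,
                "nonrohf_mean": float(ok["nonrohf"].mean()) if len(ok) else np.nan,
                "nonrohf_sd": float(ok["nonrohf"].std()) if len(ok) > 1 else np.nan,
                "mean_ratio": float(ok["ratio"].mean()) if len(ok) else np.nan,
                "n_individuals": len(ok),
                "p_value": pval,
            }
        )
    return ROHfResult(per_ind, pd.DataFrame(pop_rows))


# ---------------------------------------------------------------------------
# Rxy
# ---------------------------------------------------------------------------

@dataclass
class RxyResult:
    l_x: float
    l_y: float
    r: float
    se: float
    pseudo_values: np.ndarray = field(repr=False)
    n_blocks: int = 0

    @property
    def interval(self) -> tuple[float, float]:
        """Normal-approximation 95% interval for R."""
        return self.r - 1.96 * self.se, self.r + 1.96 * self.se


def _rxy_point(mx, sx, my, sy, c_idx, i_idx) -> tuple[float, float, float]:
    def ratio_of_sums(m1, s1, m2, s2, idx):
        ok = idx[(s1[idx] > 0) & (s2[idx] > 0)]
        return float(np.sum((m1[ok] / s1[ok]) * (1.0 - m2[ok] / s2[ok])))

    num_x = ratio_of_sums(mx, sx, my, sy, c_idx)
    den_x = ratio_of_sums(mx, sx, my, sy, i_idx)
    num_y = ratio_of_sums(my, sy, mx, sx, c_idx)
    den_y = ratio_of_sums(my, sy, mx, sx, i_idx)
    if den_x == 0 or den_y == 0:
        raise ZeroDivisionError("zero intergenic denominator: Rxy undefined")
    l_x = num_x / den_x
    l_y = num_y / den_y
    return l_x, l_y, l_x / l_y


def rxy(
    polar: PolarizedTable,
    pop_x: str,
    pop_y: str,
    category_sites: np.ndarray,
    intergenic_sites: np.ndarray,
    n_blocks: int = 20,
) -> RxyResult:
    """Rxy for one mutation category, with delete-one-block jackknife SE.

    ``category_sites`` / ``intergenic_sites`` are boolean masks or index
    arrays over the polarized table's sites.  Sites with zero called alleles
    in either population are skipped in both sums.  The jackknife partitions
    C and I jointly into ``n_blocks`` contiguous blocks (genomic order) and
    recomputes R leaving each block out; the SE is the usual delete-one
    jackknife estimate over blocks.
    """
    mx, sx = polar.m[pop_x], polar.s[pop_x]
    my, sy = polar.m[pop_y], polar.s[pop_y]
    c_idx = np.arange(mx.size)[category_sites]
    i_idx = np.arange(mx.size)[intergenic_sites]
    if c_idx.size == 0 or i_idx.size == 0:
        raise ValueError("category and intergenic site sets must be nonempty")
    l_x, l_y, r = _rxy_point(mx, sx, my, sy, c_idx, i_idx)

    # jackknife blocks partition the informative sites only
    c_idx = c_idx[(sx[c_idx] > 0) & (sy[c_idx] > 0)]
    i_idx = i_idx[(sx[i_idx] > 0) & (sy[i_idx] > 0)]

    n_blocks = int(min(n_blocks, c_idx.size, i_idx.size))
    if n_blocks < 2:
        return RxyResult(l_x, l_y, r, np.nan, np.array([]), n_blocks)
    c_blocks = np.array_split(c_idx, n_blocks)
    i_blocks = np.array_split(i_idx, n_blocks)
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        c_keep = np.concatenate([c_blocks[k] for k in range(n_blocks) if k != b])
        i_keep = np.concatenate([i_blocks[k] for k in range(n_blocks) if k != b])
        loo[b] = _rxy_point(mx, sx, my, sy, c_keep, i_keep)[2]
    pseudo = n_blocks * r - (n_blocks - 1) * loo
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2)))
    return RxyResult(l_x, l_y, r, se, pseudo, n_blocks)


# ---------------------------------------------------------------------------
# Conservation-weighted (GERP-style) relative load
# ---------------------------------------------------------------------------

@dataclass
class ConservationTrack:
    """Per-site conservation scores with a top-quantile mask.

    The mask marks the ``ceil(q * n_scored)`` highest-scoring sites
    (ties broken by site order), reproducible from the scores.
    """

    scores: np.ndarray
    quantile: float = 0.001
    top_mask: np.ndarray = field(init=False)
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        n = scores.size
        k = int(np.ceil(self.quantile * n))
        k = max(min(k, n), 0)
        order = np.lexsort((np.arange(n), -scores))  # stable: score desc, then order
        mask = np.zeros(n, dtype=bool)
        if k:
            mask[order[:k]] = True
        self.scores = scores
        self.top_mask = mask
        self.threshold = float(scores[order[k - 1]]) if k else np.inf


@dataclass
class GERPLoadResult:
    per_individual: pd.DataFrame   # sample, population, weighted_sum, n_derived, relative_load
    threshold: float
    quantile: float


def gerp_relative_load(
    vt: VariantTable,
    polar: PolarizedTable,
    track: ConservationTrack,
    panel: SamplePanel,
) -> GERPLoadResult:
    """Relative mutational load weighted by conservation score.

    Per individual: sum of derived-allele dose (het = 1, hom = 2) times the
    site's conservation score over the top-quantile sites, divided by the
    individual's total derived-allele dose over all polarized sites.
    Individuals with zero derived alleles report ``NaN``.
    """
    if track.scores.size != vt.n_sites:
        raise ValueError("conservation track must align with variant table sites")
    rows = []
    for sample in vt.samples:
        dose = derived_dose(vt, polar, sample)
        weighted = float(np.sum(dose[track.top_mask] * track.scores[track.top_mask]))
        total = int(dose.sum())
        rows.append(
            {
                "sample": sample,
                "population": panel.population_of(sample),
                "weighted_sum": weighted,
                "n_derived": total,
                "relative_load": weighted / total if total > 0 else np.nan,
            }
        )
    return GERPLoadResult(pd.DataFrame(rows), track.threshold, track.quantile)


# ---------------------------------------------------------------------------
# Site-frequency spectrum
# ---------------------------------------------------------------------------

@dataclass
class SFSResult:
    population: str
    subsample_2n: int
    spectra: dict[str, np.ndarray]   # class -> proportions over bins 0..2n
    n_sites: dict[str, int]          # class -> sites contributing

    def proportion_fixed(self) -> dict[str, float]:
        """Share of spectrum mass in the fixed (frequency = 1) bin."""
        return {cls: float(spec[-1]) for cls, spec in self.spectra.items()}


#: SFS mutation classes following the damaging/neutral contrast.
SFS_CLASSES = {"damaging": ("LoF", "missense"), "neutral": ("intergenic",)}


def sfs(
    polar: PolarizedTable,
    effects: pd.DataFrame,
    panel: SamplePanel,
    population: str,
    subsample_2n: int,
    mode: str = "expected",
    seed: int | None = None,
) -> SFSResult:
    """Derived-allele site-frequency spectrum on a fixed subsample size.

    At each resolved site with s >= ``subsample_2n`` called alleles (m of
    them derived), ``subsample_2n`` alleles are drawn without replacement.
    ``mode='expected'`` adds the exact hypergeometric pmf over derived counts
    0..2n' (deterministic projection); ``mode='mc'`` adds a single seeded
    hypergeometric draw per site.  Bins 0 (absent) and 2n' (fixed) are part
    of the spectrum.  Sites with fewer called alleles than the subsample
    size are skipped.
    """
    if subsample_2n <= 0 or subsample_2n % 2:
        raise ValueError("subsample_2n must be a positive even count of alleles")
    if mode not in ("expected", "mc"):
        raise ValueError(f"unknown SFS mode {mode!r}")
    eff = effects["effect"].to_numpy()
    m_all = polar.m[population]
    s_all = polar.s[population]
    rng = np.random.default_rng(seed)
    spectra: dict[str, np.ndarray] = {}
    n_sites: dict[str, int] = {}
    k = np.arange(subsample_2n + 1)
    for cls, members in SFS_CLASSES.items():
        mask = np.isin(eff, members) & polar.resolved & (s_all >= subsample_2n)
        m = m_all[mask]
        s = s_all[mask]
        spec = np.zeros(subsample_2n + 1)
        if mode == "expected":
            for mi, si in zip(m, s):
                spec += hypergeom.pmf(k, si, mi, subsample_2n)
        else:
            draws = rng.hypergeometric(m, s - m, subsample_2n) if m.size else np.array([], dtype=int)
            np.add.at(spec, draws.astype(int), 1.0)
        total = spec.sum()
        spectra[cls] = spec / total if total > 0 else spec
        n_sites[cls] = int(mask.sum())
    return SFSResult(population, subsample_2n, spectra, n_sites)


def proportion_fixed(result: SFSResult) -> dict[str, float]:
    """Fraction of spectrum mass in the fixed bin, per mutation class."""
    return result.proportion_fixed()
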