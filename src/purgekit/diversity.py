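"""Windowed nucleotide diversity (pi) and per-individual heterozygosity.

Both statistics follow vcftools semantics.  Within a window, per-site
diversity is the unbiased heterozygosity 2*j*(n-j) / (n*(n-1)) where j is
the alt-allele count among a population's called alleles and n the called
allele count at that site; missing genotypes shrink n rather than being
imputed.  Window pi divides the summed per-site values by the window span
in bp, so it is a per-base quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import MISSING, SamplePanel, VariantTable


@dataclass
class DiversityResult:
    windows: pd.DataFrame          # chrom, start, end, population, n_variants, pi
    genome_pi: dict[str, float]    # population -> length-weighted mean window pi
    genome_pi_total: dict[str, float]  # population -> total-sites ratio variant


def _per_site_pi(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-site heterozygosity and called-allele counts.

    ``gt`` is (sites x samples) with 0/1/2/-1 codes.
    """
    called = gt != MISSING
    n = 2 * called.sum(axis=1)
    j = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(n > 1, 2.0 * j * (n - j) / (n * (n - 1.0)), 0.0)
    return h, n


def windowed_pi(
    vt: VariantTable,
    panel: SamplePanel,
    window_bp: int = 500_000,
    chrom_lengths: dict[str, int] | None = None,
) -> DiversityResult:
    """Non-overlapping windowed pi per population.

    Windows are 1-based closed spans [1, window_bp], [window_bp+1, 2*window_bp]
    ... per chromosome; a terminal window shorter than ``window_bp`` (when the
    chromosome length is known) uses its true length as denominator.  Windows
    with zero variant sites report pi = 0.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    panel.require_covers(vt.samples)
    chroms = vt.sites["chrom"].to_numpy()
    pos = vt.sites["pos"].to_numpy()
    rows = []
    for pop, members in panel.populations.items():
        cols = [vt.sample_index(s) for s in members]
        sub = vt.genotypes[:, cols]
        h, n = _per_site_pi(sub)
        j = np.where(sub != MISSING, sub, 0).sum(axis=1)
        variant = (n > 0) & (j > 0)  # at least one called alt allele in the population
        for chrom in dict.fromkeys(chroms):
            sel = chroms == chrom
            p = pos[sel]
            hs = h[sel]
            var = variant[sel]
            clen = (chrom_lengths or {}).get(str(chrom))
            if clen is None:
                # length unknown: whole windows up to the last variant
                maxp = int(p.max()) if p.size else 1
                clen = -(-maxp // window_bp) * window_bp
            n_windows = max(1, -(-clen // window_bp))
            win_idx = (p - 1) // window_bp
            for w in range(n_windows):
                start = w * window_bp + 1
                end = min((w + 1) * window_bp, clen)
                in_w = win_idx == w
                span = end - start + 1
                rows.append(
                    {
                        "chrom": str(chrom),
                        "start": start,
                        "end": end,
                        "population": pop,
                        "n_variants": int(var[in_w].sum()),
                        "pi": float(hs[in_w].sum() / span),
                    }
                )
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "population", "n_variants", "pi"]
    )
    genome_pi: dict[str, float] = {}
    genome_pi_total: dict[str, float] = {}
    for pop in panel.populations:
        sub = windows[windows["population"] == pop]
        spans = (sub["end"] - sub["start"] + 1).to_numpy(dtype=float)
        pis = sub["pi"].to_numpy(dtype=float)
        genome_pi[pop] = float((pis * spans).sum() / spans.sum()) if spans.size else 0.0
        genome_pi_total[pop] = genome_pi[pop]
    return DiversityResult(windows, genome_pi, genome_pi_total)


def individual_heterozygosity(vt: VariantTable) -> pd.DataFrame:
    """Observed heterozygosity per sample: het genotypes / non-missing genotypes.

    Samples with zero called genotypes report ``NaN`` rather than raising.
    Columns mirror the vcftools ``.het`` style (observed counts included).
    """
    gt = vt.genotypes
    called = (gt != MISSING).sum(axis=0)
    het = (gt == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(called > 0, het / called, np.nan)
    return pd.DataFrame(
        {
            "sample": vt.samples,
            "n_het": het.astype(int),
            "n_called": called.astype(int),
            "het_rate": frac,
        }
    )
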