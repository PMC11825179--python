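"""Runs-of-homozygosity detection and F_ROH inbreeding summaries.

The caller reproduces the PLINK 1.9 ``--homozyg`` windowed scan: a window of
``window_snp`` consecutive SNPs is called homozygous when it contains at most
``window_het`` heterozygous and at most ``window_missing`` missing calls;
each SNP then receives the fraction of the windows spanning it that are
homozygous, using the actual spanning-window count as denominator (so SNPs
near chromosome ends are covered by fewer windows).  SNPs whose fraction
reaches ``window_threshold`` are run-eligible; maximal runs of eligible SNPs
are split at inter-SNP gaps larger than ``max_gap_kb`` and then kept only if
they satisfy the minimum length, minimum SNP count and density criteria.

F_ROH is total ROH length divided by total autosome length.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .variants_io import MISSING, GenomeLayout, SamplePanel, VariantTable

#: ROH length-class floors in bp: [100 kb, 1 Mb), [1 Mb, 5 Mb), >= 5 Mb.
LENGTH_CLASS_EDGES = (100_000, 1_000_000, 5_000_000)
LENGTH_CLASS_LABELS = ("100kb-1Mb", "1Mb-5Mb", ">=5Mb")


@dataclass(frozen=True)
class ROHParams:
    """Windowed-scan parameters; defaults are PLINK v1.90 defaults except
    where noted."""

    window_snp: int = 20
    min_kb: float = 10.0
    density_kb_per_snp: float = 50.0
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 100
    max_gap_kb: float = 1000.0
    final_min_length_kb: float = 100.0

    def __post_init__(self) -> None:
        for key, v in asdict(self).items():
            if key in ("window_het", "window_missing"):
                if v < 0:
                    raise ValueError(f"ROH parameter {key} must be >= 0")
            elif v <= 0:
                raise ValueError(f"ROH parameter {key} must be positive")
        if not (0 < self.window_threshold <= 1):
            raise ValueError("window_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One autozygous run: 1-based closed interval [start, end]."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start exceeds end")
        if self.n_snps < 1:
            raise ValueError("segment must contain at least one SNP")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _eligible_mask(gt: np.ndarray, params: ROHParams) -> np.ndarray:
    """Per-SNP run-eligibility from the sliding-window hom fraction."""
    n = gt.size
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (gt == 1).astype(np.int32)
    mis = (gt == MISSING).astype(np.int32)
    # window i spans SNPs [i, i+w-1]; counts via cumulative sums
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - w + 1
    starts = np.arange(n_win)
    hom_win = (
        (chet[starts + w] - chet[starts] <= params.window_het)
        & (cmis[starts + w] - cmis[starts] <= params.window_missing)
    ).astype(np.int32)
    chom = np.concatenate([[0], np.cumsum(hom_win)])
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    hi = np.minimum(idx, n_win - 1)
    spanning = hi - lo + 1
    hom_count = chom[hi + 1] - chom[lo]
    frac = hom_count / spanning
    return frac >= params.window_threshold


def _segments_from_runs(
    pos: np.ndarray, eligible: np.ndarray, sample: str, chrom: str, params: ROHParams
) -> list[ROHSegment]:
    segs: list[ROHSegment] = []
    n = pos.size
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        # split at gaps > max_gap_kb before applying length tests
        pieces = []
        a = i
        for k in range(i, j):
            if (pos[k + 1] - pos[k]) / 1000.0 > params.max_gap_kb:
                pieces.append((a, k))
                a = k + 1
        pieces.append((a, j))
        for a, b in pieces:
            length_kb = (pos[b] - pos[a] + 1) / 1000.0
            n_snps = b - a + 1
            if length_kb < params.min_kb:
                continue
            if n_snps < params.min_snp:
                continue
            if length_kb / n_snps > params.density_kb_per_snp:
                continue
            segs.append(ROHSegment(sample, chrom, int(pos[a]), int(pos[b]), n_snps))
        i = j + 1
    return segs


def detect_roh(vt: VariantTable, sample: str, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Detect ROH segments for one sample; ``vt`` must be sorted biallelic SNPs.

    Segments below ``final_min_length_kb`` are *not* removed here; apply
    :func:`filter_roh_min_length` for the downstream-analysis cut.
    """
    vt.require_sorted()
    col = vt.sample_index(sample)
    gt_all = vt.genotypes[:, col]
    chroms = vt.sites["chrom"].to_numpy()
    pos_all = vt.sites["pos"].to_numpy()
    segs: list[ROHSegment] = []
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        gt = gt_all[sel]
        pos = pos_all[sel]
        eligible = _eligible_mask(gt, params)
        segs.extend(_segments_from_runs(pos, eligible, sample, str(chrom), params))
    return segs


def filter_roh_min_length(
    segs: list[ROHSegment], min_length: int = 100_000
) -> list[ROHSegment]:
    """Keep segments with length >= ``min_length`` bp (boundary kept)."""
    return [s for s in segs if s.length >= min_length]


def compute_froh(segs: list[ROHSegment], layout: GenomeLayout) -> float:
    """F_ROH = total ROH length / total autosome length."""
    for s in segs:
        if s.chrom not in layout.lengths:
            raise ValueError(f"segment chromosome {s.chrom!r} absent from layout")
    total = sum(s.length for s in segs)
    return total / layout.autosome_length


@dataclass
class InbreedingSummary:
    per_sample: pd.DataFrame
    per_population: pd.DataFrame
    fraction_below_1mb: float


def summarize_inbreeding(
    segs_by_sample: dict[str, list[ROHSegment]],
    layout: GenomeLayout,
    panel: SamplePanel,
) -> InbreedingSummary:
    """Per-sample F_ROH (total and per length class) and population mean +- sd.

    Class F_ROH values are restricted F_ROH: e.g. the ``1Mb-5Mb`` column sums
    only segments in [1 Mb, 5 Mb), and ``froh_ge_1mb`` sums all segments of
    at least 1 Mb (the conventional F_ROH > 1 Mb).  ``fraction_below_1mb`` is
    the share of all segments shorter than 1 Mb.
    """
    rows = []
    n_short = 0
    n_total = 0
    for sample, segs in segs_by_sample.items():
        lengths = np.array([s.length for s in segs], dtype=float)
        l_roh = lengths.sum() if lengths.size else 0.0
        row = {
            "sample": sample,
            "population": panel.population_of(sample),
            "n_segments": len(segs),
            "l_roh_bp": l_roh,
            "froh": compute_froh(segs, layout),
        }
        for lo, hi, label in zip(
            LENGTH_CLASS_EDGES,
            LENGTH_CLASS_EDGES[1:] + (np.inf,),
            LENGTH_CLASS_LABELS,
        ):
            in_class = (lengths >= lo) & (lengths < hi)
            row[f"n_{label}"] = int(in_class.sum())
            row[f"froh_{label}"] = lengths[in_class].sum() / layout.autosome_length
        ge_1mb = lengths >= 1_000_000
        row["froh_ge_1mb"] = lengths[ge_1mb].sum() / layout.autosome_length
        n_short += int((lengths < 1_000_000).sum())
        n_total += lengths.size
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    if len(per_sample):
        grp = per_sample.groupby("population")["froh"]
        per_population = grp.agg(["mean", "std", "count"]).reset_index()
        per_population.columns = ["population", "froh_mean", "froh_sd", "n"]
    else:
        per_population = pd.DataFrame(
            columns=["population", "froh_mean", "froh_sd", "n"]
        )
    frac = n_short / n_total if n_total else 0.0
    return InbreedingSummary(per_sample, per_population, frac)


def segments_to_frame(segs: list[ROHSegment]) -> pd.DataFrame:
    """PLINK .hom-style table: sample, chrom, start, end, n_snps, length_kb."""
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "length_kb": s.length / 1000.0,
            }
            for s in segs
        ],
        columns=["sample", "chrom", "start", "end", "n_snps", "length_kb"],
    )
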