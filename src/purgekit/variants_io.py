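"""Reading, validation and filtering of variant tables and sample metadata.

The in-memory workhorse is :class:`VariantTable`: a site table (chrom, pos,
ref, alt plus optional INFO annotations) paired with a dense genotype matrix
coded 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.  Genotypes are treated
as unphased throughout; phase separators in the VCF are ignored.

Coordinates are 1-based and intervals fully closed, matching VCF, PLINK and
vcftools conventions.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

HARD_FILTER_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class VariantTable:
    """Biallelic-SNP-oriented variant matrix.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` (``alt`` may hold a
        comma-joined list for multiallelic records retained at parse time)
        plus any INFO columns (``QD``, ``FS``, ...) and optional ``ann``
        (raw effect annotation string).
    genotypes
        int8 array of shape (n_sites, n_samples); values 0/1/2/-1.
    samples
        Ordered sample identifiers.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            self.genotypes = self.genotypes.reshape(len(self.sites), len(self.samples))
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def take_sites(self, mask_or_index) -> "VariantTable":
        """Subset sites (order preserved); pure subset operation."""
        idx = np.arange(self.n_sites)[mask_or_index]
        return VariantTable(
            self.sites.iloc[idx].reset_index(drop=True),
            self.genotypes[idx],
            list(self.samples),
        )

    def require_sorted(self) -> None:
        """Validate sites strictly sorted by (chrom, pos) within chromosome blocks."""
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        seen: set[str] = set()
        last = None
        for i in range(len(chrom)):
            if chrom[i] != last:
                if chrom[i] in seen:
                    raise ValueError(f"chromosome {chrom[i]} occurs in two blocks")
                seen.add(chrom[i])
                last = chrom[i]
            elif pos[i] <= pos[i - 1]:
                raise ValueError(
                    f"sites not strictly sorted at {chrom[i]}:{pos[i]}"
                )

    def is_biallelic_snp(self) -> np.ndarray:
        ref = self.sites["ref"].to_numpy()
        alt = self.sites["alt"].to_numpy()
        ok = np.empty(self.n_sites, dtype=bool)
        for i in range(self.n_sites):
            r, a = str(ref[i]), str(alt[i])
            ok[i] = (
                len(r) == 1 and r in _BASES
                and len(a) == 1 and a in _BASES
                and r != a
            )
        return ok


@dataclass
class SamplePanel:
    """Mapping of samples to populations."""

    assignments: dict[str, str]
    populations: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        pops: dict[str, list[str]] = {}
        for sample, pop in self.assignments.items():
            pops.setdefault(pop, []).append(sample)
        if any(len(v) == 0 for v in pops.values()):
            raise ValueError("empty population in panel")
        self.populations = pops

    def population_of(self, sample: str) -> str:
        return self.assignments[sample]

    def members(self, population: str) -> list[str]:
        return list(self.populations[population])

    def require_covers(self, samples) -> None:
        missing = [s for s in samples if s not in self.assignments]
        if missing:
            raise ValueError(f"samples absent from panel: {missing}")


@dataclass
class GenomeLayout:
    """Chromosome lengths with an autosome subset.

    ``autosome_length`` (the F_ROH denominator) sums autosomes only.
    """

    lengths: dict[str, int]
    autosomes: list[str]

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        unknown = [c for c in self.autosomes if c not in self.lengths]
        if unknown:
            raise ValueError(f"autosomes missing from length table: {unknown}")

    @property
    def autosome_length(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, region: tuple[str, int, int] | None = None) -> VariantTable:
    """Read a VCF 4.x file (plain or bgzipped) into a :class:`VariantTable`.

    Multiallelic records and non-SNPs are retained (alt alleles comma-joined)
    so that :func:`filter_biallelic_snps` can drop them explicitly.  Missing
    genotypes map to ``MISSING``.  ``region`` is an optional
    ``(chrom, start, end)`` 1-based closed span applied after parsing.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows = []
    gts = []
    for rec in vcf:
        alt = ",".join(rec.ALT) if rec.ALT else "."
        row = {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": alt}
        for key in HARD_FILTER_FIELDS:
            val = rec.INFO.get(key)
            if val is not None:
                try:
                    row[key] = float(val)
                except (TypeError, ValueError):
                    raise VcfParseError(
                        f"non-numeric {key}={val!r} at {rec.CHROM}:{rec.POS}"
                    ) from None
        ann = rec.INFO.get("ANN")
        if ann is not None:
            row["ann"] = str(ann)
        rows.append(row)
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        if len(g) != len(samples):
            raise VcfParseError(
                f"record {rec.CHROM}:{rec.POS} has {len(g)} genotypes for "
                f"{len(samples)} samples"
            )
        gts.append(g)
    vcf.close()

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]) if not rows else pd.DataFrame(rows)
    geno = np.array(gts, dtype=np.int8) if gts else np.empty((0, len(samples)), dtype=np.int8)
    vt = VariantTable(sites, geno, samples)
    if region is not None:
        chrom, start, end = region
        mask = (
            (vt.sites["chrom"] == chrom)
            & (vt.sites["pos"] >= start)
            & (vt.sites["pos"] <= end)
        ).to_numpy()
        vt = vt.take_sites(mask)
    return vt


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path: str | os.PathLike, layout: GenomeLayout | None = None) -> None:
    """Write a VariantTable as minimal VCF 4.2 (round-trips through read_vcf)."""
    info_cols = [c for c in HARD_FILTER_FIELDS if c in vt.sites.columns]
    has_ann = "ann" in vt.sites.columns
    with io.open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if layout is not None:
            for chrom, length in layout.lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(vt.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        for col in info_cols:
            fh.write(f'##INFO=<ID={col},Number=1,Type=Float,Description="{col}">\n')
        if has_ann:
            fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(vt.samples) + "\n")
        sites = vt.sites
        for i in range(vt.n_sites):
            row = sites.iloc[i]
            parts = []
            for col in info_cols:
                val = row.get(col)
                if val is not None and not (isinstance(val, float) and np.isnan(val)):
                    parts.append(f"{col}={val:g}")
            if has_ann and isinstance(row.get("ann"), str):
                parts.append(f"ANN={row['ann']}")
            info = ";".join(parts) if parts else "."
            gts = "\t".join(_GT_STR[int(g)] for g in vt.genotypes[i])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Site filters (pure subset operations, order preserved)
# ---------------------------------------------------------------------------

def filter_biallelic_snps(vt: VariantTable) -> VariantTable:
    """Keep sites with single-base ref and exactly one single-base alt."""
    return vt.take_sites(vt.is_biallelic_snp())


def apply_hard_filter(vt: VariantTable) -> VariantTable:
    """GATK-style hard filter.

    A site is removed iff any of QD < 2.0, FS > 60.0, MQ < 40.0,
    MQRankSum < -12.5 or ReadPosRankSum < -8.0 fires; an absent annotation
    never triggers removal.
    """
    n = vt.n_sites
    bad = np.zeros(n, dtype=bool)
    thresholds = {
        "QD": ("lt", 2.0),
        "FS": ("gt", 60.0),
        "MQ": ("lt", 40.0),
        "MQRankSum": ("lt", -12.5),
        "ReadPosRankSum": ("lt", -8.0),
    }
    for key, (op, cut) in thresholds.items():
        if key not in vt.sites.columns:
            continue
        col = pd.to_numeric(vt.sites[key], errors="raise").to_numpy(dtype=float)
        present = ~np.isnan(col)
        if op == "lt":
            bad |= present & (col < cut)
        else:
            bad |= present & (col > cut)
    return vt.take_sites(~bad)


def filter_missingness(
    vt: VariantTable, panel: SamplePanel, max_missing_frac: float = 0.20
) -> VariantTable:
    """Drop sites missing in more than ``max_missing_frac`` of any population.

    The comparison is strict (> 0.20 removes, exactly 0.20 keeps).  Sites
    failing in any one population are dropped globally so that every
    downstream statistic shares one site set.
    """
    panel.require_covers(vt.samples)
    keep = np.ones(vt.n_sites, dtype=bool)
    for pop, members in panel.populations.items():
        cols = [vt.sample_index(s) for s in members if s in vt.samples]
        if not cols:
            continue
        sub = vt.genotypes[:, cols]
        frac = (sub == MISSING).mean(axis=1)
        keep &= ~(frac > max_missing_frac)
    return vt.take_sites(keep)


# ---------------------------------------------------------------------------
# Sidecar table readers
# ---------------------------------------------------------------------------

def read_panel(path: str | os.PathLike) -> SamplePanel:
    """2-column headerless TSV: sample, population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str)
    return SamplePanel(dict(zip(df["sample"], df["population"])))


def write_panel(panel: SamplePanel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, pop in panel.assignments.items():
            fh.write(f"{sample}\t{pop}\n")


def read_layout(path: str | os.PathLike, autosomes: list[str] | None = None) -> GenomeLayout:
    """2-column TSV (chrom, length); ``autosomes`` defaults to all chroms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64})
    lengths = dict(zip(df["chrom"], df["length"].astype(int)))
    return GenomeLayout(lengths, autosomes if autosomes is not None else list(lengths))


def write_layout(layout: GenomeLayout, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_site_table(path: str | os.PathLike, value_name: str, dtype=str) -> pd.DataFrame:
    """Generic per-site TSV: chrom, pos, value (headerless)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", value_name],
                     dtype={"chrom": str, "pos": np.int64})
    df[value_name] = df[value_name].astype(dtype)
    return df
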