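"""Functional-effect classification, Grantham distances, derived-allele
polarization and per-individual load tabulation.

Effect classes
--------------
``LoF`` (stop gained, splice acceptor, splice donor), ``missense``,
``synonymous``, ``intergenic``, ``other``.  A nonsynonymous change whose
Grantham distance is at least 150 is additionally flagged as a deleterious
nonsynonymous SNP (dnsSNP) — a subset of missense.

Polarization
------------
An allele is called ancestral when it matches the outgroup allele at the
site *and* is the major allele (frequency strictly above 50%) in the focal
population; the opposite allele is derived.  Sites failing either condition
are UNRESOLVED and excluded from all derived-allele statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants_io import MISSING, SamplePanel, VariantTable

# -- effect vocabulary -------------------------------------------------------

LOF_TERMS = frozenset({"stop_gained", "splice_acceptor_variant", "splice_donor_variant"})

_CLASS_BY_TERM = {
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
}

#: severity order used to collapse multi-transcript annotations
SEVERITY = {"LoF": 4, "missense": 3, "synonymous": 2, "intergenic": 1, "other": 0}

CATEGORIES = ("LoF", "missense", "dnsSNP", "synonymous")


def classify_term(term: str) -> str:
    term = term.strip()
    if term in LOF_TERMS:
        return "LoF"
    if term in _CLASS_BY_TERM:
        return _CLASS_BY_TERM[term]
    if term:
        warnings.warn(f"unrecognized effect term {term!r}; classed as 'other'",
                      stacklevel=2)
    return "other"


def classify_effects(annotations: pd.DataFrame) -> pd.DataFrame:
    """Map raw effect terms to primary classes and dnsSNP flags.

    ``annotations`` columns: chrom, pos, term and optionally aa_ref, aa_alt.
    A term cell may hold several ``&``- or ``,``-separated transcript terms;
    the most severe class wins.  Returns chrom, pos, effect, aa_ref, aa_alt,
    dnssnp, term.
    """
    out = annotations.copy()
    effects = []
    for term in out["term"].astype(str):
        parts = [p for chunk in term.split(",") for p in chunk.split("&")]
        cls = max((classify_term(p) for p in parts), key=SEVERITY.__getitem__)
        effects.append(cls)
    out["effect"] = effects
    if "aa_ref" not in out.columns:
        out["aa_ref"] = None
        out["aa_alt"] = None
    dns = []
    for eff, a1, a2 in zip(out["effect"], out["aa_ref"], out["aa_alt"]):
        if eff == "missense" and isinstance(a1, str) and isinstance(a2, str) \
                and a1 in GRANTHAM_PROPERTIES and a2 in GRANTHAM_PROPERTIES:
            dns.append(grantham(a1, a2) >= DNSSNP_THRESHOLD)
        else:
            dns.append(False)
    out["dnssnp"] = dns
    return out[["chrom", "pos", "effect", "aa_ref", "aa_alt", "dnssnp", "term"]]


def effects_from_ann_column(vt: VariantTable) -> pd.DataFrame:
    """Extract a raw term table from a SnpEff-style ANN INFO column.

    Each ANN entry is ``Allele|Annotation|Impact|...|HGVS.p|...``; only the
    annotation term (field 2) and, when present, a ``p.Xaa123Yaa`` protein
    change are used.
    """
    if "ann" not in vt.sites.columns:
        raise ValueError("variant table has no ANN annotations")
    rows = []
    for _, site in vt.sites.iterrows():
        ann = site.get("ann")
        terms = []
        aa = (None, None)
        if isinstance(ann, str):
            for entry in ann.split(","):
                fields = entry.split("|")
                if len(fields) > 1:
                    terms.append(fields[1])
                if len(fields) > 10 and fields[10].startswith("p."):
                    parsed = _parse_hgvs_p(fields[10])
                    if parsed is not None:
                        aa = parsed
        rows.append(
            {
                "chrom": site["chrom"],
                "pos": site["pos"],
                "term": "&".join(terms) if terms else "",
                "aa_ref": aa[0],
                "aa_alt": aa[1],
            }
        )
    return pd.DataFrame(rows)


_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


def _parse_hgvs_p(code: str) -> tuple[str, str] | None:
    body = code[2:]
    if len(body) < 7:
        return None
    a1, a2 = body[:3], body[-3:]
    if a1 in _AA3TO1 and a2 in _AA3TO1:
        return _AA3TO1[a1], _AA3TO1[a2]
    return None


# -- Grantham distance -------------------------------------------------------

#: Grantham (1974) side-chain properties: composition c, polarity p,
#: molecular volume v, per amino acid (one-letter code).
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

_ALPHA, _BETA, _GAMMA = 1.833, 0.1018, 0.000399

#: Grantham distance at or above which a missense change counts as dnsSNP.
DNSSNP_THRESHOLD = 150.0


def _raw_distance(a: str, b: str) -> float:
    c1, p1, v1 = GRANTHAM_PROPERTIES[a]
    c2, p2, v2 = GRANTHAM_PROPERTIES[b]
    return math.sqrt(
        _ALPHA * (c1 - c2) ** 2 + _BETA * (p1 - p2) ** 2 + _GAMMA * (v1 - v2) ** 2
    )


def _mean_scale() -> float:
    aas = list(GRANTHAM_PROPERTIES)
    total = 0.0
    npairs = 0
    for i, a in enumerate(aas):
        for b in aas[i + 1:]:
            total += _raw_distance(a, b)
            npairs += 1
    return 100.0 * npairs / total


_SCALE = _mean_scale()


def grantham_matrix() -> pd.DataFrame:
    """Full symmetric 20x20 Grantham distance matrix (mean distance 100)."""
    aas = sorted(GRANTHAM_PROPERTIES)
    mat = np.zeros((20, 20))
    for i, a in enumerate(aas):
        for j, b in enumerate(aas):
            mat[i, j] = 0.0 if a == b else _SCALE * _raw_distance(a, b)
    return pd.DataFrame(mat, index=aas, columns=aas)


def grantham(aa1: str, aa2: str) -> float:
    """Grantham physicochemical distance between two standard amino acids."""
    for aa in (aa1, aa2):
        if aa not in GRANTHAM_PROPERTIES:
            raise ValueError(f"nonstandard amino acid {aa!r}")
    if aa1 == aa2:
        return 0.0
    return _SCALE * _raw_distance(aa1, aa2)


def is_dnssnp(aa1: str, aa2: str) -> bool:
    return grantham(aa1, aa2) >= DNSSNP_THRESHOLD


# -- polarization ------------------------------------------------------------

ANCESTRAL_REF = 0
ANCESTRAL_ALT = 1
UNRESOLVED = -1


@dataclass
class PolarizedTable:
    """Ancestral-state calls plus per-population derived-allele counts.

    ``ancestral`` holds ANCESTRAL_REF / ANCESTRAL_ALT / UNRESOLVED per site.
    ``m`` and ``s`` map population -> arrays of derived and called allele
    counts per site; UNRESOLVED sites carry m = s = 0.
    """

    ancestral: np.ndarray
    m: dict[str, np.ndarray]
    s: dict[str, np.ndarray]
    focal_population: str

    @property
    def resolved(self) -> np.ndarray:
        return self.ancestral != UNRESOLVED


def polarize(
    vt: VariantTable,
    outgroup_alleles: pd.DataFrame,
    panel: SamplePanel,
    focal_population: str,
) -> PolarizedTable:
    """Assign ancestral/derived states from an outgroup plus a majority rule.

    ``outgroup_alleles`` columns: chrom, pos, base.  The candidate ancestral
    allele must equal the outgroup base and exceed 50% frequency in
    ``focal_population``; otherwise the site is UNRESOLVED (also when the
    outgroup base matches neither allele or is absent).
    """
    base_col = "base" if "base" in outgroup_alleles.columns else outgroup_alleles.columns[2]
    bad = ~outgroup_alleles[base_col].astype(str).isin(["A", "C", "G", "T"])
    if bad.any():
        raise ValueError(
            f"invalid outgroup base(s): {outgroup_alleles.loc[bad, base_col].unique()[:5]}"
        )
    lookup = {
        (c, p): b
        for c, p, b in zip(
            outgroup_alleles["chrom"].astype(str),
            outgroup_alleles["pos"].astype(int),
            outgroup_alleles[base_col].astype(str),
        )
    }
    focal_cols = [vt.sample_index(smp) for smp in panel.members(focal_population)]
    gt_focal = vt.genotypes[:, focal_cols]
    called = gt_focal != MISSING
    n_focal = 2 * called.sum(axis=1)
    alt_focal = np.where(called, gt_focal, 0).sum(axis=1)

    n_sites = vt.n_sites
    ancestral = np.full(n_sites, UNRESOLVED, dtype=np.int8)
    chroms = vt.sites["chrom"].astype(str).to_numpy()
    poss = vt.sites["pos"].to_numpy()
    refs = vt.sites["ref"].astype(str).to_numpy()
    alts = vt.sites["alt"].astype(str).to_numpy()
    for i in range(n_sites):
        out_base = lookup.get((chroms[i], int(poss[i])))
        if out_base is None or n_focal[i] == 0:
            continue
        if out_base == refs[i]:
            freq = (n_focal[i] - alt_focal[i]) / n_focal[i]
            if freq > 0.5:
                ancestral[i] = ANCESTRAL_REF
        elif out_base == alts[i]:
            freq = alt_focal[i] / n_focal[i]
            if freq > 0.5:
                ancestral[i] = ANCESTRAL_ALT

    m: dict[str, np.ndarray] = {}
    s: dict[str, np.ndarray] = {}
    resolved = ancestral != UNRESOLVED
    derived_is_alt = ancestral == ANCESTRAL_REF
    for pop, members in panel.populations.items():
        cols = [vt.sample_index(smp) for smp in members]
        gt = vt.genotypes[:, cols]
        call = gt != MISSING
        s_pop = 2 * call.sum(axis=1)
        alt_count = np.where(call, gt, 0).sum(axis=1)
        m_pop = np.where(derived_is_alt, alt_count, s_pop - alt_count)
        m_pop = np.where(resolved, m_pop, 0)
        s_pop = np.where(resolved, s_pop, 0)
        m[pop] = m_pop.astype(np.int64)
        s[pop] = s_pop.astype(np.int64)
    return PolarizedTable(ancestral, m, s, focal_population)


def derived_dose(vt: VariantTable, polar: PolarizedTable, sample: str) -> np.ndarray:
    """Per-site derived-allele dose (0/1/2; 0 at UNRESOLVED or missing)."""
    gt = vt.genotypes[:, vt.sample_index(sample)].astype(np.int64)
    called = gt != MISSING
    dose_alt = np.where(called, gt, 0)
    dose = np.where(polar.ancestral == ANCESTRAL_REF, dose_alt,
                    np.where(called, 2 - dose_alt, 0))
    return np.where(polar.resolved, dose, 0)


# -- load tabulation ---------------------------------------------------------

@dataclass
class LoadCounts:
    per_individual: pd.DataFrame   # sample, population, category, n_het, n_hom, n_total
    per_population: pd.DataFrame   # population, category, total/mean columns


def category_masks(effects: pd.DataFrame) -> dict[str, np.ndarray]:
    """Site masks for the four load categories (dnsSNP subset of missense)."""
    eff = effects["effect"].to_numpy()
    dns = effects["dnssnp"].to_numpy(dtype=bool)
    return {
        "LoF": eff == "LoF",
        "missense": eff == "missense",
        "dnsSNP": (eff == "missense") & dns,
        "synonymous": eff == "synonymous",
    }


def tabulate_load(
    vt: VariantTable,
    effects: pd.DataFrame,
    polar: PolarizedTable,
    panel: SamplePanel,
) -> LoadCounts:
    """Count heterozygous and derived-homozygous genotypes per individual
    and category.  Counting is polarity-aware: at sites where the derived
    allele is the reference, hom-ref genotypes count as derived homozygotes.
    UNRESOLVED sites and missing genotypes are skipped.
    """
    if len(effects) != vt.n_sites:
        raise ValueError("effects table must align with variant table sites")
    masks = category_masks(effects)
    rows = []
    for sample in vt.samples:
        dose = derived_dose(vt, polar, sample)
        gt = vt.genotypes[:, vt.sample_index(sample)]
        het = (gt == 1) & polar.resolved
        hom = (dose == 2)
        for cat, mask in masks.items():
            n_het = int((het & mask).sum())
            n_hom = int((hom & mask).sum())
            rows.append(
                {
                    "sample": sample,
                    "population": panel.population_of(sample),
                    "category": cat,
                    "n_het": n_het,
                    "n_hom": n_hom,
                    "n_total": n_het + n_hom,
                }
            )
    per_ind = pd.DataFrame(rows)
    agg = (
        per_ind.groupby(["population", "category"])
        .agg(
            total_het=("n_het", "sum"),
            total_hom=("n_hom", "sum"),
            total=("n_total", "sum"),
            mean_per_individual=("n_total", "mean"),
        )
        .reset_index()
    )
    return LoadCounts(per_ind, agg)


def hom_load_ratio(counts: LoadCounts, category: str) -> pd.DataFrame:
    """Homozygous-load ratio 2*hom / (2*hom + het) per individual.

    Individuals with a zero denominator report ``NaN``; the population mean
    ignores them.
    """
    sub = counts.per_individual[counts.per_individual["category"] == category].copy()
    denom = 2 * sub["n_hom"] + sub["n_het"]
    with np.errstate(divide="ignore", invalid="ignore"):
        sub["hom_ratio"] = np.where(denom > 0, 2 * sub["n_hom"] / denom, np.nan)
    pop_mean = (
        sub.groupby("population")["hom_ratio"].mean().rename("mean_hom_ratio")
    )
    return sub.merge(pop_mean, on="population")
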