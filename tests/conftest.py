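import numpy as np
import pandas as pd
import pytest

from purgekit.variants_io import GenomeLayout, SamplePanel, VariantTable


def build_vt(genotypes, pos=None, chrom="chr1", samples=None, ref="A", alt="G",
             info=None):
    """Construct a VariantTable from a (sites x samples) genotype list."""
    gt = np.asarray(genotypes, dtype=np.int8)
    if gt.ndim == 1:
        gt = gt[:, None]
    n_sites, n_samples = gt.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "pos": pos,
            "ref": ref,
            "alt": alt,
        }
    )
    if info:
        for key, vals in info.items():
            sites[key] = vals
    return VariantTable(sites, gt, list(samples))


@pytest.fixture
def toy_panel():
    return SamplePanel({"s0": "pop1", "s1": "pop1", "s2": "pop2", "s3": "pop2"})


@pytest.fixture
def small_layout():
    return GenomeLayout({"chr1": 100_000_000}, ["chr1"])


TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
chr1\t100\t.\tA\tG\t50\tPASS\tQD=20.0\tGT\t0/0\t0/1
chr1\t200\t.\tC\tT\t50\tPASS\tQD=15.0\tGT\t1/1\t./.
chr1\t300\t.\tG\tA\t50\tPASS\t.\tGT\t0/1\t0/0
"""


@pytest.fixture
def toy_vcf_path(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p
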