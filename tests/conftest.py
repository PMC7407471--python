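import numpy as np
import pytest

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=RD,Number=1,Type=Integer,Description="Reference depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small VCF from (samples, records) and return its path."""

    def _make(records, samples=("s1", "s2"), name="test.vcf"):
        path = tmp_path / name
        body = "\n".join(records)
        path.write_text(VCF_HEADER.format(samples="\t".join(samples)) + body + "\n")
        return path

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
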