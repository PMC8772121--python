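import numpy as np
import pytest

from beepop.genotype_io import GenotypeMatrix, VariantSite
from beepop.synthetic_data import make_fixture_suite


def matrix_from_dosage(dosage, chrom="chr1", spacing=100, samples=None):
    """Build a GenotypeMatrix from a (sites x samples) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if samples is None:
        samples = [f"s{i+1}" for i in range(n_samples)]
    sites = [
        VariantSite(chrom, (i + 1) * spacing, "A", "T") for i in range(n_sites)
    ]
    return GenotypeMatrix(sites, list(samples), dosage)


@pytest.fixture
def make_matrix():
    return matrix_from_dosage


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The default synthetic scenario written once per session."""
    out = tmp_path_factory.mktemp("fixtures") / "default"
    manifest = make_fixture_suite(out, seed=0)
    return out, manifest


TOY_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t./.\t0/.\t1/1
chr1\t300\t.\tG\tC,A\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2
chr1\t400\t.\tGT\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
"""


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path
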