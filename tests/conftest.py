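import numpy as np
import pytest

from archepop.genotype_io import GenotypeMatrix
from archepop.simulate import simulate_panel


@pytest.fixture
def small_vcf(tmp_path):
    """Hand-written VCF exercising het/hom/phased/missing calls plus records
    the reader must skip (monomorphic, multi-allelic, indel)."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1,length=1000000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
            "1\t100\tv1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1|1",
            "1\t200\tv2\tG\tT\t.\tPASS\t.\tGT\t./.\t1/1\t0/0",
            "1\t300\tv3\tG\t.\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0",
            "1\t400\tv4\tG\tT,C\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0",
            "1\t500\tv5\tGA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0",
            "",
        ]
    )
    path = tmp_path / "small.vcf"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_matrix():
    return GenotypeMatrix(
        dosages=np.array([[0.0, 0.5, 1.0], [0.5, 0.5, 0.0], [1.0, 0.0, 0.5], [0.0, 1.0, 1.0]]),
        sample_ids=["a", "b", "c", "d"],
        variant_ids=["v1", "v2", "v3"],
    )


@pytest.fixture(scope="session")
def sim_panel():
    """Moderate admixed panel shared by read-only tests."""
    return simulate_panel(60, 120, 3, seed=42)
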