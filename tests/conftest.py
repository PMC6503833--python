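import numpy as np
import pandas as pd
import pytest

from stocksim import GenotypeMatrix


def make_matrix(geno, pops, chrom=None, pos=None, locus=None):
    """Small helper to assemble a GenotypeMatrix from raw pieces."""
    geno = np.asarray(geno, dtype=np.int16)
    n, L = geno.shape
    meta = pd.DataFrame(
        dict(
            chrom=chrom if chrom is not None else ["1"] * L,
            pos=pos if pos is not None else np.arange(1, L + 1) * 10,
            locus=locus if locus is not None else [f"loc{j}" for j in range(L)],
            ref="A",
            alt="T",
        )
    )
    ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(geno, meta, ids, dict(zip(ids, pops)))


@pytest.fixture
def toy_vcf(tmp_path):
    """3-sample, 2-site VCF with one missing call, plus its pop map."""
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "chr1\t100\tL1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        "chr1\t200\tL2\tG\tC\t.\t.\t.\tGT\t./.\t1/1\t0/1\n"
    )
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(text)
    popmap = tmp_path / "popmap.tsv"
    popmap.write_text("a\tP1\nb\tP1\nc\tP2\n")
    return str(vcf), str(popmap)


@pytest.fixture
def triallelic_vcf(tmp_path):
    text = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
        "chr1\t100\tL1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\n"
        "chr1\t200\tL2\tG\tC,T\t.\t.\t.\tGT\t1/2\t0/1\n"
    )
    vcf = tmp_path / "tri.vcf"
    vcf.write_text(text)
    popmap = tmp_path / "popmap.tsv"
    popmap.write_text("a\tP1\nb\tP1\n")
    return str(vcf), str(popmap)
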