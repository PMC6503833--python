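"""VCF and population-map input/output.

Reading goes through cyvcf2; writing emits a minimal genotype-only VCF 4.2
that round-trips through :func:`read_vcf`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix

_GT_CODE = {0: 0, 1: 1, 2: 2, 3: MISSING}  # cyvcf2 gts012 coding


class VcfParseError(ValueError):
    pass


class PopMapError(ValueError):
    pass


def read_pop_map(path: str) -> dict[str, str]:
    """Read a two-column TSV (sample_id, site_code)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise PopMapError("population map needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_vcf(
    path: str,
    pop_map_path: str | None = None,
    *,
    pop_map: dict[str, str] | None = None,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Load biallelic SNP genotypes from a VCF file.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped).
    pop_map_path / pop_map:
        Sample -> site-code mapping; must cover every sample in the VCF.
    on_multiallelic:
        "error" (strict, default), "skip" (drop the record) or "split"
        (one biallelic pseudo-site per ALT allele).

    The RAD-locus id of each site is taken from the ID column when present,
    otherwise ``chrom_pos``.
    """
    if on_multiallelic not in ("error", "skip", "split"):
        raise ValueError("on_multiallelic must be error|skip|split")
    if pop_map is None:
        pop_map = read_pop_map(pop_map_path) if pop_map_path else {}
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if pop_map:
        absent = [s for s in samples if s not in pop_map]
        if absent:
            raise PopMapError(f"samples missing from pop map: {absent[:5]}")

    rows, meta = [], []
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1:
            if on_multiallelic == "error":
                raise VcfParseError(
                    f"multiallelic record at {var.CHROM}:{var.POS} under strict mode"
                )
            if on_multiallelic == "skip":
                continue
            # split: each ALT allele coded against all other alleles
            gts = np.asarray(var.genotypes, dtype=object)
            for k, alt in enumerate(alts, start=1):
                counts = np.empty(len(samples), dtype=np.int16)
                for i, gt in enumerate(gts):
                    alleles = [a for a in gt[:-1]]
                    if any(a < 0 for a in alleles):
                        counts[i] = MISSING
                    else:
                        counts[i] = sum(1 for a in alleles if a == k)
                rows.append(counts)
                meta.append(
                    (var.CHROM, var.POS, var.ID or f"{var.CHROM}_{var.POS}", var.REF, alt)
                )
            continue
        g = np.array([_GT_CODE[int(x)] for x in var.gt_types], dtype=np.int16)
        rows.append(g)
        meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}_{var.POS}", var.REF, alts[0]))
    vcf.close()

    geno = (
        np.vstack(rows).T if rows else np.empty((len(samples), 0), dtype=np.int16)
    )
    site_meta = pd.DataFrame(meta, columns=["chrom", "pos", "locus", "ref", "alt"])
    if not pop_map:
        pop_map = {s: "pop0" for s in samples}
    return GenotypeMatrix(geno, site_meta, samples, pop_map)


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a minimal genotype-only VCF 4.2 file."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stocksim\n")
        for chrom in pd.unique(G.site_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        meta = G.site_meta
        for j in range(G.n_sites):
            row = meta.iloc[j]
            gts = "\t".join(gt_str[int(g)] for g in G.genotypes[:, j])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.locus}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_pop_map(G: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        for s in G.sample_ids:
            fh.write(f"{s}\t{G.pop_map[s]}\n")
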