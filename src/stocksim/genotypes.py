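"""Diploid biallelic genotype container shared by the whole package.

Genotypes are stored as the count of the alternate allele per individual and
site (0, 1, 2) with ``-1`` marking a missing call.  Site metadata (chromosome,
1-based position, RAD-locus id, ref/alt alleles) travels alongside as a
pandas DataFrame, and every individual carries a sampling-site code through
``pop_map``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_META_COLUMNS = ("chrom", "pos", "locus", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """n_individuals x n_sites matrix of alt-allele counts.

    Parameters
    ----------
    genotypes:
        Integer array with values in {0, 1, 2, -1}; -1 is a missing call.
    site_meta:
        DataFrame with columns ``chrom, pos, locus, ref, alt`` (one row per
        site). Positions are 1-based and strictly increasing within a
        chromosome.
    sample_ids:
        Per-individual identifiers (unique).
    pop_map:
        Mapping of sample id -> sampling-site / population code covering
        every individual.
    """

    genotypes: np.ndarray
    site_meta: pd.DataFrame
    sample_ids: list[str]
    pop_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.site_meta) != self.genotypes.shape[1]:
            raise ValueError("site_meta length does not match genotype columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be in {0, 1, 2, -1}")
        missing_pop = [s for s in self.sample_ids if s not in self.pop_map]
        if self.pop_map and missing_pop:
            raise ValueError(f"samples missing from pop_map: {missing_pop[:5]}")
        self.site_meta = self.site_meta.reset_index(drop=True)

    # -- basic shape ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population codes in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_map[s], None)
        return list(seen)

    def pop_indices(self, pop: str) -> np.ndarray:
        """Row indices of the individuals sampled at ``pop``."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.pop_map[s] == pop],
            dtype=np.intp,
        )

    # -- per-site summaries ----------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING

    def allele_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called allele count) per site over ``rows``."""
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def alt_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per site (NaN where no calls)."""
        alt, tot = self.allele_counts(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def maf(self, rows: np.ndarray | None = None) -> np.ndarray:
        p = self.alt_freq(rows)
        return np.minimum(p, 1.0 - p)

    def call_rate(self, rows: np.ndarray | None = None) -> np.ndarray:
        g = self.genotypes if rows is None else self.genotypes[rows]
        return (g != MISSING).mean(axis=0)

    # -- subsetting -------------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            self.site_meta.iloc[idx].reset_index(drop=True),
            self.sample_ids,
            dict(self.pop_map),
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        ids = [self.sample_ids[i] for i in idx]
        return GenotypeMatrix(
            self.genotypes[idx],
            self.site_meta.copy(),
            ids,
            {s: self.pop_map[s] for s in ids},
        )


@dataclass
class FilterReport:
    """Book-keeping for site filtering: each removed site is attributed to
    the first rule that rejected it."""

    n_sites_in: int
    n_sites_out: int
    n_removed_by_rule: dict[str, int]

    def __post_init__(self) -> None:
        removed = sum(self.n_removed_by_rule.values())
        if self.n_sites_in - self.n_sites_out != removed:
            raise ValueError("filter report counts are inconsistent")
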