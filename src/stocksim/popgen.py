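"""Diversity and differentiation statistics.

Per-population observed heterozygosity (H_o), gene diversity (H_s),
proportion of polymorphic sites (P), nucleotide diversity (pi) and private
polymorphisms; pairwise Weir & Cockerham theta, D_xy and net divergence D_a;
Mantel isolation-by-distance test on linearized F_ST; Spearman correlation of
stocking ancestry and individual heterozygosity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "DiversityReport",
    "PairwiseDivergence",
    "diversity",
    "count_private",
    "fst_wc",
    "dxy_da",
    "pairwise_divergence",
    "linearize_fst",
    "mantel_ibd",
    "ancestry_het_correlation",
]


@dataclass
class DiversityReport:
    per_population: pd.DataFrame  # index pop; columns Ho, Hs, P, pi, n_private, n, reliable


@dataclass
class PairwiseDivergence:
    """Pairwise divergence table indexed by (pop1, pop2)."""

    table: pd.DataFrame  # columns: fst_wc, dxy, da, fst_linearized
    fst_global: float = np.nan

    def matrix(self, stat: str = "fst_wc") -> pd.DataFrame:
        pops: list[str] = []
        for a, b in self.table.index:
            for p in (a, b):
                if p not in pops:
                    pops.append(p)
        M = pd.DataFrame(0.0, index=pops, columns=pops)
        for (a, b), row in self.table.iterrows():
            M.loc[a, b] = M.loc[b, a] = row[stat]
        return M


def _pop_site_stats(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt freq, called-gene count, het fraction, called individuals)."""
    called = g != MISSING
    n_ind = called.sum(axis=0)
    n_gene = 2 * n_ind
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_gene > 0, alt / np.maximum(n_gene, 1), np.nan)
        het = np.where(n_ind > 0, (g == 1).sum(axis=0) / np.maximum(n_ind, 1), np.nan)
    return p, n_gene, het, n_ind


def diversity(
    G: GenotypeMatrix,
    *,
    exclude_monomorphic: str = "per_population",
) -> DiversityReport:
    """Per-population diversity summary.

    H_o and H_s are averaged over sites polymorphic within the population
    (``exclude_monomorphic="per_population"``, the default convention) or
    over globally polymorphic sites (``"global"``).  H_s uses the unbiased
    n/(n-1) small-sample correction on gene copies; pi is the mean pairwise
    difference per assayed site (same correction, averaged over *all* sites).
    P is the fraction of the global site set polymorphic in the population.
    """
    if exclude_monomorphic not in ("per_population", "global"):
        raise ValueError("exclude_monomorphic must be per_population|global")
    priv = count_private(G) if len(G.populations) >= 2 else {}
    rows = {}
    for pop in G.populations:
        idx = G.pop_indices(pop)
        g = G.genotypes[idx]
        p, n_gene, het, n_ind = _pop_site_stats(g)
        ok = n_gene >= 2
        poly = ok & (p > 0) & (p < 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_unb = np.where(ok, 2.0 * p * (1.0 - p) * n_gene / np.maximum(n_gene - 1, 1), np.nan)
        if exclude_monomorphic == "per_population":
            sel = poly
        else:
            p_all = G.alt_freq()
            sel = ok & (p_all > 0) & (p_all < 1)
        ho = float(np.nanmean(het[sel])) if sel.any() else 0.0
        hs = float(np.nanmean(h_unb[sel])) if sel.any() else 0.0
        pi = float(np.nanmean(h_unb[ok])) if ok.any() else 0.0
        P = float(poly.sum() / G.n_sites) if G.n_sites else 0.0
        reliable = len(idx) >= 2
        if not reliable:
            warnings.warn(f"population {pop} has <2 individuals; statistics unreliable",
                          stacklevel=2)
        rows[pop] = dict(Ho=ho, Hs=hs, P=P, pi=pi, n_private=priv.get(pop, 0),
                         n=len(idx), reliable=reliable)
    return DiversityReport(pd.DataFrame(rows).T)


def count_private(G: GenotypeMatrix, grouping: dict[str, str] | None = None) -> dict[str, int]:
    """Sites polymorphic in exactly one group (monomorphic in all others).

    ``grouping`` maps sample id -> group; defaults to the pop map.
    """
    if grouping is None:
        grouping = G.pop_map
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(G.sample_ids):
        groups.setdefault(grouping[s], []).append(i)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    poly = {}
    for grp, idx in groups.items():
        p, n_gene, _, _ = _pop_site_stats(G.genotypes[np.asarray(idx)])
        poly[grp] = (n_gene >= 2) & (p > 0) & (p < 1)
    out = {}
    for grp in groups:
        others = np.logical_or.reduce([poly[o] for o in groups if o != grp])
        out[grp] = int((poly[grp] & ~others).sum())
    return out


def _wc_components(g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components a, b, c for two
    populations of diploids (r = 2)."""
    p1, n1g, h1, n1 = _pop_site_stats(g1)
    p2, n2g, h2, n2 = _pop_site_stats(g2)
    ok = (n1 >= 2) & (n2 >= 2)
    n1 = n1.astype(float)
    n2 = n2.astype(float)
    r = 2.0
    n_tot = n1 + n2
    nbar = n_tot / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / n_tot
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / n_tot
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    c = np.where(ok, c, 0.0)
    return np.nan_to_num(a), np.nan_to_num(b), np.nan_to_num(c)


def fst_wc(G: GenotypeMatrix, pops: list[str] | None = None) -> PairwiseDivergence:
    """Pairwise multilocus Weir & Cockerham theta (ratio of sums of the
    per-site variance components).  Pairs monomorphic at every site are
    reported as NaN."""
    pops = pops or G.populations
    rows = {}
    for p1, p2 in itertools.combinations(pops, 2):
        g1 = G.genotypes[G.pop_indices(p1)]
        g2 = G.genotypes[G.pop_indices(p2)]
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError("each population needs >=2 called diploids")
        a, b, c = _wc_components(g1, g2)
        denom = (a + b + c).sum()
        theta = a.sum() / denom if denom > 0 else np.nan
        lin = theta / (1.0 - theta) if theta < 1.0 else np.inf
        rows[(p1, p2)] = dict(fst_wc=theta, dxy=np.nan, da=np.nan, fst_linearized=lin)
    table = pd.DataFrame(rows).T
    return PairwiseDivergence(table)


def dxy_da(G: GenotypeMatrix, pops: list[str] | None = None) -> PairwiseDivergence:
    """Pairwise D_xy (mean between-population difference per site) and net
    divergence D_a = D_xy - (pi1 + pi2)/2."""
    pops = pops or G.populations
    rows = {}
    for pa, pb in itertools.combinations(pops, 2):
        g1 = G.genotypes[G.pop_indices(pa)]
        g2 = G.genotypes[G.pop_indices(pb)]
        p1, n1g, _, _ = _pop_site_stats(g1)
        p2, n2g, _, _ = _pop_site_stats(g2)
        ok = (n1g >= 2) & (n2g >= 2)
        with np.errstate(invalid="ignore"):
            dxy_site = p1 * (1 - p2) + p2 * (1 - p1)
            pi1 = 2 * p1 * (1 - p1) * n1g / np.maximum(n1g - 1, 1)
            pi2 = 2 * p2 * (1 - p2) * n2g / np.maximum(n2g - 1, 1)
        dxy = float(np.nanmean(np.where(ok, dxy_site, np.nan)))
        da = dxy - float(np.nanmean(np.where(ok, (pi1 + pi2) / 2.0, np.nan)))
        rows[(pa, pb)] = dict(fst_wc=np.nan, dxy=dxy, da=da, fst_linearized=np.nan)
    return PairwiseDivergence(pd.DataFrame(rows).T)


def pairwise_divergence(G: GenotypeMatrix, pops: list[str] | None = None) -> PairwiseDivergence:
    """F_ST, D_xy and D_a for every population pair in one table."""
    f = fst_wc(G, pops).table
    d = dxy_da(G, pops).table
    f[["dxy", "da"]] = d[["dxy", "da"]]
    return PairwiseDivergence(f)


def linearize_fst(f: float | np.ndarray) -> float | np.ndarray:
    """Rousset's F/(1-F) genetic distance (+inf at F=1)."""
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(f >= 1.0, np.inf, f / (1.0 - f))
    return float(out) if out.ndim == 0 else out


def mantel_ibd(
    fst_matrix: np.ndarray,
    distance_matrix: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-tailed Mantel test of isolation by distance.

    r is the Pearson correlation of the upper off-diagonal triangles;
    the p-value is (1 + #{permuted r >= observed}) / (n_perm + 1) under
    random row/column permutation of one matrix.
    """
    A = np.asarray(fst_matrix, dtype=float)
    B = np.asarray(distance_matrix, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    n = A.shape[0]
    if n < 4:
        raise ValueError("need dimension >= 4")
    iu = np.triu_indices(n, k=1)

    def corr(M: np.ndarray) -> float:
        return float(np.corrcoef(A[iu], M[iu])[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    ident = np.arange(n)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        while np.array_equal(perm, ident):  # identity carries no information
            perm = rng.permutation(n)
        if corr(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def ancestry_het_correlation(
    q_stock: np.ndarray, h_obs: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between per-individual stocking ancestry and
    observed heterozygosity, with a two-sided t-based p-value."""
    q = np.asarray(q_stock, dtype=float)
    h = np.asarray(h_obs, dtype=float)
    if q.shape != h.shape or q.size < 5:
        raise ValueError("need equal-length vectors with n >= 5")
    if np.all(q == q[0]) or np.all(h == h[0]):
        warnings.warn("constant input vector; rho undefined", stacklevel=2)
        return np.nan, np.nan
    res = sstats.spearmanr(q, h)
    return float(res.statistic), float(res.pvalue)
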