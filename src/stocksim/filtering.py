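"""SNP-level filtering and LD pruning.

The filters mirror a standard RADseq quality pipeline: per-site observed
heterozygosity (paralog control), per-population and global call rate,
minor-allele frequency, one SNP per RAD locus (highest MAF), and a
plink-style sliding-window variance-inflation-factor prune.
"""

from __future__ import annotations

import warnings

import numpy as np

from .genotypes import MISSING, FilterReport, GenotypeMatrix


def apply_site_filters(
    G: GenotypeMatrix,
    max_het: float = 0.6,
    min_presence_per_pop: float = 0.7,
    min_presence_global: float = 0.7,
    maf_min: float = 0.0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply per-site quality filters, preserving site order.

    A retained site has observed heterozygosity strictly below ``max_het``,
    call rate at least ``min_presence_per_pop`` within every sampling
    location and ``min_presence_global`` overall, and MAF at least
    ``maf_min``.  Missing genotypes are excluded from the heterozygosity and
    MAF denominators.  Each removed site is attributed to the first rule
    (in the order above) that rejects it.
    """
    for thr in (max_het, min_presence_per_pop, min_presence_global, maf_min):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must be in [0, 1]")

    g = G.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, (g == 1).sum(axis=0) / np.maximum(n_called, 1), 0.0)
    ok_het = het < max_het

    ok_pop = np.ones(G.n_sites, dtype=bool)
    for pop in G.populations:
        rows = G.pop_indices(pop)
        ok_pop &= called[rows].mean(axis=0) >= min_presence_per_pop
    ok_glob = called.mean(axis=0) >= min_presence_global
    maf = G.maf()
    ok_maf = np.where(np.isnan(maf), False, maf >= maf_min)

    removed_by = {"heterozygosity": 0, "presence_per_pop": 0, "presence_global": 0, "maf": 0}
    keep = np.ones(G.n_sites, dtype=bool)
    for name, ok in (
        ("heterozygosity", ok_het),
        ("presence_per_pop", ok_pop),
        ("presence_global", ok_glob),
        ("maf", ok_maf),
    ):
        newly = keep & ~ok
        removed_by[name] = int(newly.sum())
        keep &= ok

    out = G.take_sites(np.flatnonzero(keep))
    if out.n_sites == 0:
        warnings.warn("all sites removed by filters", stacklevel=2)
    report = FilterReport(G.n_sites, out.n_sites, removed_by)
    return out, report


def select_one_snp_per_locus(G: GenotypeMatrix) -> GenotypeMatrix:
    """Keep, per RAD locus, the SNP with the highest MAF.

    Ties are broken deterministically toward the smallest position.
    """
    maf = np.nan_to_num(G.maf(), nan=-1.0)
    loci = G.site_meta["locus"].to_numpy()
    pos = G.site_meta["pos"].to_numpy()
    best: dict[str, int] = {}
    for j in range(G.n_sites):
        loc = loci[j]
        if loc not in best:
            best[loc] = j
            continue
        b = best[loc]
        if maf[j] > maf[b] or (maf[j] == maf[b] and pos[j] < pos[b]):
            best[loc] = j
    idx = np.sort(np.fromiter(best.values(), dtype=np.intp))
    return G.take_sites(idx)


def _vif(X: np.ndarray, j: int) -> float:
    """VIF of column j regressed on the other columns (mean-centred)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    vy = y @ y
    if vy <= 0:
        return 1.0
    coef, *_ = np.linalg.lstsq(others, y, rcond=None)
    resid = y - others @ coef
    r2 = 1.0 - (resid @ resid) / vy
    r2 = min(max(r2, 0.0), 1.0 - 1e-12)
    return 1.0 / (1.0 - r2)


def vif_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    vif_max: float = 2.0,
) -> GenotypeMatrix:
    """Sliding-window VIF prune of physically linked SNPs.

    Windows of ``window`` SNPs shifted by ``step`` SNPs; within each window
    the SNP with the largest VIF (> ``vif_max``) is removed and the window
    re-evaluated until stable.  Genotype vectors are mean-imputed before the
    regression.  A window larger than the site count degenerates to a single
    window.
    """
    if not window > step > 0:
        raise ValueError("require window > step > 0")

    X = G.genotypes.astype(float)
    X[G.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)

    keep = np.ones(G.n_sites, dtype=bool)
    start = 0
    while True:
        active = np.flatnonzero(keep)
        win = active[(active >= start) & (active < start + window)]
        while len(win) > 1:
            vifs = np.array([_vif(X[:, win], k) for k in range(len(win))])
            worst = int(np.argmax(vifs))
            if vifs[worst] <= vif_max:
                break
            keep[win[worst]] = False
            win = np.delete(win, worst)
        if start + window >= G.n_sites:
            break
        start += step
    return G.take_sites(np.flatnonzero(keep))
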