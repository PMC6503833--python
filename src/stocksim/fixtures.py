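"""Synthetic data generators with known ground truth.

These stand in for restricted empirical genotype data: Balding-Nichols
structured genotypes with known ancestry (admixture test bed), equilibrium
Wright-Fisher populations of known size (LD-Ne test bed), two-population
IM/SI coalescent datasets (ABC test bed), and the packaged empirical
13-statistic target vector.  Every generator is bit-reproducible given its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import CoalescentModelSpec, observed_summary
from .forward import unlinked_wf
from .genotypes import GenotypeMatrix
from .summaries import GROUPS, SummaryVector, load_reference_table

__all__ = [
    "BaldingNicholsTruth",
    "balding_nichols_genotypes",
    "wf_reference_population",
    "two_pop_im_dataset",
    "empirical_vector",
]


@dataclass
class BaldingNicholsTruth:
    Q: np.ndarray    # n x K true ancestry fractions
    F: np.ndarray    # K x L true cluster allele frequencies
    p_anc: np.ndarray


def _site_meta(L: int, chrom: list[str] | np.ndarray | None = None) -> pd.DataFrame:
    pos = np.arange(1, L + 1) * 100
    ch = chrom if chrom is not None else ["1"] * L
    return pd.DataFrame(
        dict(chrom=ch, pos=pos, locus=[f"loc{j}" for j in range(L)], ref="A", alt="T")
    )


def balding_nichols_genotypes(
    n_per_group: int | list[int] = 100,
    n_sites: int = 2000,
    F_k: float | list[float] = 0.2,
    K: int = 3,
    dirichlet_alpha: float | None = None,
    seed: int = 0,
    group_names: list[str] | None = None,
) -> tuple[GenotypeMatrix, BaldingNicholsTruth]:
    """Structured diploid genotypes under the Balding-Nichols drift model.

    Ancestral frequencies p ~ U(0.05, 0.95); cluster k frequencies
    f_kl ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k); genotypes
    g_il ~ Binomial(2, sum_k q_ik f_kl).  When ``dirichlet_alpha`` is None
    each individual is unadmixed (one-hot Q by group); otherwise
    Q ~ Dirichlet(alpha) with the group label set by the largest component.
    """
    rng = np.random.default_rng(seed)
    sizes = [n_per_group] * K if np.isscalar(n_per_group) else list(n_per_group)
    if len(sizes) != K:
        raise ValueError("need one group size per cluster")
    Fk = np.full(K, F_k) if np.isscalar(F_k) else np.asarray(F_k, float)
    if not np.all((Fk > 0) & (Fk < 1)):
        raise ValueError("F_k must lie in (0, 1)")
    n = int(sum(sizes))
    p = rng.uniform(0.05, 0.95, size=n_sites)
    F = np.empty((K, n_sites))
    for k in range(K):
        a = p * (1 - Fk[k]) / Fk[k]
        b = (1 - p) * (1 - Fk[k]) / Fk[k]
        F[k] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
    if dirichlet_alpha is None:
        Q = np.zeros((n, K))
        start = 0
        for k, sz in enumerate(sizes):
            Q[start:start + sz, k] = 1.0
            start += sz
        labels = np.repeat(np.arange(K), sizes)
    else:
        Q = rng.dirichlet(np.full(K, dirichlet_alpha), size=n)
        labels = Q.argmax(axis=1)
    geno = rng.binomial(2, Q @ F).astype(np.int16)
    names = group_names or [f"grp{k}" for k in range(K)]
    sample_ids = [f"ind{i}" for i in range(n)]
    pop_map = {s: names[labels[i]] for i, s in enumerate(sample_ids)}
    G = GenotypeMatrix(geno, _site_meta(n_sites), sample_ids, pop_map)
    return G, BaldingNicholsTruth(Q, F, p)


def wf_reference_population(
    N: int = 100,
    n_sample: int = 50,
    n_snps: int = 400,
    seed: int = 0,
    t_gens: int | None = None,
    theta_site: float = 0.02,
    oversample: int | None = None,
) -> GenotypeMatrix:
    """Sample from a Wright-Fisher population of known size N at ``n_snps``
    unlinked loci (each labelled with its own chromosome).

    Loci start at the mutation-drift stationary law for per-site
    theta = ``theta_site`` (segregating classes plus fixed boundary states)
    and the population evolves for ``t_gens`` (default 50) generations with
    matching recurrent mutation — long enough for the pedigree linkage
    disequilibrium the LD-Ne estimator reads out to equilibrate while the
    site-frequency spectrum stays at its neutral stationary shape (the
    small default theta keeps two-allele back-mutation bias negligible).
    Monomorphic loci are then discarded (enough extra loci are simulated to
    compensate) and ``n_sample`` individuals are drawn.
    """
    rng = np.random.default_rng(seed)
    if oversample is None:
        seg_frac = theta_site * np.sum(1.0 / np.arange(1, 2 * N))
        n_loci = int(np.ceil(n_snps * 1.6 / min(seg_frac, 1.0)))
    else:
        n_loci = n_snps * oversample
    if t_gens is None:
        t_gens = 50
    hapA, hapB = unlinked_wf(N, n_loci, t_gens, init_freq="stationary",
                             seed=int(rng.integers(2**31 - 1)),
                             mutation_rate=theta_site / (4 * N))
    freq = (hapA + hapB).mean(axis=0) / 2.0
    seg = np.flatnonzero((freq > 0) & (freq < 1))
    if len(seg) < n_snps:
        raise RuntimeError("too many loci fixed; increase oversample")
    keep = seg[:n_snps]
    take = rng.choice(N, size=min(n_sample, N), replace=False)
    geno = (hapA[np.ix_(take, keep)] + hapB[np.ix_(take, keep)]).astype(np.int16)
    meta = _site_meta(n_snps, chrom=[f"chr{j}" for j in range(n_snps)])
    ids = [f"ind{i}" for i in range(len(take))]
    return GenotypeMatrix(geno, meta, ids, {s: "popA" for s in ids})


def two_pop_im_dataset(
    M12: float = 1.0,
    M21: float = 1.0,
    T_split: float = 1.0,
    n1: int = 8,
    n2: int = 8,
    n_loci: int = 100,
    theta_ref: float = 1.0,
    model: str = "IM",
    seed: int = 0,
) -> tuple[np.ndarray, CoalescentModelSpec]:
    """Pseudo-observed two-population summary vector for ABC recovery tests.

    Returns the observed 12-statistic vector and the generating model spec.
    """
    spec = CoalescentModelSpec(
        model=model, n1=n1, n2=n2, n_loci=n_loci, theta_ref=theta_ref,
        M12=0.0 if model == "SI" else M12,
        M21=0.0 if model == "SI" else M21,
        T_split=T_split,
    )
    return observed_summary(spec, seed), spec


def empirical_vector() -> SummaryVector:
    """The packaged 13-value empirical target exactly as published."""
    row = load_reference_table().set_index("model").loc["empirical"]
    vals = row.drop("rmse").to_numpy(dtype=float)
    return SummaryVector.from_array(vals)
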