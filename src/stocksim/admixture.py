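"""Maximum-likelihood admixture estimation and ancestry classification.

The model: individual i carries ancestry fractions q_i (summing to 1 over K
clusters) and cluster k has allele frequency f_kl at site l.  Each of the
two allele copies at (i, l) is alternate with probability
a_il = sum_k q_ik f_kl, so the genotype g_il ~ Binomial(2, a_il) and the
log-likelihood is

    L = sum_{i,l} g_il log(a_il) + (2 - g_il) log(1 - a_il)

maximised by EM over (Q, F) at fixed K.  Missing genotypes are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from .genotypes import MISSING, GenotypeMatrix

_F_EPS = 1e-6  # clamp for cluster frequencies, avoids log(0)

ANCESTRY_CLASSES = ("F0_immigrant", "resident", "admixed_domestic", "wild_ancestry")


@dataclass
class AdmixtureFit:
    Q: np.ndarray          # n_individuals x K
    F: np.ndarray          # K x n_sites
    loglik: float
    K: int
    seed: int | None
    n_iter: int
    converged: bool
    loglik_path: np.ndarray  # per-iteration log-likelihood of the best start


class AdmixtureEM(BaseEstimator):
    """EM estimator of the binomial admixture likelihood at fixed K.

    Parameters
    ----------
    n_clusters:
        Number of ancestral clusters K.
    tol:
        Convergence threshold on the relative log-likelihood change.
    max_iter:
        EM iteration cap per start; non-convergence sets ``converged_`` to
        False with a warning rather than raising.
    n_starts:
        Independent random restarts; the best log-likelihood wins.
    random_state:
        Seed; results are deterministic given it.

    Attributes (after ``fit``)
    --------------------------
    Q_ : (n_individuals, K) ancestry fractions, rows sum to 1.
    F_ : (K, n_sites) cluster allele frequencies in [_F_EPS, 1-_F_EPS].
    loglik_ : best log-likelihood reached.
    n_iter_, converged_, loglik_path_.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        tol: float = 1e-6,
        max_iter: int = 2000,
        n_starts: int = 5,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.tol = tol
        self.max_iter = max_iter
        self.n_starts = n_starts
        self.random_state = random_state

    # -- internals --------------------------------------------------------
    @staticmethod
    def _prepare(G) -> tuple[np.ndarray, np.ndarray]:
        geno = G.genotypes if isinstance(G, GenotypeMatrix) else np.asarray(G)
        geno = geno.astype(np.float64)
        mask = geno != MISSING
        if not np.isin(geno[mask], (0, 1, 2)).all():
            raise ValueError("genotypes must be 0/1/2 with -1 for missing")
        geno[~mask] = 0.0
        return geno, mask.astype(np.float64)

    def _em(self, geno, mask, rng):
        # single-precision inner loop: the EM fixed point is insensitive to
        # the accumulation precision at these problem sizes, and the
        # log-likelihood is re-evaluated in float64 for the convergence test
        n, L = geno.shape
        K = self.n_clusters
        Q = rng.dirichlet(np.ones(K), size=n).astype(np.float32)
        p_hat = geno.sum(axis=0) / np.maximum(2.0 * mask.sum(axis=0), 1.0)
        F = np.clip(p_hat + rng.uniform(-0.1, 0.1, size=(K, L)),
                    _F_EPS, 1 - _F_EPS).astype(np.float32)
        g1 = (geno * mask).astype(np.float32)
        g0 = ((2.0 - geno) * mask).astype(np.float32)
        denom_q = (2.0 * mask.sum(axis=1, keepdims=True)).astype(np.float32)
        ll_prev = -np.inf
        path = []
        converged = False
        n_done = self.max_iter
        for it in range(1, self.max_iter + 1):
            A = Q @ F
            np.clip(A, _F_EPS, 1 - _F_EPS, out=A)
            # likelihood of the parameters entering this iteration, from the
            # same A the update uses (float64 accumulation)
            ll = float(np.sum(g1 * np.log(A), dtype=np.float64)
                       + np.sum(g0 * np.log1p(-A), dtype=np.float64))
            path.append(ll)
            if abs(ll - ll_prev) < self.tol * (1.0 + abs(ll)):
                converged = True
                n_done = it
                break
            ll_prev = ll
            T1 = g1 / A
            T0 = g0 / (1.0 - A)
            # T1 @ F.T + T0 @ (1-F).T == (T1 - T0) @ F.T + rowsum(T0)
            Q_new = Q * ((T1 - T0) @ F.T + T0.sum(axis=1, keepdims=True)) / denom_q
            num = F * (Q.T @ T1)
            den = num + (1.0 - F) * (Q.T @ T0)
            with np.errstate(invalid="ignore", divide="ignore"):
                F_new = np.where(den > 0, num / np.maximum(den, 1e-30), F)
            Q = Q_new / Q_new.sum(axis=1, keepdims=True)
            F = np.clip(F_new, _F_EPS, 1 - _F_EPS)
        ll = path[-1]
        return (Q.astype(np.float64), F.astype(np.float64), ll, n_done,
                converged, np.array(path))

    # -- sklearn API ------------------------------------------------------
    def fit(self, G, y=None) -> "AdmixtureEM":
        geno, mask = self._prepare(G)
        n = geno.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError("n_clusters must be in [1, n_individuals]")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_starts):
            res = self._em(geno, mask, rng)
            if best is None or res[2] > best[2]:
                best = res
        Q, F, ll, n_iter, converged, path = best
        if not converged:
            warnings.warn("admixture EM did not converge within max_iter", stacklevel=2)
        self.Q_, self.F_, self.loglik_ = Q, F, ll
        self.n_iter_, self.converged_, self.loglik_path_ = n_iter, converged, path
        return self

    def fit_transform(self, G, y=None) -> np.ndarray:
        return self.fit(G).Q_


def fit_admixture(
    G,
    K: int = 3,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_starts: int = 5,
) -> AdmixtureFit:
    """Functional wrapper over :class:`AdmixtureEM`."""
    est = AdmixtureEM(n_clusters=K, tol=tol, max_iter=max_iter,
                      n_starts=n_starts, random_state=seed).fit(G)
    return AdmixtureFit(est.Q_, est.F_, est.loglik_, K, seed,
                        est.n_iter_, est.converged_, est.loglik_path_)


def _group_mean_q(Q: np.ndarray, sample_ids, pop_map, groups) -> np.ndarray:
    M = np.empty((len(groups), Q.shape[1]))
    for gi, grp in enumerate(groups):
        rows = [i for i, s in enumerate(sample_ids) if pop_map[s] == grp]
        if not rows:
            raise ValueError(f"empty group {grp}")
        M[gi] = Q[rows].mean(axis=0)
    return M


def match_clusters(
    Q: np.ndarray,
    pop_map: dict[str, str],
    reference_groups: list[str],
    sample_ids: list[str],
) -> dict[int, str]:
    """Bijective cluster -> reference-group labelling.

    Chooses the assignment maximising the summed mean within-group
    membership (Hungarian algorithm).  A degenerate Q with identical
    columns yields an arbitrary but deterministic mapping with a warning.
    """
    K = Q.shape[1]
    if K != len(reference_groups):
        raise ValueError("need one reference group per cluster")
    M = _group_mean_q(Q, sample_ids, pop_map, reference_groups)
    if np.allclose(M - M.mean(axis=1, keepdims=True), 0.0, atol=1e-9):
        warnings.warn("degenerate Q: identical cluster columns", stacklevel=2)
    rows, cols = linear_sum_assignment(-M)  # rows: groups, cols: clusters
    return {int(c): reference_groups[r] for r, c in zip(rows, cols)}


def mean_group_q(
    Q: np.ndarray,
    pop_map: dict[str, str],
    mapping: dict[int, str],
    sample_ids: list[str],
    groups: list[str],
) -> pd.DataFrame:
    """Mean membership of each group's individuals in each labelled cluster.

    Rows are groups, columns are the cluster labels from ``mapping``;
    each row sums to 1.
    """
    M = _group_mean_q(Q, sample_ids, pop_map, groups)
    cols = [mapping[k] for k in range(Q.shape[1])]
    df = pd.DataFrame(M, index=groups, columns=cols)
    return df


@dataclass
class AncestryClassification:
    per_individual: pd.DataFrame  # index sample; columns class, q_stock, q_local
    fractions: pd.DataFrame       # per population: fraction in each class


def classify_ancestry(
    Q: np.ndarray,
    pop_map: dict[str, str],
    stocking_clusters: list[int],
    local_cluster: dict[str, int],
    sample_ids: list[str],
) -> AncestryClassification:
    """Threshold-based ancestry classes.

    Per individual with home population p and local cluster
    ``local_cluster[p]``:

    - ``F0_immigrant``  if any non-local cluster has q > 0.9 (checked first);
    - ``resident``      if the local cluster has q > 0.9;
    - ``admixed_domestic`` if total stocking-cluster ancestry q_stock > 0.10;
    - ``wild_ancestry`` if some foreign non-stocking cluster has q > 0.10;
    - otherwise ``resident`` (no class threshold crossed).
    """
    records = []
    for i, s in enumerate(sample_ids):
        pop = pop_map[s]
        loc = local_cluster[pop]
        q = Q[i]
        q_local = float(q[loc])
        q_stock = float(q[stocking_clusters].sum())
        foreign = [k for k in range(Q.shape[1]) if k != loc]
        foreign_wild = [k for k in foreign if k not in stocking_clusters]
        if any(q[k] > 0.9 for k in foreign):
            cls = "F0_immigrant"
        elif q_local > 0.9:
            cls = "resident"
        elif q_stock > 0.10:
            cls = "admixed_domestic"
        elif any(q[k] > 0.10 for k in foreign_wild):
            cls = "wild_ancestry"
        else:
            cls = "resident"
        records.append(dict(sample=s, pop=pop, cls=cls, q_stock=q_stock, q_local=q_local))
    per_ind = pd.DataFrame(records).set_index("sample")
    frac = (
        per_ind.groupby("pop")["cls"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(ANCESTRY_CLASSES), fill_value=0.0)
    )
    return AncestryClassification(per_ind, frac)


def masked_cv_loglik(
    G,
    K: int,
    seed: int = 0,
    holdout: float = 0.10,
    **em_kwargs,
) -> float:
    """Masked-genotype cross-validation score for choosing K.

    Holds out a fraction of called cells, fits on the rest and returns the
    mean held-out log-likelihood per cell (higher is better).
    """
    geno = G.genotypes if isinstance(G, GenotypeMatrix) else np.asarray(G)
    rng = np.random.default_rng(seed)
    called = np.argwhere(geno != MISSING)
    n_hold = max(1, int(holdout * len(called)))
    hold = called[rng.choice(len(called), size=n_hold, replace=False)]
    masked = geno.copy()
    masked[hold[:, 0], hold[:, 1]] = MISSING
    est = AdmixtureEM(n_clusters=K, random_state=int(rng.integers(2**31)), **em_kwargs).fit(masked)
    A = np.clip(est.Q_ @ est.F_, _F_EPS, 1 - _F_EPS)
    g = geno[hold[:, 0], hold[:, 1]].astype(float)
    a = A[hold[:, 0], hold[:, 1]]
    return float(np.mean(g * np.log(a) + (2 - g) * np.log1p(-a)))
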