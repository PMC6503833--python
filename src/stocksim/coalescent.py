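"""Structured-coalescent simulator for two-population IM and SI models.

Two demes of relative sizes N1 and N2 (in units of a reference size N_ref)
exchange lineages backward in time at per-lineage rates M12 (lineages in
deme 1 jump to deme 2, i.e. forward migration 1 <- 2) and M21, merge into an
ancestral deme of relative size N_anc at T_split, and mutations fall on
branches at rate theta_ref = 4 N_ref mu l per locus.  Time is measured in
units of 4 N_ref generations, so a pair of lineages in a deme of relative
size n coalesces at rate 2/n and migration rates are the scaled
M = 4 N_ref m.  The strict-isolation (SI) model is the M12 = M21 = 0 case.

Per locus the simulator returns the mscalc-style statistic set: within-
population diversities pi1 and pi2, the number of segregating sites S, the
Hudson-type F_ST = 1 - mean-within/D_xy, the between-population diversity
D_xy, the net divergence D_a (all pi/D quantities on the per-locus theta
scale), and the Wakeley-Hey site classes — exclusive polymorphisms sxA and
sxB, shared polymorphisms ss and fixed differences sf — which carry the
directional information needed to resolve asymmetric migration.  Loci are
independent (no intralocus recombination, free recombination between loci).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

STAT_NAMES = ("pi1", "pi2", "S", "fst", "dxy", "da", "sxA", "sxB", "ss", "sf")

DEFAULT_PRIORS: dict[str, tuple] = {
    "M12": ("loguniform", 0.01, 100.0),
    "M21": ("loguniform", 0.01, 100.0),
    "N1": ("uniform", 0.05, 5.0),
    "N2": ("uniform", 0.05, 5.0),
    "N_anc": ("uniform", 0.05, 5.0),
    "T_split": ("uniform", 0.0, 5.0),
}


@dataclass(frozen=True)
class CoalescentModelSpec:
    """Two-population divergence model ("IM" with asymmetric migration, or
    "SI" with none) plus the sampling configuration and priors."""

    model: str = "IM"
    n1: int = 8
    n2: int = 8
    n_loci: int = 100
    theta_ref: float = 1.0        # 4 N_ref mu * locus_length, per locus
    N1: float = 1.0               # relative to N_ref
    N2: float = 1.0
    N_anc: float = 1.0
    M12: float = 0.0              # scaled migration into deme 1 from deme 2
    M21: float = 0.0
    T_split: float = 1.0          # units of 4 N_ref generations
    priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def __post_init__(self) -> None:
        if self.model not in ("IM", "SI"):
            raise ValueError("model must be IM or SI")
        for v in (self.N1, self.N2, self.N_anc, self.M12, self.M21,
                  self.T_split, self.theta_ref):
            if v < 0:
                raise ValueError("model parameters must be >= 0")
        if self.model == "SI" and (self.M12 != 0 or self.M21 != 0):
            raise ValueError("SI model forces M12 = M21 = 0")

    @property
    def free_parameters(self) -> list[str]:
        base = ["N1", "N2", "N_anc", "T_split"]
        return (["M12", "M21"] + base) if self.model == "IM" else base


@njit(cache=False)
def _one_genealogy(n1, n2, rn1, rn2, rnanc, Ml1, Ml2, T, theta, out):
    """Simulate one genealogy and accumulate the per-locus statistics into
    ``out``: (pi1, pi2, S, fst, dxy, da, sxA, sxB, ss, sf); fst is left NaN
    when dxy = 0.  sxA/sxB are Wakeley-Hey exclusive polymorphism counts,
    ss shared polymorphisms and sf fixed differences."""
    n = n1 + n2
    deme = np.empty(n, np.int64)
    c1 = np.empty(n, np.int64)
    c2 = np.empty(n, np.int64)
    birth = np.zeros(n, np.float64)
    for i in range(n1):
        deme[i] = 0
        c1[i] = 1
        c2[i] = 0
    for i in range(n1, n):
        deme[i] = 1
        c1[i] = 0
        c2[i] = 1
    k = n
    t = 0.0
    merged = False
    pi1 = 0.0
    pi2 = 0.0
    dxy = 0.0
    S = 0.0
    sxA = 0.0
    sxB = 0.0
    ssh = 0.0
    sfx = 0.0
    while k > 1:
        if not merged:
            k1 = 0
            for i in range(k):
                if deme[i] == 0:
                    k1 += 1
            k2 = k - k1
            rc1 = k1 * (k1 - 1) / rn1
            rc2 = k2 * (k2 - 1) / rn2
            rm1 = k1 * Ml1
            rm2 = k2 * Ml2
            tot = rc1 + rc2 + rm1 + rm2
            if tot <= 0.0:
                t = T
                merged = True
                continue
            dt = np.random.exponential(1.0 / tot)
            if t + dt >= T:
                t = T
                merged = True
                continue
            t += dt
            u = np.random.random() * tot
            if u < rc1 + rc2:
                d = 0 if u < rc1 else 1
                # choose two distinct lineages in deme d
                kd = k1 if d == 0 else k2
                a = np.random.randint(kd)
                b = np.random.randint(kd - 1)
                if b >= a:
                    b += 1
                ia = -1
                ib = -1
                cnt = 0
                for i in range(k):
                    if deme[i] == d:
                        if cnt == a:
                            ia = i
                        if cnt == b:
                            ib = i
                        cnt += 1
            else:
                d = 0 if u < rc1 + rc2 + rm1 else 1
                kd = k1 if d == 0 else k2
                a = np.random.randint(kd)
                cnt = 0
                for i in range(k):
                    if deme[i] == d:
                        if cnt == a:
                            deme[i] = 1 - d
                            break
                        cnt += 1
                continue
        else:
            rc = k * (k - 1) / rnanc
            dt = np.random.exponential(1.0 / rc)
            t += dt
            ia = np.random.randint(k)
            ib = np.random.randint(k - 1)
            if ib >= ia:
                ib += 1
        # coalesce lineages ia and ib at time t
        for idx in (ia, ib):
            ln = t - birth[idx]
            km = np.random.poisson(theta * ln) if ln > 0 else 0
            if km > 0:
                a1 = c1[idx]
                a2 = c2[idx]
                if n1 > 1:
                    pi1 += km * 2.0 * a1 * (n1 - a1) / (n1 * (n1 - 1.0))
                if n2 > 1:
                    pi2 += km * 2.0 * a2 * (n2 - a2) / (n2 * (n2 - 1.0))
                dxy += km * (a1 * (n2 - a2) + a2 * (n1 - a1)) / (n1 * 1.0 * n2)
                S += km
                polyA = 0 < a1 < n1
                polyB = 0 < a2 < n2
                if polyA and polyB:
                    ssh += km
                elif polyA:
                    sxA += km
                elif polyB:
                    sxB += km
                elif (a1 == n1 and a2 == 0) or (a1 == 0 and a2 == n2):
                    sfx += km
        # parent lineage replaces child ia (same deme); swap-remove child ib
        c1[ia] += c1[ib]
        c2[ia] += c2[ib]
        birth[ia] = t
        k -= 1
        deme[ib] = deme[k]
        c1[ib] = c1[k]
        c2[ib] = c2[k]
        birth[ib] = birth[k]
    out[0] = pi1
    out[1] = pi2
    out[2] = S
    out[4] = dxy
    out[5] = dxy - 0.5 * (pi1 + pi2)
    out[3] = 1.0 - 0.5 * (pi1 + pi2) / dxy if dxy > 0 else np.nan
    out[6] = sxA
    out[7] = sxB
    out[8] = ssh
    out[9] = sfx


@njit(cache=False)
def _simulate_loci(n1, n2, n_loci, rn1, rn2, rnanc, Ml1, Ml2, T, theta, seed):
    np.random.seed(seed)
    out = np.empty((n_loci, 10))
    for j in range(n_loci):
        _one_genealogy(n1, n2, rn1, rn2, rnanc, Ml1, Ml2, T, theta, out[j])
    return out


@njit(cache=False)
def _simulate_table(n1, n2, n_loci, params, theta, seed):
    """params columns: N1, N2, N_anc, M12, M21, T_split.  Returns the
    (n_draws, 20) matrix of across-locus means and SDs of the ten
    statistics."""
    np.random.seed(seed)
    n_draws = params.shape[0]
    nstat = 10
    stats = np.empty((n_draws, 2 * nstat))
    row = np.empty(nstat)
    for i in range(n_draws):
        rn1, rn2, rnanc, m12, m21, T = params[i]
        s = np.zeros(nstat)
        ss = np.zeros(nstat)
        cnt = np.zeros(nstat)
        for j in range(n_loci):
            _one_genealogy(n1, n2, rn1, rn2, rnanc, m12, m21, T, theta, row)
            for q in range(nstat):
                if not np.isnan(row[q]):
                    s[q] += row[q]
                    ss[q] += row[q] * row[q]
                    cnt[q] += 1.0
        for q in range(nstat):
            if cnt[q] > 0:
                m = s[q] / cnt[q]
                stats[i, q] = m
                v = ss[q] / cnt[q] - m * m
                stats[i, nstat + q] = np.sqrt(v) if v > 0 else 0.0
            else:
                stats[i, q] = np.nan
                stats[i, nstat + q] = np.nan
    return stats


def simulate_locus(spec: CoalescentModelSpec, seed: int) -> dict[str, float]:
    """One locus under the structured coalescent; returns the per-locus
    statistic row (pi1, pi2, S, fst, dxy, da)."""
    arr = _simulate_loci(
        spec.n1, spec.n2, 1, spec.N1, spec.N2, spec.N_anc,
        spec.M12, spec.M21, spec.T_split, spec.theta_ref, _nseed(seed),
    )[0]
    return dict(zip(STAT_NAMES, (float(x) for x in arr)))


def simulate_loci(spec: CoalescentModelSpec, seed: int) -> pd.DataFrame:
    """``spec.n_loci`` independent loci as a statistic DataFrame."""
    arr = _simulate_loci(
        spec.n1, spec.n2, spec.n_loci, spec.N1, spec.N2, spec.N_anc,
        spec.M12, spec.M21, spec.T_split, spec.theta_ref, _nseed(seed),
    )
    return pd.DataFrame(arr, columns=list(STAT_NAMES))


STAT_COLUMNS = [f"{s}_mean" for s in STAT_NAMES] + [f"{s}_sd" for s in STAT_NAMES]


def observed_summary(spec: CoalescentModelSpec, seed: int) -> np.ndarray:
    """Across-locus means and SDs of the six statistics for one dataset
    simulated at the spec's fixed parameters (a pseudo-observed vector)."""
    df = simulate_loci(spec, seed)
    means = df.mean(skipna=True).to_numpy()
    sds = df.std(ddof=0, skipna=True).to_numpy()
    return np.concatenate([means, sds])


def sample_prior(spec: CoalescentModelSpec, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name in ("N1", "N2", "N_anc", "M12", "M21", "T_split"):
        if spec.model == "SI" and name in ("M12", "M21"):
            cols[name] = np.zeros(n)
            continue
        if name in spec.priors:
            kind, lo, hi = spec.priors[name]
            if kind == "uniform":
                cols[name] = rng.uniform(lo, hi, size=n)
            elif kind == "loguniform":
                cols[name] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
            else:
                raise ValueError(f"unknown prior kind {kind}")
        else:
            cols[name] = np.full(n, getattr(spec, name))
    return pd.DataFrame(cols)


def simulate_table(
    spec: CoalescentModelSpec, n_sims: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ``n_sims`` parameter vectors from the priors and simulate their
    summary statistics.  Returns (params, stats) DataFrames."""
    rng = np.random.default_rng(seed)
    params = sample_prior(spec, n_sims, rng)
    arr = _simulate_table(
        spec.n1, spec.n2, spec.n_loci,
        params[["N1", "N2", "N_anc", "M12", "M21", "T_split"]].to_numpy(),
        spec.theta_ref, _nseed(int(rng.integers(2**31 - 1))),
    )
    return params, pd.DataFrame(arr, columns=STAT_COLUMNS)


def _nseed(seed: int) -> int:
    return int(seed) % (2**31 - 1)
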