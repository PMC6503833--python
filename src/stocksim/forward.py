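"""Forward-time Wright-Fisher simulator of a three-deme stocking scenario.

A single neutral chromosome evolves under discrete non-overlapping
generations.  An ancestral population at mutation-drift equilibrium splits
into three demes — the recipient river population (SLR), an adjacent lake
(LDM) and the stocking source (SRC).  SLR and LDM exchange migrants at
constant asymmetric rates; for the final ``t_stock`` generations stocking is
modelled as migration from SRC into both recipients, with migration into LDM
a fixed multiple of that into SLR.  A mortality filter can remove a fixed
number of SRC individuals from the breeding pool each stocking-era
generation (few effective breeders).  Migration is backward: each offspring
draws its parental deme from the migration fractions, then two parents
uniformly from that deme.  Crossovers and new mutations are Poisson along
the chromosome (infinite sites).

Demographic rescaling by a factor lambda (sizes and times shrunk, rates
inflated) preserves theta = 4*N*mu, rho = 4*N*r, N*m and t/N so that
desk-scale runs reproduce full-scale summary statistics; an msprime
coalescent draw can replace the long forward burn-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import msprime
import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

DEMES = ("SLR", "LDM", "SRC")

__all__ = [
    "DemographicScenario",
    "SimulatedCohort",
    "rescale_scenario",
    "coalescent_burnin",
    "run_forward",
    "unlinked_wf",
]


@dataclass(frozen=True)
class DemographicScenario:
    """Full parameterisation of the three-deme stocking simulation.

    Baseline values correspond to the full-scale study conditions: a
    10,000 kb chromosome with mu = r = 1e-8, an ancestral population of
    2,400 diploids at equilibrium after 80,000 generations, three descendant
    demes of 800 diploids diverging for 2,685 generations, stocking-era
    migration over the final 15 generations, and empirical sample sizes of
    224 (SLR), 56 (LDM) and 100 (SRC).
    """

    L: float = 1e7                 # chromosome length, bp
    mu: float = 1e-8               # mutation rate /bp/generation
    rec: float = 1e-8              # recombination rate /bp/generation
    N_anc: int = 2400              # ancestral diploid size
    N_desc: int = 800              # descendant diploid size per deme
    t_burnin: int = 80_000
    t_div: int = 2685              # total divergence generations (incl. stocking era)
    t_stock: int = 15              # final generations with stocking migration
    m_slr_ldm: float = 0.0005      # forward fraction SLR -> LDM
    m_ldm_slr: float = 0.00025     # forward fraction LDM -> SLR
    m_src_slr: float = 0.00375     # stocking migration SRC -> SLR (grid 1e-6..0.1)
    m_src_ldm_factor: float = 1.5  # SRC -> LDM is this multiple of SRC -> SLR
    D_mort: int = 0                # SRC individuals removed from breeding per stocking gen
    sample_sizes: tuple[int, int, int] = (224, 56, 100)  # SLR, LDM, SRC
    rescale_lambda: float = 1.0
    purge_interval: int = 50

    def __post_init__(self) -> None:
        for r in (self.mu, self.rec, self.m_slr_ldm, self.m_ldm_slr, self.m_src_slr):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.t_stock > self.t_div:
            raise ValueError("t_stock must not exceed t_div")
        m_src_ldm = self.m_src_slr * self.m_src_ldm_factor
        into_slr = self.m_ldm_slr + self.m_src_slr
        into_ldm = self.m_slr_ldm + m_src_ldm
        if into_slr >= 1 or into_ldm >= 1:
            raise ValueError("migration fractions into a deme must sum to < 1")
        if self.D_mort >= self.N_desc:
            raise ValueError("D_mort must be below the deme size")

    @property
    def m_src_ldm(self) -> float:
        return self.m_src_slr * self.m_src_ldm_factor


@dataclass
class SimulatedCohort:
    matrix: GenotypeMatrix
    scenario: DemographicScenario
    seed: int
    replicate: int = 0


def rescale_scenario(s: DemographicScenario, lam: float, m_cap: float = 0.45) -> DemographicScenario:
    """Shrink a scenario by lambda >= 1 preserving theta, rho, Nm and t/N."""
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    n_anc = int(round(s.N_anc / lam))
    n_desc = int(round(s.N_desc / lam))
    if min(n_anc, n_desc) < 50:
        raise ValueError("rescaled population sizes must stay >= 50")
    return replace(
        s,
        N_anc=n_anc,
        N_desc=n_desc,
        t_burnin=max(1, int(round(s.t_burnin / lam))),
        t_div=max(1, int(round(s.t_div / lam))),
        t_stock=max(1, int(round(s.t_stock / lam))),
        mu=s.mu * lam,
        rec=s.rec * lam,
        m_slr_ldm=min(s.m_slr_ldm * lam, m_cap),
        m_ldm_slr=min(s.m_ldm_slr * lam, m_cap),
        m_src_slr=min(s.m_src_slr * lam, m_cap),
        D_mort=int(round(s.D_mort / lam)),
        rescale_lambda=s.rescale_lambda * lam,
    )


# ---------------------------------------------------------------------------
# population state: haplotypes (2*N_total, S) of 0/1 plus sorted positions
# ---------------------------------------------------------------------------

def coalescent_burnin(s: DemographicScenario, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium standing variation for the ancestral population.

    Draws 2*N_anc chromosomes from a neutral coalescent with
    theta = 4*N_anc*mu*L and rho = 4*N_anc*rec*L (fast path replacing the
    forward burn-in).  Returns (haplotypes, positions).
    """
    if s.mu == 0:
        return np.zeros((2 * s.N_anc, 0), dtype=np.uint8), np.empty(0)
    ts = msprime.sim_ancestry(
        samples=s.N_anc,
        ploidy=2,
        population_size=s.N_anc,
        sequence_length=s.L,
        recombination_rate=s.rec,
        random_seed=(seed % (2**31 - 2)) + 1,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=s.mu,
        random_seed=(seed % (2**31 - 2)) + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
    )
    H = ts.genotype_matrix().T.astype(np.uint8)
    H = np.minimum(H, 1)
    pos = ts.tables.sites.position.copy()
    return H, pos


def _reproduce(
    H: np.ndarray,
    positions: np.ndarray,
    parent_ind: np.ndarray,
    xover_rate: float,
    mut_rate: float,
    L: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One generation of gametogenesis for a fixed parent assignment.

    ``parent_ind`` holds, per gamete, the index of the contributing diploid
    parent.  Returns the offspring haplotypes and the (merged, sorted)
    position vector including this generation's new mutations.
    """
    G = len(parent_ind)
    S = H.shape[1]
    start = rng.integers(0, 2, size=G)
    ncross = rng.poisson(xover_rate, size=G) if S > 0 else np.zeros(G, dtype=np.int64)
    # each gamete starts as a full copy of one parental haplotype; crossover
    # segments (few per gamete) are patched in from the homologue
    child = H[2 * parent_ind + start]
    for g in np.flatnonzero(ncross):
        bp = np.sort(rng.uniform(0.0, L, size=ncross[g]))
        sidx = np.searchsorted(positions, bp)
        hapA = H[2 * parent_ind[g] + start[g]]
        hapB = H[2 * parent_ind[g] + 1 - start[g]]
        for j in range(len(sidx)):
            lo = sidx[j]
            hi = sidx[j + 1] if j + 1 < len(sidx) else S
            if lo < hi:
                child[g, lo:hi] = (hapB if j % 2 == 0 else hapA)[lo:hi]

    # new mutations (infinite sites; collisions with existing sites redrawn)
    nmut = rng.poisson(mut_rate, size=G)
    tot_m = int(nmut.sum())
    if tot_m:
        mpos = rng.uniform(0.0, L, size=tot_m)
        while np.isin(mpos, positions).any() or len(np.unique(mpos)) < tot_m:
            bad = np.isin(mpos, positions)
            dup = np.ones_like(bad)
            _, first = np.unique(mpos, return_index=True)
            dup[first] = False
            redo = bad | dup
            mpos[redo] = rng.uniform(0.0, L, size=int(redo.sum()))
        gid_m = np.repeat(np.arange(G), nmut)
        block = np.zeros((G, tot_m), dtype=np.uint8)
        block[gid_m, np.arange(tot_m)] = 1
        positions = np.concatenate([positions, mpos])
        order = np.argsort(positions, kind="stable")
        child = np.concatenate([child, block], axis=1)[:, order]
        positions = positions[order]
    return child, positions


def _purge(H: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = H.sum(axis=0)
    keep = (counts > 0) & (counts < H.shape[0])
    return np.ascontiguousarray(H[:, keep]), positions[keep]


def run_forward(
    s: DemographicScenario,
    seed: int,
    burnin: str = "coalescent",
    replicate: int = 0,
) -> SimulatedCohort:
    """Run the three-deme stocking scenario and sample a cohort.

    ``burnin`` is "coalescent" (equilibrium draw, default) or "forward"
    (explicit ``t_burnin`` Wright-Fisher generations from a monomorphic
    start).  Output is bit-reproducible given (scenario, seed).
    """
    if burnin not in ("coalescent", "forward"):
        raise ValueError("burnin must be coalescent|forward")
    rng = np.random.default_rng(seed)
    xover = s.rec * s.L
    mut = s.mu * s.L

    if burnin == "coalescent":
        H, pos = coalescent_burnin(s, int(rng.integers(2**31 - 1)))
    else:
        H = np.zeros((2 * s.N_anc, 0), dtype=np.uint8)
        pos = np.empty(0)
        for gen in range(s.t_burnin):
            parents = rng.integers(0, s.N_anc, size=(s.N_anc, 2)).reshape(-1)
            H, pos = _reproduce(H, pos, parents, xover, mut, s.L, rng)
            if (gen + 1) % s.purge_interval == 0:
                H, pos = _purge(H, pos)
    H, pos = _purge(H, pos)

    # split: three descendant demes founded from the ancestral pool
    n = s.N_desc
    sizes = (n, n, n)
    founders = rng.choice(s.N_anc, size=(3 * n, 2), replace=True)
    H, pos = _reproduce(H, pos, founders.reshape(-1), xover, mut, s.L, rng)

    deme_slices = [slice(0, n), slice(n, 2 * n), slice(2 * n, 3 * n)]
    mig_div = np.zeros((3, 3))
    mig_div[1, 0] = s.m_slr_ldm   # offspring in LDM draws SLR parents
    mig_div[0, 1] = s.m_ldm_slr
    mig_stock = mig_div.copy()
    mig_stock[0, 2] = s.m_src_slr
    mig_stock[1, 2] = s.m_src_ldm

    def step(mig: np.ndarray, src_pool: np.ndarray, gen: int) -> None:
        nonlocal H, pos
        # per offspring: parental deme from the backward migration fractions,
        # then two parents drawn uniformly (and independently) from that deme
        parent_ind = np.empty((3 * n, 2), dtype=np.int64)
        offset = 0
        for d in range(3):
            probs = mig[d].copy()
            probs[d] = 1.0 - probs.sum() + probs[d]
            src_deme = rng.choice(3, size=n, p=probs)
            for sd in range(3):
                rows = np.flatnonzero(src_deme == sd)
                if not len(rows):
                    continue
                pool = src_pool if sd == 2 else np.arange(deme_slices[sd].start,
                                                          deme_slices[sd].stop)
                parent_ind[offset + rows] = rng.choice(pool, size=(len(rows), 2))
            offset += n
        H, pos = _reproduce(H, pos, parent_ind.reshape(-1), xover, mut, s.L, rng)
        if (gen + 1) % s.purge_interval == 0:
            H, pos = _purge(H, pos)

    full_src_pool = np.arange(deme_slices[2].start, deme_slices[2].stop)
    t_pre = s.t_div - s.t_stock
    for gen in range(t_pre):
        step(mig_div, full_src_pool, gen)
    d_mort = min(s.D_mort, n - 2)
    for gen in range(t_pre, s.t_div):
        if d_mort > 0:
            survivors = rng.choice(n, size=n - d_mort, replace=False)
            pool = full_src_pool[np.sort(survivors)]
        else:
            pool = full_src_pool
        step(mig_stock, pool, gen)
    H, pos = _purge(H, pos)

    # sample individuals (capped at deme size), export as GenotypeMatrix
    take: list[int] = []
    codes: list[str] = []
    for d, (name, want) in enumerate(zip(DEMES, s.sample_sizes)):
        k = min(want, n)
        if k < want:
            warnings.warn(
                f"sample size {want} for {name} capped at deme size {n}", stacklevel=2
            )
        sel = np.sort(rng.choice(n, size=k, replace=False)) + deme_slices[d].start
        take.extend(sel.tolist())
        codes.extend([name] * k)
    take_arr = np.asarray(take)
    geno = (H[2 * take_arr] + H[2 * take_arr + 1]).astype(np.int16)
    seg = (geno.sum(axis=0) > 0) & (geno.sum(axis=0) < 2 * len(take_arr))
    geno = geno[:, seg]
    pos_seg = pos[seg]
    ipos = _strictly_increasing(np.floor(pos_seg).astype(np.int64) + 1)
    sample_ids = [f"{c}_{i}" for i, c in enumerate(codes)]
    meta = pd.DataFrame(
        dict(chrom="1", pos=ipos, locus=[f"1_{p}" for p in ipos], ref="A", alt="T")
    )
    gm = GenotypeMatrix(geno, meta, sample_ids, dict(zip(sample_ids, codes)))
    return SimulatedCohort(gm, s, seed, replicate)


def _strictly_increasing(pos: np.ndarray) -> np.ndarray:
    out = pos.copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + 1
    return out


def unlinked_wf(
    N: int,
    n_loci: int,
    t_gens: int,
    init_freq: np.ndarray | str = "sfs",
    seed: int | None = None,
    return_freq_path: bool = False,
    mutation_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wright-Fisher population of N diploids at ``n_loci`` unlinked loci.

    Loci assort independently (free recombination), so drift generates the
    pedigree linkage disequilibrium that the LD-Ne estimator measures.
    ``init_freq`` is "sfs" (neutral 1/i frequency spectrum), "uniform"
    (U(0.05, 0.95)) or an explicit array.  ``mutation_rate`` is a symmetric
    per-allele-copy flip probability per generation; a nonzero value keeps
    the population at mutation-drift equilibrium over long runs.  Returns
    the two haplotype arrays (N, n_loci); with ``return_freq_path`` also the
    per-generation mean allele-frequency trajectory (t_gens+1, n_loci).
    """
    rng = np.random.default_rng(seed)
    if isinstance(init_freq, str) and init_freq in ("sfs", "stationary"):
        # exact allele counts i placed on uniformly random haploid slots
        # (binomial placement would smear the rare-allele classes).
        # "sfs": every locus segregating, counts ~ 1/i.
        # "stationary": the full mutation-drift stationary law for symmetric
        # two-allele mutation at theta = 4*N*mutation_rate — interior mass
        # ~ (theta/2)(1/i + 1/(2N-i)), remainder split between the fixed
        # boundary states, so the process is stationary under the dynamics.
        i = np.arange(1, 2 * N)
        if init_freq == "sfs":
            w = 1.0 / i
            counts = rng.choice(i, size=n_loci, p=w / w.sum())
        else:
            theta = 4.0 * N * mutation_rate
            if theta <= 0:
                raise ValueError("'stationary' init needs mutation_rate > 0")
            w_int = 0.5 * theta * (1.0 / i + 1.0 / (2 * N - i))
            interior = w_int.sum()
            if interior >= 1.0:
                w_int = w_int / interior
                boundary = 0.0
            else:
                boundary = (1.0 - interior) / 2.0
            states = np.arange(0, 2 * N + 1)
            probs = np.concatenate([[boundary], w_int, [boundary]])
            counts = rng.choice(states, size=n_loci, p=probs / probs.sum())
        ranks = rng.random((2 * N, n_loci)).argsort(axis=0)
        hap = (ranks < counts).astype(np.uint8)
        hapA, hapB = hap[:N], hap[N:]
    else:
        if isinstance(init_freq, str):
            if init_freq != "uniform":
                raise ValueError("init_freq must be 'sfs', 'uniform' or an array")
            p0 = rng.uniform(0.05, 0.95, size=n_loci)
        else:
            p0 = np.asarray(init_freq, dtype=float)
            if p0.shape != (n_loci,):
                raise ValueError("init_freq array must have length n_loci")
        hapA = (rng.random((N, n_loci)) < p0).astype(np.uint8)
        hapB = (rng.random((N, n_loci)) < p0).astype(np.uint8)
    path = [np.concatenate([hapA, hapB]).mean(axis=0)]
    for _ in range(t_gens):
        mothers = rng.integers(0, N, size=N)
        fathers = rng.integers(0, N, size=N)
        pickA = rng.integers(0, 2, size=(N, n_loci)).astype(bool)
        pickB = rng.integers(0, 2, size=(N, n_loci)).astype(bool)
        newA = np.where(pickA, hapA[mothers], hapB[mothers])
        newB = np.where(pickB, hapA[fathers], hapB[fathers])
        if mutation_rate > 0:
            newA ^= (rng.random((N, n_loci)) < mutation_rate).astype(np.uint8)
            newB ^= (rng.random((N, n_loci)) < mutation_rate).astype(np.uint8)
        hapA, hapB = newA, newB
        if return_freq_path:
            path.append(np.concatenate([hapA, hapB]).mean(axis=0))
    if return_freq_path:
        return hapA, hapB, np.asarray(path)
    return hapA, hapB
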