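# stocksim

Population-genomic simulation and inference of hatchery-stocking impacts on
wild fish populations.

Decades of supplementation stocking leave genetic footprints — admixture
between hatchery strains and wild populations, introgression of foreign
alleles, shifts in diversity and effective population size.  `stocksim`
bundles the computational tools needed to quantify those footprints from
biallelic SNP data and to interpret them against explicit demographic
models, in the setting of a large river system (a mainstem population SLR,
an adjacent lake LDM, and a hatchery source group SRC):

- **Forward Wright–Fisher stocking simulator** — a neutral 10-Mb chromosome
  evolving through an ancestral equilibrium population, a three-deme split,
  asymmetric river–lake migration, and a recent stocking era in which the
  source deme sends migrants into both recipients (optionally with a
  mortality filter limiting its effective breeders).  Scenarios are ranked
  against an empirical 13-statistic vector (nine mean admixture q-values,
  three pairwise Weir–Cockerham F_ST values, and the count of SNPs at pooled
  MAF ≥ 1%) by RMSE.
- **Admixture estimation** — EM maximisation of the binomial admixture
  likelihood `L = Σ g log(Qf) + (2−g) log(1−Qf)` at fixed K, with Hungarian
  cluster↔group matching and threshold-based ancestry classes (resident
  q > 0.9; admixed if stocking ancestry > 0.10; F0 immigrant if a foreign
  cluster > 0.9).
- **Diversity & differentiation** — H_o, H_s, π, private polymorphisms,
  Weir–Cockerham θ, D_xy, D_a, Mantel isolation-by-distance on F/(1−F).
- **LD-based Ne** — Burrows composite r² with the random-mating bias
  correction r²′ = r̄² − 1/S − 3.19/S² and
  N̂e = (1/3 + √(1/9 − 2.76 r²′))/(2 r²′), same-chromosome pair exclusion and
  delete-one jackknife intervals.
- **Coalescent ABC** — a numba structured-coalescent simulator for
  two-population isolation-with-migration (asymmetric M = 4N_ref·m) and
  strict-isolation models with mscalc-style per-locus statistics, plus
  rejection ABC with optional local-linear regression adjustment.
- **Synthetic truth generators** — Balding–Nichols genotypes with known Q,
  equilibrium Wright–Fisher populations of known N, and pseudo-observed
  IM/SI datasets, so the whole pipeline is testable without any download.

Inference components follow scikit-learn conventions (`AdmixtureEM`,
`LDNeEstimator`, `RejectionABC` with `fit` and fitted `*_` attributes);
module-level functions wrap them.

## Worked example

Simulate a desk-scale stocking scenario (rescaled by λ = 10 with a
coalescent burn-in), compute its summary vector, and compare it with the
packaged empirical target:

```python
import stocksim as st

base = st.DemographicScenario(N_anc=1800, N_desc=600,   # the N=600 setting
                              m_src_slr=0.00375, D_mort=50)
scen = st.rescale_scenario(base, 10)
cohort = st.run_forward(scen, seed=42)
vec = st.compute_summary_vector(cohort, seed=0)
emp = st.empirical_vector()
print(vec.polym, emp.polym, round(st.rmse(vec, emp), 2))
```

```
3504 3619 31.9
```

The simulated cohort segregates 3,504 SNPs at pooled MAF ≥ 1% against the
empirical 3,619; because the RMSE uses the raw SNP count, the count distance
(115) dominates the score (31.9 ≈ 115/√13) — the admixture and F_ST terms
move it only in the second decimal.  Ranking scenarios that share θ
therefore uses common random numbers across scenarios (see
`docs/methods.md`).

Estimate migration asymmetry between two river reaches by ABC:

```python
from stocksim import CoalescentModelSpec, simulate_table, abc_reject

spec = CoalescentModelSpec(model="IM", n1=8, n2=8, n_loci=200)
params, stats = simulate_table(spec, 100_000, seed=1)
obs, _ = st.two_pop_im_dataset(M12=40.0, M21=0.067, T_split=1.0,
                               n_loci=200, seed=7)
post = abc_reject(obs, params, stats.to_numpy(),
                  tolerance=0.005, adjust="loclinear")
print(post.summary().loc[["M12", "M21"]].round(3))
```

```
     median  ci_low  ci_high
M12  14.340   0.058  303.985
M21   1.539   0.018   42.731
```

The posterior recovers the strong downstream-biased asymmetry (truth 40
versus 0.067): the downstream-receiving rate's median sits an order of
magnitude above the upstream one and both truths fall inside the 95%
credible intervals.

A thin CLI mirrors the library: `stocksim filter`, `stats`, `admix`, `ne`,
`simulate`, `fixtures` (see `stocksim --help`).

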