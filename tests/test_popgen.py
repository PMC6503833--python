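import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from stocksim import (
    ancestry_het_correlation,
    balding_nichols_genotypes,
    count_private,
    diversity,
    dxy_da,
    fst_wc,
    linearize_fst,
    mantel_ibd,
)

from conftest import make_matrix


class TestDiversity:
    def test_fixed_population_is_all_zero(self):
        G = make_matrix(np.full((6, 20), 2), ["P"] * 6)
        rep = diversity(G).per_population.loc["P"]
        assert rep.Ho == 0 and rep.P == 0 and rep.pi == 0

    def test_pair_of_sequences_pi(self):
        # two individuals treated as two haploid-equivalent sequences:
        # hom-ref vs hom-alt at 2 of 1000 sites -> pi = 2/1000 per site
        geno = np.zeros((2, 1000), dtype=int)
        geno[1, :2] = 2
        G = make_matrix(geno, ["P", "P"])
        rep = diversity(G).per_population.loc["P"]
        # each diverged site: p=0.5, unbiased 2pq*n/(n-1) with 4 gene copies
        assert rep.pi == pytest.approx(2 / 1000 * (2 * 0.25 * 4 / 3), rel=1e-9)

    def test_matches_per_site_oracle_on_structured_data(self):
        G, _ = balding_nichols_genotypes(n_per_group=20, n_sites=300, F_k=0.2,
                                         K=2, seed=5, group_names=["A", "B"])
        rep = diversity(G).per_population
        # brute-force per-site recomputation for group A
        rows = G.pop_indices("A")
        g = G.genotypes[rows]
        ho, hs, pis = [], [], []
        for j in range(G.n_sites):
            col = g[:, j]
            p = col.sum() / (2 * len(col))
            ng = 2 * len(col)
            h_unb = 2 * p * (1 - p) * ng / (ng - 1)
            pis.append(h_unb)
            if 0 < p < 1:
                ho.append(np.mean(col == 1))
                hs.append(h_unb)
        assert rep.loc["A", "Ho"] == pytest.approx(np.mean(ho))
        assert rep.loc["A", "Hs"] == pytest.approx(np.mean(hs))
        assert rep.loc["A", "pi"] == pytest.approx(np.mean(pis))

    def test_hs_correction_exceeds_uncorrected(self):
        rng = np.random.default_rng(0)
        G = make_matrix(rng.integers(0, 3, (10, 50)), ["P"] * 10)
        rep = diversity(G).per_population.loc["P"]
        p = G.alt_freq()
        poly = (p > 0) & (p < 1)
        uncorrected = np.mean(2 * p[poly] * (1 - p[poly]))
        assert rep.Hs > uncorrected


class TestPrivatePolymorphisms:
    def test_identical_groups_have_none(self):
        col = np.array([0, 1, 2, 0, 1, 2])
        G = make_matrix(np.column_stack([col] * 5), ["A"] * 3 + ["B"] * 3)
        assert count_private(G) == {"A": 0, "B": 0}

    def test_hand_enumerated_three_groups(self):
        # rows are individuals; by hand: site0 poly in A only, site1 in B
        # only, site2 in C only, sites 3-4 polymorphic in every group
        geno = np.array(
            [[0, 0, 0, 1, 1], [1, 0, 0, 0, 1],   # A
             [0, 1, 0, 1, 1], [0, 0, 0, 0, 1],   # B
             [0, 0, 1, 1, 1], [0, 0, 0, 0, 1]]   # C
        )
        G = make_matrix(geno, ["A", "A", "B", "B", "C", "C"])
        assert count_private(G) == {"A": 1, "B": 1, "C": 1}


class TestWeirCockerham:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, size=500)
        geno = rng.binomial(2, p, size=(100, 500))
        G = make_matrix(geno, ["A"] * 50 + ["B"] * 50)
        theta = fst_wc(G).table.loc[("A", "B"), "fst_wc"]
        assert abs(theta) < 0.02

    def test_fixed_difference_gives_one(self):
        geno = np.vstack([np.zeros((5, 20)), np.full((5, 20), 2)]).astype(int)
        G = make_matrix(geno, ["A"] * 5 + ["B"] * 5)
        tab = fst_wc(G).table
        assert tab.loc[("A", "B"), "fst_wc"] == pytest.approx(1.0)
        assert tab.loc[("A", "B"), "fst_linearized"] == np.inf

    def test_toy_table_matches_brute_force_variance_components(self):
        g1 = np.array([[0, 1], [1, 1], [2, 0], [1, 2], [0, 0]])
        g2 = np.array([[2, 2], [1, 2], [2, 1], [2, 2], [1, 0]])
        G = make_matrix(np.vstack([g1, g2]), ["A"] * 5 + ["B"] * 5)
        theta = fst_wc(G).table.loc[("A", "B"), "fst_wc"]

        # independent hand computation of a, b, c (two pops, r=2)
        num = den = 0.0
        for j in range(2):
            n1, n2 = 5.0, 5.0
            p1 = g1[:, j].sum() / (2 * n1)
            p2 = g2[:, j].sum() / (2 * n2)
            h1 = np.mean(g1[:, j] == 1)
            h2 = np.mean(g2[:, j] == 1)
            r = 2.0
            nbar = (n1 + n2) / 2
            nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar)
                                                    - (r - 1) / r * s2 - hbar / 4))
            b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
        assert theta == pytest.approx(num / den, rel=1e-12)

    def test_theta_decreases_with_island_model_migration(self):
        # equilibrium island-model differentiation F ~ 1/(1 + 4Nm): genotypes
        # generated at the corresponding drift levels must yield multilocus
        # theta estimates ordered decreasingly in Nm
        means = {nm: [] for nm in (0.1, 1.0, 10.0)}
        for rep in range(20):
            for nm in means:
                G, _ = balding_nichols_genotypes(
                    n_per_group=25, n_sites=500, K=2,
                    F_k=1.0 / (1.0 + 4.0 * nm), seed=1000 * rep + int(10 * nm),
                    group_names=["A", "B"],
                )
                means[nm].append(fst_wc(G).table["fst_wc"].iloc[0])
        m = {nm: np.mean(v) for nm, v in means.items()}
        assert m[0.1] > m[1.0] > m[10.0]

    def test_monomorphic_pair_reported_missing(self):
        G = make_matrix(np.zeros((8, 5), dtype=int), ["A"] * 4 + ["B"] * 4)
        assert np.isnan(fst_wc(G).table.loc[("A", "B"), "fst_wc"])


class TestDxyDa:
    def test_identical_populations_da_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, 300)
        geno = rng.binomial(2, p, size=(80, 300))
        G = make_matrix(geno, ["A"] * 40 + ["B"] * 40)
        da = dxy_da(G).table.loc[("A", "B"), "da"]
        assert abs(da) < 0.01

    def test_reciprocally_fixed_site(self):
        geno = np.zeros((10, 100), dtype=int)
        geno[5:, 0] = 2  # pop B fixed alt at site 0, identical elsewhere
        G = make_matrix(geno, ["A"] * 5 + ["B"] * 5)
        row = dxy_da(G).table.loc[("A", "B")]
        assert row.dxy == pytest.approx(0.01)
        assert row.da == pytest.approx(0.01)

    def test_da_never_exceeds_dxy(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            geno = rng.integers(0, 3, size=(20, 50))
            G = make_matrix(geno, ["A"] * 10 + ["B"] * 10)
            tab = dxy_da(G).table
            assert (tab["da"] <= tab["dxy"] + 1e-12).all()


class TestMantel:
    def test_identical_matrices(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(1, 10, size=(6, 6))
        D = np.triu(d, 1) + np.triu(d, 1).T
        r, p = mantel_ibd(D, D, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_against_skbio_oracle(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(4)
        a = rng.uniform(1, 5, (7, 7))
        A = np.triu(a, 1) + np.triu(a, 1).T
        B = A + rng.normal(0, 0.5, (7, 7))
        B = np.triu(B, 1) + np.triu(B, 1).T
        np.fill_diagonal(B, 0)
        np.fill_diagonal(A, 0)
        r_ours, _ = mantel_ibd(A, B, n_perm=200, seed=0)
        r_skbio, _, _ = mantel(DistanceMatrix(A), DistanceMatrix(B),
                               method="pearson", permutations=0)
        assert r_ours == pytest.approx(r_skbio, abs=1e-10)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            mantel_ibd(np.eye(4), np.eye(5))

    def test_linearization(self):
        assert linearize_fst(0.5) == pytest.approx(1.0)
        assert linearize_fst(1.0) == np.inf


class TestSpearman:
    @pytest.mark.parametrize("flip,expected", [(1, 1.0), (-1, -1.0)])
    def test_monotone_pairs(self, flip, expected):
        x = np.arange(10, dtype=float)
        rho, p = ancestry_het_correlation(x, flip * x**2)
        assert rho == pytest.approx(expected)
        assert p < 1e-6

    def test_tied_ranks_match_manual_computation(self):
        q = np.array([0.1, 0.2, 0.2, 0.5, 0.9, 0.9])
        h = np.array([0.05, 0.10, 0.12, 0.11, 0.3, 0.2])
        rho, _ = ancestry_het_correlation(q, h)
        rq = sstats.rankdata(q)
        rh = sstats.rankdata(h)
        manual = np.corrcoef(rq, rh)[0, 1]
        assert rho == pytest.approx(manual)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = ancestry_het_correlation(np.ones(6), np.arange(6.0))
        assert np.isnan(rho)
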