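import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from stocksim import (
    CoalescentModelSpec,
    RejectionABC,
    abc_reject,
    convert_coalescent_time,
    simulate_loci,
    simulate_locus,
    simulate_table,
)
from stocksim.coalescent import sample_prior


class TestSimulator:
    def test_single_deme_neutral_diversity(self):
        # T_split = 0 collapses to one deme of relative size N_anc = 1:
        # E[pi] = theta per locus, E[S] = theta * a_{n-1}
        spec = CoalescentModelSpec(n1=8, n2=8, n_loci=8000, theta_ref=1.0,
                                   T_split=0.0, M12=1.0, M21=1.0)
        df = simulate_loci(spec, seed=1)
        assert df.pi1.mean() == pytest.approx(1.0, rel=0.05)
        assert df.dxy.mean() == pytest.approx(1.0, rel=0.05)
        a15 = np.sum(1 / np.arange(1, 16))
        assert df.S.mean() == pytest.approx(a15, rel=0.05)

    def test_zero_theta_gives_no_sites(self):
        spec = CoalescentModelSpec(theta_ref=0.0, n_loci=50)
        df = simulate_loci(spec, seed=2)
        assert (df.S == 0).all()

    def test_high_migration_is_panmictic(self):
        spec = CoalescentModelSpec(n1=8, n2=8, n_loci=2000, theta_ref=1.0,
                                   T_split=2.0, M12=100.0, M21=100.0)
        df = simulate_loci(spec, seed=3)
        assert abs(np.nanmean(df.fst)) < 0.02

    def test_deep_strict_isolation(self):
        spec = CoalescentModelSpec(model="SI", n1=8, n2=8, n_loci=1000,
                                   theta_ref=1.0, T_split=5.0)
        df = simulate_loci(spec, seed=4)
        assert np.nanmean(df.fst) > 0.8
        assert df.da.mean() > 0
        # E[da] = 2 * theta * tau under SI
        assert df.da.mean() == pytest.approx(2 * 5.0, rel=0.1)

    def test_fst_monotone_decreasing_in_migration(self):
        means = []
        for M in (0.1, 1.0, 10.0):
            spec = CoalescentModelSpec(n1=8, n2=8, n_loci=2000, theta_ref=1.0,
                                       T_split=2.0, M12=M, M21=M)
            means.append(np.nanmean(simulate_loci(spec, seed=5).fst))
        assert means[0] > means[1] > means[2]

    def test_da_monotone_increasing_in_split_time(self):
        means = []
        for T in (0.2, 1.0, 3.0):
            spec = CoalescentModelSpec(model="SI", n1=8, n2=8, n_loci=2000,
                                       theta_ref=1.0, T_split=T)
            means.append(simulate_loci(spec, seed=6).da.mean())
        assert means[0] < means[1] < means[2]

    def test_wakeley_hey_site_classes_sum_to_S(self):
        spec = CoalescentModelSpec(n1=6, n2=6, n_loci=500, theta_ref=2.0,
                                   T_split=1.0, M12=1.0, M21=0.1)
        df = simulate_loci(spec, seed=7)
        np.testing.assert_allclose(df.sxA + df.sxB + df.ss + df.sf, df.S)

    def test_against_msprime_oracle(self):
        # independent coalescent implementation at matched parameters
        import msprime

        M, tau, theta = 1.0, 1.0, 1.0
        n1 = n2 = 8
        spec = CoalescentModelSpec(n1=n1, n2=n2, n_loci=4000, theta_ref=theta,
                                   T_split=tau, M12=M, M21=M)
        ours = simulate_loci(spec, seed=8)

        # arbitrary diploid reference size; haploid lineages coalesce at
        # rate 1/(2N) when the haploid population size is 2N
        N = 1000
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=2 * N)
        dem.add_population(name="p2", initial_size=2 * N)
        dem.add_population(name="anc", initial_size=2 * N)
        dem.set_migration_rate("p1", "p2", M / (4 * N))
        dem.set_migration_rate("p2", "p1", M / (4 * N))
        dem.add_population_split(time=tau * 4 * N, derived=["p1", "p2"],
                                 ancestral="anc")
        pi1s, dxys = [], []
        reps = msprime.sim_ancestry(
            samples={"p1": n1, "p2": n2}, ploidy=1, demography=dem,
            sequence_length=1, num_replicates=1500, random_seed=9,
        )
        u = theta / (4 * N)
        for i, ts in enumerate(reps):
            mts = msprime.sim_mutations(ts, rate=u, random_seed=10 + i,
                                        discrete_genome=False)
            H = mts.genotype_matrix()
            if H.size == 0:
                pi1s.append(0.0)
                dxys.append(0.0)
                continue
            a = np.minimum(H[:, :n1], 1).sum(axis=1)
            b = np.minimum(H[:, n1:], 1).sum(axis=1)
            pi1s.append(np.sum(2 * a * (n1 - a) / (n1 * (n1 - 1))))
            dxys.append(np.sum((a * (n2 - b) + b * (n1 - a)) / (n1 * n2)))
        assert ours.pi1.mean() == pytest.approx(np.mean(pi1s), rel=0.1)
        assert ours.dxy.mean() == pytest.approx(np.mean(dxys), rel=0.1)

    def test_simulate_locus_row_shape(self):
        row = simulate_locus(CoalescentModelSpec(), seed=1)
        assert set(row) == {"pi1", "pi2", "S", "fst", "dxy", "da",
                            "sxA", "sxB", "ss", "sf"}

    def test_si_model_rejects_migration(self):
        with pytest.raises(ValueError, match="SI"):
            CoalescentModelSpec(model="SI", M12=1.0)


class TestRejectionABC:
    @pytest.fixture(scope="class")
    def small_table(self):
        spec = CoalescentModelSpec(model="IM", n1=6, n2=6, n_loci=40,
                                   theta_ref=1.0)
        return spec, *simulate_table(spec, 3000, seed=11)

    def test_tolerance_one_returns_prior(self, small_table):
        spec, params, stats = small_table
        obs = stats.iloc[0].to_numpy()
        post = abc_reject(obs, params, stats.to_numpy(), tolerance=1.0)
        prior = sample_prior(spec, 3000, np.random.default_rng(12))
        ks = ks_2samp(post.accepted["T_split"], prior["T_split"])
        assert ks.pvalue > 0.01

    def test_exact_match_returned_at_minimal_tolerance(self, small_table):
        spec, params, stats = small_table
        j = 137
        obs = stats.iloc[j].to_numpy()
        post = abc_reject(obs, params, stats.to_numpy(), tolerance=1e-9)
        assert len(post.accepted) == 1
        assert post.accepted.iloc[0]["T_split"] == params.iloc[j]["T_split"]

    def test_zero_variance_statistic_dropped_with_warning(self, small_table):
        spec, params, stats = small_table
        S = stats.to_numpy().copy()
        S[:, 3] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            post = abc_reject(S[0], params, S, tolerance=0.1)
        assert len(post.accepted) == 300

    def test_posterior_interval_contains_median(self, small_table):
        spec, params, stats = small_table
        post = abc_reject(stats.iloc[5].to_numpy(), params, stats.to_numpy(),
                          tolerance=0.05)
        for p in post.median.index:
            assert post.ci_low[p] <= post.median[p] <= post.ci_high[p]

    def test_coverage_of_prior_draws(self, small_table):
        # nominal 95% credible intervals cover the generating values for
        # most pseudo-observed datasets drawn from the prior
        from stocksim.coalescent import observed_summary
        from dataclasses import replace

        spec, params, stats = small_table
        S = stats.to_numpy()
        rng = np.random.default_rng(13)
        truths = sample_prior(spec, 50, rng)
        covered = {p: 0 for p in ("M12", "M21", "T_split")}
        for i in range(50):
            row = truths.iloc[i]
            tspec = replace(spec, M12=row.M12, M21=row.M21, N1=row.N1,
                            N2=row.N2, N_anc=row.N_anc, T_split=row.T_split)
            obs = observed_summary(tspec, seed=1000 + i)
            post = abc_reject(obs, params, S, tolerance=0.05)
            for p in covered:
                if post.ci_low[p] <= row[p] <= post.ci_high[p]:
                    covered[p] += 1
        for p, c in covered.items():
            assert c >= 40, (p, c)

    def test_sklearn_interface(self, small_table):
        spec, params, stats = small_table
        est = RejectionABC(tolerance=0.02).fit(params, stats.to_numpy(),
                                               stats.iloc[3].to_numpy())
        assert hasattr(est, "posterior_")
        assert est.get_params()["tolerance"] == 0.02


class TestTimeConversion:
    @pytest.mark.parametrize(
        "tau,expected", [(0.0, 0.0), (0.023, 23_000.0), (0.010, 10_000.0),
                         (0.045, 45_000.0)]
    )
    def test_published_scaling(self, tau, expected):
        # 4 * N_ref * generation-time = 1e6 years
        assert convert_coalescent_time(tau, 50_000, 5.0) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            convert_coalescent_time(-0.1, 1, 1)
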