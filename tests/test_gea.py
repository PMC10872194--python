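"""Core scan statistics: allele counts, Omega, XtX, Monte-Carlo Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from climagea import gea
from climagea.gea import (
    AlleleCountTable,
    db_from_bf,
    closed_form_log_bf,
    mahalanobis_xtx,
    pop_allele_frequencies,
    run_replicates,
    xtx_statistics,
    LOG10,
    _mc_log_bf,
)
from climagea.simulate import SimConfig, simulate_dataset, hierarchical_omega

from conftest import make_gm


def brute_force_counts(gm):
    pops = sorted(gm.samples["population"].unique())
    ploidy = gm.ploidy()
    alt = np.zeros((gm.n_snps, len(pops)), dtype=int)
    tot = np.zeros_like(alt)
    for i in range(gm.n_snps):
        for k in range(gm.n_samples):
            if gm.G[k, i] == -1:
                continue
            j = pops.index(gm.samples["population"].iloc[k])
            alt[i, j] += int(gm.G[k, i])
            tot[i, j] += int(ploidy[k, i])
    return alt, tot


class TestPopAlleleFrequencies:
    def test_simple_tally(self):
        G = np.array([[0], [1], [2]], dtype=np.int8)
        counts = pop_allele_frequencies(make_gm(G))
        assert counts.alt[0, 0] == 3 and counts.tot[0, 0] == 6
        assert counts.frequencies()[0, 0] == pytest.approx(0.5)

    def test_all_missing_population_flagged(self):
        G = np.array([[-1], [-1], [2]], dtype=np.int8)
        counts = pop_allele_frequencies(make_gm(G, pops=["a", "a", "b"]))
        assert counts.tot[0, 0] == 0
        assert np.isnan(counts.frequencies()[0, 0])

    def test_matches_brute_force_with_z(self):
        rng = np.random.default_rng(8)
        G = rng.integers(-1, 3, size=(12, 6)).astype(np.int8)
        sex = ["M", "F"] * 6
        chrom = ["chr1"] * 4 + ["chrZ"] * 2
        for k in range(12):
            if sex[k] == "F":
                G[k, 4:] = np.clip(G[k, 4:], -1, 1)
        gm = make_gm(G, chrom=chrom, sex=sex, z_chrom="chrZ",
                     pops=["p1"] * 6 + ["p2"] * 6)
        counts = pop_allele_frequencies(gm)
        alt, tot = brute_force_counts(gm)
        np.testing.assert_array_equal(counts.alt, alt)
        np.testing.assert_array_equal(counts.tot, tot)

    def test_count_bounds_validated(self):
        with pytest.raises(ValueError):
            AlleleCountTable(populations=["a"], snp_ids=np.array(["s"]),
                             alt=np.array([[3]]), tot=np.array([[2]]))


class TestEstimateOmega:
    def test_shape_symmetry_spd(self, small_counts_model):
        _, model = small_counts_model
        J = model.n_populations
        assert model.omega.shape == (J, J)
        np.testing.assert_allclose(model.omega, model.omega.T)
        assert np.linalg.eigvalsh(model.omega)[0] > 0

    def test_beta_hyperparameters_near_truth(self, small_counts_model, small_sim):
        cfg, _, _, _ = small_sim
        _, model = small_counts_model
        a, b = model.beta_params
        assert a == pytest.approx(cfg.freq_beta_params[0], rel=0.4)
        assert b == pytest.approx(cfg.freq_beta_params[1], rel=0.4)

    def test_duplicated_populations_have_matching_rows(self):
        cfg = SimConfig(n_populations=6, n_individuals_per_pop=15, n_snps=10_000,
                        n_selected_snps=0, missing_rate=0.0, n_related_pairs=0,
                        seed=21)
        gm, _, _ = simulate_dataset(cfg)
        counts = pop_allele_frequencies(gm)
        dup = AlleleCountTable(
            populations=counts.populations + ["popdup"],
            snp_ids=counts.snp_ids,
            alt=np.column_stack([counts.alt, counts.alt[:, 0]]),
            tot=np.column_stack([counts.tot, counts.tot[:, 0]]),
        )
        model = gea.estimate_omega(dup)
        diff = np.abs(model.omega[0, :] - model.omega[-1, :])
        # exclude the two mutual entries, which differ by construction
        assert np.max(np.delete(diff, [0, len(diff) - 1])) < 0.05

    def test_single_population_rejected(self):
        counts = AlleleCountTable(populations=["a"],
                                  snp_ids=np.array([f"s{i}" for i in range(200)]),
                                  alt=np.ones((200, 1), dtype=int),
                                  tot=np.full((200, 1), 10))
        with pytest.raises(ValueError, match="2 populations"):
            gea.estimate_omega(counts)

    def test_too_few_snps_rejected(self):
        counts = AlleleCountTable(populations=["a", "b"],
                                  snp_ids=np.array([f"s{i}" for i in range(50)]),
                                  alt=np.ones((50, 2), dtype=int),
                                  tot=np.full((50, 2), 10))
        with pytest.raises(ValueError, match="100"):
            gea.estimate_omega(counts)


class TestXtx:
    def test_zero_vector_gives_zero(self):
        assert mahalanobis_xtx(np.zeros(4), np.eye(4)) == pytest.approx(0.0)

    def test_identity_omega_unit_basis_gives_one(self):
        z = np.array([0.0, 1.0, 0.0])
        assert mahalanobis_xtx(z, np.eye(3)) == pytest.approx(1.0)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        omega = A @ A.T + np.eye(5)
        z = rng.normal(size=5)
        noise = rng.uniform(0.01, 0.1, 5)
        expected = z @ np.linalg.inv(omega + np.diag(noise)) @ z
        assert mahalanobis_xtx(z, omega, noise) == pytest.approx(expected, abs=1e-10)

    def test_population_with_no_alleles_dropped_from_quadratic_form(
        self, small_counts_model
    ):
        counts, model = small_counts_model
        alt = counts.alt.copy()
        tot = counts.tot.copy()
        tot[0, 2] = 0
        alt[0, 2] = 0
        masked = AlleleCountTable(populations=counts.populations,
                                  snp_ids=counts.snp_ids, alt=alt, tot=tot)
        xtx = xtx_statistics(masked, model)
        assert np.isfinite(xtx[0])

    def test_neutral_mean_near_population_count(self):
        cfg = SimConfig(n_populations=12, n_individuals_per_pop=15, n_snps=4000,
                        n_selected_snps=0, n_related_pairs=0, seed=17)
        gm, _, _ = simulate_dataset(cfg)
        counts = pop_allele_frequencies(gm)
        model = gea.estimate_omega(counts)
        xtx = xtx_statistics(counts, model)
        assert np.nanmean(xtx) == pytest.approx(12, rel=0.10)


class TestBayesFactors:
    def test_deciban_conversion(self):
        assert db_from_bf(100.0) == pytest.approx(20.0)

    def test_orthogonal_covariate_never_favored(self):
        # u'd = 0: every prior draw has likelihood ratio <= 1, so dB <= 0
        rng = np.random.default_rng(0)
        logbf = _mc_log_bf(np.zeros(10), np.full(10, 50.0), np.ones(10),
                           prior_sd=0.2, n_mc=100_000, rng=rng)
        assert (logbf <= 0).all()

    def test_mc_matches_closed_form_oracle(self):
        # conjugate-Gaussian marginal likelihood as the independent oracle
        rng = np.random.default_rng(1)
        a = np.array([4.0, -2.0, 0.5, 8.0])
        b = np.array([20.0, 15.0, 30.0, 25.0])
        s2 = np.array([1.0, 1.2, 0.9, 1.1])
        mc_db = 10 * _mc_log_bf(a, b, s2, 0.2, 100_000, rng) / LOG10
        cf_db = np.array([
            10 * closed_form_log_bf(ai, bi, s2i, 0.2) / LOG10
            for ai, bi, s2i in zip(a, b, s2)
        ])
        np.testing.assert_allclose(mc_db, cf_db, atol=0.3)

    def test_non_standardized_covariate_rejected(self, small_counts_model):
        counts, model = small_counts_model
        raw = pd.Series(np.arange(model.n_populations, dtype=float),
                        index=model.populations, name="raw")
        with pytest.raises(ValueError, match="standardized"):
            gea.bf_association(counts, model, raw, n_mc=1000)

    def test_small_n_mc_rejected(self, small_counts_model):
        counts, model = small_counts_model
        c = np.random.default_rng(0).normal(size=model.n_populations)
        c = (c - c.mean()) / c.std()
        cov = pd.Series(c, index=model.populations, name="c")
        with pytest.raises(ValueError, match="1,000"):
            gea.bf_association(counts, model, cov, n_mc=100)


@pytest.fixture(scope="module")
def cov_frame(small_counts_model):
    _, model = small_counts_model
    c = np.random.default_rng(2).normal(size=model.n_populations)
    c = (c - c.mean()) / c.std()
    return pd.DataFrame({"c1": c}, index=model.populations)


class TestRunReplicates:
    def test_single_seed_min_equals_run(self, small_counts_model, cov_frame):
        counts, model = small_counts_model
        scan = run_replicates(counts, model, cov_frame, seeds=(5,), n_mc=1000)
        np.testing.assert_allclose(scan.min_db[0], scan.db[0, 0], equal_nan=True)

    def test_deterministic_given_seeds(self, small_counts_model, cov_frame):
        counts, model = small_counts_model
        s1 = run_replicates(counts, model, cov_frame, seeds=(1, 2, 3), n_mc=1000)
        s2 = run_replicates(counts, model, cov_frame, seeds=(1, 2, 3), n_mc=1000)
        np.testing.assert_array_equal(s1.db, s2.db)
        np.testing.assert_array_equal(s1.xtx, s2.xtx)

    def test_min_across_runs(self, small_counts_model, cov_frame):
        counts, model = small_counts_model
        scan = run_replicates(counts, model, cov_frame, seeds=(1, 2, 3), n_mc=1000)
        ok = np.isfinite(scan.min_db[0])
        np.testing.assert_allclose(scan.min_db[0][ok], scan.db[0, :, ok].min(axis=1))

    def test_duplicate_seeds_warn(self, small_counts_model, cov_frame):
        counts, model = small_counts_model
        with pytest.warns(UserWarning, match="duplicate seeds"):
            run_replicates(counts, model, cov_frame, seeds=(1, 1), n_mc=1000)

    def test_to_frame_schema(self, small_counts_model, cov_frame):
        counts, model = small_counts_model
        scan = run_replicates(counts, model, cov_frame, seeds=(1, 2), n_mc=1000)
        df = scan.to_frame()
        for col in ("snp", "xtx", "db_c1_run1", "db_c1_run2", "min_db_c1"):
            assert col in df.columns
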