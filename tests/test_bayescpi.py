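"""BayesC-pi Gibbs sampler: oracles, recovery, prediction."""

import numpy as np
import pandas as pd
import pytest

from orchardgs import bayescpi, simdata


def random_design(n, p, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.integers(0, 3, size=(n, p)).astype(float),
                     index=[f"i{k}" for k in range(n)],
                     columns=[f"s{k}" for k in range(p)])
    return X, rng


@pytest.fixture(scope="module")
def sparse_sim():
    """Pedigreed simulation: n=800 training, p=1000, pi_true=0.02, h2=0.6."""
    cfg = simdata.SimConfig(
        n_founders=16, n_parent_pool=16, n_training_families=8,
        training_family_sizes=(100,) * 8, n_application_families=0,
        application_family_sizes=(), n_chromosomes=5,
        markers_per_chromosome=200, chromosome_length=100.0,
        pi_true=0.02, h2_target=0.6, seed=11)
    pop = simdata.simulate_population(cfg)
    fped = pop["fped"]
    arch = pop["architectures"][0]
    tbv = arch.true_breeding_values[fped.training_ids]
    rng = np.random.default_rng(5)
    sigma_e = np.sqrt(tbv.var() * (1 - 0.6) / 0.6)
    y = tbv + rng.normal(0, sigma_e, len(tbv))
    X = pop["genotypes"].to_frame().loc[fped.training_ids]
    return {"pop": pop, "y": y, "X": X, "arch": arch}


class TestDesignMatrix:
    def test_columns_centered(self):
        X, _ = random_design(30, 10, 0)
        d = bayescpi.DesignMatrix.from_dosages(X)
        assert np.abs(d.W.mean(axis=0).to_numpy()).max() < 1e-10

    def test_monomorphic_excluded(self):
        X, _ = random_design(30, 10, 0)
        X["mono"] = 1.0
        d = bayescpi.DesignMatrix.from_dosages(X)
        assert d.excluded == ["mono"]
        assert "mono" not in d.W.columns

    def test_nan_rejected(self):
        X, _ = random_design(10, 4, 0)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            bayescpi.DesignMatrix.from_dosages(X)


class TestFit:
    def test_constant_y_rejected(self):
        X, _ = random_design(20, 5, 1)
        d = bayescpi.DesignMatrix.from_dosages(X)
        y = pd.Series(1.0, index=X.index)
        with pytest.raises(ValueError, match="constant"):
            bayescpi.fit_bayescpi(d, y)

    def test_null_data_effects_near_zero(self):
        """Pure-noise phenotype: posterior mean effects stay within 3
        posterior sd of zero."""
        X, rng = random_design(60, 40, 2)
        d = bayescpi.DesignMatrix.from_dosages(X)
        y = pd.Series(rng.normal(0, 1, 60), index=X.index)
        chain = bayescpi.ChainConfig(iterations=6000, burn_in=1000,
                                     thinning=5, seed=1)
        model = bayescpi.fit_bayescpi(d, y, chain)
        sd = model.effect_sd.to_numpy()
        assert np.all(np.abs(model.snp_effects.to_numpy())
                      <= 3 * np.maximum(sd, 1e-6))

    def test_seed_reproducibility(self):
        X, rng = random_design(40, 30, 3)
        d = bayescpi.DesignMatrix.from_dosages(X)
        y = pd.Series(rng.normal(size=40), index=X.index)
        chain = bayescpi.ChainConfig(iterations=2000, burn_in=500,
                                     thinning=2, seed=9)
        m1 = bayescpi.fit_bayescpi(d, y, chain)
        m2 = bayescpi.fit_bayescpi(d, y, chain)
        pd.testing.assert_series_equal(m1.snp_effects, m2.snp_effects)
        assert m1.pi_hat == m2.pi_hat

    def test_pi_fixed_one_matches_ridge(self):
        """With inclusion forced (pi = 1) the posterior mean effects match
        the closed-form ridge / SNP-BLUP solution at the chain's
        posterior-mean variance ratio, within 3 Monte-Carlo SE."""
        X, rng = random_design(50, 100, 42)
        beta = rng.normal(0, 0.3, 100)
        y = pd.Series(X.to_numpy() @ beta + rng.normal(0, 1, 50),
                      index=X.index)
        d = bayescpi.DesignMatrix.from_dosages(X)
        chain = bayescpi.ChainConfig(iterations=20_000, burn_in=5000,
                                     thinning=5, seed=7, pi_fixed=1.0)
        model = bayescpi.fit_bayescpi(d, y, chain)
        lam = model.sigma_e2 / model.sigma_beta2
        W = d.W.loc[y.index].to_numpy()
        ridge = np.linalg.solve(W.T @ W + lam * np.eye(W.shape[1]),
                                W.T @ (y.to_numpy() - y.mean()))
        n_samples = (20_000 - 5000) // 5
        # conservative effective-sample deflation for autocorrelation
        mcse = model.effect_sd.to_numpy() / np.sqrt(n_samples / 10)
        assert np.all(np.abs(model.snp_effects.to_numpy() - ridge)
                      <= 3 * mcse + 1e-8)

    def test_pi_recovery_on_sparse_architecture(self, sparse_sim):
        """pi_true = 0.02 with 20 causal SNPs: the posterior mean of pi
        lands in [0.005, 0.08] and the causal SNPs are enriched among the
        top 5% inclusion probabilities."""
        d = bayescpi.DesignMatrix.from_dosages(sparse_sim["X"])
        chain = bayescpi.ChainConfig(iterations=12_000, burn_in=3000,
                                     thinning=5, seed=3)
        model = bayescpi.fit_bayescpi(d, sparse_sim["y"], chain)
        assert 0.005 <= model.pi_hat <= 0.08
        snps = sparse_sim["pop"]["map"].snps
        causal = {snps[i] for i in sparse_sim["arch"].causal_indices}
        top = set(model.inclusion_prob.nlargest(
            int(0.05 * len(model.inclusion_prob))).index)
        assert len(causal & top) >= 10

    def test_two_seeds_agree_on_pi(self, sparse_sim):
        """Chain stability: independent seeds give pi_hat within 0.05."""
        d = bayescpi.DesignMatrix.from_dosages(sparse_sim["X"])
        pis = []
        for seed in (3, 17):
            chain = bayescpi.ChainConfig(iterations=8000, burn_in=2000,
                                         thinning=5, seed=seed)
            pis.append(bayescpi.fit_bayescpi(d, sparse_sim["y"], chain).pi_hat)
        assert abs(pis[0] - pis[1]) < 0.05


class TestPredict:
    def make_model(self, effects, snps):
        return bayescpi.PredictionModel(
            snp_effects=pd.Series(effects, index=snps),
            inclusion_prob=pd.Series(0.5, index=snps),
            pi_hat=0.5, sigma_beta2=1.0, sigma_e2=1.0, intercept=0.0,
            training_means=pd.Series(0.0, index=snps),
            chain=bayescpi.ChainConfig())

    def test_zero_effects_zero_gbv(self):
        model = self.make_model([0.0, 0.0], ["a", "b"])
        X = pd.DataFrame({"a": [1.0, 2], "b": [0.0, 1]}, index=["x", "y"])
        out = bayescpi.predict_gbv(model, X)
        assert (out["gbv"] == 0).all()

    def test_single_snp_linearity(self):
        model = self.make_model([1.0], ["a"])
        X = pd.DataFrame({"a": [0.7]}, index=["x"])
        assert bayescpi.predict_gbv(model, X)["gbv"].iloc[0] == pytest.approx(0.7)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        snps = [f"s{k}" for k in range(5)]
        eff = rng.normal(size=5)
        X = pd.DataFrame(rng.integers(0, 3, (4, 5)).astype(float),
                         columns=snps, index=list("wxyz"))
        g1 = bayescpi.predict_gbv(self.make_model(eff, snps), X)["gbv"]
        g2 = bayescpi.predict_gbv(self.make_model(2 * eff, snps), X)["gbv"]
        np.testing.assert_allclose(g2, 2 * g1)

    def test_missing_snps_rejected(self):
        model = self.make_model([1.0, 1.0], ["a", "b"])
        X = pd.DataFrame({"a": [1.0]}, index=["x"])
        with pytest.raises(ValueError, match="missing"):
            bayescpi.predict_gbv(model, X)

    def test_permuted_phenotype_predicts_nothing(self, sparse_sim):
        """Training on a permuted phenotype destroys holdout accuracy."""
        X = sparse_sim["X"]
        y = sparse_sim["y"]
        train = X.index[:600]
        hold = X.index[600:]
        d = bayescpi.DesignMatrix.from_dosages(X.loc[train])
        rs = []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            chain = bayescpi.ChainConfig(iterations=4000, burn_in=1000,
                                         thinning=5, seed=2)
            model = bayescpi.fit_bayescpi(d, y_perm.loc[train], chain)
            g = bayescpi.predict_gbv(model, X.loc[hold])["gbv"]
            rs.append(np.corrcoef(g, y.loc[hold])[0, 1])
        # the family-structured holdout leaves per-permutation noise, but
        # the null accuracy averages to ~0
        assert abs(np.mean(rs)) < 0.1


class TestAccuracyScaling:
    def test_accuracy_grows_with_training_size(self):
        """Holdout accuracy improves with training population size
        (mean over 5 replicates, sizes 200/400/800)."""
        means = []
        for n_train in (200, 400, 800):
            accs = []
            for rep in range(5):
                cfg = simdata.SimConfig(
                    n_founders=12, n_parent_pool=12,
                    n_training_families=10,
                    training_family_sizes=(n_train // 10,) * 10,
                    n_application_families=2,
                    application_family_sizes=(50, 50),
                    n_chromosomes=3, markers_per_chromosome=100,
                    chromosome_length=100.0, pi_true=0.05, h2_target=0.5,
                    seed=7000 + rep)
                pop = simdata.simulate_population(cfg)
                fped = pop["fped"]
                arch = pop["architectures"][0]
                tbv = arch.true_breeding_values
                rng = np.random.default_rng(rep)
                tv = tbv[fped.training_ids]
                sigma_e = np.sqrt(tv.var() * (1 - 0.5) / 0.5)
                y = tv + rng.normal(0, sigma_e, len(tv))
                d = bayescpi.DesignMatrix.from_dosages(
                    pop["genotypes"].to_frame().loc[fped.training_ids])
                chain = bayescpi.ChainConfig(iterations=2500, burn_in=500,
                                             thinning=5, seed=rep)
                model = bayescpi.fit_bayescpi(d, y, chain)
                Xa = pop["genotypes"].to_frame().loc[fped.application_ids]
                g = bayescpi.predict_gbv(model, Xa)["gbv"]
                accs.append(np.corrcoef(g, tbv[fped.application_ids])[0, 1])
            means.append(np.mean(accs))
        assert means[0] < means[1] < means[2]


class TestSummaries:
    def test_relative_effects_arithmetic(self):
        snps = ["a", "b"]
        model = bayescpi.PredictionModel(
            snp_effects=pd.Series([0.2, -0.4], index=snps),
            inclusion_prob=pd.Series([0.9, 0.8], index=snps),
            pi_hat=0.5, sigma_beta2=1.0, sigma_e2=1.0, intercept=0.0,
            training_means=pd.Series(0.0, index=snps),
            chain=bayescpi.ChainConfig())
        y = pd.Series([-2.0, 2.0, -2.0, 2.0, -2.0, 2.0])
        sd = float(np.std(y, ddof=1))
        out = bayescpi.relative_effects(model, y)
        assert out["relative_effects"]["a"] == pytest.approx(0.2 / sd)
        assert out["max"] == pytest.approx(0.4 / sd)

    def test_zero_effects(self):
        snps = ["a"]
        model = bayescpi.PredictionModel(
            snp_effects=pd.Series([0.0], index=snps),
            inclusion_prob=pd.Series([0.1], index=snps),
            pi_hat=0.1, sigma_beta2=1.0, sigma_e2=1.0, intercept=0.0,
            training_means=pd.Series(0.0, index=snps),
            chain=bayescpi.ChainConfig())
        out = bayescpi.relative_effects(model, pd.Series([1.0, 2.0, 3.0]))
        assert out["max"] == 0.0
        assert out["fraction_below_1e4"] == 1.0

    def test_genotyped_fraction_counting(self):
        snps = [f"s{k}" for k in range(10)]
        model = bayescpi.PredictionModel(
            snp_effects=pd.Series(0.1, index=snps),
            inclusion_prob=pd.Series([0.9] * 10, index=snps),
            pi_hat=0.5, sigma_beta2=1.0, sigma_e2=1.0, intercept=0.0,
            training_means=pd.Series(0.0, index=snps),
            chain=bayescpi.ChainConfig())
        assert bayescpi.genotyped_fraction(model, snps) == 1.0
        assert bayescpi.genotyped_fraction(model, ["other"]) == 0.0
        assert bayescpi.genotyped_fraction(model, snps[:2]) == pytest.approx(0.2)

    def test_empty_inclusion_returns_none(self):
        snps = ["a"]
        model = bayescpi.PredictionModel(
            snp_effects=pd.Series([0.0], index=snps),
            inclusion_prob=pd.Series([0.01], index=snps),
            pi_hat=0.01, sigma_beta2=1.0, sigma_e2=1.0, intercept=0.0,
            training_means=pd.Series(0.0, index=snps),
            chain=bayescpi.ChainConfig())
        assert bayescpi.genotyped_fraction(model, snps, 0.5) is None
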