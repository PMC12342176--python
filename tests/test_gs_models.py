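"""REML, GBLUP/RR-BLUP, the Bayesian alphabet and the ML regressor contract."""

import numpy as np
import pandas as pd
import pytest

from popgs.config import SimulationConfig, TraitPreset
from popgs.genotypes import GenotypeMatrix
from popgs.gs_models import (
    BayesAlphabet,
    BayesConfig,
    GBLUP,
    PredictionResult,
    RRBLUP,
    SklearnGS,
    VarianceComponents,
    fit_model,
    reml_fit,
)
from popgs.popstruct import GRM, compute_grm
from popgs.simpop import simulate_founders, simulate_traits


def founder_panel(n, m, seed, ld_rho=0.2, length=5_000_000):
    cfg = SimulationConfig(
        n_founders=n, chromosomes=[(length, m)], ld_rho=ld_rho, seed=seed
    )
    return simulate_founders(cfg)


def dense_reml_oracle(y, G):
    """Independent REML: direct restricted likelihood on dense matrices.

    l_R(σ²g, σ²e) = −½[log|V| + log|X'V⁻¹X| + y'Py] with X = 1 and explicit
    inverses (no spectral shortcut); for each δ on a fine grid, σ²g is
    estimated by GLS residual variance and the dense likelihood evaluated.
    """
    n = len(y)
    X = np.ones((n, 1))

    def ll(sg, se):
        V = sg * G + se * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        _, ld = np.linalg.slogdet(V)
        return -0.5 * (ld + np.log(XtViX[0, 0]) + y @ P @ y)

    best = None
    for delta in np.geomspace(1e-4, 1e4, 400):
        Vd = G + delta * np.eye(n)
        Vdi = np.linalg.inv(Vd)
        beta = (X.T @ Vdi @ y).item() / (X.T @ Vdi @ X).item()
        r = y - beta
        sg = float(r @ Vdi @ r) / (n - 1)
        v = ll(sg, sg * delta)
        if best is None or v > best[0]:
            best = (v, delta)
    return 1.0 / (1.0 + best[1])


class TestREML:
    def test_matches_independent_dense_oracle(self):
        g = founder_panel(40, 300, seed=50)
        ph, truth = simulate_traits(
            g, [TraitPreset("X", 0.0, 1.0, 0.6)], n_qtn=30, seed=51
        )
        grm = compute_grm(g)
        vc = reml_fit(ph["X"].to_numpy(), grm)
        h2_oracle = dense_reml_oracle(ph["X"].to_numpy(), grm.matrix)
        assert vc.h2 == pytest.approx(h2_oracle, abs=0.02)

    def test_pure_noise_hits_the_zero_boundary(self, family_pop):
        # needs a structured kinship (family GRM); with G ≈ I the likelihood
        # is flat in δ and h² is unidentifiable
        grm = compute_grm(family_pop.progeny)
        n = grm.n
        boundary_hits = 0
        for rep in range(20):
            y = np.random.default_rng(rep).normal(0, 1, n)
            vc = reml_fit(y, grm)
            if vc.h2 < 0.05:
                boundary_hits += 1
        assert boundary_hits >= 18  # ≥90% of replicates collapse to h²≈0

    def test_high_heritability_recovered(self):
        # lighter version of the acceptance check: 5 reps, n=300, m=1000
        vals = []
        for rep in range(5):
            g = founder_panel(300, 1000, seed=60 + rep)
            ph, _ = simulate_traits(
                g, [TraitPreset("BD", 0.41, 0.03, 0.80)], n_qtn=50, seed=70 + rep
            )
            vals.append(reml_fit(ph["BD"].to_numpy(), compute_grm(g)).h2)
        assert np.mean(vals) == pytest.approx(0.80, abs=0.06)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            reml_fit(np.zeros(5), np.eye(5))


class TestBLUPs:
    def test_gblup_rrblup_identity(self):
        g = founder_panel(120, 400, seed=80)
        ph, _ = simulate_traits(g, [TraitPreset("X", 0, 1, 0.5)], n_qtn=20, seed=81)
        y = ph["X"].to_numpy()
        train = np.arange(90)
        r_g = GBLUP(y[train], compute_grm(g), train_idx=train).fit()
        r_r = RRBLUP(y[train], g, train_idx=train).fit()
        scale = np.abs(r_g.gebv).max()
        assert np.abs(r_g.gebv - r_r.gebv).max() / scale < 1e-6
        assert r_g.mu == pytest.approx(r_r.mu, rel=1e-8)

    def test_infinite_noise_shrinks_gebvs_to_zero(self):
        g = founder_panel(50, 100, seed=82)
        y = np.random.default_rng(0).normal(0, 1, 50)
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1e10, mu=0.0, loglik=0.0)
        res = GBLUP(y, compute_grm(g)).fit(varcomp=vc)
        assert np.abs(res.gebv).max() < 1e-6

    def test_zero_noise_interpolates_the_phenotype(self):
        g = founder_panel(50, 200, seed=83)
        y = np.random.default_rng(1).normal(5, 1, 50)
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1e-10, mu=0.0, loglik=0.0)
        res = GBLUP(y, compute_grm(g)).fit(varcomp=vc)
        np.testing.assert_allclose(res.gebv + res.mu, y, atol=1e-4)

    def test_single_marker_ridge_closed_form(self):
        d = np.array([[0], [1], [2], [1], [0], [2], [1], [0], [1], [2], [0], [1]])
        markers = pd.DataFrame({"chrom": "Chr01", "pos": [100], "ref": "A", "alt": "G"})
        g = GenotypeMatrix(d, [f"S{i}" for i in range(12)], markers)
        y = np.array([1.0, 2, 3, 2, 1, 3, 2, 1, 2.2, 2.8, 1.1, 2.1])
        delta = 0.7
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=delta, mu=0.0, loglik=0.0)
        res = RRBLUP(y, g).fit(varcomp=vc)
        # hand computation: w = d − 2p; lambda = c·delta with c = 2p(1−p)
        p = d.mean() / 2
        w = (d[:, 0] - 2 * p).astype(float)
        lam = 2 * p * (1 - p) * delta
        A = np.outer(w, w) + lam * np.eye(12)
        ones = np.ones(12)
        mu = (ones @ np.linalg.solve(A, y)) / (ones @ np.linalg.solve(A, ones))
        ahat = w @ np.linalg.solve(A, y - mu)
        assert res.effects[0] == pytest.approx(ahat, rel=1e-10)
        np.testing.assert_allclose(res.gebv, w * ahat, rtol=1e-10)

    def test_vanishing_penalty_recovers_least_squares(self):
        g = founder_panel(60, 10, seed=84, ld_rho=0.0)
        y = np.random.default_rng(2).normal(0, 1, 60)
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1e-10, mu=0.0, loglik=0.0)
        res = RRBLUP(y, g).fit(varcomp=vc)
        W = g.centered()
        X = np.column_stack([np.ones(60), W])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res.gebv, W @ beta[1:], atol=1e-3)

    def test_shrinkage_is_monotone_in_the_penalty(self):
        g = founder_panel(80, 150, seed=85)
        ph, _ = simulate_traits(g, [TraitPreset("X", 0, 1, 0.6)], n_qtn=10, seed=86)
        y = ph["X"].to_numpy()
        norms = []
        for delta in [0.01, 0.1, 1.0, 10.0, 100.0]:
            vc = VarianceComponents(1.0, delta, 0.0, 0.0)
            norms.append(np.linalg.norm(RRBLUP(y, g).fit(varcomp=vc).effects))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_accuracy_grows_with_training_size(self):
        gains = []
        for rep in range(6):
            g = founder_panel(300, 500, seed=90 + rep)
            ph, truth = simulate_traits(
                g, [TraitPreset("X", 0, 1, 0.6)], n_qtn=30, seed=95 + rep
            )
            y, tbv = ph["X"].to_numpy(), truth.tbv("X")
            test = np.arange(200, 300)
            accs = []
            for n_train in (50, 200):
                train = np.arange(n_train)
                res = GBLUP(y[train], compute_grm(g), train_idx=train).fit()
                accs.append(np.corrcoef(res.gebv[test], tbv[test])[0, 1])
            assert max(accs) <= 1.0
            gains.append(accs[1] - accs[0])
        assert np.mean(gains) > 0


class TestBayes:
    def test_chains_are_seed_reproducible(self):
        g = founder_panel(60, 80, seed=100)
        ph, _ = simulate_traits(g, [TraitPreset("X", 0, 1, 0.5)], n_qtn=5, seed=101)
        cfg = BayesConfig(n_iter=400, burn_in=100, seed=7)
        a = BayesAlphabet("BayesC", cfg).fit(ph["X"].to_numpy(), g)
        b = BayesAlphabet("BayesC", cfg).fit(ph["X"].to_numpy(), g)
        np.testing.assert_array_equal(a.effects, b.effects)
        assert a.mu == b.mu

    def test_bayesb_with_pi_zero_reduces_to_bayesa(self):
        g = founder_panel(100, 120, seed=102)
        ph, _ = simulate_traits(g, [TraitPreset("X", 0, 1, 0.6)], n_qtn=8, seed=103)
        y = ph["X"].to_numpy()
        cfg = dict(n_iter=3000, burn_in=1000, seed=11)
        ra = BayesAlphabet("BayesA", BayesConfig(**cfg)).fit(y, g)
        rb = BayesAlphabet("BayesB", BayesConfig(pi=0.0, **cfg)).fit(y, g)
        # same priors, same limit: GEBVs agree within Monte-Carlo error
        assert np.corrcoef(ra.gebv, rb.gebv)[0, 1] > 0.99
        assert np.all(rb.posterior["inclusion"] == 1.0)

    def test_bayesb_inclusion_concentrates_on_true_qtns(self):
        g = founder_panel(300, 500, seed=104, ld_rho=0.0)
        ph, truth = simulate_traits(
            g, [TraitPreset("X", 0, 1, 0.6)], n_qtn=10, seed=105
        )
        cfg = BayesConfig(n_iter=2000, burn_in=500, thin=2, seed=13)
        res = BayesAlphabet("BayesB", cfg).fit(ph["X"].to_numpy(), g)
        incl = res.posterior["inclusion"]
        qtn = truth.qtn_indices["X"]
        background = np.setdiff1d(np.arange(g.n_markers), qtn)
        assert incl[qtn].mean() > 10 * incl[background].mean()

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            BayesConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            BayesConfig(pi=1.0)
        with pytest.raises(ValueError):
            BayesAlphabet("BayesZ")


class TestMLRegressors:
    def test_constant_target_predicts_the_constant(self):
        g = founder_panel(40, 60, seed=110)
        y = np.full(40, 7.5)
        for tag in ("RF", "GBDT", "KRR", "RR", "EN"):
            res = SklearnGS(tag, seed=0).fit(y, g)
            np.testing.assert_allclose(res.predicted_values(), 7.5, atol=0.05)

    def test_sklearn_ridge_equals_rrblup_at_matched_penalty(self):
        from sklearn.linear_model import Ridge

        g = founder_panel(80, 50, seed=111)
        ph, _ = simulate_traits(g, [TraitPreset("X", 0, 1, 0.5)], n_qtn=10, seed=112)
        y = ph["X"].to_numpy()
        delta = 2.0
        vc = VarianceComponents(1.0, delta, 0.0, 0.0)
        rr = RRBLUP(y, g).fit(varcomp=vc)
        p = g.allele_freq()
        poly = (p > 0) & (p < 1)
        lam = 2 * np.sum(p[poly] * (1 - p[poly])) * delta
        W = g.centered()[:, poly]
        sk = Ridge(alpha=lam, fit_intercept=False).fit(W, y - rr.mu)
        np.testing.assert_allclose(rr.gebv, W @ sk.coef_, atol=1e-8)

    def test_trees_beat_gblup_on_nonadditive_low_h2_signal(self):
        diffs = []
        for rep in range(5):
            g = founder_panel(250, 200, seed=120 + rep, ld_rho=0.0)
            rng = np.random.default_rng(130 + rep)
            d = g.dosages.astype(float)
            # purely epistatic signal: pairwise XOR-style interactions
            sig = np.zeros(250)
            for a, b in zip(range(0, 10), range(10, 20)):
                sig += ((d[:, a] == 1) ^ (d[:, b] == 1)).astype(float)
            sig = (sig - sig.mean()) / sig.std()
            y = sig * np.sqrt(0.4) + rng.normal(0, np.sqrt(0.6), 250)
            train, test = np.arange(180), np.arange(180, 250)
            pa = {}
            for tag in ("GBDT", "GBLUP"):
                res = fit_model(tag, y[train], g, train_idx=train, seed=rep)
                pa[tag] = np.corrcoef(res.gebv[test], y[test])[0, 1]
            diffs.append(pa["GBDT"] - pa["GBLUP"])
        assert np.mean(diffs) > 0

    def test_registry_covers_all_tags_and_rejects_unknown(self):
        g = founder_panel(40, 30, seed=140)
        y = np.random.default_rng(3).normal(0, 1, 40)
        res = fit_model("RR", y, g, seed=1)
        assert isinstance(res, PredictionResult)
        with pytest.raises(KeyError):
            fit_model("DNNGP", y, g)

    def test_summary_mentions_model_and_h2(self):
        g = founder_panel(60, 100, seed=141)
        ph, _ = simulate_traits(g, [TraitPreset("X", 0, 1, 0.7)], n_qtn=10, seed=142)
        res = GBLUP(ph["X"].to_numpy(), compute_grm(g)).fit()
        text = res.summary()
        assert "GBLUP" in text and "h2" in text
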