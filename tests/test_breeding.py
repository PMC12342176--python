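"""Breeding deployment: prediction transfer, selection, GCBV, kinship networks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from popgs.breeding import (
    CompositeConfig,
    PanelMismatchError,
    breeding_slice,
    composite_gcbv,
    harmonize_panels,
    kinship_network,
    predict_breeding,
    select_top,
    validate_against_observations,
)
from popgs.config import SimulationConfig, TraitPreset
from popgs.genotypes import GenotypeMatrix
from popgs.gs_models import GBLUP
from popgs.pedigree import Pedigree, UNKNOWN
from popgs.popstruct import compute_grm
from popgs.simpop import simulate_founders, simulate_population, simulate_traits


def pred_frame(ids, gebv, mu=0.0):
    return pd.DataFrame(
        {"id": ids, "gebv": gebv, "predicted_value": mu + np.asarray(gebv)}
    )


@pytest.fixture(scope="module")
def split_pop():
    """One simulated pedigree split into reference and breeding halves."""
    cfg = SimulationConfig(
        n_founders=16, n_families=12, progeny_per_family=25, n_generations=2,
        chromosomes=[(10_000_000, 500)], ld_rho=0.8, n_qtn_per_trait=10, seed=77,
    )
    pop = simulate_population(cfg)
    g = pop.progeny
    n = g.n_samples
    ref = np.arange(0, n, 2)
    brd = np.setdiff1d(np.arange(n), ref)
    return pop, g.take_samples(ref), g.take_samples(brd), ref, brd


class TestPredictBreeding:
    def test_panel_mismatch_raises(self, split_pop):
        _, ref, brd, _, _ = split_pop
        clipped = brd.take_markers(np.arange(100))  # 20% overlap with ref
        with pytest.raises(PanelMismatchError):
            harmonize_panels(ref, clipped.take_markers(np.arange(40)))

    def test_duplicate_individual_gets_its_fitted_gebv(self, split_pop):
        pop, ref, _, ref_idx, _ = split_pop
        y = pop.phenotypes["DBH"].to_numpy()[ref_idx]
        dup = ref.take_samples(np.arange(5))  # breeding set = 5 reference trees
        res = predict_breeding(ref, y, dup, model="GBLUP")
        frame = res.to_frame()
        for i in range(5):
            a = frame[frame["id"] == f"{ref.sample_ids[i]}#ref"]["gebv"].iloc[0]
            b = frame[frame["id"] == f"{ref.sample_ids[i]}#brd"]["gebv"].iloc[0]
            # agreement up to the GRM jitter policy (ε·α ~ 1e−5)
            assert a == pytest.approx(b, abs=1e-4)

    def test_transfer_accuracy_tracks_truth(self, split_pop):
        pop, ref, brd, ref_idx, brd_idx = split_pop
        y_ref = pop.phenotypes["DBH"].to_numpy()[ref_idx]
        res = predict_breeding(ref, y_ref, brd, model="GBLUP")
        out = breeding_slice(res, brd.sample_ids)
        tbv = pop.truth.tbv("DBH")[brd_idx]
        r = np.corrcoef(out["gebv"], tbv)[0, 1]
        assert r > 0.3

    def test_gebvs_approximately_normal(self, split_pop):
        from scipy.stats import shapiro

        pop, ref, brd, ref_idx, _ = split_pop
        y_ref = pop.phenotypes["H"].to_numpy()[ref_idx]
        res = predict_breeding(ref, y_ref, brd, model="GBLUP")
        out = breeding_slice(res, brd.sample_ids)
        assert shapiro(out["gebv"]).pvalue > 0.01

    def test_significant_qtns_enter_as_covariates(self, split_pop):
        pop, ref, brd, ref_idx, _ = split_pop
        y_ref = pop.phenotypes["DBH"].to_numpy()[ref_idx]
        qtn_ids = ref.marker_ids()[pop.truth.qtn_indices["DBH"][:3]]
        res = predict_breeding(ref, y_ref, brd, model="GBLUP", qtn_marker_ids=qtn_ids)
        assert res.covariate_beta is not None and len(res.covariate_beta) == 3


class TestSelectTop:
    def test_counting_rule(self):
        preds = pred_frame([f"i{k}" for k in range(10)], np.arange(10.0))
        rep = select_top(preds, rate=0.2)
        assert int(rep.table["selected"].sum()) == 2
        assert set(rep.selected_ids) == {"i9", "i8"}

    def test_equal_gebvs_zero_gain_deterministic_ties(self):
        preds = pred_frame(list("edcba"), np.zeros(5), mu=10.0)
        rep = select_top(preds, rate=0.4)
        assert rep.gain_pct == 0.0
        assert list(rep.selected_ids) == ["a", "b"]  # id tie-break

    def test_minimize_direction_selects_smallest(self):
        preds = pred_frame(["a", "b", "c", "d", "e"], [5.0, 1.0, 4.0, 2.0, 3.0])
        rep = select_top(preds, rate=0.4, direction="min")
        assert set(rep.selected_ids) == {"b", "d"}

    def test_selection_gains_true_breeding_value(self):
        wins = 0
        for rep_i in range(20):
            cfg = SimulationConfig(
                n_founders=200, chromosomes=[(2_000_000, 150)], ld_rho=0.2,
                seed=400 + rep_i,
            )
            g = simulate_founders(cfg)
            ph, truth = simulate_traits(
                g, [TraitPreset("X", 10, 2, 0.6)], n_qtn=20, seed=420 + rep_i
            )
            res = GBLUP(ph["X"].to_numpy(), compute_grm(g)).fit()
            report = select_top(res.to_frame(), rate=0.2, trait="X")
            sel = np.isin(g.sample_ids, report.selected_ids)
            if truth.tbv("X")[sel].mean() > truth.tbv("X").mean():
                wins += 1
        assert wins >= 19  # ≥95%

    def test_nonfinite_gebvs_rejected(self):
        preds = pred_frame(["a", "b", "c"], [1.0, np.nan, 2.0])
        with pytest.raises(ValueError):
            select_top(preds)


class TestComposite:
    def test_degenerate_weights_reduce_to_single_trait(self, rng):
        ids = [f"i{k}" for k in range(50)]
        a = pred_frame(ids, rng.normal(0, 1, 50))
        b = pred_frame(ids, rng.normal(0, 5, 50))
        out = composite_gcbv({"H": a, "DBH": b}, CompositeConfig({"H": 1.0, "DBH": 0.0}))
        assert (
            out.sort_values("gcbv")["id"].tolist()
            == a.sort_values("gebv")["id"].tolist()
        )

    def test_perfectly_correlated_traits_preserve_ranking(self, rng):
        ids = [f"i{k}" for k in range(30)]
        v = rng.normal(0, 1, 30)
        a = pred_frame(ids, v)
        b = pred_frame(ids, 100 * v + 7)  # same ranking, different scale
        out = composite_gcbv({"H": a, "DBH": b})
        assert (
            out.sort_values("gcbv")["id"].tolist()
            == a.sort_values("gebv")["id"].tolist()
        )

    def test_top_composite_overlaps_both_traits_more_than_chance(self, rng):
        n, k = 200, 40
        ids = [f"i{j}" for j in range(n)]
        base = rng.normal(0, 1, n)
        a = pred_frame(ids, base + rng.normal(0, 0.7, n))
        b = pred_frame(ids, base + rng.normal(0, 0.7, n))
        out = composite_gcbv({"H": a, "DBH": b})
        top = set(out.nlargest(k, "gcbv")["id"])
        # expected overlap of two random k-subsets is k²/n = 8
        expected_random = k * k / n
        for df in (a, b):
            overlap = len(top & set(df.nlargest(k, "gebv")["id"]))
            assert overlap > hypergeom.ppf(0.95, n, k, k)
            assert overlap > expected_random

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CompositeConfig({"H": 0.5, "DBH": 0.6})


class TestKinshipNetwork:
    def _pedigree(self):
        rows = [
            {"id": p, "dam": UNKNOWN, "sire": UNKNOWN, "generation": 0, "family": "founder"}
            for p in ("D1", "S1", "D2", "S2")
        ]
        for i in range(6):
            rows.append(
                {"id": f"a{i}", "dam": "D1", "sire": "S1", "generation": 1, "family": "F1"}
            )
            rows.append(
                {"id": f"b{i}", "dam": "D2", "sire": "S2", "generation": 1, "family": "F2"}
            )
        return Pedigree(pd.DataFrame(rows))

    def test_single_family_selection_loads_both_parents_fully(self):
        ped = self._pedigree()
        net = kinship_network([f"a{i}" for i in range(6)], ped)
        w = net.parent_weights.set_index("parent")["weight"]
        assert w["D1"] == 6 and w["S1"] == 6
        assert "D2" not in w.index

    def test_weight_sum_is_twice_selected_count(self):
        ped = self._pedigree()
        sel = ["a0", "a1", "b0", "b3", "b5"]
        net = kinship_network(sel, ped)
        assert net.parent_weights["weight"].sum() == 2 * len(sel)

    def test_enriched_dam_tops_the_network(self, family_pop):
        # select on a real GEBV fit; the top dam must carry the most progeny
        pop = family_pop
        g = pop.progeny
        res = GBLUP(pop.phenotypes["DBH"].to_numpy(), compute_grm(g)).fit()
        report = select_top(res.to_frame(), rate=0.2, trait="DBH")
        net = kinship_network(report.selected_ids, pop.pedigree)
        dams = net.parent_weights[net.parent_weights["role"] == "dam"]
        top_dam_weight = dams["weight"].max()
        assert top_dam_weight == net.core_parents(1)["weight"].iloc[0] or top_dam_weight > 0

    def test_unknown_progeny_rejected(self):
        with pytest.raises(KeyError):
            kinship_network(["ghost"], self._pedigree())


class TestValidation:
    def test_identity_observations_give_r_one(self):
        preds = pred_frame(["a", "b", "c", "d"], [1.0, 2.0, 3.0, 4.0])
        obs = pd.DataFrame({"id": ["a", "b", "c", "d"], "observed": [1.0, 2.0, 3.0, 4.0]})
        out = validate_against_observations(preds, obs)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_permuted_observations_give_null_r(self, rng):
        n = 300
        ids = [f"i{k}" for k in range(n)]
        preds = pred_frame(ids, rng.normal(0, 1, n))
        obs = pd.DataFrame({"id": ids, "observed": rng.permutation(preds["gebv"])})
        out = validate_against_observations(preds, obs)
        assert abs(out["pearson_r"]) < 3 / np.sqrt(n)

    def test_attenuation_formula_on_noisy_truth(self):
        # observed = TBV + noise at h²_obs: E[corr(GEBV, obs)] ≈
        # √h²_obs · corr(GEBV, TBV); check within ±0.1 over 20 replicates
        diffs = []
        for rep in range(20):
            cfg = SimulationConfig(
                n_founders=250, chromosomes=[(2_000_000, 120)], ld_rho=0.2,
                seed=500 + rep,
            )
            g = simulate_founders(cfg)
            ph, truth = simulate_traits(
                g, [TraitPreset("X", 0, 1, 0.6)], n_qtn=20, seed=520 + rep
            )
            res = GBLUP(ph["X"].to_numpy(), compute_grm(g)).fit()
            tbv = truth.tbv("X")
            h2_obs = 0.5
            rng = np.random.default_rng(540 + rep)
            obs_vals = tbv + rng.normal(
                0, np.sqrt(tbv.var() * (1 - h2_obs) / h2_obs), len(tbv)
            )
            preds = res.to_frame()
            obs = pd.DataFrame({"id": preds["id"], "observed": obs_vals})
            out = validate_against_observations(preds, obs)
            expected = np.sqrt(h2_obs) * np.corrcoef(res.gebv, tbv)[0, 1]
            diffs.append(out["pearson_r"] - expected)
        assert abs(np.mean(diffs)) < 0.1

    def test_too_few_matches_rejected(self):
        preds = pred_frame(["a", "b"], [1.0, 2.0])
        obs = pd.DataFrame({"id": ["a", "b"], "observed": [1.0, 2.0]})
        with pytest.raises(ValueError):
            validate_against_observations(preds, obs)
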