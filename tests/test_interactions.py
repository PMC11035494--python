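import numpy as np
import pandas as pd
import pytest

import frperturb as fp
from frperturb.containers import DesignMatrix
from frperturb.interactions import ModuleSets


def design_from_rows(rows, perturbation_ids):
    X = np.asarray(rows, dtype=float)
    g = np.maximum(X.sum(axis=1), 1).astype(int)
    return DesignMatrix(X, perturbation_ids, [f"d{i}" for i in range(len(X))], g)


class TestExpandPairwise:
    def test_candidate_pair_count(self):
        assert fp.count_candidate_pairs(598) == 178503
        assert fp.count_candidate_pairs(4) == 6

    def test_triple_droplet_sets_all_three_pairs(self):
        d = design_from_rows([[1, 1, 1, 0, 0]] * 5, ["A", "B", "C"])
        pd2 = fp.expand_pairwise(d, min_cells=5)
        assert set(pd2.pair_ids) == {("A", "B"), ("A", "C"), ("B", "C")}
        np.testing.assert_array_equal(pd2.X2, 1.0)
        assert pd2.n_candidate_pairs == 3

    def test_support_filter_drops_rare_pairs(self):
        rows = [[1, 1, 0, 0, 0]] * 4 + [[1, 0, 1, 0, 0]] * 5
        d = design_from_rows(rows, ["A", "B", "C"])
        pd2 = fp.expand_pairwise(d, min_cells=5)
        assert pd2.pair_ids == [("A", "C")]

    def test_all_singletons_give_empty_design(self):
        d = design_from_rows([[1, 0, 0, 0], [0, 1, 0, 0]], ["A", "B"])
        pd2 = fp.expand_pairwise(d, min_cells=1)
        assert pd2.X2.shape[1] == 0 and pd2.pair_ids == []


class TestModuleSets:
    def _design(self):
        # perturbations: M1, M2 in module; S significant outside; C null outside
        rows = [
            [0, 0, 0, 0, 1, 0],  # d0: NT only -> control
            [1, 0, 0, 0, 1, 0],  # d1: one module guide + NT -> first order
            [1, 1, 0, 0, 0, 0],  # d2: two module guides -> second order
            [1, 1, 0, 1, 0, 0],  # d3: two module + significant other -> excluded
            [0, 0, 0, 1, 0, 0],  # d4: significant other only -> excluded
            [0, 0, 1, 0, 0, 0],  # d5: insignificant other only -> control
            [1, 0, 1, 0, 0, 0],  # d6: module + insignificant -> first order
            [0, 0, 0, 0, 0, 1],  # d7: safe-targeting only -> control
        ]
        return design_from_rows(rows, ["M1", "M2", "C", "S"])

    def test_partition_rules(self):
        sets = fp.module_sets(self._design(), ["M1", "M2"], {"S", "M1", "M2"})
        assert list(sets.control) == [0, 5, 7]
        assert list(sets.first_order) == [1, 6]
        assert list(sets.second_order) == [2]

    def test_inter_module_partition(self):
        rows = [
            [0, 0, 0, 0, 1, 0],  # control
            [1, 0, 0, 0, 0, 0],  # first order M1
            [0, 0, 1, 0, 0, 0],  # first order M2
            [1, 0, 1, 0, 0, 0],  # second order (one from each)
            [1, 1, 0, 0, 0, 0],  # two from M1, none from M2 -> no set
        ]
        d = design_from_rows(rows, ["A1", "A2", "B1", "B2"])
        sets = fp.module_sets(d, ["A1", "A2"], {"A1", "A2", "B1", "B2"},
                              module_genes_2=["B1", "B2"])
        assert list(sets.control) == [0]
        assert list(sets.first_order) == [1]
        assert list(sets.first_order_2) == [2]
        assert list(sets.second_order) == [3]


class TestModuleInteractionArithmetic:
    def _run(self, mu0, mu1, mu_int, mu2=None):
        # one "gene"; 40 cells per set with exact set means; kind from mu2
        means = [mu0, mu1] + ([mu2] if mu2 is not None else []) + [mu_int]
        Y = np.concatenate([np.full(40, m) for m in means])[:, None]
        groups = [np.arange(40 * k, 40 * (k + 1)) for k in range(len(means))]
        sets = ModuleSets(
            control=groups[0],
            first_order=groups[1],
            second_order=groups[-1],
            first_order_2=groups[2] if mu2 is not None else None,
        )
        return fp.module_interaction(
            Y, np.array([0]), sets, kind="intra" if mu2 is None else "inter",
            n_permutations=20, n_bootstrap=20, seed=0,
        )

    def test_perfect_additivity_intra(self):
        mi = self._run(0.0, -0.5, -1.0)
        assert mi.beta1 == pytest.approx(-0.5)
        assert mi.beta_int == pytest.approx(0.0, abs=1e-12)

    def test_positive_interaction_intra(self):
        mi = self._run(0.0, -0.5, -0.4)
        assert mi.beta_int == pytest.approx(0.6)

    def test_perfect_additivity_inter(self):
        mi = self._run(0.0, -0.3, -0.5, mu2=-0.2)
        assert mi.beta1 == pytest.approx(-0.3)
        assert mi.beta2 == pytest.approx(-0.2)
        assert mi.beta_int == pytest.approx(0.0, abs=1e-12)


class TestModuleInteractionInference:
    @pytest.fixture(scope="class")
    def null_instance(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((400, 30))
        sets = ModuleSets(control=np.arange(200),
                          first_order=np.arange(200, 320),
                          second_order=np.arange(320, 400))
        return Y, sets

    def test_permutation_null_is_mean_zero(self, null_instance):
        Y, sets = null_instance
        rng = np.random.default_rng(2)
        scores = Y[:, :5].mean(axis=1)
        pooled = np.concatenate([sets.control, sets.first_order, sets.second_order])
        bounds = np.cumsum([len(sets.control), len(sets.first_order)])
        draws = []
        for _ in range(400):
            perm = rng.permutation(pooled)
            g0, g1, g2 = np.split(perm, bounds)
            b1 = scores[g1].mean() - scores[g0].mean()
            draws.append(scores[g2].mean() - 2 * b1 - scores[g0].mean())
        draws = np.array(draws)
        assert abs(draws.mean()) <= 3 * draws.std(ddof=1) / np.sqrt(len(draws))

    def test_null_data_gives_large_p(self, null_instance):
        Y, sets = null_instance
        mi = fp.module_interaction(Y, np.arange(5), sets, n_permutations=300,
                                   n_bootstrap=50, seed=3)
        assert mi.p > 0.05

    def test_bootstrap_se_stable_under_doubling(self, null_instance):
        Y, sets = null_instance
        a = fp.module_interaction(Y, np.arange(5), sets, n_permutations=10,
                                  n_bootstrap=500, seed=4)
        b = fp.module_interaction(Y, np.arange(5), sets, n_permutations=10,
                                  n_bootstrap=1000, seed=4)
        assert abs(a.se - b.se) / b.se < 0.10

    def test_empty_set_raises(self, null_instance):
        Y, _ = null_instance
        sets = ModuleSets(control=np.arange(10), first_order=np.array([], int),
                          second_order=np.arange(10, 20))
        with pytest.raises(ValueError, match="non-empty"):
            fp.module_interaction(Y, np.arange(3), sets)


class TestSecondOrderFit:
    def test_empty_pair_design_returns_empty_result(self, tiny_screen,
                                                    tiny_prepared):
        Y, prof, _ = tiny_prepared
        d = tiny_screen.design
        est = fp.FRPerturb(rank=3, mode="guide_pooled",
                           bias_correction=False).fit(d, Y)
        empty = fp.PairDesign(np.zeros((Y.shape[0], 0)), [], 5,
                              fp.count_candidate_pairs(d.n_perturbations))
        res = fp.fit_second_order(Y, d, est.result(), empty)
        assert res.B_hat.shape == (0, Y.shape[1])

    def test_additive_screen_yields_few_second_order_discoveries(self):
        truth = fp.make_truth(12, 150, 2, 3, effect_scale=0.5, seed=30,
                              n_non_targeting=6, n_safe_targeting=6)
        model = fp.make_control_model(150, seed=31)
        scr = fp.simulate_guide_pooled(truth, model, 1200, 2, seed=32)
        Y, prof, _ = fp.prepare_expression(scr.counts, scr.design)
        est = fp.FRPerturb(rank=2, mode="guide_pooled",
                           bias_correction=False).fit(scr.design, Y)
        pd2 = fp.expand_pairwise(scr.design, min_cells=5)
        assert pd2.X2.shape[1] > 0
        res = fp.fit_second_order(Y, scr.design, est.result(), pd2, rank=2,
                                  n_permutations=100, seed=33)
        frac = (res.q_values < 0.05).mean()
        # purely additive truth: second-order discoveries at chance level
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / res.q_values.size)


class TestModuleHelpers:
    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("m1\tdesc\tg1\tg2\nm2\tdesc\tg3\n")
        assert fp.read_gmt(path) == {"m1": ["g1", "g2"], "m2": ["g3"]}

    def test_make_modules_disjoint(self):
        ids = [f"p{i}" for i in range(100)]
        mods = fp.make_modules(ids, 10, 5, seed=0)
        all_members = [g for v in mods.values() for g in v]
        assert len(all_members) == len(set(all_members)) == 50

    def test_module_pair_enumeration(self):
        mods = {f"m{i}": [] for i in range(30)}
        assert len(fp.module_pairs(mods)) == 435

    def test_standardize_expression_zscores(self, rng):
        Y = rng.standard_normal((50, 4)) * 3 + 1
        Z = fp.standardize_expression(Y)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-10)
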