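import numpy as np
import pytest

import frperturb as fp
from frperturb.containers import EffectResult
from frperturb.solvers import elastic_net_prox


class TestElasticNetEffects:
    def test_single_column_matches_prox_oracle(self, rng):
        X = (rng.random((120, 8)) < 0.3).astype(float)
        X[:, -2:] = 0.0
        X[X.sum(axis=1) == 0, 0] = 1.0
        y = rng.standard_normal((120, 1))
        est = fp.ElasticNetEffects(l1=0.05, l2=0.05, mode="guide_pooled",
                                   n_null_perms=0)
        est.fit(X, y)
        oracle = elastic_net_prox(X, y[:, 0], 0.05, 0.05)
        np.testing.assert_allclose(est.effects_[:, 0], oracle, atol=1e-5)

    def test_large_l1_shrinks_to_zero(self, rng):
        X = (rng.random((60, 5)) < 0.4).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1.0
        Y = rng.standard_normal((60, 3))
        est = fp.ElasticNetEffects(l1=1e6, l2=0.00025, mode="guide_pooled",
                                   n_null_perms=0)
        est.fit(X, Y)
        np.testing.assert_allclose(est.effects_, 0.0, atol=1e-10)

    def test_permutation_pvalues_attached(self, tiny_screen, tiny_prepared):
        Y, prof, _ = tiny_prepared
        est = fp.ElasticNetEffects(mode="guide_pooled", n_null_perms=5)
        est.fit(tiny_screen.design, Y)
        assert est.p_values_.shape == est.effects_.shape
        assert (est.p_values_ > 0).all() and (est.p_values_ <= 1).all()
        assert (est.q_values_ >= est.p_values_ - 1e-12).all()

    def test_default_penalties(self):
        est = fp.ElasticNetEffects()
        assert est.l1 == est.l2 == 0.00025


class TestSignConcordance:
    def test_identical_matrices(self, rng):
        B = rng.standard_normal((5, 6))
        assert fp.sign_concordance(B, B) == 1.0

    def test_negated_matrices(self, rng):
        B = rng.standard_normal((5, 6))
        assert fp.sign_concordance(B, -B) == 0.0

    def test_zeros_excluded_from_denominator(self):
        a = np.array([[1.0, 0.0, -2.0, 3.0]])
        b = np.array([[2.0, 5.0, -1.0, 0.0]])
        assert fp.sign_concordance(a, b) == 1.0

    def test_independent_signs_near_half(self, rng):
        a = rng.choice([-1.0, 1.0], size=(100, 100))
        b = rng.choice([-1.0, 1.0], size=(100, 100))
        assert fp.sign_concordance(a, b) == pytest.approx(0.5, abs=0.015)


class TestTopEffectCorrelation:
    def _result(self, B, p=None):
        P, G = B.shape
        return EffectResult(B, [f"p{i}" for i in range(P)],
                            [f"g{j}" for j in range(G)], p_values=p)

    def test_self_correlation_is_one(self, rng):
        B = rng.standard_normal((10, 20))
        p = rng.uniform(size=(10, 20))
        r = fp.top_effect_correlation(self._result(B, p), self._result(B, p), 50)
        assert r == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        B = rng.standard_normal((10, 20))
        p = rng.uniform(size=(10, 20))
        r = fp.top_effect_correlation(self._result(B, p),
                                      self._result(2 * B, p), 50)
        assert r == pytest.approx(1.0)

    def test_selection_uses_significance_ordering(self):
        B = np.array([[0.1, 5.0, 0.2]])
        p = np.array([[0.001, 0.9, 0.5]])
        other = np.array([[0.1, -5.0, 0.2]])
        # top-1 by p is the first entry, where the two results agree in sign;
        # with k=2 the 0.5-p entry joins (ties broken before the large-|b| one)
        rows, cols = fp.evaluate._top_k_order(self._result(B, p), 1)
        assert cols[0] == 0


class TestPrecisionRecall:
    def test_perfect_classifier_auprc_one(self, rng):
        p = rng.uniform(0.5, 1.0, size=100)
        truth = np.zeros(100, dtype=bool)
        best = np.argsort(p)[:20]
        truth[best] = True
        p[best] = p[best] / 1000
        _, _, auprc = fp.precision_recall(p, truth)
        assert auprc == pytest.approx(1.0, abs=1e-6)

    def test_random_pvalues_auprc_near_prevalence(self, rng):
        p = rng.uniform(size=20_000)
        truth = rng.random(20_000) < 0.3
        _, _, auprc = fp.precision_recall(p, truth)
        assert auprc == pytest.approx(0.3, abs=0.02)

    def test_adding_top_discoveries_never_lowers_auprc(self, rng):
        p = rng.uniform(0.2, 1.0, size=200)
        truth = rng.random(200) < 0.25
        _, _, base = fp.precision_recall(p, truth)
        p2 = p.copy()
        extra = np.where(truth)[0][:5]
        p2[extra] = 1e-6  # promote five true effects to the top
        _, _, better = fp.precision_recall(p2, truth)
        assert better >= base - 1e-12

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            fp.precision_recall(np.array([0.5]), np.array([False]))


class TestDownsampleHarness:
    @pytest.fixture(scope="class")
    def screen(self):
        truth = fp.make_truth(10, 120, 2, 3, effect_scale=0.6, seed=50,
                              n_non_targeting=5, n_safe_targeting=5)
        model = fp.make_control_model(120, seed=51)
        scr = fp.simulate_guide_pooled(truth, model, 800, 2, seed=52)
        Y, prof, _ = fp.prepare_expression(scr.counts, scr.design)
        return scr, Y, prof

    def test_full_fraction_equals_full_train_fit(self, screen):
        scr, Y, prof = screen
        table = fp.downsample_harness(
            Y, scr.design, fractions=[1.0], seeds=[0], mode="guide_pooled",
            control_level=prof.level, top_k=200,
            estimator_kwargs={"rank": 2},
        )
        n = Y.shape[0]
        rng = np.random.default_rng(0)
        order = rng.permutation(n)
        train, held = np.sort(order[: n // 2]), np.sort(order[n // 2 :])
        assert set(train) & set(held) == set()
        ref = fp.FRPerturb(rank=2, mode="guide_pooled", random_state=0).fit(
            scr.design.X[held], Y[held], control_level=prof.level)
        full = fp.FRPerturb(rank=2, mode="guide_pooled", random_state=0).fit(
            scr.design.X[train], Y[train], control_level=prof.level)
        expected = fp.sign_concordance(full.effects_, ref.effects_)
        assert table["sign_concordance"].iloc[0] == pytest.approx(expected)
        assert table["n_droplets"].iloc[0] == len(train)

    def test_metrics_trend_upward_with_fraction(self, screen):
        scr, Y, prof = screen
        table = fp.downsample_harness(
            Y, scr.design, fractions=[0.25, 1.0], seeds=[0, 1, 2],
            mode="guide_pooled", control_level=prof.level, top_k=200,
            estimator_kwargs={"rank": 2},
        )
        means = table.groupby("fraction")["top_k_pearson_r"].mean()
        assert means.loc[1.0] >= means.loc[0.25]

    def test_invalid_fraction_raises(self, screen):
        scr, Y, prof = screen
        with pytest.raises(ValueError):
            fp.downsample_harness(Y, scr.design, fractions=[0.0], seeds=[0],
                                  estimator_kwargs={"rank": 2})


def test_fr_replicates_better_than_elastic_net_across_halves():
    """Held-out replication on composite (guide-pooled) screens: the top
    effects estimated by factorize-recover correlate better across random
    sample halves than the per-gene elastic net's, at equal sample size."""

    def replication_r(est_cls, kwargs, Y, X, halves, k=500):
        fits = [est_cls(**kwargs).fit(X[h], Y[h]) for h in halves]
        results = [
            EffectResult(f.effects_,
                         [str(i) for i in range(f.effects_.shape[0])],
                         [str(j) for j in range(f.effects_.shape[1])])
            for f in fits
        ]
        return fp.top_effect_correlation(results[0], results[1], k)

    wins = 0
    seeds = [60, 61, 62, 63, 64]
    for seed in seeds:
        truth = fp.make_truth(30, 300, 3, 5, effect_scale=0.6, seed=seed,
                              n_non_targeting=8, n_safe_targeting=8)
        model = fp.make_control_model(300, seed=seed + 1)
        scr = fp.simulate_guide_pooled(truth, model, 1600, 3, seed=seed + 2)
        Y, _, _ = fp.prepare_expression(scr.counts, scr.design)
        n = Y.shape[0]
        order = np.random.default_rng(seed).permutation(n)
        halves = (np.sort(order[: n // 2]), np.sort(order[n // 2 :]))
        r_fr = replication_r(
            fp.FRPerturb,
            dict(rank=3, mode="guide_pooled", bias_correction=False),
            Y, scr.design.X, halves)
        r_en = replication_r(
            fp.ElasticNetEffects,
            dict(mode="guide_pooled", n_null_perms=0),
            Y, scr.design.X, halves)
        if r_fr > r_en:
            wins += 1
    assert wins >= 4
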