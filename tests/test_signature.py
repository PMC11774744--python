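"""Logistic fits, ROC-AUC, CV, and the gated beam search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemosig as cs
from chemosig.signature import _gate, _newton_logistic


def make_cohort(X, y, genes=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    expr = cs.ExpressionMatrix(genes, [f"p{j}" for j in range(X.shape[1])],
                               X, "external_normalized")
    return cs.LabeledCohort(expr, np.asarray(y))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        cohort = make_cohort(np.zeros((1, 100)) + np.arange(100) * 0, y)
        m = cs.fit_logistic([], cohort)
        assert m.intercept == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 200))
        eta = 0.8 * X[0] - 0.5 * X[1]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(int)
        cohort = make_cohort(X, y)
        m = cs.fit_logistic(["g0", "g1", "g2"], cohort)
        ref = sm.GLM(y, sm.add_constant(X.T), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(m.intercept, ref.params[0], atol=1e-6)
        np.testing.assert_allclose(m.coefficients, ref.params[1:], atol=1e-6)
        np.testing.assert_allclose(m.p_values, ref.pvalues[1:], atol=1e-6)

    def test_perfect_separation_flagged(self):
        X = np.concatenate([np.linspace(-2, -1, 20), np.linspace(1, 2, 20)])[None, :]
        y = np.array([0] * 20 + [1] * 20)
        m = cs.fit_logistic(["g0"], make_cohort(X, y))
        assert m.separation

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            cs.fit_logistic(["g0"], make_cohort(np.ones((1, 10)), np.ones(10)))

    def test_null_gene_wald_p_uniform(self):
        """Fraction of null-gene Wald p < 0.05 consistent with 5% (200 sims)."""
        rng = np.random.default_rng(31)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            X = rng.standard_normal((1, 500))
            y = rng.integers(0, 2, 500)
            m = cs.fit_logistic(["g0"], make_cohort(X, y))
            hits += m.p_values[0] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(hits / n_sim - 0.05) < 3 * se


def auc_pair_oracle(scores, labels):
    """Exhaustive concordant/discordant pair enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


class TestRocAuc:
    def test_perfect_separation(self):
        assert cs.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_half_concordant(self):
        assert cs.roc_auc([0.9, 0.4, 0.6, 0.2], [1, 0, 0, 1]) == pytest.approx(0.5)
        assert auc_pair_oracle([0.9, 0.4, 0.6, 0.2], [1, 0, 0, 1]) == 0.5

    def test_all_tied_scores(self):
        assert cs.roc_auc([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cs.roc_auc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_pair_counting_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        scores = data.draw(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                                    min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        got = cs.roc_auc(scores, labels)
        assert got == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=25, deadline=None)
    def test_score_negation_complements_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(10)
        labels = np.array([0, 1] * 5)
        assert cs.roc_auc(scores, labels) + cs.roc_auc(-scores, labels) == \
            pytest.approx(1.0)


class TestCvAuc:
    def test_deterministic_given_seed(self, labeled_cohort):
        cfg = cs.SearchConfig(seed=7)
        a = cs.cv_auc(["STRONG"], labeled_cohort, cfg)
        b = cs.cv_auc(["STRONG"], labeled_cohort, cfg)
        assert a == b

    def test_null_genes_near_half(self):
        """Mean CV AUC of unrelated genes stays near 0.5 (50 simulations)."""
        rng = np.random.default_rng(17)
        vals = []
        cfg = cs.SearchConfig(seed=5, cv_repeats=2)
        for _ in range(50):
            X = rng.standard_normal((1, 300))
            y = rng.integers(0, 2, 300)
            vals.append(cs.cv_auc(["g0"], make_cohort(X, y), cfg))
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_planted_strong_gene_detected(self):
        """log-OR 2/SD gene reaches CV AUC > 0.75 in >= 95% of 50 draws."""
        rng = np.random.default_rng(23)
        wins = 0
        cfg = cs.SearchConfig(seed=5, cv_repeats=2)
        for _ in range(50):
            x = rng.standard_normal(300)
            y = (rng.random(300) < 1 / (1 + np.exp(-2 * x))).astype(int)
            wins += cs.cv_auc(["g0"], make_cohort(x[None, :], y), cfg) > 0.75
        assert wins >= 0.95 * 50

    def test_class_too_small_to_stratify(self):
        y = np.array([1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="stratify"):
            cs.cv_auc(["g0"], make_cohort(np.random.default_rng(0).standard_normal((1, 6)), y),
                      cs.SearchConfig(cv_folds=3))


class TestGate:
    def mk(self, genes, pvals, **kw):
        k = len(genes)
        return cs.GeneSignatureModel(genes, 0.0, np.zeros(k), np.array(pvals),
                                     train_auc=0.5, **kw)

    def test_new_gene_above_p_new_dropped(self):
        m = self.mk(("A", "B"), [0.01, 0.20])
        assert not _gate(m, {"B"}, cs.SearchConfig())

    def test_retained_gene_above_p_retained_dropped(self):
        m = self.mk(("A", "B"), [0.08, 0.01])
        assert not _gate(m, {"B"}, cs.SearchConfig())

    def test_marginal_new_gene_kept(self):
        m = self.mk(("A", "B"), [0.01, 0.10])
        assert _gate(m, {"B"}, cs.SearchConfig())

    def test_any_order_attribution_may_pass(self):
        # weakest gene is A; passes only if A can be the newly added gene
        m = self.mk(("A", "B"), [0.10, 0.01])
        assert _gate(m, {"A", "B"}, cs.SearchConfig())
        assert not _gate(m, {"B"}, cs.SearchConfig())

    def test_separated_fit_fails_gate(self):
        m = self.mk(("A",), [0.001], separation=True)
        assert not _gate(m, {"A"}, cs.SearchConfig())


class TestBeamSearch:
    def make_planted(self, seed=0, n=160, pool=12, planted=3, beta=1.2):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((pool, n))
        eta = beta * X[:planted].sum(axis=0)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return make_cohort(X, y)

    def test_candidate_dedup_counts(self):
        cohort = self.make_planted(seed=3, pool=3, planted=2, n=200)
        cfg = cs.SearchConfig(seed=1, keep_fraction=1.0, cv_repeats=1)
        survivors = [cs.fit_logistic((g,), cohort) for g in ["g0", "g1"]]
        for m in survivors:
            m.cv_auc = 0.6
        counts = {}
        from chemosig.signature import beam_step
        beam_step(survivors, ["g0", "g1", "g2"], cohort, cfg, _counts=counts)
        assert counts["raw_candidates"] == 4   # {g0}+g1,g2 and {g1}+g0,g2
        assert counts["unique_candidates"] == 3  # {g0,g1}, {g0,g2}, {g1,g2}

    def test_max_size_one_boundary(self):
        cohort = self.make_planted(seed=4)
        reg = cs.search_signatures(cohort, cohort.expr.gene_ids,
                                   cs.SearchConfig(max_size=1, seed=2, cv_repeats=2))
        assert set(reg.models_by_size) == {1}

    def test_empty_pool_rejected(self):
        cohort = self.make_planted()
        with pytest.raises(ValueError, match="empty"):
            cs.search_signatures(cohort, [], cs.SearchConfig())

    def test_registry_models_refit_clean_and_unique(self):
        cohort = self.make_planted(seed=5)
        cfg = cs.SearchConfig(seed=9, max_size=4, cv_repeats=2)
        reg = cs.search_signatures(cohort, cohort.expr.gene_ids, cfg)
        seen = set()
        for m in reg.models:
            key = frozenset(m.genes)
            assert key not in seen
            seen.add(key)
            refit = cs.fit_logistic(m.genes, cohort)
            np.testing.assert_allclose(refit.coefficients, m.coefficients,
                                       atol=1e-8)
            # gate predicate: at most one gene in [p_retained, p_new)
            p = refit.p_values
            assert np.all(p < cfg.p_new)
            assert (p >= cfg.p_retained).sum() <= 1

    def test_bit_reproducible(self):
        cohort = self.make_planted(seed=6)
        cfg = cs.SearchConfig(seed=13, max_size=3, cv_repeats=2)
        r1 = cs.search_signatures(cohort, cohort.expr.gene_ids, cfg)
        r2 = cs.search_signatures(cohort, cohort.expr.gene_ids, cfg)
        assert [m.genes for m in r1.models] == [m.genes for m in r2.models]
        for a, b in zip(r1.models, r2.models):
            assert a.cv_auc == b.cv_auc
            np.testing.assert_array_equal(a.coefficients, b.coefficients)


class TestSelectBest:
    def test_single_passing_model_selected(self):
        cohort = TestBeamSearch().make_planted(seed=7)
        train, test = cs.split_cohort(cohort.expr, cohort.y.astype(int), seed=7)
        cfg = cs.SearchConfig(seed=7, max_size=3, cv_repeats=2,
                              auc_select_threshold=0.6)
        reg = cs.search_signatures(train, train.expr.gene_ids, cfg)
        sel = cs.select_best(reg, train, test, cfg)
        assert sel.model is not None
        # chosen model maximizes cv_auc among threshold passers
        passing = [m for m in reg.models
                   if m.train_auc > 0.6 and m.test_auc > 0.6]
        assert sel.model.cv_auc == max(m.cv_auc for m in passing)

    def test_no_model_meets_threshold(self):
        cohort = TestBeamSearch().make_planted(seed=8)
        train, test = cs.split_cohort(cohort.expr, cohort.y.astype(int), seed=8)
        cfg = cs.SearchConfig(seed=8, max_size=2, cv_repeats=2,
                              auc_select_threshold=0.999)
        reg = cs.search_signatures(train, train.expr.gene_ids, cfg)
        sel = cs.select_best(reg, train, test, cfg)
        assert sel.model is None
        assert not sel.threshold_attained
        assert sel.n_passing == 0


class TestClassify:
    def test_probability_half_is_favorable(self):
        m = cs.GeneSignatureModel(("g0",), 0.0, [0.0], [0.5], train_auc=0.5)
        expr = cs.ExpressionMatrix(["g0"], ["p0"], np.array([[3.0]]),
                                   "external_normalized")
        labels, prob = cs.classify(m, expr)
        assert prob[0] == pytest.approx(0.5)
        assert labels[0] == cs.FAVORABLE

    def test_large_intercept_all_unfavorable(self):
        m = cs.GeneSignatureModel((), 10.0, [], [], train_auc=0.5)
        expr = cs.ExpressionMatrix(["g0"], ["a", "b"], np.zeros((1, 2)),
                                   "external_normalized")
        labels, prob = cs.classify(m, expr)
        assert (labels == cs.UNFAVORABLE).all()

    def test_missing_gene_listed(self):
        m = cs.GeneSignatureModel(("gX",), 0.0, [1.0], [0.5], train_auc=0.5)
        expr = cs.ExpressionMatrix(["g0"], ["a"], np.zeros((1, 1)),
                                   "external_normalized")
        with pytest.raises(KeyError, match="gX"):
            cs.classify(m, expr)

    def test_reproduces_train_auc_on_training_cohort(self, labeled_cohort):
        m = cs.fit_logistic(["STRONG", "NULL1"], labeled_cohort)
        _, prob = cs.classify(m, labeled_cohort.expr)
        assert cs.roc_auc(prob, labeled_cohort.y) == pytest.approx(m.train_auc)


class TestSplitCohort:
    def test_stratified_fractions(self):
        y = np.array([1] * 40 + [0] * 60)
        expr = cs.ExpressionMatrix(["g0"], [f"p{i}" for i in range(100)],
                                   np.zeros((1, 100)), "external_normalized")
        train, test = cs.split_cohort(expr, y, train_fraction=0.7, seed=1)
        assert train.y.sum() == 28 and test.y.sum() == 12
        assert train.expr.n_samples == 70

    def test_model_json_round_trip(self, tmp_path):
        m = cs.GeneSignatureModel(("a", "b"), 0.3, [1.0, -2.0], [0.01, 0.04],
                                  train_auc=0.9, cv_auc=0.8)
        path = tmp_path / "m.json"
        cs.save_model(m, path)
        back = cs.load_model(path)
        assert back.genes == m.genes
        np.testing.assert_array_equal(back.coefficients, m.coefficients)
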