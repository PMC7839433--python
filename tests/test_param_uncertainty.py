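import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ubn import (
    SENTINEL,
    Cpt,
    DirichletRow,
    EnhancedBn,
    EnhancedCpt,
    InputError,
    NodeSpec,
    PropagationError,
    Query,
    build_network,
    classify_network,
    ClassificationAnswers,
    collapse_to_aleatory,
    collapse_to_predictive,
    eliminate_query,
    generate_fixture,
    make_enhanced,
    make_enhanced_bn,
    propagate,
    sample_cpts,
    summarize,
    update_from_cases,
    Evidence,
)


class TestMakeEnhanced:
    def test_alpha_is_s_times_t(self):
        ecpt = make_enhanced(Cpt("X", {(): (0.5, 0.5)}), s=4.0)
        assert ecpt.rows[()].concentration == (2.0, 2.0)

    def test_three_state_alpha_sums_to_s(self):
        ecpt = make_enhanced(Cpt("X", {(): (0.2, 0.3, 0.5)}), s=10.0)
        assert ecpt.rows[()].concentration == pytest.approx((2.0, 3.0, 5.0))
        assert sum(ecpt.rows[()].concentration) == pytest.approx(10.0)

    def test_zero_mass_state_with_finite_s_rejected(self):
        with pytest.raises(InputError, match="zero"):
            make_enhanced(Cpt("X", {(): (1.0, 0.0)}), s=5.0)

    def test_zero_mass_state_allowed_under_sentinel(self):
        ecpt = make_enhanced(Cpt("X", {(): (1.0, 0.0)}), s=SENTINEL)
        assert ecpt.rows[()].is_sentinel

    def test_nonpositive_s_rejected(self):
        with pytest.raises(InputError):
            make_enhanced(Cpt("X", {(): (0.5, 0.5)}), s=0.0)


class TestUpdateFromCases:
    def _root_enhanced(self, alpha=(1.0, 1.0)):
        s = sum(alpha)
        m = build_network(
            [NodeSpec("X", ("x1", "x2"))],
            [Cpt("X", {(): tuple(a / s for a in alpha)})],
        )
        return make_enhanced_bn(m, s)

    def test_zero_cases_leaves_model_unchanged(self):
        e = self._root_enhanced()
        updated = update_from_cases(e, pd.DataFrame({"X": []}, dtype=str))
        assert updated.enhanced_cpts["X"].rows[()] == e.enhanced_cpts["X"].rows[()]

    def test_conjugate_posterior_closed_form(self):
        """alpha=(1,1) + counts (3,1) -> alpha'=(4,2), mean (2/3, 1/3)."""
        e = self._root_enhanced((1.0, 1.0))
        cases = pd.DataFrame({"X": ["x1"] * 3 + ["x2"]})
        updated = update_from_cases(e, cases)
        row = updated.enhanced_cpts["X"].rows[()]
        assert row.concentration == pytest.approx((4.0, 2.0))
        assert row.mean == pytest.approx((2 / 3, 1 / 3))
        assert row.equivalent_sample_size == pytest.approx(6.0)

    def test_child_counts_tallied_within_parent_configuration(self):
        """Row totals equal the number of cases with that configuration."""
        a = NodeSpec("A", ("a1", "a2"))
        b = NodeSpec("B", ("b1", "b2"), parents=("A",))
        m = build_network(
            [a, b],
            [
                Cpt("A", {(): (0.5, 0.5)}),
                Cpt("B", {("a1",): (0.5, 0.5), ("a2",): (0.5, 0.5)}),
            ],
        )
        e = make_enhanced_bn(m, 2.0)
        cases = pd.DataFrame(
            {
                "A": ["a1", "a1", "a1", "a2", "a2", "a1", "a2", "a1", "a2", "a1"],
                "B": ["b1", "b2", "b1", "b2", "b2", "b1", "b1", "b2", "b2", "b1"],
            }
        )
        updated = update_from_cases(e, cases)
        rows = updated.enhanced_cpts["B"].rows
        n_a1 = (cases["A"] == "a1").sum()
        n_a2 = (cases["A"] == "a2").sum()
        assert rows[("a1",)].equivalent_sample_size == pytest.approx(2.0 + n_a1)
        assert rows[("a2",)].equivalent_sample_size == pytest.approx(2.0 + n_a2)
        # per-state counts inside the a1 configuration
        n_b1_a1 = ((cases["A"] == "a1") & (cases["B"] == "b1")).sum()
        assert rows[("a1",)].concentration[0] == pytest.approx(1.0 + n_b1_a1)

    def test_unknown_state_label_rejected(self):
        e = self._root_enhanced()
        with pytest.raises(InputError, match="X"):
            update_from_cases(e, pd.DataFrame({"X": ["weird"]}))

    def test_missing_values_rejected(self):
        e = self._root_enhanced()
        with pytest.raises(InputError, match="missing"):
            update_from_cases(e, pd.DataFrame({"X": ["x1", None]}))


class TestSampleAndCollapse:
    def test_sentinel_rows_sample_to_mean_exactly(self, chain_model):
        e = make_enhanced_bn(chain_model, SENTINEL)
        sampled = sample_cpts(e, seed=3)
        collapsed = collapse_to_aleatory(e)
        assert sampled.cpts == collapsed.cpts

    def test_sampled_rows_sum_to_one(self):
        e, _ = generate_fixture(4, seed=11, enhanced_s_range=(2.0, 8.0))
        sampled = sample_cpts(e, seed=5)
        for cpt in sampled.cpts.values():
            for row in cpt.rows.values():
                assert math.fsum(row) == pytest.approx(1.0, abs=1e-9)

    def test_sampling_deterministic_under_seed(self):
        e, _ = generate_fixture(3, seed=2, enhanced_s_range=(2.0, 8.0))
        assert sample_cpts(e, seed=9).cpts == sample_cpts(e, seed=9).cpts

    def test_empirical_mean_matches_dirichlet_moments(self):
        m = build_network(
            [NodeSpec("X", ("x1", "x2"))], [Cpt("X", {(): (0.5, 0.5)})]
        )
        e = make_enhanced_bn(m, 4.0)  # alpha = (2, 2)
        rng = np.random.default_rng(0)
        rng_draws = [sample_cpts(e, rng).cpts["X"].rows[()][0] for _ in range(10_000)]
        mean = float(np.mean(rng_draws))
        se = math.sqrt(1 / 20) / math.sqrt(10_000)  # Var Beta(2,2) = 1/20
        assert abs(mean - 0.5) < 3 * se

    def test_collapse_mean_formula(self):
        row = DirichletRow(mean=(2 / 3, 1 / 3), equivalent_sample_size=6.0)
        assert row.concentration == pytest.approx((4.0, 2.0))
        m = build_network(
            [NodeSpec("X", ("x1", "x2"))], [Cpt("X", {(): (2 / 3, 1 / 3)})]
        )
        e = EnhancedBn(base=m, enhanced_cpts={"X": EnhancedCpt("X", {(): row})})
        collapsed = collapse_to_aleatory(e)
        assert collapsed.cpts["X"].rows[()] == pytest.approx((2 / 3, 1 / 3))

    def test_collapse_round_trips_make_enhanced(self, three_chain_model):
        e = make_enhanced_bn(three_chain_model, 7.5)
        collapsed = collapse_to_aleatory(e)
        for name, cpt in three_chain_model.cpts.items():
            for key, row in cpt.rows.items():
                assert collapsed.cpts[name].rows[key] == pytest.approx(row, abs=1e-15)

    def test_predictive_tables_equal_aleatory_with_different_tag(self, chain_model):
        e = make_enhanced_bn(chain_model, 5.0)
        aleatory = collapse_to_aleatory(e)
        predictive = collapse_to_predictive(e)
        assert predictive.cpts == aleatory.cpts
        assert predictive.bn_type == "predictive"
        assert "no clear separation" in predictive.provenance

    def test_predictive_result_classifies_as_predictive(self):
        tag, _ = classify_network(
            ClassificationAnswers(
                models_unique_event=False,
                quantities_uncertain=True,
                informed_by="both",
                parameters_known=False,
                case_learning_inside=False,
                parameters_marginalized_into_variables=True,
            )
        )
        assert tag == "predictive"


class TestPropagate:
    def test_sentinel_model_gives_point_distribution(self, chain_model):
        e = make_enhanced_bn(chain_model, SENTINEL)
        q = Query("B", ("b1",))
        point = eliminate_query(chain_model, q)
        qu = propagate(e, q, draws=50, seed=1)
        assert all(x == pytest.approx(point, abs=1e-12) for x in qu.samples)

    def test_uniform_prior_on_binary_root_gives_uniform_query(self):
        """With alpha=(1,1) the query probability is exactly Beta(1,1)."""
        m = build_network(
            [NodeSpec("X", ("x1", "x2"))], [Cpt("X", {(): (0.5, 0.5)})]
        )
        e = make_enhanced_bn(m, 2.0)  # alpha = (1, 1)
        qu = propagate(e, Query("X", ("x1",)), draws=10_000, seed=42)
        x = np.asarray(qu.samples)
        se = math.sqrt(1 / 12) / math.sqrt(len(x))
        assert abs(x.mean() - 0.5) < 3 * se
        assert stats.kstest(x, "uniform").pvalue > 0.01

    def test_reproducible_under_seed(self):
        e, _ = generate_fixture(4, seed=8, enhanced_s_range=(3.0, 9.0))
        q = Query(e.base.node_names()[-1], (e.base.node(e.base.node_names()[-1]).states[0],))
        qu1 = propagate(e, q, draws=100, seed=7)
        qu2 = propagate(e, q, draws=100, seed=7)
        assert qu1.samples == qu2.samples

    def test_no_evidence_mean_matches_collapsed_query(self):
        """The no-evidence query probability is multilinear in independent
        rows, so its expectation equals the query at the mean tables."""
        e, _ = generate_fixture(4, seed=21, enhanced_s_range=(3.0, 10.0))
        target = e.base.node_names()[-1]
        q = Query(target, (e.base.node(target).states[0],))
        qu = propagate(e, q, draws=4000, seed=3)
        x = np.asarray(qu.samples)
        collapsed = eliminate_query(collapse_to_aleatory(e), q)
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - collapsed) < 3 * se

    def test_with_evidence_collapsed_query_within_envelope(self):
        e, _ = generate_fixture(4, seed=33, enhanced_s_range=(3.0, 10.0))
        names = e.base.node_names()
        target = names[-1]
        ev = (Evidence.hard(names[0], e.base.node(names[0]).states[0]),)
        q = Query(target, (e.base.node(target).states[0],), ev)
        qu = propagate(e, q, draws=1000, seed=4)
        collapsed = eliminate_query(collapse_to_aleatory(e), q)
        assert min(qu.samples) <= collapsed <= max(qu.samples)

    def test_all_draws_inconsistent_is_propagation_error(self):
        m = build_network(
            [NodeSpec("X", ("x1", "x2"))], [Cpt("X", {(): (0.0, 1.0)})]
        )
        e = make_enhanced_bn(m, SENTINEL)
        q = Query("X", ("x2",), (Evidence.hard("X", "x1"),))
        with pytest.raises(PropagationError):
            propagate(e, q, draws=10, seed=0)


class TestSummarize:
    def _qu(self, samples, seed=0):
        from ubn import QueryUncertainty

        return QueryUncertainty(
            samples=tuple(samples),
            draw_count=len(samples),
            seed=seed,
            query=Query("X", ("x1",), name="risk of extinction"),
        )

    def test_degenerate_samples_give_full_certainty(self):
        s = summarize(self._qu([0.03] * 20), thresholds=(0.05,))
        assert s["certainty"][0.05] == pytest.approx(1.0)
        assert "less than 5%" in s["statements"][0]

    def test_certainty_is_fraction_strictly_below_threshold(self):
        samples = [0.005 + 0.0009545454545454546 * i for i in range(100)]
        expected = sum(1 for x in samples if x < 0.05) / 100
        s = summarize(self._qu(samples), thresholds=(0.05,))
        assert s["certainty"][0.05] == pytest.approx(expected)

    def test_statement_template_at_ninety_percent(self):
        samples = [0.01] * 90 + [0.99] * 10
        s = summarize(self._qu(samples), thresholds=(0.05,))
        assert s["certainty"][0.05] == pytest.approx(0.90)
        assert (
            "we are 90% certain that the risk of extinction is less than 5%"
            in s["statements"][0]
        )

    def test_equal_tailed_interval(self):
        samples = list(np.linspace(0, 1, 1001))
        s = summarize(self._qu(samples), interval_levels=(0.90,))
        lo, hi = s["intervals"][0.90]
        assert lo == pytest.approx(0.05, abs=1e-9)
        assert hi == pytest.approx(0.95, abs=1e-9)

    def test_mean_flagged_as_composite(self):
        s = summarize(self._qu([0.1, 0.2]))
        assert "composite probability" in s["composite_caveat"]

    def test_empty_samples_rejected(self):
        from ubn import QueryUncertainty

        qu = QueryUncertainty(samples=(), draw_count=0, seed=0,
                              query=Query("X", ("x1",)))
        with pytest.raises(InputError):
            summarize(qu)
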