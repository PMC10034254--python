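"""Utility metrics: Hellinger, transition matrices, multivariate distance,
random-cohort fuzzing, SMD and CI overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longsynth import (Cohort, DiscreteDistribution, attribute_hellinger,
                       ci_overlap, compare_transition_matrices,
                       estimate_transition_matrix,
                       event_distribution_hellinger, hellinger,
                       multivariate_hellinger, random_cohort_assessment,
                       sequence_length_report, simulate_cohort, small_spec,
                       smd_binary, smd_continuous, summarize,
                       true_transition_matrix)
from longsynth.utility import normalized_euclidean, numeric_event_table


def _dist(*probs):
    return DiscreteDistribution(support=list(range(len(probs))),
                                probs=np.asarray(probs))


class TestHellinger:
    def test_identity_and_disjoint(self):
        p = _dist(0.2, 0.8)
        assert hellinger(p, p) == 0.0
        q = DiscreteDistribution(support=["x", "y"], probs=[0.5, 0.5])
        assert hellinger(p, q) == pytest.approx(1.0)

    def test_two_point_closed_form(self):
        p = _dist(0.5, 0.5)
        q = _dist(0.9, 0.1)
        expect = np.sqrt(1 - (np.sqrt(0.45) + np.sqrt(0.05)))
        assert hellinger(p, q) == pytest.approx(expect, abs=1e-12)
        assert hellinger(p, q) == pytest.approx(0.3249, abs=5e-5)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            _dist(0.5, 0.6)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
           st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
           st.lists(st.floats(0.01, 1), min_size=3, max_size=3))
    def test_metric_properties(self, a, b, c):
        """Symmetry, identity of indiscernibles, triangle inequality."""
        p, q, r = (_dist(*(np.asarray(v) / np.sum(v))) for v in (a, b, c))
        dpq = hellinger(p, q)
        assert 0 <= dpq <= 1
        assert dpq == pytest.approx(hellinger(q, p), abs=1e-12)
        assert hellinger(p, p) == 0
        assert dpq <= hellinger(p, r) + hellinger(r, q) + 1e-9


class TestCohortComparisons:
    def test_identical_cohorts_all_zero(self, sim_cohort, sim_spec):
        assert event_distribution_hellinger(sim_cohort, sim_cohort) == 0.0
        rep = sequence_length_report(sim_cohort, sim_cohort)
        assert rep["percent_diff"] == 0.0
        ah = attribute_hellinger(sim_cohort, sim_cohort, sim_spec.schema)
        assert all(v == 0 for v in ah["per_attribute"].values())

    def test_doubling_lengths_gives_100_percent(self, sim_cohort):
        doubled = Cohort(
            baseline=sim_cohort.baseline,
            events=pd.concat([sim_cohort.events, sim_cohort.events],
                             ignore_index=True),
            schema=sim_cohort.schema)
        rep = sequence_length_report(sim_cohort, doubled)
        assert rep["percent_diff"] == pytest.approx(100.0)

    def test_mean_comparison_example(self):
        """Means 58.14 vs 58.39 differ by ~0.43%."""
        diff = 100 * abs(58.39 - 58.14) / 58.14
        assert diff == pytest.approx(0.43, abs=0.005)

    def test_label_swap_between_equal_frequency_cohorts(self, toy_schema):
        """Swapping two equally frequent labels leaves the pooled marginal
        unchanged, so the event-distribution distance stays 0."""
        def mk(labels):
            ev = pd.DataFrame({
                "pid": 0, "pos": range(len(labels)), "label": labels,
                "date": range(len(labels)), "sojourn": 0.0,
                "lab_result": np.nan, "triage": np.nan})
            return Cohort(pd.DataFrame({"pid": [0]}), ev, toy_schema)
        real = mk(["LAB", "ED"] * 4)
        swapped = mk(["ED", "LAB"] * 4)
        assert event_distribution_hellinger(real, swapped) == 0.0

    def test_hand_tabulated_two_label_cohorts(self, toy_schema):
        def mk(labels):
            ev = pd.DataFrame({
                "pid": 0, "pos": range(len(labels)), "label": labels,
                "date": range(len(labels)), "sojourn": 0.0,
                "lab_result": np.nan, "triage": np.nan})
            return Cohort(pd.DataFrame({"pid": [0]}), ev, toy_schema)
        real = mk(["LAB"] * 3 + ["ED"] * 1)
        syn = mk(["LAB"] * 1 + ["ED"] * 1)
        expect = np.sqrt(1 - (np.sqrt(0.75 * 0.5) + np.sqrt(0.25 * 0.5)))
        assert event_distribution_hellinger(real, syn) == \
            pytest.approx(expect, abs=1e-12)

    def test_attribute_absent_from_synthetic_scores_one(self, toy_schema,
                                                        toy_cohort):
        from longsynth import compute_sojourn
        real = compute_sojourn(toy_cohort)
        syn_events = real.events[real.events.label != "ED"].reset_index(
            drop=True)
        syn = Cohort(real.baseline, syn_events, toy_schema)
        ah = attribute_hellinger(real, syn, toy_schema)
        assert ah["per_attribute"]["triage"] == 1.0

    def test_relevance_filtering_matches_bruteforce(self, toy_schema,
                                                    toy_cohort):
        from longsynth import compute_sojourn
        real = compute_sojourn(toy_cohort)
        syn = Cohort(real.baseline, real.events.copy(), toy_schema)
        syn.events.loc[syn.events.label == "ED", "triage"] = "1"
        ah = attribute_hellinger(real, syn, toy_schema)
        rv = real.events.loc[real.events.label == "ED", "triage"]
        sv = syn.events.loc[syn.events.label == "ED", "triage"]
        expect = hellinger(DiscreteDistribution.from_values(rv),
                           DiscreteDistribution.from_values(sv))
        assert ah["per_attribute"]["triage"] == pytest.approx(expect)


class TestTransitionMatrices:
    def test_first_order_window_counts(self):
        tm = estimate_transition_matrix([["A", "B", "A", "B", "C"]], k=1)
        assert tm.row(("A",))["B"] == 1.0
        assert tm.row(("B",))["A"] == 0.5
        assert tm.row(("B",))["C"] == 0.5

    def test_second_order_window_counts(self):
        tm = estimate_transition_matrix([["A", "B", "A", "B", "C"]], k=2)
        assert set(tm.contexts) == {("A", "B"), ("B", "A")}
        assert tm.row(("A", "B")).to_dict() == \
            pytest.approx({"A": 0.5, "B": 0.0, "C": 0.5})
        assert tm.row(("B", "A"))["B"] == 1.0

    def test_rows_sum_to_one(self, sim_cohort):
        for k in (1, 2):
            tm = estimate_transition_matrix(sim_cohort, k)
            assert np.allclose(tm.probs.sum(axis=1), 1.0)

    def test_windows_never_cross_individuals(self):
        tm = estimate_transition_matrix([["A", "B"], ["C", "A"]], k=1)
        assert ("B",) not in tm.contexts  # B ended the first individual

    def test_terminal_never_in_context(self, sim_cohort):
        tm = estimate_transition_matrix(sim_cohort, k=2)
        assert all("EOS" not in ctx for ctx in tm.contexts)

    def test_self_comparison_is_zero(self, sim_cohort):
        tm = estimate_transition_matrix(sim_cohort, 1)
        cmp = compare_transition_matrices(tm, tm)
        assert cmp["summary"]["mean"] == 0.0

    def test_printed_second_order_example_self_identity(self):
        """A published-style order-2 matrix compared with itself gives 0."""
        rows = {
            ("A", "B"): [0.31, 0.29, 0.39, 0.00],
            ("B", "A"): [0.42, 0.21, 0.22, 0.16],
            ("A", "D"): [0.64, 0.11, 0.08, 0.18],
            ("D", "A"): [0.38, 0.05, 0.23, 0.34],
            ("B", "D"): [0.41, 0.31, 0.26, 0.02],
            ("D", "B"): [0.01, 0.16, 0.57, 0.26],
            ("A", "A"): [0.20, 0.40, 0.30, 0.10],
            ("B", "B"): [0.36, 0.34, 0.25, 0.04],
            ("D", "D"): [0.34, 0.48, 0.17, 0.01],
        }
        from longsynth.utility import TransitionMatrix
        probs = pd.DataFrame.from_dict(rows, orient="index",
                                       columns=list("ABCD"))
        probs.index = pd.Index(list(rows), tupleize_cols=False)
        tm = TransitionMatrix(order=2, probs=probs, counts=probs * 100)
        assert all("C" not in ctx for ctx in tm.contexts)  # C is terminal
        cmp = compare_transition_matrices(tm, tm)
        assert cmp["summary"]["mean"] == 0.0

    def test_disjoint_row_scores_one(self):
        a = estimate_transition_matrix([["A", "A", "A", "B", "B", "B"]], k=1)
        b = estimate_transition_matrix([["A", "A", "A", "B", "C", "C"]], k=1)
        cmp = compare_transition_matrices(a, b)
        assert cmp["per_row"][("A",)] == 0.0  # same row in both
        # B's rows are disjoint: {B} vs {C}
        assert cmp["per_row"][("B",)] == pytest.approx(1.0)

    def test_unmatched_context_policies(self):
        a = estimate_transition_matrix([["A", "B", "A"]], k=1)
        b = estimate_transition_matrix([["A", "B", "C", "B"]], k=1)
        scored = compare_transition_matrices(a, b, unmatched="score_one")
        assert scored["per_row"][("C",)] == 1.0
        skipped = compare_transition_matrices(a, b, unmatched="skip")
        assert ("C",) not in skipped["per_row"]

    def test_independent_simulations_are_close(self):
        spec = small_spec(n=5000, max_length=40, seed=0)
        a = simulate_cohort(spec, seed=31)
        b = simulate_cohort(spec, seed=32)
        cmp = compare_transition_matrices(
            estimate_transition_matrix(a, 1), estimate_transition_matrix(b, 1))
        assert cmp["summary"]["mean"] < 0.1

    def test_convergence_to_spec_kernel(self):
        """Estimated rows approach the generating kernel as n grows."""
        spec = small_spec(n=500, max_length=40, seed=0)
        spec_big = small_spec(n=5000, max_length=40, seed=0)

        def distance(cohort):
            ds = []
            strata = spec.stratum_of(cohort.baseline)
            for s in range(spec.n_strata):
                pids = set(cohort.baseline.pid[strata == s])
                sub = Cohort(cohort.baseline[cohort.baseline.pid.isin(pids)],
                             cohort.events[cohort.events.pid.isin(pids)],
                             spec.schema)
                tm = estimate_transition_matrix(sub, 1)
                kernel = true_transition_matrix(spec, s)
                for ctx in tm.contexts:
                    p = tm.probs.loc[[ctx]].reindex(
                        columns=kernel.columns, fill_value=0).to_numpy()[0]
                    q = kernel.loc[ctx[0]].to_numpy()
                    bc = np.sqrt(p * q).sum()
                    ds.append(np.sqrt(max(0, 1 - bc)))
            return np.mean(ds)

        d_small = distance(simulate_cohort(spec, seed=41))
        d_big = distance(simulate_cohort(spec_big, seed=41))
        assert d_big < d_small


class TestMultivariateHellinger:
    def test_identical_tables_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        assert multivariate_hellinger(df, df) == pytest.approx(0.0, abs=1e-9)

    def test_univariate_gaussian_closed_form(self):
        """Equal variances, mean gap delta: sqrt(1 - exp(-delta^2/(8 s^2)))."""
        rng = np.random.default_rng(1)
        n = 200_000
        sigma, delta = 2.0, 1.5
        a = pd.DataFrame({"x": rng.normal(0, sigma, n)})
        b = pd.DataFrame({"x": rng.normal(delta, sigma, n)})
        # closed form on the *sample* moments to avoid sampling error
        m1, v1 = a.x.mean(), a.x.var()
        m2, v2 = b.x.mean(), b.x.var()
        vbar = (v1 + v2) / 2
        bd = (m1 - m2) ** 2 / (8 * vbar) + 0.5 * np.log(
            vbar / np.sqrt(v1 * v2))
        expect = np.sqrt(1 - np.exp(-bd))
        assert multivariate_hellinger(a, b, ridge=0.0) == \
            pytest.approx(expect, abs=1e-9)
        assert multivariate_hellinger(a, b) == pytest.approx(
            np.sqrt(1 - np.exp(-delta ** 2 / (8 * sigma ** 2))), abs=5e-3)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.normal(size=(3000, 3)), columns=list("abc"))
        b = pd.DataFrame(rng.normal(0.3, 1.2, size=(3000, 3)),
                         columns=list("abc"))
        d0 = multivariate_hellinger(a, b, ridge=0.0)
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        shift = rng.normal(size=3)
        at = pd.DataFrame(a.to_numpy() @ M + shift, columns=list("abc"))
        bt = pd.DataFrame(b.to_numpy() @ M + shift, columns=list("abc"))
        assert multivariate_hellinger(at, bt, ridge=0.0) == \
            pytest.approx(d0, abs=1e-6)

    def test_column_mismatch_rejected(self):
        a = pd.DataFrame({"x": [1.0, 2.0]})
        b = pd.DataFrame({"y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            multivariate_hellinger(a, b)

    def test_numeric_encoding_of_cohort(self, sim_cohort, sim_spec):
        tbl = numeric_event_table(sim_cohort, sim_spec.schema)
        assert tbl.select_dtypes(exclude="number").empty
        assert len(tbl) == len(sim_cohort.events)


class TestRandomCohorts:
    def test_identical_copy_all_zero(self, sim_cohort, sim_spec):
        res = random_cohort_assessment(sim_cohort, sim_cohort,
                                       sim_spec.schema, n_queries=25, seed=0)
        assert all(q.distance == 0 for q in res["queries"])

    def test_aggregate_closed_form(self):
        assert normalized_euclidean(3.0, 4.0) == pytest.approx(0.2)
        assert normalized_euclidean(0.0, 0.0) == 0.0

    def test_same_seed_same_queries(self, sim_cohort, sim_spec):
        syn = simulate_cohort(sim_spec, seed=99)
        a = random_cohort_assessment(sim_cohort, syn, sim_spec.schema,
                                     n_queries=20, seed=5)
        b = random_cohort_assessment(sim_cohort, syn, sim_spec.schema,
                                     n_queries=20, seed=5)
        assert [q.query for q in a["queries"]] == \
            [q.query for q in b["queries"]]
        assert [q.distance for q in a["queries"]] == \
            [q.distance for q in b["queries"]]

    def test_summaries_match_bruteforce(self, sim_cohort, sim_spec):
        syn = simulate_cohort(sim_spec, seed=98)
        res = random_cohort_assessment(sim_cohort, syn, sim_spec.schema,
                                       n_queries=30, seed=6)
        hd = [q.distance for q in res["queries"] if q.kind == "distribution"]
        s = res["hellinger_summary"]
        assert s["mean"] == pytest.approx(np.mean(hd))
        assert s["median"] == pytest.approx(np.median(hd))
        assert s["iqr"] == pytest.approx(
            np.percentile(hd, 75) - np.percentile(hd, 25))


class TestSMD:
    @pytest.mark.parametrize("m1,s1,m2,s2,expect", [
        (43.32, 17.87, 44.79, 19.83, 0.078),   # age
        (31.67, 63.90, 40.72, 111.92, 0.099),  # ALT
        (1474.48, 772.23, 1077.88, 722.44, 0.530),  # follow-up time
    ])
    def test_continuous_published_values(self, m1, s1, m2, s2, expect):
        assert round(smd_continuous(m1, s1, m2, s2), 3) == expect

    @pytest.mark.parametrize("x1,x2,expect", [
        (3299, 1440, 0.141),    # mortality
        (22495, 21582, 0.027),  # hospitalization
        (64376, 65193, 0.031),  # ED visit
        (64848, 65497, 0.025),  # composite endpoint
        (28224, 29651, 0.039),  # antidepressant use
        (1758, 2649, 0.070),    # morphine
    ])
    def test_binary_published_values(self, x1, x2, expect):
        assert round(smd_binary(x1, 75660, x2, 75660), 3) == expect

    def test_identical_moments_zero(self):
        assert smd_continuous(5, 2, 5, 2) == 0.0
        assert smd_binary(10, 100, 10, 100) == 0.0

    def test_symmetry_and_scale_invariance(self):
        a = smd_continuous(3, 1, 5, 2)
        assert a == pytest.approx(smd_continuous(5, 2, 3, 1))
        assert a == pytest.approx(smd_continuous(30, 10, 50, 20))
        assert smd_binary(3, 10, 7, 20) == pytest.approx(
            smd_binary(7, 20, 3, 10))

    def test_degenerate_cases(self):
        assert smd_continuous(4, 0, 4, 0) == 0.0
        assert smd_continuous(4, 0, 5, 0) == float("inf")
        assert smd_binary(0, 10, 10, 10) == float("inf")


class TestCIOverlap:
    def test_identical_and_disjoint(self):
        assert ci_overlap(0.5, 0.7, 0.5, 0.7) == 100.0
        assert ci_overlap(0.1, 0.2, 0.3, 0.4) == 0.0

    def test_closed_form_example(self):
        assert ci_overlap(0.57, 0.67, 0.60, 0.68) == pytest.approx(78.75)

    def test_symmetry(self):
        assert ci_overlap(0.57, 0.67, 0.60, 0.68) == \
            ci_overlap(0.60, 0.68, 0.57, 0.67)

    def test_zero_width_interval(self):
        assert ci_overlap(0.5, 0.5, 0.4, 0.6) == pytest.approx(50.0)
        assert ci_overlap(0.9, 0.9, 0.4, 0.6) == 0.0

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            ci_overlap(0.7, 0.6, 0.1, 0.2)


def test_summarize_matches_bruteforce():
    vals = [0.1, 0.4, 0.2, 0.9, 0.3]
    s = summarize(vals)
    assert s["mean"] == pytest.approx(np.mean(vals))
    assert s["sd"] == pytest.approx(np.std(vals, ddof=1))
    assert s["median"] == pytest.approx(np.median(vals))
    assert s["iqr"] == pytest.approx(
        np.percentile(vals, 75) - np.percentile(vals, 25))
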