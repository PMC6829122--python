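"""Benchmark statistics and protocol orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gpbench.bench import (
    CellResult,
    EN_5_MEMBERS,
    EN_11_MEMBERS,
    EnsembleMembershipError,
    bh_qvalues,
    derive_seed,
    ensemble_predict,
    evaluate_predictions,
    grid_search,
    paired_improvement_test,
    percent_improvement,
    run_benchmark,
    summarize_benchmark,
    win_percentage_matrix,
)
from gpbench.datatypes import AlignmentError
from gpbench.kernels_trees import HyperGrid
from gpbench.simulate import make_split_plan, simulate_genotypes, simulate_trait


def _cell(alg, rep, r, trait="t"):
    return CellResult(
        algorithm=alg, trait=trait, replicate=rep,
        predictions=np.zeros(3), y_true=np.zeros(3), r=r, mse=0.0,
    )


class TestEvaluatePredictions:
    def test_perfect_prediction(self):
        r, mse = evaluate_predictions([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert r == pytest.approx(1.0)
        assert mse == 0.0

    def test_perfect_anticorrelation(self):
        y = np.array([0.0, 0.4, 1.0])
        r, _ = evaluate_predictions(1.0 - y, y)
        assert r == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        yhat = np.array([0.1, 0.4, 0.5, 0.9])
        y = np.array([0.2, 0.3, 0.6, 0.8])
        r, mse = evaluate_predictions(yhat, y)
        # spreadsheet-style oracle from the raw sums
        n = 4
        sxy = np.sum(yhat * y) - np.sum(yhat) * np.sum(y) / n
        sxx = np.sum(yhat**2) - np.sum(yhat) ** 2 / n
        syy = np.sum(y**2) - np.sum(y) ** 2 / n
        assert r == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-12)
        assert mse == pytest.approx(np.sum((yhat - y) ** 2) / n, abs=1e-12)

    def test_constant_prediction_flags_undefined_r(self):
        r, mse = evaluate_predictions([0.5, 0.5, 0.5], [0.1, 0.5, 0.9])
        assert np.isnan(r)
        assert mse == pytest.approx(np.mean((0.5 - np.array([0.1, 0.5, 0.9])) ** 2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            evaluate_predictions([1, 2, 3], [1, 2])


class TestEnsemble:
    def test_identical_members_identity(self):
        pred = np.array([0.2, 0.8])
        out = ensemble_predict({m: pred for m in EN_5_MEMBERS}, "EN_5")
        assert np.array_equal(out, pred)

    def test_two_member_mean(self):
        out = ensemble_predict(
            {"a": np.array([0.2]), "b": np.array([0.4])}, membership=("a", "b")
        )
        assert out[0] == pytest.approx(0.3)

    def test_membership_definitions(self):
        assert EN_5_MEMBERS == ("rrBLUP", "BL", "SVR_poly", "RF", "ANN")
        assert len(EN_11_MEMBERS) == 11
        assert "CNN" not in EN_11_MEMBERS

    def test_missing_member_named_in_error(self):
        with pytest.raises(EnsembleMembershipError, match="ANN"):
            ensemble_predict({m: np.zeros(2) for m in EN_5_MEMBERS[:-1]}, "EN_5")


class TestSummaries:
    def test_single_algorithm_is_best_by_definition(self):
        cells = [_cell("rrBLUP", rep, r) for rep, r in enumerate([0.5, 0.6])]
        s = summarize_benchmark(cells)
        assert s["pct_of_best"].iloc[0] == 100.0
        assert s["rank"].iloc[0] == 1.0

    def test_percent_of_best_and_ranks(self):
        cells = [_cell("A", 0, 0.5), _cell("A", 1, 0.5),
                 _cell("B", 0, 0.4), _cell("B", 1, 0.4)]
        s = summarize_benchmark(cells).set_index("algorithm")
        assert s.loc["A", "pct_of_best"] == pytest.approx(100.0)
        assert s.loc["B", "pct_of_best"] == pytest.approx(80.0)
        assert s.loc["A", "rank"] == 1.0 and s.loc["B", "rank"] == 2.0

    def test_tied_algorithms_share_average_rank(self):
        cells = [_cell("A", 0, 0.5), _cell("B", 0, 0.5)]
        s = summarize_benchmark(cells)
        assert (s["rank"] == 1.5).all()

    def test_degenerate_replicates_excluded_with_count(self):
        cells = [_cell("A", 0, 0.6), _cell("A", 1, float("nan"))]
        s = summarize_benchmark(cells)
        assert s["mean_r"].iloc[0] == pytest.approx(0.6)
        assert s["n_degenerate"].iloc[0] == 1


class TestWinMatrix:
    def test_self_comparison_all_ties(self):
        cells = [_cell("A", rep, 0.1 * rep) for rep in range(5)]
        wins, ties = win_percentage_matrix(cells)
        assert wins.loc["A", "A"] == 0.0
        assert ties.loc["A", "A"] == 100.0

    def test_hand_counted_example(self):
        # a beats b in 7 of 10 replicates, ties once, loses twice
        ra = [0.5] * 10
        rb = [0.4] * 7 + [0.5] + [0.6] * 2
        cells = [_cell("a", i, ra[i]) for i in range(10)]
        cells += [_cell("b", i, rb[i]) for i in range(10)]
        wins, ties = win_percentage_matrix(cells)
        assert wins.loc["a", "b"] == pytest.approx(70.0)
        assert wins.loc["b", "a"] == pytest.approx(20.0)
        assert ties.loc["a", "b"] == pytest.approx(10.0)

    @given(st.data())
    def test_partition_identity(self, data):
        n_reps = data.draw(st.integers(min_value=2, max_value=8))
        rng = np.random.default_rng(data.draw(st.integers(0, 1000)))
        cells = []
        for alg in "ABC":
            rs = rng.choice([0.1, 0.2, 0.3], size=n_reps)  # many ties
            cells += [_cell(alg, i, rs[i]) for i in range(n_reps)]
        wins, ties = win_percentage_matrix(cells)
        for a in "ABC":
            for b in "ABC":
                if a != b:
                    total = wins.loc[a, b] + wins.loc[b, a] + ties.loc[a, b]
                    assert total == pytest.approx(100.0)

    def test_replicate_mismatch_rejected(self):
        cells = [_cell("A", 0, 0.5), _cell("B", 1, 0.4)]
        with pytest.raises(AlignmentError):
            win_percentage_matrix(cells)


class TestPairedTests:
    def test_no_change_gives_p_one_with_flag(self):
        p, all_zero = paired_improvement_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert p == 1.0 and all_zero

    def test_ten_uniform_improvements_exact_p(self):
        before = np.linspace(0.1, 0.4, 10)
        after = before + np.linspace(0.01, 0.1, 10)
        p, _ = paired_improvement_test(before, after)
        assert p == pytest.approx(1 / 1024)

    def test_bh_qvalues_hand_computed(self):
        q = bh_qvalues([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_decrease_is_not_evidence_of_increase(self):
        before = np.linspace(0.5, 0.9, 8)
        p, _ = paired_improvement_test(before, before - 0.1)
        assert p > 0.99


class TestPercentImprovement:
    @pytest.mark.parametrize(
        "base,new,expected", [(0.17, 0.41, 141.0), (0.25, 0.32, 28.0), (0.4, 0.4, 0.0)]
    )
    def test_worked_examples(self, base, new, expected):
        assert percent_improvement(base, new) == expected

    def test_unrounded_value_available(self):
        assert percent_improvement(0.17, 0.41, round_to_percent=False) == pytest.approx(
            141.176, abs=1e-2
        )

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_improvement(0.0, 0.3)


class TestGridSearch:
    def test_single_candidate_returned_without_cv(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        grid = HyperGrid(algorithm="SVR_lin", grid={"C": [2.0]})
        assert grid_search("SVR_lin", X, y, grid=grid, seed=0) == {"C": 2.0}

    def test_selects_lower_cv_mse_candidate(self, medium_dataset):
        # strong linear signal: a vanishing C underfits badly
        G, pheno, _ = medium_dataset
        X, y = G.X(), pheno.values[:, 0]
        grid = HyperGrid(algorithm="SVR_lin", grid={"C": [1e-6, 1.0]})
        best = grid_search("SVR_lin", X, y, grid=grid, repeats=2, seed=1)
        assert best == {"C": 1.0}
        # brute-force oracle on a single held-out split
        from gpbench.kernels_trees import fit_svr

        half = len(y) // 2
        mses = {}
        for C in (1e-6, 1.0):
            fit = fit_svr(X[:half], y[:half], kernel="lin", C=C)
            mses[C] = np.mean((fit.predict(X[half:]) - y[half:]) ** 2)
        assert mses[1.0] < mses[1e-6]


class TestRunBenchmark:
    def _setup(self, n=200, p=40, n_reps=3):
        G = simulate_genotypes(n, p, seed=70)
        pheno, _ = simulate_trait(G, n_qtl=8, h2=0.8, seed=71)
        plan = make_split_plan(
            n, n_replicates=n_reps, validation_fraction_of_train=0.2, seed=72
        )
        return G, pheno, plan

    def test_smoke_two_algorithms(self):
        G, pheno, plan = self._setup()
        out = run_benchmark(
            G, pheno, ["rrBLUP", "RF"], plan, master_seed=1,
            sampler_iterations=400, sampler_burn_in=100,
        )
        assert len(out.summary) == 2
        assert set(out.summary["algorithm"]) == {"rrBLUP", "RF"}
        assert len(out.results) == 2 * plan.n_replicates
        assert (out.summary["pct_of_best"].max()) == pytest.approx(100.0)

    def test_rerun_bit_identical_for_deterministic_algorithms(self):
        G, pheno, plan = self._setup(n_reps=2)
        kw = dict(master_seed=3, sampler_iterations=300, sampler_burn_in=100)
        a = run_benchmark(G, pheno, ["rrBLUP", "BRR"], plan, **kw)
        b = run_benchmark(G, pheno, ["rrBLUP", "BRR"], plan, **kw)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        for ca, cb in zip(a.results, b.results):
            assert np.array_equal(ca.predictions, cb.predictions)

    def test_ensemble_of_identical_members_equals_member(self):
        G, pheno, plan = self._setup(n_reps=2)
        out = run_benchmark(
            G, pheno, ["rrBLUP"], plan, master_seed=4,
            ensembles=[("rrBLUP", "rrBLUP", "rrBLUP")],
        )
        single = {c.replicate: c for c in out.results if c.algorithm == "rrBLUP"}
        ens_cells = [c for c in out.results if c.algorithm.startswith("EN(")]
        assert ens_cells
        for c in ens_cells:
            # exact up to float associativity of the three-term mean
            assert np.allclose(
                c.predictions, single[c.replicate].predictions, rtol=0, atol=1e-14
            )

    def test_leakage_audit_shuffled_test_phenotypes(self):
        # shuffling phenotypes of the test lines must leave every training
        # artifact checksum unchanged (selection + model fitting see train only)
        G, pheno, plan = self._setup(n=150, p=30, n_reps=1)
        sp = plan.replicates[0]
        y = pheno.values.copy()
        rng = np.random.default_rng(0)
        shuffled = y.copy()
        shuffled[sp.test, 0] = rng.permutation(shuffled[sp.test, 0])
        pheno_shuffled = type(pheno)(
            line_ids=list(pheno.line_ids), trait_names=list(pheno.trait_names),
            values=shuffled,
        )
        kw = dict(
            master_seed=5, sampler_iterations=300, sampler_burn_in=100,
            feature_selection={"method": "RF", "k": 10, "exempt": ("RF",)},
        )
        a = run_benchmark(G, pheno, ["rrBLUP", "RF"], plan, **kw)
        b = run_benchmark(G, pheno_shuffled, ["rrBLUP", "RF"], plan, **kw)
        for ca, cb in zip(a.results, b.results):
            assert ca.training_checksum == cb.training_checksum
        # but the reported r does change (it depends on the test labels)
        assert not np.allclose(
            [c.r for c in a.results], [c.r for c in b.results]
        )

    def test_cell_failure_recorded_run_continues(self):
        G, pheno, _ = self._setup()
        # a plan without a validation slice: ANN cells must fail cleanly
        plan = make_split_plan(G.n_lines, n_replicates=2, seed=73)
        out = run_benchmark(G, pheno, ["rrBLUP", "ANN"], plan, master_seed=6)
        errs = [c for c in out.results if c.error is not None]
        oks = [c for c in out.results if c.error is None]
        assert len(oks) == 2  # rrBLUP cells survive
        assert len(errs) == 2


class TestDeriveSeed:
    def test_deterministic_and_bounded(self):
        s1 = derive_seed(1, "rrBLUP", "height", 0)
        s2 = derive_seed(1, "rrBLUP", "height", 0)
        assert s1 == s2
        assert 0 <= s1 < 2**31

    def test_distinct_across_cells(self):
        seeds = {
            derive_seed(1, alg, trait, rep)
            for alg in ("A", "B")
            for trait in ("t1", "t2")
            for rep in range(5)
        }
        assert len(seeds) == 20
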