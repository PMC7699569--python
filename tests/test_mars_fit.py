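"""Two-stage fitting: forward search oracle, pruning, recovery, importance."""

import numpy as np
import pytest

from panelmars import (
    BasisTerm,
    DesignMatrix,
    FitConfig,
    Hinge,
    PiecewiseSpec,
    backward_pass,
    fit,
    forward_pass,
    gen_figure1_grid,
    gen_piecewise_response,
    model_from_json,
    model_report,
    model_to_json,
    parse_term,
    predict,
    term_signature,
    variable_importance,
)
from panelmars.mars import parse_report_terms

from .conftest import make_design, with_response


def exhaustive_first_split(x: np.ndarray, y: np.ndarray):
    """Brute-force oracle for the first forward step on one predictor.

    Enumerates every candidate knot; the observed minimum contributes a
    single bare-variable column, every other knot a reflected hinge pair.
    Returns (kind, knot) of the RSS-minimising candidate, smaller knots
    winning ties.
    """
    n = y.size
    kn = np.unique(x)
    best = None
    for t in kn:
        if t == kn[0]:
            B = np.column_stack([np.ones(n), x])
            cand = ("linear", float(t))
        else:
            B = np.column_stack(
                [np.ones(n), np.maximum(0, x - t), np.maximum(0, t - x)]
            )
            cand = ("pair", float(t))
        beta, *_ = np.linalg.lstsq(B, y, rcond=None)
        rss = float(((y - B @ beta) ** 2).sum())
        if best is None or rss < best[0] - 1e-12:
            best = (rss, cand)
    return best[1]


class TestForwardPass:
    @pytest.mark.parametrize("seed", range(8))
    def test_first_split_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        x = rng.uniform(0, 1, n)
        y = rng.normal(size=n) + 2.0 * np.sin(3 * x)
        D = DesignMatrix(y, x[:, None], [("s", i) for i in range(n)], ["x"])
        terms, _ = forward_pass(D, FitConfig(max_terms=3))
        kind, knot = exhaustive_first_split(x, y)
        if kind == "linear":
            assert len(terms) >= 1 and terms[0].factors[0].linear
        else:
            assert len(terms) >= 2
            assert terms[0].factors[0].knot == pytest.approx(knot)
            assert {t.factors[0].direction for t in terms[:2]} == {"+", "-"}

    def test_exact_hinge_found_with_zero_rss(self):
        x = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        y = np.maximum(0.0, x - 0.5)
        D = DesignMatrix(y, x[:, None], [("s", i) for i in range(5)], ["x"])
        terms, trace = forward_pass(D, FitConfig(max_terms=5))
        assert terms[0].factors[0].knot == 0.5
        assert trace[-1] == pytest.approx(0.0, abs=1e-24)

    def test_constant_response_intercept_only(self):
        D = make_design(0, 20)
        D = with_response(D, np.full(20, 3.0))
        terms, trace = forward_pass(D)
        assert terms == [] and len(trace) == 1

    def test_constant_predictors_intercept_only(self):
        y = np.random.default_rng(0).normal(size=10)
        D = DesignMatrix(
            y, np.ones((10, 2)), [("s", i) for i in range(10)], ["a", "b"]
        )
        terms, _ = forward_pass(D)
        assert terms == []

    def test_rss_trace_nonincreasing(self):
        D = make_design(5, 50)
        rng = np.random.default_rng(6)
        y = np.sin(4 * D.column("x1")) + 0.3 * rng.normal(size=50)
        _, trace = forward_pass(with_response(D, y), FitConfig(max_terms=13))
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


class TestBackwardPass:
    def _fitted(self, seed=3, n=60, max_terms=13):
        D = make_design(seed, n)
        rng = np.random.default_rng(seed + 100)
        y = (
            2 * np.maximum(0, D.column("x1") - 0.4)
            - 1.0 * D.column("x2")
            + 0.2 * rng.normal(size=n)
        )
        D = with_response(D, y)
        cfg = FitConfig(max_terms=max_terms)
        terms, _ = forward_pass(D, cfg)
        return D, cfg, terms

    def test_trace_nested_decreasing_by_one(self):
        D, cfg, terms = self._fitted()
        _, trace = backward_pass(terms, D, cfg)
        sets = [s for s, _, _ in trace.subsets]
        assert len(sets[0]) == len(terms)
        for a, b in zip(sets, sets[1:]):
            assert b < a and len(a) - len(b) == 1

    def test_best_is_global_minimum_of_trace(self):
        D, cfg, terms = self._fitted()
        model, trace = backward_pass(terms, D, cfg)
        gcvs = [g for _, _, g in trace.subsets]
        assert trace.subsets[trace.best_index][2] == min(gcvs)
        assert model.gcv <= gcvs[0] + 1e-15  # never worse than forward model

    def test_oversupplied_linear_target_pruned(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 40)
        y = 3.0 * x
        D = DesignMatrix(y, x[:, None], [("s", i) for i in range(40)], ["x"])
        cfg = FitConfig(max_terms=11)
        terms, _ = forward_pass(D, cfg)
        model, trace = backward_pass(terms, D, cfg)
        assert model.gcv <= trace.subsets[0][2]
        assert model.rss == pytest.approx(0.0, abs=1e-18)


class TestFit:
    def test_deterministic_refit(self):
        D = make_design(11, 80)
        rng = np.random.default_rng(12)
        y = np.cos(5 * D.column("x1")) + 0.1 * rng.normal(size=80)
        D = with_response(D, y)
        m1, _ = fit(D, FitConfig(max_terms=11))
        m2, _ = fit(D, FitConfig(max_terms=11))
        assert model_to_json(m1) == model_to_json(m2)

    def test_noiseless_piecewise_recovery(self):
        D = make_design(21, 50)
        # place the true knots at observed values
        X = D.X.copy()
        X[7, 0], X[23, 1] = 0.5, 0.7
        D = DesignMatrix(np.zeros(50), X, D.row_index, ["x1", "x2"])
        spec = PiecewiseSpec(
            terms=(
                BasisTerm((Hinge("x1", 0.5, "+"),), coefficient=2.0),
                BasisTerm((Hinge("x2", 0.7, "-"),), coefficient=-3.0),
            )
        )
        y = gen_piecewise_response(D, spec)
        D = with_response(D, y)
        model, _ = fit(D, FitConfig(max_terms=11))
        assert model.rss < 1e-12
        knots = {
            (f.var, round(f.knot, 10))
            for t in model.terms
            for f in t.factors
            if not f.linear
        }
        assert {("x1", 0.5), ("x2", 0.7)} & knots
        assert np.allclose(predict(model, D), y, atol=1e-8)

    def test_figure_surface_fit(self):
        D = gen_figure1_grid(21)
        model, _ = fit(D, FitConfig(max_terms=21, max_degree=2))
        assert model.rsq >= 0.9

    def test_irrelevant_predictor_stays_unused(self):
        D = make_design(31, 70, names=("x1", "x2"))
        y = 2.0 * np.maximum(0, D.column("x1") - float(D.column("x1")[9]))
        D = with_response(D, y)
        model, trace = fit(D, FitConfig(max_terms=11))
        imp = variable_importance(trace, model, ["x1", "x2"])
        assert imp.row("x1").used
        assert not imp.row("x2").used
        assert imp.row("x2").gcv_score is None

    @pytest.mark.parametrize("seed", range(6))
    def test_grsq_below_rsq(self, seed):
        D = make_design(seed + 50, 40)
        rng = np.random.default_rng(seed)
        y = D.column("x1") + 0.5 * rng.normal(size=40)
        model, _ = fit(with_response(D, y), FitConfig(max_terms=9))
        if model.terms:
            assert model.grsq <= model.rsq + 1e-12
        assert model.rsq <= 1.0


class TestImportanceAndReport:
    def _model(self):
        D = make_design(41, 80)
        rng = np.random.default_rng(42)
        # x1 drives ~90% of the signal variance, x2 is minor
        y = (
            3.0 * np.maximum(0, D.column("x1") - 0.3)
            + 0.4 * D.column("x2")
            + 0.05 * rng.normal(size=80)
        )
        D = with_response(D, y)
        model, trace = fit(D, FitConfig(max_terms=13))
        return D, model, trace

    def test_dominant_variable_ranked_first(self):
        _, model, trace = self._model()
        imp = variable_importance(trace, model, ["x1", "x2"])
        r1, r2 = imp.row("x1"), imp.row("x2")
        assert r1.gcv_score == 100.0 and r1.rss_score == 100.0
        if r2.used:
            assert r2.gcv_score <= r1.gcv_score
            assert r2.rss_score <= r1.rss_score

    def test_single_variable_model_scores_100(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 40)
        y = np.maximum(0, x - 0.5) + 0.05 * rng.normal(size=40)
        D = DesignMatrix(y, x[:, None], [("s", i) for i in range(40)], ["x"])
        model, trace = fit(D, FitConfig(max_terms=9))
        imp = variable_importance(trace, model, ["x"])
        assert imp.row("x").gcv_score == 100.0
        assert imp.row("x").rss_score == 100.0

    def test_report_round_trip(self):
        _, model, trace = self._model()
        report = model_report(model)
        intercept, terms = parse_report_terms(report)
        assert intercept == pytest.approx(model.intercept, abs=5e-6)
        assert [term_signature(t) for t in terms] == [
            term_signature(t) for t in model.terms
        ]
        for parsed, orig in zip(terms, model.terms):
            assert parsed.coefficient == pytest.approx(orig.coefficient, abs=5e-6)

    def test_intercept_only_report(self):
        D = make_design(0, 20)
        model, trace = fit(with_response(D, np.full(20, 2.0)))
        report = model_report(model, variable_importance(trace, model, ["x1", "x2"]))
        assert "Intercept" in report and "Main Features" in report

    def test_json_round_trip(self):
        _, model, _ = self._model()
        back = model_from_json(model_to_json(model))
        assert model_to_json(back) == model_to_json(model)

    def test_training_predictions_reproduce_rss(self):
        D, model, _ = self._model()
        resid = D.y - predict(model, D)
        assert float(resid @ resid) == pytest.approx(model.rss, rel=1e-9)
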