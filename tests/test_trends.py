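"""Series assembly, GRU forecasting, MASE and trendiness."""

import numpy as np
import pandas as pd
import pytest

from litmine import (
    CitationGraph,
    Corpus,
    GeneAnnotationSet,
    OrganisationList,
    Publication,
    assemble_series,
    compute_trendiness,
    mase,
    tag_affiliations,
    train_forecaster,
)
from litmine.trends import GRUForecaster, _right_tail
from oracles import kde_right_tail_quadrature


def _annotations(mapping):
    ann = GeneAnnotationSet()
    for g, docs in mapping.items():
        for p in docs:
            ann.add(g, p, "community")
    return ann


class TestAssembleSeries:
    def test_cumulative_totals(self):
        pubs = [
            Publication(pub_id="a", year=1990),
            Publication(pub_id="b", year=1990),
            Publication(pub_id="c", year=1995),
            Publication(pub_id="d", year=1995),
            Publication(pub_id="e", year=1995),
        ]
        series = assemble_series(
            _annotations({"G1": {"a", "b", "c", "d", "e"}}),
            Corpus(pubs),
            CitationGraph(),
            train_end=2013,
            horizon_end=2019,
        )
        assert series["G1"].loc[1995, "publications"] == 5
        assert series["G1"].loc[1990, "publications"] == 2
        # final cumulative equals annotation-set size
        assert series["G1"].iloc[-1]["publications"] == 5

    def test_citation_direction(self):
        orgs = OrganisationList({"BigCo": "big"})
        corpus = Corpus(
            [
                Publication(pub_id="cited", year=2000),
                Publication(pub_id="citer", year=2005, affiliations=("BigCo",)),
            ]
        )
        corpus = tag_affiliations(corpus, orgs)
        ann = _annotations({"G1": {"cited"}, "G2": {"citer"}})
        citations = CitationGraph({("citer", "cited")})
        series = assemble_series(ann, corpus, citations, horizon_end=2019)
        # the big-pharma paper CITES the annotated paper: counts for G1 in 2005
        assert series["G1"].loc[2005, "cit_big_pharma"] == 1
        assert series["G1"].loc[2004, "cit_big_pharma"] == 0
        # the cited paper being big-pharma-cited adds nothing to G2
        assert (series["G2"]["cit_big_pharma"] == 0).all()

    def test_empty_citations_zero(self):
        corpus = Corpus([Publication(pub_id="a", year=2000)])
        series = assemble_series(_annotations({"G1": {"a"}}), corpus, CitationGraph())
        for cat in ["citations", "cit_reviews", "cit_trials", "cit_big_pharma", "cit_med_pharma"]:
            assert (series["G1"][cat] == 0).all()

    def test_series_non_decreasing(self):
        corpus = Corpus([Publication(pub_id=f"p{i}", year=1990 + i) for i in range(20)])
        series = assemble_series(
            _annotations({"G1": {f"p{i}" for i in range(20)}}), corpus, CitationGraph()
        )
        assert (series["G1"].diff().fillna(0) >= 0).all().all()


class TestMase:
    def test_perfect_forecast(self):
        assert mase([5, 6], [5, 6], [1, 2, 3]) == 0.0

    def test_naive_forecast_is_one(self):
        history = [1, 2, 10]
        actual = [12, 14]
        assert mase(actual, [10, 10], history) == 1.0

    def test_hand_example(self):
        assert mase([12, 14], [11, 13], [10]) == pytest.approx(1 / 3)

    def test_flat_series_conventions(self):
        assert mase([10, 10], [10, 10], [10]) == 0.0
        assert mase([10, 10], [11, 11], [10]) == float("inf")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mase([1, 2], [1], [0])


def _linear_series(rng, n, years):
    out = {}
    for i in range(n):
        slope = rng.uniform(0.5, 6.0)
        vals = 5 + slope * (years - years[0]) + rng.normal(0, slope * 0.3, size=years.size)
        vals = np.maximum.accumulate(np.maximum(vals, 0))
        out[f"G{i}"] = pd.DataFrame({"publications": vals}, index=years)
    return out


class TestForecaster:
    years = np.arange(1990, 2020)

    def test_forecast_shape_contract(self):
        rng = np.random.default_rng(0)
        series = _linear_series(rng, 12, self.years)
        fc = train_forecaster(series, train_end=2013, horizon_end=2019, epochs=5, seed=0)
        table = fc.forecast(series)
        assert all(len(p) == 6 for p in table["predicted"])  # 2014..2019

    def test_constant_series_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        series = _linear_series(rng, 12, self.years)
        series["FLAT"] = pd.DataFrame(
            {"publications": np.full(self.years.size, 7.0)}, index=self.years
        )
        with pytest.warns(UserWarning, match="constant training series"):
            fc = train_forecaster(series, train_end=2013, horizon_end=2019, epochs=5, seed=0)
        # degenerate scaling maps the flat train window to zeros and the
        # inverse keeps predictions non-negative
        table = fc.forecast({"FLAT": series["FLAT"]})
        assert (np.concatenate(table["predicted"].to_list()) >= 0).all()

    def test_too_few_series_rejected(self):
        rng = np.random.default_rng(2)
        series = _linear_series(rng, 3, self.years)
        with pytest.raises(ValueError, match="fewer than 10"):
            train_forecaster(series, train_end=2013, horizon_end=2019, epochs=1)

    def test_short_train_window_rejected(self):
        years = np.arange(2011, 2020)
        rng = np.random.default_rng(3)
        series = _linear_series(rng, 12, years)
        with pytest.raises(ValueError, match="shorter than 5"):
            train_forecaster(series, train_end=2013, horizon_end=2019, epochs=1)

    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(4)
        model = GRUForecaster(t_in=6, t_out=2, units=3, n_layers=2, seed=5, epochs=1)
        x = rng.normal(size=(4, 6))
        y = rng.normal(size=(4, 2))
        model._loss_and_grads(x, y)
        analytic = model.encoder[0].grads["Wh"].copy()
        eps = 1e-6
        numeric = np.zeros_like(analytic)
        params = model.encoder[0].params["Wh"]
        for i in range(params.shape[0]):
            for j in range(params.shape[1]):
                orig = params[i, j]
                params[i, j] = orig + eps
                lp = model._loss_only(x, y)
                params[i, j] = orig - eps
                lm = model._loss_only(x, y)
                params[i, j] = orig
                numeric[i, j] = (lp - lm) / (2 * eps)
        assert np.allclose(analytic, numeric, rtol=1e-4, atol=1e-8)

    def test_beats_naive_on_growth(self):
        rng = np.random.default_rng(6)
        series = _linear_series(rng, 40, self.years)
        fc = train_forecaster(series, train_end=2013, horizon_end=2019, epochs=200, seed=6)
        table = fc.forecast(series)
        assert table["mase"].median() < 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        series = _linear_series(rng, 12, self.years)
        t1 = train_forecaster(series, epochs=10, seed=9).forecast(series)
        t2 = train_forecaster(series, epochs=10, seed=9).forecast(series)
        assert np.allclose(
            np.stack(t1["predicted"].to_list()), np.stack(t2["predicted"].to_list())
        )


class TestTrendiness:
    @staticmethod
    def _table(rng, n=60):
        return pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n)],
                "category": "publications",
                "initial": rng.uniform(1, 100, size=n),
                "fold_change": rng.lognormal(0, 0.5, size=n),
            }
        )

    def test_tail_monotone_in_fold_change(self):
        rng = np.random.default_rng(0)
        trend = compute_trendiness(self._table(rng))
        for (_, _), group in trend.groupby(["category", "bin"]):
            ordered = group.sort_values("log2_fold_change")
            diffs = np.diff(ordered["trendiness"].to_numpy())
            assert (diffs < 0).all()  # strictly decreasing

    def test_extreme_fold_minimal_trendiness(self):
        rng = np.random.default_rng(1)
        trend = compute_trendiness(self._table(rng))
        for (_, _), group in trend.groupby(["category", "bin"]):
            top = group.loc[group["log2_fold_change"].idxmax()]
            assert top["trendiness"] == group["trendiness"].min()

    def test_single_kernel_symmetry(self):
        # all fold changes in a bin equal: the tail at that value is exactly 0.5
        table = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(10)],
                "category": "publications",
                "initial": np.arange(10, dtype=float),
                "fold_change": 2.0,
            }
        )
        trend = compute_trendiness(table)
        assert np.allclose(trend["trendiness"], 0.5)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(2)
        trend = compute_trendiness(self._table(rng))
        assert trend["trendiness"].between(0, 1).all()

    def test_tail_matches_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            points = rng.normal(0, 1, size=rng.integers(2, 30))
            x0 = float(rng.normal(0, 1.5))
            closed = _right_tail(points, x0, 0.1)
            numeric = kde_right_tail_quadrature(points, x0, 0.1)
            assert closed == pytest.approx(numeric, abs=1e-6)

    def test_undersized_bin_merged(self):
        table = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(6)],
                "category": "publications",
                # one extreme outlier volume forms a singleton top bin
                "initial": [1.0, 1.1, 1.2, 1.3, 1.4, 500.0],
                "fold_change": [1.0, 1.1, 0.9, 1.2, 1.0, 3.0],
            }
        )
        with pytest.warns(UserWarning, match="merged"):
            trend = compute_trendiness(table)
        assert len(trend) == 6
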