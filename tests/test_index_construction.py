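from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hpuindex as H

from _oracles import straightline_index
from conftest import make_article


def panel(values, papers=None, months=None) -> H.CountPanel:
    values = np.asarray(values, dtype=float)
    papers = papers or [f"p{i}" for i in range(values.shape[0])]
    months = months or [f"2003-{t + 1:02d}" for t in range(values.shape[1])]
    return H.CountPanel(papers, months, values)


class TestScaleCounts:
    def test_hand_ratios(self):
        X = H.scale_counts(panel([[0, 2]]), panel([[100, 100]]))
        assert X.values[0, 0] == 0.0
        assert X.values[0, 1] == pytest.approx(0.02, abs=0)

    def test_target_exceeding_total_rejected(self):
        with pytest.raises(H.ValidationError, match="exceeds"):
            H.scale_counts(panel([[1, 0]]), panel([[0, 5]]))

    def test_zero_volume_cell_dropped_and_flagged(self):
        with pytest.warns(UserWarning, match="zero total"):
            X = H.scale_counts(panel([[0, 1]]), panel([[0, 10]]))
        assert np.isnan(X.values[0, 0])
        assert X.zero_volume_cells == [("p0", "2003-01")]

    def test_mismatched_missing_patterns_rejected(self):
        A = panel([[1, np.nan]])
        B = panel([[10, 10]])
        with pytest.raises(H.ValidationError, match="MISSING"):
            H.scale_counts(A, B)


class TestStandardize:
    def test_hand_computed_unit_sd(self):
        X = H.RatioPanel(["p"], ["2003-01", "2003-02"], np.array([[1.0, 3.0]]))
        Y = H.standardize(X)
        assert Y.sigma["p"] == pytest.approx(math.sqrt(2), rel=1e-15)
        assert Y.values[0].tolist() == pytest.approx(
            [0.7071067811865475, 2.1213203435596424], rel=1e-12
        )
        assert np.std(Y.values[0], ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_idempotent_on_unit_sd_series(self):
        row = np.array([[0.5, 1.5, 2.5]])
        row = row / np.std(row, ddof=1)
        X = H.RatioPanel(["p"], ["2003-01", "2003-02", "2003-03"], row)
        Y = H.standardize(X)
        assert Y.values == pytest.approx(row, rel=1e-12)

    def test_constant_series_is_degenerate(self):
        X = H.RatioPanel(["p"], ["2003-01", "2003-02"], np.array([[0.5, 0.5]]))
        with pytest.raises(H.DegenerateSeriesError, match="'p'"):
            H.standardize(X)

    def test_single_month_is_degenerate(self):
        X = H.RatioPanel(
            ["p"], ["2003-01", "2003-02"], np.array([[0.5, np.nan]])
        )
        with pytest.raises(H.DegenerateSeriesError, match="observed month"):
            H.standardize(X)


class TestAggregate:
    def test_single_paper_identity(self):
        Y = H.RatioPanel(["p"], ["2003-01", "2003-02"], np.array([[1.0, 3.0]]))
        Z = H.aggregate(Y)
        assert Z.values.tolist() == [1.0, 3.0]

    def test_two_paper_mean(self):
        Y = H.RatioPanel(
            ["a", "b"], ["2003-01"], np.array([[1.0], [3.0]])
        )
        assert H.aggregate(Y).values[0] == 2.0

    def test_missing_cell_excluded_from_mean(self):
        vals = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 4.0]])
        Y = H.RatioPanel(["a", "b", "c"], ["2003-01", "2003-02"], vals)
        Z = H.aggregate(Y)
        # brute-force means over present papers
        assert Z.values[0] == pytest.approx((1 + 3 + 5) / 3)
        assert Z.values[1] == pytest.approx((2 + 4) / 2)

    def test_empty_month_rejected(self):
        vals = np.array([[1.0, np.nan]])
        Y = H.RatioPanel(["a"], ["2003-01", "2003-02"], vals)
        with pytest.raises(H.EmptyMonthError, match="2003-02"):
            H.aggregate(Y)


class TestNormalize:
    def test_two_point_series(self):
        Z = H.IndexSeries(["2003-01", "2003-02"], np.array([1.0, 3.0]))
        out = H.normalize(Z)
        assert out.values.tolist() == [50.0, 150.0]
        assert out.normalization_constant == 2.0

    def test_idempotent_on_mean_100(self):
        Z = H.IndexSeries(["2003-01", "2003-02"], np.array([50.0, 150.0]))
        assert H.normalize(Z).values.tolist() == [50.0, 150.0]

    def test_zero_series_rejected(self):
        Z = H.IndexSeries(["2003-01", "2003-02"], np.zeros(2))
        with pytest.raises(H.DegenerateSeriesError):
            H.normalize(Z)

    @given(
        values=st.lists(
            st.floats(0.01, 1e6), min_size=2, max_size=24
        ).filter(lambda v: len(set(v)) > 1)
    )
    def test_mean_is_always_100(self, values):
        months = [f"{2003 + t // 12}-{t % 12 + 1:02d}" for t in range(len(values))]
        out = H.normalize(H.IndexSeries(months, np.array(values)))
        assert float(out.values.mean()) == pytest.approx(100.0, rel=1e-9)


class TestBuildIndex:
    def test_toy_corpus_matches_straightline_oracle(self, toy_corpus, lexicon):
        # A = [[1,2,3],[0,2,4]], B = 10 everywhere
        idx = H.build_index(toy_corpus, lexicon)
        expected = straightline_index(
            [[1, 2, 3], [0, 2, 4]], [[10, 10, 10], [10, 10, 10]]
        )
        assert idx.values.tolist() == pytest.approx(expected, abs=1e-12)
        assert float(idx.values.mean()) == pytest.approx(100.0, rel=1e-9)

    def test_duplicating_every_article_leaves_index_unchanged(
        self, toy_corpus, lexicon
    ):
        doubled = H.Corpus(
            toy_corpus.articles
            + tuple(
                dataclasses.replace(a, article_id=a.article_id + "_dup")
                for a in toy_corpus.articles
            ),
            toy_corpus.newspapers,
            toy_corpus.month_range,
        )
        a = H.build_index(toy_corpus, lexicon)
        b = H.build_index(doubled, lexicon)
        assert b.values == pytest.approx(a.values, rel=1e-12)

    def test_newspaper_order_is_irrelevant(self, toy_corpus, lexicon):
        a = H.build_index(toy_corpus, lexicon, newspapers=["p1", "p2"])
        b = H.build_index(toy_corpus, lexicon, newspapers=["p2", "p1"])
        assert np.array_equal(a.values, b.values)

    def test_scaling_one_papers_counts_leaves_index_unchanged(
        self, lexicon
    ):
        # tripling every article of one paper scales its A and B alike;
        # the ratio X is unchanged, so the index is too
        def corpus(reps: dict[str, int]) -> H.Corpus:
            match_t = "卫生政府前景不确定"
            plain_t = "晴天"
            arts = []
            k = 0
            for paper in ("p1", "p2"):
                for month, n_match in [(1, 1), (2, 2), (3, 1)]:
                    for _ in range(reps[paper]):
                        for j in range(4):
                            k += 1
                            arts.append(
                                make_article(
                                    paper=paper, month=month,
                                    art_id=f"s{k:04d}",
                                    text=match_t if j < n_match else plain_t,
                                )
                            )
            return H.Corpus(tuple(arts), ("p1", "p2"), ("2003-01", "2003-03"))

        a = H.build_index(corpus({"p1": 1, "p2": 1}), lexicon)
        b = H.build_index(corpus({"p1": 3, "p2": 1}), lexicon)
        assert b.values == pytest.approx(a.values, rel=1e-12)

    def test_subset_equals_full_build_on_reduced_corpus(
        self, small_corpus, lexicon
    ):
        corpus, _ = small_corpus
        keep = list(corpus.newspapers[:2])
        sub_idx = H.build_index(corpus, lexicon, newspapers=keep)
        reduced = H.Corpus(
            tuple(a for a in corpus.articles if a.newspaper_id in keep),
            tuple(keep),
            corpus.month_range,
        )
        full_idx = H.build_index(reduced, lexicon)
        assert sub_idx.values == pytest.approx(full_idx.values, rel=1e-12)

    def test_unknown_subset_member_rejected(self, toy_corpus, lexicon):
        with pytest.raises(H.ValidationError, match="ghost"):
            H.build_index(toy_corpus, lexicon, newspapers=["p1", "ghost"])

    def test_error_names_the_build(self, lexicon):
        # p1 matches nothing -> constant zero series -> degenerate
        corpus = H.Corpus(
            tuple(
                make_article(month=m, art_id=f"a{m}", text="晴天")
                for m in (1, 2)
            ),
            ("p1",),
            ("2003-01", "2003-02"),
        )
        with pytest.raises(H.DegenerateSeriesError, match="building index"):
            H.build_index(corpus, lexicon, label="toy")


class TestSplice:
    def _series(self, months, values):
        return H.IndexSeries(list(months), np.array(values, dtype=float))

    def test_empty_gap_is_renormalization_noop(self):
        s = self._series(["2003-01", "2003-02"], [50.0, 150.0])
        out = H.splice_indexes(s, s, [])
        assert out.index.values.tolist() == [50.0, 150.0]

    def test_union_of_months_mean_100(self):
        gapped = self._series(
            ["2003-01", "2003-02", "2003-04"], [80.0, 120.0, 100.0]
        )
        donor = self._series(
            ["2003-01", "2003-02", "2003-03", "2003-04"],
            [80.0, 120.0, 60.0, 100.0],
        )
        out = H.splice_indexes(gapped, donor, ["2003-03"])
        assert out.index.months == [
            "2003-01", "2003-02", "2003-03", "2003-04"
        ]
        assert float(out.index.values.mean()) == pytest.approx(100.0, rel=1e-9)
        assert out.overlap_r == pytest.approx(1.0)
        # gap month got the donor value, re-scaled by the union mean
        assert out.index.values[2] == pytest.approx(60.0 / 90.0 * 100.0)

    def test_donor_missing_gap_month_rejected(self):
        gapped = self._series(["2003-01", "2003-02"], [80.0, 120.0])
        donor = self._series(["2003-01", "2003-02"], [80.0, 120.0])
        with pytest.raises(H.ValidationError, match="2003-03"):
            H.splice_indexes(gapped, donor, ["2003-03"])

    def test_disjoint_series_cannot_be_validated(self):
        gapped = self._series(["2003-01", "2003-02"], [80.0, 120.0])
        donor = self._series(["2004-01", "2004-02"], [80.0, 120.0])
        with pytest.raises(H.ValidationError, match="overlap|share"):
            H.splice_indexes(gapped, donor, ["2004-01"])


class TestIndexIO:
    def test_round_trip_to_six_decimals(self, tmp_path, toy_corpus, lexicon):
        idx = H.build_index(toy_corpus, lexicon, label="toy")
        path = tmp_path / "index.csv"
        H.write_index(idx, path)
        back = H.read_index(path)
        assert back.months == idx.months
        assert back.values == pytest.approx(idx.values, abs=5e-7)
        assert (tmp_path / "index.csv.meta.json").exists()
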