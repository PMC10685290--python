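from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hpuindex as H

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lexicon() -> H.KeywordLexicon:
    return H.builtin_lexicon()


def make_article(paper="p1", year=2003, month=1, art_id="a1", text="正文"):
    return H.Article(
        newspaper_id=paper, year=year, month=month, article_id=art_id,
        text=text,
    )


@pytest.fixture
def toy_corpus() -> H.Corpus:
    """Two papers, three months, hand-chosen counts.

    Per cell (paper, month): p1 has 1/2/3 matching of 10 total, p2 has
    0/2/4 matching of 10 total.  Matching articles carry one term of each
    category; the rest are plain filler.
    """
    match_text = "昨日卫生系统传达，政府文件指出前景不确定。"
    plain_text = "昨日天气晴好，球队赢得比赛。"
    A = {"p1": [1, 2, 3], "p2": [0, 2, 4]}
    total = 10
    articles = []
    k = 0
    for paper, counts in A.items():
        for month, n_match in enumerate(counts, start=1):
            for j in range(total):
                k += 1
                articles.append(
                    make_article(
                        paper=paper, year=2003, month=month,
                        art_id=f"t{k:04d}",
                        text=match_text if j < n_match else plain_text,
                    )
                )
    return H.Corpus(
        articles=tuple(articles),
        newspapers=("p1", "p2"),
        month_range=("2003-01", "2003-03"),
    )


@pytest.fixture(scope="session")
def small_spec() -> H.SyntheticSpec:
    """A fast 3-paper, 12-month simulation used by unit tests."""
    return H.SyntheticSpec(
        newspapers=tuple(
            H.NewspaperSpec(id=p, monthly_volume=40.0)
            for p in ("alpha", "beta", "gamma")
        ),
        month_range=("2010-01", "2010-12"),
        baseline_rate=0.05,
        events={"2010-07": 5.0},
        decoy_rate=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return H.generate_corpus(small_spec)
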