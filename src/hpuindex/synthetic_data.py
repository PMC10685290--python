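"""Synthetic newspaper corpora with known ground truth.

The real measurement model behind a newspaper-count uncertainty index is:
each paper prints a month-varying number of articles, a small fraction of
which concern policy uncertainty, and that fraction moves with a latent
monthly intensity all papers partly share (event shocks, news climate)
plus paper-specific noise.  The generator emulates exactly that:

* per newspaper-month, total articles ~ Poisson(lambda_i);
* each article is HPU-relevant with probability
  p_t = p0 * m_t * exp(eps_shared_t + eps_i_t), where m_t is a
  month-specific event multiplier and the eps are Gaussian log-rate
  perturbations (shared across papers vs idiosyncratic);
* relevant articles receive at least one term from EACH lexicon category,
  embedded in filler text; a ``decoy_rate`` fraction of the non-relevant
  articles receive terms from exactly two categories (so a correct
  three-category screen must reject them); the rest are pure filler;
* declared coverage gaps produce newspaper-months with no articles at all.

Every planted count is bookkept in :class:`GroundTruth`, so the keyword
screen can be checked for *exact* agreement and the index pipeline for
signal recovery.  Filler vocabulary is validated to share no characters
with the lexicon and planted terms are never adjacent, so no unintended
category match can arise by construction.

Randomness is a single hierarchical stream keyed (seed, newspaper, month):
adding or removing a newspaper never perturbs another newspaper's draws.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .corpus_io import Article, Corpus, CountPanel
from .errors import InputOutputError, ValidationError
from .index_construction import (
    IndexSeries,
    RatioPanel,
    aggregate,
    normalize,
    standardize,
)
from .keyword_matching import CATEGORIES, KeywordLexicon, builtin_lexicon
from .months import month_span, parse_month

__all__ = [
    "NewspaperSpec",
    "SyntheticSpec",
    "GroundTruth",
    "DEFAULT_FILLER_VOCAB",
    "default_spec",
    "generate_corpus",
    "expected_index",
    "load_spec",
]

# Filler words whose characters are disjoint from every builtin lexicon
# term, so concatenation can never complete a keyword across a boundary.
DEFAULT_FILLER_VOCAB: tuple[str, ...] = (
    "天空", "足球", "音乐", "旅游", "森林", "咖啡", "电影", "小说",
    "火车", "城市", "学校", "朋友", "晚餐", "公园", "河边", "山顶",
    "星辰", "跑步", "唱歌", "夏季", "窗外", "茶馆", "画展", "舞蹈",
    "棋盘", "云彩", "海洋", "沙滩", "厨房", "早晨",
)

_SHARED_TAG = 0x5A11CE  # stream tag for the shared monthly perturbation


@dataclass(frozen=True)
class NewspaperSpec:
    """One simulated paper: id, mean monthly article volume, gap months."""

    id: str
    monthly_volume: float
    gap_months: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.id.strip():
            raise ValidationError("newspaper id must be non-empty")
        if not self.monthly_volume > 0:
            raise ValidationError(
                f"newspaper {self.id!r}: monthly_volume must be positive"
            )
        object.__setattr__(
            self, "gap_months", frozenset(str(m) for m in self.gap_months)
        )
        for m in self.gap_months:
            parse_month(m)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of a simulated corpus."""

    newspapers: tuple[NewspaperSpec, ...]
    month_range: tuple[str, str]
    baseline_rate: float
    events: Mapping[str, float] = field(default_factory=dict)
    decoy_rate: float = 0.1
    shared_signal_sd: float = 0.25
    idiosyncratic_sd: float = 0.15
    seed: int = 0
    lexicon: KeywordLexicon = field(default_factory=builtin_lexicon)
    filler_vocab: tuple[str, ...] = DEFAULT_FILLER_VOCAB

    def __post_init__(self):
        if not self.newspapers:
            raise ValidationError("spec needs at least one newspaper")
        ids = [n.id for n in self.newspapers]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate newspaper ids in spec")
        month_span(*self.month_range)
        if not (0.0 <= self.baseline_rate <= 1.0):
            raise ValidationError("baseline_rate must lie in [0, 1]")
        if not (0.0 <= self.decoy_rate < 1.0):
            raise ValidationError("decoy_rate must lie in [0, 1)")
        if self.shared_signal_sd < 0 or self.idiosyncratic_sd < 0:
            raise ValidationError("signal SDs must be nonnegative")
        events = {str(k): float(v) for k, v in dict(self.events).items()}
        for m, mult in events.items():
            parse_month(m)
            if mult < 0:
                raise ValidationError(f"event multiplier at {m} is negative")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "filler_vocab", tuple(self.filler_vocab))
        if not self.filler_vocab:
            raise ValidationError("filler_vocab must be non-empty")
        terms = self.lexicon.all_terms()
        for w in self.filler_vocab:
            for t in terms:
                if t in w:
                    raise ValidationError(
                        f"filler word {w!r} contains lexicon term {t!r}"
                    )
        # ground-truth exactness also needs no term of one category hiding
        # inside a term of another (a planted decoy could then complete a
        # triple)
        by_cat = {c: self.lexicon.category(c) for c in CATEGORIES}
        for c1, t1s in by_cat.items():
            for c2, t2s in by_cat.items():
                if c1 == c2:
                    continue
                for t1 in t1s:
                    for t2 in t2s:
                        if t2 in t1:
                            raise ValidationError(
                                f"lexicon term {t2!r} ({c2}) occurs inside "
                                f"{t1!r} ({c1}); planted counts would not "
                                "be exact"
                            )

    @property
    def months(self) -> list[str]:
        return month_span(*self.month_range)

    def multiplier(self, month: str) -> float:
        return float(self.events.get(month, 1.0))

    def rate_bound(self) -> float:
        """Documented worst-case relevance probability:
        p0 * max multiplier * exp(3 * (shared_sd + idio_sd)).  Rates above
        1 are clamped (with a warning) during generation."""
        max_m = max([1.0, *self.events.values()]) if self.events else 1.0
        return self.baseline_rate * max_m * float(
            np.exp(3.0 * (self.shared_signal_sd + self.idiosyncratic_sd))
        )

    def gap_declarations(self) -> dict[str, list[str]]:
        return {
            n.id: sorted(n.gap_months)
            for n in self.newspapers
            if n.gap_months
        }


@dataclass
class GroundTruth:
    """Planted bookkeeping for a generated corpus: per newspaper-month
    total / relevant / decoy counts, and the shared latent relevance path
    p0 * m_t * exp(eps_shared_t) per month."""

    totals: CountPanel
    relevant: CountPanel
    decoys: CountPanel
    latent_path: dict[str, float]


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default study-shaped simulation: 11 papers at 100 articles per
    month over 60 months, a 3% baseline relevance rate, and one event
    month with an 8-fold shock."""
    from .robustness_audit import GROUP_PRESETS

    papers = tuple(
        NewspaperSpec(id=p, monthly_volume=100.0)
        for p in GROUP_PRESETS["ALL"].members
    )
    return SyntheticSpec(
        newspapers=papers,
        month_range=("2003-01", "2007-12"),
        baseline_rate=0.03,
        events={"2005-06": 8.0},
        decoy_rate=0.1,
        seed=seed,
    )


def _paper_tag(paper_id: str) -> int:
    h = hashlib.blake2b(paper_id.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(h, "big")


def _cell_rng(seed: int, tag: int, t_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, t_index])
    )


_PERM3 = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
_PAIRS = [(0, 1), (0, 2), (1, 2)]


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, GroundTruth]:
    """Simulate a corpus and its ground truth, reproducibly from the seed."""
    months = spec.months
    papers = [n.id for n in spec.newspapers]
    lam = {n.id: n.monthly_volume for n in spec.newspapers}
    gaps = {n.id: n.gap_months for n in spec.newspapers}
    cat_terms = [sorted(spec.lexicon.category(c)) for c in CATEGORIES]
    filler = list(spec.filler_vocab)
    nf = len(filler)

    # shared monthly log-rate perturbation, one sub-stream per month so the
    # path does not depend on the newspaper roster
    eps_shared = np.array(
        [
            _cell_rng(spec.seed, _SHARED_TAG, t).normal(0.0, spec.shared_signal_sd)
            if spec.shared_signal_sd > 0
            else 0.0
            for t in range(len(months))
        ]
    )
    latent_path = {
        m: spec.baseline_rate * spec.multiplier(m) * float(np.exp(eps_shared[t]))
        for t, m in enumerate(months)
    }

    shape = (len(papers), len(months))
    totals = np.full(shape, np.nan)
    relevant = np.full(shape, np.nan)
    decoys = np.full(shape, np.nan)
    articles: list[Article] = []
    clamped = 0

    for i, paper in enumerate(papers):
        tag = _paper_tag(paper)
        for t, m in enumerate(months):
            if m in gaps[paper]:
                continue
            rng = _cell_rng(spec.seed, tag, t)
            n = int(rng.poisson(lam[paper]))
            eps_i = (
                rng.normal(0.0, spec.idiosyncratic_sd)
                if spec.idiosyncratic_sd > 0
                else 0.0
            )
            p = latent_path[m] * float(np.exp(eps_i))
            if p > 1.0:
                clamped += 1
                p = 1.0
            totals[i, t] = n
            if n == 0:
                relevant[i, t] = 0
                decoys[i, t] = 0
                continue
            k_rel = int(rng.binomial(n, p))
            perm = rng.permutation(n)
            rel_pos = set(perm[:k_rel].tolist())
            rest = perm[k_rel:]
            if spec.decoy_rate > 0 and rest.size:
                decoy_mask = rng.random(rest.size) < spec.decoy_rate
                decoy_pos = set(rest[decoy_mask].tolist())
            else:
                decoy_pos = set()
            relevant[i, t] = k_rel
            decoys[i, t] = len(decoy_pos)

            # pre-drawn randomness for fast text assembly
            fw = rng.integers(0, nf, size=(n, 7))
            n_fill = rng.integers(2, 6, size=n)
            term_idx = [
                rng.integers(0, len(ts), size=n) for ts in cat_terms
            ]
            perm_id = rng.integers(0, 6, size=n)
            pair_id = rng.integers(0, 3, size=n)
            year, mon = parse_month(m)
            for k in range(n):
                if k in rel_pos:
                    order = _PERM3[perm_id[k]]
                    terms = [
                        cat_terms[c][term_idx[c][k]] for c in order
                    ]
                elif k in decoy_pos:
                    c1, c2 = _PAIRS[pair_id[k]]
                    terms = [
                        cat_terms[c1][term_idx[c1][k]],
                        cat_terms[c2][term_idx[c2][k]],
                    ]
                    if perm_id[k] % 2:
                        terms.reverse()
                else:
                    terms = []
                # planted terms separated by filler, never adjacent
                parts = [filler[fw[k, 0]]]
                for j, term in enumerate(terms):
                    parts.append(term)
                    parts.append(filler[fw[k, j + 1]])
                parts.extend(
                    filler[fw[k, 3 + j]] for j in range(int(n_fill[k]) % 4)
                )
                articles.append(
                    Article(
                        newspaper_id=paper,
                        year=year,
                        month=mon,
                        article_id=f"{paper}-{m}-{k:05d}",
                        text="".join(parts),
                    )
                )

    if clamped:
        warnings.warn(
            f"relevance rate clamped to 1 in {clamped} newspaper-month(s); "
            f"documented rate bound is {spec.rate_bound():.3f}",
            stacklevel=2,
        )
    corpus = Corpus(
        articles=tuple(articles),
        newspapers=tuple(papers),
        month_range=spec.month_range,
    )
    truth = GroundTruth(
        totals=CountPanel(papers, months, totals),
        relevant=CountPanel(papers, months, relevant),
        decoys=CountPanel(papers, months, decoys),
        latent_path=latent_path,
    )
    return corpus, truth


def expected_index(spec: SyntheticSpec) -> IndexSeries:
    """The noise-free index implied by the latent path.

    Runs the scale/standardize/average/normalize cascade on the
    deterministic scaled frequencies X_it = p0 * m_t, identical across
    newspapers — the target the pipeline should recover up to sampling
    noise.  A flat path (no events) is degenerate, exactly as a constant
    newspaper series is for standardization.
    """
    months = spec.months
    papers = [n.id for n in spec.newspapers]
    row = np.array(
        [spec.baseline_rate * spec.multiplier(m) for m in months]
    )
    X = RatioPanel(papers, months, np.tile(row, (len(papers), 1)))
    out = normalize(aggregate(standardize(X)))
    out.label = "expected"
    return out


def load_spec(path: str | Path) -> SyntheticSpec:
    """Read a simulation spec from YAML.

    Recognized keys: ``newspapers`` (list of {id, monthly_volume,
    gap_months}), ``month_range`` ([first, last]), ``baseline_rate``,
    ``events`` ({month: multiplier}), ``decoy_rate``,
    ``shared_signal_sd``, ``idiosyncratic_sd``, ``seed``.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"spec file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, Mapping):
        raise ValidationError("spec file must be a mapping")
    try:
        papers = tuple(
            NewspaperSpec(
                id=str(n["id"]),
                monthly_volume=float(n.get("monthly_volume", 100.0)),
                gap_months=frozenset(
                    str(g) for g in n.get("gap_months", ())
                ),
            )
            for n in data["newspapers"]
        )
        rng = data["month_range"]
        kwargs = dict(
            newspapers=papers,
            month_range=(str(rng[0]), str(rng[1])),
            baseline_rate=float(data["baseline_rate"]),
        )
    except (KeyError, TypeError, IndexError) as e:
        raise ValidationError(f"malformed simulation spec: {e}") from e
    for key in (
        "events", "decoy_rate", "shared_signal_sd", "idiosyncratic_sd", "seed",
    ):
        if key in data:
            kwargs[key] = data[key]
    return SyntheticSpec(**kwargs)
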