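"""Three-category keyword screening of articles.

An article is a *target article* when its text contains at least one term
from EACH of the three categories — health, policy, uncertainty.  Matching
is plain substring containment on NFKC-normalized Unicode text, with no
word segmentation: the counts are meant to reproduce what a keyword query
against a newspaper database would return, and segmentation would silently
change them.  Chinese needs no token boundaries for this; a custom lexicon
file may carry terms in any language.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .corpus_io import Corpus, CountPanel, CoverageMask
from .errors import InputOutputError, ValidationError

__all__ = [
    "CATEGORIES",
    "BUILTIN_LEXICON_NAME",
    "KeywordLexicon",
    "MatchResult",
    "load_lexicon",
    "article_matches",
    "count_matches",
]

CATEGORIES = ("health", "policy", "uncertainty")

BUILTIN_LEXICON_NAME = "hpu-china-2003"

# The Chinese screening lexicon for the China HPU index. Slash-separated
# variant groups are expanded to individual terms; matching treats every
# term independently.
_BUILTIN_TERMS: dict[str, tuple[str, ...]] = {
    # health care / medicine
    "health": ("卫生", "医药"),
    # policy/measures; government/authority; country leaders; regulation;
    # health care reform
    "policy": (
        "制度", "体制", "战略", "措施", "条例",
        "政府", "国务院", "人大", "人民代表大会",
        "主席", "总书记", "总理",
        "整治", "监管", "规章",
        "医改", "医疗改革", "医保",
    ),
    # uncertainty/uncertain; volatile; unstable/unclear; unpredictable;
    # plunge/surge
    "uncertainty": (
        "不确定", "不明确",
        "波动", "不稳",
        "不明朗", "未明",
        "难料", "难以预计", "难以预测", "难以估计", "难以预料",
        "流失", "亏损", "骤跌", "衰退", "激增", "滞后",
    ),
}


def _norm(s: str) -> str:
    return unicodedata.normalize("NFKC", s)


@dataclass(frozen=True)
class KeywordLexicon:
    """Three named term sets. Terms are NFKC-normalized and deduplicated
    at construction; every category must end up non-empty."""

    health: frozenset[str]
    policy: frozenset[str]
    uncertainty: frozenset[str]
    name: str = "custom"

    def __post_init__(self):
        for cat in CATEGORIES:
            terms = getattr(self, cat)
            normed = frozenset(_norm(t) for t in terms)
            if not normed:
                raise ValidationError(f"lexicon category {cat!r} is empty")
            if any(not t for t in normed):
                raise ValidationError(
                    f"lexicon category {cat!r} contains an empty term"
                )
            object.__setattr__(self, cat, normed)

    def category(self, cat: str) -> frozenset[str]:
        if cat not in CATEGORIES:
            raise ValidationError(f"unknown lexicon category {cat!r}")
        return getattr(self, cat)

    def all_terms(self) -> frozenset[str]:
        return self.health | self.policy | self.uncertainty


def builtin_lexicon() -> KeywordLexicon:
    """The default China HPU screening lexicon."""
    return KeywordLexicon(
        health=frozenset(_BUILTIN_TERMS["health"]),
        policy=frozenset(_BUILTIN_TERMS["policy"]),
        uncertainty=frozenset(_BUILTIN_TERMS["uncertainty"]),
        name=BUILTIN_LEXICON_NAME,
    )


def load_lexicon(path: str | Path | None = None) -> KeywordLexicon:
    """Load a lexicon from a YAML/JSON file, or the builtin.

    ``path`` of None or the builtin name returns the packaged Chinese
    lexicon.  A file must carry the keys ``health``, ``policy`` and
    ``uncertainty``, each a non-empty list of strings; duplicates are
    collapsed.
    """
    if path is None or str(path) == BUILTIN_LEXICON_NAME:
        return builtin_lexicon()
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"lexicon file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, Mapping):
        raise ValidationError("lexicon file must be a mapping")
    missing = set(CATEGORIES) - set(data)
    if missing:
        raise ValidationError(f"lexicon missing categories: {sorted(missing)}")
    sets = {}
    for cat in CATEGORIES:
        terms = data[cat]
        if not isinstance(terms, (list, tuple)):
            raise ValidationError(f"lexicon category {cat!r} must be a list")
        sets[cat] = frozenset(str(t) for t in terms)
    return KeywordLexicon(name=str(data.get("name", path.stem)), **sets)


@dataclass(frozen=True)
class MatchResult:
    """Screening outcome for one article: the decision plus, for audit
    transparency, exactly which terms of each category were found."""

    matched: bool
    hits: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def match_text(text: str, lexicon: KeywordLexicon) -> MatchResult:
    """Screen a raw text string (already any language; NFKC applied here)."""
    normed = _norm(text)
    hits: dict[str, tuple[str, ...]] = {}
    matched = True
    for cat in CATEGORIES:
        found = tuple(sorted(t for t in lexicon.category(cat) if t in normed))
        hits[cat] = found
        if not found:
            matched = False
    return MatchResult(matched=matched, hits=hits)


def article_matches(article, lexicon: KeywordLexicon) -> MatchResult:
    """Decide whether an article satisfies the three-category criterion."""
    return match_text(article.text, lexicon)


def count_matches(
    corpus: Corpus,
    lexicon: KeywordLexicon,
    mask: CoverageMask | None = None,
) -> CountPanel:
    """The target-article panel A_it: matching articles per newspaper-month.

    Cells where ``mask`` is False become MISSING; by construction
    A_it <= B_it cell-wise against :func:`hpuindex.corpus_io.monthly_totals`
    built with the same mask.
    """
    months = corpus.months
    papers = list(corpus.newspapers)
    if mask is not None and (mask.newspapers != papers or mask.months != months):
        raise ValidationError("coverage mask does not match corpus layout")
    month_pos = {m: j for j, m in enumerate(months)}
    paper_pos = {p: i for i, p in enumerate(papers)}
    counts = np.zeros((len(papers), len(months)), dtype=float)
    # cheap pre-normalized term tuples, health first: most articles fail
    # the smallest category quickly
    cats = [tuple(lexicon.category(c)) for c in CATEGORIES]
    for a in corpus.articles:
        text = _norm(a.text)
        ok = True
        for terms in cats:
            if not any(t in text for t in terms):
                ok = False
                break
        if ok:
            counts[paper_pos[a.newspaper_id], month_pos[a.ym]] += 1
    if mask is not None:
        counts[~mask.covered] = np.nan
    return CountPanel(papers, months, counts)
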