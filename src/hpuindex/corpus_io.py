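"""Newspaper corpora: reading, writing, validation, and monthly count panels.

A corpus is a flat collection of articles, each tagged with a newspaper
identifier and a publication year-month.  The index construction consumes
two per-newspaper monthly panels derived from a corpus: the total article
count B_it (built here by :func:`monthly_totals`) and the screened target
count A_it (built by :mod:`hpuindex.keyword_matching`).

Coverage gaps — newspaper-months for which the source database simply has
no data — are *declared* metadata, never inferred from zero counts: a
covered month with zero articles is a legitimate 0, while a gap month is
MISSING (NaN) and is excluded from every downstream statistic.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    EmptyCorpusError,
    InputOutputError,
    ParseError,
    ValidationError,
)
from .months import expand_gap_token, month_key, month_span, parse_month

__all__ = [
    "Article",
    "Corpus",
    "CountPanel",
    "CoverageMask",
    "read_corpus",
    "write_corpus",
    "monthly_totals",
    "coverage_mask",
    "load_gap_declarations",
]


@dataclass(frozen=True)
class Article:
    """One newspaper story: source paper, publication month, full text."""

    newspaper_id: str
    year: int
    month: int
    article_id: str
    text: str

    def __post_init__(self):
        if not str(self.newspaper_id).strip():
            raise ValidationError("newspaper_id must be a non-empty token")
        month_key(self.year, self.month)  # range validation
        if not str(self.article_id):
            raise ValidationError("article_id must be non-empty")
        if not str(self.text).strip():
            raise ValidationError(
                f"article {self.article_id!r}: text empty after stripping"
            )

    @property
    def ym(self) -> str:
        return month_key(self.year, self.month)


@dataclass(frozen=True)
class Corpus:
    """An ordered article collection plus its newspaper roster and the
    inclusive month range the counts should span.

    The roster and month range may be wider than what the articles touch
    (a newspaper with zero articles in some covered month contributes a
    legitimate B_it = 0), but every article must fall inside both.
    """

    articles: tuple[Article, ...]
    newspapers: tuple[str, ...]
    month_range: tuple[str, str]

    def __post_init__(self):
        roster = set(self.newspapers)
        if len(roster) != len(self.newspapers):
            raise ValidationError("duplicate newspaper_id in roster")
        months = set(month_span(*self.month_range))
        seen_ids: set[str] = set()
        for a in self.articles:
            if a.newspaper_id not in roster:
                raise ValidationError(
                    f"article {a.article_id!r}: newspaper {a.newspaper_id!r} "
                    "not in roster"
                )
            if a.ym not in months:
                raise ValidationError(
                    f"article {a.article_id!r}: month {a.ym} outside "
                    f"range {self.month_range[0]}..{self.month_range[1]}"
                )
            if a.article_id in seen_ids:
                raise ValidationError(f"duplicate article_id {a.article_id!r}")
            seen_ids.add(a.article_id)

    @property
    def months(self) -> list[str]:
        return month_span(*self.month_range)

    def __len__(self) -> int:
        return len(self.articles)

    def restrict(
        self,
        newspapers: Sequence[str] | None = None,
        month_range: tuple[str, str] | None = None,
    ) -> "Corpus":
        """A sub-corpus limited to a newspaper subset and/or month range.

        Equivalent to having collected only those papers/months in the
        first place; articles outside the restriction are dropped.
        """
        papers = tuple(newspapers) if newspapers is not None else self.newspapers
        unknown = set(papers) - set(self.newspapers)
        if unknown:
            raise ValidationError(
                f"unknown newspaper(s) in subset: {sorted(unknown)}"
            )
        if not papers:
            raise ValidationError("newspaper subset must be non-empty")
        rng = month_range if month_range is not None else self.month_range
        keep_months = set(month_span(*rng))
        keep_papers = set(papers)
        arts = tuple(
            a
            for a in self.articles
            if a.newspaper_id in keep_papers and a.ym in keep_months
        )
        return Corpus(articles=arts, newspapers=papers, month_range=rng)


def _build_corpus(
    records: Iterable[tuple[int, dict]],
    month_range: tuple[str, str] | None,
) -> Corpus:
    articles: list[Article] = []
    auto = 0
    for lineno, rec in records:
        try:
            paper = str(rec["newspaper"])
            year = int(rec["year"])
            month = int(rec["month"])
            text = str(rec["text"])
        except KeyError as e:
            raise ParseError(f"missing field {e.args[0]!r}", line=lineno) from e
        except (TypeError, ValueError) as e:
            raise ParseError(f"bad field value: {e}", line=lineno) from e
        art_id = rec.get("id")
        if art_id is None or str(art_id) == "":
            auto += 1
            art_id = f"a{auto:06d}"
        try:
            articles.append(
                Article(
                    newspaper_id=paper,
                    year=year,
                    month=month,
                    article_id=str(art_id),
                    text=text,
                )
            )
        except ValidationError as e:
            raise ParseError(str(e), line=lineno) from e
    if not articles:
        raise EmptyCorpusError("corpus file contains no records")
    roster = tuple(dict.fromkeys(a.newspaper_id for a in articles))
    if month_range is None:
        keys = sorted(a.ym for a in articles)
        month_range = (keys[0], keys[-1])
    return Corpus(tuple(articles), roster, month_range)


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    month_range: tuple[str, str] | None = None,
) -> Corpus:
    """Read a corpus from a JSONL or CSV file.

    JSONL: one object per line with keys ``newspaper``, ``year``,
    ``month``, ``text`` and optional ``id``.  CSV: the same columns with a
    header row.  Files must be UTF-8; undecodable input is a hard error
    rather than a silent skip, because skipped records would bias counts.

    ``month_range`` overrides the inferred min..max observed span (useful
    when the collection window is wider than the articles happen to cover).
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"corpus file not found: {path}")
    try:
        raw = path.read_bytes().decode("utf-8")
    except UnicodeDecodeError as e:
        raise ParseError(f"file is not valid UTF-8: {e}") from e
    if format == "jsonl":
        def records():
            for lineno, line in enumerate(raw.splitlines(), start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as e:
                    raise ParseError(f"invalid JSON: {e.msg}", line=lineno) from e
                if not isinstance(obj, dict):
                    raise ParseError("record is not an object", line=lineno)
                yield lineno, obj
        return _build_corpus(records(), month_range)
    if format == "csv":
        def records():
            reader = csv.DictReader(io.StringIO(raw))
            if reader.fieldnames is None:
                raise EmptyCorpusError("CSV file has no header")
            missing = {"newspaper", "year", "month", "text"} - set(
                reader.fieldnames
            )
            if missing:
                raise ParseError(f"CSV header missing columns {sorted(missing)}")
            for rowno, row in enumerate(reader, start=2):
                yield rowno, {k: v for k, v in row.items() if v is not None}
        return _build_corpus(records(), month_range)
    raise ValidationError(f"unknown corpus format {format!r}")


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus so that :func:`read_corpus` reproduces it exactly
    (article order preserved; roster and month range re-inferred)."""
    if not corpus.newspapers:
        raise ValidationError("refusing to write a corpus with an empty roster")
    if not corpus.articles:
        raise ValidationError("refusing to write an empty corpus")
    path = Path(path)
    try:
        if format == "jsonl":
            with path.open("w", encoding="utf-8") as fh:
                for a in corpus.articles:
                    fh.write(
                        json.dumps(
                            {
                                "newspaper": a.newspaper_id,
                                "year": a.year,
                                "month": a.month,
                                "id": a.article_id,
                                "text": a.text,
                            },
                            ensure_ascii=False,
                        )
                        + "\n"
                    )
        elif format == "csv":
            with path.open("w", encoding="utf-8", newline="") as fh:
                writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
                writer.writerow(["newspaper", "year", "month", "id", "text"])
                for a in corpus.articles:
                    writer.writerow(
                        [a.newspaper_id, a.year, a.month, a.article_id, a.text]
                    )
        else:
            raise ValidationError(f"unknown corpus format {format!r}")
    except OSError as e:
        raise InputOutputError(f"cannot write {path}: {e}") from e


@dataclass
class CountPanel:
    """A newspapers x months matrix of nonnegative counts.

    ``values`` is a float matrix; NaN marks a MISSING (gap) cell, every
    present cell is a nonnegative integer stored as float.  Rows follow
    ``newspapers``, columns follow ``months`` (strictly increasing).
    """

    newspapers: list[str]
    months: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.newspapers = list(self.newspapers)
        self.months = list(self.months)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.newspapers), len(self.months)):
            raise ValidationError(
                f"panel shape {self.values.shape} != "
                f"({len(self.newspapers)}, {len(self.months)})"
            )
        for k in self.months:
            parse_month(k)
        if any(a >= b for a, b in zip(self.months, self.months[1:])):
            raise ValidationError("months must be strictly increasing")
        present = self.values[~np.isnan(self.values)]
        if present.size and (present < 0).any():
            raise ValidationError("counts must be nonnegative")
        if present.size and not np.array_equal(present, np.floor(present)):
            raise ValidationError("counts must be integers")

    @property
    def present(self) -> np.ndarray:
        """Boolean matrix: True where the cell holds a count."""
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.newspapers), columns=list(self.months)
        )

    def cell(self, newspaper: str, month: str) -> float:
        return self.values[self.newspapers.index(newspaper),
                           self.months.index(month)]


@dataclass
class CoverageMask:
    """Boolean newspapers x months matrix: True where the newspaper-month
    is covered (data exists, possibly zero articles)."""

    newspapers: list[str]
    months: list[str]
    covered: np.ndarray

    def __post_init__(self):
        self.newspapers = list(self.newspapers)
        self.months = list(self.months)
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.covered.shape != (len(self.newspapers), len(self.months)):
            raise ValidationError("mask shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.covered, index=list(self.newspapers), columns=list(self.months)
        )


def coverage_mask(
    corpus: Corpus,
    declared_gaps: Mapping[str, Iterable[str]] | None = None,
) -> CoverageMask:
    """Build the coverage mask from declared gaps.

    ``declared_gaps`` maps newspaper_id to an iterable of gap tokens, each
    either ``"YYYY-MM"`` or a bare ``"YYYY"`` (expands to all 12 months).
    With no declarations every cell is covered.
    """
    months = corpus.months
    papers = list(corpus.newspapers)
    covered = np.ones((len(papers), len(months)), dtype=bool)
    if declared_gaps:
        month_pos = {m: j for j, m in enumerate(months)}
        roster = set(papers)
        for paper, tokens in declared_gaps.items():
            if paper not in roster:
                raise ValidationError(
                    f"gap declared for unknown newspaper {paper!r}"
                )
            i = papers.index(paper)
            for token in tokens:
                for m in expand_gap_token(token):
                    j = month_pos.get(m)
                    if j is not None:
                        covered[i, j] = False
    return CoverageMask(papers, months, covered)


def monthly_totals(corpus: Corpus, mask: CoverageMask | None = None) -> CountPanel:
    """The total-article panel B_it: articles per newspaper per month.

    Covered months with no articles are 0; months falling in a declared
    gap (mask False) are MISSING regardless of counts.
    """
    months = corpus.months
    papers = list(corpus.newspapers)
    month_pos = {m: j for j, m in enumerate(months)}
    paper_pos = {p: i for i, p in enumerate(papers)}
    counts = np.zeros((len(papers), len(months)), dtype=float)
    for a in corpus.articles:
        counts[paper_pos[a.newspaper_id], month_pos[a.ym]] += 1
    if mask is not None:
        if mask.newspapers != papers or mask.months != months:
            raise ValidationError("coverage mask does not match corpus layout")
        counts[~mask.covered] = np.nan
    return CountPanel(papers, months, counts)


def load_gap_declarations(path: str | Path) -> dict[str, list[str]]:
    """Read a YAML/JSON map of newspaper -> list of gap tokens."""
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"gap declaration file not found: {path}")
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValidationError("gap declarations must be a mapping")
    out: dict[str, list[str]] = {}
    for paper, tokens in data.items():
        if isinstance(tokens, (str, int)):
            tokens = [tokens]
        out[str(paper)] = [str(t) for t in tokens]
    return out
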