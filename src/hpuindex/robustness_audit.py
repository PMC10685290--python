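"""Robustness battery and audit-sampling workflow.

Two checks guard a newspaper-count uncertainty index.  First, the index
should not depend on which papers were sampled: indexes rebuilt from
newspaper subgroups (national papers, party papers, metropolitan papers)
should correlate strongly with the full index and with each other — a
pairwise Pearson r of at least 0.74 is the conventional pass criterion.
Second, the keyword screen should actually retrieve articles about health
policy uncertainty: a stratified random half of the target articles per
paper is drawn for human review, and the resulting pass rate tabulated.

Human adjudication itself is out of scope: this module samples, stores
two rounds of labels, and tabulates; people read the articles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Corpus
from .errors import (
    DegenerateDataError,
    InputOutputError,
    InsufficientOverlapError,
    ValidationError,
)
from .index_construction import IndexSeries, build_index
from .keyword_matching import KeywordLexicon
from .months import parse_month

__all__ = [
    "NewspaperGroup",
    "CorrelationResult",
    "AuditSample",
    "PassRate",
    "GROUP_PRESETS",
    "pearson",
    "robustness_report",
    "RobustnessReport",
    "sample_for_audit",
    "pass_rate",
    "resolve_labels",
    "compare_external",
    "read_external_series",
]


@dataclass(frozen=True)
class NewspaperGroup:
    """A named newspaper subset (e.g. ALL, NNI, PNI, MNI)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"group {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"group {self.name!r} has duplicate members")

    def validate_against(self, roster: Iterable[str]) -> None:
        unknown = set(self.members) - set(roster)
        if unknown:
            raise ValidationError(
                f"group {self.name!r} references unknown newspaper(s): "
                f"{sorted(unknown)}"
            )


# Default subgroup presets for an 11-paper Chinese roster: the full set,
# the national papers (local Beijing papers removed), the two party organs,
# and the nine market-oriented metropolitan papers.
_PD, _GD = "peoples_daily", "guangming_daily"
_METRO = (
    "southern_metropolis_daily",
    "yangcheng_evening_news",
    "new_express_daily",
    "xinmin_evening_news",
    "morning_news",
    "nanfang_daily",
    "morning_post",
)
_LOCAL = ("beijing_evening_news", "beijing_daily")

GROUP_PRESETS: dict[str, NewspaperGroup] = {
    "ALL": NewspaperGroup("ALL", (_PD, _GD) + _METRO + _LOCAL),
    "NNI": NewspaperGroup("NNI", (_PD, _GD) + _METRO),
    "PNI": NewspaperGroup("PNI", (_PD, _GD)),
    "MNI": NewspaperGroup("MNI", _METRO + _LOCAL),
}


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-sided p-value and overlap size."""

    r: float
    p_value: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise ValidationError("correlation needs n >= 3")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"r = {self.r} outside [-1, 1]")

    def render_p(self) -> str:
        """P-value formatted for report tables: '<.001' below 0.001."""
        if self.p_value < 0.001:
            return "<.001"
        return f"{self.p_value:.3f}".lstrip("0") or ".000"


def pearson(a: IndexSeries, b: IndexSeries) -> CorrelationResult:
    """Pearson product-moment correlation on the months both series cover.

    The p-value is the exact two-sided value from the t transform with
    n - 2 degrees of freedom.
    """
    pos_b = {m: i for i, m in enumerate(b.months)}
    overlap = [m for m in a.months if m in pos_b]
    if len(overlap) < 3:
        raise InsufficientOverlapError(
            f"series overlap on {len(overlap)} month(s); need >= 3"
        )
    pos_a = {m: i for i, m in enumerate(a.months)}
    x = np.array([a.values[pos_a[m]] for m in overlap])
    y = np.array([b.values[pos_b[m]] for m in overlap])
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError(
            "correlation undefined: a series is constant on the overlap"
        )
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p_value=float(res.pvalue), n=len(overlap)
    )


@dataclass
class RobustnessReport:
    """Pairwise subgroup correlations with pass/fail flags."""

    groups: list[str]
    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    n_matrix: pd.DataFrame
    passed: pd.DataFrame
    threshold: float
    indexes: dict[str, IndexSeries]
    errors: dict[str, str] = field(default_factory=dict)

    def all_pass(self) -> bool:
        off = ~np.eye(len(self.groups), dtype=bool)
        vals = self.passed.to_numpy()[off]
        return bool(np.all(vals[~pd.isna(vals)].astype(bool)))

    def render_text(self) -> str:
        """A human-readable matrix shaped like a subgroup-robustness
        table: per group, a row of r and a row of rendered p-values."""
        lines = []
        header = ["Group"] + self.groups
        lines.append("\t".join(header))
        for g in self.groups:
            if g in self.errors:
                lines.append(f"{g}\t<build failed: {self.errors[g]}>")
                continue
            r_row, p_row = [f"{g}  r"], ["    P value"]
            for h in self.groups:
                r = self.r_matrix.loc[g, h]
                if pd.isna(r):
                    r_row.append("—")
                    p_row.append("—")
                elif g == h:
                    r_row.append("1")
                    p_row.append("—")
                else:
                    r_row.append(f"{r:.3f}")
                    p = self.p_matrix.loc[g, h]
                    p_row.append(
                        "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0")
                    )
            lines.append("\t".join(r_row))
            lines.append("\t".join(p_row))
        lines.append(
            f"criterion: pairwise r >= {self.threshold} -> "
            + ("PASS" if self.all_pass() else "FAIL")
        )
        return "\n".join(lines)


def robustness_report(
    corpus: Corpus,
    lexicon: KeywordLexicon,
    groups: Sequence[NewspaperGroup],
    threshold: float = 0.74,
    months: tuple[str, str] | None = None,
    gaps: Mapping[str, Iterable[str]] | None = None,
) -> RobustnessReport:
    """Build one index per group and correlate all pairs.

    A group whose build fails is recorded in ``errors`` and its pairs
    left NA; remaining pairs are still computed.
    """
    if len(groups) < 2:
        raise ValidationError("robustness report needs at least 2 groups")
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValidationError("group names must be distinct")
    indexes: dict[str, IndexSeries] = {}
    errors: dict[str, str] = {}
    for g in groups:
        try:
            g.validate_against(corpus.newspapers)
            indexes[g.name] = build_index(
                corpus, lexicon, newspapers=g.members, months=months,
                gaps=gaps, label=g.name,
            )
        except Exception as e:  # keep remaining pairs alive
            errors[g.name] = str(e)
    r = pd.DataFrame(np.nan, index=names, columns=names)
    p = pd.DataFrame(np.nan, index=names, columns=names)
    n = pd.DataFrame(np.nan, index=names, columns=names)
    ok = pd.DataFrame(pd.NA, index=names, columns=names, dtype=object)
    for g in names:
        if g in indexes:
            r.loc[g, g] = 1.0
            n.loc[g, g] = len(indexes[g].months)
            ok.loc[g, g] = True
    for i, g in enumerate(names):
        for h in names[i + 1:]:
            if g not in indexes or h not in indexes:
                continue
            c = pearson(indexes[g], indexes[h])
            r.loc[g, h] = r.loc[h, g] = c.r
            p.loc[g, h] = p.loc[h, g] = c.p_value
            n.loc[g, h] = n.loc[h, g] = c.n
            ok.loc[g, h] = ok.loc[h, g] = bool(c.r >= threshold)
    return RobustnessReport(
        groups=names, r_matrix=r, p_matrix=p, n_matrix=n, passed=ok,
        threshold=threshold, indexes=indexes, errors=errors,
    )


def _stratum_seed(seed: int, stratum: str) -> np.random.Generator:
    # per-stratum stream keyed on (seed, newspaper) so sampling one paper
    # is unaffected by which other papers are present
    import hashlib

    h = hashlib.blake2b(stratum.encode("utf-8"), digest_size=4).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(h, "big")])
    )


@dataclass
class AuditSample:
    """A stratified audit draw: per newspaper, a simple random sample
    without replacement of ceil(fraction * n) target articles.  Two label
    rounds can be attached; see :func:`resolve_labels`."""

    sampled: dict[str, list[str]]
    seed: int
    fraction: float
    labels_round1: dict[str, bool] = field(default_factory=dict)
    labels_round2: dict[str, bool] = field(default_factory=dict)

    @property
    def sampled_article_ids(self) -> list[str]:
        return [i for ids in self.sampled.values() for i in ids]

    @property
    def per_newspaper_counts(self) -> dict[str, int]:
        return {p: len(ids) for p, ids in self.sampled.items()}


def sample_for_audit(
    target_ids: Mapping[str, Sequence[str]],
    fraction: float = 0.5,
    seed: int = 0,
) -> AuditSample:
    """Draw the audit sample: per newspaper, ceil(fraction * n_i) ids
    without replacement, reproducible from ``seed``.  Empty strata are
    skipped with a warning."""
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("audit fraction must be in (0, 1]")
    sampled: dict[str, list[str]] = {}
    for paper in sorted(target_ids):
        ids = list(target_ids[paper])
        if not ids:
            warnings.warn(
                f"newspaper {paper!r} has no target articles; stratum skipped",
                stacklevel=2,
            )
            continue
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate target ids for {paper!r}")
        k = math.ceil(fraction * len(ids))
        rng = _stratum_seed(seed, paper)
        pick = rng.choice(len(ids), size=k, replace=False)
        sampled[paper] = [ids[int(i)] for i in sorted(pick)]
    return AuditSample(sampled=sampled, seed=int(seed), fraction=fraction)


def resolve_labels(
    round1: Mapping[str, bool], round2: Mapping[str, bool]
) -> dict[str, bool]:
    """Final audit labels across two review rounds: where the rounds
    disagree the second (post-discussion) round stands."""
    if set(round1) != set(round2):
        raise ValidationError("label rounds cover different article sets")
    return {k: bool(round2[k]) for k in round1}


@dataclass(frozen=True)
class PassRate:
    """An audit pass rate: the percentage to one decimal place plus the
    raw fraction it came from."""

    percent: float
    passes: int
    total: int

    @property
    def fraction(self) -> str:
        return f"{self.passes}/{self.total}"


def pass_rate(labels: Mapping[str, bool]) -> PassRate:
    """100 x passes / total, rounded to one decimal place."""
    if not labels:
        raise ValidationError("no audit labels supplied")
    passes = sum(1 for v in labels.values() if v)
    total = len(labels)
    return PassRate(
        percent=round(100.0 * passes / total, 1), passes=passes, total=total
    )


def read_external_series(path: str | Path, label: str = "") -> IndexSeries:
    """Read an external monthly index from a two-column month,value CSV.

    Months may be ``"YYYY-MM"`` or ``"YYYY-M"``; they are canonicalized.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"external series file not found: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError("external series needs two columns: month, value")
    months_raw = df.iloc[:, 0].astype(str)
    values = df.iloc[:, 1].to_numpy(dtype=float)
    months = ["{:04d}-{:02d}".format(*parse_month(m)) for m in months_raw]
    order = np.argsort(months)
    return IndexSeries(
        months=[months[i] for i in order],
        values=values[order],
        label=label or path.stem,
    )


def compare_external(
    index: IndexSeries, external: IndexSeries
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Correlate the built index with an externally constructed monthly
    series (e.g. another country's HPU index) on their common months and
    return the aligned pair for plotting."""
    corr = pearson(index, external)
    pos_e = {m: i for i, m in enumerate(external.months)}
    pos_i = {m: i for i, m in enumerate(index.months)}
    overlap = [m for m in index.months if m in pos_e]
    aligned = pd.DataFrame(
        {
            "month": overlap,
            index.label or "index": [index.values[pos_i[m]] for m in overlap],
            external.label or "external": [
                external.values[pos_e[m]] for m in overlap
            ],
        }
    ).set_index("month")
    return corr, aligned
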