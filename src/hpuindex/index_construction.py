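"""Construction of the monthly health policy uncertainty index.

The index follows the newspaper-count policy-uncertainty recipe:

1. count target articles A_it per newspaper i and month t;
2. scale by each paper's total monthly volume, X_it = A_it / B_it;
3. standardize each paper's series to unit sample SD, Y_it = X_it / sigma_i,
   where sigma_i is the SD of X_it over the paper's observed months;
4. average across papers within each month, Z_t = mean_i Y_it;
5. normalize the series to a mean of 100 over the study window,
   index_t = Z_t * (100 / M) with M = mean_t Z_t.

Scaling removes differences in overall volume between papers and months;
unit-SD standardization stops high-variance papers from dominating the
cross-paper mean; the mean-100 normalization fixes the otherwise arbitrary
scale.  Standardization divides by sigma_i without centering, so all index
values stay nonnegative.

Coverage gaps propagate as MISSING cells: sigma_i uses only a paper's
observed months, and each month's mean runs over the papers present that
month.  :func:`splice_indexes` implements the gap-filling protocol in
which an index built from fully covered papers donates values for the gap
months of a wider but gappy index, with the overlap correlation reported
as the systematic-bias check.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import (
    Corpus,
    CountPanel,
    CoverageMask,
    coverage_mask,
    monthly_totals,
)
from .errors import (
    DegenerateSeriesError,
    EmptyMonthError,
    InputOutputError,
    ValidationError,
)
from .keyword_matching import KeywordLexicon, count_matches
from .months import month_span, parse_month

__all__ = [
    "RatioPanel",
    "IndexSeries",
    "SpliceResult",
    "scale_counts",
    "standardize",
    "aggregate",
    "normalize",
    "index_from_panels",
    "build_index",
    "splice_indexes",
    "write_index",
    "read_index",
]


@dataclass
class RatioPanel:
    """Newspapers x months matrix of scaled frequencies (X_it) or their
    standardized form (Y_it).  NaN marks MISSING.  ``sigma`` maps each
    newspaper to the sample SD used for standardization (populated by
    :func:`standardize`); ``zero_volume_cells`` lists (newspaper, month)
    pairs dropped because the paper printed nothing that month."""

    newspapers: list[str]
    months: list[str]
    values: np.ndarray
    sigma: dict[str, float] | None = None
    zero_volume_cells: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.newspapers = list(self.newspapers)
        self.months = list(self.months)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.newspapers), len(self.months)):
            raise ValidationError("ratio panel shape mismatch")
        present = self.values[~np.isnan(self.values)]
        if present.size and (present < 0).any():
            raise ValidationError("scaled frequencies must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.newspapers), columns=list(self.months)
        )


@dataclass
class IndexSeries:
    """A monthly index: month keys, values, and (after normalization) the
    constant M such that values = Z * (100 / M).  ``meta`` carries build
    provenance (per-paper sigma, newspapers used, gap declarations)."""

    months: list[str]
    values: np.ndarray
    normalization_constant: float | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.months = list(self.months)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.months),):
            raise ValidationError("index series length mismatch")
        for k in self.months:
            parse_month(k)
        if any(a >= b for a, b in zip(self.months, self.months[1:])):
            raise ValidationError("index months must be strictly increasing")
        if np.isnan(self.values).any():
            raise ValidationError("index values must be fully observed")
        if (self.values < 0).any():
            raise ValidationError("index values must be nonnegative")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.months), name=self.label)

    def restrict(self, months: Iterable[str]) -> "IndexSeries":
        keep = [m for m in self.months if m in set(months)]
        pos = {m: i for i, m in enumerate(self.months)}
        return IndexSeries(
            months=keep,
            values=self.values[[pos[m] for m in keep]],
            normalization_constant=self.normalization_constant,
            label=self.label,
            meta=dict(self.meta),
        )


def scale_counts(A: CountPanel, B: CountPanel) -> RatioPanel:
    """Step 2: X_it = A_it / B_it.

    The two panels must agree in layout and missingness, and A <= B
    cell-wise.  A covered month in which a paper printed nothing at all
    (B_it = 0, hence A_it = 0) cannot form a ratio; the cell becomes
    MISSING and is flagged in ``zero_volume_cells``.
    """
    if A.newspapers != B.newspapers or A.months != B.months:
        raise ValidationError("A and B panels have different layouts")
    if not np.array_equal(A.present, B.present):
        raise ValidationError("A and B panels have different MISSING patterns")
    both = A.present
    if (A.values[both] > B.values[both]).any():
        raise ValidationError("target count exceeds total count in some cell")
    with np.errstate(divide="ignore", invalid="ignore"):
        X = A.values / B.values
    zero_cells = []
    zi, zj = np.nonzero(both & (B.values == 0))
    for i, j in zip(zi.tolist(), zj.tolist()):
        zero_cells.append((A.newspapers[i], A.months[j]))
        X[i, j] = np.nan
    if zero_cells:
        warnings.warn(
            f"{len(zero_cells)} covered newspaper-month(s) had zero total "
            "articles; cells dropped from the ratio panel",
            stacklevel=2,
        )
    return RatioPanel(A.newspapers, A.months, X, zero_volume_cells=zero_cells)


def standardize(X: RatioPanel) -> RatioPanel:
    """Step 3: Y_it = X_it / sigma_i with sigma_i the sample SD (ddof=1)
    of newspaper i's observed X values over the build window.

    A paper whose series is constant (sigma = 0) or has fewer than two
    observed months cannot be standardized and is a degenerate-data error
    naming the paper.
    """
    Y = np.full_like(X.values, np.nan)
    sigma: dict[str, float] = {}
    for i, paper in enumerate(X.newspapers):
        row = X.values[i]
        obs = row[~np.isnan(row)]
        if obs.size < 2:
            raise DegenerateSeriesError(
                f"newspaper {paper!r} has {obs.size} observed month(s); "
                "at least 2 needed for standardization"
            )
        s = float(np.std(obs, ddof=1))
        # a numerically constant series: zero spread, or an SD at the
        # level of float round-off relative to the values themselves
        if (
            not math.isfinite(s)
            or np.ptp(obs) == 0
            or s <= float(np.abs(obs).max()) * 1e-13
        ):
            raise DegenerateSeriesError(
                f"newspaper {paper!r} has a constant scaled-frequency "
                "series (sigma = 0); cannot standardize"
            )
        sigma[paper] = s
        Y[i] = row / s
    return RatioPanel(
        X.newspapers,
        X.months,
        Y,
        sigma=sigma,
        zero_volume_cells=list(X.zero_volume_cells),
    )


def aggregate(Y: RatioPanel) -> IndexSeries:
    """Step 4: Z_t = mean over newspapers observed in month t.

    MISSING cells are excluded from both numerator and denominator, so the
    index remains computable in months where some papers are gapped.  A
    month with no observed paper at all is an error.
    """
    Z = np.empty(len(Y.months))
    for j, m in enumerate(Y.months):
        col = Y.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise EmptyMonthError(f"month {m} has no covered newspaper")
        Z[j] = float(np.mean(obs))
    return IndexSeries(months=Y.months, values=Z, meta={"sigma": Y.sigma})


def normalize(Z: IndexSeries) -> IndexSeries:
    """Step 5: rescale by 100 / M so the series mean is exactly 100."""
    M = float(np.mean(Z.values))
    if not (M > 0.0):
        raise DegenerateSeriesError(
            "index is identically zero; cannot normalize to mean 100"
        )
    return IndexSeries(
        months=Z.months,
        values=Z.values * (100.0 / M),
        normalization_constant=M,
        label=Z.label,
        meta=dict(Z.meta),
    )


def index_from_panels(
    A: CountPanel, B: CountPanel, label: str = ""
) -> IndexSeries:
    """Steps 2-5 composed on pre-counted panels."""
    out = normalize(aggregate(standardize(scale_counts(A, B))))
    out.label = label
    return out


def build_index(
    corpus: Corpus,
    lexicon: KeywordLexicon,
    newspapers: Sequence[str] | None = None,
    months: tuple[str, str] | None = None,
    gaps: Mapping[str, Iterable[str]] | None = None,
    exclude_months: Iterable[str] | None = None,
    label: str = "",
) -> IndexSeries:
    """Steps 1-5 end to end: screen, count, scale, standardize, average,
    normalize.  ``newspapers``/``months`` restrict the build; ``gaps``
    declares coverage gaps; ``exclude_months`` removes individual months
    from the panels entirely before scaling (the way an index is rebuilt
    "without the missing year" so all papers share one time interval),
    which also excludes them from every sigma.  Deterministic for a fixed
    corpus: papers are processed in sorted order so floating-point
    reductions have a fixed order regardless of input order.
    """
    sub = corpus.restrict(
        newspapers=sorted(newspapers) if newspapers is not None
        else sorted(corpus.newspapers),
        month_range=months,
    )
    relevant_gaps = None
    if gaps:
        relevant_gaps = {
            p: list(toks) for p, toks in gaps.items() if p in set(sub.newspapers)
        }
    mask = coverage_mask(sub, relevant_gaps)
    try:
        B = monthly_totals(sub, mask)
        A = count_matches(sub, lexicon, mask)
        if exclude_months:
            excl = {"{:04d}-{:02d}".format(*parse_month(m))
                    for m in exclude_months}
            keep = [j for j, m in enumerate(B.months) if m not in excl]
            if not keep:
                raise ValidationError("exclude_months removes every month")
            kept_months = [B.months[j] for j in keep]
            A = CountPanel(A.newspapers, kept_months, A.values[:, keep])
            B = CountPanel(B.newspapers, kept_months, B.values[:, keep])
        index = index_from_panels(A, B, label=label)
    except (ValidationError, DegenerateSeriesError, EmptyMonthError) as e:
        e.args = (f"building index {label or '(unlabeled)'}: {e.args[0]}",)
        raise
    index.meta.update(
        {
            "newspapers": list(sub.newspapers),
            "month_range": list(sub.month_range),
            "gaps": {p: sorted(t) for p, t in (relevant_gaps or {}).items()},
            "lexicon": lexicon.name,
        }
    )
    return index


@dataclass
class SpliceResult:
    """A spliced index plus the pre-splice donor/gapped agreement on their
    overlapping months — the check that the donor shows no systematic
    bias relative to the series it is patching."""

    index: IndexSeries
    overlap_r: float
    overlap_n: int
    gap_months: list[str]


def splice_indexes(
    gapped: IndexSeries,
    donor: IndexSeries,
    gap_months: Iterable[str],
) -> SpliceResult:
    """Fill ``gap_months`` of ``gapped`` with the donor's values.

    The donor must cover every gap month and share at least one non-gap
    month with ``gapped`` (that overlap is where agreement is measured).
    Donor values are inserted unrescaled, then the union is re-normalized
    to mean 100 — the only scale constraint the construction states.
    """
    gap_set = set(gap_months)
    for m in gap_set:
        parse_month(m)
    donor_pos = {m: i for i, m in enumerate(donor.months)}
    gapped_pos = {m: i for i, m in enumerate(gapped.months)}
    missing = sorted(gap_set - set(donor.months))
    if missing:
        raise ValidationError(
            f"donor index does not cover gap month(s): {missing}"
        )
    overlap = [
        m for m in gapped.months if m in donor_pos and m not in gap_set
    ]
    if not overlap:
        raise ValidationError(
            "donor and gapped series share no non-gap months; cannot "
            "check for systematic bias"
        )
    if len(overlap) >= 3:
        a = np.array([gapped.values[gapped_pos[m]] for m in overlap])
        b = np.array([donor.values[donor_pos[m]] for m in overlap])
        if np.std(a) > 0 and np.std(b) > 0:
            r = float(np.corrcoef(a, b)[0, 1])
        else:
            r = float("nan")
    else:
        r = float("nan")
    union = sorted(set(gapped.months) | gap_set)
    values = np.empty(len(union))
    for j, m in enumerate(union):
        if m in gap_set:
            values[j] = donor.values[donor_pos[m]]
        elif m in gapped_pos:
            values[j] = gapped.values[gapped_pos[m]]
        else:
            raise ValidationError(f"gapped series does not cover month {m}")
    spliced = normalize(IndexSeries(months=union, values=values))
    spliced.label = gapped.label
    spliced.meta = {
        "spliced_from": donor.label,
        "gap_months": sorted(gap_set),
        "overlap_r": r,
        "renormalized": True,
    }
    return SpliceResult(
        index=spliced, overlap_r=r, overlap_n=len(overlap),
        gap_months=sorted(gap_set),
    )


def write_index(index: IndexSeries, path: str | Path) -> None:
    """Write an index as CSV (month, value to 6 decimals) with a JSON
    sidecar carrying M, per-paper sigma, and build provenance."""
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8") as fh:
            fh.write("month,value\n")
            for m, v in zip(index.months, index.values):
                fh.write(f"{m},{v:.6f}\n")
        sidecar = {
            "label": index.label,
            "normalization_constant": index.normalization_constant,
            **index.meta,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, ensure_ascii=False, indent=2, default=str),
            encoding="utf-8",
        )
    except OSError as e:
        raise InputOutputError(f"cannot write {path}: {e}") from e


def read_index(path: str | Path, label: str = "") -> IndexSeries:
    """Read a month,value CSV back into an :class:`IndexSeries`."""
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"index file not found: {path}")
    df = pd.read_csv(path)
    if not {"month", "value"} <= set(df.columns):
        raise ValidationError("index CSV needs columns month,value")
    months = [
        "{:04d}-{:02d}".format(*parse_month(m)) for m in df["month"].astype(str)
    ]
    return IndexSeries(
        months=months,
        values=df["value"].to_numpy(dtype=float),
        label=label or path.stem,
    )
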