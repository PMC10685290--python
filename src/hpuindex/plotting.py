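"""Line plots of monthly index series with optional event annotations."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import ValidationError
from .index_construction import IndexSeries


def plot_index(
    series: Sequence[IndexSeries],
    out_path: str | Path,
    annotations: Mapping[str, str] | None = None,
    title: str = "Health policy uncertainty index",
) -> Path:
    """Overlay one or more index series and save a PNG.

    ``annotations`` maps month keys to event labels; months outside every
    plotted series are skipped with a warning.
    """
    if not series:
        raise ValidationError("nothing to plot: no series supplied")
    fig, ax = plt.subplots(figsize=(11, 4.5))
    all_months: set[str] = set()
    for s in series:
        x = range(len(s.months))
        ax.plot(list(x), s.values, label=s.label or "index", linewidth=1.2)
        all_months.update(s.months)
    base = series[0]
    tick_step = max(1, len(base.months) // 12)
    ax.set_xticks(range(0, len(base.months), tick_step))
    ax.set_xticklabels(base.months[::tick_step], rotation=45, fontsize=8)
    if annotations:
        pos = {m: i for i, m in enumerate(base.months)}
        for month, label in sorted(annotations.items()):
            if month not in all_months or month not in pos:
                warnings.warn(
                    f"annotation month {month} outside plotted range; skipped",
                    stacklevel=2,
                )
                continue
            i = pos[month]
            ax.axvline(i, color="grey", linestyle=":", linewidth=0.8)
            ax.annotate(
                label,
                xy=(i, float(base.values[i])),
                xytext=(0, 8),
                textcoords="offset points",
                fontsize=7,
                rotation=90,
                va="bottom",
            )
    ax.set_ylabel("index (mean = 100)")
    ax.set_title(title)
    if len(series) > 1:
        ax.legend(fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
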