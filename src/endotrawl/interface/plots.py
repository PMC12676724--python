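"""Stacked-area relative-abundance plot with shaded fall-winter windows."""

from __future__ import annotations

import datetime as _dt

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ..timeseries import AbundanceTable, relative_abundance, season_label


def plot_timeseries(table: AbundanceTable, path, title: str | None = None) -> None:
    fractions, _fam, _zero = relative_abundance(table)
    dates = table.dates
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.stackplot(dates, fractions.T.to_numpy(), labels=fractions.columns)
    _shade_fall_winter(ax, dates)
    ax.set_ylabel("relative abundance")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize="x-small", ncol=2)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _shade_fall_winter(ax, dates: list[_dt.date]) -> None:
    if not dates:
        return
    day, last = dates[0], dates[-1]
    start = None
    while day <= last:
        in_window = season_label(day) == "fall_winter"
        if in_window and start is None:
            start = day
        elif not in_window and start is not None:
            ax.axvspan(start, day, color="grey", alpha=0.2, linewidth=0)
            start = None
        day += _dt.timedelta(days=1)
    if start is not None:
        ax.axvspan(start, last, color="grey", alpha=0.2, linewidth=0)
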