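"""Temporal analysis of dated taxon count tables.

Relative abundance and family aggregation, detection fractions across
sampling units, the fall-winter season window (21 September - 21 March,
boundaries inclusive), coexistence richness and robust bloom calling
(median + k * MAD excursions with a peak floor).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

META_COLUMNS = ("sample_id", "date", "plant")

FALL_WINTER_START = (9, 21)  # (month, day), inclusive
FALL_WINTER_END = (3, 21)  # inclusive


@dataclass
class AbundanceTable:
    """Samples-by-taxa counts with dates and an optional family mapping."""

    counts: pd.DataFrame  # columns: sample_id, date, plant, <taxon...>
    family_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for col in META_COLUMNS:
            if col not in self.counts.columns:
                raise InputError(f"count table lacks required column {col!r}")
        values = self.counts[self.taxa]
        if (values.to_numpy() < 0).any():
            raise InputError("counts must be nonnegative")
        if not (values.dtypes.map(lambda t: np.issubdtype(t, np.integer))).all():
            raise InputError("counts must be integers")

    @property
    def taxa(self) -> list[str]:
        return [c for c in self.counts.columns if c not in META_COLUMNS]

    @property
    def dates(self) -> list[_dt.date]:
        return [parse_date(d) for d in self.counts["date"]]

    @classmethod
    def read_tsv(cls, path, family_map=None) -> "AbundanceTable":
        return cls(pd.read_csv(path, sep="\t"), family_map or {})

    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def parse_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise InputError(f"unparsable date {value!r}") from exc


def relative_abundance(
    table: AbundanceTable,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-sample fractions, family-aggregated fractions, and a flag series
    marking all-zero samples (whose fraction rows are all zero)."""
    taxa = table.taxa
    counts = table.counts[taxa].astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    safe_totals = totals.replace(0, 1.0)
    fractions = counts.div(safe_totals, axis=0)
    fractions[zero] = 0.0
    families = sorted({table.family_map.get(t, t) for t in taxa})
    fam = pd.DataFrame(
        {f: fractions[[t for t in taxa if table.family_map.get(t, t) == f]].sum(axis=1)
         for f in families}
    )
    for frame in (fractions, fam):
        frame.index = table.counts["sample_id"]
    zero.index = table.counts["sample_id"]
    return fractions, fam, zero


def detection_fraction(
    table: AbundanceTable, taxon: str, min_count: int = 1
) -> float:
    """Percent of samples where the taxon (or family) reaches ``min_count``
    reads, to 1 decimal, half away from zero."""
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    if len(table.counts) == 0:
        raise InputError("empty table")
    if taxon in table.counts.columns:
        values = table.counts[taxon]
    else:
        members = [t for t in table.taxa if table.family_map.get(t) == taxon]
        if not members:
            raise InputError(f"unknown taxon or family {taxon!r}")
        values = table.counts[members].sum(axis=1)
    positives = int((values >= min_count).sum())
    return round_half_away(100.0 * positives / len(values), 1)


def round_half_away(value: float, places: int) -> float:
    """Round to ``places`` decimals with ties away from zero."""
    factor = 10.0**places
    scaled = value * factor
    return (np.floor(scaled + 0.5) if scaled >= 0 else np.ceil(scaled - 0.5)) / factor


def season_label(date) -> str:
    """``fall_winter`` between 21 September and 21 March inclusive."""
    d = parse_date(date)
    key = (d.month, d.day)
    if key >= FALL_WINTER_START or key <= FALL_WINTER_END:
        return "fall_winter"
    return "rest_of_year"


def richness_series(table: AbundanceTable, min_rel_abundance: float = 0.0) -> pd.Series:
    """Per-sample count of taxa at or above a relative-abundance threshold.

    With the default threshold of 0, only taxa with nonzero counts are
    counted (an all-zero taxon is absent, not 'present at 0')."""
    if min_rel_abundance < 0:
        raise ParameterError("threshold must be >= 0")
    fractions, _, _ = relative_abundance(table)
    counts = table.counts[table.taxa]
    present = (counts.to_numpy() > 0) & (
        fractions.to_numpy() >= min_rel_abundance
    )
    return pd.Series(present.sum(axis=1), index=fractions.index, name="richness")


@dataclass
class BloomEvent:
    taxon: str
    start_index: int
    end_index: int  # inclusive
    start_date: _dt.date
    end_date: _dt.date
    peak: float
    fold: float

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "start_index": self.start_index,
            "end_index": self.end_index,
            "start_date": self.start_date.isoformat(),
            "end_date": self.end_date.isoformat(),
            "peak": self.peak,
            "fold": self.fold,
        }


def detect_blooms(
    series: pd.Series,
    dates: list | None = None,
    taxon: str = "taxon",
    window: int = 5,
    k_mad: float = 5.0,
    min_peak: float = 0.0001,
) -> list[BloomEvent]:
    """Maximal runs of samples above ``median + k_mad * MAD`` whose peak
    reaches ``min_peak`` (relative abundance).

    The median and (unscaled) MAD are taken over the full series, so a
    transient bloom barely moves the baseline.  ``window`` is the minimum
    required series length.
    """
    values = np.asarray(series, dtype=float)
    if len(values) <= window:
        raise InputError(f"series of {len(values)} samples is not longer than window {window}")
    if dates is None:
        if isinstance(series, pd.Series):
            dates = list(series.index)
        else:
            dates = list(range(len(values)))
    parsed = [parse_date(d) if not isinstance(d, int) else _dt.date(1970, 1, 1) + _dt.timedelta(days=d) for d in dates]
    median = float(np.median(values))
    mad = float(np.median(np.abs(values - median)))
    threshold = median + k_mad * mad
    above = values > threshold
    events: list[BloomEvent] = []
    i = 0
    n = len(values)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        peak = float(values[i : j + 1].max())
        if peak >= min_peak:
            fold = peak / median if median > 0 else float("inf")
            events.append(
                BloomEvent(taxon, i, j, parsed[i], parsed[j], peak, fold)
            )
        i = j + 1
    return events
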