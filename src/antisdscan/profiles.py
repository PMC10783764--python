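"""Anti-SD positional profiles and the 15-group catalog.

For every SD-positive gene the tail positions paired in its best match are
registered in central-U coordinates (position 0 = the central U of the
CCUCC core).  Per-position frequencies are taken over *all* scanned mRNAs;
the anti-SD profile is the contiguous block of positions whose frequency
exceeds 0.4x the histogram mode.  Organisms with at most 5.5% SD-positive
genes are SD-scarce and receive no profile.  Profiles are matched to a
catalog of 15 span-defined anti-SD groups.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .rrna_tail import CoreAnnotation, TailRecord
from .scan import SDCall, summarize_organism
from .seqio import reverse_complement

logger = logging.getLogger(__name__)

MODE_FRACTION = 0.4
MIN_PCT_SD = 5.5


@dataclass(frozen=True)
class AntiSDProfile:
    profile_id: str
    freq: dict[int, float]          # central-U position -> fraction of mRNAs
    span: tuple[int, int]           # inclusive (first, last)
    consensus: str                  # tail bases over the span, 5'->3'
    n_genes: int
    pct_sd: float

    @property
    def mode_freq(self) -> float:
        return max(self.freq.values())

    @property
    def sd_consensus(self) -> str:
        return reverse_complement(self.consensus)

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass(frozen=True)
class SDScarce:
    """Sentinel returned instead of a profile for poor SD users."""

    profile_id: str
    pct_sd: float


@dataclass(frozen=True)
class GroupEntry:
    group_id: int
    span: tuple[int, int]
    antisd: str
    sd: str


class GroupCatalog:
    """The 15 class-level anti-SD groups (span in central-U coordinates)."""

    def __init__(self, entries: Sequence[GroupEntry]):
        self.entries = list(entries)

    @classmethod
    def load(cls) -> "GroupCatalog":
        text = (
            resources.files("antisdscan.data")
            .joinpath("antisd_groups.tsv")
            .read_text()
        )
        entries = []
        for line in text.splitlines()[1:]:
            g, first, last, length, antisd, sd = line.split("\t")
            entry = GroupEntry(int(g), (int(first), int(last)), antisd, sd)
            assert entry.span[1] - entry.span[0] + 1 == int(length)
            assert reverse_complement(entry.antisd) == entry.sd
            entries.append(entry)
        return cls(entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def _positions_histogram(calls: Sequence[SDCall]) -> Counter:
    counts: Counter = Counter()
    for c in calls:
        if c.is_sd:
            counts.update(c.tail_positions)
    return counts


def _contiguous_span(positions: list[int], anchor: int) -> tuple[int, int]:
    """Maximal contiguous run of ``positions`` containing ``anchor``."""
    pos = set(positions)
    first = last = anchor
    while first - 1 in pos:
        first -= 1
    while last + 1 in pos:
        last += 1
    return first, last


def build_profile(
    calls: Sequence[SDCall],
    tail: TailRecord,
    core: CoreAnnotation,
    profile_id: str | None = None,
    mode_fraction: float = MODE_FRACTION,
    min_pct_sd: float = MIN_PCT_SD,
) -> AntiSDProfile | SDScarce:
    """Positional anti-SD profile of one organism, or the SD-scarce signal.

    Frequencies are per-position fractions over all scanned genes; only
    SD-positive genes contribute paired positions.  The span is the
    maximal contiguous block of positions with freq > mode_fraction * mode
    that contains the histogram peak.
    """
    if not calls:
        raise ValueError("no scanned genes")
    pid = profile_id or tail.organism_id
    summary = summarize_organism(calls, pid)
    if not summary.pct_sd > min_pct_sd:
        return SDScarce(pid, summary.pct_sd)
    counts = _positions_histogram(calls)
    if not counts:
        return SDScarce(pid, summary.pct_sd)
    n = len(calls)
    freq = {p: c / n for p, c in counts.items()}
    mode_pos = min(p for p, c in counts.items() if c == max(counts.values()))
    cutoff = mode_fraction * freq[mode_pos]
    passing = sorted(p for p, f in freq.items() if f > cutoff)
    first, last = _contiguous_span(passing, mode_pos)
    if set(passing) - set(range(first, last + 1)):
        logger.info(
            "%s: non-contiguous positions above the mode cutoff; span kept "
            "to the contiguous block around the peak", pid,
        )
    u = core.central_u_index
    consensus = tail.tail[u + first: u + last + 1]
    return AntiSDProfile(
        profile_id=pid,
        freq=dict(sorted(freq.items())),
        span=(first, last),
        consensus=consensus,
        n_genes=n,
        pct_sd=summary.pct_sd,
    )


def assign_group(
    profile: AntiSDProfile, catalog: GroupCatalog | None = None
) -> tuple[int | None, GroupEntry]:
    """Exact span match against the catalog; (None, nearest_entry) when the
    span matches no group (nearest by |d_first| + |d_last|, lowest id)."""
    catalog = catalog or GroupCatalog.load()
    for entry in catalog:
        if entry.span == profile.span:
            return entry.group_id, entry
    nearest = min(
        catalog,
        key=lambda e: (
            abs(e.span[0] - profile.span[0]) + abs(e.span[1] - profile.span[1]),
            e.group_id,
        ),
    )
    return None, nearest


def aggregate_class(
    members: Sequence[tuple[Sequence[SDCall], TailRecord, CoreAnnotation]],
    class_id: str,
    mode_fraction: float = MODE_FRACTION,
    min_pct_sd: float = MIN_PCT_SD,
) -> tuple[AntiSDProfile, pd.DataFrame]:
    """Class-level profile: per-gene paired positions pooled across member
    organisms (each anchored at its own central U), consensus read from the
    class's most common tail.

    Also returns a per-organism report with the mean SD window position and
    the mean profile position, the ingredients of the position-correlation
    check.
    """
    if not members:
        raise ValueError("empty class")
    any_profile = False
    pooled: Counter = Counter()
    n_total = 0
    n_sd = 0
    rows = []
    for calls, tail, core in members:
        prof = build_profile(calls, tail, core, mode_fraction=mode_fraction,
                             min_pct_sd=min_pct_sd)
        if isinstance(prof, AntiSDProfile):
            any_profile = True
        pooled.update(_positions_histogram(calls))
        n_total += len(calls)
        sd_calls = [c for c in calls if c.is_sd]
        n_sd += len(sd_calls)
        positions = [p for c in sd_calls for p in c.tail_positions]
        rows.append(
            dict(
                organism_id=tail.organism_id,
                mean_sd_window_position=(
                    float(np.mean([c.window_start for c in sd_calls]))
                    if sd_calls else np.nan
                ),
                mean_profile_position=(
                    float(np.mean(positions)) if positions else np.nan
                ),
            )
        )
    if not any_profile:
        raise ValueError(f"class {class_id!r}: no member organism has a profile")
    tail_counts = Counter(t.tail for _, t, _ in members)
    top = max(tail_counts.values())
    class_tail = sorted(s for s, c in tail_counts.items() if c == top)[0]
    class_core_u = next(
        (core.central_u_index for _, t, core in members if t.tail == class_tail),
        members[0][2].central_u_index,
    )
    freq = {p: c / n_total for p, c in pooled.items()}
    mode_pos = min(p for p, c in pooled.items() if c == max(pooled.values()))
    cutoff = mode_fraction * freq[mode_pos]
    passing = sorted(p for p, f in freq.items() if f > cutoff)
    first, last = _contiguous_span(passing, mode_pos)
    consensus = class_tail[class_core_u + first: class_core_u + last + 1]
    profile = AntiSDProfile(
        profile_id=class_id,
        freq=dict(sorted(freq.items())),
        span=(first, last),
        consensus=consensus,
        n_genes=n_total,
        pct_sd=100.0 * n_sd / n_total,
    )
    return profile, pd.DataFrame(rows)


def position_correlation(report: pd.DataFrame) -> float:
    """Pearson correlation between mean SD window position and mean profile
    position across organisms (NaN with < 2 complete organisms)."""
    from scipy import stats

    df = report.dropna()
    if len(df) < 2:
        return float("nan")
    if df["mean_sd_window_position"].nunique() < 2 or \
            df["mean_profile_position"].nunique() < 2:
        return float("nan")
    r, _p = stats.pearsonr(
        df["mean_sd_window_position"], df["mean_profile_position"]
    )
    return float(r)


def profile_to_table(profile: AntiSDProfile) -> pd.DataFrame:
    """TSV-ready per-position table: position, frequency, in_span flag."""
    first, last = profile.span
    return pd.DataFrame(
        dict(
            position=list(profile.freq),
            frequency=list(profile.freq.values()),
            in_span=[first <= p <= last for p in profile.freq],
        )
    )
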