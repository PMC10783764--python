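"""Sliding-window SD detection in upstream regions.

Each 18-nt UTR window set (nine 10-nt windows) is hybridized against the
organism's 16S tail; the most favorable window is the gene's match, and
genes whose best energy passes the threshold (default -8.4 kcal/mol,
inclusive) carry a Shine-Dalgarno sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .rrna_tail import CoreAnnotation, TailRecord
from .seqio import DEFAULT_UTR_SPAN, UTRRecord
from .thermo import (
    INF,
    DuplexMatch,
    EnergyModel,
    LoopLimits,
    default_model,
    duplex_mfe,
    duplex_mfe_batch,
    encode,
)

logger = logging.getLogger(__name__)


class TruncatedUTR(Exception):
    """Raised by scan_utr for truncated UTRs; callers exclude the gene
    from the organism denominator."""


@dataclass(frozen=True)
class ScanConfig:
    window_len: int = 10
    utr_span: tuple[int, int] = DEFAULT_UTR_SPAN
    dg_threshold: float = -8.4
    threshold_is_strict: bool = False  # False: dG <= threshold calls an SD
    limits: LoopLimits = field(default_factory=LoopLimits)

    def passes(self, dg: float | None) -> bool:
        if dg is None:
            return False
        if self.threshold_is_strict:
            return dg < self.dg_threshold
        return dg <= self.dg_threshold


@dataclass(frozen=True)
class SDCall:
    gene_id: str
    best_dg: float | None          # None = no possible pairing in any window
    window_start: int | None       # gene-relative position of winning window
    is_sd: bool
    match: DuplexMatch | None = None
    tail_positions: tuple[int, ...] = ()  # central-U-relative paired positions


@dataclass(frozen=True)
class OrganismSummary:
    organism_id: str
    n_genes_scanned: int
    n_sd: int
    mean_sd_window_position: float | None

    @property
    def pct_sd(self) -> float:
        return 100.0 * self.n_sd / self.n_genes_scanned


def _windows(utr: UTRRecord, cfg: ScanConfig) -> list[tuple[int, str]]:
    seq = utr.sequence
    w = cfg.window_len
    return [
        (utr.offset_of_first_base + off, seq[off: off + w])
        for off in range(len(seq) - w + 1)
    ]


def scan_utr(
    utr: UTRRecord,
    tail: TailRecord,
    model: EnergyModel | None = None,
    cfg: ScanConfig | None = None,
    core: CoreAnnotation | None = None,
) -> SDCall:
    """Hybridize every sliding window of one UTR against the tail and
    return the best-window call.  Ties go to the 5'-most window."""
    model = model or default_model()
    cfg = cfg or ScanConfig()
    if utr.truncated:
        raise TruncatedUTR(utr.gene_id)
    best: tuple | None = None
    for start, win in _windows(utr, cfg):
        m = duplex_mfe(win, tail.tail, model, cfg.limits)
        if m is None:
            continue
        key = (m.dg, start)
        if best is None or key < best[0:2]:
            best = (m.dg, start, m)
    if best is None:
        return SDCall(utr.gene_id, None, None, False)
    dg, start, m = best
    positions = ()
    if core is not None:
        positions = tuple(p - core.central_u_index for p in m.target_positions())
    return SDCall(utr.gene_id, dg, start, cfg.passes(dg), m, positions)


def scan_organism(
    utrs: Sequence[UTRRecord],
    tail: TailRecord,
    core: CoreAnnotation | None = None,
    model: EnergyModel | None = None,
    cfg: ScanConfig | None = None,
) -> list[SDCall]:
    """Scan all genes of one organism (vectorized over windows).

    Truncated UTRs and duplicate gene ids are excluded (logged); full
    matches (paired positions) are computed for SD-positive genes only.
    """
    model = model or default_model()
    cfg = cfg or ScanConfig()
    seen: set[str] = set()
    kept: list[UTRRecord] = []
    n_trunc = 0
    for u in utrs:
        if u.gene_id in seen:
            continue
        seen.add(u.gene_id)
        if u.truncated or len(u.sequence) < cfg.window_len:
            n_trunc += 1
            continue
        kept.append(u)
    if n_trunc:
        logger.info(
            "organism %s: excluded %d truncated UTRs from the denominator",
            tail.organism_id, n_trunc,
        )
    if not kept:
        return []
    starts, queries = [], []
    n_win = None
    for u in kept:
        wins = _windows(u, cfg)
        n_win = len(wins)
        for start, win in wins:
            starts.append(start)
            queries.append(encode(win))
    batch = np.stack(queries)
    cents = duplex_mfe_batch(batch, tail.tail, model, cfg.limits)
    cents = cents.reshape(len(kept), n_win)
    best_idx = np.argmin(cents, axis=1)  # first minimum = 5'-most window
    best_cents = cents[np.arange(len(kept)), best_idx]
    calls = []
    win_starts = np.array(starts).reshape(len(kept), n_win)
    for g, u in enumerate(kept):
        if best_cents[g] >= INF:
            calls.append(SDCall(u.gene_id, None, None, False))
            continue
        dg = best_cents[g] / 100.0
        start = int(win_starts[g, best_idx[g]])
        is_sd = cfg.passes(dg)
        match, positions = None, ()
        if is_sd:
            off = start - u.offset_of_first_base
            win = u.sequence[off: off + cfg.window_len]
            match = duplex_mfe(win, tail.tail, model, cfg.limits)
            if core is not None and match is not None:
                positions = tuple(
                    p - core.central_u_index for p in match.target_positions()
                )
        calls.append(SDCall(u.gene_id, dg, start, is_sd, match, positions))
    return calls


def summarize_organism(
    calls: Sequence[SDCall], organism_id: str
) -> OrganismSummary:
    """Counts, SD percentage, and mean winning-window position over SD genes."""
    if not calls:
        raise ValueError(f"organism {organism_id!r}: no scannable genes")
    sd = [c for c in calls if c.is_sd]
    mean_pos = (
        float(np.mean([c.window_start for c in sd])) if sd else None
    )
    return OrganismSummary(
        organism_id=organism_id,
        n_genes_scanned=len(calls),
        n_sd=len(sd),
        mean_sd_window_position=mean_pos,
    )


def calls_to_table(calls: Iterable[SDCall]):
    """Per-gene TSV-ready table: gene_id, best_dg, window_start, is_sd,
    comma-joined central-U-relative paired tail positions."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            dict(
                gene_id=c.gene_id,
                best_dg="NA" if c.best_dg is None else f"{c.best_dg:.2f}",
                window_start="NA" if c.window_start is None else c.window_start,
                is_sd=c.is_sd,
                tail_positions=",".join(str(p) for p in c.tail_positions),
            )
        )
    return pd.DataFrame(rows)
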