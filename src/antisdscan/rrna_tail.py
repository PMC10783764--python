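"""Annotation of the unstructured 3' tail of 16S rRNA.

The anti-SD lies in the single-stranded region between the last hairpin of
the 16S rRNA and its 3' end (about 15 nt in Bacteria, 13 nt in Archaea).
This module folds the 3'-terminal region, takes everything 3' of the last
paired base as the tail, locates the CCUCC anti-SD core (or infers its
position by pairwise alignment to a reference tail when the core is
mutated), and consolidates paralogous rRNA copies by majority rule.

Position 0 of the anti-SD coordinate system is the central U of the CCUCC
core; all profile positions are expressed relative to it.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Literal

import pandas as pd
from Bio import Align

from .errors import CoreUnresolvableError
from .folding import fold_mfe
from .seqio import GenomeRecord, read_fasta
from .thermo import CANONICAL_TAIL, EnergyModel, default_model

logger = logging.getLogger(__name__)

CORE = "CCUCC"

#: synthetic 16S 3'-terminal construct (34 nt): an unpairable leader, a
#: stable helix-45-style hairpin (GC stem, GAAA loop) and the canonical
#: 15-nt anti-SD tail.  Folding it reproduces the textbook architecture —
#: one terminal hairpin followed by the unstructured UGGAUCACCUCCUUA tail.
SYNTHETIC_LAST40 = "AAAAC" + "GGCGC" + "GAAA" + "GCGCC" + CANONICAL_TAIL


@dataclass(frozen=True)
class TailRecord:
    organism_id: str
    tail: str
    source_copy_count: int = 1

    @property
    def tail_length(self) -> int:
        return len(self.tail)


@dataclass(frozen=True)
class CoreAnnotation:
    status: Literal["present", "absent"]
    central_u_index: int          # 0-based index within the tail
    core_span: tuple[int, int]    # half-open [start, end) of the (inferred) core
    inferred: bool = False


@dataclass(frozen=True)
class ParalogReport:
    n_copies: int
    n_discordant: int
    identical: bool
    majority_has_core: bool


def find_unstructured_tail(
    last40: str,
    model: EnergyModel | None = None,
    organism_id: str = "",
) -> TailRecord:
    """Fold the 3'-terminal region (<= 40 nt) and return the unstructured
    suffix: every base strictly 3' of the last paired base of the MFE
    structure.  A completely unpairable input is returned whole."""
    model = model or default_model()
    if not last40:
        raise ValueError("empty 16S 3'-terminal sequence")
    if len(last40) > 40:
        last40 = last40[-40:]
    _energy, pairs = fold_mfe(last40, model)
    if not pairs:
        tail = last40
    else:
        last_paired = max(j for _, j in pairs)
        tail = last40[last_paired + 1:]
    if not tail:
        # structure runs to the 3' end; report the terminal base so the
        # record stays non-empty, flagged by length 1
        logger.warning("organism %s: no unstructured 3' tail; keeping last base",
                       organism_id)
        tail = last40[-1:]
    return TailRecord(organism_id=organism_id, tail=tail)


def _ecoli_reference_aligner() -> Align.PairwiseAligner:
    # EMBOSS-Needle-like global alignment scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def locate_core(
    tail: TailRecord, reference_tail: str = CANONICAL_TAIL
) -> CoreAnnotation:
    """Locate the CCUCC core in a tail, or infer its position.

    If CCUCC occurs (3'-most occurrence wins), the annotation is exact and
    independent of the reference.  Otherwise the tail is globally aligned
    to the reference tail and the tail base aligned to the reference's
    central U becomes the anchor; alignment into a gap raises
    CoreUnresolvableError (the organism is excluded from positional
    profiling but remains classifiable).
    """
    seq = tail.tail
    idx = seq.rfind(CORE)
    if idx >= 0:
        if seq.find(CORE) != idx:
            logger.info(
                "organism %s: multiple CCUCC occurrences; using 3'-most",
                tail.organism_id,
            )
        return CoreAnnotation(
            status="present",
            central_u_index=idx + 2,
            core_span=(idx, idx + len(CORE)),
        )
    ref_idx = reference_tail.rfind(CORE)
    if ref_idx < 0:
        raise ValueError("reference tail does not contain CCUCC")
    ref_u = ref_idx + 2
    aligner = _ecoli_reference_aligner()
    alignment = aligner.align(seq, reference_tail)[0]
    indices = alignment.indices  # (2, L), -1 marks a gap
    col = None
    for c in range(indices.shape[1]):
        if indices[1, c] == ref_u:
            col = c
            break
    if col is None or indices[0, col] < 0:
        raise CoreUnresolvableError(
            f"organism {tail.organism_id!r}: core position unresolvable "
            "(reference central U aligned to a gap)"
        )
    u = int(indices[0, col])
    start = max(0, u - 2)
    end = min(len(seq), u + 3)
    return CoreAnnotation(
        status="absent", central_u_index=u, core_span=(start, end), inferred=True
    )


def consolidate_paralogs(
    tails: list[TailRecord],
) -> tuple[TailRecord, ParalogReport]:
    """Majority tail across paralogous 16S copies (ties: lexicographically
    smallest, logged); the report flags discordant copies and whether the
    majority tail conserves CCUCC."""
    if not tails:
        raise ValueError("no tails to consolidate")
    counts = Counter(t.tail for t in tails)
    top = max(counts.values())
    candidates = sorted(s for s, c in counts.items() if c == top)
    majority = candidates[0]
    if len(candidates) > 1:
        logger.info(
            "organism %s: %d tied majority tails; using lexicographically "
            "smallest", tails[0].organism_id, len(candidates),
        )
    n_disc = sum(c for s, c in counts.items() if s != majority)
    record = TailRecord(
        organism_id=tails[0].organism_id,
        tail=majority,
        source_copy_count=len(tails),
    )
    report = ParalogReport(
        n_copies=len(tails),
        n_discordant=n_disc,
        identical=(len(counts) == 1),
        majority_has_core=(CORE in majority),
    )
    return record, report


def annotate_tails(
    fasta_path,
    model: EnergyModel | None = None,
    reference_tail: str = CANONICAL_TAIL,
) -> pd.DataFrame:
    """Annotate every organism in a 16S 3'-sequence FASTA.

    Record ids may carry paralog suffixes ("organism|copyN"); copies are
    folded individually and consolidated by majority.  Returns one row per
    organism: organism_id, tail, tail_length, core_status, central_u_index,
    inferred_flag, n_copies, n_discordant.
    """
    model = model or default_model()
    by_org: dict[str, list[GenomeRecord]] = {}
    for rec in read_fasta(fasta_path):
        org = rec.id.split("|")[0]
        by_org.setdefault(org, []).append(rec)
    rows = []
    for org, recs in by_org.items():
        tails = [
            find_unstructured_tail(r.sequence, model, organism_id=org)
            for r in recs
        ]
        tail, report = consolidate_paralogs(tails)
        try:
            core = locate_core(tail, reference_tail)
            rows.append(
                dict(
                    organism_id=org,
                    tail=tail.tail,
                    tail_length=tail.tail_length,
                    core_status=core.status,
                    central_u_index=core.central_u_index,
                    inferred_flag=core.inferred,
                    n_copies=report.n_copies,
                    n_discordant=report.n_discordant,
                )
            )
        except CoreUnresolvableError as exc:
            logger.warning("%s", exc)
            rows.append(
                dict(
                    organism_id=org,
                    tail=tail.tail,
                    tail_length=tail.tail_length,
                    core_status="unresolvable",
                    central_u_index=-1,
                    inferred_flag=True,
                    n_copies=report.n_copies,
                    n_discordant=report.n_discordant,
                )
            )
    return pd.DataFrame(rows)
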