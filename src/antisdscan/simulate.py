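"""Synthetic organisms with known SD/anti-SD ground truth.

The generator emulates the statistical structure the scanner assumes: a
chosen fraction of genes carries, somewhere in its 18-nt upstream window,
the exact reverse complement of a chosen stretch of the 16S tail (the
planted anti-SD span); the remaining genes have unconstrained upstream
sequence.  Every gene is verified with the real hybridization engine at
generation time — planted genes must score at or below the SD threshold,
background genes above it — so truth labels are consistent with the
scanner by construction, whatever the parameter tables contain.

Genes are tiled on a single contig with >= 40-nt spacers, alternating
between the two strands to exercise strand handling.  All outputs are
deterministic functions of the spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SimulationError
from .profiles import AntiSDProfile
from .rrna_tail import CoreAnnotation, TailRecord, locate_core
from .scan import ScanConfig, SDCall, scan_organism, summarize_organism
from .seqio import GenomeRecord, GeneModel, UTRRecord, reverse_complement, write_fasta
from .thermo import CANONICAL_TAIL, EnergyModel, default_model

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))

#: unpairable leader + GC hairpin, prepended to the tail so that the
#: emitted 16S 3' records fold into the textbook architecture (one
#: terminal helix, then the unstructured tail)
_HAIRPIN_LEADER = "AAAAC" + "GGCGC" + "GAAA" + "GCGCC"


@dataclass(frozen=True)
class SyntheticSpec:
    organism_id: str = "synth"
    antisd_tail: str = CANONICAL_TAIL
    planted_span: tuple[int, int] = (-2, 4)   # central-U coordinates
    sd_fraction: float = 0.6
    n_genes: int = 2000
    seed: int = 0
    background_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_tail_copies: int = 1
    spacer_len: int = 40
    cds_len: int = 45
    retry_rounds: int = 60

    def __post_init__(self):
        if not 0.0 <= self.sd_fraction <= 1.0:
            raise ValueError("sd_fraction must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass
class SyntheticOrganism:
    spec: SyntheticSpec
    genome: GenomeRecord
    genes: list[GeneModel]
    utrs: list[UTRRecord]
    tail: TailRecord
    core: CoreAnnotation
    tail_records: list[GenomeRecord]
    truth: pd.DataFrame


def _planted_sd(tail: str, core: CoreAnnotation, span: tuple[int, int]) -> str:
    u = core.central_u_index
    lo, hi = u + span[0], u + span[1] + 1
    if lo < 0 or hi > len(tail):
        raise SimulationError(
            f"planted span {span} falls outside the tail (central U at {u})"
        )
    return reverse_complement(tail[lo:hi])


def _random_seq(rng, n, probs) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)])


def generate_organism(
    spec: SyntheticSpec,
    outdir: str | Path | None = None,
    model: EnergyModel | None = None,
    cfg: ScanConfig | None = None,
) -> SyntheticOrganism:
    """Generate one verified synthetic organism; optionally write the
    genome FASTA, gene TSV, 16S-tail FASTA and truth table to ``outdir``."""
    model = model or default_model()
    cfg = cfg or ScanConfig()
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.background_probs, dtype=float)
    probs = probs / probs.sum()

    tail_seq = spec.antisd_tail.upper().replace("T", "U")
    tail = TailRecord(spec.organism_id, tail_seq)
    core = locate_core(tail)
    sd_seq = _planted_sd(tail_seq, core, spec.planted_span)
    utr_len = cfg.utr_span[1] - cfg.utr_span[0] + 1
    if len(sd_seq) > utr_len:
        raise SimulationError("planted SD longer than the UTR window")

    n = spec.n_genes
    planted = rng.random(n) < spec.sd_fraction
    utr_seqs = [""] * n
    offsets = np.full(n, -1, dtype=int)
    unresolved = list(range(n))
    for round_no in range(spec.retry_rounds):
        if not unresolved:
            break
        for g in unresolved:
            seq = _random_seq(rng, utr_len, probs)
            if planted[g]:
                off = int(rng.integers(0, utr_len - len(sd_seq) + 1))
                seq = seq[:off] + sd_seq + seq[off + len(sd_seq):]
                offsets[g] = off
            utr_seqs[g] = seq
        utrs = [
            UTRRecord(f"g{g:05d}", utr_seqs[g], cfg.utr_span[0])
            for g in unresolved
        ]
        calls = scan_organism(utrs, tail, core, model, cfg)
        by_id = {c.gene_id: c for c in calls}
        still = []
        for g in unresolved:
            call = by_id[f"g{g:05d}"]
            ok = call.is_sd if planted[g] else not call.is_sd
            if not ok:
                still.append(g)
        if still and round_no == 0:
            logger.info(
                "rejection sampling: %d/%d genes regenerated after round 1",
                len(still), n,
            )
        unresolved = still
    if unresolved:
        raise SimulationError(
            f"{len(unresolved)} genes unresolved after {spec.retry_rounds} "
            "rejection rounds; background composition is too SD-like"
        )

    # assemble the genome: spacer + [UTR + AUG + CDS + stop], strands alternate
    chunks: list[str] = []
    genes: list[GeneModel] = []
    pos = 0  # 0-based running length
    contig = f"{spec.organism_id}_contig1"
    for g in range(n):
        gene_id = f"g{g:05d}"
        spacer = _random_seq(rng, spec.spacer_len, probs)
        cds = _random_seq(rng, spec.cds_len, probs)
        # the UTR window spans -19..-2, so one free base sits at -1
        gap = _random_seq(rng, 1, probs)
        segment = utr_seqs[g] + gap + "AUG" + cds + "UAA"
        strand = "+" if g % 2 == 0 else "-"
        chunks.append(spacer)
        pos += len(spacer)
        aug_local = utr_len + 1  # 0-based index of AUG's A within segment
        if strand == "+":
            start = pos + aug_local + 1  # 1-based first base of AUG
            chunks.append(segment)
        else:
            rc = reverse_complement(segment)
            local = len(segment) - 1 - aug_local  # AUG's A within rc
            start = pos + local + 1
            chunks.append(rc)
        pos += len(segment)
        genes.append(GeneModel(gene_id, contig, start, strand, "AUG"))
    chunks.append(_random_seq(rng, spec.spacer_len, probs))
    genome = GenomeRecord(contig, "".join(chunks))

    utr_records = [
        UTRRecord(f"g{g:05d}", utr_seqs[g], cfg.utr_span[0]) for g in range(n)
    ]
    construct = _HAIRPIN_LEADER + tail_seq
    from .rrna_tail import find_unstructured_tail

    if find_unstructured_tail(construct, model).tail != tail_seq:
        logger.warning(
            "hairpin construct folds into the tail; emitting bare tails"
        )
        construct = tail_seq
    tail_records = [
        GenomeRecord(f"{spec.organism_id}|copy{i + 1}", construct)
        for i in range(spec.n_tail_copies)
    ]
    truth = pd.DataFrame(
        dict(
            gene_id=[f"g{g:05d}" for g in range(n)],
            strand=[m.strand for m in genes],
            start=[m.start for m in genes],
            planted=planted,
            sd_offset=offsets,
            utr=utr_seqs,
        )
    )
    organism = SyntheticOrganism(
        spec=spec, genome=genome, genes=genes, utrs=utr_records,
        tail=tail, core=core, tail_records=tail_records, truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([genome], outdir / "genome.fa")
        write_fasta(tail_records, outdir / "tails.fa")
        gene_table = pd.DataFrame(
            dict(
                gene_id=[m.gene_id for m in genes],
                contig=[m.contig for m in genes],
                start=[m.start for m in genes],
                strand=[m.strand for m in genes],
                start_codon=[m.start_codon for m in genes],
            )
        )
        gene_table.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return organism


def recovery_report(
    truth: pd.DataFrame,
    calls: list[SDCall],
    profile: AntiSDProfile | None,
    planted_span: tuple[int, int] | None = None,
) -> dict:
    """SD-call sensitivity/specificity against truth, the percentage error
    versus the planted fraction, and whether the recovered span equals the
    planted one."""
    by_id = {c.gene_id: c for c in calls}
    missing = set(truth["gene_id"]) - set(by_id)
    if missing:
        raise ValueError(f"calls missing for {len(missing)} truth genes")
    tp = fn = tn = fp = 0
    for _, row in truth.iterrows():
        call = by_id[row["gene_id"]]
        if row["planted"]:
            tp += call.is_sd
            fn += not call.is_sd
        else:
            fp += call.is_sd
            tn += not call.is_sd
    n = len(truth)
    pct_sd = 100.0 * (tp + fp) / n
    planted_pct = 100.0 * truth["planted"].sum() / n
    out = dict(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        pct_sd=pct_sd,
        planted_pct=planted_pct,
        abs_error_pct=abs(pct_sd - planted_pct),
    )
    if profile is not None and planted_span is not None:
        out["span_recovered"] = profile.span == tuple(planted_span)
        out["recovered_span"] = profile.span
    return out
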