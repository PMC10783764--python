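"""End-to-end orchestration: tails -> UTRs -> scan -> profile -> classify.

Processes one organism per run: a genome FASTA (one or more contigs), a
gene table (TSV or GFF3) and a 16S 3'-sequence FASTA (one or more
paralogous copies).  Writes per-gene calls, the organism summary, the
positional profile, the category call and a run log recording every
configuration value and the parameter-table checksum.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import SD_ABUNDANCE_THRESHOLD, categorize_organism
from .errors import AntiSDScanError, CoreUnresolvableError, PipelineError
from .profiles import (
    MIN_PCT_SD,
    MODE_FRACTION,
    AntiSDProfile,
    GroupCatalog,
    SDScarce,
    assign_group,
    build_profile,
    profile_to_table,
)
from .rrna_tail import (
    CoreAnnotation,
    TailRecord,
    consolidate_paralogs,
    find_unstructured_tail,
    locate_core,
)
from .scan import ScanConfig, calls_to_table, scan_organism, summarize_organism
from .seqio import DEFAULT_UTR_SPAN, extract_utr, read_fasta, read_gene_models
from .thermo import CANONICAL_TAIL, derive_sd_threshold, load_energy_model

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str = ""
    genes: str = ""
    tails: str = ""
    outdir: str = "antisd_out"
    genes_dialect: str = "tsv"
    window_len: int = 10
    utr_span: tuple[int, int] = DEFAULT_UTR_SPAN
    dg_threshold: float = -8.4
    threshold_is_strict: bool = False
    mode_fraction: float = MODE_FRACTION
    min_pct_sd: float = MIN_PCT_SD
    abundance_threshold: float = SD_ABUNDANCE_THRESHOLD
    params_path: str | None = None
    reference_tail: str = CANONICAL_TAIL
    seed: int = 0
    verbosity: int = 1


@dataclass
class PipelineResult:
    organism_id: str
    summary: object
    profile: AntiSDProfile | SDScarce
    group_id: int | None
    category: object
    calls: list
    tail: TailRecord
    core: CoreAnnotation | None


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = load_energy_model(cfg.params_path)
    scan_cfg = ScanConfig(
        window_len=cfg.window_len,
        utr_span=tuple(cfg.utr_span),
        dg_threshold=cfg.dg_threshold,
        threshold_is_strict=cfg.threshold_is_strict,
    )

    # --- tail annotation ---------------------------------------------------
    try:
        tail_fa = read_fasta(cfg.tails)
        by_org: dict[str, list] = {}
        for rec in tail_fa:
            by_org.setdefault(rec.id.split("|")[0], []).append(rec)
        if len(by_org) != 1:
            raise PipelineError(
                f"stage 'tails': expected one organism, found {sorted(by_org)}"
            )
        organism_id = next(iter(by_org))
        tails = [
            find_unstructured_tail(r.sequence, model, organism_id=organism_id)
            for r in by_org[organism_id]
        ]
        tail, paralog_report = consolidate_paralogs(tails)
        try:
            core = locate_core(tail, cfg.reference_tail)
        except CoreUnresolvableError:
            core = None
    except (AntiSDScanError, OSError) as exc:
        raise PipelineError(f"stage 'tails': {exc}") from exc

    # --- UTR extraction ----------------------------------------------------
    try:
        genomes = {g.id: g for g in read_fasta(cfg.genome)}
        genes = read_gene_models(
            cfg.genes, dialect=cfg.genes_dialect, genomes=list(genomes.values())
        )
        utrs = [
            extract_utr(g, genomes[g.contig], span=tuple(cfg.utr_span))
            for g in genes
        ]
    except (AntiSDScanError, OSError, KeyError) as exc:
        raise PipelineError(f"stage 'utr': {exc}") from exc

    # --- scan / summarize --------------------------------------------------
    calls = scan_organism(utrs, tail, core, model, scan_cfg)
    if not calls:
        raise PipelineError(f"stage 'scan': organism {organism_id!r} has no "
                            "scannable genes")
    summary = summarize_organism(calls, organism_id)

    # --- profile / group / category ---------------------------------------
    if core is not None:
        profile = build_profile(
            calls, tail, core,
            mode_fraction=cfg.mode_fraction, min_pct_sd=cfg.min_pct_sd,
        )
    else:
        profile = SDScarce(organism_id, summary.pct_sd)
    group_id = None
    if isinstance(profile, AntiSDProfile):
        group_id, _nearest = assign_group(profile, GroupCatalog.load())
    core_present = core is not None and core.status == "present"
    category = categorize_organism(core_present, summary,
                                   cfg.abundance_threshold)

    # --- outputs -----------------------------------------------------------
    calls_to_table(calls).to_csv(out / "per_gene.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dict(
            organism_id=organism_id,
            n_genes_scanned=summary.n_genes_scanned,
            n_sd=summary.n_sd,
            pct_sd=round(summary.pct_sd, 2),
            mean_sd_window_position=summary.mean_sd_window_position,
            tail=tail.tail,
            core_status="none" if core is None else core.status,
            central_u_index=-1 if core is None else core.central_u_index,
            n_copies=paralog_report.n_copies,
            n_discordant=paralog_report.n_discordant,
        )]
    ).to_csv(out / "organism.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dict(
            organism_id=organism_id,
            core_present=category.core_present,
            pct_sd=round(category.pct_sd, 2),
            category=category.category,
        )]
    ).to_csv(out / "category.tsv", sep="\t", index=False)
    if isinstance(profile, AntiSDProfile):
        profile_to_table(profile).to_csv(out / "profile.tsv", sep="\t",
                                         index=False)
        doc = dict(
            organism_id=organism_id,
            span=list(profile.span),
            consensus=profile.consensus,
            sd_consensus=profile.sd_consensus,
            group=group_id,
            pct_sd=round(profile.pct_sd, 2),
            freq={str(k): v for k, v in profile.freq.items()},
        )
    else:
        doc = dict(organism_id=organism_id, sd_scarce=True,
                   pct_sd=round(profile.pct_sd, 2))
    (out / "profile.json").write_text(json.dumps(doc, indent=1))
    log_lines = [
        f"antisdscan {__version__}",
        f"energy model: {model.source} checksum {model.checksum()}",
        f"derived threshold: {derive_sd_threshold(model, cfg.reference_tail)}",
    ] + [
        f"{f.name} = {getattr(cfg, f.name)}" for f in dataclasses.fields(cfg)
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        organism_id=organism_id, summary=summary, profile=profile,
        group_id=group_id, category=category, calls=calls, tail=tail, core=core,
    )
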