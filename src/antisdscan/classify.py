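"""Four-category organism classification and threshold-stability sweep.

An organism is categorized by two binary traits: does its 16S tail carry
an intact CCUCC core, and is it SD-Abundant (more than 5.5% of scanned
mRNAs with an SD call)?

    i   core present, SD-Abundant      (canonical SD users)
    ii  core present, SD-Scarce
    iii core absent,  SD-Abundant      (variant-core SD users)
    iv  core absent,  SD-Scarce
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .rrna_tail import CoreAnnotation
from .scan import OrganismSummary

SD_ABUNDANCE_THRESHOLD = 5.5  # percent, strict ">"

Category = Literal["i", "ii", "iii", "iv"]


@dataclass(frozen=True)
class CategoryCall:
    organism_id: str
    core_present: bool
    sd_abundant: bool
    pct_sd: float
    category: Category


def _category(core_present: bool, sd_abundant: bool) -> Category:
    if core_present:
        return "i" if sd_abundant else "ii"
    return "iii" if sd_abundant else "iv"


def categorize_organism(
    core: CoreAnnotation | bool,
    summary: OrganismSummary,
    threshold: float = SD_ABUNDANCE_THRESHOLD,
) -> CategoryCall:
    """Total, deterministic classification of one organism."""
    core_present = core if isinstance(core, bool) else core.status == "present"
    abundant = summary.pct_sd > threshold
    return CategoryCall(
        organism_id=summary.organism_id,
        core_present=core_present,
        sd_abundant=abundant,
        pct_sd=summary.pct_sd,
        category=_category(core_present, abundant),
    )


def threshold_sweep(
    summaries: Sequence[OrganismSummary],
    cores: Sequence[CoreAnnotation | bool],
    grid: Sequence[float],
    baseline: float = SD_ABUNDANCE_THRESHOLD,
) -> pd.DataFrame:
    """Re-categorize every organism at each grid threshold and report the
    fraction with a category unchanged from the baseline threshold."""
    if len(summaries) != len(cores):
        raise ValueError("summaries and cores must align")
    base = [
        categorize_organism(c, s, baseline).category
        for c, s in zip(cores, summaries)
    ]
    rows = []
    for thr in grid:
        cats = [
            categorize_organism(c, s, thr).category
            for c, s in zip(cores, summaries)
        ]
        agree = (
            sum(a == b for a, b in zip(base, cats)) / len(base) if base else 1.0
        )
        rows.append(dict(threshold=thr, agreement=agree))
    return pd.DataFrame(rows, columns=["threshold", "agreement"])
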