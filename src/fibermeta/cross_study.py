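"""Cross-study filtering and meta-aggregation of differential-abundance results.

OTUs are filtered per study (low-abundance/low-occupancy removal, then a
50% prevalence filter), and log2 fold changes of OTUs that are widespread
(present, i.e. prevalence-passing, in at least ``min_studies`` studies) are
averaged unweighted across the studies where they are present. The mean
sign assigns the binary response trait fed to the phylogenetic analysis;
|mean log2FC| > 1 marks top responders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountTable, ValidationError
from .diffabund import DAResult

__all__ = [
    "filter_otus",
    "prevalence_filter",
    "aggregate_log2fc",
    "TraitAssignment",
]

logger = logging.getLogger("fibermeta")

TOP_RESPONDER_CUT = 1.0


@dataclass(frozen=True)
class TraitAssignment:
    """Aggregated cross-study responses for widespread OTUs.

    ``table`` columns: mean_log2fc, response ('positive'/'negative'),
    n_studies_present, top_responder (|mean_log2fc| > 1).
    """

    table: pd.DataFrame = field(repr=False)
    min_studies: int = 3

    @property
    def positive_otus(self) -> set:
        return set(self.table.index[self.table["response"] == "positive"])

    @property
    def negative_otus(self) -> set:
        return set(self.table.index[self.table["response"] == "negative"])

    @property
    def top_responders(self) -> set:
        return set(self.table.index[self.table["top_responder"]])


def filter_otus(
    table: CountTable, min_total: int = 10, min_samples: int = 3
) -> CountTable:
    """Drop OTUs that are too rare to be trusted as real sequences.

    An OTU is removed when its total count across samples is below
    ``min_total`` or it occurs in fewer than ``min_samples`` samples —
    either failure removes it. Raises if nothing survives.
    """
    totals = table.counts.sum(axis=1)
    occupancy = (table.counts > 0).sum(axis=1)
    keep = (totals >= min_total) & (occupancy >= min_samples)
    if not keep.any():
        raise ValidationError("no OTU survives the abundance/occupancy filter")
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "filter_otus: removed %d of %d OTUs (total<%d or occupancy<%d)",
            removed, len(keep), min_total, min_samples,
        )
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    return table.select_otus(kept)


def prevalence_filter(table: CountTable, min_fraction: float = 0.5) -> CountTable:
    """Keep OTUs present in at least ``min_fraction`` of the study's samples.

    The boundary is inclusive: an OTU in exactly half the samples is kept.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = (table.counts > 0).mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValidationError("no OTU passes the prevalence filter")
    kept = [o for o, k in zip(table.otu_ids, keep) if k]
    return table.select_otus(kept)


def aggregate_log2fc(
    results: dict[str, DAResult],
    presence: dict[str, set],
    min_studies: int = 3,
) -> TraitAssignment:
    """Average per-study log2 fold changes for widespread OTUs.

    ``results`` maps study -> DAResult; ``presence`` maps study -> the set
    of OTU IDs that passed that study's prevalence filter. OTUs present in
    at least ``min_studies`` studies get the unweighted mean of their
    log2fc over exactly those studies; the sign of the mean is the response
    trait. OTUs with mean exactly 0 are dropped (no direction).
    """
    if len(results) < min_studies:
        raise ValidationError(
            f"need at least min_studies={min_studies} studies, got {len(results)}"
        )
    if set(results) != set(presence):
        raise ValidationError("results and presence must cover the same studies")
    all_ids = [set(r.table.index) for r in results.values()]
    shared = set.union(*all_ids)
    if all_ids and not set.intersection(*all_ids) and len(results) > 1:
        pairwise_empty = all(
            not (a & b) for a in all_ids for b in all_ids if a is not b
        )
        if pairwise_empty:
            raise ValidationError(
                "OTU ID spaces are disjoint across studies; harmonize OTU "
                "clustering upstream before aggregating"
            )
    rows = []
    for otu in sorted(shared):
        studies = [
            s for s in results
            if otu in presence[s] and otu in results[s].table.index
        ]
        if len(studies) < min_studies:
            continue
        lfcs = np.array([results[s].table.loc[otu, "log2fc"] for s in studies])
        mean = float(lfcs.mean())
        if mean == 0.0:
            continue
        rows.append(
            {
                "otu_id": otu,
                "mean_log2fc": mean,
                "response": "positive" if mean > 0 else "negative",
                "n_studies_present": len(studies),
                "top_responder": abs(mean) > TOP_RESPONDER_CUT,
            }
        )
    if not rows:
        raise ValidationError("no OTU is widespread enough to aggregate")
    df = pd.DataFrame(rows).set_index("otu_id")
    return TraitAssignment(df, min_studies=min_studies)
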