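"""PSI arithmetic, significance filtering and summaries over event tables.

Thresholds follow the study design: mis-splicing is called at FDR < 0.10
(strict); the regulation classes used for motif analysis require FDR < 0.05
and |ΔPSI| > 0.2; the consensus cassette-exon set keeps events significant in
at least ``min_support`` of the mutant lines; differentially expressed genes
pass |log2FC| >= 1.0 and FDR < 0.05.

Sign convention: ΔPSI = mean(mutant PSI) − mean(WT PSI). An exon whose
inclusion *rises* when Mbnl function is lost is therefore Mbnl-*repressed*
(the proteins normally suppress its inclusion), and one whose inclusion falls
is Mbnl-*activated*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import EVENT_TYPES, EventTable, SpliceEvent

__all__ = [
    "RegulationCall",
    "psi_from_band_intensities",
    "delta_psi",
    "significant_events",
    "classify_regulation",
    "count_events_by_type",
    "consensus_set",
    "magnitude_summary",
    "de_gene_filter",
]

MBNL_ACTIVATED = "mbnl_activated"
MBNL_REPRESSED = "mbnl_repressed"
NOT_REGULATED = "not_regulated"


@dataclass(frozen=True)
class RegulationCall:
    event_id: str
    genotype: str
    regulation: str  # one of the three class constants above


def psi_from_band_intensities(included_sum: float, excluded_sum: float) -> float:
    """Percent exon inclusion from background-corrected RT-PCR band sums.

    PSI = included / (included + excluded) × 100.
    """
    if included_sum < 0 or excluded_sum < 0:
        raise ValueError("band intensities must be non-negative")
    total = included_sum + excluded_sum
    if total == 0:
        raise ValueError("PSI undefined: both band sums are zero")
    return 100.0 * included_sum / total


def delta_psi(
    mutant_psis: Sequence[float], wt_psis: Sequence[float]
) -> float:
    """Mean inclusion difference, mutant − WT, on the 0–1 scale."""
    mut = np.asarray(mutant_psis, dtype=float)
    wt = np.asarray(wt_psis, dtype=float)
    mut, wt = mut[~np.isnan(mut)], wt[~np.isnan(wt)]
    if mut.size == 0 or wt.size == 0:
        raise ValueError("each group must contain at least one PSI value")
    return float(mut.mean() - wt.mean())


def significant_events(
    table: EventTable, genotype: str, fdr_threshold: float = 0.10
) -> list[SpliceEvent]:
    """Events mis-spliced in ``genotype`` at FDR strictly below the threshold."""
    if genotype not in table.sample_labels:
        raise KeyError(f"unknown genotype {genotype!r}")
    return [
        rec
        for rec in table.records
        if genotype in rec.fdr_by_genotype
        and rec.fdr_by_genotype[genotype] < fdr_threshold
    ]


def classify_regulation(
    event: SpliceEvent,
    genotype: str,
    fdr_threshold: float = 0.05,
    dpsi_threshold: float = 0.2,
) -> RegulationCall:
    """Assign the Mbnl regulation class used for motif-enrichment sets.

    ΔPSI > +0.2 at FDR < 0.05 → inclusion rises on Mbnl loss → mbnl_repressed;
    ΔPSI < −0.2 at FDR < 0.05 → mbnl_activated; anything else not_regulated.
    """
    fdr = event.fdr_by_genotype.get(genotype)
    dpsi = event.delta_psi_by_genotype.get(genotype)
    if fdr is None or dpsi is None:
        raise KeyError(f"event {event.event_id}: no test result for {genotype!r}")
    if fdr < fdr_threshold and dpsi > dpsi_threshold:
        cls = MBNL_REPRESSED
    elif fdr < fdr_threshold and dpsi < -dpsi_threshold:
        cls = MBNL_ACTIVATED
    else:
        cls = NOT_REGULATED
    return RegulationCall(event_id=event.event_id, genotype=genotype, regulation=cls)


def count_events_by_type(
    table: EventTable, genotype: str, fdr_threshold: float = 0.10
) -> dict[str, int]:
    """Significant-event tally per splicing type (zero-count types included)."""
    counts = {t: 0 for t in EVENT_TYPES}
    for rec in significant_events(table, genotype, fdr_threshold):
        counts[rec.event_type] += 1
    return counts


def consensus_set(
    table: EventTable,
    genotypes: Sequence[str],
    min_support: int = 4,
    fdr_threshold: float = 0.10,
) -> list[SpliceEvent]:
    """Cassette exons mis-spliced in at least ``min_support`` mutant lines.

    The study's consensus set uses min_support=4 over its seven mutant lines.
    """
    if min_support > len(genotypes):
        raise ValueError(
            f"min_support={min_support} exceeds the {len(genotypes)} genotypes given"
        )
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    sig_ids = [
        {rec.event_id for rec in significant_events(table, g, fdr_threshold)}
        for g in genotypes
    ]
    out = []
    for rec in table.records:
        if rec.event_type != "SE":
            continue
        support = sum(rec.event_id in ids for ids in sig_ids)
        if support >= min_support:
            out.append(rec)
    return out


def magnitude_summary(
    subset: Sequence[SpliceEvent], genotype: str
) -> float:
    """Mean |ΔPSI| of ``genotype`` over an event subset (NaN ΔPSI dropped)."""
    if len(subset) == 0:
        raise ValueError("cannot summarize an empty event subset")
    vals = np.array(
        [rec.delta_psi_by_genotype.get(genotype, np.nan) for rec in subset],
        dtype=float,
    )
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"no ΔPSI values for genotype {genotype!r}")
    return float(np.abs(vals).mean())


def magnitude_table(
    table: EventTable,
    genotypes: Sequence[str],
    subset: Sequence[SpliceEvent],
) -> pd.Series:
    """Per-genotype mean |ΔPSI| over a shared event subset, sorted descending."""
    return pd.Series(
        {g: magnitude_summary(subset, g) for g in genotypes}
    ).sort_values(ascending=False)


def de_gene_filter(
    expression_table: Mapping[str, tuple[float, float]],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """Genes passing |log2FC| >= lfc_threshold (inclusive) and FDR < fdr_threshold."""
    return [
        gene
        for gene, (lfc, fdr) in expression_table.items()
        if abs(lfc) >= lfc_threshold and fdr < fdr_threshold
    ]
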