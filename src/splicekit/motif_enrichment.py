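"""YGCY motif enrichment around regulated cassette exons.

MBNL-family proteins bind pyrimidine-G-C-pyrimidine (YGCY) elements; their
positional bias around a cassette exon predicts the direction of regulation
(downstream-intron binding promotes inclusion, upstream/exonic binding
represses it). This module quantifies that bias over five windows per
cassette exon — the exon itself, the 250 nt of intron immediately 5′ and 3′
of it, and the 250 nt of intron immediately adjacent to the two flanking
constitutive exons — as a log2 ratio of motif enrichment (relative to
composition-matched control 4-mers) in regulated versus non-regulated exons.

Two motif presets are shipped: the canonical YGCY expansion
{TGCT, TGCC, CGCT, CGCC}, and a second preset reproducing a published list
(GCTT, CGCT, TGCT, GCGC) that deviates from the strict YGCY pattern; both
are first-class and selectable.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SpliceEvent, Transcript
from .splice_events import MBNL_ACTIVATED, MBNL_REPRESSED, RegulationCall

__all__ = [
    "REGION_NAMES",
    "MotifSet",
    "RegionWindow",
    "MotifEnrichmentCell",
    "YGCY_CANONICAL",
    "PAPER_PRINTED",
    "PRESETS",
    "extract_windows",
    "count_motifs",
    "kmer_spectrum",
    "control_kmers",
    "enrichment_ratio",
    "enrichment_heatmap",
    "heatmap_frame",
]

REGION_NAMES = (
    "cassette_exon",
    "intron_5prime_of_cassette",
    "intron_3prime_of_cassette",
    "intron_3prime_of_upstream_constitutive",
    "intron_5prime_of_downstream_constitutive",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSet:
    name: str
    motifs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif set must be non-empty")
        if any(len(m) != 4 for m in self.motifs):
            raise ValueError("all motifs must be 4-mers")


YGCY_CANONICAL = MotifSet("ygcy", frozenset({"TGCT", "TGCC", "CGCT", "CGCC"}))
PAPER_PRINTED = MotifSet("printed", frozenset({"GCTT", "CGCT", "TGCT", "GCGC"}))
PRESETS = {m.name: m for m in (YGCY_CANONICAL, PAPER_PRINTED)}


@dataclass
class RegionWindow:
    """One coding-strand-oriented sequence window with its genomic source."""

    name: str
    sequence: str
    chrom: str
    start: int  # 0-based half-open genomic interval on the plus strand
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown region name {self.name!r}")
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence must use A/C/G/T/N")


@dataclass(frozen=True)
class MotifEnrichmentCell:
    region: str
    regulation_class: str  # mbnl_activated | mbnl_repressed
    set_label: str
    log2_ratio: float


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Plus-strand slice from a dict-of-strings or pyfaidx.Fasta-like source."""
    return str(genome[chrom][start:end]).upper()


def _intron_windows(
    istart: int, iend: int, strand: str, window_nt: int, cassette_first: bool
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Genomic intervals of the two windows claiming one intron.

    Returns ((first_tx_window), (last_tx_window)) where "first" abuts the
    transcriptionally upstream exon. Overlap in short introns is resolved at
    the intron midpoint; on odd lengths the cassette-adjacent window
    (``cassette_first`` says which end that is) takes the extra base.
    """
    length = iend - istart
    if length >= 2 * window_nt:
        w_first = w_last = window_nt
    else:
        half = length // 2
        if cassette_first:
            w_first, w_last = length - half, half
        else:
            w_first, w_last = half, length - half
    w_first, w_last = min(w_first, window_nt), min(w_last, window_nt)
    if strand == "+":
        first = (istart, istart + w_first)
        last = (iend - w_last, iend)
    else:  # transcription runs right-to-left
        first = (iend - w_first, iend)
        last = (istart, istart + w_last)
    return first, last


def extract_windows(
    gene_model: GeneModel,
    cassette_exon_index: int,
    genome: Mapping[str, str],
    window_nt: int = 250,
    transcript_id: str | None = None,
) -> dict[str, RegionWindow]:
    """The five motif windows around one cassette exon, coding-strand oriented.

    ``cassette_exon_index`` is the transcription-order index within the
    chosen transcript; the exon must have constitutive neighbours on both
    sides. Intronic windows are truncated at the intron midpoint when the two
    windows claiming a short intron would overlap.
    """
    tx = gene_model.transcript(transcript_id)
    if not 0 < cassette_exon_index < len(tx.exons) - 1:
        raise ValueError(
            f"cassette exon index {cassette_exon_index} of transcript "
            f"{tx.transcript_id!r} lacks flanking exons"
        )
    strand, chrom = gene_model.strand, gene_model.chrom
    cas = tx.exons[cassette_exon_index]
    up = tx.exons[cassette_exon_index - 1]  # transcriptionally upstream
    down = tx.exons[cassette_exon_index + 1]

    def intron_between(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
        # a precedes b in transcription order
        return (a[1], b[0]) if strand == "+" else (b[1], a[0])

    up_intron = intron_between(up, cas)
    down_intron = intron_between(cas, down)
    # upstream intron: first window abuts the constitutive exon, last abuts cassette
    up_first, up_last = _intron_windows(
        *up_intron, strand=strand, window_nt=window_nt, cassette_first=False
    )
    down_first, down_last = _intron_windows(
        *down_intron, strand=strand, window_nt=window_nt, cassette_first=True
    )
    intervals = {
        "cassette_exon": cas,
        "intron_5prime_of_cassette": up_last,
        "intron_3prime_of_cassette": down_first,
        "intron_3prime_of_upstream_constitutive": up_first,
        "intron_5prime_of_downstream_constitutive": down_last,
    }
    out: dict[str, RegionWindow] = {}
    for name, (s, e) in intervals.items():
        seq = _fetch(genome, chrom, s, e)
        if strand == "-":
            seq = reverse_complement(seq)
        out[name] = RegionWindow(
            name=name, sequence=seq, chrom=chrom, start=s, end=e, strand=strand
        )
    return out


def count_motifs(window: RegionWindow | str, motifs: MotifSet) -> int:
    """Overlapping occurrences of any motif in the window (N never matches)."""
    seq = window if isinstance(window, str) else window.sequence
    seq = seq.upper()
    if len(seq) < 4:
        return 0
    hits = 0
    for i in range(len(seq) - 3):
        word = seq[i : i + 4]
        if "N" not in word and word in motifs.motifs:
            hits += 1
    return hits


def kmer_spectrum(sequences: Iterable[str], k: int = 4) -> Counter:
    """Overlapping k-mer counts pooled over sequences (windows with N skipped)."""
    counts: Counter = Counter()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if "N" not in word:
                counts[word] += 1
    return counts


def _at_count(kmer: str) -> int:
    return sum(base in "AT" for base in kmer)


def _cg_dinucleotides(kmer: str) -> int:
    return sum(kmer[i : i + 2] == "CG" for i in range(len(kmer) - 1))


def control_kmers(motif: str, exclude: MotifSet | Iterable[str] = ()) -> set[str]:
    """All 4-mers matching the motif's A+T base count and CG-dinucleotide count.

    The query motif and everything in ``exclude`` (typically the whole
    analysis motif set, to avoid self-contamination of the control mean) are
    removed from the result.
    """
    if len(motif) != 4:
        raise ValueError("motif must be a 4-mer")
    excluded = set(exclude.motifs) if isinstance(exclude, MotifSet) else set(exclude)
    at, cg = _at_count(motif), _cg_dinucleotides(motif)
    controls = {
        "".join(word)
        for word in itertools.product("ACGT", repeat=4)
        if _at_count("".join(word)) == at and _cg_dinucleotides("".join(word)) == cg
    }
    controls -= excluded | {motif}
    if not controls:
        raise ValueError(
            f"control set for {motif!r} is empty; relax the exclude policy"
        )
    return controls


def _control_union(motifs: MotifSet) -> set[str]:
    out: set[str] = set()
    for m in motifs.motifs:
        out |= control_kmers(m, exclude=motifs)
    return out


def enrichment_ratio(
    windows: Sequence[RegionWindow | str],
    motifs: MotifSet,
    pseudocount: float = 1.0,
    _spectrum: Counter | None = None,
) -> float:
    """Motif frequency over the mean control-4-mer frequency, pooled over windows.

    Counts are pooled across windows (pooled occurrences / pooled nt), the
    motif side is the mean per-motif count over the set, and ``pseudocount``
    is added to the motif mean and to each control count to keep downstream
    log ratios finite.
    """
    seqs = [w if isinstance(w, str) else w.sequence for w in windows]
    total_nt = sum(len(s) for s in seqs)
    if total_nt == 0:
        raise ValueError("zero analyzed sequence length")
    spectrum = _spectrum if _spectrum is not None else kmer_spectrum(seqs)
    motif_mean = np.mean([spectrum[m] for m in sorted(motifs.motifs)])
    controls = sorted(_control_union(motifs))
    control_mean = np.mean([spectrum[c] + pseudocount for c in controls])
    return float(((motif_mean + pseudocount) / total_nt) / (control_mean / total_nt))


def _windows_by_region(
    events: Sequence[SpliceEvent],
    gene_models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    cassette_index: Mapping[str, int] | None,
    window_nt: int,
) -> dict[str, list[str]]:
    pooled: dict[str, list[str]] = {name: [] for name in REGION_NAMES}
    for ev in events:
        model = gene_models[ev.gene_id]
        if cassette_index is not None:
            idx = cassette_index[ev.gene_id]
        else:
            idx = locate_cassette_exon(model, ev)
        for name, win in extract_windows(model, idx, genome, window_nt).items():
            pooled[name].append(win.sequence)
    return pooled


def locate_cassette_exon(model: GeneModel, event: SpliceEvent) -> int:
    """Transcription-order index of the event's cassette exon in the gene model."""
    target = (event.exon_start, event.exon_end)
    for tx in model.transcripts.values():
        if target in tx.exons:
            return tx.exons.index(target)
    raise ValueError(
        f"cassette exon {target} of event {event.event_id} not found in "
        f"gene {model.gene_id}"
    )


def enrichment_heatmap(
    regulated_sets: Mapping[str, Sequence[RegulationCall]],
    nonregulated: Sequence[SpliceEvent],
    events_by_id: Mapping[str, SpliceEvent],
    gene_models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    motifs: MotifSet = YGCY_CANONICAL,
    window_nt: int = 250,
    pseudocount: float = 1.0,
    cassette_index: Mapping[str, int] | None = None,
) -> list[MotifEnrichmentCell]:
    """One log2 enrichment cell per (region × regulation class × set label).

    Each cell is log2 of the regulated-set enrichment ratio over the
    non-regulated-set ratio for the same region, computed separately for
    Mbnl-activated and Mbnl-repressed exons. ``cassette_index`` may map
    gene_id → transcription-order cassette index to skip coordinate lookup.
    """
    if not nonregulated:
        raise ValueError("non-regulated exon set must be non-empty")
    nonreg_windows = _windows_by_region(
        nonregulated, gene_models, genome, cassette_index, window_nt
    )
    nonreg_ratio = {
        region: enrichment_ratio(seqs, motifs, pseudocount)
        for region, seqs in nonreg_windows.items()
    }
    cells: list[MotifEnrichmentCell] = []
    for label, calls in regulated_sets.items():
        for cls in (MBNL_ACTIVATED, MBNL_REPRESSED):
            events = [
                events_by_id[c.event_id] for c in calls if c.regulation == cls
            ]
            if not events:
                continue  # a set may legitimately lack one regulation class
            pooled = _windows_by_region(
                events, gene_models, genome, cassette_index, window_nt
            )
            for region, seqs in pooled.items():
                ratio = enrichment_ratio(seqs, motifs, pseudocount)
                cells.append(
                    MotifEnrichmentCell(
                        region=region,
                        regulation_class=cls,
                        set_label=label,
                        log2_ratio=math.log2(ratio / nonreg_ratio[region]),
                    )
                )
    return cells


def heatmap_frame(cells: Sequence[MotifEnrichmentCell]) -> pd.DataFrame:
    """Long-format frame (region, class, set, log2_ratio) for plotting/export."""
    return pd.DataFrame(
        [
            {
                "region": c.region,
                "regulation_class": c.regulation_class,
                "set_label": c.set_label,
                "log2_ratio": c.log2_ratio,
            }
            for c in cells
        ]
    )
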