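"""Readers and writers for every external file the pipeline touches.

Conventions enforced here, once, so downstream modules never reason about
dialects:

* inclusion levels (PSI) are stored on the 0–1 scale; the ×100 percent scale
  is formatting only;
* all genomic coordinates are 0-based half-open internally (rMATS SE tables
  already use ``exonStart_0base``; BED is 0-based half-open; GFF3 input is
  converted from 1-based closed on read);
* exon indices are transcription order: exon 0 is the 5′-most exon on the
  coding strand, so for minus-strand transcripts it is the rightmost block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

EVENT_TYPES = ("SE", "A3SS", "A5SS", "RI", "MXE")

__all__ = [
    "EVENT_TYPES",
    "SpliceEvent",
    "EventTable",
    "TankGeometry",
    "TrajectoryFile",
    "GeneModel",
    "Transcript",
    "FormatError",
    "read_rmats_table",
    "write_rmats_table",
    "read_gene_models",
    "read_trajectory",
]


class FormatError(ValueError):
    """A file violates the dialect this reader expects."""


# ---------------------------------------------------------------------------
# splicing events


@dataclass
class SpliceEvent:
    """One alternative-splicing event with per-replicate inclusion levels.

    Coordinates are 0-based half-open on ``chrom``. For SE events
    ``exon_start/exon_end`` bound the cassette exon and the ``upstream_*`` /
    ``downstream_*`` fields bound the flanking constitutive exons in genomic
    (left-to-right) order, mirroring the rMATS table layout.
    """

    event_id: str
    event_type: str
    gene_id: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_start: int
    upstream_end: int
    downstream_start: int
    downstream_end: int
    psi_by_replicate: dict[str, float] = field(default_factory=dict)
    fdr_by_genotype: dict[str, float] = field(default_factory=dict)
    pvalue_by_genotype: dict[str, float] = field(default_factory=dict)
    delta_psi_by_genotype: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        for rep, psi in self.psi_by_replicate.items():
            if not math.isnan(psi) and not 0.0 <= psi <= 1.0:
                raise ValueError(f"PSI {psi} of replicate {rep!r} outside [0, 1]")


@dataclass
class EventTable:
    """Ordered collection of SpliceEvents plus the genotype → replicates map."""

    records: list[SpliceEvent]
    sample_labels: dict[str, list[str]]

    def __post_init__(self) -> None:
        ids = [r.event_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("event identifiers must be unique")
        known = {rep for reps in self.sample_labels.values() for rep in reps}
        for rec in self.records:
            missing = set(rec.psi_by_replicate) - known
            if missing:
                raise ValueError(
                    f"event {rec.event_id}: replicate(s) {sorted(missing)} "
                    "not covered by sample_labels"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genotypes(self) -> list[str]:
        return list(self.sample_labels)

    def psi_matrix(self) -> pd.DataFrame:
        """Replicates × events PSI frame (NaN where coverage was missing)."""
        reps = [r for reps in self.sample_labels.values() for r in reps]
        data = {
            rec.event_id: [rec.psi_by_replicate.get(r, np.nan) for r in reps]
            for rec in self.records
        }
        return pd.DataFrame(data, index=reps)


_RMATS_COORD_COLUMNS = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
            "2ndExonEnd", "upstreamES", "upstreamEE"],
}


def _parse_inclevel(cell: str, row_num: int, column: str) -> list[float]:
    values: list[float] = []
    for tok in str(cell).split(","):
        tok = tok.strip()
        if tok in ("", "NA", "nan"):
            values.append(float("nan"))
            continue
        v = float(tok)
        if not 0.0 <= v <= 1.0:
            raise ValueError(
                f"row {row_num}: inclusion level {v} in column {column} outside [0, 1]"
            )
        values.append(v)
    return values


def read_rmats_table(
    path: str | Path,
    event_type: str,
    genotype: str = "mutant",
    wt_label: str = "WT",
) -> EventTable:
    """Read one rMATS-style per-comparison TSV (mutant group vs WT group).

    ``IncLevel1`` carries the mutant replicates and ``IncLevel2`` the WT
    replicates, comma-separated, as rMATS writes them. The per-event FDR and
    IncLevelDifference are stored under ``genotype``.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = (
        ["ID", "GeneID", "chr", "strand"]
        + _RMATS_COORD_COLUMNS[event_type]
        + ["IncLevel1", "IncLevel2", "PValue", "FDR", "IncLevelDifference"]
    )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    coord_cols = _RMATS_COORD_COLUMNS[event_type]
    records: list[SpliceEvent] = []
    n_mut = n_wt = 0
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        mut = _parse_inclevel(row["IncLevel1"], row_num, "IncLevel1")
        wt = _parse_inclevel(row["IncLevel2"], row_num, "IncLevel2")
        n_mut, n_wt = max(n_mut, len(mut)), max(n_wt, len(wt))
        coords = [int(row[c]) for c in coord_cols]
        psi = {f"{genotype}_r{i + 1}": v for i, v in enumerate(mut)}
        psi.update({f"{wt_label}_r{i + 1}": v for i, v in enumerate(wt)})
        records.append(
            SpliceEvent(
                event_id=f"{event_type}:{row['ID']}",
                event_type=event_type,
                gene_id=str(row["GeneID"]),
                chrom=str(row["chr"]),
                strand=str(row["strand"]),
                exon_start=coords[0],
                exon_end=coords[1],
                upstream_start=coords[2],
                upstream_end=coords[3],
                downstream_start=coords[4],
                downstream_end=coords[5],
                psi_by_replicate=psi,
                fdr_by_genotype={genotype: float(row["FDR"])},
                pvalue_by_genotype={genotype: float(row["PValue"])},
                delta_psi_by_genotype={genotype: float(row["IncLevelDifference"])},
            )
        )
    sample_labels = {
        genotype: [f"{genotype}_r{i + 1}" for i in range(n_mut)],
        wt_label: [f"{wt_label}_r{i + 1}" for i in range(n_wt)],
    }
    return EventTable(records=records, sample_labels=sample_labels)


def write_rmats_table(
    table: EventTable, path: str | Path, genotype: str, wt_label: str = "WT"
) -> None:
    """Write one genotype-vs-WT comparison back out in the rMATS SE dialect.

    Numeric fields round-trip at full precision (repr formatting).
    """
    rows = []
    for rec in table.records:
        cols = _RMATS_COORD_COLUMNS[rec.event_type]
        mut = [rec.psi_by_replicate.get(r, float("nan"))
               for r in table.sample_labels[genotype]]
        wt = [rec.psi_by_replicate.get(r, float("nan"))
              for r in table.sample_labels[wt_label]]
        fmt = lambda vals: ",".join("NA" if math.isnan(v) else repr(v) for v in vals)
        row = {
            "ID": rec.event_id.split(":", 1)[1],
            "GeneID": rec.gene_id,
            "chr": rec.chrom,
            "strand": rec.strand,
            cols[0]: rec.exon_start,
            cols[1]: rec.exon_end,
            cols[2]: rec.upstream_start,
            cols[3]: rec.upstream_end,
            cols[4]: rec.downstream_start,
            cols[5]: rec.downstream_end,
            "IncLevel1": fmt(mut),
            "IncLevel2": fmt(wt),
            "PValue": repr(rec.pvalue_by_genotype.get(genotype, float("nan"))),
            "FDR": repr(rec.fdr_by_genotype.get(genotype, float("nan"))),
            "IncLevelDifference": repr(
                rec.delta_psi_by_genotype.get(genotype, float("nan"))
            ),
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models


@dataclass
class Transcript:
    """Exon blocks of one transcript, stored in transcription order."""

    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, transcription order

    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class GeneModel:
    """Exon/intron structure of one gene with strand-aware exon indexing."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript]

    def transcript(self, transcript_id: str | None = None) -> Transcript:
        if transcript_id is None:
            return next(iter(self.transcripts.values()))
        return self.transcripts[transcript_id]


def _order_exons(blocks: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    blocks = sorted(blocks)
    return blocks if strand == "+" else blocks[::-1]


def _read_gff3(path: Path) -> list[GeneModel]:
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_strands: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype in ("mRNA", "transcript"):
                tid = attr["ID"]
                gene = attr.get("Parent", tid)
                tx_meta[tid] = (gene, chrom, strand)
                tx_exons.setdefault(tid, [])
                tx_strands.setdefault(tid, set()).add(strand)
            elif ftype == "exon":
                tid = attr["Parent"]
                # GFF3 is 1-based closed; convert to 0-based half-open
                tx_exons.setdefault(tid, []).append((int(start) - 1, int(end)))
                tx_strands.setdefault(tid, set()).add(strand)
    genes: dict[str, GeneModel] = {}
    for tid, blocks in tx_exons.items():
        if len(tx_strands.get(tid, set())) > 1:
            raise FormatError(f"transcript {tid!r} has exons on mixed strands")
        gene, chrom, strand = tx_meta.get(tid, (tid, "?", "+"))
        if tid not in tx_meta:
            raise FormatError(f"exon references unknown transcript {tid!r}")
        model = genes.setdefault(
            gene, GeneModel(gene_id=gene, chrom=chrom, strand=strand, transcripts={})
        )
        if model.strand != strand:
            raise FormatError(f"gene {gene!r} mixes strands across transcripts")
        model.transcripts[tid] = Transcript(tid, _order_exons(blocks, strand))
    return list(genes.values())


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError("BED12 requires 12 columns")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                (chrom_start + s, chrom_start + s + size)
                for s, size in zip(starts, sizes)
            ]
            # convention: BED name is "gene|transcript", else one tx per gene
            gene_id, _, tid = name.partition("|")
            tid = tid or name
            model = genes.setdefault(
                gene_id,
                GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts={}),
            )
            if model.strand != strand:
                raise FormatError(f"gene {gene_id!r} mixes strands")
            model.transcripts[tid] = Transcript(tid, _order_exons(blocks, strand))
    return list(genes.values())


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 (auto-detected by extension/content).

    Exons come back in transcription order: index 0 is the 5′-most exon on the
    coding strand (the rightmost block for minus-strand transcripts).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path)
    if suffix == ".bed":
        return _read_bed12(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or first.count("\t") == 8:
        return _read_gff3(path)
    return _read_bed12(path)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class TankGeometry:
    """Novel-tank dimensions in centimetres (default: 18 deep × 25.4 × 7.6)."""

    depth_cm: float = 18.0
    length_cm: float = 25.4
    width_cm: float = 7.6

    def __post_init__(self) -> None:
        if min(self.depth_cm, self.length_cm, self.width_cm) <= 0:
            raise ValueError("tank dimensions must be positive")


@dataclass
class TrajectoryFile:
    """Frame-indexed 2-D positions in centimetres with acquisition metadata.

    ``gap_after`` flags indices i where frame numbering jumps between stored
    sample i and i+1 (dropped tracking frames); kinematics treats the speed
    across a flagged gap as undefined.
    """

    frames: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    fps: float
    tank: TankGeometry
    gap_after: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(np.diff(self.frames) <= 0):
            raise FormatError("frame numbers must be strictly increasing")
        if not (np.all(np.isfinite(self.x_cm)) and np.all(np.isfinite(self.y_cm))):
            raise ValueError("positions must be finite")
        if self.gap_after is None:
            self.gap_after = np.diff(self.frames) > 1
        self.gap_after = np.asarray(self.gap_after, dtype=bool)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        return len(self.frames) / self.fps

    @property
    def n_gaps(self) -> int:
        return int(self.gap_after.sum())


def read_trajectory(
    path: str | Path,
    fps: float,
    tank: TankGeometry,
    px_per_cm: float,
    flip_y: bool = False,
) -> TrajectoryFile:
    """Read a frame,x,y tracking CSV, converting pixels to centimetres.

    ``flip_y`` handles image coordinates (y grows downward): y_cm becomes
    height above the tank bottom.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    df = pd.read_csv(path)
    for col in ("frame", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    frames = df["frame"].to_numpy(dtype=int)
    if np.any(np.diff(frames) <= 0):
        raise FormatError("frame numbers must be strictly increasing")
    x = df["x"].to_numpy(dtype=float) / px_per_cm
    y = df["y"].to_numpy(dtype=float) / px_per_cm
    if flip_y:
        y = tank.depth_cm - y
    return TrajectoryFile(frames=frames, x_cm=x, y_cm=y, fps=fps, tank=tank)


def merge_event_tables(
    tables: Mapping[str, EventTable], wt_label: str = "WT"
) -> EventTable:
    """Combine per-comparison tables (one genotype vs WT each) into one
    multi-genotype table keyed on event identity.

    Events are matched by event_id; WT replicate PSI values must agree across
    comparisons (they come from the same WT samples).
    """
    merged: dict[str, SpliceEvent] = {}
    sample_labels: dict[str, list[str]] = {}
    for genotype, table in tables.items():
        sample_labels[genotype] = list(table.sample_labels[genotype])
        wt_reps = table.sample_labels.get(wt_label, [])
        if wt_label not in sample_labels:
            sample_labels[wt_label] = list(wt_reps)
        for rec in table.records:
            if rec.event_id not in merged:
                merged[rec.event_id] = SpliceEvent(
                    event_id=rec.event_id,
                    event_type=rec.event_type,
                    gene_id=rec.gene_id,
                    chrom=rec.chrom,
                    strand=rec.strand,
                    exon_start=rec.exon_start,
                    exon_end=rec.exon_end,
                    upstream_start=rec.upstream_start,
                    upstream_end=rec.upstream_end,
                    downstream_start=rec.downstream_start,
                    downstream_end=rec.downstream_end,
                )
            target = merged[rec.event_id]
            target.psi_by_replicate.update(rec.psi_by_replicate)
            target.fdr_by_genotype.update(rec.fdr_by_genotype)
            target.pvalue_by_genotype.update(rec.pvalue_by_genotype)
            target.delta_psi_by_genotype.update(rec.delta_psi_by_genotype)
    return EventTable(records=list(merged.values()), sample_labels=sample_labels)


def to_one_based_closed(start: int, end: int) -> tuple[int, int]:
    """0-based half-open → 1-based closed interval."""
    return start + 1, end


def from_one_based_closed(start: int, end: int) -> tuple[int, int]:
    """1-based closed → 0-based half-open interval."""
    return start - 1, end
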