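"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, each a pure function of its spec (seed included):

* :func:`simulate_splice_table` — multi-genotype cassette-exon tables with a
  known fraction of planted, direction-consistent mis-splicing. Junction
  reads are binomial around a latent PSI with logit-normal replicate noise;
  per-event significance is a two-sample t-test on empirical-logit PSI with
  Benjamini–Hochberg FDR (standing in for the upstream caller's likelihood
  test: the table schema is identical either way and downstream filtering is
  what is under test).
* :func:`simulate_trajectory` — piecewise-constant-speed swim tracks with
  active/pause segments, reflecting tank walls, and per-frame ground-truth
  mode labels.
* :func:`simulate_gene_sequences` — multi-exon genes on both strands whose
  background sequence is scrubbed of the analysis motifs, with motifs then
  planted at controlled per-window densities around a designated cassette
  exon.

Defaults mirror the study conditions: three biological replicates per
genotype, ten tracking frames per second, an 18×25.4×7.6 cm novel tank,
250-nt intronic windows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import (
    EventTable,
    GeneModel,
    SpliceEvent,
    TankGeometry,
    TrajectoryFile,
    Transcript,
)
from .motif_enrichment import (
    REGION_NAMES,
    MotifSet,
    YGCY_CANONICAL,
    reverse_complement,
)
from .stats_core import bh_fdr

__all__ = [
    "SpliceSimSpec",
    "TrajectorySimSpec",
    "SequenceSimSpec",
    "SpliceSimResult",
    "TrajectorySimResult",
    "SequenceSimResult",
    "MotifStudyResult",
    "simulate_motif_study",
    "simulate_splice_table",
    "simulate_trajectory",
    "simulate_gene_sequences",
]


# ---------------------------------------------------------------------------
# splicing tables


@dataclass(frozen=True)
class SpliceSimSpec:
    """Conditions for one synthetic multi-genotype splicing experiment.

    ``genotypes`` maps genotype label → replicate count and must include
    ``wt_label``. ``frac_regulated`` of events are planted as mis-spliced per
    mutant genotype with |ΔPSI| ~ Normal(delta_mean, delta_sd) in a random
    direction; ``read_depth`` is the mean junction-read total per event and
    replicate. ``rep_noise_sd`` is logit-scale biological replicate noise.
    """

    n_events: int = 500
    genotypes: Mapping[str, int] = field(
        default_factory=lambda: {"WT": 3, "mut": 3}
    )
    frac_regulated: float = 0.1
    delta_mean: float = 0.4
    delta_sd: float = 0.1
    delta_mean_by_genotype: Mapping[str, float] | None = None
    read_depth: float = 100.0
    rep_noise_sd: float = 0.3
    wt_label: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_regulated <= 1.0:
            raise ValueError("frac_regulated must lie in [0, 1]")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.wt_label not in self.genotypes:
            raise ValueError(f"genotypes must include {self.wt_label!r}")
        if any(n < 2 for n in self.genotypes.values()):
            raise ValueError("every genotype needs >= 2 replicates")


@dataclass
class SpliceSimResult:
    table: EventTable
    truth: pd.DataFrame  # event_id, genotype, planted, delta_true


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_splice_table(spec: SpliceSimSpec) -> SpliceSimResult:
    """Generate an EventTable with planted mis-splicing and ground truth.

    Baseline PSI is uniform on [0.05, 0.95]; a planted (event, genotype)
    shifts the latent PSI by its drawn delta, and baselines for which a drawn
    delta cannot fit inside [0, 1] are resampled rather than clipping the
    planted effect. Observed PSI per replicate is binomial inclusion reads
    over a Poisson junction total. Per-genotype p-values (t-test on empirical
    logits vs WT) are BH-corrected across events within each genotype.
    """
    rng = np.random.default_rng(spec.seed)
    mutants = [g for g in spec.genotypes if g != spec.wt_label]

    n = spec.n_events
    planted = {
        g: np.zeros(n, dtype=bool) for g in mutants
    }
    n_planted = int(round(spec.frac_regulated * n))
    for g in mutants:
        if n_planted:
            planted[g][rng.choice(n, size=n_planted, replace=False)] = True

    # one direction per event, shared by all genotypes: mis-splicing is
    # direction-consistent across mutant lines (the exon's regulatory sign)
    shared_direction = rng.choice([-1.0, 1.0], size=n)
    direction = {g: shared_direction for g in mutants}
    per_genotype_mean = spec.delta_mean_by_genotype or {}
    delta_mag = {
        g: np.abs(
            rng.normal(per_genotype_mean.get(g, spec.delta_mean), spec.delta_sd, size=n)
        )
        for g in mutants
    }

    baseline = np.empty(n)
    for i in range(n):
        for _ in range(1000):
            b = rng.uniform(0.05, 0.95)
            ok = True
            for g in mutants:
                if planted[g][i]:
                    target = b + direction[g][i] * delta_mag[g][i]
                    if not 0.0 <= target <= 1.0:
                        ok = False
                        break
            if ok:
                baseline[i] = b
                break
        else:
            raise ValueError(
                f"event {i}: planted delta cannot fit in [0, 1] for any baseline"
            )

    # latent per-replicate PSI -> junction counts -> observed PSI
    obs_psi: dict[str, np.ndarray] = {}
    logit_psi: dict[str, np.ndarray] = {}
    for g, n_rep in spec.genotypes.items():
        target = baseline.copy()
        if g != spec.wt_label:
            shift = planted[g] * direction[g] * delta_mag[g]
            target = np.clip(baseline + shift, 1e-4, 1 - 1e-4)
        latent = _expit(
            _logit(np.clip(target, 1e-4, 1 - 1e-4))[:, None]
            + rng.normal(0.0, spec.rep_noise_sd, size=(n, n_rep))
        )
        totals = np.maximum(rng.poisson(spec.read_depth, size=(n, n_rep)), 1)
        inc = rng.binomial(totals, latent)
        obs_psi[g] = inc / totals
        logit_psi[g] = np.log((inc + 0.5) / (totals - inc + 0.5))

    fdr: dict[str, np.ndarray] = {}
    pvals: dict[str, np.ndarray] = {}
    dpsi: dict[str, np.ndarray] = {}
    for g in mutants:
        t, p = sps.ttest_ind(logit_psi[g], logit_psi[spec.wt_label], axis=1)
        p = np.where(np.isnan(p), 1.0, p)
        pvals[g] = p
        fdr[g] = bh_fdr(p)
        dpsi[g] = obs_psi[g].mean(axis=1) - obs_psi[spec.wt_label].mean(axis=1)

    sample_labels = {
        g: [f"{g}_r{r + 1}" for r in range(n_rep)]
        for g, n_rep in spec.genotypes.items()
    }
    records: list[SpliceEvent] = []
    for i in range(n):
        # synthetic but well-formed SE coordinates on one chromosome
        anchor = 10_000 + 2_000 * i
        psi = {}
        for g in spec.genotypes:
            for r, rep in enumerate(sample_labels[g]):
                psi[rep] = float(obs_psi[g][i, r])
        records.append(
            SpliceEvent(
                event_id=f"SE:{i}",
                event_type="SE",
                gene_id=f"gene{i}",
                chrom="chrS",
                strand="+",
                exon_start=anchor + 500,
                exon_end=anchor + 650,
                upstream_start=anchor,
                upstream_end=anchor + 150,
                downstream_start=anchor + 1_150,
                downstream_end=anchor + 1_300,
                psi_by_replicate=psi,
                fdr_by_genotype={g: float(fdr[g][i]) for g in mutants},
                pvalue_by_genotype={g: float(pvals[g][i]) for g in mutants},
                delta_psi_by_genotype={g: float(dpsi[g][i]) for g in mutants},
            )
        )
    table = EventTable(records=records, sample_labels=sample_labels)
    truth = pd.DataFrame(
        [
            {
                "event_id": f"SE:{i}",
                "genotype": g,
                "planted": bool(planted[g][i]),
                "delta_true": float(direction[g][i] * delta_mag[g][i])
                if planted[g][i]
                else 0.0,
            }
            for g in mutants
            for i in range(n)
        ]
    )
    return SpliceSimResult(table=table, truth=truth)


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class TrajectorySimSpec:
    """Piecewise-constant-speed swim plan: (duration_s, mode, speed_cm_s)."""

    segments: Sequence[tuple[float, str, float]]
    fps: float = 10.0
    tank: TankGeometry = field(default_factory=TankGeometry)
    jitter_sd: float = 0.0
    turn_sd: float = 0.3  # heading noise, radians per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("at least one segment required")
        for dur, mode, speed in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if mode == "pause":
                if speed >= 1.5:
                    raise ValueError("pause-mode speed must be < 1.5 cm/s")
            elif mode == "active":
                if speed < 1.5:
                    raise ValueError("active-mode speed must be >= 1.5 cm/s")
            else:
                raise ValueError(f"unknown mode {mode!r}")


@dataclass
class TrajectorySimResult:
    trajectory: TrajectoryFile
    frame_mode: np.ndarray  # per-frame "active"/"pause" ground truth
    segment_table: pd.DataFrame


def simulate_trajectory(spec: TrajectorySimSpec) -> TrajectorySimResult:
    """Integrate the segment plan in the tank's side-view (length × depth) plane.

    A persistent heading with Gaussian turning noise carries the fish at each
    segment's speed; walls reflect. Positional jitter is added after
    integration and never changes the ground-truth mode labels.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.fps
    lx, ly = spec.tank.length_cm, spec.tank.depth_cm
    for _, _, speed in spec.segments:
        if speed * dt >= min(lx, ly):
            raise ValueError(
                f"speed {speed} cm/s cannot be realized inside the tank at "
                f"{spec.fps} fps"
            )
    pos = np.array([lx / 2.0, ly / 2.0])
    heading = rng.uniform(0, 2 * math.pi)
    xs, ys, modes, seg_rows = [], [], [], []
    frame = 0
    for seg_idx, (dur, mode, speed) in enumerate(spec.segments):
        n_frames = int(round(dur * spec.fps))
        seg_rows.append(
            {
                "segment": seg_idx,
                "mode": mode,
                "speed_cm_s": speed,
                "start_frame": frame,
                "end_frame": frame + n_frames,
            }
        )
        for _ in range(n_frames):
            xs.append(pos[0])
            ys.append(pos[1])
            modes.append(mode)
            frame += 1
            heading += rng.normal(0.0, spec.turn_sd)
            step = speed * dt
            # reflect the heading *before* moving so every frame's
            # displacement is exactly speed·dt (no wall-shortened steps)
            direction = np.array([math.cos(heading), math.sin(heading)])
            if not 0 <= pos[0] + step * direction[0] <= lx:
                heading = math.pi - heading
                direction[0] = -direction[0]
            if not 0 <= pos[1] + step * direction[1] <= ly:
                heading = -heading
                direction[1] = -direction[1]
            pos = pos + step * direction
    x = np.asarray(xs)
    y = np.asarray(ys)
    if spec.jitter_sd > 0:
        x = np.clip(x + rng.normal(0, spec.jitter_sd, x.size), 0, lx)
        y = np.clip(y + rng.normal(0, spec.jitter_sd, y.size), 0, ly)
    traj = TrajectoryFile(
        frames=np.arange(len(x)),
        x_cm=x,
        y_cm=y,
        fps=spec.fps,
        tank=spec.tank,
    )
    return TrajectorySimResult(
        trajectory=traj,
        frame_mode=np.asarray(modes),
        segment_table=pd.DataFrame(seg_rows),
    )


# ---------------------------------------------------------------------------
# gene sequences with planted motifs


@dataclass(frozen=True)
class SequenceSimSpec:
    """Gene-structure and motif-planting plan for window-extraction tests.

    ``motif_density`` gives planted motif occurrences per 100 nt, either one
    value for every window or a mapping window-name → density. Intron lengths
    must be >= 60 so truncation of 250-nt windows stays predictable.
    """

    n_genes: int = 50
    exon_count_range: tuple[int, int] = (3, 5)
    exon_length_range: tuple[int, int] = (90, 180)
    intron_length_range: tuple[int, int] = (400, 700)
    motif_density: float | Mapping[str, float] = 0.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motifs: MotifSet = YGCY_CANONICAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exon_count_range[0] < 3:
            raise ValueError("need >= 3 exons for a flanked cassette")
        if self.intron_length_range[0] < 60:
            raise ValueError("intron lengths must be >= 60")
        dens = self.density_map()
        if any(d < 0 for d in dens.values()):
            raise ValueError("motif densities must be >= 0")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")

    def density_map(self) -> dict[str, float]:
        if isinstance(self.motif_density, Mapping):
            unknown = set(self.motif_density) - set(REGION_NAMES)
            if unknown:
                raise ValueError(f"unknown window names {sorted(unknown)}")
            return {r: float(self.motif_density.get(r, 0.0)) for r in REGION_NAMES}
        return {r: float(self.motif_density) for r in REGION_NAMES}


@dataclass
class SequenceSimResult:
    fasta_text: str
    genome: dict[str, str]
    models: dict[str, GeneModel]
    cassette_index: dict[str, int]
    planted: dict[str, dict[str, list[tuple[int, str]]]]  # gene -> window -> hits

    def planted_json(self) -> str:
        return json.dumps(self.planted, sort_keys=True)


@dataclass
class MotifStudyResult:
    """A ready-to-analyze motif-enrichment study over synthetic exon classes."""

    regulated_sets: dict[str, list]  # set label -> RegulationCalls
    nonregulated: list[SpliceEvent]
    events_by_id: dict[str, SpliceEvent]
    models: dict[str, GeneModel]
    genome: dict[str, str]
    cassette_index: dict[str, int]


def simulate_motif_study(
    n_per_class: int,
    density_activated: float | Mapping[str, float],
    density_repressed: float | Mapping[str, float],
    density_nonregulated: float | Mapping[str, float],
    seed: int = 0,
    set_label: str = "double_mutant",
    genotype: str = "mut",
    **seq_kwargs,
) -> MotifStudyResult:
    """Three exon classes (Mbnl-activated, Mbnl-repressed, non-regulated) drawn
    from one background spec but with class-specific motif planting.

    Gene and contig identifiers are prefixed per class so the three draws
    coexist in one genome; each gene contributes one cassette-exon event with
    the matching regulation call.
    """
    from .splice_events import MBNL_ACTIVATED, MBNL_REPRESSED, RegulationCall

    class_plan = [
        ("act", MBNL_ACTIVATED, density_activated),
        ("rep", MBNL_REPRESSED, density_repressed),
        ("non", None, density_nonregulated),
    ]
    models: dict[str, GeneModel] = {}
    genome: dict[str, str] = {}
    cassette_index: dict[str, int] = {}
    events_by_id: dict[str, SpliceEvent] = {}
    calls: list[RegulationCall] = []
    nonregulated: list[SpliceEvent] = []
    for offset, (prefix, regulation, density) in enumerate(class_plan):
        sim = simulate_gene_sequences(
            SequenceSimSpec(
                n_genes=n_per_class,
                motif_density=density,
                seed=seed * 3 + offset,
                **seq_kwargs,
            )
        )
        for gid, model in sim.models.items():
            new_id = f"{prefix}_{gid}"
            tx = model.transcript()
            renamed = GeneModel(
                gene_id=new_id,
                chrom=new_id,
                strand=model.strand,
                transcripts={f"{new_id}.t1": Transcript(f"{new_id}.t1", tx.exons)},
            )
            models[new_id] = renamed
            genome[new_id] = sim.genome[gid]
            idx = sim.cassette_index[gid]
            cassette_index[new_id] = idx
            cas = tx.exons[idx]
            up = tx.exons[idx - 1]
            down = tx.exons[idx + 1]
            # flanks in genomic (left-to-right) order, as in event tables
            left, right = (up, down) if model.strand == "+" else (down, up)
            event = SpliceEvent(
                event_id=f"SE:{new_id}",
                event_type="SE",
                gene_id=new_id,
                chrom=new_id,
                strand=model.strand,
                exon_start=cas[0],
                exon_end=cas[1],
                upstream_start=left[0],
                upstream_end=left[1],
                downstream_start=right[0],
                downstream_end=right[1],
            )
            events_by_id[event.event_id] = event
            if regulation is None:
                nonregulated.append(event)
            else:
                calls.append(
                    RegulationCall(
                        event_id=event.event_id,
                        genotype=genotype,
                        regulation=regulation,
                    )
                )
    return MotifStudyResult(
        regulated_sets={set_label: calls},
        nonregulated=nonregulated,
        events_by_id=events_by_id,
        models=models,
        genome=genome,
        cassette_index=cassette_index,
    )


_BASES = np.array(list("ACGT"))


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _scrub_motifs(seq: np.ndarray, banned: set[str], rng: np.random.Generator) -> None:
    """Mutate single bases until no banned 4-mer occurs (in place)."""
    banned_codes = np.array(
        sorted(
            sum(_BASE_CODE[b] * 4 ** (3 - i) for i, b in enumerate(word))
            for word in banned
        )
    )
    for _ in range(200):
        codes = np.array([_BASE_CODE[b] for b in seq])
        if codes.size < 4:
            return
        words = (
            codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
        )
        hits = np.flatnonzero(np.isin(words, banned_codes))
        if hits.size == 0:
            return
        targets = hits + rng.integers(0, 4, size=hits.size)
        for j in np.unique(targets):
            choices = [b for b in "ACGT" if b != seq[j]]
            seq[j] = choices[int(rng.integers(0, 3))]
    raise RuntimeError("failed to scrub banned motifs from background")


def simulate_gene_sequences(spec: SequenceSimSpec) -> SequenceSimResult:
    """Generate genes (one per contig, random strand) with planted motifs.

    Background bases are i.i.d. at ``base_composition`` with every
    analysis-set motif occurrence scrubbed (on the coding-strand reading), so
    a window's motif count equals its planted count exactly. Motifs are then
    planted without overlap at the per-window densities; planted counts are
    Poisson around density × window-length / 100.
    """
    rng = np.random.default_rng(spec.seed)
    density = spec.density_map()
    genome: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    cassette_index: dict[str, int] = {}
    planted: dict[str, dict[str, list[tuple[int, str]]]] = {}
    motif_list = sorted(spec.motifs.motifs)
    banned = set(spec.motifs.motifs) | {
        reverse_complement(m) for m in spec.motifs.motifs
    }

    from .motif_enrichment import extract_windows  # local to avoid cycle at import

    for g in range(spec.n_genes):
        gene_id = f"gene{g + 1}"
        chrom = gene_id
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(spec.exon_count_range[0], spec.exon_count_range[1] + 1))
        exon_lens = rng.integers(
            spec.exon_length_range[0], spec.exon_length_range[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            spec.intron_length_range[0], spec.intron_length_range[1] + 1,
            size=n_exons - 1,
        )
        flank = 50
        blocks: list[tuple[int, int]] = []
        cursor = flank
        for k in range(n_exons):
            blocks.append((cursor, cursor + int(exon_lens[k])))
            cursor += int(exon_lens[k])
            if k < n_exons - 1:
                cursor += int(intron_lens[k])
        total_len = cursor + flank
        seq = rng.choice(_BASES, size=total_len, p=spec.base_composition)
        _scrub_motifs(seq, banned, rng)

        tx = Transcript(
            f"{gene_id}.t1",
            blocks if strand == "+" else blocks[::-1],
        )
        model = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand, transcripts={tx.transcript_id: tx}
        )
        cas_idx = len(blocks) // 2
        genome[chrom] = "".join(seq)
        windows = extract_windows(model, cas_idx, genome)
        gene_hits: dict[str, list[tuple[int, str]]] = {}
        for name, win in windows.items():
            d = density[name]
            wlen = win.end - win.start
            n_plant = int(rng.poisson(d * wlen / 100.0)) if d > 0 else 0
            hits: list[tuple[int, str]] = []
            occupied: set[int] = set()
            tries = 0
            while len(hits) < n_plant:
                tries += 1
                if tries > 200 * max(n_plant, 1):
                    raise ValueError(
                        f"density {d}/100nt too high to place without overlap "
                        f"in window {name!r} ({wlen} nt)"
                    )
                pos = int(rng.integers(win.start, win.end - 3))
                if any(p in occupied for p in range(pos - 3, pos + 4)):
                    continue
                motif = motif_list[int(rng.integers(0, len(motif_list)))]
                ins = motif if strand == "+" else reverse_complement(motif)
                seq[pos : pos + 4] = list(ins)
                occupied.update(range(pos, pos + 4))
                hits.append((pos, motif))
            gene_hits[name] = sorted(hits)
        genome[chrom] = "".join(seq)
        models[gene_id] = model
        cassette_index[gene_id] = cas_idx
        planted[gene_id] = gene_hits

    fasta = "".join(f">{c}\n{genome[c]}\n" for c in genome)
    return SequenceSimResult(
        fasta_text=fasta,
        genome=genome,
        models=models,
        cassette_index=cassette_index,
        planted=planted,
    )
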