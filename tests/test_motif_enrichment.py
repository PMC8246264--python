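"""Window extraction, motif counting, control k-mers and enrichment cells."""

import itertools
from collections import Counter

import numpy as np
import pytest

from splicekit.io_formats import GeneModel, Transcript
from splicekit.motif_enrichment import (
    PAPER_PRINTED,
    REGION_NAMES,
    YGCY_CANONICAL,
    MotifSet,
    RegionWindow,
    control_kmers,
    count_motifs,
    enrichment_heatmap,
    enrichment_ratio,
    extract_windows,
    heatmap_frame,
    kmer_spectrum,
    reverse_complement,
)
from splicekit.synthetic_data import simulate_motif_study


def brute_force_count(seq: str, motifs: set[str]) -> int:
    """Independent oracle: compare every offset's slice against every motif."""
    hits = 0
    for i in range(len(seq)):
        for m in motifs:
            if seq[i : i + len(m)] == m and "N" not in seq[i : i + len(m)]:
                hits += 1
    return hits


def make_gene(strand: str, exons: list[tuple[int, int]], gene_id="g") -> GeneModel:
    ordered = exons if strand == "+" else exons[::-1]
    tx = Transcript("t1", ordered)
    return GeneModel(gene_id=gene_id, chrom="c", strand=strand, transcripts={"t1": tx})


class TestCountMotifs:
    def test_overlapping_occurrences(self):
        assert count_motifs("TGCTGCT", MotifSet("m", frozenset({"TGCT"}))) == 2

    def test_n_positions_never_match(self):
        assert count_motifs("TGNT", MotifSet("m", frozenset({"TGNT"}))) == 0

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            length = int(rng.integers(4, 200))
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=length))
            assert count_motifs(seq, YGCY_CANONICAL) == brute_force_count(
                seq, set(YGCY_CANONICAL.motifs)
            )

    def test_concatenation_junction_effects_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s1 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 80))))
            s2 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 80))))
            joint = count_motifs(s1 + s2, YGCY_CANONICAL)
            parts = count_motifs(s1, YGCY_CANONICAL) + count_motifs(s2, YGCY_CANONICAL)
            assert parts - 3 <= joint <= parts + 3

    def test_kmer_spectrum_consistent_with_count(self):
        rng = np.random.default_rng(2)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=60)) for _ in range(10)
        ]
        spectrum = kmer_spectrum(seqs)
        for motif in YGCY_CANONICAL.motifs:
            single = MotifSet("s", frozenset({motif}))
            assert spectrum[motif] == sum(count_motifs(s, single) for s in seqs)


class TestControlKmers:
    @staticmethod
    def _oracle(motif):
        at = sum(b in "AT" for b in motif)
        cg = sum(motif[i : i + 2] == "CG" for i in range(3))
        out = set()
        for word in map("".join, itertools.product("ACGT", repeat=4)):
            if (
                sum(b in "AT" for b in word) == at
                and sum(word[i : i + 2] == "CG" for i in range(3)) == cg
            ):
                out.add(word)
        return out

    @pytest.mark.parametrize("preset", [YGCY_CANONICAL, PAPER_PRINTED])
    def test_matches_exhaustive_enumeration(self, preset):
        for motif in preset.motifs:
            expected = self._oracle(motif) - set(preset.motifs) - {motif}
            assert control_kmers(motif, exclude=preset) == expected

    def test_never_contains_query(self):
        for motif in YGCY_CANONICAL.motifs:
            assert motif not in control_kmers(motif)

    def test_defining_property_holds_for_every_member(self):
        motif = "TGCT"
        at = sum(b in "AT" for b in motif)
        cg = sum(motif[i : i + 2] == "CG" for i in range(3))
        for kmer in control_kmers(motif, exclude=YGCY_CANONICAL):
            assert sum(b in "AT" for b in kmer) == at
            assert sum(kmer[i : i + 2] == "CG" for i in range(3)) == cg


class TestExtractWindows:
    GENOME = None  # built per test

    def _genome(self, length=6000, seed=0):
        rng = np.random.default_rng(seed)
        return {"c": "".join(rng.choice(list("ACGT"), size=length))}

    def test_long_introns_give_full_windows(self):
        # introns of 1000 nt on both sides
        gene = make_gene("+", [(100, 300), (1300, 1500), (2500, 2700)])
        wins = extract_windows(gene, 1, self._genome())
        assert set(wins) == set(REGION_NAMES)
        for name in REGION_NAMES:
            if name != "cassette_exon":
                assert len(wins[name].sequence) == 250
        assert len(wins["cassette_exon"].sequence) == 200

    def test_short_intron_truncated_at_midpoint(self):
        # 300-nt introns: each claiming window truncated to 150
        gene = make_gene("+", [(100, 300), (600, 800), (1100, 1300)])
        wins = extract_windows(gene, 1, self._genome())
        assert len(wins["intron_5prime_of_cassette"].sequence) == 150
        assert len(wins["intron_3prime_of_upstream_constitutive"].sequence) == 150
        assert len(wins["intron_3prime_of_cassette"].sequence) == 150
        assert len(wins["intron_5prime_of_downstream_constitutive"].sequence) == 150

    def test_windows_abut_the_correct_exons(self):
        genome = self._genome()
        gene = make_gene("+", [(100, 300), (1300, 1500), (2500, 2700)])
        wins = extract_windows(gene, 1, genome)
        seq = genome["c"]
        assert wins["intron_5prime_of_cassette"].sequence == seq[1050:1300]
        assert wins["intron_3prime_of_cassette"].sequence == seq[1500:1750]
        assert wins["intron_3prime_of_upstream_constitutive"].sequence == seq[300:550]
        assert wins["intron_5prime_of_downstream_constitutive"].sequence == seq[2250:2500]

    def test_minus_strand_is_reverse_complement_of_mirrored_gene(self):
        """Strand-flip oracle: reverse-complementing the genome and mirroring
        the exon coordinates must reproduce the plus-strand windows."""
        genome = self._genome(length=4000, seed=3)
        exons = [(100, 300), (700, 900), (1400, 1600)]
        plus = make_gene("+", exons)
        plus_wins = extract_windows(plus, 1, genome)

        L = len(genome["c"])
        mirrored_genome = {"c": reverse_complement(genome["c"])}
        mirrored_exons = sorted((L - e, L - s) for s, e in exons)
        minus = make_gene("-", mirrored_exons)
        minus_wins = extract_windows(minus, 1, mirrored_genome)
        for name in REGION_NAMES:
            assert minus_wins[name].sequence == plus_wins[name].sequence, name

    def test_first_or_last_exon_rejected(self):
        gene = make_gene("+", [(100, 300), (700, 900), (1400, 1600)])
        with pytest.raises(ValueError, match="flanking"):
            extract_windows(gene, 0, self._genome())
        with pytest.raises(ValueError, match="flanking"):
            extract_windows(gene, 2, self._genome())


class TestEnrichmentRatio:
    def test_equal_motif_and_control_density_gives_unity(self):
        spectrum = Counter()
        for motif in YGCY_CANONICAL.motifs:
            spectrum[motif] = 10
        for kmer in control_kmers("TGCT", exclude=YGCY_CANONICAL) | control_kmers(
            "CGCC", exclude=YGCY_CANONICAL
        ):
            spectrum[kmer] = 10
        for motif in ("TGCC", "CGCT"):
            for kmer in control_kmers(motif, exclude=YGCY_CANONICAL):
                spectrum[kmer] = 10
        ratio = enrichment_ratio(["A" * 500], YGCY_CANONICAL, _spectrum=spectrum)
        assert ratio == pytest.approx(1.0)

    def test_duplicating_windows_leaves_ratio_invariant(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGT"), size=250)) for _ in range(20)]
        once = enrichment_ratio(windows, YGCY_CANONICAL)
        twice = enrichment_ratio(windows * 2, YGCY_CANONICAL)
        # pooled counts and pooled length both double; pseudocount makes the
        # agreement approximate, converging as counts grow
        assert twice == pytest.approx(once, rel=0.05)

    def test_planted_excess_gives_ratio_above_one(self):
        rng = np.random.default_rng(6)
        base = list("".join(rng.choice(list("ACGT"), size=250)))
        for pos in range(0, 250 - 4, 10):
            base[pos : pos + 4] = "TGCT"
        assert enrichment_ratio(["".join(base)], YGCY_CANONICAL) > 1.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio([""], YGCY_CANONICAL)


@pytest.fixture(scope="module")
def study():
    return simulate_motif_study(
        n_per_class=40,
        density_activated={"intron_3prime_of_cassette": 4.0},
        density_repressed={"intron_5prime_of_cassette": 4.0, "cassette_exon": 4.0},
        density_nonregulated=0.0,
        seed=11,
    )


class TestHeatmap:
    def test_directional_planting_lights_expected_cells(self, study):
        cells = enrichment_heatmap(
            study.regulated_sets,
            study.nonregulated,
            study.events_by_id,
            study.models,
            study.genome,
            cassette_index=study.cassette_index,
        )
        frame = heatmap_frame(cells).set_index(["regulation_class", "region"])
        hot = {
            ("mbnl_activated", "intron_3prime_of_cassette"),
            ("mbnl_repressed", "intron_5prime_of_cassette"),
            ("mbnl_repressed", "cassette_exon"),
        }
        for idx, row in frame.iterrows():
            if idx in hot:
                assert row["log2_ratio"] > 1.0, idx
            else:
                assert abs(row["log2_ratio"]) < 0.3, idx

    def test_antisymmetric_under_set_swap(self, study):
        kwargs = dict(
            events_by_id=study.events_by_id,
            gene_models=study.models,
            genome=study.genome,
            cassette_index=study.cassette_index,
        )
        forward = enrichment_heatmap(
            study.regulated_sets, study.nonregulated, **kwargs
        )
        # regulated events become the non-regulated pool and vice versa,
        # class by class
        from splicekit.splice_events import RegulationCall

        for cls in ("mbnl_activated", "mbnl_repressed"):
            reg_events = [
                study.events_by_id[c.event_id]
                for c in study.regulated_sets["double_mutant"]
                if c.regulation == cls
            ]
            swapped = enrichment_heatmap(
                {
                    "swap": [
                        RegulationCall(e.event_id, "mut", cls)
                        for e in study.nonregulated
                    ]
                },
                reg_events,
                **kwargs,
            )
            fwd = {
                (c.region): c.log2_ratio
                for c in forward
                if c.regulation_class == cls
            }
            back = {c.region: c.log2_ratio for c in swapped if c.regulation_class == cls}
            for region in REGION_NAMES:
                assert back[region] == pytest.approx(-fwd[region], abs=1e-12)

    def test_empty_nonregulated_rejected(self, study):
        with pytest.raises(ValueError):
            enrichment_heatmap(
                study.regulated_sets,
                [],
                study.events_by_id,
                study.models,
                study.genome,
            )
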