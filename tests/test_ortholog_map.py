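"""Three-criterion exon orthology and cross-species ΔPSI concordance."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from splicekit.io_formats import Transcript
from splicekit.ortholog_map import (
    KARLIN_K,
    KARLIN_LAMBDA,
    GenePair,
    call_orthologous_exons,
    cross_species_concordance,
    exon_index_match,
    gene_conservation,
    smith_waterman_score,
    translated_exon_evalue,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestGeneConservation:
    def test_identical_sequences_are_100(self):
        assert gene_conservation("MKVLAW", "MKVLAW") == pytest.approx(100.0)

    def test_hand_alignment_oracle(self):
        # MKV/MKI align without gaps: 2 identities over 3 columns
        assert gene_conservation("MKV", "MKI") == pytest.approx(200.0 / 3.0)

    def test_symmetric(self):
        a, b = "MKVLAWCHEDRAK", "MKILAWHEDRK"
        assert gene_conservation(a, b) == pytest.approx(gene_conservation(b, a))

    def test_x_never_matches(self):
        assert gene_conservation("MXK", "MXK") == pytest.approx(200.0 / 3.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gene_conservation("", "MK")


class TestExonIndexMatch:
    def test_same_index_different_exon_counts(self):
        tx_a = Transcript("a1", [(i * 100, i * 100 + 50) for i in range(10)])
        tx_b = Transcript("b1", [(i * 100, i * 100 + 60) for i in range(8)])
        assert exon_index_match(tx_a.exons[4], [tx_a], tx_b.exons[4], [tx_b])

    def test_different_index_no_isoforms_false(self):
        tx_a = Transcript("a1", [(i * 100, i * 100 + 50) for i in range(10)])
        tx_b = Transcript("b1", [(i * 100, i * 100 + 60) for i in range(10)])
        assert not exon_index_match(tx_a.exons[4], [tx_a], tx_b.exons[5], [tx_b])

    def test_existential_over_isoform_pairs(self):
        # exon sits at 1-based index 5 in one isoform, index 4 in another;
        # the partner sits at index 4, so the second isoform matches
        exon = (1000, 1050)
        iso1 = Transcript("a1", [(i * 100, i * 100 + 50) for i in range(4)] + [exon])
        iso2 = Transcript("a2", [(i * 100, i * 100 + 50) for i in range(3)] + [exon])
        partner = (2000, 2060)
        tx_b = Transcript("b1", [(i * 100, i * 100 + 60) for i in range(3)] + [partner])
        assert exon_index_match(exon, [iso1, iso2], partner, [tx_b])

    def test_unknown_exon_rejected(self):
        tx = Transcript("a1", [(0, 50)])
        with pytest.raises(ValueError):
            exon_index_match((999, 1000), [tx], (0, 50), [tx])


CODING_120 = (
    "ATGGACGAGCTGTACAAGGGCAGCGGCGAGGAGCTGTTCACCGGGGTGGTGCCCATCCTG"
    "GTCGAGCTGGACGGCGACGTAAACGGCCACAAGTTCAGCGTGTCCGGCGAGGGCGAGGGC"
)


class TestTranslatedEvalue:
    def test_identical_coding_exons_highly_significant(self):
        assert translated_exon_evalue(CODING_120, CODING_120) < 1e-6

    def test_closed_form_matches_gapless_identity_oracle(self):
        # for identical peptides the SW score is the sum of diagonal
        # BLOSUM62 entries of the frame-0 translation
        from Bio.Seq import Seq

        pep = str(Seq(CODING_120).translate())
        diag = sum(float(BLOSUM62[aa, aa]) for aa in pep)
        assert smith_waterman_score(pep, pep) == pytest.approx(diag)
        # search space: total translated residues over the three frames
        m = n = sum((len(CODING_120) - f) // 3 for f in range(3))
        expected = KARLIN_K * m * n * math.exp(-KARLIN_LAMBDA * diag)
        observed = translated_exon_evalue(CODING_120, CODING_120)
        assert observed == pytest.approx(expected, rel=1e-12)

    def test_evalue_monotone_decreasing_in_score(self):
        scores = np.linspace(10, 60, 6)
        evalues = [
            KARLIN_K * 40 * 40 * math.exp(-KARLIN_LAMBDA * s) for s in scores
        ]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))

    def test_random_pairs_rarely_significant(self):
        rng = np.random.default_rng(42)
        n_sig = 0
        trials = 100
        for _ in range(trials):
            a = "".join(rng.choice(list("ACGT"), size=120))
            b = "".join(rng.choice(list("ACGT"), size=120))
            if translated_exon_evalue(a, b) < 0.05:
                n_sig += 1
        assert n_sig <= trials * 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translated_exon_evalue("ATGATG", CODING_120)


def make_pair(identity_high=True):
    protein = "MDELYKGSGEELFTGVVPILVELDGDVNGHKFSVSGEGEG"
    other = protein if identity_high else "MW" * 20
    tx_a = Transcript("a1", [(0, 100), (200, 320), (400, 500)])
    tx_b = Transcript("b1", [(0, 100), (200, 320), (400, 500)])
    return GenePair(
        gene_a_id="zfA",
        gene_b_id="hsB",
        protein_a=protein,
        protein_b=other,
        transcripts_a=[tx_a],
        transcripts_b=[tx_b],
    )


class TestCallOrthologousExons:
    def test_all_three_criteria_met(self):
        call = call_orthologous_exons(
            make_pair(), (200, 320), CODING_120, (200, 320), CODING_120
        )
        assert call.is_ortholog
        assert call.gene_identity_pct == pytest.approx(100.0)
        assert call.exon_index_match
        assert call.evalue < 1e-6

    def test_low_identity_fails_despite_other_criteria(self):
        call = call_orthologous_exons(
            make_pair(identity_high=False), (200, 320), CODING_120, (200, 320), CODING_120
        )
        assert not call.is_ortholog
        assert call.gene_identity_pct < 75.0
        # the other criterion values are still reported
        assert call.exon_index_match
        assert call.evalue < 1e-6

    def test_evalue_bound_is_strict(self):
        # set the threshold to the pair's own e-value: strict < must reject
        probe = call_orthologous_exons(
            make_pair(), (200, 320), CODING_120, (200, 320), "ACGT" * 30
        )
        call = call_orthologous_exons(
            make_pair(),
            (200, 320),
            CODING_120,
            (200, 320),
            "ACGT" * 30,
            evalue_threshold=probe.evalue,
        )
        assert not call.is_ortholog

    def test_symmetric_in_species(self):
        a = call_orthologous_exons(
            make_pair(), (200, 320), CODING_120, (200, 320), CODING_120
        )
        pair = make_pair()
        swapped = GenePair(
            gene_a_id=pair.gene_b_id,
            gene_b_id=pair.gene_a_id,
            protein_a=pair.protein_b,
            protein_b=pair.protein_a,
            transcripts_a=pair.transcripts_b,
            transcripts_b=pair.transcripts_a,
        )
        b = call_orthologous_exons(
            swapped, (200, 320), CODING_120, (200, 320), CODING_120
        )
        assert a.is_ortholog == b.is_ortholog
        assert a.gene_identity_pct == pytest.approx(b.gene_identity_pct)

    def test_disabling_all_criteria_accepts_everything(self):
        call = call_orthologous_exons(
            make_pair(identity_high=False),
            (200, 320),
            "".join(np.random.default_rng(0).choice(list("ACGT"), 120)),
            (400, 500),
            "".join(np.random.default_rng(1).choice(list("ACGT"), 120)),
            require_identity=False,
            require_index=False,
            require_evalue=False,
        )
        assert call.is_ortholog


class TestConcordance:
    def test_rank_concordant_pairs(self):
        pairs = [{"dpsi_a": d, "dpsi_b": d * 2} for d in (0.1, 0.3, -0.2, 0.5)]
        rho, _ = cross_species_concordance(pairs)
        assert rho == pytest.approx(1.0)

    def test_rank_reversed_pairs(self):
        pairs = [{"dpsi_a": d, "dpsi_b": -d} for d in (0.1, 0.3, -0.2, 0.5)]
        rho, _ = cross_species_concordance(pairs)
        assert rho == pytest.approx(-1.0)

    def test_table_ordered_by_magnitude(self):
        pairs = [{"dpsi_a": d, "dpsi_b": d} for d in (0.1, -0.6, 0.3)]
        _, table = cross_species_concordance(pairs)
        assert table["dpsi_a"].abs().is_monotonic_decreasing

    def test_shared_direction_with_noise_is_positive(self):
        positives = 0
        trials = 40
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            true = rng.uniform(-0.6, 0.6, 12)
            pairs = [
                {
                    "dpsi_a": t + rng.normal(0, 0.1),
                    "dpsi_b": t + rng.normal(0, 0.1),
                }
                for t in true
            ]
            rho, _ = cross_species_concordance(pairs)
            positives += rho > 0
        assert positives >= trials * 0.95

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cross_species_concordance([{"dpsi_a": 1, "dpsi_b": 1}] * 2)
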