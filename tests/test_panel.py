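"""Panel design: target selection, amplicons, controls, probes, barcodes."""

import itertools
import random

import pytest

from circscreen.discovery import BackspliceJunction
from circscreen.io_formats import (
    FormatError,
    GenomeSequence,
    SpanRecord,
    TranscriptModel,
    reverse_complement,
)
from circscreen.panel import (
    Codebook,
    DesignParams,
    assign_barcodes,
    build_circ_amplicon,
    circle_sequence,
    design_padlock_probe,
    enumerate_negative_candidates,
    hamming,
    place_linear_control,
    sample_negative_controls,
    select_circ_targets,
)
from circscreen.quantify import QuantParams, read_spans_target


def _genome_with(transcript: TranscriptModel, length: int, seed=0) -> GenomeSequence:
    rnd = random.Random(seed)
    g = GenomeSequence()
    g[transcript.contig] = "".join(rnd.choice("ACGT") for _ in range(length))
    return g


def _junction(t: TranscriptModel, i: int, j: int, count=1) -> BackspliceJunction:
    return BackspliceJunction(
        contig=t.contig, strand=t.strand, donor=t.exons[j][1],
        acceptor=t.exons[i][0], count=count, motif="GTAG",
        transcript_ids=(t.transcript_id,),
    )


TX = TranscriptModel(
    "tx1", "g1", "chr1", "+",
    ((1000, 1160), (1400, 1560), (1800, 1960), (2200, 2360), (2600, 2760)),
)


class TestSelectCircTargets:
    def test_one_per_transcript_highest_count_wins(self):
        j_small = _junction(TX, 1, 2, count=10)
        j_big = _junction(TX, 1, 3, count=40)
        selected = select_circ_targets([j_small, j_big], [TX])
        assert [(j.count, t.transcript_id) for j, t in selected] == [(40, "tx1")]

    def test_short_circle_excluded(self):
        short_tx = TranscriptModel("s", "g", "chr1", "+", ((0, 150), (300, 449)))
        j = _junction(short_tx, 0, 1)  # 299 nt spliced
        assert select_circ_targets([j], [short_tx]) == []
        ok_tx = TranscriptModel("s", "g", "chr1", "+", ((0, 150), (300, 450)))
        j = _junction(ok_tx, 0, 1)  # exactly 300 nt
        assert len(select_circ_targets([j], [ok_tx])) == 1

    def test_sorted_by_count_matches_brute_force(self):
        txs = [
            TranscriptModel(
                f"t{k}", f"g{k}", "chr1", "+",
                ((5000 * k, 5000 * k + 200), (5000 * k + 400, 5000 * k + 600)),
            )
            for k in range(5)
        ]
        junctions = [_junction(t, 0, 1, count=c) for t, c in zip(txs, (3, 9, 1, 7, 5))]
        selected = select_circ_targets(junctions, txs)
        assert [j.count for j, _ in selected] == sorted(
            (j.count for j in junctions), reverse=True
        )


class TestCircAmplicon:
    def test_plus_strand_construction(self):
        genome = _genome_with(TX, 4000)
        j = _junction(TX, 0, 1)  # 320 nt circle
        target = build_circ_amplicon(j, TX, genome)
        circ = circle_sequence(j, TX, genome)
        assert target.sequence == circ[-60:] + circ[:60]
        assert target.junction_offset == 60
        assert len(target.sequence) == 120

    def test_small_flank(self):
        genome = _genome_with(TX, 4000)
        j = _junction(TX, 0, 1)
        params = DesignParams(amplicon_flank=25)
        target = build_circ_amplicon(j, TX, genome, params)
        assert len(target.sequence) == 50 and target.junction_offset == 25

    def test_minus_strand_matches_rotation_oracle(self):
        minus = TranscriptModel("m", "g", "chr1", "-", TX.exons)
        genome = _genome_with(minus, 4000, seed=3)
        j = _junction(minus, 0, 2)
        target = build_circ_amplicon(j, minus, genome)
        # independent oracle: splice exons genomically, reverse-complement,
        # then rotate the circle so the junction is centered
        spliced = "".join(
            genome["chr1"][s:e]
            for s, e in minus.exons
            if s >= j.acceptor and e <= j.donor
        )
        circ = reverse_complement(spliced)
        rotated = circ[-60:] + circ[:60]
        assert target.sequence == rotated

    def test_circle_shorter_than_window_is_error(self):
        tiny = TranscriptModel("t", "g", "chr1", "+", ((100, 200),))
        genome = _genome_with(tiny, 500)
        j = _junction(tiny, 0, 0)
        with pytest.raises(FormatError, match="flank"):
            build_circ_amplicon(j, tiny, genome)


class TestLinearControl:
    def test_upstream_placement_preferred(self):
        genome = _genome_with(TX, 4000)
        j = _junction(TX, 3, 4)  # circle on last two exons; 3*160 nt upstream
        target = place_linear_control(j, TX, genome)
        spliced = TX.spliced_sequence(genome)
        circ_start = TX.genomic_to_transcript(j.acceptor)
        assert target.sequence == spliced[circ_start - 300 - 120 : circ_start - 300]
        assert target.junction_offset is None

    def test_downstream_fallback(self):
        genome = _genome_with(TX, 4000)
        j = _junction(TX, 0, 1)  # nothing upstream of the first exon
        target = place_linear_control(j, TX, genome)
        spliced = TX.spliced_sequence(genome)
        circ_end = TX.genomic_to_transcript(j.donor)
        assert target.sequence == spliced[circ_end + 300 : circ_end + 420]

    def test_no_room_either_side_is_error(self):
        tx = TranscriptModel("t", "g", "chr1", "+", ((100, 260), (400, 560)))
        genome = _genome_with(tx, 1000)
        j = _junction(tx, 0, 1)
        with pytest.raises(FormatError, match="no room"):
            place_linear_control(j, tx, genome)

    def test_minus_strand_upstream_is_genomic_right(self):
        minus = TranscriptModel("m", "g", "chr1", "-", TX.exons)
        genome = _genome_with(minus, 4000, seed=5)
        # circle on the transcript's 3' exons (genomic left); upstream room
        # lies at the genomic right end
        j = _junction(minus, 0, 1)
        target = place_linear_control(j, minus, genome)
        spliced = minus.spliced_sequence(genome)
        circ_start = minus.genomic_to_transcript(j.donor)
        assert target.sequence == spliced[circ_start - 420 : circ_start - 300]


class TestNegativeControls:
    def test_only_candidate_observed_is_error(self):
        tx = TranscriptModel("t", "g", "chr1", "+", ((0, 200), (400, 600)))
        genome = _genome_with(tx, 1000)
        observed = [
            _junction(tx, i, j)
            for i, jj in itertools.product(range(2), range(2))
            for j in [jj]
            if tx.exons[i][0] < tx.exons[jj][1]
        ]
        params = DesignParams(n_negative=1)
        with pytest.raises(FormatError, match="0 negative-control candidates"):
            sample_negative_controls([tx], observed, genome, params)

    def test_seeded_determinism(self, toy_annotation):
        genome, transcripts, planted = toy_annotation
        params = DesignParams(n_negative=5, negative_seed=42)
        a = sample_negative_controls(transcripts, planted, genome, params)
        b = sample_negative_controls(transcripts, planted, genome, params)
        assert [t.target_id for t in a] == [t.target_id for t in b]
        assert [t.sequence for t in a] == [t.sequence for t in b]

    def test_sample_distinct_and_unobserved(self, toy_annotation):
        genome, transcripts, planted = toy_annotation
        params = DesignParams(n_negative=15, negative_seed=1)
        negatives = sample_negative_controls(transcripts, planted, genome, params)
        assert len({t.target_id for t in negatives}) == 15
        observed = {(j.contig, j.strand, j.acceptor, j.donor) for j in planted}
        candidates = enumerate_negative_candidates(transcripts, planted, params)
        candidate_keys = {
            (j.contig, j.strand, j.acceptor, j.donor) for j, _ in candidates
        }
        for t in negatives:
            contig, span, strand = t.source_junction.rsplit(":", 2)
            acceptor, donor = (int(x) for x in span.split("-"))
            key = (contig, strand, acceptor, donor)
            assert key not in observed
            assert key in candidate_keys

    def test_never_emits_observed_over_many_seeds(self, toy_annotation):
        genome, transcripts, planted = toy_annotation
        observed = {(j.contig, j.strand, j.acceptor, j.donor) for j in planted}
        for seed in range(1000):
            params = DesignParams(n_negative=2, negative_seed=seed)
            for t in sample_negative_controls(transcripts, planted, genome, params):
                contig, span, strand = t.source_junction.rsplit(":", 2)
                acceptor, donor = (int(x) for x in span.split("-"))
                assert (contig, strand, acceptor, donor) not in observed


class TestPadlockProbe:
    def _circ_target(self, seed=0):
        genome = _genome_with(TX, 4000, seed=seed)
        return build_circ_amplicon(_junction(TX, 0, 1), TX, genome)

    def test_arms_reconstruct_junction_window(self):
        target = self._circ_target()
        probe = design_padlock_probe(target, "ACGT")
        # target-facing concatenation must be complementary to the 40-mer
        # centered on the junction of the cDNA
        cdna = reverse_complement(target.sequence)
        jc = len(cdna) - target.junction_offset
        window = cdna[jc - 20 : jc + 20]
        assert reverse_complement(probe.arm_5p + probe.arm_3p) == window

    def test_arm_length_one(self):
        from circscreen.panel import PanelTarget

        target = PanelTarget(
            target_id="t", target_class="circ", gene_id="g", sequence="ACGT",
            junction_offset=2, contig="c", strand="+", footprint=((0, 4),),
        )
        probe = design_padlock_probe(target, "AAAA", arm_length=1)
        # amplicon AC|GT on the sense strand; cDNA is ACGT reverse-complemented
        # arms are complementary to the cDNA bases flanking the junction
        cdna = reverse_complement("ACGT")
        assert probe.arm_3p == reverse_complement(cdna[1:2])
        assert probe.arm_5p == reverse_complement(cdna[2:3])

    def test_short_barcode_rejected(self):
        target = self._circ_target()
        with pytest.raises(ValueError, match="4 nucleotides"):
            design_padlock_probe(target, "ACG")

    def test_insufficient_flank_is_error(self):
        target = self._circ_target()
        with pytest.raises(FormatError, match="side"):
            design_padlock_probe(target, "ACGT", arm_length=70)

    def test_backbone_carries_anchor_and_barcode(self):
        probe = design_padlock_probe(self._circ_target(), "TTGG", anchor_site="AAACCC")
        assert probe.backbone == "AAACCC" + "TTGG"


class TestAssignBarcodes:
    def test_distance_four_pair(self):
        book = assign_barcodes(["a", "b"], min_pairwise_hamming=4, seed=1)
        (c1, c2) = book.keys()
        assert hamming(c1, c2) == 4

    def test_more_targets_than_codes_is_error(self):
        with pytest.raises(ValueError, match="256"):
            assign_barcodes([f"t{i}" for i in range(257)], min_pairwise_hamming=1)

    def test_nine_targets_all_pairs_checked(self):
        book = assign_barcodes([f"t{i}" for i in range(9)], min_pairwise_hamming=2, seed=2)
        codes = list(book)
        assert len(codes) == 9
        for a, b in itertools.combinations(codes, 2):
            assert hamming(a, b) >= 2

    def test_deterministic_per_seed(self):
        a = assign_barcodes([f"t{i}" for i in range(9)], seed=5)
        b = assign_barcodes([f"t{i}" for i in range(9)], seed=5)
        assert a == b

    def test_codebook_tsv_round_trip(self, tmp_path):
        book = assign_barcodes(["x", "y", "z"], seed=3)
        p = tmp_path / "book.tsv"
        book.to_tsv(p)
        assert Codebook.from_tsv(p) == book


class TestCrossModuleJunctionRule:
    def test_amplicon_counts_only_junction_spanning_reads(self, toy_panel):
        """A circ amplicon admits exactly the reads that truly span the
        junction under the quantification middle rule."""
        targets, _, _ = toy_panel
        circ = next(t for t in targets if t.target_class == "circ")
        j, params = circ.junction_offset, QuantParams()
        length = len(circ.sequence)
        for start in range(0, length - 50):
            for end in range(start + 1, length + 1):
                span = SpanRecord("s", circ.target_id, "r", start, end)
                truly_spans = start <= j - 25 and end >= j + 25
                assert read_spans_target(span, circ, params) == truly_spans
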