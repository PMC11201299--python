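"""Junction extraction, clip realignment, clustering, calling and
hybrid-reference validation."""

import numpy as np
import pytest

from pbtrace.align import AlignmentRecord, build_index
from pbtrace.caller import (
    build_hybrid_reference,
    call_integration,
    cluster_junctions,
    extract_softclipped,
    realign_clips,
    screen_vector_integration,
    validate_with_hybrid,
)
from pbtrace.genome import (
    PlantedInsertion,
    default_construct,
    insert_transgene,
    make_toy_genome,
    reverse_complement,
)
from pbtrace.pipeline import CallerConfig, discover_integrations
from pbtrace.reads import ReadSimParams, simulate_paired_reads


def _aln(rid, ref, pos, cigar, seq, strand="+"):
    return AlignmentRecord(
        read_id=rid, mapped=True, ref=ref, pos=pos, strand=strand, cigar=cigar, seq=seq
    )


class TestExtractSoftclipped:
    def test_right_clip_anchor_arithmetic(self):
        rec = _aln("r", "chr1", 2000, [("M", 80), ("S", 70)], "A" * 80 + "C" * 70)
        (ev,) = extract_softclipped([rec])
        assert ev.side == "right"
        assert ev.anchor_pos == 2079  # last matched base of 80M starting at 2000
        assert ev.clipped_seq == "C" * 70

    def test_left_clip_anchor_is_first_matched_base(self):
        rec = _aln("r", "chr1", 500, [("S", 30), ("M", 120)], "G" * 30 + "A" * 120)
        (ev,) = extract_softclipped([rec])
        assert ev.side == "left" and ev.anchor_pos == 500
        assert ev.clipped_seq == "G" * 30

    def test_full_match_yields_nothing(self):
        assert extract_softclipped([_aln("r", "chr1", 1, [("M", 150)], "A" * 150)]) == []

    def test_below_threshold_clip_ignored(self):
        rec = _aln("r", "chr1", 11, [("S", 10), ("M", 140)], "G" * 10 + "A" * 140)
        assert extract_softclipped([rec], min_clip_len=20) == []

    def test_both_side_clips_yield_two_items(self):
        rec = _aln("r", "chr1", 100, [("S", 25), ("M", 100), ("S", 25)], "G" * 25 + "A" * 100 + "C" * 25)
        assert len(extract_softclipped([rec])) == 2


@pytest.fixture(scope="module")
def targets(toy_genome, construct):
    t = dict(toy_genome.chromosomes)
    t[construct.name] = construct.sequence
    return t


@pytest.fixture(scope="module")
def full_run(toy_genome, construct):
    pos = toy_genome.chromosomes["chr1"].find("TTAA", 8000)
    site = PlantedInsertion("chr1", pos, "reverse")
    modified, truth = insert_transgene(toy_genome, construct, site)
    pairs, _ = simulate_paired_reads(modified, ReadSimParams(coverage=20, seed=13))
    result = discover_integrations(toy_genome, construct, pairs)
    return truth, pairs, result


class TestRealignClips:
    def _evidence(self, seq, side="right"):
        from pbtrace.caller import SoftClipEvidence

        return SoftClipEvidence("r", "chr1", 1000, side, seq, "+")

    def test_exact_transgene_prefix_hits_full_identity(self, targets, construct):
        ev = self._evidence(construct.sequence[:70])
        (hit,) = realign_clips([ev], targets)
        assert hit.target == construct.name
        assert hit.identity == 100.0
        assert (hit.start, hit.end) == (1, 70)
        assert hit.strand == "+"

    def test_reverse_strand_clip_detected(self, targets, toy_genome):
        ev = self._evidence(reverse_complement(toy_genome.chromosomes["chr2"][500:570]))
        (hit,) = realign_clips([ev], targets)
        assert hit.target == "chr2" and hit.strand == "-"
        assert (hit.start, hit.end) == (501, 570)

    def test_random_clip_produces_no_hit(self, targets):
        rng = np.random.default_rng(123)
        evs = [self._evidence("".join(rng.choice(list("ACGT"), 70))) for _ in range(20)]
        assert realign_clips(evs, targets) == []

    def test_min_identity_gate(self, targets, construct):
        clip = list(construct.sequence[:40])
        for i in (5, 15, 25):  # 3 mismatches in 40 bp -> 92.5% identity
            clip[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[clip[i]]
        assert realign_clips([self._evidence("".join(clip))], targets, min_identity=95.0) == []

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            realign_clips([], {})


class TestClusterJunctions:
    def _mk_obs(self, toy_genome, construct, positions, side="right"):
        from pbtrace.caller import SoftClipEvidence

        evidence = [
            SoftClipEvidence(f"r{i}", "chr1", p, side, construct.sequence[:40], "+")
            for i, p in enumerate(positions)
        ]
        targets = dict(toy_genome.chromosomes)
        targets[construct.name] = construct.sequence
        hits = realign_clips(evidence, targets)
        return cluster_junctions(
            evidence, hits, set(toy_genome.chromosomes), construct.name, len(construct)
        )

    def test_identical_breakpoints_form_one_cluster(self, toy_genome, construct):
        clusters = self._mk_obs(toy_genome, construct, [5000] * 12)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.breakpoint == 5000 and c.support == 12 and c.spread == 0
        assert c.flank == "left" and c.orientation == "forward"

    def test_distant_breakpoints_split(self, toy_genome, construct):
        clusters = self._mk_obs(toy_genome, construct, [5000] * 3 + [5200] * 3)
        assert len(clusters) == 2

    def test_modal_breakpoint_tie_takes_smallest(self, toy_genome, construct):
        clusters = self._mk_obs(toy_genome, construct, [5000, 5000, 5002, 5002])
        assert clusters[0].breakpoint == 5000

    def test_empty_inputs(self):
        assert cluster_junctions([], [], {"chr1"}, "tg", 2000) == []


class TestCallAndHybrid:
    def test_single_pass_call_at_truth(self, full_run):
        truth, _, result = full_run
        assert len(result.pass_calls) == 1
        call = result.pass_calls[0]
        assert call.chrom == truth.chrom
        assert call.junction == truth.junction
        assert call.orientation == "reverse"
        assert call.tsd_found == "TTAA"

    def test_validation_coherent_with_call(self, full_run):
        _, _, result = full_run
        call = result.pass_calls[0]
        assert call.validation is not None and call.validation.passed
        assert call.validation.left_spanning >= 3
        assert call.validation.right_spanning >= 3

    def test_no_evidence_no_calls(self, toy_genome, construct):
        calls = call_integration([], toy_genome, construct)
        assert calls == []

    def test_hybrid_length_with_tsd(self, full_run, toy_genome, construct):
        truth, _, result = full_run
        hybrid = build_hybrid_reference(result.pass_calls[0], toy_genome, construct, flank=500)
        assert len(hybrid.sequence) == 2 * 500 + len(construct) + 2 * 4

    def test_hybrid_reverse_call_embeds_revcomp(self, full_run, toy_genome, construct):
        _, _, result = full_run
        hybrid = build_hybrid_reference(result.pass_calls[0], toy_genome, construct, flank=300)
        start = hybrid.junction_left
        cargo = hybrid.sequence[start : start + len(construct)]
        assert cargo == reverse_complement(construct.sequence)

    def test_hybrid_matches_sample_genome_locally(self, full_run, toy_genome, construct):
        # the hybrid must reconstruct the transgene-bearing chromosome around
        # the junction, so junction reads align to it without clips
        truth, _, result = full_run
        pos = toy_genome.chromosomes["chr1"].find("TTAA", 8000)
        modified, _ = insert_transgene(
            toy_genome, construct, PlantedInsertion("chr1", pos, "reverse")
        )
        hybrid = build_hybrid_reference(result.pass_calls[0], toy_genome, construct, flank=400)
        assert hybrid.sequence in modified.chromosomes["chr1"]

    def test_coordinate_map_total_and_consistent(self, full_run, toy_genome, construct):
        _, _, result = full_run
        hybrid = build_hybrid_reference(result.pass_calls[0], toy_genome, construct, flank=100)
        for hpos in range(1, len(hybrid.sequence) + 1):
            src, spos, strand = hybrid.map_to_source(hpos)
            base = hybrid.sequence[hpos - 1]
            if src == hybrid.transgene_name:
                tg_base = construct.sequence[spos - 1]
                assert base == (tg_base if strand == "+" else reverse_complement(tg_base))
            else:
                assert base == toy_genome.chromosomes[src][spos - 1]

    def test_fabricated_call_fails_validation(self, toy_genome, construct):
        # reads from an insertion-free genome vs a fabricated call
        from pbtrace.caller import IntegrationCall

        pairs, _ = simulate_paired_reads(toy_genome, ReadSimParams(coverage=10, seed=29))
        fake = IntegrationCall(
            chrom="chr1", junction=(9000, 9001), orientation="forward",
            status="PASS", tsd_found=None, left_support=5, right_support=5,
        )
        hybrid = build_hybrid_reference(fake, toy_genome, construct, flank=500)
        res = validate_with_hybrid(fake, hybrid, pairs)
        assert res.left_spanning == 0 and res.right_spanning == 0 and not res.passed

    def test_flank_truncation_warns(self, toy_genome, construct):
        from pbtrace.caller import IntegrationCall

        call = IntegrationCall(
            chrom="chr1", junction=(50, 51), orientation="forward",
            status="PASS", tsd_found=None, left_support=3, right_support=3,
        )
        with pytest.warns(UserWarning, match="truncated"):
            build_hybrid_reference(call, toy_genome, construct, flank=500)


class TestRobustness:
    def test_low_coverage_calls_stay_within_two_bases(self, toy_genome, construct):
        """At 5x coverage a call may be missed, but any call made lies
        within +/-2 bp of the planted junction."""
        pos = toy_genome.chromosomes["chr1"].find("TTAA", 8000)
        modified, truth = insert_transgene(
            toy_genome, construct, PlantedInsertion("chr1", pos, "forward")
        )
        made = 0
        for seed in range(4):
            pairs, _ = simulate_paired_reads(modified, ReadSimParams(coverage=5, seed=60 + seed))
            result = discover_integrations(toy_genome, construct, pairs)
            for call in result.calls:
                assert abs(call.junction[0] - truth.junction[0]) <= 2
                made += 1
        assert made >= 1  # at least one seed yields a call

    def test_mirrored_input_gives_mirrored_call(self, construct):
        """Calling on reverse-complemented chromosomes yields the mirrored
        junction coordinate and the flipped orientation (TTAA is its own
        reverse complement, so the site stays a valid target)."""
        from pbtrace.genome import ToyGenome

        genome = make_toy_genome(1, 30000, seed=71)
        seq = genome.chromosomes["chr1"]
        pos = seq.find("TTAA", 12000)
        modified, truth = insert_transgene(
            genome, construct, PlantedInsertion("chr1", pos, "forward")
        )
        pairs, _ = simulate_paired_reads(modified, ReadSimParams(coverage=20, seed=72))
        call_fwd = discover_integrations(genome, construct, pairs).pass_calls[0]

        mirror = ToyGenome({"chr1": reverse_complement(seq)})
        # oracle: planting at the mirrored TTAA reproduces the revcomp'd
        # sample chromosome exactly, and fixes the expected junction
        N = len(seq)
        mirror_mod, mirror_truth = insert_transgene(
            mirror, construct, PlantedInsertion("chr1", N - pos - 4, "reverse")
        )
        assert mirror_mod.chromosomes["chr1"] == reverse_complement(modified.chromosomes["chr1"])
        pairs_m, _ = simulate_paired_reads(mirror_mod, ReadSimParams(coverage=20, seed=73))
        call_mir = discover_integrations(mirror, construct, pairs_m).pass_calls[0]

        assert call_fwd.junction == truth.junction
        assert call_mir.junction == mirror_truth.junction == (N - pos, N - pos + 1)
        assert call_fwd.orientation == "forward" and call_mir.orientation == "reverse"


class TestVectorScreen:
    def test_transgene_only_simulation_is_vector_clean(self, planted, construct):
        modified, _ = planted
        pairs, _ = simulate_paired_reads(modified, ReadSimParams(coverage=10, seed=41))
        vector = default_construct(seed=1234, length=3000, name="vector").sequence
        genome_no_insert = make_toy_genome(2, [20000, 15000], seed=7)
        assert screen_vector_integration(pairs, vector, genome_no_insert) == 0

    def test_planted_vector_detected(self, toy_genome):
        vector_construct = default_construct(seed=1234, length=3000, name="vector")
        pos = toy_genome.chromosomes["chr2"].find("TTAA", 5000)
        modified, _ = insert_transgene(
            toy_genome, vector_construct, PlantedInsertion("chr2", pos, "forward")
        )
        pairs, _ = simulate_paired_reads(modified, ReadSimParams(coverage=15, seed=43))
        assert screen_vector_integration(pairs, vector_construct.sequence, toy_genome) >= 1

    def test_episomal_vector_not_called(self, toy_genome):
        # free vector molecules sequenced alongside the genome: plenty of
        # vector reads, but none linking vector to genome
        from pbtrace.genome import ToyGenome

        vector = default_construct(seed=1234, length=3000, name="vector").sequence
        combined = ToyGenome({**toy_genome.chromosomes, "episome": vector})
        pairs, _ = simulate_paired_reads(combined, ReadSimParams(coverage=12, seed=47))
        assert screen_vector_integration(pairs, vector, toy_genome) == 0

    def test_empty_vector_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            screen_vector_integration([], "", toy_genome)
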