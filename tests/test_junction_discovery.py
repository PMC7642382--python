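import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncsplice.junction_discovery import (
    SpliceJunction,
    boundary_distance,
    compute_jaf,
    depth_anchor,
    extract_junctions,
    find_candidates,
    read_junctions,
    site_depth,
    spliced_in_fraction,
)
from ncsplice.io_formats import AnnotationIndex, PipelineConfig, SomaticMutation

from conftest import make_candidate, make_read


def empty_annotation():
    return AnnotationIndex(set(), {}, {})


class TestExtractJunctions:
    def test_single_spliced_read(self, bam_factory):
        bam = bam_factory([make_read("r1", 1001, "30M200N45M")])
        tally = extract_junctions(bam, "chr1", 900, 1400, min_mapq=20)
        assert tally == {("chr1", 1031, 1230): 1}

    def test_two_introns_in_one_read(self, bam_factory):
        bam = bam_factory([make_read("r1", 2001, "20M100N20M100N20M")])
        tally = extract_junctions(bam, "chr1", 1900, 2400, min_mapq=20)
        assert tally == {
            ("chr1", 2021, 2120): 1,
            ("chr1", 2141, 2240): 1,
        }

    def test_mapq_filter(self, bam_factory):
        reads = [
            make_read(f"hi{i}", 3001, "30M100N45M", mapq=60) for i in range(5)
        ] + [make_read(f"lo{i}", 3001, "30M100N45M", mapq=10) for i in range(2)]
        bam = bam_factory(reads)
        tally = extract_junctions(bam, "chr1", 2900, 3300, min_mapq=20)
        assert tally[("chr1", 3031, 3130)] == 5

    def test_unknown_chromosome_raises(self, bam_factory):
        bam = bam_factory([make_read("r1", 1001, "75M")])
        with pytest.raises(ValueError, match="chrZ"):
            extract_junctions(bam, "chrZ", 1, 100, 20)

    def test_matches_brute_force_on_random_cigars(self):
        """CIGAR-walk equivalence against an independent regex-based oracle."""

        class FakeRead:
            def __init__(self, start, cigar):
                self.reference_start = start
                self.cigarstring = cigar
                ops = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "=": 7, "X": 8}
                self.cigartuples = [
                    (ops[o], int(n)) for n, o in re.findall(r"(\d+)([MIDNS=X])", cigar)
                ]

        def oracle(start, cigar):
            introns = []
            pos = start
            for n, op in re.findall(r"(\d+)([MIDNS=X])", cigar):
                n = int(n)
                if op == "N":
                    introns.append((pos + 1, pos + n))
                if op in "MDN=X":
                    pos += n
            return introns

        rng = np.random.default_rng(11)
        for _ in range(150):
            start = int(rng.integers(0, 10000))
            parts = []
            for _ in range(int(rng.integers(1, 4))):
                parts.append(f"{rng.integers(1, 50)}M")
                if rng.random() < 0.7:
                    parts.append(f"{rng.integers(30, 5000)}N")
            parts.append(f"{rng.integers(1, 50)}M")
            if rng.random() < 0.3:
                parts.append(f"{rng.integers(1, 10)}S")
            cigar = "".join(parts)
            read = FakeRead(start, cigar)
            assert read_junctions(read) == oracle(start, cigar)


class TestSiteDepth:
    def test_no_reads_zero(self, bam_factory):
        bam = bam_factory([make_read("r1", 1001, "75M")])
        assert site_depth(bam, "chr1", 5000, 20) == 0

    def test_spliced_reads_do_not_cover_intron(self, bam_factory):
        reads = [make_read(f"m{i}", 1001, "75M") for i in range(15)] + [
            make_read(f"j{i}", 1001, "30M200N45M") for i in range(5)
        ]
        bam = bam_factory(reads)
        # intronic base for the junction reads: only the 15 exonic reads cover
        assert site_depth(bam, "chr1", 1050, 20) == 15
        # flanking exonic base: all 20 reads have an aligned base
        assert site_depth(bam, "chr1", 1030, 20) == 20

    def test_matches_per_read_brute_force(self, bam_factory):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(60):
            pos = int(rng.integers(900, 1100))
            cigar = "75M" if rng.random() < 0.5 else "25M150N50M"
            reads.append(make_read(f"r{i}", pos, cigar, mapq=int(rng.choice([10, 60]))))
        bam = bam_factory(reads)
        for probe in (950, 1000, 1049, 1120, 1200):
            expected = 0
            for r in reads:
                if r.mapq < 20:
                    continue
                pos = r.pos
                covered = False
                for n, op in re.findall(r"(\d+)([MN])", r.cigar):
                    n = int(n)
                    if op == "M" and pos <= probe < pos + n:
                        covered = True
                    pos += n
                expected += covered
            assert site_depth(bam, "chr1", probe, 20) == expected


class TestComputeJaf:
    @pytest.mark.parametrize(
        "n,depth,expected", [(5, 20, 0.25), (0, 100, 0.0), (7, 7, 1.0), (0, 0, 0.0)]
    )
    def test_examples(self, n, depth, expected):
        assert compute_jaf(n, depth) == expected

    def test_support_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            compute_jaf(10, 5)

    @given(depth=st.integers(0, 500), n=st.integers(0, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_monotone(self, depth, n):
        n = min(n, depth)
        jaf = compute_jaf(n, depth)
        assert 0.0 <= jaf <= 1.0
        if n + 1 <= depth:
            assert compute_jaf(n + 1, depth) >= jaf


class TestFindCandidates:
    def test_distance_measured_to_nearest_boundary(self, config):
        mut = SomaticMutation("chr1", 1050, "A", "G", "S1", "Intron")
        tally = {("chr1", 1031, 1230): 5}
        cands = find_candidates(mut, tally, empty_annotation(), config)
        assert len(cands) == 1
        assert cands[0].distance_bp == 19
        # independent check: enumerate the four boundary anchors
        assert cands[0].distance_bp == min(
            abs(1050 - 1031), abs(1050 - 1030), abs(1050 - 1230), abs(1050 - 1231)
        )

    def test_below_min_support_dropped(self, config):
        mut = SomaticMutation("chr1", 1050, "A", "G", "S1", "Intron")
        assert find_candidates(mut, {("chr1", 1031, 1230): 4}, empty_annotation(), config) == []

    def test_outside_window_dropped(self, config):
        mut = SomaticMutation("chr1", 1006, "A", "G", "S1", "Intron")
        # both boundaries 25 bp away from the mutation
        tally = {("chr1", 1031, 1230): 50}
        mut_near = SomaticMutation("chr1", 1250, "A", "G", "S1", "Intron")
        assert find_candidates(mut_near, {("chr1", 1031, 1230): 50}, empty_annotation(), config) != []
        mut25 = SomaticMutation("chr1", 1005, "A", "G", "S1", "Intron")
        cands = find_candidates(mut25, tally, empty_annotation(), config)
        assert cands == []

    def test_emitted_candidates_respect_thresholds(self, config):
        rng = np.random.default_rng(5)
        mut = SomaticMutation("chr1", 5000, "A", "G", "S1", "Intron")
        tally = {}
        for _ in range(200):
            s = int(rng.integers(4000, 6000))
            e = s + int(rng.integers(50, 800))
            tally[("chr1", s, e)] = int(rng.integers(0, 15))
        for cand in find_candidates(mut, tally, empty_annotation(), config):
            assert cand.distance_bp <= config.window
            assert cand.junction.n_supporting_reads >= config.min_supporting_reads


class TestSplicedInFraction:
    def build_case(self, bam_factory, n_alt, n_ref_base, mut_pos=1025):
        # junction reads start at 1001: 30M200N45M covers 1001-1030 then 1231-
        reads = []
        for i in range(n_alt):
            seq = "A" * 75
            seq = seq[: mut_pos - 1001] + "G" + seq[mut_pos - 1001 + 1 :]
            reads.append(make_read(f"alt{i}", 1001, "30M200N45M", seq=seq))
        for i in range(n_ref_base):
            reads.append(make_read(f"ref{i}", 1001, "30M200N45M", seq="A" * 75))
        return bam_factory(reads)

    def test_fraction_of_mutant_junction_reads(self, bam_factory):
        bam = self.build_case(bam_factory, n_alt=6, n_ref_base=4)
        cand = make_candidate(1031, 1230, 1025)
        assert spliced_in_fraction(cand, bam, 20) == pytest.approx(0.6)

    def test_low_fraction_detected(self, bam_factory):
        bam = self.build_case(bam_factory, n_alt=2, n_ref_base=8)
        cand = make_candidate(1031, 1230, 1025)
        assert spliced_in_fraction(cand, bam, 20) == pytest.approx(0.2)

    def test_spliced_out_mutation_is_absent(self, bam_factory):
        bam = self.build_case(bam_factory, n_alt=5, n_ref_base=5)
        cand = make_candidate(1031, 1230, 1100)  # inside the skipped intron
        assert spliced_in_fraction(cand, bam, 20) is None


def test_depth_anchor_selects_exonic_side():
    # mutation near the donor boundary -> anchor is the exonic base before it
    assert depth_anchor(1029, 1031, 1230) == 1030
    # near the acceptor -> exonic base after the intron
    assert depth_anchor(1233, 1031, 1230) == 1231


def test_junction_invariants():
    with pytest.raises(ValueError):
        SpliceJunction("chr1", 100, 100)
    assert boundary_distance(1031, 1031, 1230) == 0
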