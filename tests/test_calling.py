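"""Deletion callers: CIGAR parsing, chimeric pairing, realignment, merging."""

import numpy as np
import pytest

from mitodel.alignments import ReadBundle
from mitodel.calling import (
    CallerError,
    CallerParams,
    DeletionCall,
    annotate_calls,
    call_chimeric,
    call_primary_cigar,
    call_realign,
    combine_calls,
    needs_realignment,
    parse_cigar,
)
from mitodel.simulate import SimConfig, _apply_errors

from conftest import make_segment

PARAMS = CallerParams()


class TestPrimaryCigarCaller:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("2000M5000D1000M", [(2001, 7001)]),
            ("1000M100D1000M", []),  # 100 is not > 100
            ("1000M101D1000M", [(1001, 1102)]),
            ("500M200D250M300D500M", [(501, 1251)]),  # gap 250 <= 300: merged
            ("500M200D301M300D500M", [(501, 701), (1002, 1302)]),  # gap 301: kept apart
            ("3000M", []),
            ("100S2000M500D100M50S", [(2001, 2501)]),
        ],
    )
    def test_examples(self, cigar, expected):
        seg = make_segment(ref_start=0, cigar=cigar, read_length=20000)
        calls = call_primary_cigar(seg, PARAMS)
        assert [(c.start_rot, c.end_rot) for c in calls] == expected
        assert all(c.source == "primary_cigar" for c in calls)

    def test_ref_start_offsets_calls(self):
        seg = make_segment(ref_start=1500, cigar="100M200D100M")
        (call,) = call_primary_cigar(seg, PARAMS)
        assert (call.start_rot, call.end_rot, call.size) == (1601, 1801, 200)

    def test_malformed_cigar_rejected(self):
        with pytest.raises(CallerError):
            parse_cigar("12Q3M")
        with pytest.raises(CallerError):
            parse_cigar("")

    def test_merge_matches_bruteforce_interval_merge(self):
        # random D-run layouts vs an independent interval-merge oracle
        rng = np.random.default_rng(77)
        for _ in range(200):
            n_runs = int(rng.integers(1, 6))
            cigar_parts, intervals = [], []
            pos = 0
            for i in range(n_runs):
                m = int(rng.integers(50, 500))
                d = int(rng.integers(50, 800))
                cigar_parts.append(f"{m}M{d}D")
                if d > PARAMS.min_deletion:
                    intervals.append((pos + m, pos + m + d))
                pos += m + d
            cigar = "".join(cigar_parts) + "200M"
            expected = []
            for s, e in intervals:  # oracle: sequential merge on sorted runs
                if expected and s - expected[-1][1] <= PARAMS.merge_window:
                    expected[-1] = (expected[-1][0], e)
                else:
                    expected.append((s, e))
            seg = make_segment(ref_start=0, cigar=cigar, read_length=50000)
            got = [(c.start_rot - 1, c.end_rot - 1) for c in call_primary_cigar(seg, PARAMS)]
            assert got == expected


def _bundle(segs):
    prim = next(s for s in segs if s.is_primary)
    supp = [s for s in segs if not s.is_primary]
    return ReadBundle(prim.read_id, prim.read_length, prim, sorted(supp, key=lambda s: s.query_start))


def _spec_pair(read_len=6010):
    prim = make_segment(ref_start=0, ref_end=3000, query_start=0, query_end=3000,
                        read_length=read_len)
    supp = make_segment(ref_start=8000, ref_end=11000, query_start=3010, query_end=6010,
                        is_supplementary=True, read_length=read_len)
    return prim, supp


class TestChimericCaller:
    def test_canonical_pair_yields_junction_call(self):
        prim, supp = _spec_pair()
        (call,) = call_chimeric(_bundle([prim, supp]), PARAMS)
        assert (call.start_rot, call.end_rot, call.size) == (3001, 8001, 5000)
        assert call.source == "chimeric"

    def test_query_gap_over_300_rejected(self):
        prim, _ = _spec_pair()
        supp = make_segment(ref_start=8000, ref_end=11000, query_start=3301,
                            query_end=6301, is_supplementary=True, read_length=6301)
        assert call_chimeric(_bundle([prim, supp]), PARAMS) == []
        # boundary: gap exactly 300 is accepted
        supp2 = make_segment(ref_start=8000, ref_end=11000, query_start=3300,
                             query_end=6300, is_supplementary=True, read_length=6300)
        assert len(call_chimeric(_bundle([prim, supp2]), PARAMS)) == 1

    def test_query_overlap_50_or_more_rejected(self):
        prim, _ = _spec_pair()
        supp = make_segment(ref_start=8000, ref_end=11000, query_start=2940,
                            query_end=5940, is_supplementary=True, read_length=5940)
        assert call_chimeric(_bundle([prim, supp]), PARAMS) == []  # overlap 60
        supp2 = make_segment(ref_start=8000, ref_end=11000, query_start=2951,
                             query_end=5951, is_supplementary=True, read_length=5951)
        assert len(call_chimeric(_bundle([prim, supp2]), PARAMS)) == 1  # overlap 49

    def test_short_segments_rejected(self):
        prim = make_segment(ref_start=0, ref_end=200, query_start=0, query_end=200,
                            read_length=3210)
        supp = make_segment(ref_start=8000, ref_end=11000, query_start=210,
                            query_end=3210, is_supplementary=True, read_length=3210)
        assert call_chimeric(_bundle([prim, supp]), PARAMS) == []

    def test_opposite_strands_rejected(self):
        prim, supp = _spec_pair()
        supp = make_segment(ref_start=8000, ref_end=11000, query_start=3010,
                            query_end=6010, is_supplementary=True, strand="-",
                            read_length=6010)
        assert call_chimeric(_bundle([prim, supp]), PARAMS) == []

    def test_reference_proximate_segments_rejected(self):
        # ref gap 80 <= min_ref_gap: not "distant on the reference"
        prim = make_segment(ref_start=0, ref_end=3000, query_start=0, query_end=3000,
                            read_length=6010)
        supp = make_segment(ref_start=3080, ref_end=6080, query_start=3010,
                            query_end=6010, is_supplementary=True, read_length=6010)
        assert call_chimeric(_bundle([prim, supp]), PARAMS) == []

    def test_supplementary_first_on_query(self):
        # reference order reversed relative to query order still calls the gap
        prim = make_segment(ref_start=8000, ref_end=11000, query_start=0,
                            query_end=3000, read_length=6010)
        supp = make_segment(ref_start=0, ref_end=3000, query_start=3010,
                            query_end=6010, is_supplementary=True, read_length=6010)
        (call,) = call_chimeric(_bundle([prim, supp]), PARAMS)
        assert (call.start_rot, call.end_rot) == (3001, 8001)

    def test_no_supplementary_no_calls(self):
        prim, _ = _spec_pair()
        assert call_chimeric(_bundle([prim]), PARAMS) == []


def _random_two_segment_bundle(rng):
    """A primary + one supplementary with thresholds straddled at random."""
    read_id = f"rb{rng.integers(1e9)}"
    q1 = int(rng.integers(150, 4000))
    gap = int(rng.choice([-80, -60, -49, -10, 0, 10, 150, 299, 300, 301, 500]))
    q2 = int(rng.integers(150, 4000))
    r1_start = int(rng.integers(0, 3000))
    ref_gap = int(rng.choice([-100, -49, 0, 50, 100, 101, 150, 1000, 5000]))
    strands = rng.choice(["++", "+-", "--"])
    swap = bool(rng.random() < 0.3)
    a_q = (0, q1)
    b_q = (q1 + gap, q1 + gap + q2)
    a_r = (r1_start, r1_start + q1)
    b_r = (a_r[1] + ref_gap, a_r[1] + ref_gap + q2)
    if swap:
        a_r, b_r = b_r, a_r
    read_len = max(a_q[1], b_q[1])
    prim = make_segment(read_id=read_id, ref_start=a_r[0], ref_end=a_r[1],
                        query_start=a_q[0], query_end=a_q[1], strand=strands[0],
                        read_length=read_len)
    supp = make_segment(read_id=read_id, ref_start=b_r[0], ref_end=b_r[1],
                        query_start=b_q[0], query_end=b_q[1], strand=strands[1],
                        is_supplementary=True, read_length=read_len)
    return _bundle([prim, supp])


def _oracle_chimeric(bundle, p):
    """Literal pairwise-predicate enumeration over all segment pairs."""
    out = set()
    segs = bundle.segments
    for x in segs:
        for y in segs:
            if x is y:
                continue
            if x.query_start > y.query_start:
                continue  # consider each unordered pair once, query-ordered
            left, right = (x, y) if x.ref_start <= y.ref_start else (y, x)
            qgap = y.query_start - x.query_end
            qoverlap = max(0, -qgap)
            roverlap = max(0, left.ref_end - right.ref_start)
            rgap = right.ref_start - left.ref_end
            if (
                x.query_span > p.min_segment
                and y.query_span > p.min_segment
                and x.strand == y.strand
                and qgap <= p.max_query_gap
                and qoverlap < p.max_overlap
                and roverlap < p.max_overlap
                and rgap > p.min_ref_gap
            ):
                out.add((left.ref_end + 1, right.ref_start + 1))
    return out


class TestChimericOracleEquivalence:
    def test_matches_bruteforce_on_randomized_bundles(self):
        rng = np.random.default_rng(123)
        n_calls = 0
        for _ in range(100):
            for _ in range(20):
                bundle = _random_two_segment_bundle(rng)
                got = {(c.start_rot, c.end_rot) for c in call_chimeric(bundle, PARAMS)}
                want = _oracle_chimeric(bundle, PARAMS)
                assert got == want
                n_calls += len(got)
        assert n_calls > 100  # the randomization produced plenty of positives


class TestRealignTrigger:
    @pytest.mark.parametrize(
        "read_len,ref_span,expected",
        [(5000, 12000, True), (5000, 5400, False), (5000, 5500, False),
         (5000, 5501, True), (12000, 5000, True)],
    )
    def test_span_divergence_boundary(self, read_len, ref_span, expected):
        seg = make_segment(ref_start=0, ref_end=ref_span, query_end=min(read_len, ref_span),
                           read_length=read_len)
        assert needs_realignment(seg, PARAMS) is expected


class TestRealignCaller:
    def test_error_free_read_recovers_exact_breakpoints(self, small_ref):
        # 1500 bp deletion at position 2001..3500 (1-based)
        read = small_ref.sequence[0:2000] + small_ref.sequence[3500:5500]
        (call,) = call_realign(read, small_ref, PARAMS, read_id="r0")
        assert (call.start_rot, call.end_rot, call.size) == (2001, 3501, 1500)
        assert call.source == "realign"

    def test_reverse_complement_read_gives_same_call(self, small_ref):
        comp = str.maketrans("ACGT", "TGCA")
        read = small_ref.sequence[0:2000] + small_ref.sequence[3500:5500]
        rc = read.translate(comp)[::-1]
        (call,) = call_realign(rc, small_ref, PARAMS, read_id="r1")
        assert (call.start_rot, call.end_rot) == (2001, 3501)

    def test_deletion_free_read_yields_nothing(self, small_ref):
        assert call_realign(small_ref.sequence[100:4100], small_ref, PARAMS) == []

    def test_noisy_read_breakpoints_within_tolerance(self, small_ref):
        rng = np.random.default_rng(5)
        cfg = SimConfig(mismatch_rate=0.06, insertion_rate=0.02, deletion_rate=0.02)
        clean = small_ref.sequence[0:2000] + small_ref.sequence[3500:5500]
        arr = np.frombuffer(clean.encode(), dtype=np.uint8)
        noisy = _apply_errors(arr, rng, cfg).tobytes().decode()
        (call,) = call_realign(noisy, small_ref, PARAMS, read_id="r2")
        assert abs(call.start_rot - 2001) <= 300
        assert abs(call.end_rot - 3501) <= 300

    def test_low_scoring_read_yields_nothing(self, small_ref):
        rng = np.random.default_rng(6)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        assert call_realign(junk, small_ref, PARAMS) == []


class TestCombineCalls:
    def test_cross_source_duplicates_collapse_to_widest(self):
        p = DeletionCall("r1", 3001, 8001, "primary_cigar")
        c = DeletionCall("r1", 3011, 8021, "chimeric")
        (merged,) = combine_calls([p], [c])
        assert (merged.start_rot, merged.end_rot) == (3001, 8021)
        assert merged.source == "chimeric"

    def test_different_reads_never_merge(self):
        p = DeletionCall("r1", 3001, 8001, "primary_cigar")
        c = DeletionCall("r2", 3001, 8001, "chimeric")
        assert len(combine_calls([p], [c])) == 2

    def test_distant_calls_on_same_read_stay_separate(self):
        p = DeletionCall("r1", 1001, 1501, "primary_cigar")
        c = DeletionCall("r1", 5001, 9001, "chimeric")
        assert len(combine_calls([p], [c])) == 2

    def test_empty_chimeric_set_is_identity(self):
        p = [DeletionCall("r1", 1001, 1501, "primary_cigar"),
             DeletionCall("r2", 2001, 4001, "primary_cigar")]
        assert combine_calls(p, []) == sorted(p, key=lambda c: (c.read_id,))


class TestAnnotation:
    def test_standard_frame_and_arc_fill(self, human_scale_ref):
        call = DeletionCall("r1", 6923, 11930, "chimeric")  # the common deletion
        (ann,) = annotate_calls([call], human_scale_ref)
        assert (ann.start_std, ann.end_std) == (8470, 13477)
        assert ann.arc == "major"
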