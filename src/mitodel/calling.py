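"""Per-read mtDNA deletion callers.

Three complementary routes detect a deletion in a single sequenced molecule:

``primary_cigar``
    Long ``D`` runs in the primary alignment's CIGAR.  Sensitive for small
    and mid-sized deletions, but aligners stop representing very large
    deletions as in-alignment gaps.
``chimeric``
    A primary + supplementary (flag 2048) pair from one read whose segments
    are contiguous on the query but distant on the reference — the typical
    representation of a large deletion.
``realign``
    Two-pass local realignment of the raw read against the rotated
    reference: mask the best local hit, align the remainder, and pair the
    two hits under the same contiguity rules as the chimeric caller.  Used
    for reads whose aligned span disagrees with their length.

All calls are half-open 1-based rotated-frame intervals ``[start, end)``
(``start`` = first deleted base, ``end`` = first retained base after the
deletion) and can be annotated with standard-frame coordinates and arc class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio.Align import PairwiseAligner

from mitodel.alignments import AlignmentSegment, ReadBundle
from mitodel.reference import ArcModel, RotatedReference, classify_arc

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_SOURCE_PRIORITY = {"chimeric": 2, "primary_cigar": 1, "realign": 0}


class CallerError(ValueError):
    """Raised for malformed caller input (e.g. an unparsable CIGAR)."""


@dataclass
class CallerParams:
    """Thresholds shared by the three callers.

    Attributes
    ----------
    min_deletion
        Deletions must be strictly larger than this (bp).
    merge_window
        CIGAR ``D`` runs (and cross-caller duplicate calls) closer than this
        on the reference are merged into a single event.
    min_segment
        Each segment of a chimeric/realigned pair must cover more than this
        many read bases.
    max_query_gap
        Segments must be contiguous on the query within this distance.
    max_overlap
        Segments may overlap by strictly less than this on query and
        reference.
    realign_trigger
        Realignment is attempted when read length and primary aligned span
        disagree by more than this.
    min_ref_gap
        Segments must be at least this far apart on the reference ("distant"),
        giving chimeric calls the same size floor as CIGAR calls.
    min_align_score
        Minimum local-alignment score for a realignment segment (match 2,
        mismatch -3, gap open -5, gap extend -2).
    """

    min_deletion: int = 100
    merge_window: int = 300
    min_segment: int = 200
    max_query_gap: int = 300
    max_overlap: int = 50
    realign_trigger: int = 500
    min_ref_gap: int = 100
    min_align_score: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "min_deletion",
            "merge_window",
            "min_segment",
            "max_query_gap",
            "max_overlap",
            "realign_trigger",
            "min_ref_gap",
        ):
            if getattr(self, name) < 0:
                raise CallerError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class DeletionCall:
    """A single-molecule deletion event.

    ``start_rot``/``end_rot`` are 1-based half-open rotated coordinates;
    ``size = end_rot - start_rot``.  Standard-frame coordinates and arc class
    are filled in by :func:`annotate_calls` (the standard-frame interval may
    wrap the conventional origin, in which case ``end_std < start_std``).
    """

    read_id: str
    start_rot: int
    end_rot: int
    source: str
    sample_id: str = ""
    start_std: int | None = None
    end_std: int | None = None
    arc: str | None = None

    @property
    def size(self) -> int:
        return self.end_rot - self.start_rot


def parse_cigar(cigar: str) -> list[tuple[int, int]]:
    """Parse a CIGAR string into pysam-style (op_code, length) tuples."""
    ops = "MIDNSHP=X"
    out = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise CallerError(f"malformed CIGAR {cigar!r}")
        out.append((ops.index(m.group(2)), int(m.group(1))))
        pos = m.end()
    if pos != len(cigar) or not out:
        raise CallerError(f"malformed CIGAR {cigar!r}")
    return out


def call_primary_cigar(
    segment: AlignmentSegment, params: CallerParams | None = None
) -> list[DeletionCall]:
    """Deletions from ``D`` runs in a primary alignment's CIGAR.

    Every ``D`` run strictly longer than ``min_deletion`` becomes a candidate
    at its reference interval; candidates on the same read whose reference gap
    is at most ``merge_window`` are combined into a single event spanning from
    the first candidate's start to the last candidate's end.
    """
    params = params or CallerParams()
    candidates: list[tuple[int, int]] = []  # 0-based half-open
    ref_pos = segment.ref_start
    for op, n in parse_cigar(segment.cigar):
        if op in (2, 3):  # D, N consume reference without query
            if op == 2 and n > params.min_deletion:
                candidates.append((ref_pos, ref_pos + n))
            ref_pos += n
        elif op in (0, 7, 8):  # M, =, X
            ref_pos += n
    merged = _merge_candidates(candidates, params.merge_window)
    return [
        DeletionCall(segment.read_id, s + 1, e + 1, source="primary_cigar")
        for s, e in merged
    ]


def _merge_candidates(
    candidates: list[tuple[int, int]], window: int
) -> list[tuple[int, int]]:
    if not candidates:
        return []
    candidates = sorted(candidates)
    merged = [list(candidates[0])]
    for s, e in candidates[1:]:
        if s - merged[-1][1] <= window:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _pair_call(
    a: AlignmentSegment | "_RealignHit",
    b: AlignmentSegment | "_RealignHit",
    params: CallerParams,
) -> tuple[int, int] | None:
    """Apply the chimeric-pair predicate to two query-ordered segments.

    Returns the 0-based half-open reference interval of the implied deletion,
    or ``None`` if the pair is incompatible.  Requirements: each segment
    covers more than ``min_segment`` read bases; the query gap lies in
    ``(-max_overlap, max_query_gap]``; reference intervals overlap by less
    than ``max_overlap``; both segments are on the same strand; and the
    reference gap exceeds ``min_ref_gap``.
    """
    if a.query_span <= params.min_segment or b.query_span <= params.min_segment:
        return None
    if a.strand != b.strand:
        return None
    qgap = b.query_start - a.query_end
    if not (-params.max_overlap < qgap <= params.max_query_gap):
        return None
    lo, hi = (a, b) if a.ref_start <= b.ref_start else (b, a)
    ref_gap = hi.ref_start - lo.ref_end
    if ref_gap <= -params.max_overlap:  # reference overlap >= max_overlap
        return None
    if ref_gap <= params.min_ref_gap:  # not distant on the reference
        return None
    return (lo.ref_end, hi.ref_start)


def call_chimeric(
    bundle: ReadBundle, params: CallerParams | None = None
) -> list[DeletionCall]:
    """Deletions between chimeric (primary/supplementary) alignment pairs.

    Segments are ordered along the query; each adjacent pair satisfying the
    pair predicate (see :func:`_pair_call`) yields one call covering the
    reference interval between the reference-ordered segments.  Reads with
    more than one supplementary are chained pairwise, emitting one call per
    compatible junction.
    """
    params = params or CallerParams()
    if not bundle.supplementaries:
        return []
    segs = sorted(bundle.segments, key=lambda s: (s.query_start, s.query_end))
    calls = []
    for a, b in zip(segs, segs[1:]):
        interval = _pair_call(a, b, params)
        if interval is not None:
            s, e = interval
            calls.append(DeletionCall(bundle.read_id, s + 1, e + 1, source="chimeric"))
    return calls


def needs_realignment(
    segment: AlignmentSegment, params: CallerParams | None = None
) -> bool:
    """True when read length and primary aligned span disagree by more than
    ``realign_trigger`` bp, flagging the read for local realignment."""
    params = params or CallerParams()
    return abs(segment.read_length - segment.ref_span) > params.realign_trigger


@dataclass(frozen=True)
class _RealignHit:
    """A local-alignment hit in read coordinates (duck-types the pair fields)."""

    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    score: float
    strand: str = "+"

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


_REVCOMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def _best_local_hit(
    aligner: PairwiseAligner, ref_seq: str, query: str
) -> tuple[_RealignHit, list[tuple[int, int]]] | None:
    """Best local alignment as a hit plus its internal reference gaps.

    An affine local aligner will bridge a deletion smaller than its flanking
    match score as one alignment containing a long reference gap, so those
    internal gaps (reference advances with little or no query advance) are
    reported alongside the hit's overall extent.
    """
    if not query:
        return None
    alns = aligner.align(ref_seq, query)
    try:
        # .score raises for empty result sets; avoid len(), which enumerates
        # co-optimal paths and can overflow
        if alns.score <= 0:
            return None
        aln = alns[0]
    except (IndexError, AttributeError, ValueError):
        return None
    tgt_blocks, qry_blocks = aln.aligned
    if len(tgt_blocks) == 0:
        return None
    gaps: list[tuple[int, int]] = []
    for i in range(1, len(tgt_blocks)):
        ref_adv = int(tgt_blocks[i][0] - tgt_blocks[i - 1][1])
        qry_adv = int(qry_blocks[i][0] - qry_blocks[i - 1][1])
        if qry_adv == 0 and ref_adv > 0:
            gaps.append((int(tgt_blocks[i - 1][1]), int(tgt_blocks[i][0])))
    hit = _RealignHit(
        ref_start=int(tgt_blocks[0][0]),
        ref_end=int(tgt_blocks[-1][1]),
        query_start=int(qry_blocks[0][0]),
        query_end=int(qry_blocks[-1][1]),
        score=float(aln.score),
    )
    return hit, gaps


def call_realign(
    read_sequence: str,
    ref: RotatedReference,
    params: CallerParams | None = None,
    read_id: str = "",
) -> list[DeletionCall]:
    """Deletions from two-pass local realignment of a raw read.

    The read (both orientations; the better-scoring one wins) is locally
    aligned to the rotated reference with affine gap scores.  The aligned
    query interval is masked and the flanking query prefix/suffix are aligned
    in a second pass; if the best secondary hit and the first hit satisfy the
    chimeric pair predicate, one ``realign`` call is emitted between them.
    """
    params = params or CallerParams()
    aligner = _make_aligner()
    best: tuple[float, str, _RealignHit, list[tuple[int, int]]] | None = None
    oriented = {
        "+": read_sequence.upper(),
        "-": read_sequence.upper().translate(_REVCOMP)[::-1],
    }
    for strand, seq in oriented.items():
        res = _best_local_hit(aligner, ref.sequence, seq)
        if res is not None and (best is None or res[0].score > best[0]):
            best = (res[0].score, strand, res[0], res[1])
    if best is None or best[0] < params.min_align_score:
        return []
    _, strand, first, internal_gaps = best
    seq = oriented[strand]

    # candidate deletions: reference gaps bridged inside the first alignment...
    candidates = [(s, e) for s, e in internal_gaps if e - s > params.min_deletion]

    # ...plus a split pair against the best hit on the unaligned remainder
    second: _RealignHit | None = None
    for piece_start, piece_end in (
        (0, first.query_start),
        (first.query_end, len(seq)),
    ):
        if piece_end - piece_start <= params.min_segment:
            continue
        res = _best_local_hit(aligner, ref.sequence, seq[piece_start:piece_end])
        if res is None or res[0].score < params.min_align_score:
            continue
        hit = replace(
            res[0],
            query_start=res[0].query_start + piece_start,
            query_end=res[0].query_end + piece_start,
        )
        if second is None or hit.score > second.score:
            second = hit
    if second is not None:
        a, b = sorted((first, second), key=lambda h: h.query_start)
        interval = _pair_call(a, b, params)
        if interval is not None:
            candidates.append(interval)
    merged = _merge_candidates(candidates, params.merge_window)
    return [
        DeletionCall(read_id, s + 1, e + 1, source="realign") for s, e in merged
    ]


def combine_calls(
    primary_calls: list[DeletionCall],
    chimeric_calls: list[DeletionCall],
    merge_window: int = 300,
) -> list[DeletionCall]:
    """De-duplicate calls for the same event found by different callers.

    Within one read, calls whose start and end breakpoints are each within
    ``merge_window`` are collapsed to a single call spanning the widest
    extent; when sources differ the higher-sensitivity source (chimeric) is
    recorded.  Calls on different reads never merge.
    """
    by_read: dict[tuple[str, str], list[DeletionCall]] = {}
    for call in [*primary_calls, *chimeric_calls]:
        by_read.setdefault((call.sample_id, call.read_id), []).append(call)
    out: list[DeletionCall] = []
    for calls in by_read.values():
        calls = sorted(calls, key=lambda c: (c.start_rot, c.end_rot))
        clusters: list[list[DeletionCall]] = []
        for call in calls:
            placed = False
            for cluster in clusters:
                if any(
                    abs(call.start_rot - c.start_rot) <= merge_window
                    and abs(call.end_rot - c.end_rot) <= merge_window
                    for c in cluster
                ):
                    cluster.append(call)
                    placed = True
                    break
            if not placed:
                clusters.append([call])
        for cluster in clusters:
            start = min(c.start_rot for c in cluster)
            end = max(c.end_rot for c in cluster)
            source = max(cluster, key=lambda c: _SOURCE_PRIORITY[c.source]).source
            out.append(
                replace(cluster[0], start_rot=start, end_rot=end, source=source)
            )
    return sorted(out, key=lambda c: (c.sample_id, c.read_id, c.start_rot))


def annotate_calls(
    calls: list[DeletionCall],
    ref: RotatedReference,
    arc_model: ArcModel | None = None,
) -> list[DeletionCall]:
    """Fill in standard-frame breakpoints and arc class for each call."""
    out = []
    for c in calls:
        out.append(
            replace(
                c,
                start_std=ref.rot_to_std(c.start_rot),
                end_std=ref.rot_to_std(c.end_rot) if c.end_rot <= ref.length else 1,
                arc=classify_arc(c.start_rot, max(c.start_rot + 1, c.end_rot - 1), ref, arc_model),
            )
        )
    return out


def calls_to_dataframe(calls: list[DeletionCall]) -> pd.DataFrame:
    """Tabulate calls (one row per event; breakpoints in both frames)."""
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "read_id": c.read_id,
                "start_rot": c.start_rot,
                "end_rot": c.end_rot,
                "start_std": c.start_std,
                "end_std": c.end_std,
                "size": c.size,
                "source": c.source,
                "arc": c.arc,
            }
            for c in calls
        ],
        columns=[
            "sample_id",
            "read_id",
            "start_rot",
            "end_rot",
            "start_std",
            "end_std",
            "size",
            "source",
            "arc",
        ],
    )


def write_deletion_tsv(calls: list[DeletionCall], path) -> None:
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)


def write_bed(calls: list[DeletionCall], path, ref_name: str) -> None:
    """0-based rotated-frame BED of deletion intervals."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{ref_name}\t{c.start_rot - 1}\t{c.end_rot - 1}\t"
                f"{c.read_id}\t{c.size}\t.\n"
            )
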