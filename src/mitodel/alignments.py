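"""SAM/BAM ingestion: per-read alignment bundles, spans and read filters.

A nanopore read aligned to the rotated mitochondrial genome contributes one
primary record and zero or more supplementary (flag 2048) records.  Deletion
calling needs, for every record, its reference span and its span on the
*original read* — recovered from the CIGAR clips and the strand, since SAM
stores reverse-strand sequences reference-forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

log = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_REF_OPS = {0, 2, 3, 7, 8}  # M, D, N, =, X consume reference
_QRY_OPS = {0, 1, 4, 7, 8}  # M, I, S, =, X consume query
_CLIP_OPS = {4, 5}  # S, H


class AlignmentInputError(ValueError):
    """Raised for unreadable input or a missing target contig."""


@dataclass(frozen=True)
class AlignmentSegment:
    """One SAM record reduced to its coordinate geometry.

    ``query_start``/``query_end`` are half-open coordinates on the read in its
    *original orientation* (as sequenced), so segments from one read can be
    ordered along the molecule regardless of strand.  ``ref_start``/``ref_end``
    are half-open 0-based rotated-reference coordinates.
    """

    read_id: str
    is_primary: bool
    is_supplementary: bool
    ref_name: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str
    cigar: str
    mapq: int
    read_length: int

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class ReadBundle:
    """All alignment segments of one read: a primary plus supplementaries."""

    read_id: str
    read_length: int
    primary: AlignmentSegment
    supplementaries: list[AlignmentSegment] = field(default_factory=list)
    mean_read_quality: float | None = None

    @property
    def segments(self) -> list[AlignmentSegment]:
        return [self.primary, *self.supplementaries]


def _cigar_spans(cigartuples: list[tuple[int, int]]) -> tuple[int, int, int, int, int]:
    """Return (ref_consumed, query_consumed, left_clip, right_clip, full_read_len)."""
    ref_len = sum(n for op, n in cigartuples if op in _REF_OPS)
    qry_len = sum(n for op, n in cigartuples if op in _QRY_OPS and op != 4)
    left_clip = 0
    for op, n in cigartuples:
        if op in _CLIP_OPS:
            left_clip += n
        else:
            break
    right_clip = 0
    for op, n in reversed(cigartuples):
        if op in _CLIP_OPS:
            right_clip += n
        else:
            break
    full = left_clip + qry_len + right_clip
    return ref_len, qry_len, left_clip, right_clip, full


def segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment:
    """Convert an aligned pysam record into an :class:`AlignmentSegment`.

    Query coordinates are normalized to the original read orientation: for a
    reverse-strand record the SAM-order left clip sits at the *end* of the
    read as sequenced.
    """
    cig = rec.cigartuples
    if cig is None:
        raise AlignmentInputError(f"record {rec.query_name} has no CIGAR")
    ref_len, qry_len, left_clip, right_clip, full = _cigar_spans(cig)
    reverse = rec.is_reverse
    if reverse:
        q_start, q_end = right_clip, right_clip + qry_len
    else:
        q_start, q_end = left_clip, left_clip + qry_len
    return AlignmentSegment(
        read_id=rec.query_name,
        is_primary=not rec.is_supplementary and not rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        ref_name=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_start + ref_len,
        query_start=q_start,
        query_end=q_end,
        strand="-" if reverse else "+",
        cigar=rec.cigarstring,
        mapq=rec.mapping_quality,
        read_length=full,
    )


def load_alignments(
    path: str | Path,
    target_contig: str | None = None,
) -> list[ReadBundle]:
    """Read a SAM/BAM file and group records into per-read bundles.

    Secondary (flag 256) and unmapped records are discarded; records without a
    CIGAR are skipped with a logged count.  When ``target_contig`` is given it
    must be present in the header and only records on it are kept.
    """
    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    primaries: dict[str, AlignmentSegment] = {}
    supps: dict[str, list[AlignmentSegment]] = {}
    quals: dict[str, float] = {}
    skipped = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if target_contig is not None and target_contig not in fh.references:
            raise AlignmentInputError(
                f"contig {target_contig!r} not in header of {path}"
            )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if target_contig is not None and rec.reference_name != target_contig:
                continue
            if rec.cigartuples is None:
                skipped += 1
                continue
            seg = segment_from_record(rec)
            if seg.is_supplementary:
                supps.setdefault(seg.read_id, []).append(seg)
            else:
                primaries[seg.read_id] = seg
                if rec.query_qualities is not None and len(rec.query_qualities):
                    quals[seg.read_id] = float(
                        sum(rec.query_qualities) / len(rec.query_qualities)
                    )
    if skipped:
        log.warning("skipped %d records without CIGAR", skipped)
    bundles = []
    for read_id, prim in primaries.items():
        # the primary record carries the full sequence, so its inferred read
        # length is authoritative even when supplementaries are hard-clipped
        bundles.append(
            ReadBundle(
                read_id=read_id,
                read_length=prim.read_length,
                primary=prim,
                supplementaries=sorted(
                    supps.get(read_id, []), key=lambda s: s.query_start
                ),
                mean_read_quality=quals.get(read_id),
            )
        )
    return bundles


def passes_read_filters(
    bundle: ReadBundle,
    min_len: int = 400,
    max_len: int = 17000,
    min_quality: float = 5.0,
) -> bool:
    """Read-level inclusion filter.

    Keeps reads strictly longer than ``min_len`` and strictly shorter than
    ``max_len`` (nuclear-contamination guards: short reads map ambiguously,
    over-long reads suggest non-mitochondrial origin), and with mean base
    quality at least ``min_quality`` when quality is available.
    """
    if not (min_len < bundle.read_length < max_len):
        return False
    if bundle.mean_read_quality is not None and bundle.mean_read_quality < min_quality:
        return False
    return True


def count_mt_reads(bundles: list[ReadBundle]) -> int:
    """Number of distinct reads with a primary alignment.

    This is the denominator of every per-read deletion-frequency statistic;
    supplementary records never inflate it.
    """
    return len({b.read_id for b in bundles})
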