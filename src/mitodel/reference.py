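"""Rotated mitochondrial reference and coordinate conversion.

The human mitochondrial genome is circular (16,569 bp in rCRS numbering).
Cas9-targeted sequencing cuts every molecule at one site, so sequenced
fragments start near the cut and run around the circle.  Aligning against the
*rotated* reference — the circle linearized at the cut site — keeps reads
contiguous and prevents deletions from appearing to wrap the sequence ends.

Two coordinate frames are used throughout the package:

``standard``
    1-based positions on the conventional (rCRS-style) sequence.
``rotated``
    1-based positions on the re-origined sequence, where rotated position 1
    is standard position ``offset + 1``.

Internally all intervals are 0-based half-open; the 1-based conversions here
are the reporting surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes (upper case after normalization).
_IUPAC = frozenset("ACGTUWSMKRYBDHVN")

#: Human defaults: rCRS length, Cas9 cut-site offset, minor-arc boundaries.
HUMAN_MT_LENGTH = 16569
DEFAULT_ROTATION_OFFSET = 1547
DEFAULT_MINOR_ARC = (408, 5746)


class ReferenceError(ValueError):
    """Raised for malformed sequences or out-of-range coordinates."""


@dataclass(frozen=True)
class RotatedReference:
    """A circular genome linearized at the Cas9 cut site.

    Parameters
    ----------
    name
        Contig name used in SAM headers and FASTA output.
    sequence
        The rotated-frame nucleotide sequence (upper case).
    rotation_offset
        Number of leading standard-frame bases moved to the end; rotated
        position 1 corresponds to standard position ``rotation_offset + 1``.
    """

    name: str
    sequence: str
    rotation_offset: int

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L == 0:
            raise ReferenceError("empty reference sequence")
        if not 1 <= self.rotation_offset < L:
            raise ReferenceError(
                f"rotation_offset {self.rotation_offset} out of range [1, {L - 1}]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def rot_to_std(self, pos: int) -> int:
        """Convert a 1-based rotated position to the standard frame."""
        L, off = self.length, self.rotation_offset
        if not 1 <= pos <= L:
            raise ReferenceError(f"rotated position {pos} outside [1, {L}]")
        return pos + off if pos <= L - off else pos - (L - off)

    def std_to_rot(self, pos: int) -> int:
        """Convert a 1-based standard position to the rotated frame."""
        L, off = self.length, self.rotation_offset
        if not 1 <= pos <= L:
            raise ReferenceError(f"standard position {pos} outside [1, {L}]")
        return pos - off if pos > off else pos + (L - off)

    def standard_sequence(self) -> str:
        """Undo the rotation, returning the standard-frame sequence."""
        off = self.rotation_offset
        return self.sequence[-off:] + self.sequence[:-off]


def rotate_reference(
    sequence: str,
    rotation_offset: int = DEFAULT_ROTATION_OFFSET,
    name: str = "chrM_rotated",
) -> RotatedReference:
    """Re-origin a circular sequence at ``rotation_offset``.

    The first ``rotation_offset`` bases (standard positions 1..offset, i.e.
    everything before the cut site) are moved to the end, so the rotated
    sequence starts at standard position ``offset + 1``.

    Raises
    ------
    ReferenceError
        If the offset is out of range or the sequence contains characters
        outside the IUPAC nucleotide alphabet.
    """
    seq = sequence.upper()
    if not seq:
        raise ReferenceError("empty reference sequence")
    bad = set(seq) - _IUPAC
    if bad:
        raise ReferenceError(f"non-nucleotide characters in reference: {sorted(bad)}")
    if not 1 <= rotation_offset < len(seq):
        raise ReferenceError(
            f"rotation_offset {rotation_offset} out of range [1, {len(seq) - 1}]"
        )
    rotated = seq[rotation_offset:] + seq[:rotation_offset]
    return RotatedReference(name=name, sequence=rotated, rotation_offset=rotation_offset)


def load_reference_fasta(
    path: str | Path,
    rotation_offset: int = DEFAULT_ROTATION_OFFSET,
    name: str | None = None,
) -> RotatedReference:
    """Read a single-contig FASTA and return its rotated form."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ReferenceError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ReferenceError(f"multi-contig references are not supported ({path})")
    rec = records[0]
    return rotate_reference(
        str(rec.seq), rotation_offset, name=name or f"{rec.id}_rotated"
    )


def write_reference_fasta(ref: RotatedReference, path: str | Path) -> None:
    """Write the rotated sequence as FASTA, for use by external aligners."""
    rec = SeqRecord(
        Seq(ref.sequence),
        id=ref.name,
        description=f"rotation_offset={ref.rotation_offset}",
    )
    SeqIO.write([rec], str(path), "fasta")


@dataclass(frozen=True)
class ArcModel:
    """Minor/major arc partition of the mitochondrial circle.

    The minor arc spans standard positions ``minor_arc_start..minor_arc_end``
    (408–5746 for human mtDNA); the major arc is the complementary interval,
    which wraps the standard origin (5747..16569 plus 1..407).  In the rotated
    frame neither arc needs to wrap as long as the cut site lies in the major
    arc, but the model handles any offset by carrying explicit interval lists.
    """

    minor_arc_start: int = DEFAULT_MINOR_ARC[0]
    minor_arc_end: int = DEFAULT_MINOR_ARC[1]

    def rotated_intervals(self, ref: RotatedReference) -> dict[str, list[tuple[int, int]]]:
        """1-based inclusive rotated-frame intervals for each arc.

        Returns a mapping ``{"minor": [...], "major": [...]}`` whose intervals
        partition ``[1, L]`` exactly.
        """
        L = ref.length
        if not 1 <= self.minor_arc_start < self.minor_arc_end <= L:
            raise ReferenceError("minor arc boundaries outside reference")

        def to_rot_intervals(lo_std: int, hi_std: int) -> list[tuple[int, int]]:
            # Map a standard-frame (possibly origin-wrapping via caller) interval
            # into the rotated frame, splitting at the rotation seam.
            lo, hi = ref.std_to_rot(lo_std), ref.std_to_rot(hi_std)
            if lo <= hi:
                return [(lo, hi)]
            # interval crosses the rotated origin: split into suffix + prefix
            return [(lo, L), (1, hi)]

        minor = to_rot_intervals(self.minor_arc_start, self.minor_arc_end)
        # major arc wraps the standard origin: (end+1 .. L) and (1 .. start-1)
        major: list[tuple[int, int]] = []
        if self.minor_arc_end < L:
            major.extend(to_rot_intervals(self.minor_arc_end + 1, L))
        if self.minor_arc_start > 1:
            major.extend(to_rot_intervals(1, self.minor_arc_start - 1))
        # adjacent pieces produced by the two seams may themselves be mergeable
        major = _merge_adjacent(sorted(major))
        minor = _merge_adjacent(sorted(minor))
        return {"minor": minor, "major": major}


def _merge_adjacent(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in intervals:
        if out and lo == out[-1][1] + 1:
            out[-1] = (out[-1][0], hi)
        else:
            out.append((lo, hi))
    return out


def classify_arc(
    del_start_rot: int,
    del_end_rot: int,
    ref: RotatedReference,
    arc_model: ArcModel | None = None,
) -> str:
    """Classify a rotated-frame deletion as ``minor``, ``major`` or ``both``.

    ``del_start_rot``/``del_end_rot`` are 1-based inclusive breakpoints of the
    deleted interval.  A deletion is ``minor`` (``major``) if it lies entirely
    within one rotated minor-arc (major-arc) interval, and ``both`` otherwise.
    Rotated-frame deletions never wrap because molecules are linearized at the
    cut site.
    """
    if del_start_rot >= del_end_rot:
        raise ReferenceError(
            f"deletion start {del_start_rot} must precede end {del_end_rot}"
        )
    if not (1 <= del_start_rot and del_end_rot <= ref.length):
        raise ReferenceError("deletion interval outside reference")
    arcs = (arc_model or ArcModel()).rotated_intervals(ref)
    for label in ("minor", "major"):
        for lo, hi in arcs[label]:
            if lo <= del_start_rot and del_end_rot <= hi:
                return label
    return "both"
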