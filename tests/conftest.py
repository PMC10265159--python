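import numpy as np
import pytest

from mitodel.alignments import AlignmentSegment
from mitodel.reference import RotatedReference


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def human_scale_ref() -> RotatedReference:
    """Synthetic 16,569 bp genome rotated at the human cut-site offset."""
    return RotatedReference(
        name="chrM_rotated",
        sequence=random_sequence(16569, seed=42),
        rotation_offset=1547,
    )


@pytest.fixture(scope="session")
def small_ref() -> RotatedReference:
    """A 6 kbp genome for realignment tests (local alignment is O(n*m))."""
    return RotatedReference(
        name="mini_rotated",
        sequence=random_sequence(6000, seed=7),
        rotation_offset=500,
    )


def make_segment(
    read_id="r1",
    ref_start=0,
    ref_end=1000,
    query_start=0,
    query_end=1000,
    strand="+",
    is_supplementary=False,
    read_length=None,
    cigar=None,
    ref_name="chrM_rotated",
    mapq=60,
) -> AlignmentSegment:
    qspan = query_end - query_start
    return AlignmentSegment(
        read_id=read_id,
        is_primary=not is_supplementary,
        is_supplementary=is_supplementary,
        ref_name=ref_name,
        ref_start=ref_start,
        ref_end=ref_end,
        query_start=query_start,
        query_end=query_end,
        strand=strand,
        cigar=cigar or f"{qspan}M",
        mapq=mapq,
        read_length=read_length if read_length is not None else query_end,
    )
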