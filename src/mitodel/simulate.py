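"""nCATS-style long-read simulator with ground truth.

Cas9-targeted sequencing (nCATS) produces reads that start at the cut site —
position 1 of the rotated reference — run predominantly along one strand, and
carry nanopore-scale indel/substitution noise.  This module generates such
reads from deletion-bearing template genomes, records per-read ground truth,
and can serialize alignment fixtures directly as SAM (CIGAR-deletion style or
chimeric primary/supplementary style) so the callers can be exercised without
any external aligner.

The default configuration is the benchmark design used throughout the
package's evaluation: ten template genomes, each carrying one deletion
starting at rotated bp 4000 and extending 1–10 kbp, with 500 reads per
template and an aggregate per-base error rate of ~8%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from mitodel.reference import RotatedReference

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


class SimulationError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass
class SimConfig:
    """Simulator settings.

    Parameters
    ----------
    deletion_start
        1-based rotated position of the first deleted base in every template.
    deletion_sizes
        One template genome is built per size (bp).
    reads_per_template
        Reads drawn from each template.
    length_log_mean, length_log_sigma
        Read lengths are lognormal: ``exp(N(length_log_mean, length_log_sigma))``
        bp, clipped to the template.  The defaults give a median of ~8 kbp,
        typical of Cas9-enriched mtDNA runs where most molecules extend well
        past mid-genome.
    mismatch_rate, insertion_rate, deletion_rate
        Independent per-base error probabilities (defaults sum to 8%).
    forward_strand_fraction
        Probability a read is emitted from the forward strand (Cas9 adapter
        ligation favors the strand downstream of the PAM; ~85% observed).
    start_jitter
        Reads begin at template position ``1 + U{0..start_jitter}``.
    quality_char_phred
        Constant Phred score written for every base in FASTQ output.
    seed
        Seed for the simulator's private RNG.
    """

    deletion_start: int = 4000
    deletion_sizes: tuple[int, ...] = tuple(range(1000, 10001, 1000))
    reads_per_template: int = 500
    length_log_mean: float = float(np.log(8000.0))
    length_log_sigma: float = 0.4
    mismatch_rate: float = 0.05
    insertion_rate: float = 0.015
    deletion_rate: float = 0.015
    forward_strand_fraction: float = 0.85
    start_jitter: int = 10
    min_read_length: int = 50
    quality_char_phred: int = 12
    seed: int = 0

    def validate(self, ref_length: int | None = None) -> None:
        for rate in (
            self.mismatch_rate,
            self.insertion_rate,
            self.deletion_rate,
            self.forward_strand_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"probability {rate} outside [0, 1]")
        if self.reads_per_template < 1:
            raise SimulationError("reads_per_template must be >= 1")
        if any(s <= 0 for s in self.deletion_sizes):
            raise SimulationError("deletion sizes must be positive")
        if self.deletion_start < 1:
            raise SimulationError("deletion_start must be >= 1")
        if ref_length is not None and self.deletion_sizes:
            if self.deletion_start + max(self.deletion_sizes) >= ref_length:
                raise SimulationError("deletion extends beyond reference")


@dataclass(frozen=True)
class TemplateDeletion:
    """The single deletion carried by a template genome.

    ``start_rot`` is 1-based; deleted rotated positions are
    ``start_rot .. start_rot + size - 1`` (half-open ``[start, start+size)``).
    ``None``-deletion templates (the intact genome) are represented by a
    separate ``None`` record, not by size 0.
    """

    start_rot: int
    size: int


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    phred: int


def make_templates(
    ref: RotatedReference, config: SimConfig
) -> list[tuple[str, TemplateDeletion | None]]:
    """Build one deletion-bearing template genome per configured size.

    Each template is the rotated reference with rotated positions
    ``[deletion_start, deletion_start + size)`` excised, so its length is
    ``L - size``.
    """
    config.validate(ref.length)
    out: list[tuple[str, TemplateDeletion | None]] = []
    for size in config.deletion_sizes:
        i0 = config.deletion_start - 1
        template = ref.sequence[:i0] + ref.sequence[i0 + size :]
        out.append((template, TemplateDeletion(config.deletion_start, size)))
    return out


def intact_template(ref: RotatedReference) -> tuple[str, None]:
    """A deletion-free template (the rotated reference itself)."""
    return (ref.sequence, None)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _apply_errors(seq: np.ndarray, rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Apply iid per-base substitution/insertion/deletion noise.

    ``seq`` is a uint8 array of ASCII bases; returns a new uint8 array.
    """
    n = seq.size
    if n == 0:
        return seq
    u = rng.random(n)
    is_del = u < config.deletion_rate
    is_mis = (u >= config.deletion_rate) & (u < config.deletion_rate + config.mismatch_rate)
    has_ins = rng.random(n) < config.insertion_rate

    base = seq.copy()
    if is_mis.any():
        # substitute with a uniformly chosen different base
        idx = np.flatnonzero(is_mis)
        shift = rng.integers(1, 4, size=idx.size)
        cur = np.searchsorted(_BASES, base[idx])
        cur = np.clip(cur, 0, 3)  # non-ACGT (e.g. N) substitutes arbitrarily
        base[idx] = _BASES[(cur + shift) % 4]

    # each position contributes 0 (deleted) or 1 copies, plus 1 inserted base
    counts = (~is_del).astype(np.int64) + has_ins.astype(np.int64)
    total = int(counts.sum())
    out = np.empty(total, dtype=np.uint8)
    ends = np.cumsum(counts)
    starts = ends - counts
    kept = ~is_del
    out[starts[kept]] = base[kept]
    ins_pos = ends[has_ins] - 1
    out[ins_pos] = _BASES[rng.integers(0, 4, size=ins_pos.size)]
    return out


def simulate_reads(
    templates: list[tuple[str, TemplateDeletion | None]],
    config: SimConfig,
    read_id_prefix: str = "sim",
) -> tuple[list[SimRead], pd.DataFrame]:
    """Draw reads from each template and return them with a truth table.

    Reads start at template position ``1 + U{0..start_jitter}`` (nCATS reads
    begin at the cut site), lengths are lognormal clipped to the template, the
    strand is Bernoulli(``forward_strand_fraction``), and per-base errors are
    applied independently.  Reverse-strand reads are reverse-complemented in
    the returned sequence; all truth coordinates stay in the forward
    (template/rotated) frame.

    Returns
    -------
    reads
        ``SimRead`` records ready for FASTQ output.
    truth
        One row per read: read_id, template_deletion_start,
        template_deletion_size, read_start, read_length, strand,
        contains_deletion.  ``contains_deletion`` is true iff the read's
        template span covers the deletion junction with at least one base on
        each side.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    reads: list[SimRead] = []
    rows: list[dict] = []
    for t_idx, (template, deletion) in enumerate(templates):
        tarr = np.frombuffer(template.encode(), dtype=np.uint8)
        tlen = tarr.size
        # junction position in template coordinates: the deletion sits between
        # template positions (start_rot - 1) and start_rot (1-based)
        junction = deletion.start_rot - 1 if deletion is not None else None
        for r_idx in range(config.reads_per_template):
            start = 1 + int(rng.integers(0, config.start_jitter + 1))
            length = int(np.exp(rng.normal(config.length_log_mean, config.length_log_sigma)))
            length = max(config.min_read_length, min(length, tlen - start + 1))
            fragment = tarr[start - 1 : start - 1 + length]
            noisy = _apply_errors(fragment, rng, config)
            seq = noisy.tobytes().decode()
            forward = bool(rng.random() < config.forward_strand_fraction)
            if not forward:
                seq = _revcomp(seq)
            read_id = f"{read_id_prefix}_t{t_idx}_r{r_idx}"
            spans = (
                junction is not None
                and start <= junction
                and start + length - 1 >= junction + 1
            )
            reads.append(SimRead(read_id, seq, config.quality_char_phred))
            rows.append(
                {
                    "read_id": read_id,
                    "template_deletion_start": deletion.start_rot if deletion else 0,
                    "template_deletion_size": deletion.size if deletion else 0,
                    "read_start": start,
                    "read_length": length,
                    "strand": "+" if forward else "-",
                    "contains_deletion": bool(spans),
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "template_deletion_start",
            "template_deletion_size",
            "read_start",
            "read_length",
            "strand",
            "contains_deletion",
        ],
    )
    return reads, truth


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    qchar = None
    with open(path, "w") as fh:
        for r in reads:
            qchar = chr(33 + r.phred)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qchar * len(r.sequence)}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class CohortConfig:
    """Synthetic cohort design for the frequency-vs-age statistics.

    The generator emulates the empirical structure of an aging muscle cohort:
    per-donor deletion frequency above the signal size grows log-linearly
    with age (about +0.035 log10 units/year from ~4e-5 at age 25), while a
    small age-independent background of sub-signal deletions sits in the
    minor arc.  Signal deletions live in the major arc with sizes
    ``> signal_size`` (exponential tail); a few percent span both arcs.
    """

    n_samples: int = 15
    age_min: float = 26.0
    age_max: float = 81.0
    n_mt_reads: int = 150_000
    freq_intercept: float = -5.25  # log10 frequency at age 0
    freq_slope: float = 0.0354  # log10 units per year
    freq_sigma: float = 0.12  # per-donor lognormal scatter (dex)
    signal_size: int = 2000  # deletions carrying the age signal are > this
    signal_size_max: int = 2400  # signal sizes uniform in (signal_size, max]
    background_freq: float = 3e-3
    background_size_range: tuple[int, int] = (601, 2000)
    both_arc_fraction: float = 0.065
    tissue: str = "muscle"
    ddpcr_sigma: float = 0.1
    genome_length: int = 16569
    rotation_offset: int = 1547
    seed: int = 0


def simulate_cohort(config: CohortConfig | None = None):
    """Generate per-sample deletion tables with a known age signal.

    Returns a list of :class:`mitodel.stats.SampleSummary` whose deletion
    frequency above ``signal_size`` follows
    ``log10 f = freq_intercept + freq_slope * age`` with lognormal scatter,
    plus an age-independent background of smaller minor-arc deletions.
    Calls are annotated with standard-frame coordinates and arc class.
    """
    from mitodel.calling import DeletionCall, annotate_calls
    from mitodel.reference import ArcModel, RotatedReference
    from mitodel.stats import SampleSummary

    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    ref = RotatedReference(
        name="chrM_rotated",
        sequence="A" * cfg.genome_length,
        rotation_offset=cfg.rotation_offset,
    )
    arc_model = ArcModel()
    arcs = arc_model.rotated_intervals(ref)
    major_lo, major_hi = arcs["major"][0]
    minor_lo, minor_hi = arcs["minor"][0]

    ages = np.linspace(cfg.age_min, cfg.age_max, cfg.n_samples)
    samples = []
    for i, age in enumerate(ages):
        calls: list[DeletionCall] = []
        sample_id = f"synth{i:02d}"
        log_f = cfg.freq_intercept + cfg.freq_slope * age + rng.normal(0, cfg.freq_sigma)
        n_signal = rng.poisson(cfg.n_mt_reads * 10 ** log_f)
        for j in range(n_signal):
            size = int(rng.integers(cfg.signal_size + 1, cfg.signal_size_max + 1))
            if rng.random() < cfg.both_arc_fraction:
                # span the minor/major arc boundary
                lo = max(1, major_lo - size + 100)
                start = int(rng.integers(lo, major_lo)) if lo < major_lo else major_lo
            else:
                start = int(rng.integers(major_lo, major_hi - size))
            calls.append(
                DeletionCall(f"{sample_id}_sig{j}", start, start + size, "chimeric", sample_id)
            )
        n_bg = rng.poisson(cfg.n_mt_reads * cfg.background_freq)
        lo_sz, hi_sz = cfg.background_size_range
        for j in range(n_bg):
            size = int(rng.integers(lo_sz, hi_sz + 1))
            start = int(rng.integers(minor_lo, max(minor_lo + 1, minor_hi - size)))
            calls.append(
                DeletionCall(f"{sample_id}_bg{j}", start, start + size, "primary_cigar", sample_id)
            )
        ddpcr = 10 ** (
            cfg.freq_intercept + cfg.freq_slope * age + rng.normal(0, cfg.ddpcr_sigma)
        )
        samples.append(
            SampleSummary(
                sample_id=sample_id,
                age=float(age),
                tissue=cfg.tissue,
                n_mt_reads=cfg.n_mt_reads,
                deletion_table=annotate_calls(calls, ref, arc_model),
                ddpcr_frequency=float(ddpcr),
            )
        )
    return samples


def write_sam_fixture(
    truth: pd.DataFrame,
    ref: RotatedReference,
    path: str | Path,
    style: str = "cigar_D",
    seed: int = 0,
) -> None:
    """Serialize truth reads as an aligned SAM fixture.

    Every deletion-spanning read is written either as one primary record whose
    CIGAR encodes the deletion as a ``D`` run (``style="cigar_D"``), or as a
    primary + supplementary (flag 2048) pair split at the junction with
    query-contiguous, reference-distant spans (``style="chimeric"``);
    ``style="mixed"`` chooses per read at random.  Non-spanning reads become
    single full-length ``M`` records.  Sequences are reconstructed error-free
    from the reference, so the fixture tests caller geometry, not alignment
    accuracy.  Reverse-strand reads carry flag 16 (0x10) with reference-forward
    coordinates, soft clips on the primary and hard clips on the supplementary.
    """
    if style not in ("cigar_D", "chimeric", "mixed"):
        raise SimulationError(f"unknown fixture style {style!r}")
    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": ref.name, "LN": ref.length}],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in truth.itertuples(index=False):
            start = int(row.read_start)
            length = int(row.read_length)
            del_start = int(row.template_deletion_start)
            del_size = int(row.template_deletion_size)
            reverse = row.strand == "-"
            junction = del_start - 1  # template pos of last pre-deletion base
            if row.contains_deletion:
                pre = junction - start + 1
                post = length - pre
                use_chimeric = style == "chimeric" or (
                    style == "mixed" and bool(rng.random() < 0.5)
                )
            else:
                pre, post, use_chimeric = length, 0, False

            # reference coordinates (0-based) of the template span
            ref_pre_start = start - 1
            if del_size and start > junction:
                ref_pre_start += del_size  # read entirely after the junction
            seq_pre = ref.sequence[ref_pre_start : ref_pre_start + pre]
            ref_post_start = junction + del_size  # 0-based
            seq_post = ref.sequence[ref_post_start : ref_post_start + post]
            seq_fwd = seq_pre + seq_post  # reference-forward orientation

            flag_rev = 16 if reverse else 0
            if not row.contains_deletion or not use_chimeric:
                a = pysam.AlignedSegment(header)
                a.query_name = row.read_id
                a.flag = flag_rev
                a.reference_id = 0
                a.reference_start = ref_pre_start
                if row.contains_deletion:
                    a.cigarstring = f"{pre}M{del_size}D{post}M"
                else:
                    a.cigarstring = f"{length}M"
                a.mapping_quality = 60
                a.query_sequence = seq_fwd if not reverse else seq_fwd
                out.write(a)
            else:
                p = pysam.AlignedSegment(header)
                p.query_name = row.read_id
                p.flag = flag_rev
                p.reference_id = 0
                p.reference_start = ref_pre_start
                p.cigarstring = f"{pre}M{post}S"
                p.mapping_quality = 60
                p.query_sequence = seq_fwd
                out.write(p)

                s = pysam.AlignedSegment(header)
                s.query_name = row.read_id
                s.flag = flag_rev | 2048
                s.reference_id = 0
                s.reference_start = ref_post_start
                s.cigarstring = f"{pre}H{post}M"
                s.mapping_quality = 60
                s.query_sequence = seq_post
                out.write(s)
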