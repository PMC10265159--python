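"""Cohort statistics: deletion frequency, threshold sweeps, density tests.

The per-sample quantity of interest is the *deletion frequency*: the number
of called deletions above a minimum size divided by the number of
mtDNA-mapped reads.  Frequencies are log10-transformed and regressed on
covariates (donor age, or orthogonal ddPCR quantification); sweeping the
minimum-size threshold locates the size class that carries the covariate
signal.  Breakpoint position distributions are compared between groups with
a kernel-density permutation test of equality (fixed Gaussian bandwidth,
integrated squared difference statistic) — the long-read analogue of the R
``sm`` package's ``sm.density.compare``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from mitodel.calling import DeletionCall


class StatsError(ValueError):
    """Raised for degenerate statistical input."""


@dataclass
class SampleSummary:
    """Per-sample inputs for cohort statistics."""

    sample_id: str
    age: float
    tissue: str
    n_mt_reads: int
    deletion_table: list[DeletionCall]
    ddpcr_frequency: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


@dataclass(frozen=True)
class SweepResult:
    thresholds: list[int]
    r_squared: list[float | None]
    best_threshold: int


@dataclass(frozen=True)
class DensityTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    bandwidth: float


def deletion_frequency(sample: SampleSummary, min_size: int) -> float:
    """Deletions strictly larger than ``min_size`` per mtDNA read."""
    if sample.n_mt_reads <= 0:
        raise StatsError(f"sample {sample.sample_id} has no mtDNA reads")
    n = sum(1 for c in sample.deletion_table if c.size > min_size)
    return n / sample.n_mt_reads


def _covariate_value(sample: SampleSummary, covariate: str) -> float | None:
    if covariate == "age":
        return sample.age
    if covariate == "log10_ddpcr":
        if sample.ddpcr_frequency is None or sample.ddpcr_frequency <= 0:
            return None
        return math.log10(sample.ddpcr_frequency)
    raise StatsError(f"unknown covariate {covariate!r}")


def regress_log_freq(
    samples: list[SampleSummary],
    covariate: str = "age",
    min_size: int = 2000,
    arc_class: str | None = None,
) -> RegressionResult:
    """OLS of log10 deletion frequency on a covariate.

    Samples with zero qualifying deletions (log undefined) or a missing
    covariate are excluded; at least three usable samples are required.
    When ``arc_class`` is given, only calls of that arc class count.
    """
    xs, ys = [], []
    for s in samples:
        x = _covariate_value(s, covariate)
        if x is None:
            continue
        table = s.deletion_table
        if arc_class is not None:
            table = [c for c in table if c.arc == arc_class]
        n = sum(1 for c in table if c.size > min_size)
        if n == 0:
            continue
        xs.append(x)
        ys.append(math.log10(n / s.n_mt_reads))
    if len(xs) < 3:
        raise StatsError(
            f"only {len(xs)} samples with nonzero frequency at min_size={min_size}"
        )
    if len(set(ys)) == 1:  # flat response: R^2 = 0 by definition
        return RegressionResult(0.0, ys[0], 0.0, 1.0, 0.0, len(xs))
    fit = sps.linregress(xs, ys)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=len(xs),
    )


def threshold_sweep(
    samples: list[SampleSummary],
    thresholds: list[int],
    covariate: str = "age",
) -> SweepResult:
    """Regress log10 frequency on the covariate at each minimum-size cutoff.

    Thresholds where fewer than three samples retain nonzero frequency are
    reported as missing (``None``), not zero.  ``best_threshold`` is the
    smallest threshold attaining the maximum R².
    """
    if not thresholds:
        raise StatsError("no thresholds given")
    r2: list[float | None] = []
    for t in thresholds:
        try:
            r2.append(regress_log_freq(samples, covariate, min_size=t).r_squared)
        except StatsError:
            r2.append(None)
    usable = [(t, r) for t, r in zip(thresholds, r2) if r is not None]
    if not usable:
        raise StatsError("no threshold with enough usable samples")
    best = max(usable, key=lambda tr: (tr[1], -tr[0]))[0]
    return SweepResult(list(thresholds), r2, best)


def arc_frequency_trend(
    samples: list[SampleSummary],
    arc_class: str,
    min_size: int = 2000,
    covariate: str = "age",
) -> RegressionResult:
    """Age trend of deletion frequency restricted to one arc class."""
    return regress_log_freq(samples, covariate, min_size=min_size, arc_class=arc_class)


def mean_size_trend(samples: list[SampleSummary]) -> RegressionResult:
    """OLS of per-sample mean deletion size on age."""
    xs, ys = [], []
    for s in samples:
        if not s.deletion_table:
            continue
        xs.append(s.age)
        ys.append(float(np.mean([c.size for c in s.deletion_table])))
    if len(xs) < 3:
        raise StatsError("need >= 3 samples with at least one call")
    if len(set(ys)) == 1:
        return RegressionResult(0.0, ys[0], 0.0, 1.0, 0.0, len(xs))
    fit = sps.linregress(xs, ys)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2,
        float(fit.pvalue), float(fit.stderr), len(xs),
    )


def welch_t(
    freqs_a: list[float], freqs_b: list[float], log_transform: bool = True
) -> tuple[float, float]:
    """Two-sided Welch's unequal-variance t-test on deletion frequencies.

    Frequencies are log10-transformed by default (frequency distributions are
    right-skewed across donors); pass ``log_transform=False`` for raw scale.
    """
    if len(freqs_a) < 2 or len(freqs_b) < 2:
        raise StatsError("each group needs >= 2 values")
    a, b = np.asarray(freqs_a, float), np.asarray(freqs_b, float)
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise StatsError("log transform requires positive frequencies")
        a, b = np.log10(a), np.log10(b)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate zero-variance groups: no evidence either way unless the
        # constants differ
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (float("inf"), 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _kde_matrix(points: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """Gaussian kernel evaluated at each (point, grid) pair: shape (n, G)."""
    z = (grid[None, :] - points[:, None]) / h
    return np.exp(-0.5 * z * z) / (h * math.sqrt(2 * math.pi))


def density_compare(
    breakpoints_a: list[float] | np.ndarray,
    breakpoints_b: list[float] | np.ndarray,
    genome_length: int = 16569,
    h: float = 50.0,
    n_permutations: int = 1000,
    seed: int = 0,
    grid_size: int = 512,
) -> DensityTestResult:
    """Permutation test of equality of two breakpoint densities.

    Kernel density estimates with a common fixed Gaussian bandwidth ``h`` (bp)
    are evaluated on ``grid_size`` equally spaced points over
    ``[1, genome_length]``; the test statistic is the integrated squared
    difference ``T = sum((f_a - f_b)^2) * dx``.  The null distribution is
    built by pooling both samples and permuting group labels, preserving
    group sizes; ``p = (1 + #{T_perm >= T_obs}) / (1 + n_permutations)``.
    """
    a = np.asarray(breakpoints_a, dtype=float)
    b = np.asarray(breakpoints_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both breakpoint samples must be nonempty")
    grid = np.linspace(1.0, float(genome_length), grid_size)
    dx = grid[1] - grid[0]
    pooled = np.concatenate([a, b])
    K = _kde_matrix(pooled, grid, h)  # (n_a + n_b, G)
    na, nb = a.size, b.size
    n = na + nb
    total = K.sum(axis=0)

    def stat(rows: np.ndarray, k: int) -> float:
        # density of the complementary group follows from the pooled total,
        # so each evaluation only sums the k rows assigned to one group
        sum_k = K[rows].sum(axis=0)
        d = sum_k / k - (total - sum_k) / (n - k)
        return float((d * d).sum() * dx)

    # observed statistic from the group densities directly (identical groups
    # give exactly zero)
    d_obs = K[:na].mean(axis=0) - K[na:].mean(axis=0)
    t_obs = float((d_obs * d_obs).sum() * dx)
    # canonical null: sort rows by position (equal positions give identical
    # kernel rows) and always permute into the smaller group, so swapping the
    # group labels leaves both T and p exactly unchanged
    K = K[np.argsort(pooled, kind="stable")]
    k = min(na, nb)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(n)[:k], k) >= t_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return DensityTestResult(t_obs, p, n_permutations, h)


def call_breakpoints(
    calls: list[DeletionCall], which: str = "both", frame: str = "std"
) -> np.ndarray:
    """Pool breakpoint positions from calls for density analysis.

    ``which`` selects ``starts``, ``ends`` or ``both`` endpoints; ``frame``
    selects rotated or standard coordinates (standard requires annotated
    calls).
    """
    if frame == "std":
        starts = [c.start_std for c in calls]
        ends = [c.end_std for c in calls]
        if any(v is None for v in starts + ends):
            raise StatsError("calls lack standard-frame annotation")
    elif frame == "rot":
        starts = [c.start_rot for c in calls]
        ends = [c.end_rot for c in calls]
    else:
        raise StatsError(f"unknown frame {frame!r}")
    if which == "starts":
        vals = starts
    elif which == "ends":
        vals = ends
    elif which == "both":
        vals = starts + ends
    else:
        raise StatsError(f"unknown breakpoint selection {which!r}")
    return np.asarray(vals, dtype=float)


def subsample_reads(items: list, n: int, seed: int = 0) -> list:
    """Uniform subsample without replacement, deterministic under ``seed``.

    If ``n`` exceeds the number of items, all items are returned.  Used to
    normalize read depth across samples before plotting or density tests.
    """
    if n >= len(items):
        return list(items)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(items), size=n, replace=False)
    return [items[i] for i in sorted(idx)]


def sensitivity_by_size(
    truth: pd.DataFrame,
    calls: list[DeletionCall],
    match_tolerance: int = 300,
) -> pd.DataFrame:
    """Fraction of expected deletions recovered, per expected size.

    A ground-truth deletion counts as detected if its read carries a call
    whose start and end breakpoints are each within ``match_tolerance`` bp of
    the truth interval.  The denominator is deletion-spanning reads only.
    """
    calls_by_read: dict[str, list[DeletionCall]] = {}
    for c in calls:
        calls_by_read.setdefault(c.read_id, []).append(c)
    rows = []
    spanning = truth[truth["contains_deletion"]]
    for size, group in spanning.groupby("template_deletion_size"):
        detected = 0
        for row in group.itertuples(index=False):
            t_start = int(row.template_deletion_start)
            t_end = t_start + int(row.template_deletion_size)
            for c in calls_by_read.get(row.read_id, []):
                if (
                    abs(c.start_rot - t_start) <= match_tolerance
                    and abs(c.end_rot - t_end) <= match_tolerance
                ):
                    detected += 1
                    break
        rows.append(
            {
                "expected_size": int(size),
                "n_spanning_reads": len(group),
                "n_detected": detected,
                "fraction_detected": detected / len(group) if len(group) else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values("expected_size").reset_index(drop=True)


def read_breakpoint_list(path) -> np.ndarray:
    """Read an external breakpoint list (MitoMap/MitoBreak-style TSV).

    Accepts one or two position columns (deletion start / end, standard
    frame); all positions are pooled into a flat array for density
    comparison against the package's own calls.
    """
    df = pd.read_csv(path, sep="\t")
    numeric = df.select_dtypes("number")
    if numeric.shape[1] == 0:
        raise StatsError(f"no numeric position columns in {path}")
    return numeric.to_numpy(dtype=float).ravel()


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, age, tissue[, ddpcr_frequency])."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise StatsError(f"sample sheet missing columns: {sorted(missing)}")
    return df
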