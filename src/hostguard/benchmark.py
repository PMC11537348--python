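"""Benchmarking of filtration runs: truth scoring, paired tests, grid search,
coverage diagnostics.

Two axes score a filtration run against ground truth: how many host reads
leaked through (``human_remaining``) and how many microbial reads were
wrongly removed (``microbial_lost``).  Paired method comparisons use the
two-sided Wilcoxon signed-rank test with zero differences dropped, exact for
small samples.  The threshold grid search sweeps the custom metric's
(threshold, minimum run length) plane — defaults 0.145–0.200 by 0.005 and
2–12 by 1, a 12 x 11 grid.  Coverage depth/breadth summaries expose the
signature of artifactual mismapping: depth concentrated in a narrow peak
(high depth, low breadth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pml import MatchIndex, compute_pml
from .scoring import ScoringConfig, classify_read, compute_score

__all__ = [
    "BenchmarkResult",
    "CoverageSummary",
    "evaluate_filtering",
    "wilcoxon_signed_rank",
    "threshold_grid_search",
    "coverage_depth_breadth",
    "share_percent",
    "boxplot_stats",
    "DEFAULT_GRID_THRESHOLDS",
    "DEFAULT_GRID_RUN_LENGTHS",
]

DEFAULT_GRID_THRESHOLDS = tuple(np.round(np.arange(0.145, 0.2005, 0.005), 3))
DEFAULT_GRID_RUN_LENGTHS = tuple(range(2, 13))

# Exact Wilcoxon null enumeration is used up to this many non-zero pairs.
_EXACT_WILCOXON_LIMIT = 25


@dataclass(frozen=True)
class BenchmarkResult:
    dataset_id: str
    n_host_total: int
    n_microbe_total: int
    human_remaining: int
    microbial_lost: int

    def __post_init__(self):
        if not 0 <= self.human_remaining <= self.n_host_total:
            raise ValueError("human_remaining out of range")
        if not 0 <= self.microbial_lost <= self.n_microbe_total:
            raise ValueError("microbial_lost out of range")

    @property
    def microbial_remaining(self) -> int:
        return self.n_microbe_total - self.microbial_lost


@dataclass(frozen=True)
class CoverageSummary:
    genome_id: str
    genome_length: int
    mean_depth: float
    breadth: float

    def __post_init__(self):
        if not 0 <= self.breadth <= 1 or self.mean_depth < 0:
            raise ValueError("invalid coverage summary")


def evaluate_filtering(
    surviving_ids: Iterable[str], truth_table: pd.DataFrame, dataset_id: str = ""
) -> BenchmarkResult:
    """Count leaked host reads and lost microbial reads.

    ``truth_table`` needs columns ``read_id`` and ``truth_label`` (values
    'host'/'microbe').  Every surviving id must appear in the table.
    """
    truth = truth_table.set_index("read_id")["truth_label"]
    surviving = set(surviving_ids)
    unknown = surviving - set(truth.index)
    if unknown:
        raise ValueError(f"surviving ids not in truth table: {sorted(unknown)[:5]}")
    host_ids = set(truth.index[truth == "host"])
    microbe_ids = set(truth.index[truth == "microbe"])
    return BenchmarkResult(
        dataset_id=dataset_id,
        n_host_total=len(host_ids),
        n_microbe_total=len(microbe_ids),
        human_remaining=len(surviving & host_ids),
        microbial_lost=len(microbe_ids - surviving),
    )


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    # Distribution of W+ over all 2^n sign assignments, by convolution over
    # doubled ranks (doubling keeps midranks integral under ties).
    doubled = np.rint(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    upper = 0
    for r in doubled:
        counts[r : upper + r + 1] += counts[: upper + 1]
        upper += r
    counts /= counts.sum()
    w2 = int(round(2 * w))
    p = counts[: w2 + 1].sum() + counts[total - w2 :].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  The statistic is
    W = min(W+, W-).  The P-value is exact (full null enumeration of the
    signed-rank-sum distribution, ties handled via midranks) for up to 25
    non-zero pairs, and a normal approximation with continuity and tie
    correction beyond.  Raises if every difference is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= _EXACT_WILCOXON_LIMIT:
        return w, _exact_signed_rank_p(ranks, w)
    mean = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
    z = (w - mean + 0.5) / np.sqrt(var)
    return w, float(min(1.0, 2 * stats.norm.cdf(z)))


def threshold_grid_search(
    labeled_reads,
    index: MatchIndex,
    thresholds: Sequence[float] = DEFAULT_GRID_THRESHOLDS,
    run_lengths: Sequence[int] = DEFAULT_GRID_RUN_LENGTHS,
) -> pd.DataFrame:
    """Sweep the custom metric's (threshold, w) grid against truth labels.

    Returns one row per grid cell with host recall (truth-host reads
    flagged), host precision (flagged reads that are truth-host; 1.0 when
    nothing is flagged, i.e. no false positives), and the fraction of
    microbial reads retained.
    """
    if not len(thresholds) or not len(run_lengths):
        raise ValueError("grid must be non-empty")
    labels = np.array([r.truth_label for r in labeled_reads])
    n_host = int((labels == "host").sum())
    n_microbe = int((labels == "microbe").sum())
    pmls = [compute_pml(r.record.sequence, index, r.record.read_id) for r in labeled_reads]
    rows = []
    for w in run_lengths:
        scores = np.array(
            [compute_score(p, ScoringConfig(metric="custom", min_run_length=w)) for p in pmls]
        )
        for thr in thresholds:
            flagged = np.round(scores, 3) >= thr
            tp = int((flagged & (labels == "host")).sum())
            fp = int((flagged & (labels == "microbe")).sum())
            rows.append(
                {
                    "threshold": float(thr),
                    "min_run_length": int(w),
                    "recall_host": tp / n_host if n_host else 0.0,
                    "precision_host": tp / (tp + fp) if (tp + fp) else 1.0,
                    "microbial_retained_fraction": (n_microbe - fp) / n_microbe
                    if n_microbe
                    else 1.0,
                }
            )
    return pd.DataFrame(rows)


def coverage_depth_breadth(
    intervals: Sequence[tuple[int, int]], genome_length: int, genome_id: str = ""
) -> CoverageSummary:
    """Mean depth and breadth of coverage from half-open alignment intervals."""
    if genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    covered_bases = 0
    union = 0
    last_end = 0
    for start, end in sorted(intervals):
        if not 0 <= start < end <= genome_length:
            raise ValueError(f"interval ({start}, {end}) out of range")
        covered_bases += end - start
        if start > last_end:
            union += end - start
            last_end = end
        elif end > last_end:
            union += end - last_end
            last_end = end
    return CoverageSummary(
        genome_id=genome_id,
        genome_length=genome_length,
        mean_depth=covered_bases / genome_length,
        breadth=union / genome_length,
    )


def share_percent(count: int, total: int) -> float:
    """Percentage share ``100 * count / total`` (reporting helper)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total


def boxplot_stats(values: Sequence[float]) -> dict:
    """Median, quartiles and 1.5-IQR whiskers (figure reporting convention)."""
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }
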