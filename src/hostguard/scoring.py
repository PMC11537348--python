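"""Per-read scores over matching-statistics distributions and host calls.

Three metrics condense a read's PML distribution into one number:

* ``maximum`` — the largest per-position match length;
* ``average`` — the arithmetic mean over all read positions;
* ``custom``  — ``(1/2L) * (max(PML) + (sum of qualifying run lengths) * ln(|R|+1))``
  where ``R`` is the set of matching runs strictly longer than the minimum
  run length ``w``.  The log factor magnifies scores of reads with several
  long contiguous matching stretches, which discriminates host reads whose
  matches are broken by variants from microbial reads with incidental short
  matches.

Default decision thresholds come from a theoretical host read of length 150
carrying a single contiguous matching run of length 31 (one exact 31-mer
match): maximum -> 31, average -> 3.306, custom -> 0.175 at w=5.  A read is
called host when its score reaches the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .pml import PMLDistribution

__all__ = [
    "MatchRun",
    "ScoringConfig",
    "ReadScore",
    "extract_runs",
    "score_maximum",
    "score_average",
    "score_custom",
    "compute_score",
    "derive_theoretical_threshold",
    "classify_read",
    "DEFAULT_THRESHOLDS",
]

METRICS = ("maximum", "average", "custom")

#: Thresholds implied by the theoretical read (L=150, one run of 31, w=5),
#: at the precision they are conventionally quoted.
DEFAULT_THRESHOLDS = {"maximum": 31.0, "average": 3.306, "custom": 0.175}
DEFAULT_MIN_RUN_LENGTH = 5


@dataclass(frozen=True)
class MatchRun:
    """One maximal contiguous matching stretch.

    ``length`` is the peak PML value inside the ramp segment, i.e. the
    length of the underlying exact match.
    """

    start: int
    length: int


@dataclass(frozen=True)
class ScoringConfig:
    """Metric choice, decision threshold and minimum run length.

    ``precision`` controls the host call: scores are rounded to this many
    decimals before comparison with the threshold, so the threshold-defining
    read itself classifies as host.  ``None`` compares at full precision.
    """

    metric: str = "custom"
    threshold: float | None = None
    min_run_length: int = DEFAULT_MIN_RUN_LENGTH
    precision: int | None = 3

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.min_run_length < 0:
            raise ValueError("min_run_length must be non-negative")
        if self.threshold is None:
            object.__setattr__(self, "threshold", DEFAULT_THRESHOLDS[self.metric])


@dataclass(frozen=True)
class ReadScore:
    read_id: str
    metric: str
    score: float
    is_host: bool


def extract_runs(pml: PMLDistribution) -> list[MatchRun]:
    """Segment a distribution into maximal matching runs.

    A segment extends while ``values[i] == values[i-1] + 1``; its run length
    is the peak PML value within the segment.  Segments whose peak is 0
    (no match at all) produce no run.
    """
    values = pml.values
    runs: list[MatchRun] = []
    seg_start = 0
    peak = values[0]
    for i in range(1, len(values)):
        if values[i] == values[i - 1] + 1:
            peak = max(peak, values[i])
        else:
            if peak > 0:
                runs.append(MatchRun(seg_start, peak))
            seg_start = i
            peak = values[i]
    if peak > 0:
        runs.append(MatchRun(seg_start, peak))
    return runs


def score_maximum(pml: PMLDistribution) -> float:
    """Largest per-position match length; 0 when nothing matches."""
    return float(max(pml.values))


def score_average(pml: PMLDistribution) -> float:
    """Arithmetic mean of the distribution over all L positions."""
    return sum(pml.values) / pml.L


def score_custom(pml: PMLDistribution, w: int = DEFAULT_MIN_RUN_LENGTH) -> float:
    """Run-magnified score ``(1/2L)(max + (Σ_{r∈R} len(r))·ln(|R|+1))``.

    ``R`` holds runs with length strictly greater than ``w``; with ``R``
    empty the score reduces to ``max(PML)/(2L)``.
    """
    if w < 0:
        raise ValueError("minimum run length w must be non-negative")
    qualifying = [run.length for run in extract_runs(pml) if run.length > w]
    total = sum(qualifying) * math.log(len(qualifying) + 1)
    return (max(pml.values) + total) / (2 * pml.L)


def compute_score(pml: PMLDistribution, config: ScoringConfig) -> float:
    if config.metric == "maximum":
        return score_maximum(pml)
    if config.metric == "average":
        return score_average(pml)
    return score_custom(pml, config.min_run_length)


def derive_theoretical_threshold(
    metric: str, L: int = 150, run_length: int = 31, w: int = DEFAULT_MIN_RUN_LENGTH
) -> float:
    """Score the theoretical host read: one ramp 1..run_length, zeros elsewhere.

    Returns the full-precision metric value; callers quote it truncated
    (average) or rounded (custom) to three decimals.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if run_length > L:
        raise ValueError("run_length cannot exceed read length L")
    values = list(range(1, run_length + 1)) + [0] * (L - run_length)
    pml = PMLDistribution("theoretical", values)
    if metric == "custom":
        return score_custom(pml, w)
    return compute_score(pml, ScoringConfig(metric=metric))


def classify_read(pml: PMLDistribution, config: ScoringConfig) -> ReadScore:
    """Score a read and call it host when the score reaches the threshold.

    The comparison rounds the score to ``config.precision`` decimals (the
    precision at which default thresholds are stated), making the call
    stable at the threshold boundary.
    """
    score = compute_score(pml, config)
    compared = round(score, config.precision) if config.precision is not None else score
    return ReadScore(
        read_id=pml.read_id,
        metric=config.metric,
        score=score,
        is_host=compared >= config.threshold,
    )
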