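"""Labeled synthetic genomes and reads for filtration benchmarking.

The generator produces i.i.d.-uniform host and microbe genomes, substitution-
only reads with ground-truth source intervals, and 50/50 (or arbitrary)
host/microbe mixtures.  Two failure mechanisms of real host filtration can be
planted deliberately:

* ``holdout_region`` removes an interval from the *filtering* copy of the
  host genome while leaving the full copy intact — emulating host reads from
  genome regions absent from an incomplete reference (the Y-chromosome leak).
* ``inject_shared_segment`` splices one identical (typically low-complexity)
  segment into both a host and a microbe genome — emulating the shared
  sequence that lets leaked host reads mismap to microbial references.

All outputs are pure functions of their inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import reverse_complement

from .pipeline import ReadRecord

__all__ = [
    "SyntheticGenome",
    "SimulationConfig",
    "LabeledRead",
    "generate_genome",
    "holdout_region",
    "inject_shared_segment",
    "simulate_reads",
    "mix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: Constant quality (Q37) — the scoring layer consumes sequence only.
_QUALITY_CHAR = "F"


@dataclass(frozen=True)
class SyntheticGenome:
    label: str  # "host" or "microbe"
    identifier: str
    sequence: str
    seed: int

    def __post_init__(self):
        if self.label not in ("host", "microbe"):
            raise ValueError("label must be 'host' or 'microbe'")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimulationConfig:
    """Read-simulation parameters.

    ``error_rate`` is the per-base substitution probability; indels are not
    modelled.  ``fragment_length`` applies in paired mode only (inward-facing
    mates, no size jitter).
    """

    read_length: int = 150
    error_rate: float = 0.0
    n_reads: int = 1000
    paired: bool = False
    fragment_length: int = 400
    host_proportion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.host_proportion <= 1:
            raise ValueError("host_proportion must be in [0, 1]")
        if self.paired and self.fragment_length < 2 * self.read_length:
            raise ValueError("fragment_length must be >= 2 * read_length in paired mode")


@dataclass(frozen=True)
class LabeledRead:
    """A simulated read with its ground-truth origin.

    The source interval is half-open, 0-based, on the genome's forward
    strand; ``strand`` records which strand the read was drawn from.
    """

    record: ReadRecord
    truth_label: str
    genome_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end - self.start != len(self.record):
            raise ValueError("source interval length must equal read length")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def generate_genome(length: int, seed: int, label: str, identifier: str | None = None) -> SyntheticGenome:
    """I.i.d.-uniform random genome over {A,C,G,T}; reproducible per seed."""
    if length < 300:
        raise ValueError("genome length must be >= 300")
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    if identifier is None:
        identifier = f"{label}_g{seed}"
    return SyntheticGenome(label=label, identifier=identifier, sequence=seq, seed=seed)


def holdout_region(genome: SyntheticGenome, start: int, end: int) -> tuple[SyntheticGenome, SyntheticGenome]:
    """Return (filter_reference, full_reference) with [start, end) held out.

    The filter reference concatenates the flanks; the full reference is the
    genome unchanged.  Reads wholly inside the held-out interval cannot
    exact-seed-match the filter reference beyond flank overlap.
    """
    if not 0 <= start < end <= len(genome):
        raise ValueError(f"invalid hold-out interval [{start}, {end}) for length {len(genome)}")
    filtered = replace(
        genome,
        identifier=f"{genome.identifier}_holdout_{start}_{end}",
        sequence=genome.sequence[:start] + genome.sequence[end:],
    )
    return filtered, genome


def inject_shared_segment(
    host_genome: SyntheticGenome,
    microbe_genome: SyntheticGenome,
    segment: str,
    positions: tuple[int, int],
) -> tuple[SyntheticGenome, SyntheticGenome]:
    """Splice one identical segment into both genomes at the given positions."""
    pos_host, pos_microbe = positions
    out = []
    for genome, pos in ((host_genome, pos_host), (microbe_genome, pos_microbe)):
        if not 0 <= pos <= len(genome):
            raise ValueError(f"splice position {pos} out of range for {genome.identifier!r}")
        out.append(
            replace(genome, sequence=genome.sequence[:pos] + segment + genome.sequence[pos:])
        )
    return out[0], out[1]


def _substitute(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < error_rate
    if hit.any():
        # replace each hit base with a uniformly chosen *different* base
        idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=int(hit.sum()))
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(genome: SyntheticGenome, config: SimulationConfig) -> list[LabeledRead]:
    """Draw reads uniformly from both strands with substitution errors."""
    rl = config.read_length
    if len(genome) < rl or (config.paired and len(genome) < config.fragment_length):
        raise ValueError("genome shorter than the requested read/fragment length")
    rng = np.random.default_rng(config.seed)
    reads: list[LabeledRead] = []
    quality = _QUALITY_CHAR * rl
    for i in range(config.n_reads):
        if config.paired:
            fstart = int(rng.integers(0, len(genome) - config.fragment_length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            w1 = (fstart, fstart + rl)
            w2 = (fstart + config.fragment_length - rl, fstart + config.fragment_length)
            if strand == "-":
                w1, w2 = w2, w1
            for mate, (s, e) in ((1, w1), (2, w2)):
                raw = genome.sequence[s:e]
                mate_strand = strand if mate == 1 else ("-" if strand == "+" else "+")
                if mate_strand == "-":
                    raw = reverse_complement(raw)
                seq = _substitute(raw, rng, config.error_rate)
                rid = f"{genome.identifier}_r{i}"
                reads.append(
                    LabeledRead(
                        record=ReadRecord(rid, seq, quality, mate=mate),
                        truth_label=genome.label,
                        genome_id=genome.identifier,
                        start=s,
                        end=e,
                        strand=mate_strand,
                    )
                )
        else:
            start = int(rng.integers(0, len(genome) - rl + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            raw = genome.sequence[start : start + rl]
            if strand == "-":
                raw = reverse_complement(raw)
            seq = _substitute(raw, rng, config.error_rate)
            reads.append(
                LabeledRead(
                    record=ReadRecord(f"{genome.identifier}_r{i}", seq, quality),
                    truth_label=genome.label,
                    genome_id=genome.identifier,
                    start=start,
                    end=start + rl,
                    strand=strand,
                )
            )
    return reads


def mix(
    host_reads: list[LabeledRead],
    microbe_reads: list[LabeledRead],
    host_proportion: float,
    seed: int,
    n_total: int | None = None,
) -> list[LabeledRead]:
    """Deterministically shuffled mixture with an exact class composition."""
    if not 0 <= host_proportion <= 1:
        raise ValueError("host_proportion must be in [0, 1]")
    if n_total is None:
        n_total = len(host_reads) + len(microbe_reads)
    n_host = round(n_total * host_proportion)
    n_microbe = n_total - n_host
    if n_host > len(host_reads) or n_microbe > len(microbe_reads):
        raise ValueError(
            f"insufficient reads: need {n_host} host / {n_microbe} microbe, "
            f"have {len(host_reads)} / {len(microbe_reads)}"
        )
    dataset = list(host_reads[:n_host]) + list(microbe_reads[:n_microbe])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    return [dataset[i] for i in order]
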