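"""Host-filtration pipeline: length filter, alignment surrogate, index stage.

Three method topologies are supported, differing in how many reference sets
are used for the (fast, per-genome) alignment-style stage before the final
aggregated-index stage:

* Method 1 — align against two single references in sequence, then score the
  survivors against one aggregated index of all references.
* Method 2 — align sequentially against every reference, then the aggregated
  index stage.
* Method 3 — the aggregated index stage only.

The alignment stage here is an exact-seed surrogate: a read "maps" when its
longest exact match to the stage reference reaches the seed length ``S``
(default 31).  This keeps the pipeline deterministic and desk-scale while
preserving the stage topology; an external aligner back-end could be plugged
in behind the same interface.

For paired-end data, a pair survives only if BOTH mates survive every
host-removal stage; single surviving mates (orphans) are dropped and counted,
mirroring the both-mates-unmapped extraction convention of SAM-flag based
filtering.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pml import MatchIndex, ReferenceCollection, build_index, compute_pml, max_exact_match
from .scoring import ScoringConfig, classify_read

__all__ = [
    "ReadRecord",
    "ReadPair",
    "MethodConfig",
    "StageCount",
    "FilterReport",
    "length_filter",
    "alignment_filter",
    "index_filter",
    "pair_reads",
    "pair_sync",
    "run_method",
]

_ALPHABET = frozenset("ACGTN")
_MATE_SUFFIX = re.compile(r"(/[12]|[ \t].*)$")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with its quality string and optional mate tag."""

    read_id: str
    sequence: str
    quality: str
    mate: int | None = None

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.read_id!r}: sequence/quality length mismatch")
        bad = set(self.sequence.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id!r}: characters outside alphabet {sorted(bad)}")
        if self.mate not in (None, 1, 2):
            raise ValueError("mate must be None, 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    read1: ReadRecord
    read2: ReadRecord

    @property
    def read_id(self) -> str:
        return self.read1.read_id


@dataclass(frozen=True)
class MethodConfig:
    """Topology and parameters of one filtration run.

    ``alignment_refs`` / ``index_refs`` are labels resolved against a
    reference catalog at run time; ``min_length`` is the pre-filter length
    cutoff in bp and ``seed_length`` the exact-seed length S of the
    alignment surrogate.
    """

    method: int
    alignment_refs: tuple[str, ...]
    index_refs: tuple[str, ...]
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    min_length: int = 45
    seed_length: int = 31
    paired: bool = False

    def __post_init__(self):
        object.__setattr__(self, "alignment_refs", tuple(self.alignment_refs))
        object.__setattr__(self, "index_refs", tuple(self.index_refs))
        if self.method not in (1, 2, 3):
            raise ValueError("method must be 1, 2 or 3")
        if self.method == 1 and len(self.alignment_refs) != 2:
            raise ValueError("method 1 requires exactly two alignment references")
        if self.method == 2 and not self.alignment_refs:
            raise ValueError("method 2 requires at least one alignment reference")
        if self.method == 3 and self.alignment_refs:
            raise ValueError("method 3 uses no alignment references")
        if not self.index_refs:
            raise ValueError("an index stage reference set is required")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_input: int
    n_removed: int
    n_surviving: int

    def __post_init__(self):
        if self.n_input != self.n_removed + self.n_surviving:
            raise ValueError(f"stage {self.stage!r}: counts do not reconcile")


@dataclass
class FilterReport:
    """Per-stage read accounting for one filtration run."""

    stages: list[StageCount] = field(default_factory=list)
    orphan_pairs: int = 0

    def add(self, stage: str, n_input: int, n_removed: int) -> None:
        self.stages.append(StageCount(stage, n_input, n_removed, n_input - n_removed))

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "input": s.n_input,
                    "removed": s.n_removed,
                    "surviving": s.n_surviving,
                }
                for s in self.stages
            ],
            "orphan_pairs": self.orphan_pairs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)


def length_filter(
    reads: Sequence[ReadRecord], min_length: int
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Split reads into (kept, removed) by an inclusive minimum length."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [r for r in reads if len(r) >= min_length]
    removed = [r for r in reads if len(r) < min_length]
    return kept, removed


def alignment_filter(
    reads: Sequence[ReadRecord], ref_index: MatchIndex, seed_length: int
) -> tuple[set[str], list[ReadRecord]]:
    """Exact-seed alignment surrogate: mapped iff max exact match >= S."""
    if seed_length < 1:
        raise ValueError("seed_length must be >= 1")
    mapped_ids: set[str] = set()
    unmapped: list[ReadRecord] = []
    for read in reads:
        if max_exact_match(read.sequence, ref_index) >= seed_length:
            mapped_ids.add(read.read_id)
        else:
            unmapped.append(read)
    return mapped_ids, unmapped


def index_filter(
    reads: Sequence[ReadRecord], index: MatchIndex, scoring: ScoringConfig
) -> tuple[set[str], list[ReadRecord]]:
    """Score each read's PML distribution; host-called reads are removed."""
    host_ids: set[str] = set()
    nonhost: list[ReadRecord] = []
    for read in reads:
        pml = compute_pml(read.sequence, index, read_id=read.read_id)
        if classify_read(pml, scoring).is_host:
            host_ids.add(read.read_id)
        else:
            nonhost.append(read)
    return host_ids, nonhost


def _strip_mate_tag(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def pair_reads(reads1: Sequence[ReadRecord], reads2: Sequence[ReadRecord]) -> list[ReadPair]:
    """Match two mate files into pairs by shared identifier.

    Trailing ``/1``, ``/2`` or whitespace-delimited mate tags are stripped.
    Duplicate identifiers within one mate file are an input error; unpaired
    identifiers are dropped.
    """
    pairs = []
    by_id: dict[str, ReadRecord] = {}
    for read in reads2:
        base = _strip_mate_tag(read.read_id)
        if base in by_id:
            raise ValueError(f"duplicate read id {base!r} in mate-2 input")
        by_id[base] = ReadRecord(base, read.sequence, read.quality, mate=2)
    seen: set[str] = set()
    for read in reads1:
        base = _strip_mate_tag(read.read_id)
        if base in seen:
            raise ValueError(f"duplicate read id {base!r} in mate-1 input")
        seen.add(base)
        mate = by_id.get(base)
        if mate is not None:
            pairs.append(ReadPair(ReadRecord(base, read.sequence, read.quality, mate=1), mate))
    return pairs


def pair_sync(
    surviving_ids: Iterable[str], pairs: Sequence[ReadPair]
) -> tuple[list[ReadPair], int]:
    """Retain pairs whose BOTH mates survived; count dropped orphans."""
    surviving = set(surviving_ids)
    retained: list[ReadPair] = []
    orphans = 0
    for pair in pairs:
        id1 = _mate_key(pair.read1)
        id2 = _mate_key(pair.read2)
        alive1, alive2 = id1 in surviving, id2 in surviving
        if alive1 and alive2:
            retained.append(pair)
        elif alive1 or alive2:
            orphans += 1
    return retained, orphans


def _mate_key(read: ReadRecord) -> str:
    return f"{read.read_id}/{read.mate}" if read.mate else read.read_id


def _resolve_index(label: str, catalog: Mapping[str, object], cache: dict) -> MatchIndex:
    if label not in catalog:
        raise KeyError(f"reference label {label!r} missing from catalog")
    if label not in cache:
        entry = catalog[label]
        cache[label] = entry if isinstance(entry, MatchIndex) else build_index(entry)
    return cache[label]


def _aggregate_index(labels: Sequence[str], catalog: Mapping[str, object], cache: dict) -> MatchIndex:
    key = ("__aggregate__",) + tuple(labels)
    if key not in cache:
        records = []
        for label in labels:
            if label not in catalog:
                raise KeyError(f"reference label {label!r} missing from catalog")
            entry = catalog[label]
            refs = entry.references if isinstance(entry, MatchIndex) else entry
            records.extend(refs.records)
        cache[key] = build_index(ReferenceCollection(records))
    return cache[key]


def run_method(
    reads_or_pairs: Sequence[ReadRecord] | Sequence[ReadPair],
    config: MethodConfig,
    catalog: Mapping[str, ReferenceCollection | MatchIndex],
) -> tuple[list, FilterReport]:
    """Execute one method topology end to end.

    Stages run in order: length filter, then each alignment surrogate stage,
    then the aggregated index stage; pair re-synchronization follows every
    removal stage in paired mode.  Returns the surviving reads (or pairs) in
    input order together with a reconciling per-stage report.
    """
    report = FilterReport()
    cache: dict = {}
    paired = config.paired

    if paired:
        pairs: list[ReadPair] = list(reads_or_pairs)  # type: ignore[arg-type]
        reads = [r for p in pairs for r in (p.read1, p.read2)]
        reads = [
            ReadRecord(_mate_key(r), r.sequence, r.quality, mate=r.mate) for r in reads
        ]
    else:
        reads = list(reads_or_pairs)  # type: ignore[arg-type]

    def sync(stage: str) -> None:
        nonlocal reads, pairs
        if not paired:
            return
        alive = {r.read_id for r in reads}
        retained, orphans = pair_sync(alive, pairs)
        report.orphan_pairs += orphans
        keep_ids = {_mate_key(r) for p in retained for r in (p.read1, p.read2)}
        n_in = len(reads)
        reads = [r for r in reads if r.read_id in keep_ids]
        report.add(f"pair_sync_after_{stage}", n_in, n_in - len(reads))
        pairs = retained

    kept, removed = length_filter(reads, config.min_length)
    report.add("length_filter", len(reads), len(removed))
    reads = kept
    sync("length_filter")

    for label in config.alignment_refs:
        index = _resolve_index(label, catalog, cache)
        mapped_ids, reads_next = alignment_filter(reads, index, config.seed_length)
        report.add(f"align_{label}", len(reads), len(mapped_ids))
        reads = reads_next
        sync(f"align_{label}")

    index = _aggregate_index(config.index_refs, catalog, cache)
    host_ids, reads_next = index_filter(reads, index, config.scoring)
    report.add("index_filter", len(reads), len(host_ids))
    reads = reads_next
    sync("index_filter")

    if paired:
        return pairs, report
    return reads, report
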