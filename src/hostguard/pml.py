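"""Exact per-position matching statistics of reads against a reference collection.

Indexing-based host filters score a read by how long its substrings match a
(pan)genome reference set.  This module computes, for every read position
``i``, the length of the longest suffix of ``read[0..i]`` that occurs exactly
somewhere in the reference collection (forward or reverse-complement strand)
— the classical *matching statistics*.  Approximate variants of this quantity
(pseudo-matching lengths) are what compressed-index tools report; here the
exact value is computed so that every downstream score is deterministic and
verifiable against a brute-force oracle.

Implementation: a suffix automaton over the concatenation of both strands of
all references, separated by sentinel characters, queried with the standard
matching-statistics walk.  Build and query are linear in reference and read
length; intended for desk-scale references (up to a few megabases).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "ReferenceCollection",
    "MatchIndex",
    "PMLDistribution",
    "build_index",
    "compute_pml",
    "max_exact_match",
]

_ALPHABET = frozenset("ACGTN")
# Sentinel separates reference strands inside the automaton text and replaces
# N, which must never match any read character (including N).
_SENTINEL = "\x00"


@dataclass(frozen=True)
class ReferenceCollection:
    """A named set of DNA sequences over {A,C,G,T,N}.

    Sequences are upper-cased on construction; characters outside the
    alphabet are rejected.  At least one non-empty record is required.
    """

    records: tuple[tuple[str, str], ...]

    def __init__(self, records):
        records = tuple((str(name), str(seq).upper()) for name, seq in records)
        if not records:
            raise ValueError("reference collection must contain at least one record")
        for name, seq in records:
            if not seq:
                raise ValueError(f"reference record {name!r} has an empty sequence")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"reference record {name!r} contains characters outside "
                    f"{{A,C,G,T,N}}: {sorted(bad)}"
                )
        object.__setattr__(self, "records", records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceCollection":
        """Load a (possibly gzip-compressed) multi-record FASTA file."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
        return cls(records)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def __iter__(self):
        return iter(self.records)


class _SuffixAutomaton:
    """Suffix automaton recognising every substring of the input text."""

    __slots__ = ("next", "link", "length")

    def __init__(self, text: str):
        self.next: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        last = 0
        for ch in text:
            last = self._extend(last, ch)

    def _extend(self, last: int, ch: str) -> int:
        nxt, link, length = self.next, self.link, self.length
        cur = len(nxt)
        nxt.append({})
        link.append(-1)
        length.append(length[last] + 1)
        p = last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
            return cur
        q = nxt[p][ch]
        if length[p] + 1 == length[q]:
            link[cur] = q
            return cur
        clone = len(nxt)
        nxt.append(dict(nxt[q]))
        link.append(link[q])
        length.append(length[p] + 1)
        while p != -1 and nxt[p].get(ch) == q:
            nxt[p][ch] = clone
            p = link[p]
        link[q] = clone
        link[cur] = clone
        return cur

    def contains(self, pattern: str) -> bool:
        state = 0
        for ch in pattern:
            state = self.next[state].get(ch, -1)
            if state == -1:
                return False
        return True

    def matching_statistics(self, query: str) -> list[int]:
        nxt, link, length = self.next, self.link, self.length
        state, matched = 0, 0
        out = []
        for ch in query:
            while state != 0 and ch not in nxt[state]:
                state = link[state]
                matched = length[state]
            if ch in nxt[state]:
                state = nxt[state][ch]
                matched += 1
            else:
                state, matched = 0, 0
            out.append(matched)
        return out


class MatchIndex:
    """Exact substring index over both strands of a reference collection.

    A string is *present* iff it occurs with no mismatches in some reference
    sequence or its reverse complement.  ``N`` never matches any character.
    """

    def __init__(self, refs: ReferenceCollection):
        if not isinstance(refs, ReferenceCollection):
            refs = ReferenceCollection(refs)
        parts = []
        for _, seq in refs:
            parts.append(seq.replace("N", _SENTINEL))
            parts.append(_SENTINEL)
            parts.append(reverse_complement(seq).replace("N", _SENTINEL))
            parts.append(_SENTINEL)
        self._automaton = _SuffixAutomaton("".join(parts))
        self.references = refs

    def contains(self, sequence: str) -> bool:
        """Exact membership of ``sequence`` on either indexed strand."""
        sequence = _check_query(sequence)
        if "N" in sequence:
            return False
        return self._automaton.contains(sequence)

    def matching_statistics(self, sequence: str) -> list[int]:
        return self._automaton.matching_statistics(_check_query(sequence))


@dataclass(frozen=True)
class PMLDistribution:
    """Per-position longest-suffix-match lengths for one read.

    ``values[i]`` is the length of the longest suffix of ``read[0..i]``
    present in the index.  Valid distributions satisfy the matching-statistics
    ramp property ``values[i] <= values[i-1] + 1`` and ``values[i] <= i + 1``.
    """

    read_id: str
    values: tuple[int, ...]

    def __init__(self, read_id: str, values):
        values = tuple(int(v) for v in values)
        if not values:
            raise ValueError("PML distribution must cover at least one position")
        if values[0] not in (0, 1):
            raise ValueError("first matching-statistics value must be 0 or 1")
        for i, v in enumerate(values):
            if v < 0 or v > i + 1:
                raise ValueError(f"value {v} at position {i} is out of range")
            if i and v > values[i - 1] + 1:
                raise ValueError(
                    f"ramp property violated at position {i}: "
                    f"{v} > {values[i - 1]} + 1"
                )
        object.__setattr__(self, "read_id", str(read_id))
        object.__setattr__(self, "values", values)

    @property
    def L(self) -> int:
        """Read length (number of positions)."""
        return len(self.values)


def _check_query(sequence: str) -> str:
    sequence = str(sequence).upper()
    if not sequence:
        raise ValueError("query sequence must be non-empty")
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValueError(f"query contains characters outside {{A,C,G,T,N}}: {sorted(bad)}")
    return sequence


def build_index(refs: ReferenceCollection) -> MatchIndex:
    """Build an exact substring index over forward and reverse strands."""
    return MatchIndex(refs)


def compute_pml(read_sequence: str, index: MatchIndex, read_id: str = "") -> PMLDistribution:
    """Exact matching statistics of a read against an index."""
    return PMLDistribution(read_id, index.matching_statistics(read_sequence))


def max_exact_match(read_sequence: str, index: MatchIndex) -> int:
    """Length of the longest exact substring shared with any indexed strand."""
    return max(index.matching_statistics(read_sequence))
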