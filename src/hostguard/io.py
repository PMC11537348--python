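"""File-format plumbing: FASTA/FASTQ via Biopython, TSV tables via pandas.

All readers accept gzip-compressed input by file extension.  The genotype
panel TSV has one row per site (first column ``site_id``) and one column per
sample with dosage values 0/1/2 or NA; frequencies are (site_id, p) and
pileups (site_id, n, k) with k counting reference-supporting reads.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pipeline import ReadRecord
from .pml import ReferenceCollection
from .reid import MISSING, GenotypePanel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_truth_table",
    "write_truth_table",
    "read_genotype_panel",
    "read_allele_frequencies",
    "read_pileup",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def read_fasta(path: str | Path) -> ReferenceCollection:
    return ReferenceCollection.from_fasta(path)


def write_fasta(records, path: str | Path) -> None:
    """Write (identifier, sequence) pairs or SyntheticGenome objects."""
    with _open_text(path, "wt") as handle:
        for item in records:
            if hasattr(item, "identifier"):
                name, seq = item.identifier, item.sequence
            else:
                name, seq = item
            SeqIO.write(SeqRecord(Seq(seq), id=name, description=""), handle, "fasta")


def read_fastq(path: str | Path, mate: int | None = None) -> list[ReadRecord]:
    with _open_text(path) as handle:
        return [
            ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
                mate=mate,
            )
            for rec in SeqIO.parse(handle, "fastq")
        ]


def write_fastq(reads, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            record = read.record if hasattr(read, "record") else read
            handle.write(f"@{record.read_id}\n{record.sequence}\n+\n{record.quality}\n")


def write_truth_table(labeled_reads, path: str | Path) -> None:
    rows = [
        {
            "read_id": r.record.read_id,
            "truth_label": r.truth_label,
            "genome_id": r.genome_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
        }
        for r in labeled_reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genotype_panel(path: str | Path) -> GenotypePanel:
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    site_ids = table.iloc[:, 0].tolist()
    samples = table.columns[1:].tolist()
    genotypes = table.iloc[:, 1:].to_numpy(dtype=float)
    genotypes = pd.DataFrame(genotypes).fillna(MISSING).to_numpy(dtype="int8")
    return GenotypePanel(site_ids, samples, genotypes)


def read_allele_frequencies(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    return pd.Series(table.iloc[:, 1].to_numpy(dtype=float), index=table.iloc[:, 0])


def read_pileup(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    return table[["site_id", "n", "k"]]
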