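"""File I/O and basic sequence containers.

FASTA is read and written through Biopython; GFF3 gene tracks and the
tabular evidence/hit files are plain pandas tables.  All on-disk
coordinates are 1-based inclusive (GFF3 / BLAST-tabular convention);
in-memory slicing helpers convert to Python's 0-based half-open form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """Named DNA sequences for one strain; the unit of search and annotation."""

    genome_id: str
    contigs: dict[str, str]

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of contig[start..end] (1-based inclusive), oriented by strand."""
        seq = self.contigs[contig][start - 1 : end]
        return seq if strand == "+" else revcomp(seq)

    @classmethod
    def from_fasta(cls, path: str | Path, genome_id: str | None = None) -> "GenomeAssembly":
        path = Path(path)
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(genome_id or path.stem, contigs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {id: sequence} with sequences upper-cased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a 9-column DataFrame (comments skipped)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=GFF3_COLUMNS,
        dtype={"start": int, "end": int},
    )
    return df


def write_gff3(path: str | Path, rows: pd.DataFrame | Iterable[dict]) -> None:
    df = pd.DataFrame(rows, columns=GFF3_COLUMNS)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def parse_gff3_attributes(attributes: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attributes.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key] = value
    return out


def format_gff3_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, **kwargs)
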