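"""Annotated genome container and FASTA/GFF3 I/O.

Coordinates are 1-based inclusive throughout (GFF3 convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad gene interval {self.gene_id}: {self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """A DNA sequence with an ordered, non-overlapping gene annotation."""

    id: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not re.fullmatch("[ACGT]*", self.sequence):
            raise ValueError(f"genome {self.id}: sequence contains non-ACGT characters")
        prev_end = 0
        prev_start = 0
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(f"gene {g.gene_id} extends past end of {self.id}")
            if g.start < prev_start:
                raise ValueError(f"genes of {self.id} are not sorted by start")
            if g.start <= prev_end:
                raise ValueError(f"gene {g.gene_id} overlaps previous gene")
            prev_end, prev_start = g.end, g.start

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, gene_id: str) -> str:
        g = self.gene(gene_id)
        seq = self.sequence[g.start - 1 : g.end]
        return revcomp(seq) if g.strand == "-" else seq

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# I/O


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path, gff_path: str | Path) -> None:
    write_fasta(fasta_path, {genome.id: genome.sequence})
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{genome.id}\tsyntrack\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_genome(fasta_path: str | Path, gff_path: str | Path) -> AnnotatedGenome:
    seqs = read_fasta(fasta_path)
    if len(seqs) != 1:
        raise ValueError(f"{fasta_path} must contain exactly one reference sequence")
    seq_id, sequence = next(iter(seqs.items()))
    df = pd.read_csv(
        gff_path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    genes = []
    for row in df.itertuples():
        if row.type != "gene" or row.seqid != seq_id:
            continue
        m = re.search(r"ID=([^;]+)", row.attributes)
        gid = m.group(1) if m else f"gene_{row.start}"
        genes.append(Gene(gid, int(row.start), int(row.end), row.strand))
    genes.sort(key=lambda g: g.start)
    return AnnotatedGenome(seq_id, sequence, genes)
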