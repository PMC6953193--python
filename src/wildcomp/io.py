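"""Genome containers and readers/writers for the standard flat formats.

Internally every coordinate is 0-based half-open.  GFF3 is read and written
with the usual 1-based inclusive convention, VCF positions are 1-based, BED
and BEDGRAPH are 0-based half-open.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class WildcompError(Exception):
    """Base class for all package errors."""


class ParseError(WildcompError):
    """Malformed or inconsistent input file."""


@dataclass(frozen=True)
class Gene:
    """A gene model: 0-based half-open genomic interval on one scaffold."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ParseError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ParseError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """Scaffold sequences plus ordered gene models.

    The coordinate backbone for synteny, PAV calling and read mapping: genes
    are kept sorted by (scaffold, start) and indexed by identifier.
    """

    def __init__(self, name: str, sequences: Mapping[str, str], genes: Iterable[Gene]):
        self.name = name
        self.sequences = {k: str(v).upper() for k, v in sequences.items()}
        self.genes = sorted(genes, key=lambda g: (g.scaffold, g.start, g.gene_id))
        self._by_id: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ParseError(f"duplicate gene ID {g.gene_id!r}")
            if g.scaffold not in self.sequences:
                raise ParseError(f"gene {g.gene_id}: unknown scaffold {g.scaffold!r}")
            if g.end > len(self.sequences[g.scaffold]):
                raise ParseError(
                    f"gene {g.gene_id}: end {g.end} beyond scaffold "
                    f"{g.scaffold} length {len(self.sequences[g.scaffold])}"
                )
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, scaffold: str) -> list[Gene]:
        return [g for g in self.genes if g.scaffold == scaffold]

    def scaffold_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sequences.items()}

    def gene_sequence(self, gene_id: str) -> str:
        """Genomic sequence of the gene in transcript orientation."""
        g = self._by_id[gene_id]
        s = self.sequences[g.scaffold][g.start : g.end]
        return revcomp(s) if g.strand == "-" else s

    def cdna_set(self) -> dict[str, str]:
        """All gene sequences keyed by identifier (gene span = cDNA here)."""
        return {g.gene_id: self.gene_sequence(g.gene_id) for g in self.genes}


class Read(NamedTuple):
    read_id: str
    seq: str


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[Read]:
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Read], path: str | os.PathLike, quality: int = 40) -> None:
    # constant Phred+33 quality; the simulator does not model quality decay
    qchar = chr(33 + quality)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qchar * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genome: GenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name in genome.sequences:
            fh.write(f"##sequence-region {name} 1 {len(genome.sequences[name])}\n")
        for g in genome.genes:
            fh.write(
                f"{g.scaffold}\twildcomp\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_genome(
    fasta_path: str | os.PathLike, gff3_path: str | os.PathLike, name: str | None = None
) -> GenomeAnnotation:
    """Load a genome from FASTA + GFF3 `gene` features.

    Gene coordinates are converted to 0-based half-open; duplicate IDs,
    missing scaffolds and out-of-bounds genes raise :class:`ParseError`.
    """
    sequences = read_fasta(fasta_path)
    if not sequences:
        raise ParseError(f"{fasta_path}: no sequences")
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several concrete types
        raise ParseError(f"{gff3_path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ParseError(f"{gff3_path}: gene feature without ID at line {feat.start}")
        genes.append(
            Gene(
                gene_id=ids[0],
                scaffold=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
            )
        )
    return GenomeAnnotation(name or os.path.basename(str(fasta_path)), sequences, genes)


# ---------------------------------------------------------------------------
# TSV helpers


def write_tsv(rows: Iterable[Mapping], path: str | os.PathLike, columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def tsv_text(rows: Iterable[Mapping], columns: list[str]) -> str:
    buf = _io.StringIO()
    buf.write("\t".join(columns) + "\n")
    for row in rows:
        buf.write("\t".join(str(row[c]) for c in columns) + "\n")
    return buf.getvalue()
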