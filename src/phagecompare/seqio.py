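"""Sequence and feature-table I/O.

Sequences are plain upper-case strings over a strict alphabet: nucleotides
``ACGTN`` (only ``N`` is accepted as an ambiguity code) or the 20 standard
amino acids plus ``X`` and ``*``.  Feature coordinates are 1-based inclusive
throughout the package (GFF3 convention); a feature of length L spans
``end - start + 1 == L``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlphabetError, CoordinateError, FormatError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_TSV_COLUMNS = [
    "genome_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "product",
    "family_labels",
]


def _infer_alphabet(residues: str) -> str:
    return "nucleotide" if set(residues) <= NUCLEOTIDE_ALPHABET else "protein"


@dataclass
class SequenceRecord:
    """A named sequence with an explicit alphabet.

    Residues are upper-cased on construction and validated against the
    declared alphabet.  When ``alphabet`` is omitted it is inferred:
    a sequence drawn entirely from ``ACGTN`` is nucleotide, otherwise protein.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        if not self.alphabet:
            self.alphabet = _infer_alphabet(self.residues)
        allowed = (
            NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        )
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FeatureRecord:
    """A gene on a genome: 1-based inclusive coordinates, strand, labels."""

    genome_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    family_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(
                f"feature {self.gene_id!r}: start {self.start} < 1 "
                "(coordinates are 1-based)"
            )
        if self.start > self.end:
            raise CoordinateError(
                f"feature {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature {self.gene_id!r}: unknown strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Features of one genome, kept sorted by (start, end)."""

    genome_id: str
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            if f.genome_id != self.genome_id:
                raise FormatError(
                    f"feature {f.gene_id!r} references genome {f.genome_id!r}, "
                    f"not {self.genome_id!r}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        ids = [f.gene_id for f in self.features]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene ids in {self.genome_id!r}: {dup}")

    def feature(self, gene_id: str) -> FeatureRecord:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(f"gene {gene_id!r} not found in genome {self.genome_id!r}")

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Wrapped sequence lines are concatenated and upper-cased; the first
    whitespace-delimited token of the header is the id, the remainder the
    description.  Raises :class:`FormatError` on an empty file or a
    duplicated id.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(rec.id, str(rec.seq), description=desc, alphabet=alphabet)
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Sequence[SequenceRecord], path: str | Path, width: int = 70
) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    if not records:
        raise FormatError("refusing to write an empty FASTA file")
    if width < 1:
        raise ValueError("width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature tables: GFF3 subset and TSV fallback
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _feature_from_gff_line(line: str, lineno: int) -> FeatureRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise FormatError(f"line {lineno}: expected 9 tab-separated GFF columns")
    seqid, _source, _type, start, end, _score, strand, _phase, attr_text = fields
    attrs = _parse_gff_attributes(attr_text)
    if "ID" not in attrs:
        raise FormatError(f"line {lineno}: GFF attributes lack ID=")
    families = [t for t in attrs.get("family", "").split(",") if t]
    return FeatureRecord(
        genome_id=seqid,
        gene_id=attrs["ID"],
        start=int(start),
        end=int(end),
        strand=strand,
        product=attrs.get("product", ""),
        family_labels=families,
    )


def _feature_from_tsv_row(row: dict[str, str]) -> FeatureRecord:
    families = [t for t in row.get("family_labels", "").split(",") if t]
    return FeatureRecord(
        genome_id=row["genome_id"],
        gene_id=row["gene_id"],
        start=int(row["start"]),
        end=int(row["end"]),
        strand=row["strand"],
        product=row.get("product", ""),
        family_labels=families,
    )


def read_feature_table(path: str | Path) -> GenomeAnnotation:
    """Read a single genome's features from a GFF3 subset or TSV file.

    The GFF3 subset carries ``ID=``, optional ``product=`` and ``family=``
    (comma-separated) attributes.  The TSV fallback needs a header row with
    columns ``genome_id gene_id start end strand product family_labels``.
    All features must belong to one genome.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"no feature lines found in {path}")
    features: list[FeatureRecord]
    header = lines[0].split("\t")
    if header[0] == "genome_id":
        missing = [c for c in _TSV_COLUMNS[:5] if c not in header]
        if missing:
            raise FormatError(f"{path}: TSV header lacks columns {missing}")
        features = [
            _feature_from_tsv_row(dict(zip(header, ln.split("\t"))))
            for ln in lines[1:]
        ]
    else:
        features = [_feature_from_gff_line(ln, i + 1) for i, ln in enumerate(lines)]
    genomes = {f.genome_id for f in features}
    if len(genomes) != 1:
        raise FormatError(
            f"{path}: expected one genome per feature table, found {sorted(genomes)}"
        )
    return GenomeAnnotation(genome_id=features[0].genome_id, features=features)


def write_feature_table(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write features as a GFF3 subset (inverse of :func:`read_feature_table`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotation.features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            if f.family_labels:
                attrs += ";family=" + ",".join(f.family_labels)
            fh.write(
                "\t".join(
                    [
                        f.genome_id,
                        "phagecompare",
                        "CDS",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Basic sequence operations
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string; ``N`` maps to ``N``."""
    seq = seq.upper()
    bad = set(seq) - NUCLEOTIDE_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str, strand: str = "+") -> str:
    """Translate a CDS with the bacterial/plastid code (translation table 11).

    A minus-strand CDS is reverse-complemented first.  The terminal stop is
    trimmed; internal stops are rendered ``*``.
    """
    if strand not in ("+", "-"):
        raise FormatError(f"unknown strand {strand!r}")
    seq = seq.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    if len(seq) % 3 != 0:
        raise FormatError(f"CDS length {len(seq)} is not divisible by 3")
    protein = str(Seq(seq).translate(table=11))
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein
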