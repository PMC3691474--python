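"""Genome sequence and annotation input.

Reads FASTA contigs and CDS annotations (GenBank flat file or GFF3) and
extracts strand-corrected, in-frame coding sequences as codon lists.

Coordinates are 1-based inclusive on every public object (GenBank
convention); any internal window arithmetic converts to 0-based half-open
at the point of use.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "NucleotideRecord",
    "CdsFeature",
    "CodonSequence",
    "read_fasta",
    "read_annotations",
    "extract_cds",
]

IUPAC_NT = set("ACGTURYSWKMBDHVN")
_UNAMBIGUOUS = set("ACGT")


@dataclass(frozen=True)
class NucleotideRecord:
    """A named nucleotide sequence, stored upper-case."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsFeature:
    """A CDS location on a contig, 1-based inclusive, strand '+' or '-'."""

    locus_tag: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.locus_tag}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CodonSequence:
    """An in-frame coding sequence partitioned into codons.

    The codon is the resampling unit for bootstrap work downstream, so it
    is the atomic element here.
    """

    locus_tag: str
    codons: tuple[str, ...]
    trimmed_tail: int = 0  # nt trimmed from a partial CDS (0-2)

    def __post_init__(self) -> None:
        if not self.codons:
            raise ValueError(f"{self.locus_tag}: no codons")
        for c in self.codons:
            if len(c) != 3:
                raise ValueError(f"{self.locus_tag}: malformed codon {c!r}")
        object.__setattr__(self, "codons", tuple(c.upper() for c in self.codons))

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def nucleotides(self) -> str:
        return "".join(self.codons)


def read_fasta(path: str | Path) -> list[NucleotideRecord]:
    """Read a (multi-)FASTA file into NucleotideRecords, order preserved.

    Raises on an empty file and on duplicate record ids.
    """
    records: list[NucleotideRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _features_from_genbank(path: Path) -> Iterable[CdsFeature]:
    ordinal = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            ordinal += 1
            tag = feat.qualifiers.get("locus_tag", [f"cds_{ordinal}"])[0]
            product = feat.qualifiers.get("product", [None])[0]
            # Biopython locations are 0-based half-open.
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            partial = "<" in str(feat.location) or ">" in str(feat.location)
            yield CdsFeature(tag, rec.id, start, end, strand, product, partial)


def _features_from_gff3(path: Path) -> Iterable[CdsFeature]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        try:
            db = gffutils.create_db(
                str(path),
                tmp.name,
                force=True,
                merge_strategy="create_unique",
                keep_order=True,
            )
        except Exception as exc:  # gffutils raises assorted parse errors
            raise ValueError(f"cannot parse GFF3 {path}: {exc}") from exc
        ordinal = 0
        for feat in db.features_of_type("CDS", order_by="start"):
            ordinal += 1
            tag = feat.attributes.get("locus_tag", [None])[0]
            if tag is None:
                tag = feat.attributes.get("ID", [f"cds_{ordinal}"])[0]
            product = feat.attributes.get("product", [None])[0]
            strand = "-" if feat.strand == "-" else "+"
            partial = feat.attributes.get("partial", ["false"])[0] == "true"
            # gffutils keeps GFF3's native 1-based inclusive coordinates.
            yield CdsFeature(tag, feat.seqid, feat.start, feat.end, strand, product, partial)


def read_annotations(path: str | Path, format: str = "gff3") -> list[CdsFeature]:
    """Read CDS features from a GenBank flat file or GFF3.

    Only CDS-type features are returned, in file order (GFF3 sorted by
    start within the file's record order). Coordinates are 1-based
    inclusive regardless of source dialect.
    """
    path = Path(path)
    if format == "genbank":
        feats = list(_features_from_genbank(path))
    elif format == "gff3":
        feats = list(_features_from_gff3(path))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return feats


_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def extract_cds(
    record: NucleotideRecord,
    feature: CdsFeature,
    allow_partial: bool = False,
) -> CodonSequence:
    """Extract a strand-corrected, in-frame codon list for one CDS.

    Minus-strand features are reverse-complemented before the codon
    partition. With ``allow_partial`` a trailing 1-2 nt remainder is
    trimmed and recorded on the result.
    """
    if feature.end > len(record):
        raise ValueError(
            f"{feature.locus_tag}: feature {feature.start}..{feature.end} "
            f"outside contig {record.id} (length {len(record)})"
        )
    sub = record.sequence[feature.start - 1 : feature.end]
    if feature.strand == "-":
        sub = reverse_complement(sub)
    rem = len(sub) % 3
    if rem:
        if not (allow_partial or feature.partial):
            raise ValueError(
                f"{feature.locus_tag}: CDS length {len(sub)} not divisible by 3"
            )
        sub = sub[: len(sub) - rem]
    if not sub:
        raise ValueError(f"{feature.locus_tag}: CDS empty after trimming")
    codons = tuple(sub[i : i + 3] for i in range(0, len(sub), 3))
    return CodonSequence(feature.locus_tag, codons, trimmed_tail=rem)


def translate_codons(codons: Sequence[str], table: int = 11) -> str:
    """Translate a codon list with the bacterial code ('*' for stops)."""
    return str(Seq("".join(codons)).translate(table=table))
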