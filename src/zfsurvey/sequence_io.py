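"""Sequence and gene-model I/O plus the wheat Traes gene-ID dialect.

All internal coordinates are 0-based half-open; report tables are 1-based
inclusive.  Protein sequences are stored uppercase over the 20 standard amino
acids plus ``X`` (unknown residue); ``X`` is accepted at read time but never
matches a zinc-ligand or QALGGH position downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from zfsurvey.errors import FastaFormatError, GeneIdError, GffFormatError

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: ``Traes_<chr 1-7><subgenome A/B/D><arm S/L>_<hash>[.<variant>]`` (case-sensitive)
_TRAES_RE = re.compile(r"^Traes_([1-7])([ABD])([SL])_([A-Za-z0-9]+)(?:\.([0-9]+))?$")

#: variant suffix used for free-form ids: trailing ``.<digits>``
_VARIANT_RE = re.compile(r"^(.*)\.([0-9]+)$")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its splice-variant bookkeeping.

    ``gene_id`` is ``id`` with a trailing ``.<n>`` splice index stripped;
    ``variant`` is that index, or ``None`` when the id carries no suffix.
    """

    id: str
    sequence: str
    gene_id: str
    variant: Optional[int] = None

    @classmethod
    def from_parts(cls, identifier: str, sequence: str) -> "ProteinRecord":
        seq = sequence.strip().upper().rstrip("*")
        if not seq:
            raise FastaFormatError(f"record {identifier!r} has an empty sequence")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise FastaFormatError(
                f"record {identifier!r} contains invalid residues {sorted(bad)}; "
                "only the 20 standard amino acids plus X are accepted"
            )
        m = _VARIANT_RE.match(identifier)
        if m:
            gene_id, variant = m.group(1), int(m.group(2))
        else:
            gene_id, variant = identifier, None
        return cls(id=identifier, sequence=seq, gene_id=gene_id, variant=variant)


@dataclass(frozen=True)
class GeneLocus:
    """Genomic placement parsed from a Traes-dialect identifier."""

    chromosome: int  # 1..7
    subgenome: str   # A / B / D
    arm: str         # S (short) / L (long)
    hash: str

    def __post_init__(self) -> None:
        if self.chromosome not in range(1, 8):
            raise GeneIdError(f"chromosome must be 1-7, got {self.chromosome}")
        if self.subgenome not in ("A", "B", "D"):
            raise GeneIdError(f"subgenome must be A/B/D, got {self.subgenome!r}")
        if self.arm not in ("S", "L"):
            raise GeneIdError(f"arm must be S/L, got {self.arm!r}")


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one mRNA; intervals 0-based half-open, sorted, disjoint."""

    gene_id: str
    mrna_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise GffFormatError(
                    f"{self.mrna_id}: exon ({start}, {end}) has end <= start"
                )
            if prev_end is not None and start < prev_end:
                raise GffFormatError(
                    f"{self.mrna_id}: exons overlap or are unsorted at ({start}, {end})"
                )
            prev_end = end


def parse_gene_id(identifier: str) -> tuple[GeneLocus, Optional[int]]:
    """Parse a Traes-dialect id into (locus, splice variant).

    ``Traes_5BL_D53A846BE.1`` -> chromosome 5, subgenome B, long arm,
    hash ``D53A846BE``, variant 1.  Non-matching ids raise :class:`GeneIdError`;
    callers that accept arbitrary proteomes should use :func:`try_parse_gene_id`.
    """
    m = _TRAES_RE.match(identifier)
    if not m:
        raise GeneIdError(f"{identifier!r} does not match the Traes gene-id dialect")
    chrom, sub, arm, hashval, variant = m.groups()
    locus = GeneLocus(chromosome=int(chrom), subgenome=sub, arm=arm, hash=hashval)
    return locus, (int(variant) if variant is not None else None)


def try_parse_gene_id(identifier: str) -> tuple[Optional[GeneLocus], Optional[int]]:
    """Like :func:`parse_gene_id` but returns ``(None, variant)`` for foreign ids."""
    try:
        return parse_gene_id(identifier)
    except GeneIdError:
        m = _VARIANT_RE.match(identifier)
        return None, (int(m.group(2)) if m else None)


def compose_gene_id(locus: GeneLocus, variant: Optional[int] = None) -> str:
    """Inverse of :func:`parse_gene_id` on valid loci."""
    base = f"Traes_{locus.chromosome}{locus.subgenome}{locus.arm}_{locus.hash}"
    return f"{base}.{variant}" if variant is not None else base


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects, order preserved.

    Sequences are uppercased and terminal ``*`` stop symbols stripped.  An empty
    file or duplicate ids raise :class:`FastaFormatError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord.from_parts(rec.id, str(rec.seq)))
    if not records:
        raise FastaFormatError(f"{path} contains no FASTA records")
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon features from a GFF3 file into :class:`GeneModel` rows.

    GFF3 coordinates are 1-based inclusive per the standard and converted to
    0-based half-open here.  Exons lacking an mRNA parent, and overlapping exons
    within one mRNA, are format errors.  An empty file yields an empty list.
    """
    import gffutils

    path = Path(path)
    text = path.read_text()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return []
    for line in text.splitlines():
        if line.strip() and not line.startswith("#") and len(line.split("\t")) != 9:
            raise GffFormatError(f"{path}: expected 9 tab-separated columns, got: {line!r}")
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise GffFormatError(f"failed to parse GFF3 {path}: {exc}") from exc

    mrna_parent: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        mrna_parent[mrna.id] = parents[0] if parents else mrna.id

    exons_by_mrna: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            raise GffFormatError(f"{path}: exon at {exon.start}-{exon.end} has no parent mRNA")
        for parent in parents:
            if parent not in mrna_parent:
                raise GffFormatError(
                    f"{path}: exon parent {parent!r} is not a declared mRNA"
                )
            exons_by_mrna.setdefault(parent, []).append((exon.start - 1, exon.end))

    models: list[GeneModel] = []
    for mrna_id, intervals in exons_by_mrna.items():
        intervals.sort()
        models.append(
            GeneModel(gene_id=mrna_parent[mrna_id], mrna_id=mrna_id,
                      exons=tuple(intervals))
        )
    models.sort(key=lambda m: (m.gene_id, m.mrna_id))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | Path,
                      seqid_of: Optional[dict[str, str]] = None) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon), 1-based inclusive."""
    lines = ["##gff-version 3"]
    for m in models:
        seqid = (seqid_of or {}).get(m.gene_id, "chrUn")
        start1 = m.exons[0][0] + 1
        end1 = m.exons[-1][1]
        lines.append(f"{seqid}\tzfsurvey\tgene\t{start1}\t{end1}\t.\t+\t.\tID={m.gene_id}")
        lines.append(
            f"{seqid}\tzfsurvey\tmRNA\t{start1}\t{end1}\t.\t+\t.\t"
            f"ID={m.mrna_id};Parent={m.gene_id}"
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                f"{seqid}\tzfsurvey\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                f"ID={m.mrna_id}.exon{i};Parent={m.mrna_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
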