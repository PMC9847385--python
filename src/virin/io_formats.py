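"""Readers and writers for SAM, FASTA, FASTQ, BED, GTF and the breakpoint TSV.

Coordinate conventions
----------------------
Internal breakpoint coordinates are 1-based inclusive (SAM convention).  BED
intervals are kept half-open 0-based exactly as on disk; conversion happens
explicitly at module boundaries (`GenomicInterval.contains_1based`).
Chromosome names are normalized by stripping a leading ``chr`` prefix so that
inputs mixing ``1`` and ``chr1`` unify.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

# CIGAR ops that consume query / reference
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_CIGAR_OPS = set("MIDNSHP=X")

BREAKPOINT_TSV_COLUMNS = [
    "sample_id",
    "chrom",
    "pos_1based",
    "virus_id",
    "evidence",
    "support",
    "region_class",
    "dnase",
    "repeat_class",
    "gene_name",
    "gene_type",
]


class FormatError(ValueError):
    """Raised for malformed records in any supported text format."""


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix so 'chr1' and '1' compare equal."""
    return name[3:] if name.lower().startswith("chr") and len(name) > 3 else name


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into an ordered list of (op, length) tuples.

    '*' yields an empty list.  Grammar errors (length missing, unknown op,
    trailing digits) raise FormatError.
    """
    if cigar == "*":
        return []
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            if not num:
                raise FormatError(f"CIGAR grammar error (length must precede op): {cigar!r}")
            ops.append((ch, int(num)))
            num = ""
        else:
            raise FormatError(f"unknown CIGAR op {ch!r} in {cigar!r}")
    if num:
        raise FormatError(f"CIGAR ends with dangling length: {cigar!r}")
    if not ops:
        raise FormatError(f"empty CIGAR: {cigar!r}")
    return ops


def cigar_to_string(ops: list[tuple[str, int]]) -> str:
    return "*" if not ops else "".join(f"{n}{op}" for op, n in ops)


def cigar_query_length(ops: Iterable[tuple[str, int]]) -> int:
    """Number of query bases consumed (M, I, S, =, X)."""
    return sum(n for op, n in ops if op in _QUERY_OPS)


def cigar_reference_span(ops: Iterable[tuple[str, int]]) -> int:
    """Number of reference bases consumed (M, D, N, =, X)."""
    return sum(n for op, n in ops if op in _REF_OPS)


@dataclass
class ReadRecord:
    """One SAM alignment line with decoded flag bits and CIGAR."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost mapped position; 0 sentinel when unmapped
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    qual: str  # ASCII Phred+33 string, "*" allowed
    mate_rname: str = "*"
    mate_pos: int = 0
    tlen: int = 0
    tags: list[str] = field(default_factory=list)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary_or_supplementary(self) -> bool:
        return bool(self.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY))

    @property
    def reference_span(self) -> int:
        return cigar_reference_span(self.cigar)

    @property
    def reference_end(self) -> int:
        """1-based last aligned base (pos + reference span - 1); 0 if unmapped."""
        if self.is_unmapped or not self.cigar:
            return 0
        return self.pos + self.reference_span - 1

    def validate(self) -> None:
        if self.seq != "*" and self.qual != "*" and len(self.seq) != len(self.qual):
            raise FormatError(f"{self.qname}: SEQ/QUAL length mismatch")
        if self.cigar and self.seq != "*":
            qlen = cigar_query_length(self.cigar)
            if qlen != len(self.seq):
                raise FormatError(
                    f"{self.qname}: CIGAR query length {qlen} != SEQ length {len(self.seq)}"
                )


def parse_sam_record(line: str, line_number: int | None = None) -> ReadRecord:
    """Parse one tab-delimited SAM alignment line into a ReadRecord.

    Raises FormatError naming the line number on malformed field counts or
    CIGAR grammar; errors are never silently skipped.
    """
    where = f" at line {line_number}" if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise FormatError(f"SAM record has {len(fields)} fields (< 11){where}")
    try:
        rec = ReadRecord(
            qname=fields[0],
            flag=int(fields[1]),
            rname=fields[2],
            pos=int(fields[3]),
            mapq=int(fields[4]),
            cigar=parse_cigar(fields[5]),
            seq=fields[9],
            qual=fields[10],
            mate_rname=fields[6],
            mate_pos=int(fields[7]),
            tlen=int(fields[8]),
            tags=fields[11:],
        )
    except FormatError as exc:
        raise FormatError(f"{exc}{where}") from None
    except ValueError as exc:
        raise FormatError(f"non-integer SAM field ({exc}){where}") from None
    rec.validate()
    return rec


def write_sam_record(rec: ReadRecord) -> str:
    """Render the 11 mandatory SAM columns (plus tags) byte-identically."""
    fields = [
        rec.qname,
        str(rec.flag),
        rec.rname,
        str(rec.pos),
        str(rec.mapq),
        cigar_to_string(rec.cigar),
        rec.mate_rname,
        str(rec.mate_pos),
        str(rec.tlen),
        rec.seq,
        rec.qual,
    ]
    fields.extend(rec.tags)
    return "\t".join(fields)


def read_sam(path_or_handle) -> Iterator[ReadRecord]:
    """Iterate ReadRecords from a SAM file, skipping @ header lines."""
    handle, close = _open(path_or_handle)
    try:
        for i, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            yield parse_sam_record(line, line_number=i)
    finally:
        if close:
            handle.close()


def write_sam(records: Iterable[ReadRecord], path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(h.rstrip("\n") + "\n")
        for rec in records:
            fh.write(write_sam_record(rec) + "\n")


@dataclass
class FastaRecord:
    id: str
    description: str
    seq: str


def read_fasta(path_or_handle) -> list[FastaRecord]:
    """Read FASTA; multi-line sequences concatenated, case folded to upper.

    Empty files, records with empty sequences, and duplicate ids raise
    FormatError.
    """
    handle, close = _open(path_or_handle)
    records: list[FastaRecord] = []
    seen: set[str] = set()
    rec_id: str | None = None
    desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if rec_id is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec_id!r} has empty sequence")
        if rec_id in seen:
            raise FormatError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        records.append(FastaRecord(rec_id, desc, seq))

    try:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FormatError("FASTA header with empty id")
                rec_id = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            elif line.strip():
                if rec_id is None:
                    raise FormatError("sequence data before any FASTA header")
                chunks.append(line.strip())
        flush()
    finally:
        if close:
            handle.close()
    if not records:
        raise FormatError("empty FASTA file")
    return records


def write_fasta(records: Iterable[FastaRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path_or_handle) -> Iterator[tuple[str, str, str]]:
    """Iterate (id, seq, qual) from a 4-line FASTQ file."""
    handle, close = _open(path_or_handle)
    try:
        while True:
            head = handle.readline()
            if not head:
                break
            if not head.startswith("@"):
                raise FormatError(f"FASTQ record does not start with '@': {head!r}")
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not plus.startswith("+"):
                raise FormatError("FASTQ separator line missing")
            if len(seq) != len(qual):
                raise FormatError(f"FASTQ SEQ/QUAL length mismatch for {head.strip()!r}")
            yield head[1:].strip().split()[0], seq, qual
    finally:
        if close:
            handle.close()


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


@dataclass
class GenomicInterval:
    """Half-open 0-based interval as in BED, with optional name/score/strand."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str = "."
    score: float | None = None
    strand: str = "."
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        self.chrom = normalize_chrom(self.chrom)

    def contains_1based(self, pos: int) -> bool:
        """True iff a 1-based position falls inside this BED interval.

        BED [start, end) contains 1-based pos iff start < pos <= end.
        """
        return self.start < pos <= self.end


def read_bed(path_or_handle) -> list[GenomicInterval]:
    """Read BED3-6; track/browser header lines skipped; start>=end is an error."""
    handle, close = _open(path_or_handle)
    intervals: list[GenomicInterval] = []
    try:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line {i} has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"BED line {i}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"BED line {i}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GenomicInterval(fields[0], start, end, name=name, score=score, strand=strand)
            )
    finally:
        if close:
            handle.close()
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


# gene_type vocabulary used throughout annotation
GENE_TYPES = ("protein_coding", "lncRNA", "pseudogene", "other")


def map_gene_type(raw: str) -> str:
    """Map a GENCODE biotype onto {protein_coding, lncRNA, pseudogene, other}.

    Any biotype containing 'pseudogene' (e.g. transcribed_unprocessed_pseudogene)
    maps to pseudogene.
    """
    if raw == "protein_coding":
        return "protein_coding"
    if raw == "lncRNA":
        return "lncRNA"
    if "pseudogene" in raw:
        return "pseudogene"
    return "other"


@dataclass
class Gene:
    name: str
    gene_type: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open, merged
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """0-based TSS: gene start on + strand, gene end - 1 on - strand."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    genes: list[Gene]


def _parse_gtf_attrs(attr_field: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"GTF line {line_number}: unparseable attribute {chunk!r}")
        attrs[parts[0]] = parts[1].strip().strip('"')
    return attrs


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gene_model(path_or_handle) -> GeneModel:
    """Read a GENCODE-dialect GTF into a GeneModel.

    gene/exon/CDS features are used; attributes must carry gene_name (or
    gene_id) and gene_type.  Exon and CDS intervals are merged per gene.
    """
    handle, close = _open(path_or_handle)
    genes: dict[str, Gene] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    try:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"GTF line {i} has fewer than 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attr_field = fields[:9]
            if feature not in ("gene", "exon", "CDS"):
                continue
            attrs = _parse_gtf_attrs(attr_field, i)
            name = attrs.get("gene_name") or attrs.get("gene_id")
            if name is None:
                raise FormatError(f"GTF line {i}: no gene_name/gene_id attribute")
            s0, e0 = int(start) - 1, int(end)  # GTF is 1-based inclusive
            if feature == "gene":
                genes[name] = Gene(
                    name=name,
                    gene_type=map_gene_type(attrs.get("gene_type", "other")),
                    chrom=normalize_chrom(chrom),
                    start=s0,
                    end=e0,
                    strand=strand,
                )
            elif feature == "exon":
                exons.setdefault(name, []).append((s0, e0))
            else:
                cds.setdefault(name, []).append((s0, e0))
    finally:
        if close:
            handle.close()
    for name, gene in genes.items():
        gene.exons = _merge_intervals(exons.get(name, []))
        gene.cds = _merge_intervals(cds.get(name, []))
    # exon-only features without an explicit gene line still form a gene
    for name in exons:
        if name not in genes:
            ivs = _merge_intervals(exons[name])
            genes[name] = Gene(name, "other", "?", ivs[0][0], ivs[-1][1], "+", ivs, [])
    return GeneModel(genes=sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.name)))


def read_breakpoint_tsv(path) -> pd.DataFrame:
    """Load a per-sample breakpoint table, validating the column schema."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in BREAKPOINT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"breakpoint TSV missing columns: {missing}")
    return df


def write_breakpoint_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=BREAKPOINT_TSV_COLUMNS)


def _open(path_or_handle) -> tuple[TextIO, bool]:
    if isinstance(path_or_handle, (str, Path)):
        return open(path_or_handle), True
    if isinstance(path_or_handle, io.TextIOBase):
        return path_or_handle, False
    return path_or_handle, False
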