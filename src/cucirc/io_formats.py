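"""Readers, writers and coordinate conventions.

All coordinates inside the package are 1-based inclusive, matching the
back-splice identifier style ``Chr2:1524236|1525777``.  BED-like input and
output converts at the boundary.  Unanchored scaffolds can be merged into a
single ``ChrUn`` pseudo-chromosome with N spacers, with a :class:`ScaffoldMap`
recording the offsets so positions can be lifted back and forth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp

__all__ = [
    "CircRecord",
    "GeneModel",
    "SampleStats",
    "ScaffoldMap",
    "JunctionTableError",
    "make_circ_id",
    "reverse_complement",
    "read_genome_fasta",
    "write_genome_fasta",
    "fetch_sequence",
    "read_junction_table",
    "write_junction_table",
    "read_gff3",
    "write_gff3",
    "read_sample_stats",
    "write_sample_stats",
    "read_mite_bed",
    "write_mite_bed",
    "merge_unanchored",
    "lift_circs",
]

VALID_STRANDS = {"+", "-", "unknown"}


class JunctionTableError(ValueError):
    """Raised for malformed or inconsistent junction tables."""


def make_circ_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}|{end}"


def reverse_complement(seq: str) -> str:
    return _bio_revcomp(seq)


@dataclass
class CircRecord:
    """One back-splice junction (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    junction_reads: int = 0
    reported_type: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{make_circ_id(self.chrom, self.start, self.end)}: start > end"
            )
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be >= 0")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def circ_id(self) -> str:
        return make_circ_id(self.chrom, self.start, self.end)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """A gene with strand and exons ordered in transcript orientation.

    ``exons`` are 1-based inclusive, non-overlapping intervals; the first
    exon is the 5'-most in transcript orientation (genomically last for a
    minus-strand gene).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        genomic = self.exons_genomic
        for (s, e) in genomic:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon start > end")
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping/unsorted exons")

    @classmethod
    def from_genomic_exons(
        cls, gene_id: str, chrom: str, strand: str, exons: Iterable[Tuple[int, int]]
    ) -> "GeneModel":
        ordered = sorted(exons)
        if strand == "-":
            ordered = ordered[::-1]
        return cls(gene_id, chrom, strand, ordered)

    @property
    def exons_genomic(self) -> List[Tuple[int, int]]:
        """Exons sorted by genomic coordinate."""
        return sorted(self.exons)

    @property
    def start(self) -> int:
        return self.exons_genomic[0][0]

    @property
    def end(self) -> int:
        return self.exons_genomic[-1][1]

    @property
    def introns_genomic(self) -> List[Tuple[int, int]]:
        ex = self.exons_genomic
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(ex, ex[1:]) if s2 - e1 > 1]


@dataclass
class SampleStats:
    sample_id: str
    total_reads: int
    mapped_reads: int
    read_length: int

    def __post_init__(self) -> None:
        if self.mapped_reads > self.total_reads:
            raise ValueError(f"{self.sample_id}: mapped_reads > total_reads")
        if self.read_length <= 0:
            raise ValueError(f"{self.sample_id}: read_length must be > 0")


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(
    genome: Mapping[str, str], chrom: str, start: int, end: int, strand: str = "+"
) -> str:
    """Inclusive slice of the genome; minus strand returns the reverse complement.

    Out-of-bounds coordinates raise; callers that want clamping must clamp
    explicitly before calling.
    """
    seq = genome[chrom]
    if not (1 <= start <= end <= len(seq)):
        raise IndexError(
            f"{chrom}:{start}-{end} out of bounds (length {len(seq)})"
        )
    sub = seq[start - 1 : end].upper()
    return reverse_complement(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# junction tables

CIRI2_COLUMNS = [
    "circRNA_ID",
    "chr",
    "circRNA_start",
    "circRNA_end",
    "junction_reads",
    "circRNA_type",
    "gene_id",
    "strand",
]


def _parse_int(token: str, what: str, lineno: int, path) -> int:
    try:
        return int(token)
    except ValueError:
        raise JunctionTableError(
            f"{path}, line {lineno}: malformed {what} {token!r}"
        ) from None


def read_junction_table(path, dialect: str = "ciri2") -> List[CircRecord]:
    """Read one per-sample back-splice junction table.

    ``ciri2`` rows carry 1-based inclusive coordinates, ``bedlike`` rows are
    BED6 (0-based half-open, junction reads in the score column).  Duplicate
    (chrom, start, end) rows within one sample are an error.
    """
    if dialect not in {"ciri2", "bedlike"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    records: List[CircRecord] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and _looks_like_header(fields, dialect):
                continue
            if dialect == "ciri2":
                if len(fields) < 8:
                    raise JunctionTableError(
                        f"{path}, line {lineno}: expected 8 columns, got {len(fields)}"
                    )
                chrom = fields[1]
                start = _parse_int(fields[2], "start", lineno, path)
                end = _parse_int(fields[3], "end", lineno, path)
                reads = _parse_int(fields[4], "junction_reads", lineno, path)
                rtype = fields[5] or None
                gene = fields[6] if fields[6] not in {"", "n/a", "NA", "."} else None
                strand = fields[7] if fields[7] in VALID_STRANDS else "unknown"
            else:
                if len(fields) < 6:
                    raise JunctionTableError(
                        f"{path}, line {lineno}: expected 6 columns, got {len(fields)}"
                    )
                chrom = fields[0]
                start = _parse_int(fields[1], "start", lineno, path) + 1
                end = _parse_int(fields[2], "end", lineno, path)
                reads = _parse_int(fields[4], "junction_reads", lineno, path)
                rtype, gene = None, None
                strand = fields[5] if fields[5] in VALID_STRANDS else "unknown"
            if start > end:
                raise JunctionTableError(
                    f"{path}, line {lineno}: start {start} > end {end}"
                )
            key = (chrom, start, end)
            if key in seen:
                raise JunctionTableError(
                    f"{path}, line {lineno}: duplicate junction {make_circ_id(*key)}"
                )
            seen.add(key)
            records.append(
                CircRecord(chrom, start, end, strand, reads, rtype, gene)
            )
    return records


def _looks_like_header(fields: Sequence[str], dialect: str) -> bool:
    idx = 2 if dialect == "ciri2" else 1
    if len(fields) <= idx:
        return True
    try:
        int(fields[idx])
        return False
    except ValueError:
        return True


def write_junction_table(records: Sequence[CircRecord], path, dialect: str = "ciri2") -> None:
    with open(path, "w") as fh:
        if dialect == "ciri2":
            fh.write("\t".join(CIRI2_COLUMNS) + "\n")
            for r in records:
                fh.write(
                    "\t".join(
                        [
                            r.circ_id,
                            r.chrom,
                            str(r.start),
                            str(r.end),
                            str(r.junction_reads),
                            r.reported_type or "",
                            r.gene_id or "n/a",
                            r.strand,
                        ]
                    )
                    + "\n"
                )
        elif dialect == "bedlike":
            for r in records:
                fh.write(
                    "\t".join(
                        [
                            r.chrom,
                            str(r.start - 1),
                            str(r.end),
                            r.circ_id,
                            str(r.junction_reads),
                            r.strand,
                        ]
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> List[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file.

    Exons may point at the gene directly or through an mRNA; the top-level
    gene ancestor is used.  Genes without exon children are skipped.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = [
            (ex.start, ex.end)
            for ex in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        models.append(
            GeneModel.from_genomic_exons(gene.id, gene.seqid, gene.strand, exons)
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return models


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tcucirc\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons_genomic, start=1):
                fh.write(
                    f"{g.chrom}\tcucirc\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# sample stats, MITE BED


def read_sample_stats(path) -> List[SampleStats]:
    stats: List[SampleStats] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[1].isdigit():
                continue
            stats.append(
                SampleStats(fields[0], int(fields[1]), int(fields[2]), int(fields[3]))
            )
    return stats


def write_sample_stats(stats: Sequence[SampleStats], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttotal_reads\tmapped_reads\tread_length\n")
        for s in stats:
            fh.write(f"{s.sample_id}\t{s.total_reads}\t{s.mapped_reads}\t{s.read_length}\n")


def read_mite_bed(path) -> Dict[str, List[Tuple[int, int]]]:
    """MITE intervals from BED (0-based half-open), returned 1-based inclusive."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]) + 1, int(fields[2])))
    for v in out.values():
        v.sort()
    return out


def write_mite_bed(mites: Mapping[str, Sequence[Tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mites):
            for s, e in sorted(mites[chrom]):
                fh.write(f"{chrom}\t{s - 1}\t{e}\tMITE\n")


# ---------------------------------------------------------------------------
# ChrUn merging

DEFAULT_SCAFFOLD_PATTERN = r"(?i)^(scaffold|contig)"


@dataclass
class ScaffoldMap:
    """Offsets of merged scaffolds inside the ChrUn pseudo-chromosome.

    ``lift(name, pos) = offset[name] + pos`` where offsets are 0-based and
    positions 1-based, so the map is injective across scaffolds separated by
    ``spacer_length`` Ns.
    """

    entries: Dict[str, Tuple[int, int]] = field(default_factory=dict)  # name -> (offset, length)
    spacer_length: int = 100
    chrun_name: str = "ChrUn"

    def lift(self, scaffold: str, pos: int) -> int:
        offset, length = self.entries[scaffold]
        if not (1 <= pos <= length):
            raise IndexError(f"position {pos} outside scaffold {scaffold} (len {length})")
        return offset + pos

    def invert(self, pos: int) -> Tuple[str, int]:
        for name, (offset, length) in self.entries.items():
            if offset < pos <= offset + length:
                return name, pos - offset
        raise IndexError(f"ChrUn position {pos} falls in no scaffold (spacer?)")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("scaffold\toffset\tlength\n")
            for name, (offset, length) in self.entries.items():
                fh.write(f"{name}\t{offset}\t{length}\n")

    @classmethod
    def read(cls, path, spacer_length: int = 100) -> "ScaffoldMap":
        entries: Dict[str, Tuple[int, int]] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                name, offset, length = line.rstrip("\n").split("\t")
                entries[name] = (int(offset), int(length))
        return cls(entries, spacer_length)


def merge_unanchored(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel] = (),
    spacer_length: int = 100,
    scaffold_pattern: str = DEFAULT_SCAFFOLD_PATTERN,
    chrun_name: str = "ChrUn",
) -> Tuple[Dict[str, str], List[GeneModel], ScaffoldMap]:
    """Concatenate unanchored scaffolds into one ChrUn pseudo-chromosome.

    Scaffolds are recognised by name pattern, joined in sorted name order with
    ``spacer_length`` Ns between them, and all gene annotations on them are
    lifted by the resulting offsets.
    """
    pat = re.compile(scaffold_pattern)
    scaffold_names = sorted(n for n in genome if pat.search(n))
    merged = {n: genome[n] for n in genome if n not in scaffold_names}
    if not scaffold_names:
        return merged, list(genes), ScaffoldMap({}, spacer_length, chrun_name)
    if chrun_name in merged:
        raise ValueError(f"{chrun_name!r} collides with an existing chromosome name")

    entries: Dict[str, Tuple[int, int]] = {}
    parts: List[str] = []
    offset = 0
    for i, name in enumerate(scaffold_names):
        if i > 0:
            parts.append("N" * spacer_length)
            offset += spacer_length
        seq = genome[name]
        entries[name] = (offset, len(seq))
        parts.append(seq)
        offset += len(seq)
    merged[chrun_name] = "".join(parts)
    smap = ScaffoldMap(entries, spacer_length, chrun_name)

    lifted: List[GeneModel] = []
    for g in genes:
        if g.chrom in entries:
            off = entries[g.chrom][0]
            lifted.append(
                GeneModel(
                    g.gene_id,
                    chrun_name,
                    g.strand,
                    [(s + off, e + off) for s, e in g.exons],
                )
            )
        else:
            lifted.append(g)
    return merged, lifted, smap


def lift_circs(circs: Sequence[CircRecord], smap: ScaffoldMap) -> List[CircRecord]:
    """Lift junction records on merged scaffolds onto ChrUn coordinates."""
    out: List[CircRecord] = []
    for c in circs:
        if c.chrom in smap.entries:
            out.append(
                CircRecord(
                    smap.chrun_name,
                    smap.lift(c.chrom, c.start),
                    smap.lift(c.chrom, c.end),
                    c.strand,
                    c.junction_reads,
                    c.reported_type,
                    c.gene_id,
                )
            )
        else:
            out.append(c)
    return out
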