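"""Annotation record types and their GFF3 / FASTA serialisation.

Coordinates are 0-based half-open in memory and 1-based inclusive in GFF3,
per the format specification.  A gene's span covers its RS sequence and
coding region(s); constant genes span their three exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

GFF_TYPES = {
    "V": "V_gene_segment",
    "J": "J_gene_segment",
    "D": "D_gene_segment",
    "C": "C_gene_segment",
}
_TYPE_TO_KIND = {v: k for k, v in GFF_TYPES.items()}

_PART_TYPES = {
    "V-REGION": "V_region",
    "J-REGION": "J_region",
    "D-REGION": "D_region",
}


@dataclass
class GeneAnnotation:
    """One annotated germline gene (V, J, D or C).

    ``parts`` maps part names (L-PART1, V-INTRON, L-PART2, V-REGION,
    heptamer/spacer/nonamer of the RS, J-REGION, DONOR, EX1..EX3, ...) to
    forward-strand genomic intervals.  ``functionality`` follows the IMGT
    classes F / ORF / P; ``defects`` lists the evidence behind a non-F call
    (stop_codon, frameshift, rs_defect, splice_defect,
    missing_conserved_residue, missing_FGXG).
    """

    gene_type: str
    chain: str
    contig: str
    start: int
    end: int
    strand: str
    parts: dict[str, tuple[int, int]] = field(default_factory=dict)
    functionality: str = "F"
    defects: tuple[str, ...] = ()
    name: str | None = None
    subgroup: int | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty span {self.start}..{self.end}")
        self.defects = tuple(sorted(set(self.defects)))

    def sense_seq(self, genome: str) -> str:
        s = genome[self.start : self.end]
        return s if self.strand == "+" else revcomp(s)

    def part_seq(self, genome: str, part: str) -> str:
        a, b = self.parts[part]
        s = genome[a:b]
        return s if self.strand == "+" else revcomp(s)

    @property
    def region_part(self) -> str | None:
        for p in ("V-REGION", "J-REGION", "D-REGION"):
            if p in self.parts:
                return p
        return None

    def core_tuple(self):
        """Fields compared in recovery tests (identity of the annotation)."""
        return (self.gene_type, self.contig, self.start, self.end, self.strand,
                self.functionality)


@dataclass
class ConstantGeneModel:
    """A constant (C) gene localised from a cDNA query.

    ``exons`` are forward-strand genomic intervals in transcription order.
    """

    contig: str
    strand: str
    exons: list[tuple[int, int]]
    query_id: str
    percent_identity: float
    translated_len: int
    splice_ok: bool
    chain: str

    @property
    def start(self) -> int:
        return min(a for a, _ in self.exons)

    @property
    def end(self) -> int:
        return max(b for _, b in self.exons)

    def spliced_seq(self, genome: str) -> str:
        chunks = [genome[a:b] for a, b in sorted(self.exons)]
        s = "".join(chunks)
        return s if self.strand == "+" else revcomp(s)

    def to_annotation(self) -> GeneAnnotation:
        exons = sorted(self.exons)
        order = exons if self.strand == "+" else exons[::-1]
        parts = {f"EX{i + 1}": iv for i, iv in enumerate(order)}
        return GeneAnnotation(
            gene_type="C",
            chain=self.chain,
            contig=self.contig,
            start=self.start,
            end=self.end,
            strand=self.strand,
            parts=parts,
            functionality="F",
            name=self.chain + "C",
            notes={"query_id": self.query_id, "percent_identity": self.percent_identity},
        )


def _attr(pairs: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs if v != "")


def write_gff3(annotations: list[GeneAnnotation], path: str | Path) -> None:
    """Emit annotations as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for i, ann in enumerate(sorted(annotations, key=lambda a: (a.contig, a.start))):
        gid = f"gene{i + 1}"
        attrs = [
            ("ID", gid),
            ("Name", ann.name or ""),
            ("gene_type", ann.gene_type),
            ("chain", ann.chain),
            ("functionality", ann.functionality),
            ("defects", ",".join(ann.defects)),
            ("subgroup", "" if ann.subgroup is None else str(ann.subgroup)),
        ]
        lines.append(
            "\t".join(
                [ann.contig, "tralocus", GFF_TYPES[ann.gene_type], str(ann.start + 1),
                 str(ann.end), ".", ann.strand, ".", _attr(attrs)]
            )
        )
        for part, (a, b) in sorted(ann.parts.items(), key=lambda kv: kv[1]):
            ptype = _PART_TYPES.get(part, "RSS" if ("HEPTAMER" in part or "NONAMER" in part or "SPACER" in part) else "exon")
            lines.append(
                "\t".join(
                    [ann.contig, "tralocus", ptype, str(a + 1), str(b), ".", ann.strand,
                     ".", _attr([("Parent", gid), ("part", part)])]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read back a GFF3 file produced by :func:`write_gff3`."""
    genes: dict[str, GeneAnnotation] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, _src, ftype, start, end, _score, strand, _frame, attrs = line.split("\t")
        kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
        iv = (int(start) - 1, int(end))
        if ftype in _TYPE_TO_KIND:
            genes[kv["ID"]] = GeneAnnotation(
                gene_type=_TYPE_TO_KIND[ftype],
                chain=kv.get("chain", ""),
                contig=contig,
                start=iv[0],
                end=iv[1],
                strand=strand,
                functionality=kv.get("functionality", "F"),
                defects=tuple(d for d in kv.get("defects", "").split(",") if d),
                name=kv.get("Name") or None,
                subgroup=int(kv["subgroup"]) if kv.get("subgroup") else None,
            )
        elif "Parent" in kv and kv["Parent"] in genes:
            genes[kv["Parent"]].parts[kv["part"]] = iv
    return sorted(genes.values(), key=lambda a: (a.contig, a.start))


def write_gene_fasta(
    annotations: list[GeneAnnotation], genome: str, path: str | Path,
    part: str | None = None,
) -> None:
    """Write gene (or region part) sense sequences with descriptive headers."""
    records = []
    for ann in annotations:
        if part is not None and part not in ann.parts:
            continue
        seq = ann.part_seq(genome, part) if part else ann.sense_seq(genome)
        rid = ann.name or f"{ann.gene_type}_{ann.start}"
        desc = (
            f"{ann.gene_type} {ann.chain} {ann.contig}:{ann.start + 1}-{ann.end}"
            f"({ann.strand}) functionality={ann.functionality}"
        )
        records.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(records, str(path), "fasta")
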