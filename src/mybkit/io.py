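"""FASTA/GFF3 reading and writing, CDS extraction and translation.

FASTA goes through Biopython's SeqIO.  GFF3 handling covers the
gene/mRNA/exon/CDS subset this package emits and consumes (version 3
header, 1-based inclusive coordinates, ``ID``/``Parent`` attributes, CDS
``phase`` column populated); unknown feature types are ignored on read.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genestruct import GeneModel, Transcript


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _parse_attributes(field: str) -> dict[str, str]:
    out = {}
    for token in field.strip().split(";"):
        if token and "=" in token:
            key, value = token.split("=", 1)
            out[key] = value
    return out


def read_gff3(source) -> dict[str, GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects."""
    if isinstance(source, (str, Path)):
        handle = open(source)
    else:
        handle = source
    genes: dict[str, GeneModel] = {}
    tx_parent: dict[str, str] = {}
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attributes = _parse_attributes(attrs)
            start, end = int(start), int(end)
            if ftype == "gene":
                gid = attributes["ID"]
                genes[gid] = GeneModel(gid, chrom, strand, start, end)
            elif ftype == "mRNA":
                tid, parent = attributes["ID"], attributes.get("Parent")
                if parent is None or parent not in genes:
                    raise ValueError(f"transcript {tid!r} without a parent gene")
                genes[parent].transcripts[tid] = Transcript(tid)
                tx_parent[tid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attributes.get("Parent")
                if parent is None or parent not in tx_parent:
                    raise ValueError(f"{ftype} feature without a known mRNA parent")
                tx = genes[tx_parent[parent]].transcripts[parent]
                (tx.exons if ftype == "exon" else tx.cds).append((start, end))
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    for gene in genes.values():
        for tx in gene.transcripts.values():
            tx.exons.sort()
            tx.cds.sort()
    return genes


def format_gff3(genes: dict[str, GeneModel], header_lines: list[str] | None = None) -> str:
    """Render gene/mRNA/exon/CDS features with CDS phase columns populated."""

    def fmt(chrom, ftype, start, end, strand, phase, attrs):
        return "\t".join([chrom, "mybkit", ftype, str(start), str(end), ".",
                          strand, phase, attrs])

    lines = ["##gff-version 3"]
    for extra in header_lines or []:
        lines.append(f"# {extra}")
    for gid in sorted(genes):
        gene = genes[gid]
        lines.append(fmt(gene.chrom, "gene", gene.start, gene.end, gene.strand,
                         ".", f"ID={gid}"))
        for tid in sorted(gene.transcripts):
            tx = gene.transcripts[tid]
            lines.append(fmt(gene.chrom, "mRNA", gene.start, gene.end, gene.strand,
                             ".", f"ID={tid};Parent={gid}"))
            for s, e in sorted(tx.exons):
                lines.append(fmt(gene.chrom, "exon", s, e, gene.strand, ".",
                                 f"Parent={tid}"))
            cds = sorted(tx.cds)
            ordered = cds if gene.strand == "+" else cds[::-1]
            cum = 0
            phased = []
            for s, e in ordered:
                phased.append((s, e, (3 - cum % 3) % 3))
                cum += e - s + 1
            for s, e, phase in sorted(phased):
                lines.append(fmt(gene.chrom, "CDS", s, e, gene.strand, str(phase),
                                 f"Parent={tid}"))
    return "\n".join(lines) + "\n"


def write_gff3(genes: dict[str, GeneModel], path,
               header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(format_gff3(genes, header_lines))


def extract_cds(genome: dict[str, str], gene: GeneModel,
                transcript_id: str | None = None) -> str:
    """Spliced CDS in coding orientation for one transcript."""
    tx = (gene.transcripts[transcript_id] if transcript_id is not None
          else gene.representative_transcript())
    chrom = genome[gene.chrom]
    joined = "".join(chrom[s - 1:e] for s, e in sorted(tx.cds))
    if gene.strand == "-":
        joined = str(Seq(joined).reverse_complement())
    return joined


def translate_cds(cds: str) -> str:
    """Translate a CDS (standard table), dropping one trailing stop if present."""
    protein = str(Seq(cds).translate())
    return protein[:-1] if protein.endswith("*") else protein
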