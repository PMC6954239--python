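"""Genome FASTA and gene-model I/O.

Gene models carry the fields the promoter analysis needs: annotated TSS, CDS
start and exon intervals, all 1-based inclusive in memory.  On disk they
round-trip through BED12 (0-based half-open, as the format requires) and
through a flat TSV mirror that is easier to eyeball.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Load a genome FASTA into an uppercase chrom -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class GeneModel:
    """One gene: annotated TSS, CDS start, exons (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    cds_start: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon {start}-{end} inverted")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def write_gene_models_bed12(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start0 = g.exons[0][0] - 1
            end = g.exons[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in g.exons)
            starts = ",".join(str(s - 1 - start0) for s, _ in g.exons)
            if g.strand == "+":
                thick_start, thick_end = g.cds_start - 1, end
            else:
                thick_start, thick_end = start0, g.cds_start
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, start0, end, g.gene_id, 0, g.strand,
                            thick_start, thick_end, "0,0,0",
                            len(g.exons), sizes + ",", starts + ",",
                        ],
                    )
                )
                + "\n"
            )


def read_gene_models_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start0, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start0 + off + 1, start0 + off + size)
                for off, size in zip(offsets, sizes)
            )
            tss = exons[0][0] if strand == "+" else exons[-1][1]
            cds_start = thick_start + 1 if strand == "+" else thick_end
            genes.append(GeneModel(name, chrom, strand, tss, cds_start, exons))
    return genes


def write_gene_models_tsv(genes: list[GeneModel], path) -> None:
    """Flat 1-based TSV mirror of the gene models."""
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "tss": g.tss,
            "cds_start": g.cds_start,
            "exons": ";".join(f"{s}-{e}" for s, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        exons = tuple(
            tuple(int(x) for x in part.split("-")) for part in row.exons.split(";")
        )
        genes.append(
            GeneModel(str(row.gene_id), row.chrom, row.strand,
                      int(row.tss), int(row.cds_start), exons)
        )
    return genes
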