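"""Sequence, table and interval I/O.

All in-memory coordinates are 0-based half-open.  Paper-style 1-based
inclusive coordinates appear only in the gene-table reader/writer; BED
output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ScanHit, SiteSet

__all__ = [
    "GeneRecord",
    "read_fasta", "write_fasta", "read_sites",
    "read_gene_table", "write_gene_table",
    "hits_to_bed", "write_bed", "hits_to_table",
    "one_based_to_zero", "zero_to_one_based",
]


@dataclass(frozen=True)
class GeneRecord:
    """A gene with paper-style 1-based inclusive chromosome coordinates."""

    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def translation_start(self) -> int:
        """1-based coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end


def one_based_to_zero(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start - 1, end


def zero_to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start + 1, end


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    seqrecords = [SeqRecord(Seq(s), id=name, description="")
                  for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_sites(path) -> SiteSet:
    """Read a fixed-width site alignment from FASTA."""
    recs = read_fasta(path)
    return SiteSet(tuple(recs.values()), ids=tuple(recs.keys()))


def read_gene_table(path) -> list[GeneRecord]:
    """TSV gene table: gene_id, chrom, start, end, strand (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"gene_id": str, "chrom": str, "strand": str})
    return [GeneRecord(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
            for r in df.itertuples()]


def write_gene_table(genes: list[GeneRecord], path) -> None:
    df = pd.DataFrame([(g.gene_id, g.chrom, g.start, g.end, g.strand)
                       for g in genes],
                      columns=["gene_id", "chrom", "start", "end", "strand"])
    df.to_csv(path, sep="\t", index=False)


def hits_to_bed(hits: list[ScanHit], width: int, name: str = "model") -> pd.DataFrame:
    """Scan hits as a BED6 frame (chrom, start, end, name, score, strand)."""
    return pd.DataFrame(
        [(h.seq_id, h.offset, h.offset + width, name, h.ri, h.strand)
         for h in hits],
        columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(hits: list[ScanHit], width: int, path, name: str = "model") -> None:
    hits_to_bed(hits, width, name).to_csv(path, sep="\t", index=False,
                                          header=False, float_format="%.6g")


def hits_to_table(hits: list[ScanHit], width: int) -> pd.DataFrame:
    """Scan hits as a TSV-ready frame with the matched window appended."""
    return pd.DataFrame(
        [(h.seq_id, h.offset, h.offset + width, h.strand, h.ri, h.window_seq)
         for h in hits],
        columns=["seq_id", "start", "end", "strand", "ri", "window_seq"])
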