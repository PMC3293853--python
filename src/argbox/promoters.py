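"""Promoter-region extraction and per-gene operator scanning.

Two window conventions are supported, both relative to the first base of
the start codon (position 0):

* ``"upstream"`` — positions -300 .. +100 inclusive (401 nt), the window
  used for genome-wide operator scans;
* ``"centered"`` — an 800-nt window centered on the start codon, used for
  probe-level site searches.

Windows are strand-aware: for a minus-strand gene the extracted sequence
is reverse-complemented so it reads 5'->3' relative to the gene.  Windows
truncated at contig ends are flagged and logged, never errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import GeneRecord
from .model import InformationModel, TandemModel, reverse_complement, scan

__all__ = ["PromoterRegion", "extract_promoters", "scan_promoters",
           "best_hits"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter window in forward 0-based half-open coordinates.

    ``sequence`` reads 5'->3' relative to the gene (reverse-complemented
    for minus-strand genes).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    window: str
    truncated: bool
    sequence: str


def extract_promoters(
    genes: list[GeneRecord],
    genome: dict[str, str],
    window: str = "upstream",
    *,
    upstream: int = 300,
    downstream: int = 100,
    centered_length: int = 800,
) -> list[PromoterRegion]:
    """Extract one promoter window per gene from a genome."""
    if window not in {"upstream", "centered"}:
        raise ValueError(f"unknown window spec {window!r}")
    regions = []
    for gene in genes:
        if gene.chrom not in genome:
            raise KeyError(f"{gene.gene_id}: chromosome {gene.chrom!r} "
                           "not in genome")
        contig = genome[gene.chrom]
        t = gene.translation_start - 1  # 0-based start-codon base
        if window == "upstream":
            if gene.strand == "+":
                s, e = t - upstream, t + downstream + 1
            else:
                s, e = t - downstream, t + upstream + 1
        else:
            half = centered_length // 2
            s, e = t - half, t + half
        cs, ce = max(s, 0), min(e, len(contig))
        if ce <= cs:
            raise ValueError(f"{gene.gene_id}: window entirely outside contig")
        truncated = (cs, ce) != (s, e)
        if truncated:
            logger.info("%s: promoter window truncated to [%d, %d)",
                        gene.gene_id, cs, ce)
        seq = contig[cs:ce]
        if gene.strand == "-":
            seq = reverse_complement(seq)
        regions.append(PromoterRegion(gene.gene_id, gene.chrom, cs, ce,
                                      gene.strand, window, truncated, seq))
    return regions


def scan_promoters(
    model: InformationModel | TandemModel,
    promoters: list[PromoterRegion],
    threshold: float,
    *,
    strands: str = "both",
    dedupe: bool = False,
) -> pd.DataFrame:
    """Scan each promoter; hits keyed by gene with absolute coordinates.

    Offsets are reported both promoter-relative (on the gene-oriented
    sequence) and chromosome-absolute (forward strand).  Overlapping
    promoters of adjacent genes are scanned independently, so a locus may
    appear under more than one gene.
    """
    width = model.width
    rows = []
    for region in promoters:
        for hit in scan(model, region.sequence, threshold,
                        seq_id=region.gene_id, strands=strands,
                        dedupe=dedupe):
            if region.strand == "+":
                abs_start = region.start + hit.offset
                chrom_strand = hit.strand
            else:
                abs_start = region.end - hit.offset - width
                chrom_strand = "-" if hit.strand == "+" else "+"
            rows.append((region.gene_id, region.chrom, hit.offset,
                         abs_start, abs_start + width, chrom_strand,
                         hit.ri, hit.window_seq))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "offset", "chrom_start",
                       "chrom_end", "strand", "ri", "window_seq"])


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-gene best-scoring hit (ties broken by leftmost offset)."""
    if hits.empty:
        return hits
    ordered = hits.sort_values(["gene_id", "ri", "offset"],
                               ascending=[True, False, True])
    return ordered.groupby("gene_id", sort=True).head(1).set_index("gene_id")
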