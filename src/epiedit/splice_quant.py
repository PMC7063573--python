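"""Splice-junction extraction and aberrant-splicing fractions.

Junctions come from N CIGAR ops; a junction is canonical when its
(donor_end, acceptor_start) pair matches consecutive annotated exons of the
gene model exactly (no fuzzy tolerance by default). Everything else —
multi-exon skips, cryptic intronic donors/acceptors — is aberrant.

Two quantification modes cover the two normalisations in common use:
``all_junctions`` (aberrant junction reads over all junction reads of the
gene) and ``from_exon(k)`` (reads leaving exon k's donor that do not splice
into exon k+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_core import AlignedRead, GeneModel


@dataclass
class SpliceJunction:
    chrom: str
    donor_end: int  # last exonic base before the gap
    acceptor_start: int  # first exonic base after the gap
    read_count: int
    canonical: bool | None = None

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end + 1:
            raise ValueError("junction gap must span at least one base")
        if self.read_count < 1:
            raise ValueError("junction must be supported by >= 1 read")


@dataclass
class SpliceSummary:
    sample_id: str
    gene_id: str
    mode: str
    total_reads: int
    aberrant_reads: int

    @property
    def fraction(self) -> float:
        if self.total_reads == 0:
            return float("nan")
        return self.aberrant_reads / self.total_reads


def read_gaps(read: AlignedRead) -> list[tuple[int, int]]:
    """(donor_end, acceptor_start) for every N op of a read."""
    gaps = []
    rpos = read.pos
    for op, n in read.cigartuples:
        if op in "M=XD":
            rpos += n
        elif op == "N":
            gaps.append((rpos - 1, rpos + n))
            rpos += n
    return gaps


def extract_junctions(reads: Iterable[AlignedRead], gene: GeneModel) -> list[SpliceJunction]:
    """Aggregate every N gap overlapping the gene into keyed junctions.

    A read with multiple N ops contributes one count per gap.
    """
    g_lo, g_hi = gene.span
    counts: dict[tuple[int, int], int] = {}
    for r in reads:
        if r.chrom != gene.chrom:
            continue
        for donor_end, acceptor_start in read_gaps(r):
            if acceptor_start < g_lo or donor_end > g_hi:
                continue
            counts[(donor_end, acceptor_start)] = counts.get((donor_end, acceptor_start), 0) + 1
    return [
        SpliceJunction(gene.chrom, d, a, n)
        for (d, a), n in sorted(counts.items())
    ]


def classify_junctions(
    junctions: Sequence[SpliceJunction], gene: GeneModel, tolerance_bp: int = 0
) -> list[SpliceJunction]:
    """Set the canonical flag: exact match to a consecutive-exon boundary pair."""
    annotated = gene.junctions()
    out = []
    for j in junctions:
        if tolerance_bp == 0:
            canonical = (j.donor_end, j.acceptor_start) in annotated
        else:
            canonical = any(
                abs(j.donor_end - d) <= tolerance_bp and abs(j.acceptor_start - a) <= tolerance_bp
                for d, a in annotated
            )
        out.append(SpliceJunction(j.chrom, j.donor_end, j.acceptor_start, j.read_count, canonical))
    return out


def aberrant_fraction(
    junctions: Sequence[SpliceJunction],
    gene: GeneModel,
    mode: str | tuple[str, int] = "all_junctions",
    sample_id: str = "",
) -> SpliceSummary:
    """Aberrant-splicing fraction of one gene in one sample.

    ``mode`` is "all_junctions" or ("from_exon", k) with k a 1-based
    transcript exon ordinal. Returns NaN fraction (with a warning) when the
    denominator is zero.
    """
    classified = classify_junctions(junctions, gene)
    if mode == "all_junctions":
        total = sum(j.read_count for j in classified)
        aberrant = sum(j.read_count for j in classified if not j.canonical)
        mode_name = "all_junctions"
    else:
        tag, k = mode
        if tag != "from_exon":
            raise ValueError(f"unknown mode {mode!r}")
        order = gene.exons_in_transcript_order()
        if not 1 <= k < len(order) + 1:
            raise ValueError(f"no exon {k} in {gene.gene_id}")
        donor = order[k - 1][1] if gene.strand == "+" else order[k - 1][0]
        if gene.strand == "-":
            raise NotImplementedError("from_exon mode expects a + strand model")
        next_acceptor = order[k][0] if k < len(order) else None
        from_k = [j for j in classified if j.donor_end == donor]
        total = sum(j.read_count for j in from_k)
        aberrant = sum(j.read_count for j in from_k if j.acceptor_start != next_acceptor)
        mode_name = f"from_exon({k})"
    if total == 0:
        warnings.warn(f"{gene.gene_id}: no junction reads; fraction undefined")
    return SpliceSummary(sample_id, gene.gene_id, mode_name, total, aberrant)


def has_multi_junction_evidence(
    junctions: Sequence[SpliceJunction], min_reads: int = 1, min_junctions: int = 2
) -> bool:
    """Sample-inclusion rule: spliced evidence at >= min_junctions distinct
    junctions, each supported by >= min_reads reads."""
    return sum(1 for j in junctions if j.read_count >= min_reads) >= min_junctions


def junction_table(junctions: Sequence[SpliceJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": j.chrom,
                "donor_end": j.donor_end,
                "acceptor_start": j.acceptor_start,
                "read_count": j.read_count,
                "canonical": j.canonical,
            }
            for j in junctions
        ],
        columns=["chrom", "donor_end", "acceptor_start", "read_count", "canonical"],
    )


def summary_table(summaries: Sequence[SpliceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "gene_id": s.gene_id,
                "mode": s.mode,
                "total_reads": s.total_reads,
                "aberrant_reads": s.aberrant_reads,
                "fraction": s.fraction,
            }
            for s in summaries
        ],
        columns=["sample_id", "gene_id", "mode", "total_reads", "aberrant_reads", "fraction"],
    )
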