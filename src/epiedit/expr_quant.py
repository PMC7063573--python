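"""Masked-exon read counting and effective-length FPKM.

When guide-site exons are amplified from genomic DNA, their read counts mix
transcript and amplicon molecules; counting against a masked annotation
(those exons absent) restores an mRNA-only count. Where an exon-skipping
isoform is being produced, the FPKM denominator uses an effective transcript
length: the skip-isoform and full-length transcript lengths mixed by the
measured aberrant-splicing ratio r,

    len_eff = r * len_skip + (1 - r) * len_full.

FPKM for a masked gene is refused unless an effective length is supplied
explicitly, since a reliable per-sample transcript length cannot be derived
from masked counts alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .io_core import AlignedRead, GeneModel


@dataclass
class EffectiveLengthSpec:
    len_full_bp: float
    len_skip_bp: float
    r_aberrant: float

    def __post_init__(self) -> None:
        if not 0 < self.len_skip_bp < self.len_full_bp:
            raise ValueError("need 0 < len_skip_bp < len_full_bp")
        if not 0 <= self.r_aberrant <= 1:
            raise ValueError("r_aberrant must be in [0, 1]")


def effective_length(spec: EffectiveLengthSpec) -> float:
    """Splicing-ratio-weighted transcript length in bp."""
    r = spec.r_aberrant
    return r * spec.len_skip_bp + (1 - r) * spec.len_full_bp


def _m_blocks(read: AlignedRead) -> list[tuple[int, int]]:
    """Reference intervals covered by aligned (M/=/X) bases."""
    blocks = []
    rpos = read.pos
    for op, n in read.cigartuples:
        if op in "M=X":
            blocks.append((rpos, rpos + n - 1))
            rpos += n
        elif op in "DN":
            rpos += n
    return blocks


def count_reads_masked(
    reads: Iterable[AlignedRead], gene: GeneModel, masked_exons: set[int] = frozenset()
) -> int:
    """Count reads overlapping >= 1 aligned base of a non-masked exon.

    ``masked_exons`` are 1-based transcript ordinals. Overlap means an M
    base on a retained exon; D and N segments, and overlap confined to
    masked exons or introns, contribute nothing. Each read counts at most
    once (supplementary records are ignored to avoid double-counting a
    split query).
    """
    order = gene.exons_in_transcript_order()
    unknown = [k for k in masked_exons if not 1 <= k <= len(order)]
    if unknown:
        raise ValueError(f"{gene.gene_id}: no such exon(s) {sorted(unknown)}")
    retained = [iv for idx, iv in enumerate(order, 1) if idx not in masked_exons]
    n = 0
    for r in reads:
        if r.chrom != gene.chrom or r.is_supplementary:
            continue
        hit = False
        for b_lo, b_hi in _m_blocks(r):
            for e_lo, e_hi in retained:
                if b_lo <= e_hi and b_hi >= e_lo:
                    hit = True
                    break
            if hit:
                break
        if hit:
            n += 1
    return n


def libsize_normalize(gene_count: int, library_size: int, scale: float = 1e6) -> float:
    """Counts-per-million (or per *scale*) library-size normalisation."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return gene_count / library_size * scale


def fpkm_manual(gene_count: int, library_size: int, effective_length_bp: float) -> float:
    """FPKM with an explicit (possibly splicing-adjusted) transcript length."""
    if effective_length_bp <= 0:
        raise ValueError("effective length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return gene_count / (library_size / 1e6) / (effective_length_bp / 1e3)


def quantify_gene(
    reads: Iterable[AlignedRead],
    gene: GeneModel,
    library_size: int,
    masked_exons: set[int] = frozenset(),
    effective_length_bp: float | None = None,
) -> dict:
    """One gene's raw/masked count, CPM and (when permitted) FPKM.

    For a gene counted against a masked annotation, FPKM is None unless an
    explicit effective length is supplied — the masked transcript length is
    not a reliable FPKM denominator.
    """
    count = count_reads_masked(reads, gene, masked_exons)
    cpm = libsize_normalize(count, library_size)
    if effective_length_bp is not None:
        fpkm = fpkm_manual(count, library_size, effective_length_bp)
    elif masked_exons:
        fpkm = None
    else:
        fpkm = fpkm_manual(count, library_size, gene.transcript_length)
    return {
        "gene_id": gene.gene_id,
        "raw_count": count,
        "cpm": cpm,
        "effective_length_bp": effective_length_bp
        if effective_length_bp is not None
        else (None if masked_exons else gene.transcript_length),
        "fpkm": fpkm,
    }
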