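"""Propagate editing events and splice variants into the CDS and translate.

The open reading frame is read from the wildtype start-codon position
(projected into the edited transcript), through the standard nuclear genetic
code, to the first in-frame stop. Reports carry protein length relative to
the wildtype protein, a frameshift flag (net inserted minus deleted coding
bases not divisible by 3) and a premature-stop flag. If an edit or exon skip
destroys the start codon, the next downstream ATG is used and the report is
flagged ``alternative_start``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .edit_genotyper import EditingEvent
from .io_core import GeneModel, GenomeRef

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfReport:
    gene_id: str
    variant: str
    protein_length_aa: int
    wt_length_aa: int
    frameshift: bool
    premature_stop: bool
    flags: list[str] = field(default_factory=list)

    @property
    def relative_length(self) -> float:
        return self.protein_length_aa / self.wt_length_aa


@dataclass
class TranscriptVariant:
    """A (possibly edited) transcript with bookkeeping for translation.

    ``cds_start`` is the 1-based position of the wildtype start codon in
    *this* sequence (None when the start was removed); ``net_coding_indel``
    is the net inserted-minus-deleted base count within the wildtype CDS.
    """

    gene_id: str
    seq: str
    cds_start: int | None
    wt_cds_len: int  # wildtype CDS length in nt, stop codon included
    net_coding_indel: int = 0
    description: str = "wildtype"

    @property
    def wt_protein_aa(self) -> int:
        return self.wt_cds_len // 3 - 1


def build_cds(model: GeneModel, ref: GenomeRef) -> str:
    """Spliced, strand-oriented CDS (stop codon included).

    Warns when the CDS does not begin with ATG — edited models may
    legitimately have lost the start.
    """
    cds = model.cds_sequence(ref)
    if not cds.startswith("ATG"):
        warnings.warn(f"{model.gene_id}: CDS does not start with ATG")
    return cds


def wildtype_variant(model: GeneModel, ref: GenomeRef) -> TranscriptVariant:
    if model.cds_start is None:
        raise ValueError(f"{model.gene_id} has no CDS")
    return TranscriptVariant(
        gene_id=model.gene_id,
        seq=model.splice(ref),
        cds_start=model.cds_start,
        wt_cds_len=model.cds_end - model.cds_start + 1,
    )


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def genomic_ops_to_transcript(ops: list[tuple], model: GeneModel) -> list[tuple]:
    """Project genomic allele ops onto wildtype-transcript coordinates.

    Input ops use the genotyper's format — ("ins", pos_after, seq),
    ("del", start, end), ("sub", start, ref, alt) — and the output uses
    transcript-space tuples ("ins", t_after, seq), ("del", t1, t2),
    ("sub", t1, alt). Purely intronic pieces are dropped; on the minus
    strand inserted/substituted bases are reverse-complemented.
    """
    out: list[tuple] = []
    for op in ops:
        if op[0] == "del":
            _, g1, g2 = op
            tpos = sorted(
                t for t in (model.transcript_pos(g) for g in range(g1, g2 + 1)) if t is not None
            )
            if not tpos:
                continue
            run_start = prev = tpos[0]
            for t in tpos[1:]:
                if t != prev + 1:
                    out.append(("del", run_start, prev))
                    run_start = t
                prev = t
            out.append(("del", run_start, prev))
        elif op[0] == "ins":
            _, g, seq = op
            t = model.transcript_pos(g)
            if t is None:
                continue
            if model.strand == "+":
                out.append(("ins", t, seq))
            else:
                out.append(("ins", t - 1, _revcomp(seq)))
        elif op[0] == "sub":
            _, g, refb, alt = op
            ts = [model.transcript_pos(p) for p in range(g, g + len(alt))]
            if any(t is None for t in ts):
                # substitution straddling an exon edge: keep exonic bases only
                keep = [(t, a) for t, a in zip(ts, alt) if t is not None]
                for t, a in keep:
                    out.append(("sub", t, a if model.strand == "+" else _revcomp(a)))
                continue
            if model.strand == "+":
                out.append(("sub", ts[0], alt))
            else:
                out.append(("sub", min(ts), _revcomp(alt)))
        else:
            raise ValueError(f"unknown op {op[0]!r}")
    return out


def _event_transcript_ops(event: EditingEvent, model: GeneModel) -> list[tuple]:
    """Convert a simple (non-compound) EditingEvent into transcript ops."""
    g_lo, g_hi = event.ref_span
    if event.category == "large_deletion" or (event.category == "indel" and event.alt == ""):
        gops: list[tuple] = [("del", g_lo, g_hi)]
    elif event.category == "indel":
        gops = [("ins", g_lo, event.alt)]
    elif event.category == "substitution":
        ref_dummy = "N" * len(event.alt)
        gops = [("sub", g_lo, ref_dummy, event.alt)]
    else:
        raise ValueError(f"unknown event category {event.category!r}")
    return genomic_ops_to_transcript(gops, model)


def apply_edit(
    variant: TranscriptVariant,
    event: EditingEvent | list[tuple],
    model: GeneModel,
) -> TranscriptVariant:
    """Apply a genomic editing event to a wildtype transcript variant.

    Accepts either a simple :class:`EditingEvent` or a list of genomic op
    tuples in the genotyper's format (compound alleles). Purely intronic
    events are a no-op with a warning.
    """
    if isinstance(event, EditingEvent):
        ops = _event_transcript_ops(event, model)
        desc = f"{event.category}@{event.ref_span[0]}-{event.ref_span[1]}"
    else:
        ops = genomic_ops_to_transcript(event, model)
        desc = "+".join(op[0] for op in event) or "empty"
    if not ops:
        warnings.warn(f"{model.gene_id}: event {desc} is entirely intronic; no-op")
        return variant
    seq = variant.seq
    cds_start = variant.cds_start
    cds_lo = variant.cds_start if variant.cds_start is not None else 1
    cds_hi = cds_lo + variant.wt_cds_len - 1
    net = variant.net_coding_indel
    # apply in descending transcript position so coordinates stay valid
    def op_pos(op):
        return op[1]

    for op in sorted(ops, key=op_pos, reverse=True):
        if op[0] == "del":
            _, t1, t2 = op
            seq = seq[: t1 - 1] + seq[t2:]
            overlap = max(0, min(t2, cds_hi) - max(t1, cds_lo) + 1)
            net -= overlap
            if cds_start is not None:
                if t2 < cds_start:
                    cds_start -= t2 - t1 + 1
                elif t1 <= cds_start + 2:  # start codon hit
                    cds_start = None
        elif op[0] == "ins":
            _, t_after, ins = op
            seq = seq[:t_after] + ins + seq[t_after:]
            if cds_lo <= t_after < cds_hi:
                net += len(ins)
            if cds_start is not None and t_after < cds_start:
                cds_start += len(ins)
        else:  # sub
            _, t1, alt = op
            seq = seq[: t1 - 1] + alt + seq[t1 - 1 + len(alt):]
    return TranscriptVariant(
        gene_id=variant.gene_id,
        seq=seq,
        cds_start=cds_start,
        wt_cds_len=variant.wt_cds_len,
        net_coding_indel=net,
        description=desc if variant.description == "wildtype" else f"{variant.description}+{desc}",
    )


def apply_splice_variant(
    model: GeneModel, ref: GenomeRef, skip_exons: set[int]
) -> TranscriptVariant:
    """Transcript with the named exons (1-based transcript ordinals) removed."""
    order = model.exons_in_transcript_order()
    unknown = [k for k in skip_exons if not 1 <= k <= len(order)]
    if unknown:
        raise ValueError(f"{model.gene_id}: no such exon(s) {sorted(unknown)}")
    if len(skip_exons) >= len(order):
        raise ValueError(f"{model.gene_id}: cannot skip every exon")
    wt = wildtype_variant(model, ref)
    if not skip_exons:
        return wt
    # transcript intervals of each exon, in transcript order
    seq_parts = []
    cds_start = wt.cds_start
    net = 0
    offset = 0
    removed_before_start = 0
    start_removed = False
    cds_lo, cds_hi = wt.cds_start, wt.cds_start + wt.wt_cds_len - 1
    for idx, (s, e) in enumerate(order, 1):
        n = e - s + 1
        t1, t2 = offset + 1, offset + n
        if idx in skip_exons:
            net -= max(0, min(t2, cds_hi) - max(t1, cds_lo) + 1)
            if t2 < wt.cds_start:
                removed_before_start += n
            elif t1 <= wt.cds_start + 2 <= t2 or t1 <= wt.cds_start <= t2:
                start_removed = True
        else:
            seq_parts.append(wt.seq[t1 - 1 : t2])
        offset += n
    new_start = None if start_removed else cds_start - removed_before_start
    return TranscriptVariant(
        gene_id=model.gene_id,
        seq="".join(seq_parts),
        cds_start=new_start,
        wt_cds_len=wt.wt_cds_len,
        net_coding_indel=net,
        description=f"skip_exons={sorted(skip_exons)}",
    )


def translate_orf(variant: TranscriptVariant) -> OrfReport:
    """Translate from the (projected) wildtype start to the first in-frame stop."""
    flags: list[str] = []
    start = variant.cds_start
    if start is None or variant.seq[start - 1 : start + 2] != "ATG":
        scan_from = (start or 1) - 1
        idx = variant.seq.find("ATG", scan_from)
        if idx < 0:
            return OrfReport(
                gene_id=variant.gene_id,
                variant=variant.description,
                protein_length_aa=0,
                wt_length_aa=variant.wt_protein_aa,
                frameshift=variant.net_coding_indel % 3 != 0,
                premature_stop=False,
                flags=["no_start"],
            )
        start = idx + 1
        flags.append("alternative_start")
    region = variant.seq[start - 1 :]
    region = region[: len(region) - len(region) % 3]
    aa = str(Seq(region).translate())
    if "*" in aa:
        protein_len = aa.index("*")
        ran_off = False
    else:
        protein_len = len(aa)
        ran_off = True
        flags.append("ran_off_end")
    frameshift = variant.net_coding_indel % 3 != 0
    if ran_off:
        premature = False
    elif "alternative_start" in flags:
        premature = protein_len < variant.wt_protein_aa
    else:
        expected_stop_nt = variant.wt_cds_len + variant.net_coding_indel
        premature = 3 * (protein_len + 1) < expected_stop_nt
    return OrfReport(
        gene_id=variant.gene_id,
        variant=variant.description,
        protein_length_aa=protein_len,
        wt_length_aa=variant.wt_protein_aa,
        frameshift=frameshift,
        premature_stop=premature,
        flags=flags,
    )
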