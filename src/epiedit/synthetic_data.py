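"""Synthetic reference, gene models and pre-aligned reads with known truth.

Emulates targeted single-cell libraries that mix spliced mRNA reads
(junction-spanning reads carry N CIGAR ops) with genomic-amplicon reads over
guide-site exons (contiguous, no N ops), with programmable editing alleles
(indels, substitutions, >10 kb deletions), aberrant splice ratios, base-call
errors, library-size variation and spike-in fractions.

Reads are emitted pre-aligned (the pipeline's scope begins at aligned
reads). Base errors are substitutions only and never land on allele-derived
bases, so truth/call discordance is attributable to the caller. The
aberrant-splice ratio ``r`` is defined per junction read — a read crossing
the skip-donor boundary follows the aberrant acceptor with probability
``r`` — so the read-level estimator downstream is unbiased by
isoform-length differences.

Every draw derives from ``SimConfig.seed``; an identical config reproduces
the output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .edit_genotyper import describe_ops
from .io_core import (
    AlignedRead,
    CountMatrix,
    GeneModel,
    GenomeRef,
    GuideSite,
    write_alignments,
    write_gene_models,
    write_genome,
    write_guide_sites,
)

BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) random non-stop codons + TAA: encodes n_aa residues."""
    codons = [_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), n_aa - 1)]
    return "ATG" + "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# toy reference

SEM_GENE = "semX"
CXC_GENE = "cxcX"
SEM_WT_AA = 791
CXC_WT_AA = 99
CXC_EXON_LENGTHS = (500, 118, 724)  # spliced 1342 bp; exon-2 skip 1224 bp


def make_toy_reference(seed: int = 0) -> tuple[GenomeRef, list[GeneModel], list[GuideSite]]:
    """Build the toy genome: semX (12 exons, guide sites in exons 2 and 10,
    >10 kb apart), cxcX (3 exons, exon 2 = 118 bp, transcript 1342 bp, 99-aa
    protein) and eight non-coding spike-in genes on their own contig.
    """
    rng = np.random.default_rng(seed)

    # --- semX on chrS: 12 exons x 198 bp, introns 1500 bp, CDS = transcript
    n_exons, exon_len, intron_len, flank = 12, 198, 1500, 1000
    sem_exons = []
    pos = flank + 1
    for _ in range(n_exons):
        sem_exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    sem_cds = _random_cds(rng, SEM_WT_AA)  # 2376 nt == 12 * 198
    assert len(sem_cds) == n_exons * exon_len
    chrS = list(_random_seq(rng, sem_exons[-1][1] + flank))
    off = 0
    for s, e in sem_exons:
        chrS[s - 1 : e] = sem_cds[off : off + (e - s + 1)]
        off += e - s + 1
    sem_model = GeneModel(SEM_GENE, "chrS", "+", sem_exons, 1, len(sem_cds))

    # --- cxcX on chrC: exons 500/118/724, CDS at transcript 401..700
    ex1, ex2, ex3 = CXC_EXON_LENGTHS
    c_flank, i1, i2 = 500, 800, 900
    cxc_exons = [
        (c_flank + 1, c_flank + ex1),
        (c_flank + ex1 + i1 + 1, c_flank + ex1 + i1 + ex2),
        (c_flank + ex1 + i1 + ex2 + i2 + 1, c_flank + ex1 + i1 + ex2 + i2 + ex3),
    ]
    transcript = list(_random_seq(rng, sum(CXC_EXON_LENGTHS)))
    cds = _random_cds(rng, CXC_WT_AA)  # 300 nt
    transcript[400:700] = cds
    transcript = "".join(transcript)
    chrC = list(_random_seq(rng, cxc_exons[-1][1] + c_flank))
    off = 0
    for s, e in cxc_exons:
        chrC[s - 1 : e] = transcript[off : off + (e - s + 1)]
        off += e - s + 1
    cxc_model = GeneModel(CXC_GENE, "chrC", "+", cxc_exons, 401, 700)

    # --- spike-in genes on chrE (non-coding, single exon)
    spike_models = []
    chrE: list[str] = []
    pos = 1
    for i in range(8):
        length = 400 + 100 * i
        chrE.extend(_random_seq(rng, length))
        spike_models.append(
            GeneModel(f"ERCC-{i + 1:04d}", "chrE", "+", [(pos, pos + length - 1)])
        )
        gap = _random_seq(rng, 200)
        chrE.extend(gap)
        pos += length + 200

    ref = GenomeRef({"chrS": "".join(chrS), "chrC": "".join(chrC), "chrE": "".join(chrE)})

    def _mid(iv: tuple[int, int]) -> int:
        return (iv[0] + iv[1]) // 2

    sites = [
        GuideSite("sem_sg1", "chrS", _mid(sem_model.exon_by_index(2)), 15),
        GuideSite("sem_sg4", "chrS", _mid(sem_model.exon_by_index(10)), 15),
        # cxc_sg1 near the CDS start (transcript 421), cxc_sg3 in exon 3
        GuideSite("cxc_sg1", "chrC", cxc_model.genomic_pos(421), 15),
        GuideSite("cxc_sg3", "chrC", cxc_model.genomic_pos(660), 15),
    ]
    assert sites[1].cut_pos - sites[0].cut_pos > 10_000
    return ref, [sem_model, cxc_model, *spike_models], sites


# ---------------------------------------------------------------------------
# segment maps: the alignment geometry of a (possibly edited) template


@dataclass
class _Seg:
    seq: str
    gstart: int | None  # 1-based genomic start; None for inserted bases
    gap_before: str = ""  # "", "N" (splice) or "D" (deletion)
    gap_len: int = 0
    pristine: bool = True  # False once bases were substituted


class SegmentMap:
    """Query-to-genome map of a template: ordered blocks with N/D gaps.

    Supports applying small alleles (insertion/deletion/substitution inside
    one block) and emitting reads with correct pos/CIGAR/sequence plus a
    per-base mask of positions that still match the reference (error
    injection is restricted to masked-true positions).
    """

    def __init__(self, chrom: str, segments: list[_Seg]):
        self.chrom = chrom
        self.segments = segments

    @classmethod
    def from_exons(cls, ref: GenomeRef, chrom: str, exons: Sequence[tuple[int, int]]) -> "SegmentMap":
        segs = []
        prev_end = None
        for s, e in exons:
            gap = 0 if prev_end is None else s - prev_end - 1
            segs.append(
                _Seg(ref.fetch(chrom, s, e), s, "N" if prev_end is not None else "", gap)
            )
            prev_end = e
        return cls(chrom, segs)

    @classmethod
    def from_interval(cls, ref: GenomeRef, chrom: str, start: int, end: int) -> "SegmentMap":
        return cls(chrom, [_Seg(ref.fetch(chrom, start, end), start)])

    @property
    def query_length(self) -> int:
        return sum(len(s.seq) for s in self.segments)

    def _locate(self, gpos: int) -> tuple[int, int]:
        for i, seg in enumerate(self.segments):
            if seg.gstart is not None and seg.gstart <= gpos < seg.gstart + len(seg.seq):
                return i, gpos - seg.gstart
        raise ValueError(f"genomic position {gpos} not in map")

    def query_pos(self, gpos: int) -> int:
        """0-based query index of genomic base *gpos*."""
        i, off = self._locate(gpos)
        return sum(len(s.seq) for s in self.segments[:i]) + off

    def _split(self, i: int, off: int) -> None:
        """Split segment i so that its first *off* bases become their own segment."""
        seg = self.segments[i]
        if off == 0 or off == len(seg.seq):
            return
        left = _Seg(seg.seq[:off], seg.gstart, seg.gap_before, seg.gap_len, seg.pristine)
        right = _Seg(seg.seq[off:], None if seg.gstart is None else seg.gstart + off,
                     "", 0, seg.pristine)
        self.segments[i : i + 1] = [left, right]

    def apply_insertion(self, gpos_after: int, seq: str) -> None:
        i, off = self._locate(gpos_after)
        self._split(i, off + 1)
        self.segments.insert(i + 1, _Seg(seq, None))

    def apply_deletion(self, gstart: int, gend: int) -> None:
        i, off = self._locate(gstart)
        seg = self.segments[i]
        if gend >= seg.gstart + len(seg.seq):
            raise ValueError("deletion must lie inside one aligned block")
        self._split(i, off)
        if off > 0:
            i += 1
        # segment i now starts at gstart; carve the deleted bases off its front
        seg = self.segments[i]
        ndel = gend - gstart + 1
        if ndel >= len(seg.seq):
            raise ValueError("deletion would remove an entire block edge")
        self.segments[i] = _Seg(
            seg.seq[ndel:], seg.gstart + ndel, "D", ndel, seg.pristine
        )

    def apply_substitution(self, gstart: int, new_bases: str) -> None:
        i, off = self._locate(gstart)
        seg = self.segments[i]
        if off + len(new_bases) > len(seg.seq):
            raise ValueError("substitution must lie inside one aligned block")
        self._split(i, off)
        if off > 0:
            i += 1
        seg = self.segments[i]
        self._split(i, len(new_bases))
        self.segments[i] = _Seg(new_bases, seg.gstart, seg.gap_before, seg.gap_len, False)

    def read_at(self, q0: int, length: int) -> tuple[int, str, str, list[bool]]:
        """Emit the read covering query interval [q0, q0+length).

        Returns (pos, cigar, seq, pristine_mask). Inserted bases at the read
        edges are soft-clipped, as an aligner would report them.
        """
        if q0 < 0 or q0 + length > self.query_length:
            raise ValueError("read outside template")
        pieces: list[tuple[str, str, bool, str, int]] = []  # (op, seq, pristine, gap_op, gap_len)
        qoff = 0
        first = True
        for seg in self.segments:
            seg_len = len(seg.seq)
            lo = max(q0, qoff)
            hi = min(q0 + length, qoff + seg_len)
            if lo < hi:
                piece = seg.seq[lo - qoff : hi - qoff]
                op = "M" if seg.gstart is not None else "I"
                gap_op, gap_len = ("", 0) if first else (seg.gap_before, seg.gap_len)
                pieces.append((op, piece, seg.pristine and op == "M", gap_op, gap_len))
                first = False
            qoff += seg_len
            if qoff >= q0 + length:
                break
        # leading/trailing insertions become soft clips
        ops: list[tuple[str, int]] = []
        seq_parts: list[str] = []
        mask: list[bool] = []
        pos: int | None = None
        n_pieces = len(pieces)
        for idx, (op, piece, pristine, gap_op, gap_len) in enumerate(pieces):
            if gap_op and gap_len > 0 and ops:
                ops.append((gap_op, gap_len))
            eff_op = op
            if op == "I" and (idx == 0 or idx == n_pieces - 1):
                eff_op = "S"
            if eff_op == "M" and pos is None:
                # genomic pos of first aligned base of this piece
                consumed = sum(len(p[1]) for p in pieces[:idx])
                seg_q0 = q0 + consumed
                pos = self._genomic_of_query(seg_q0)
            ops.append((eff_op, len(piece)))
            seq_parts.append(piece)
            mask.extend([pristine] * len(piece))
        if pos is None:
            raise ValueError("read contains no reference-aligned bases")
        merged: list[tuple[str, int]] = []
        for op, n in ops:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        cigar = "".join(f"{n}{op}" for op, n in merged)
        return pos, cigar, "".join(seq_parts), mask

    def _genomic_of_query(self, q: int) -> int:
        qoff = 0
        for seg in self.segments:
            if qoff <= q < qoff + len(seg.seq):
                if seg.gstart is None:
                    raise ValueError("query position falls in an insertion")
                return seg.gstart + (q - qoff)
            qoff += len(seg.seq)
        raise ValueError("query position outside map")


# ---------------------------------------------------------------------------
# simulation config / truth


@dataclass
class AlleleSpec:
    kind: str  # insertion | deletion | substitution | large_deletion | random
    length: int = 0
    partner: str | None = None

    def __post_init__(self) -> None:
        kinds = {"insertion", "deletion", "substitution", "large_deletion", "random"}
        if self.kind not in kinds:
            raise ValueError(f"unknown allele kind {self.kind!r}")
        if self.kind == "large_deletion" and self.partner is None:
            raise ValueError("large_deletion allele needs a partner site")


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the targeted single-cell libraries: 75-bp reads, ~30
    amplicon reads per guide site, half of samples carrying an edit, and a
    0.2 aberrant-splice ratio at the declared skip junction.
    """

    seed: int = 0
    n_samples: int = 8
    depth_mrna: int = 60  # expected mRNA reads per gene per sample
    depth_amplicon: int = 30  # amplicon reads per guide site per sample
    read_len: int = 75
    edited_fraction: float | dict[str, float] = 0.5
    allele_spec: dict[str, AlleleSpec] = field(default_factory=dict)
    allele_read_fraction: float | dict[str, float] = 1.0
    aberrant_splice_ratio: float = 0.2
    splice_targets: dict[str, tuple[int, tuple[int, ...]]] = field(
        default_factory=lambda: {CXC_GENE: (1, (2,))}
    )  # gene -> (donor exon index, contiguous skipped exon indices)
    seq_error_rate: float = 0.0
    library_size_sigma: float = 0.0  # lognormal sigma of per-sample depth factor
    ercc_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.seq_error_rate <= 0.05:
            raise ValueError("seq_error_rate must be in [0, 0.05]")
        if not 0 <= self.aberrant_splice_ratio <= 1:
            raise ValueError("aberrant_splice_ratio must be in [0, 1]")
        if not 0 <= self.ercc_fraction < 1:
            raise ValueError("ercc_fraction must be in [0, 1)")
        for v in (
            self.edited_fraction.values()
            if isinstance(self.edited_fraction, dict)
            else [self.edited_fraction]
        ):
            if not 0 <= v <= 1:
                raise ValueError("edited_fraction must be in [0, 1]")

    def edited_fraction_for(self, site: str) -> float:
        if isinstance(self.edited_fraction, dict):
            return self.edited_fraction.get(site, 0.0)
        return self.edited_fraction

    def allele_read_fraction_for(self, site: str) -> float:
        if isinstance(self.allele_read_fraction, dict):
            return self.allele_read_fraction.get(site, 1.0)
        return self.allele_read_fraction


@dataclass
class SimTruth:
    """Ground-truth manifest: the acceptance oracle for every stage."""

    editing: pd.DataFrame  # sample_id, site, edited, allele
    splicing: pd.DataFrame  # sample_id, gene_id, canonical_reads, aberrant_reads
    counts: pd.DataFrame  # genes x samples mRNA read counts
    models: list[GeneModel] = field(default_factory=list)


def write_truth_manifest(truth: SimTruth, path: str | Path) -> None:
    truth.editing.to_csv(path, sep="\t", index=False)


def read_truth_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "site": str, "allele": str}, keep_default_na=False
    )
    df["edited"] = df["edited"].map(
        lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v) == "True"
    )
    return df


# ---------------------------------------------------------------------------
# read simulation


def _draw_allele(rng: np.random.Generator, spec: AlleleSpec, ref: GenomeRef, site: GuideSite):
    """Realize an allele at a cut site; returns (ops, kind) for SegmentMap use."""
    kind = spec.kind
    if kind == "random":
        kind = ("deletion", "insertion", "substitution")[rng.integers(0, 3)]
        length = int(rng.integers(1, 13)) if kind != "substitution" else int(rng.integers(1, 4))
    else:
        length = spec.length
    cut = site.cut_pos
    if kind == "deletion":
        return [("del", cut, cut + length - 1)], "deletion"
    if kind == "insertion":
        return [("ins", cut, _random_seq(rng, length))], "insertion"
    if kind == "substitution":
        refbases = ref.fetch(site.chrom, cut, cut + length - 1)
        alt = "".join(
            BASES[(list("ACGT").index(b) + 1 + rng.integers(0, 3)) % 4] for b in refbases
        )
        return [("sub", cut, refbases, alt)], "substitution"
    raise AssertionError(kind)


def _apply_ops(m: SegmentMap, ops: list[tuple]) -> None:
    for op in ops:
        if op[0] == "del":
            m.apply_deletion(op[1], op[2])
        elif op[0] == "ins":
            m.apply_insertion(op[1], op[2])
        else:
            m.apply_substitution(op[1], op[3])


def _inject_errors(rng: np.random.Generator, seq: str, mask: list[bool], rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        if not mask[i]:
            continue
        shift = 1 + rng.integers(0, 3)
        out[i] = BASES[(list("ACGT").index(out[i]) + shift) % 4] if out[i] in "ACGT" else out[i]
    return "".join(out)


def _amplicon_reads(
    rng: np.random.Generator,
    ref: GenomeRef,
    site: GuideSite,
    allele_ops: list[tuple] | None,
    allele_read_frac: float,
    n_reads: int,
    read_len: int,
    error_rate: float,
    sample_id: str,
) -> list[AlignedRead]:
    pad = 150
    wt = SegmentMap.from_interval(ref, site.chrom, site.cut_pos - pad, site.cut_pos + pad)
    ed = None
    if allele_ops:
        ed = SegmentMap.from_interval(ref, site.chrom, site.cut_pos - pad, site.cut_pos + pad)
        _apply_ops(ed, allele_ops)
    reads = []
    lo, hi = site.cut_pos - site.window - 2, site.cut_pos + site.window + 2
    for k in range(n_reads):
        use_ed = ed is not None and rng.random() < allele_read_frac
        m = ed if use_ed else wt
        ql = m.query_pos(lo)
        qr = m.query_pos(hi)
        q_min = max(0, qr - read_len + 1)
        q_max = min(ql, m.query_length - read_len)
        if q_min > q_max:
            raise ValueError(
                f"allele at {site.name} too long for read length {read_len}"
            )
        q0 = int(rng.integers(q_min, q_max + 1))
        pos, cigar, seq, mask = m.read_at(q0, read_len)
        seq = _inject_errors(rng, seq, mask, error_rate)
        reads.append(
            AlignedRead(f"{sample_id}_{site.name}_a{k}", site.chrom, pos, cigar, seq, sample_id)
        )
    return reads


def _split_deletion_reads(
    ref: GenomeRef,
    site_a: GuideSite,
    site_b: GuideSite,
    n_reads: int,
    sample_id: str,
) -> list[AlignedRead]:
    """Split-alignment read pairs whose blocks flank both cut positions."""
    a, b = sorted((site_a, site_b), key=lambda s: s.cut_pos)
    reads = []
    for k in range(n_reads):
        qname = f"{sample_id}_{a.name}_{b.name}_ld{k}"
        left_end = a.cut_pos - 10
        right_start = b.cut_pos + 10
        left_seq = ref.fetch(a.chrom, left_end - 59, left_end)
        right_seq = ref.fetch(a.chrom, right_start, right_start + 14)
        seq = left_seq + right_seq
        reads.append(
            AlignedRead(qname, a.chrom, left_end - 59, "60M15S", seq, sample_id)
        )
        reads.append(
            AlignedRead(
                qname, a.chrom, right_start, "60S15M", seq, sample_id, is_supplementary=True
            )
        )
    return reads


def _transcript_maps(
    ref: GenomeRef,
    model: GeneModel,
    exonic_ops: list[tuple],
    splice_target: tuple[int, tuple[int, ...]] | None,
) -> tuple[SegmentMap, SegmentMap | None, int | None]:
    """(wildtype-structure map, skip-isoform map, donor_end genomic) with edits applied."""
    if model.strand != "+":
        raise ValueError("read simulation supports + strand gene models only")
    wt = SegmentMap.from_exons(ref, model.chrom, model.exons)
    skip = None
    donor_end = None
    if splice_target is not None:
        donor_exon, skip_block = splice_target
        donor_end = model.exon_by_index(donor_exon)[1]
        kept = [
            iv
            for idx, iv in enumerate(model.exons_in_transcript_order(), 1)
            if idx not in skip_block
        ]
        skip = SegmentMap.from_exons(ref, model.chrom, sorted(kept))
    for m in (wt, skip):
        if m is None:
            continue
        for op in exonic_ops:
            gpos = op[1]
            try:
                m._locate(gpos)
            except ValueError:
                continue  # edit falls in a skipped exon
            _apply_ops(m, [op])
    return wt, skip, donor_end


def simulate_reads(
    config: SimConfig,
    ref: GenomeRef,
    models: Sequence[GeneModel],
    sites: Sequence[GuideSite],
) -> tuple[dict[str, list[AlignedRead]], SimTruth]:
    """Simulate the full cohort; returns per-sample reads and the truth manifest."""
    site_by_name = {s.name: s for s in sites}
    coding = [m for m in models if not m.gene_id.startswith("ERCC-")]
    spikes = [m for m in models if m.gene_id.startswith("ERCC-")]
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]

    edit_rows = []
    splice_rows = []
    count_rows: dict[str, dict[str, int]] = {m.gene_id: {} for m in models}
    reads_by_sample: dict[str, list[AlignedRead]] = {}

    for i, sid in enumerate(sample_ids):
        rng = np.random.default_rng([config.seed, i])
        lib = float(np.exp(rng.normal(0.0, config.library_size_sigma))) if config.library_size_sigma else 1.0
        reads: list[AlignedRead] = []

        # --- editing status per site
        allele_ops: dict[str, list[tuple]] = {}
        edited: dict[str, bool] = {}
        allele_desc: dict[str, str] = {}
        ld_pairs: list[tuple[GuideSite, GuideSite]] = []
        skip_sites: set[str] = set()
        for site in sites:
            if site.name in skip_sites:
                continue
            spec = config.allele_spec.get(site.name, AlleleSpec("random"))
            is_edited = rng.random() < config.edited_fraction_for(site.name)
            if spec.kind == "large_deletion":
                partner = site_by_name[spec.partner]
                edited[site.name] = edited[partner.name] = is_edited
                skip_sites.add(partner.name)
                if is_edited:
                    a, b = sorted((site, partner), key=lambda s: s.cut_pos)
                    desc = f"large_del@{a.cut_pos}-{b.cut_pos}"
                    allele_desc[site.name] = allele_desc[partner.name] = desc
                    ld_pairs.append((site, partner))
                continue
            edited[site.name] = is_edited
            if is_edited:
                ops, _kind = _draw_allele(rng, spec, ref, site)
                allele_ops[site.name] = ops
                allele_desc[site.name] = describe_ops(ops)

        for site in sites:
            edit_rows.append(
                {
                    "sample_id": sid,
                    "site": site.name,
                    "edited": edited[site.name],
                    "allele": allele_desc.get(site.name, ""),
                }
            )

        # --- amplicon reads
        for site in sites:
            spec = config.allele_spec.get(site.name, AlleleSpec("random"))
            is_ld_site = spec.kind == "large_deletion" or site.name in skip_sites
            if is_ld_site and edited[site.name]:
                continue  # the deleted template yields split reads, not amplicons
            reads.extend(
                _amplicon_reads(
                    rng,
                    ref,
                    site,
                    allele_ops.get(site.name),
                    config.allele_read_fraction_for(site.name),
                    config.depth_amplicon,
                    config.read_len,
                    config.seq_error_rate,
                    sid,
                )
            )
        for site_a, site_b in ld_pairs:
            n_split = max(1, config.depth_amplicon // 2)
            reads.extend(_split_deletion_reads(ref, site_a, site_b, n_split, sid))

        # --- mRNA reads per coding gene
        total_mrna = 0
        for model in coding:
            gene_sites = [s for s in sites if s.chrom == model.chrom]
            deleted_span = None
            for site_a, site_b in ld_pairs:
                if site_a.chrom == model.chrom:
                    lo, hi = sorted((site_a.cut_pos, site_b.cut_pos))
                    deleted_span = (lo, hi)
            if deleted_span:
                # exons inside the deleted span are gone from the transcript
                kept = [iv for iv in model.exons if not (deleted_span[0] <= iv[0] and iv[1] <= deleted_span[1])]
                eff_model = GeneModel(model.gene_id, model.chrom, model.strand, kept)
            else:
                eff_model = model
            exonic_ops = []
            for s in gene_sites:
                for op in allele_ops.get(s.name, []):
                    exonic_ops.append(op)
            wt_map, skip_map, donor_end = _transcript_maps(
                ref, eff_model, exonic_ops, config.splice_targets.get(model.gene_id)
            )
            n_reads = int(rng.poisson(config.depth_mrna * lib))
            if wt_map.query_length < config.read_len:
                n_reads = 0
            canonical = aberrant = 0
            q_donor = None
            q_donor_skip = None
            if donor_end is not None and skip_map is not None:
                try:
                    q_donor = wt_map.query_pos(donor_end)
                    q_donor_skip = skip_map.query_pos(donor_end)
                except ValueError:
                    q_donor = None
            for k in range(n_reads):
                m = wt_map
                q0 = int(rng.integers(0, wt_map.query_length - config.read_len + 1))
                if q_donor is not None and q0 <= q_donor and q0 + config.read_len - 1 > q_donor:
                    if rng.random() < config.aberrant_splice_ratio:
                        m = skip_map
                        q0 = q0 - q_donor + q_donor_skip
                        aberrant += 1
                    else:
                        canonical += 1
                pos, cigar, seq, mask = m.read_at(q0, config.read_len)
                seq = _inject_errors(rng, seq, mask, config.seq_error_rate)
                reads.append(
                    AlignedRead(f"{sid}_{model.gene_id}_m{k}", model.chrom, pos, cigar, seq, sid)
                )
            total_mrna += n_reads
            count_rows[model.gene_id][sid] = n_reads
            if config.splice_targets.get(model.gene_id) is not None:
                splice_rows.append(
                    {
                        "sample_id": sid,
                        "gene_id": model.gene_id,
                        "canonical_reads": canonical,
                        "aberrant_reads": aberrant,
                    }
                )

        # --- spike-in reads
        if config.ercc_fraction > 0 and spikes:
            f = config.ercc_fraction
            n_spike = int(rng.poisson(total_mrna * f / (1 - f)))
            for k in range(n_spike):
                model = spikes[int(rng.integers(0, len(spikes)))]
                m = SegmentMap.from_exons(ref, model.chrom, model.exons)
                if m.query_length < config.read_len:
                    continue
                q0 = int(rng.integers(0, m.query_length - config.read_len + 1))
                pos, cigar, seq, mask = m.read_at(q0, config.read_len)
                seq = _inject_errors(rng, seq, mask, config.seq_error_rate)
                reads.append(
                    AlignedRead(f"{sid}_{model.gene_id}_e{k}", model.chrom, pos, cigar, seq, sid)
                )
                count_rows[model.gene_id][sid] = count_rows[model.gene_id].get(sid, 0) + 1
        for m in spikes:
            count_rows[m.gene_id].setdefault(sid, 0)

        reads_by_sample[sid] = reads

    counts = pd.DataFrame(count_rows).T.reindex(
        index=[m.gene_id for m in models], columns=sample_ids
    ).fillna(0).astype(int)
    truth = SimTruth(
        editing=pd.DataFrame(edit_rows, columns=["sample_id", "site", "edited", "allele"]),
        splicing=pd.DataFrame(
            splice_rows, columns=["sample_id", "gene_id", "canonical_reads", "aberrant_reads"]
        ),
        counts=counts,
        models=list(models),
    )
    return reads_by_sample, truth


def simulate_junction_reads(
    ref: GenomeRef,
    model: GeneModel,
    donor_exon: int,
    skip_block: tuple[int, ...],
    ratio: float,
    n_reads: int,
    seed: int,
    read_len: int = 75,
) -> tuple[list[AlignedRead], int]:
    """Emit exactly *n_reads* reads crossing the donor boundary of *donor_exon*,
    each following the skip acceptor with probability *ratio*.

    Returns (reads, n_aberrant_realized). Used for focused splice-fraction
    recovery runs where the full cohort generator would be wasteful.
    """
    rng = np.random.default_rng(seed)
    wt, skip, donor_end = _transcript_maps(ref, model, [], (donor_exon, skip_block))
    q_donor = wt.query_pos(donor_end)
    q_donor_skip = skip.query_pos(donor_end)
    reads = []
    n_aberrant = 0
    for k in range(n_reads):
        # q0 chosen so the read covers >=1 base each side of the junction
        q0 = int(rng.integers(q_donor - read_len + 2, q_donor + 1))
        if rng.random() < ratio:
            m, qq = skip, q0 - q_donor + q_donor_skip
            n_aberrant += 1
        else:
            m, qq = wt, q0
        pos, cigar, seq, _ = m.read_at(qq, read_len)
        reads.append(AlignedRead(f"j{k}", model.chrom, pos, cigar, seq, "bulk"))
    return reads, n_aberrant


def simulate_to_dir(
    config: SimConfig,
    out_dir: str | Path,
    ref: GenomeRef | None = None,
    models: Sequence[GeneModel] | None = None,
    sites: Sequence[GuideSite] | None = None,
) -> tuple[Path, SimTruth]:
    """Simulate a cohort and write FASTA/annotation/sites, per-sample SAMs and
    the truth manifest under *out_dir*. Returns (out_dir, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ref is None:
        ref, models, sites = make_toy_reference(config.seed)
    write_genome(ref, out / "reference.fa")
    write_gene_models(models, out / "genes.gff")
    write_guide_sites(sites, out / "sites.tsv")
    reads_by_sample, truth = simulate_reads(config, ref, models, sites)
    sam_dir = out / "alignments"
    sam_dir.mkdir(exist_ok=True)
    for sid, reads in reads_by_sample.items():
        write_alignments(reads, sam_dir / f"{sid}.sam", ref)
    write_truth_manifest(truth, out / "truth_editing.tsv")
    truth.splicing.to_csv(out / "truth_splicing.tsv", sep="\t", index=False)
    truth.counts.to_csv(out / "truth_counts.tsv", sep="\t", index_label="gene_id")
    return out, truth


# ---------------------------------------------------------------------------
# count-matrix generator (for the single-cell QC / marker stages)

_DEFAULT_GROUP_COMBOS: dict[str, dict[tuple[str, ...], float]] = {
    # only Epi1 contains triple-positive cells; Epi2 is mostly tbx18-only,
    # Epi3 mostly tcf21-only
    "Epi1": {
        ("tcf21", "tbx18", "wt1b"): 0.40,
        ("tcf21", "tbx18"): 0.15,
        ("tcf21", "wt1b"): 0.15,
        ("tcf21",): 0.10,
        ("tbx18",): 0.10,
        (): 0.10,
    },
    "Epi2": {("tbx18",): 0.80, ("tcf21", "tbx18"): 0.10, (): 0.10},
    "Epi3": {("tcf21",): 0.70, ("tcf21", "wt1b"): 0.15, (): 0.15},
}


def simulate_count_matrix(
    seed: int = 0,
    n_cells_per_group: int = 40,
    n_genes: int = 150,
    n_ercc: int = 20,
    n_mito: int = 5,
    marker_genes: tuple[str, ...] = ("tcf21", "tbx18", "wt1b"),
    group_combo_probs: dict[str, dict[tuple[str, ...], float]] | None = None,
    n_empty_wells: int = 3,
    library_size_sigma: float = 0.35,
    marker_mean: float = 40.0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Gene-by-cell counts with marker-combination, spike-in and empty-well truth.

    Returns the matrix and a truth table (cell, group, combination,
    is_empty). Empty wells emulate processed wells without a cell: all
    counts scaled to ~1% depth; they are expected to fail QC.
    """
    rng = np.random.default_rng(seed)
    if group_combo_probs is None:
        group_combo_probs = _DEFAULT_GROUP_COMBOS
    genes = [f"g{i:04d}" for i in range(n_genes)]
    mito = [f"mt-g{i}" for i in range(n_mito)]
    ercc = [f"ERCC-{i + 1:05d}" for i in range(n_ercc)]
    all_genes = list(marker_genes) + genes + mito + ercc
    lengths = pd.Series(
        rng.integers(500, 3000, len(all_genes)), index=all_genes, name="gene_length_bp"
    )
    gene_mean = np.exp(rng.normal(0.5, 1.2, n_genes))
    mito_mean = np.exp(rng.normal(2.0, 0.5, n_mito))
    ercc_mean = np.exp(rng.normal(0.8, 0.8, n_ercc))

    cells = []
    truth_rows = []
    cols = {}
    for group, combos in group_combo_probs.items():
        labels = list(combos)
        probs = np.array([combos[label] for label in labels], dtype=float)
        probs = probs / probs.sum()
        for j in range(n_cells_per_group):
            cell = f"{group}_c{j:03d}"
            lib = float(np.exp(rng.normal(0.0, library_size_sigma)))
            combo = labels[int(rng.choice(len(labels), p=probs))]
            marker_counts = [
                rng.poisson(marker_mean * lib) + 1 if g in combo else 0 for g in marker_genes
            ]
            col = np.concatenate(
                [
                    np.array(marker_counts),
                    rng.poisson(gene_mean * lib),
                    rng.poisson(mito_mean * lib),
                    rng.poisson(ercc_mean),  # spike input is constant per well
                ]
            )
            cols[cell] = col
            cells.append(cell)
            truth_rows.append(
                {
                    "cell": cell,
                    "group": group,
                    "combination": "+".join(combo) if combo else "none",
                    "is_empty": False,
                }
            )
    for j in range(n_empty_wells):
        cell = f"empty_c{j:03d}"
        col = np.concatenate(
            [
                np.zeros(len(marker_genes), dtype=int),
                rng.poisson(gene_mean * 0.01),
                rng.poisson(mito_mean * 0.01),
                rng.poisson(ercc_mean),
            ]
        )
        cols[cell] = col
        cells.append(cell)
        truth_rows.append(
            {"cell": cell, "group": "empty", "combination": "none", "is_empty": True}
        )
    counts = pd.DataFrame(cols, index=all_genes).astype(int)
    return CountMatrix(counts, lengths), pd.DataFrame(truth_rows)
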