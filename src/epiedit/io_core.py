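"""Data model, coordinate conventions and readers/writers.

All coordinates are 1-based inclusive (SAM/GFF convention). Half-open
arithmetic, where used, is internal to a function and noted there.

The domain types here are deliberately small: a genome is a mapping of
chromosome names to uppercase sequences, a gene model is a single-transcript
exon/CDS structure, and an aligned read carries exactly the fields the
downstream genotyping and splicing stages consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq


class FormatError(ValueError):
    """A file did not conform to the expected format."""


# ---------------------------------------------------------------------------
# genome

VALID_BASES = set("ACGTN")


@dataclass
class GenomeRef:
    """Named chromosome sequences; the coordinate frame for everything else."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if sum(len(s) for s in self.sequences.values()) == 0:
            raise FormatError("genome has zero total length")
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"chromosome {name!r} contains invalid bases {sorted(bad)}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` over the 1-based inclusive interval [start, end]."""
        if start < 1 or end > len(self.sequences[chrom]) or start > end:
            raise ValueError(f"interval {chrom}:{start}-{end} out of bounds")
        return self.sequences[chrom][start - 1 : end]


def read_genome(path: str | Path) -> GenomeRef:
    """Load a FASTA file into a :class:`GenomeRef` (sequences uppercased)."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate chromosome name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeRef(seqs)


def write_genome(ref: GenomeRef, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CIGAR helpers

_CIGAR_RE = re.compile(r"(\d+)([MIDNSH=X])")

#: ops that consume the query sequence
QUERY_OPS = set("MIS=X")
#: ops that consume the reference
REF_OPS = set("MDN=X")

_OP_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "=": 7, "X": 8}
_CODE_OP = {v: k for k, v in _OP_CODE.items()}


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise FormatError(f"malformed CIGAR string {cigar!r}")
    return ops


def cigar_query_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in QUERY_OPS)


def cigar_ref_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in REF_OPS)


# ---------------------------------------------------------------------------
# aligned reads


@dataclass
class AlignedRead:
    """One aligned sequencing read; the unit of evidence for genotyping.

    ``seq`` holds the full query sequence including soft-clipped bases.
    Hard clips consume neither query nor reference; soft clips consume
    query only (SAM standard).
    """

    query_name: str
    chrom: str
    pos: int  # 1-based leftmost aligned reference position
    cigar: str
    seq: str
    sample_id: str | None = None
    is_duplicate: bool = False
    is_supplementary: bool = False
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"read {self.query_name!r}: pos {self.pos} < 1")
        qlen = cigar_query_length(self.cigar)
        if qlen != len(self.seq):
            raise FormatError(
                f"read {self.query_name!r}: CIGAR query length {qlen} != "
                f"sequence length {len(self.seq)}"
            )

    @property
    def cigartuples(self) -> list[tuple[str, int]]:
        return parse_cigar(self.cigar)

    @property
    def ref_end(self) -> int:
        """1-based inclusive rightmost aligned reference position."""
        return self.pos + cigar_ref_length(self.cigar) - 1

    def ref_blocks(self) -> list[tuple[int, int]]:
        """Contiguous reference segments (1-based inclusive), split at N ops.

        D ops are merged into the surrounding block: a deletion still covers
        the reference, a splice gap does not.
        """
        blocks: list[tuple[int, int]] = []
        ref = self.pos
        start: int | None = None
        for op, n in self.cigartuples:
            if op in "M=XD":
                if start is None:
                    start = ref
                ref += n
            elif op == "N":
                if start is not None:
                    blocks.append((start, ref - 1))
                    start = None
                ref += n
        if start is not None:
            blocks.append((start, ref - 1))
        return blocks

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_index0, ref_pos1) for every M/=/X-aligned base."""
        q, r = 0, self.pos
        for op, n in self.cigartuples:
            if op in "M=X":
                for i in range(n):
                    yield q + i, r + i
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n


def read_alignments(
    paths: str | Path | Sequence[str | Path],
    drop_duplicates: bool = True,
    sample_id: str | None = None,
) -> Iterator[AlignedRead]:
    """Stream mapped reads from one or more SAM files (merged).

    Unmapped reads are skipped. When *drop_duplicates* is set, records with
    the duplicate flag are omitted. ``sample_id`` defaults to each record's
    RG tag when present.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    for path in paths:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped:
                    continue
                if drop_duplicates and rec.is_duplicate:
                    continue
                if rec.cigarstring is None or rec.query_sequence is None:
                    raise FormatError(
                        f"mapped read {rec.query_name!r} lacks CIGAR or sequence"
                    )
                sid = sample_id
                if sid is None and rec.has_tag("RG"):
                    sid = str(rec.get_tag("RG"))
                yield AlignedRead(
                    query_name=rec.query_name,
                    chrom=rec.reference_name,
                    pos=rec.reference_start + 1,
                    cigar=rec.cigarstring,
                    seq=rec.query_sequence,
                    sample_id=sid,
                    is_duplicate=rec.is_duplicate,
                    is_supplementary=rec.is_supplementary,
                    mate_chrom=rec.next_reference_name if rec.next_reference_id >= 0 else None,
                    mate_pos=rec.next_reference_start + 1 if rec.next_reference_start >= 0 else None,
                )


def write_alignments(
    reads: Iterable[AlignedRead],
    path: str | Path,
    ref_lengths: dict[str, int] | GenomeRef,
) -> None:
    """Write reads to a plain-text SAM file with @SQ lines from *ref_lengths*."""
    if isinstance(ref_lengths, GenomeRef):
        ref_lengths = {c: len(s) for c, s in ref_lengths.sequences.items()}
    reads = list(reads)
    groups = sorted({r.sample_id for r in reads if r.sample_id is not None})
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in ref_lengths.items()],
        "RG": [{"ID": g, "SM": g} for g in groups],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tid = {c: i for i, c in enumerate(ref_lengths)}
        for r in sorted(reads, key=lambda x: (tid[x.chrom], x.pos, x.query_name)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.query_name
            a.reference_id = tid[r.chrom]
            a.reference_start = r.pos - 1
            a.cigarstring = r.cigar
            a.query_sequence = r.seq
            a.mapping_quality = 60
            flag = 0
            if r.is_duplicate:
                flag |= 0x400
            if r.is_supplementary:
                flag |= 0x800
            a.flag = flag
            if r.mate_chrom is not None:
                a.next_reference_id = tid[r.mate_chrom]
                a.next_reference_start = (r.mate_pos or 1) - 1
            if r.sample_id is not None:
                a.set_tag("RG", r.sample_id)
            out.write(a)


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """Exon/CDS structure of a gene (one transcript per gene).

    ``exons`` are 1-based inclusive genomic intervals in ascending genomic
    order. ``cds_start``/``cds_end`` are transcript-relative 1-based positions
    (``None`` for non-coding models such as spike-ins). On the minus strand
    exon_index 1 is the genomically last exon.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise FormatError(f"{self.gene_id}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"{self.gene_id}: exon {s}-{e} inverted")
            if s <= prev_end:
                raise FormatError(f"{self.gene_id}: overlapping exons at {s}-{e}")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise FormatError(f"{self.gene_id}: partial CDS specification")
        if self.cds_start is not None:
            if not 1 <= self.cds_start < self.cds_end <= self.transcript_length:
                raise FormatError(
                    f"{self.gene_id}: CDS [{self.cds_start},{self.cds_end}] outside "
                    f"transcript of length {self.transcript_length}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def exon_by_index(self, exon_index: int) -> tuple[int, int]:
        """Genomic interval of the 1-based transcript-order exon ordinal."""
        return self.exons_in_transcript_order()[exon_index - 1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def junctions(self) -> set[tuple[int, int]]:
        """(donor_end, acceptor_start) genomic pairs for consecutive exons."""
        return {
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        }

    def splice(self, ref: GenomeRef) -> str:
        """Spliced transcript sequence (reverse-complemented on - strand)."""
        seq = "".join(ref.fetch(self.chrom, s, e) for s, e in self.exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def transcript_pos(self, genomic_pos: int) -> int | None:
        """Transcript-relative 1-based position of a genomic base (None if intronic)."""
        offset = 0
        for s, e in self.exons:
            if s <= genomic_pos <= e:
                plus_pos = offset + (genomic_pos - s) + 1
                if self.strand == "+":
                    return plus_pos
                return self.transcript_length - plus_pos + 1
            offset += e - s + 1
        return None

    def genomic_pos(self, tpos: int) -> int:
        """Genomic position of transcript-relative 1-based position *tpos*."""
        if not 1 <= tpos <= self.transcript_length:
            raise ValueError(f"transcript position {tpos} outside gene {self.gene_id}")
        if self.strand == "-":
            tpos = self.transcript_length - tpos + 1
        offset = 0
        for s, e in self.exons:
            n = e - s + 1
            if tpos <= offset + n:
                return s + (tpos - offset - 1)
            offset += n
        raise AssertionError("unreachable")

    def cds_sequence(self, ref: GenomeRef) -> str:
        if self.cds_start is None:
            raise ValueError(f"{self.gene_id} has no CDS")
        return self.splice(ref)[self.cds_start - 1 : self.cds_end]


def _attr_dict(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        else:
            bits = part.split(None, 1)
            if len(bits) != 2:
                continue
            k, v = bits
        out[k.strip()] = v.strip().strip('"')
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse the 9-column GFF3-style annotation into GeneModel objects.

    Recognised features are ``exon`` and ``CDS``; attributes must carry
    ``gene_id``. CDS rows are genomic intervals and are converted to
    transcript-relative coordinates.
    """
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    cds_rows: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = cols
            if feature not in ("exon", "CDS"):
                continue
            gid = _attr_dict(attrs).get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            meta.setdefault(gid, (chrom, strand))
            if meta[gid] != (chrom, strand):
                raise FormatError(f"{path}:{lineno}: inconsistent chrom/strand for {gid}")
            iv = (int(start), int(end))
            (exon_rows if feature == "exon" else cds_rows).setdefault(gid, []).append(iv)

    models = []
    for gid, exons in exon_rows.items():
        chrom, strand = meta[gid]
        model = GeneModel(gid, chrom, strand, exons)  # validates exons
        if gid in cds_rows:
            cds = sorted(cds_rows[gid])
            tpos = []
            for s, e in cds:
                for g in (s, e):
                    t = model.transcript_pos(g)
                    if t is None:
                        raise FormatError(f"{gid}: CDS base {g} not exonic")
                    tpos.append(t)
            model = GeneModel(gid, chrom, strand, exons, min(tpos), max(tpos))
        models.append(model)
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            order = m.exons_in_transcript_order()
            for idx, (s, e) in enumerate(order, 1):
                fh.write(
                    f"{m.chrom}\tepiedit\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"gene_id={m.gene_id};exon_number={idx}\n"
                )
            if m.cds_start is not None:
                # project the transcript-relative CDS back onto exon pieces
                for s, e in m.exons:
                    ts = [m.transcript_pos(g) for g in (s, e)]
                    lo, hi = min(ts), max(ts)
                    a, b = max(lo, m.cds_start), min(hi, m.cds_end)
                    if a > b:
                        continue
                    g1, g2 = m.genomic_pos(a), m.genomic_pos(b)
                    fh.write(
                        f"{m.chrom}\tepiedit\tCDS\t{min(g1, g2)}\t{max(g1, g2)}\t.\t"
                        f"{m.strand}\t.\tgene_id={m.gene_id}\n"
                    )


# ---------------------------------------------------------------------------
# guide sites


@dataclass
class GuideSite:
    """A CRISPR guide target: cut position plus an evidence window half-width."""

    name: str
    chrom: str
    cut_pos: int
    window: int = 15

    def __post_init__(self) -> None:
        if self.window < 0:
            raise FormatError(f"site {self.name}: window must be >= 0")
        if self.cut_pos < 1:
            raise FormatError(f"site {self.name}: cut_pos must be >= 1")

    @property
    def interval(self) -> tuple[int, int]:
        return self.cut_pos - self.window, self.cut_pos + self.window


def read_guide_sites(path: str | Path) -> list[GuideSite]:
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    required = {"name", "chrom", "cut_pos", "window"}
    if not required.issubset(df.columns):
        raise FormatError(f"guide-site table must have columns {sorted(required)}")
    return [
        GuideSite(r["name"], r["chrom"], int(r["cut_pos"]), int(r["window"]))
        for _, r in df.iterrows()
    ]


def write_guide_sites(sites: Sequence[GuideSite], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": s.name, "chrom": s.chrom, "cut_pos": s.cut_pos, "window": s.window} for s in sites]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrix


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with per-gene lengths.

    ``counts`` is a pandas DataFrame indexed by gene_id with sample columns;
    ``gene_length_bp`` is indexed identically. ``library_size`` is always the
    column sum (recomputed, never stored).
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.gene_length_bp.index):
            self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
            if self.gene_length_bp.isna().any():
                missing = self.gene_length_bp[self.gene_length_bp.isna()].index.tolist()
                raise ValueError(f"missing gene lengths for {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)].copy(), self.gene_length_bp.loc[list(genes)].copy())

    def to_tsv(self, path: str | Path) -> None:
        df = self.counts.copy()
        df.insert(0, "gene_length_bp", self.gene_length_bp)
        df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if "gene_length_bp" not in df.columns:
            raise FormatError("count TSV must carry a gene_length_bp column")
        lengths = df.pop("gene_length_bp")
        return cls(df.astype(int), lengths.astype(int))
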