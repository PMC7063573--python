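"""Detect and classify CRISPR editing events from reads spanning guide sites.

Reads whose reference footprint fully covers the guide window are compared
base-by-base (via their CIGAR) to the genomic reference. Deviations are
classified as indels (including compound indel+substitution alleles),
substitutions, or large deletions (>10 kb between two cut sites, evidenced by
split alignments flanking both cuts). Per-sample genotypes roll up identical
allele strings into events; mosaic samples may carry several distinct events
at one site.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io_core import AlignedRead, GenomeRef, GuideSite

logger = logging.getLogger(__name__)

LARGE_DELETION_MIN_BP = 10_000

# allele op tuples: ("ins", pos_after, seq) | ("del", start, end) | ("sub", start, ref, alt)


def describe_ops(ops: Sequence[tuple]) -> str:
    """Canonical string for a list of allele ops (sorted by position)."""
    parts = []
    for op in sorted(ops, key=lambda o: o[1]):
        if op[0] == "ins":
            parts.append(f"ins@{op[1]}:{op[2]}")
        elif op[0] == "del":
            parts.append(f"del@{op[1]}-{op[2]}")
        else:
            parts.append(f"sub@{op[1]}:{op[2]}>{op[3]}")
    return ";".join(parts)


@dataclass
class ReadAlleleCall:
    """Outcome of comparing one spanning read to the reference over a window."""

    kind: str  # match | indel | substitution | spliced
    ops: list[tuple] = field(default_factory=list)

    @property
    def allele(self) -> str:
        return describe_ops(self.ops)


@dataclass
class EditingEvent:
    sample_id: str
    site_name: str
    category: str  # indel | substitution | large_deletion
    ref_span: tuple[int, int]
    alt: str
    support: int
    spanning: int

    def __post_init__(self) -> None:
        if self.support > self.spanning:
            raise ValueError("event support cannot exceed spanning read count")
        if self.category == "large_deletion":
            span = self.ref_span[1] - self.ref_span[0]
            if span <= LARGE_DELETION_MIN_BP:
                raise ValueError(
                    f"large_deletion span {span} bp must exceed {LARGE_DELETION_MIN_BP}"
                )


@dataclass
class SampleGenotype:
    sample_id: str
    status: dict[str, str]  # site -> edited | unedited | no_coverage
    events: list[EditingEvent] = field(default_factory=list)

    @property
    def any_edited(self) -> bool:
        return any(v == "edited" for v in self.status.values())

    @property
    def any_covered(self) -> bool:
        return any(v != "no_coverage" for v in self.status.values())


def extract_site_reads(reads: Iterable[AlignedRead], site: GuideSite) -> list[AlignedRead]:
    """Reads whose reference footprint fully covers the guide window.

    A deletion (D op) still covers the reference; a splice gap (N op) does
    not split coverage for the purpose of footprint (the read's outer span is
    used), since spliced reads are later excluded from allele calling but
    still counted as spanning.
    """
    lo, hi = site.interval
    out = []
    for r in reads:
        if r.chrom != site.chrom:
            continue
        if r.pos <= lo and r.ref_end >= hi:
            out.append(r)
    return out


def call_read_allele(read: AlignedRead, ref: GenomeRef, site: GuideSite) -> ReadAlleleCall:
    """Walk the read's CIGAR over the guide window and classify its allele.

    Returns kind "spliced" when an N op crosses the window (a cDNA read
    spliced over the site carries no sequence evidence there). Indel ops
    intersecting the window, or insertions at its internal edges, make the
    read an indel call; aligned base mismatches inside the window make it a
    substitution call; both together stay in the indel category (compound
    alleles, reported with their substitutions).
    """
    lo, hi = site.interval
    ops: list[tuple] = []
    mismatch_run: list[tuple[int, str, str]] = []  # (pos, refbase, altbase)

    def flush_mismatches() -> None:
        if not mismatch_run:
            return
        start = mismatch_run[0][0]
        refs = "".join(m[1] for m in mismatch_run)
        alts = "".join(m[2] for m in mismatch_run)
        ops.append(("sub", start, refs, alts))
        mismatch_run.clear()

    q, rpos = 0, read.pos
    has_indel = False
    for op, n in read.cigartuples:
        if op in "M=X":
            for i in range(n):
                g = rpos + i
                if lo <= g <= hi:
                    rb = ref.fetch(read.chrom, g, g)
                    ab = read.seq[q + i]
                    if ab != rb and ab != "N":
                        if mismatch_run and mismatch_run[-1][0] == g - 1:
                            mismatch_run.append((g, rb, ab))
                        else:
                            flush_mismatches()
                            mismatch_run.append((g, rb, ab))
                    else:
                        flush_mismatches()
                else:
                    flush_mismatches()
            q += n
            rpos += n
        elif op == "I":
            # insertion sits between rpos-1 and rpos
            if lo <= rpos - 1 <= hi or lo <= rpos <= hi:
                flush_mismatches()
                ops.append(("ins", rpos - 1, read.seq[q : q + n]))
                has_indel = True
            q += n
        elif op == "D":
            if rpos <= hi and rpos + n - 1 >= lo:
                flush_mismatches()
                ops.append(("del", rpos, rpos + n - 1))
                has_indel = True
            rpos += n
        elif op == "N":
            if rpos <= hi and rpos + n - 1 >= lo:
                return ReadAlleleCall("spliced")
            rpos += n
        elif op == "S":
            q += n
        # H consumes neither
    flush_mismatches()

    if not ops:
        return ReadAlleleCall("match")
    kind = "indel" if has_indel else "substitution"
    return ReadAlleleCall(kind, ops)


def _read_blocks_by_query(reads: Iterable[AlignedRead]) -> dict[str, list[tuple[int, int]]]:
    blocks: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        blocks.setdefault(r.query_name, []).extend(r.ref_blocks())
    return blocks


def detect_large_deletion(
    sample_reads: Iterable[AlignedRead],
    site_a: GuideSite,
    site_b: GuideSite,
    min_support: int = 1,
    sample_id: str = "",
) -> EditingEvent | None:
    """Call a >10 kb deletion between two cut sites from split alignments.

    Evidence is a query (across its primary + supplementary records, or mate
    pair) with one aligned block ending at or before site_a's cut and another
    starting at or after site_b's cut, with no block covering the intervening
    region. Single-record N gaps (spliced reads) never qualify: splice gaps
    do not split a record into separate evidence blocks here.
    """
    if site_a.chrom != site_b.chrom:
        return None
    a, b = sorted((site_a, site_b), key=lambda s: s.cut_pos)
    if b.cut_pos - a.cut_pos <= LARGE_DELETION_MIN_BP:
        return None
    reads = [r for r in sample_reads if r.chrom == a.chrom]
    support = 0
    spanning = 0
    # split-alignment evidence only: group records of one query, ignore gaps
    # produced by N ops within a single record
    per_query: dict[str, list[AlignedRead]] = {}
    for r in reads:
        per_query.setdefault(r.query_name, []).append(r)
    for qname, recs in per_query.items():
        if len(recs) < 2:
            continue
        spans = [(r.pos, r.ref_end) for r in recs]
        left = [s for s in spans if s[1] <= a.cut_pos]
        right = [s for s in spans if s[0] >= b.cut_pos]
        middle = [s for s in spans if s[1] > a.cut_pos and s[0] < b.cut_pos]
        if left and right and not middle:
            spanning += 1
            support += 1
    if support >= min_support and support > 0:
        return EditingEvent(
            sample_id=sample_id,
            site_name=f"{a.name}--{b.name}",
            category="large_deletion",
            ref_span=(a.cut_pos, b.cut_pos),
            alt="",
            support=support,
            spanning=spanning,
        )
    return None


def genotype_sample(
    reads: Sequence[AlignedRead],
    sites: Sequence[GuideSite],
    ref: GenomeRef,
    min_support: int = 1,
    max_error_frac: float = 0.0,
    sample_id: str | None = None,
    check_large_deletions: bool = True,
) -> SampleGenotype:
    """Classify one sample's editing status at each guide site.

    Identical allele strings are aggregated into one event; a site is edited
    when some aggregated allele reaches *min_support* reads. Substitution-only
    alleles supported by at most ``max_error_frac`` of the spanning reads are
    attributed to sequencing error and ignored (indel-containing alleles are
    never filtered this way: base-call errors are substitutions). Large
    deletions between any pair of sites >10 kb apart on one chromosome mark
    both flanking sites edited.
    """
    reads = list(reads)
    if sample_id is None:
        sample_id = next((r.sample_id for r in reads if r.sample_id), "sample")
    status: dict[str, str] = {}
    events: list[EditingEvent] = []

    for site in sites:
        spanning_reads = extract_site_reads(reads, site)
        spanning = len(spanning_reads)
        if spanning == 0:
            status[site.name] = "no_coverage"
            continue
        allele_support: dict[str, int] = {}
        allele_call: dict[str, ReadAlleleCall] = {}
        for r in spanning_reads:
            call = call_read_allele(r, ref, site)
            if call.kind == "spliced":
                logger.debug("read %s spliced over site %s; excluded", r.query_name, site.name)
                continue
            if call.kind == "match":
                continue
            allele_support[call.allele] = allele_support.get(call.allele, 0) + 1
            allele_call[call.allele] = call
        edited = False
        for allele, support in sorted(allele_support.items()):
            call = allele_call[allele]
            if call.kind == "substitution" and spanning > 0:
                if support / spanning <= max_error_frac:
                    continue
            if support < min_support:
                continue
            lo = min(op[1] for op in call.ops)
            hi = max(op[2] if op[0] == "del" else op[1] for op in call.ops)
            alt = ";".join(op[2] for op in call.ops if op[0] == "ins") or (
                ";".join(op[3] for op in call.ops if op[0] == "sub")
            )
            events.append(
                EditingEvent(
                    sample_id=sample_id,
                    site_name=site.name,
                    category=call.kind,
                    ref_span=(lo, hi),
                    alt=alt,
                    support=support,
                    spanning=spanning,
                )
            )
            edited = True
        status[site.name] = "edited" if edited else "unedited"

    if check_large_deletions:
        ordered = sorted(sites, key=lambda s: (s.chrom, s.cut_pos))
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                ev = detect_large_deletion(
                    reads, ordered[i], ordered[j], min_support=min_support, sample_id=sample_id
                )
                if ev is not None:
                    events.append(ev)
                    for s in (ordered[i], ordered[j]):
                        status[s.name] = "edited"

    return SampleGenotype(sample_id=sample_id, status=status, events=events)


def summarize_cohort(genotypes: Sequence[SampleGenotype]) -> pd.DataFrame:
    """Per-site and overall edited fractions among covered samples.

    The overall row counts a sample edited if it is edited at any site, over
    the denominator of samples covered at any site (no_coverage samples are
    excluded from denominators throughout).
    """
    sites: list[str] = []
    for g in genotypes:
        for s in g.status:
            if s not in sites:
                sites.append(s)
    rows = []
    for site in sites:
        st = [g.status[site] for g in genotypes if site in g.status]
        covered = [s for s in st if s != "no_coverage"]
        edited = sum(1 for s in covered if s == "edited")
        rows.append(
            {
                "site": site,
                "n_samples": len(st),
                "n_covered": len(covered),
                "n_edited": edited,
                "edited_fraction": edited / len(covered) if covered else float("nan"),
            }
        )
    analyzed = [g for g in genotypes if g.any_covered]
    if not analyzed:
        warnings.warn("all samples lack coverage at every site; empty cohort summary")
        return pd.DataFrame(
            columns=["site", "n_samples", "n_covered", "n_edited", "edited_fraction"]
        )
    edited_overall = sum(1 for g in analyzed if g.any_edited)
    rows.append(
        {
            "site": "overall",
            "n_samples": len(genotypes),
            "n_covered": len(analyzed),
            "n_edited": edited_overall,
            "edited_fraction": edited_overall / len(analyzed),
        }
    )
    return pd.DataFrame(rows)


def edited_read_fraction(
    reads: Iterable[AlignedRead], ref: GenomeRef, site: GuideSite
) -> tuple[float, int, int]:
    """Fraction of callable reads spanning *site* that deviate from reference.

    Returns (fraction, n_edited_reads, n_callable_reads); spliced-over reads
    are excluded from the denominator. This is the read-level editing measure
    used for whole-larva RNA-seq at a guide site.
    """
    spanning = extract_site_reads(reads, site)
    edited = 0
    callable_n = 0
    for r in spanning:
        call = call_read_allele(r, ref, site)
        if call.kind == "spliced":
            continue
        callable_n += 1
        if call.kind != "match":
            edited += 1
    frac = edited / callable_n if callable_n else float("nan")
    return frac, edited, callable_n


def events_table(genotypes: Sequence[SampleGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        for ev in g.events:
            rows.append(
                {
                    "sample_id": ev.sample_id,
                    "site": ev.site_name,
                    "category": ev.category,
                    "ref_start": ev.ref_span[0],
                    "ref_end": ev.ref_span[1],
                    "alt": ev.alt,
                    "support": ev.support,
                    "spanning": ev.spanning,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "site", "category", "ref_start", "ref_end", "alt", "support", "spanning"],
    )


def genotypes_table(genotypes: Sequence[SampleGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        for site, st in g.status.items():
            rows.append({"sample_id": g.sample_id, "site": site, "status": st})
    return pd.DataFrame(rows, columns=["sample_id", "site", "status"])
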