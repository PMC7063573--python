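"""Genotyper unit and property tests, including the independent
reference-projection oracle for allele calls."""

import numpy as np
import pytest

from epiedit import edit_genotyper as eg
from epiedit.io_core import AlignedRead, GenomeRef, GuideSite
from epiedit.synthetic_data import AlleleSpec, SimConfig, simulate_reads

from conftest import random_read_near


def oracle_call(read, ref, site):
    """Brute-force oracle: reconstruct the read's reference projection
    base-by-base and compare, with no shared code with the implementation."""
    lo, hi = site.interval
    aligned = {}  # refpos -> read base
    deleted = set()
    inserted = {}  # refpos after which bases sit -> seq
    q, rpos = 0, read.pos
    for op, n in read.cigartuples:
        if op in "M=X":
            for i in range(n):
                aligned[rpos + i] = read.seq[q + i]
            q += n
            rpos += n
        elif op == "I":
            inserted[rpos - 1] = inserted.get(rpos - 1, "") + read.seq[q : q + n]
            q += n
        elif op == "D":
            for g in range(rpos, rpos + n):
                deleted.add(g)
            rpos += n
        elif op == "N":
            if any(lo <= g <= hi for g in (rpos, rpos + n - 1)) or (rpos <= lo and rpos + n - 1 >= hi):
                return "spliced"
            rpos += n
        elif op == "S":
            q += n
    has_indel = any(lo <= g <= hi for g in deleted) or any(
        lo <= p <= hi or lo <= p + 1 <= hi for p in inserted
    )
    has_sub = any(
        g in aligned and aligned[g] not in (ref.fetch(read.chrom, g, g), "N")
        for g in range(lo, hi + 1)
    )
    if has_indel:
        return "indel"
    if has_sub:
        return "substitution"
    return "match"


@pytest.fixture(scope="module")
def flat_ref():
    rng = np.random.default_rng(99)
    return GenomeRef({"c": "".join("ACGT"[i] for i in rng.integers(0, 4, 600))})


class TestExtractSiteReads:
    site = GuideSite("g", "c", 150, 10)

    def test_fully_spanning_read_included(self, flat_ref):
        r = AlignedRead("a", "c", 100, "76M", flat_ref.fetch("c", 100, 175))
        assert eg.extract_site_reads([r], self.site) == [r]

    def test_short_read_excluded(self, flat_ref):
        r = AlignedRead("a", "c", 100, "46M", flat_ref.fetch("c", 100, 145))
        assert eg.extract_site_reads([r], self.site) == []

    def test_read_with_deletion_over_window_still_covers(self, flat_ref):
        # 45M covers 100-144, 12D covers 145-156, then 19M covers 157-175
        seq = flat_ref.fetch("c", 100, 144) + flat_ref.fetch("c", 157, 175)
        r = AlignedRead("a", "c", 100, "45M12D19M", seq)
        assert eg.extract_site_reads([r], self.site) == [r]

    def test_wrong_chromosome_excluded(self, flat_ref):
        r = AlignedRead("a", "other", 100, "76M", "A" * 76)
        assert eg.extract_site_reads([r], self.site) == []


class TestCallReadAllele:
    site = GuideSite("g", "c", 150, 15)

    def test_reference_identical_read_is_match(self, flat_ref):
        r = AlignedRead("a", "c", 110, "80M", flat_ref.fetch("c", 110, 189))
        assert eg.call_read_allele(r, flat_ref, self.site).kind == "match"

    def test_38bp_insertion_is_indel(self, flat_ref):
        ins = "ACGT" * 9 + "AC"
        seq = flat_ref.fetch("c", 120, 150) + ins + flat_ref.fetch("c", 151, 170)
        r = AlignedRead("a", "c", 120, f"31M38I20M", seq)
        call = eg.call_read_allele(r, flat_ref, self.site)
        assert call.kind == "indel"
        assert call.ops == [("ins", 150, ins)]

    def test_compound_7del_1sub_is_single_indel_category_event(self, flat_ref):
        # 7-bp deletion at the cut plus a 1-bp substitution just after
        sub_pos = 158
        refbase = flat_ref.fetch("c", sub_pos, sub_pos)
        alt = "ACGT"[("ACGT".index(refbase) + 1) % 4]
        seq = (
            flat_ref.fetch("c", 120, 149)
            + flat_ref.fetch("c", 157, sub_pos - 1)
            + alt
            + flat_ref.fetch("c", sub_pos + 1, 178)
        )
        r = AlignedRead("a", "c", 120, "30M7D22M", seq)
        call = eg.call_read_allele(r, flat_ref, self.site)
        assert call.kind == "indel"
        assert ("del", 150, 156) in call.ops
        assert ("sub", sub_pos, refbase, alt) in call.ops

    def test_spliced_read_excluded_with_reason(self, flat_ref):
        seq = flat_ref.fetch("c", 100, 139) + flat_ref.fetch("c", 340, 379)
        r = AlignedRead("a", "c", 100, "40M200N40M", seq)
        assert eg.call_read_allele(r, flat_ref, self.site).kind == "spliced"

    def test_oracle_equivalence_on_random_fixtures(self, flat_ref):
        """Implementation kind agrees with the brute-force reference
        projection on 1,000 random CIGAR/sequence fixtures."""
        rng = np.random.default_rng(7)
        site = GuideSite("g", "c", 300, 15)
        mismatches = 0
        for _ in range(1000):
            r = random_read_near(rng, flat_ref, "c", 300)
            got = eg.call_read_allele(r, flat_ref, site).kind
            if r.pos <= site.interval[0] and r.ref_end >= site.interval[1]:
                want = oracle_call(r, flat_ref, site)
            else:
                want = got  # non-spanning reads are out of contract
            if got != want:
                mismatches += 1
        assert mismatches == 0


class TestLargeDeletion:
    def test_split_read_pair_yields_event_spanning_both_cuts(self):
        # two guide cuts on one chromosome, 94,703 bp apart
        rng = np.random.default_rng(1)
        a = GuideSite("sg4", "chr11", 35213000, 15)
        b = GuideSite("sg1", "chr11", 35307703, 15)
        reads = [
            AlignedRead("q1", "chr11", 35212920, "60M15S", "A" * 75),
            AlignedRead("q1", "chr11", 35307723, "60S15M", "A" * 75, is_supplementary=True),
        ]
        ev = eg.detect_large_deletion(reads, a, b, sample_id="s")
        assert ev is not None
        assert ev.category == "large_deletion"
        assert ev.ref_span == (35213000, 35307703)
        assert ev.ref_span[1] - ev.ref_span[0] == 94703

    def test_spliced_read_with_2kb_gap_is_not_a_large_deletion(self):
        a = GuideSite("x", "c", 1000, 15)
        b = GuideSite("y", "c", 20000, 15)
        r = AlignedRead("q", "c", 900, "40M2000N35M", "A" * 75)
        assert eg.detect_large_deletion([r], a, b) is None

    def test_sites_closer_than_10kb_never_called(self):
        a = GuideSite("x", "c", 1000, 15)
        b = GuideSite("y", "c", 5000, 15)
        reads = [
            AlignedRead("q", "c", 900, "40M35S", "A" * 75),
            AlignedRead("q", "c", 5100, "40S35M", "A" * 75, is_supplementary=True),
        ]
        assert eg.detect_large_deletion(reads, a, b) is None

    def test_no_qualifying_reads_absent(self):
        a = GuideSite("x", "c", 1000, 15)
        b = GuideSite("y", "c", 20000, 15)
        assert eg.detect_large_deletion([], a, b) is None


class TestGenotypeSample:
    def _reads(self, flat_ref, n_match, n_del, del_len=5):
        site = GuideSite("g", "c", 150, 15)
        reads = []
        for i in range(n_match):
            reads.append(
                AlignedRead(f"m{i}", "c", 110, "80M", flat_ref.fetch("c", 110, 189), "s")
            )
        for i in range(n_del):
            seq = flat_ref.fetch("c", 110, 149) + flat_ref.fetch("c", 150 + del_len, 189 + del_len)
            reads.append(
                AlignedRead(f"d{i}", "c", 110, f"40M{del_len}D40M", seq, "s")
            )
        return reads, site

    def test_identical_alleles_aggregate_with_support_counts(self, flat_ref):
        reads, site = self._reads(flat_ref, 4, 6)
        g = eg.genotype_sample(reads, [site], flat_ref, sample_id="s")
        assert g.status["g"] == "edited"
        assert len(g.events) == 1
        assert g.events[0].support == 6
        assert g.events[0].spanning == 10

    def test_all_match_is_unedited(self, flat_ref):
        reads, site = self._reads(flat_ref, 10, 0)
        g = eg.genotype_sample(reads, [site], flat_ref)
        assert g.status["g"] == "unedited"
        assert g.events == []

    def test_uncovered_site_is_no_coverage(self, flat_ref):
        reads, site = self._reads(flat_ref, 5, 5)
        far = GuideSite("far", "c", 450, 15)
        g = eg.genotype_sample(reads, [site, far], flat_ref)
        assert g.status["g"] == "edited"
        assert g.status["far"] == "no_coverage"

    def test_min_support_monotonicity(self, flat_ref):
        reads, site = self._reads(flat_ref, 8, 2)
        edited_calls = []
        for ms in (1, 2, 3):
            g = eg.genotype_sample(reads, [site], flat_ref, min_support=ms)
            edited_calls.append(sum(1 for v in g.status.values() if v == "edited"))
        assert edited_calls == sorted(edited_calls, reverse=True)
        assert edited_calls[0] >= 1 and edited_calls[2] == 0

    def test_max_error_frac_filters_minority_substitutions_only(self, flat_ref):
        site = GuideSite("g", "c", 150, 15)
        reads = [
            AlignedRead(f"m{i}", "c", 110, "80M", flat_ref.fetch("c", 110, 189), "s")
            for i in range(19)
        ]
        seq = list(flat_ref.fetch("c", 110, 189))
        seq[40] = "ACGT"[("ACGT".index(seq[40]) + 1) % 4]
        reads.append(AlignedRead("e", "c", 110, "80M", "".join(seq), "s"))
        loose = eg.genotype_sample(reads, [site], flat_ref, max_error_frac=0.0)
        strict = eg.genotype_sample(reads, [site], flat_ref, max_error_frac=0.1)
        assert loose.status["g"] == "edited"  # paper-faithful: any deviant read
        assert strict.status["g"] == "unedited"


class TestCohortSummary:
    def _genotype(self, sid, status):
        return eg.SampleGenotype(sid, status)

    def test_seven_of_fourteen_covered_is_half(self):
        gts = (
            [self._genotype(f"e{i}", {"s": "edited"}) for i in range(7)]
            + [self._genotype(f"u{i}", {"s": "unedited"}) for i in range(7)]
            + [self._genotype(f"n{i}", {"s": "no_coverage"}) for i in range(3)]
        )
        df = eg.summarize_cohort(gts)
        overall = df[df["site"] == "overall"].iloc[0]
        assert overall["n_covered"] == 14
        assert overall["edited_fraction"] == 0.5

    def test_zero_edited_is_zero(self):
        gts = [self._genotype(f"u{i}", {"s": "unedited"}) for i in range(10)]
        df = eg.summarize_cohort(gts)
        assert (df["edited_fraction"] == 0.0).all()

    def test_all_no_coverage_warns_and_returns_empty(self):
        gts = [self._genotype(f"n{i}", {"s": "no_coverage"}) for i in range(3)]
        with pytest.warns(UserWarning, match="lack coverage"):
            df = eg.summarize_cohort(gts)
        assert df.empty


class TestSimulationRecovery:
    def test_error_free_recovery_is_exact(self, toy):
        """With no sequencing error the genotyper reproduces the truth
        manifest exactly across 500 samples x 2 sites."""
        ref, models, sites = toy
        sem_sites = [s for s in sites if s.chrom == "chrS"]
        cfg = SimConfig(seed=21, n_samples=500, depth_mrna=0, depth_amplicon=12,
                        edited_fraction=0.5)
        reads, truth = simulate_reads(cfg, ref, models, sem_sites)
        te = truth.editing.set_index(["sample_id", "site"])["edited"]
        discordant = 0
        for sid, rs in reads.items():
            g = eg.genotype_sample(rs, sem_sites, ref, sample_id=sid)
            for s in sem_sites:
                want = "edited" if te[(sid, s.name)] else "unedited"
                if g.status[s.name] != want:
                    discordant += 1
        assert discordant == 0

    def test_large_deletion_cohort_recovered(self, toy):
        ref, models, sites = toy
        sem_sites = [s for s in sites if s.chrom == "chrS"]
        cfg = SimConfig(
            seed=22, n_samples=40, depth_mrna=0, depth_amplicon=10, edited_fraction=0.5,
            allele_spec={"sem_sg1": AlleleSpec("large_deletion", partner="sem_sg4")},
        )
        reads, truth = simulate_reads(cfg, ref, models, sem_sites)
        te = truth.editing.set_index(["sample_id", "site"])["edited"]
        for sid, rs in reads.items():
            g = eg.genotype_sample(rs, sem_sites, ref, sample_id=sid)
            want = "edited" if te[(sid, "sem_sg1")] else "unedited"
            assert g.status["sem_sg1"] == want
            assert g.status["sem_sg4"] == want
            if want == "edited":
                assert any(e.category == "large_deletion" for e in g.events)


class TestEditedReadFraction:
    def test_read_level_fraction_counts_deviant_reads(self, flat_ref):
        site = GuideSite("g", "c", 150, 15)
        reads = []
        for i in range(8):
            reads.append(AlignedRead(f"m{i}", "c", 110, "80M", flat_ref.fetch("c", 110, 189), "s"))
        for i in range(2):
            seq = flat_ref.fetch("c", 110, 149) + flat_ref.fetch("c", 155, 194)
            reads.append(AlignedRead(f"d{i}", "c", 110, "40M5D40M", seq, "s"))
        frac, n_e, n_c = eg.edited_read_fraction(reads, flat_ref, site)
        assert (frac, n_e, n_c) == (0.2, 2, 10)
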