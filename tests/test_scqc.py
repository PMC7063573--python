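"""QC, gene-filter, FPKM and marker-combination tests with brute-force
re-implementations as oracles."""

import numpy as np
import pandas as pd
import pytest

from epiedit import scqc
from epiedit.io_core import CountMatrix
from epiedit.synthetic_data import simulate_count_matrix


def _cm(counts: np.ndarray, genes=None, samples=None, lengths=None):
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    lengths = pd.Series(lengths if lengths is not None else 1000, index=genes)
    return CountMatrix(df, lengths)


def brute_qc(counts: CountMatrix, ercc_prefix="ERCC-", nmads=3.0):
    """Independent loop-based QC re-implementation."""
    lib = {s: counts.counts[s].sum() for s in counts.sample_ids}
    ngen = {s: (counts.counts[s] > 0).sum() for s in counts.sample_ids}
    ercc_rows = [g for g in counts.gene_ids if g.startswith(ercc_prefix)]
    efrac = {
        s: (counts.counts.loc[ercc_rows, s].sum() / lib[s]) if lib[s] > 0 else 1.0
        for s in counts.sample_ids
    }

    def mad(vals):
        med = float(np.median(vals))
        return med, 1.4826 * float(np.median([abs(v - med) for v in vals]))

    m_lib, d_lib = mad(list(lib.values()))
    m_g, d_g = mad(list(ngen.values()))
    m_e, d_e = mad(list(efrac.values()))
    out = {}
    for s in counts.sample_ids:
        fails = []
        if lib[s] < m_lib - nmads * d_lib:
            fails.append("low_libsize")
        if ngen[s] < m_g - nmads * d_g:
            fails.append("low_genes")
        if efrac[s] > m_e + nmads * d_e:
            fails.append("high_ercc")
        out[s] = fails
    return out


class TestQcFilterCells:
    def test_hand_computed_libsize_outlier(self):
        """Library sizes {1,8,9,10,11,12}e4: median 9.5e4, scaled MAD
        ~2.2239e4 -> only the 1e4 cell fails low_libsize."""
        libs = [1, 8, 9, 10, 11, 12]
        counts = np.zeros((40, 6), dtype=int)
        for j, l in enumerate(libs):
            counts[:, j] = l * 10**4 // 40
        cm = _cm(counts)
        rep = scqc.qc_filter_cells(cm)
        med = 9.5e4
        mad = 1.4826 * np.median([abs(l * 1e4 - med) for l in libs])
        assert mad == pytest.approx(2.2239e4, rel=1e-4)
        assert rep.thresholds["library_size"] == pytest.approx(med - 3 * mad)
        assert list(rep.table["fail_reasons"]) == ["low_libsize", "", "", "", "", ""]

    def test_identical_samples_all_pass_with_zero_mad_warning(self):
        counts = np.full((10, 6), 5, dtype=int)
        with pytest.warns(UserWarning, match="MAD"):
            rep = scqc.qc_filter_cells(_cm(counts))
        assert rep.table["pass"].all()

    def test_high_ercc_cell_fails(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(10, size=(50, 10)).astype(int)
        genes = [f"g{i}" for i in range(45)] + [f"ERCC-{i}" for i in range(5)]
        counts[45:, :] = 1  # ~1% spike fraction everywhere...
        counts[45:, 9] = 200  # ...except the last cell
        rep = scqc.qc_filter_cells(_cm(counts, genes=genes))
        assert "high_ercc" in rep.table.iloc[9]["fail_reasons"]
        assert not rep.table.iloc[:9]["fail_reasons"].str.contains("high_ercc").any()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            scqc.qc_filter_cells(_cm(np.ones((5, 3), dtype=int)))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for trial in range(15):
            counts = rng.poisson(rng.uniform(0.5, 8), size=(50, 20)).astype(int)
            genes = [f"g{i}" for i in range(44)] + [f"ERCC-{i}" for i in range(6)]
            # a couple of degenerate cells
            counts[:, 0] = 0
            counts[: rng.integers(1, 50), 1] = 0
            cm = _cm(counts, genes=genes)
            rep = scqc.qc_filter_cells(cm)
            want = brute_qc(cm)
            got = {s: (r.split(",") if r else []) for s, r in rep.table["fail_reasons"].items()}
            assert got == want


class TestFilterGenes:
    def test_mean_threshold_kept_and_dropped(self):
        counts = np.zeros((2, 12), dtype=int)
        counts[0, :4] = 1  # mean 4/12 = 0.333 -> kept
        counts[1, 0] = 1  # mean 1/12 = 0.083 -> dropped
        out = scqc.filter_genes(_cm(counts))
        assert out.gene_ids == ["g0"]

    def test_three_cell_mean_boundary(self):
        counts = np.array([[0, 0, 1], [0, 0, 0], [1, 1, 1], [2, 0, 0]])
        out = scqc.filter_genes(_cm(counts), min_mean=0.1)
        assert out.gene_ids == ["g0", "g2", "g3"]

    def test_exclusion_list_overrides_high_mean(self):
        counts = np.full((3, 6), 50, dtype=int)
        cm = _cm(counts, genes=["mt-co1", "a", "b"])
        out = scqc.filter_genes(cm, exclusion_lists={"mito": ["mt-co1"]})
        assert out.gene_ids == ["a", "b"]

    def test_unknown_excluded_gene_warns_not_errors(self):
        cm = _cm(np.ones((3, 6), dtype=int))
        with pytest.warns(UserWarning, match="unknown"):
            out = scqc.filter_genes(cm, exclusion_lists={"cc": ["nonexistent"]})
        assert len(out.gene_ids) == 3

    def test_matches_brute_force(self):
        rng = np.random.default_rng(29)
        counts = rng.poisson(0.12, size=(50, 20)).astype(int)
        cm = _cm(counts)
        excl = {"x": [f"g{i}" for i in range(0, 50, 7)]}
        out = scqc.filter_genes(cm, 0.1, excl)
        want = [
            g
            for i, g in enumerate(cm.gene_ids)
            if counts[i].mean() >= 0.1 and g not in excl["x"]
        ]
        assert out.gene_ids == want


class TestFpkm:
    def test_unit_case(self):
        cm = _cm(np.array([[100]]), lengths=[1000])
        # single sample: library is the gene's own 100 counts
        expr = scqc.compute_fpkm(cm)
        assert expr.fpkm.iloc[0, 0] == pytest.approx(100 / (100 / 1e6) / 1.0 / 1e3 * 1e3)

    @pytest.mark.parametrize(
        "count,lib_other,length,expected",
        [(100, 10**6 - 100, 1000, 100.0), (0, 10**6, 1000, 0.0), (50, 2 * 10**6 - 50, 500, 50.0)],
    )
    def test_textbook_values(self, count, lib_other, length, expected):
        counts = np.array([[count], [lib_other]])
        cm = _cm(counts, lengths=[length, 10**6])
        expr = scqc.compute_fpkm(cm)
        assert expr.fpkm.iloc[0, 0] == pytest.approx(expected)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, size=(20, 4)).astype(int) + 1
        cm1 = _cm(counts)
        cm2 = _cm(counts * 7)
        f1 = scqc.compute_fpkm(cm1).fpkm
        f2 = scqc.compute_fpkm(cm2).fpkm
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_library_sample_rejected(self):
        counts = np.array([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="library"):
            scqc.compute_fpkm(_cm(counts))

    def test_log2_display_transform_uses_offset(self):
        cm = _cm(np.array([[0, 100], [100, 0]]), lengths=[1000, 1000])
        expr = scqc.compute_fpkm(cm)
        assert (expr.log2() >= 0).all().all()


class TestMarkerCombinations:
    def _expr(self, tcf, tbx, wt1):
        fpkm = pd.DataFrame(
            {"s": [tcf, tbx, wt1]}, index=["tcf21", "tbx18", "wt1b"], dtype=float
        )
        return scqc.ExpressionMatrix(fpkm)

    def test_two_marker_cell_label(self):
        cells, _ = scqc.classify_marker_combinations(
            self._expr(5, 0, 2), ("tcf21", "tbx18", "wt1b"), 0.0
        )
        assert cells.iloc[0]["combination"] == "tcf21+wt1b"

    def test_triple_positive_label(self):
        cells, _ = scqc.classify_marker_combinations(
            self._expr(1, 1, 1), ("tcf21", "tbx18", "wt1b"), 0.0
        )
        assert cells.iloc[0]["combination"] == "tcf21+tbx18+wt1b"

    def test_threshold_gates_positivity(self):
        cells, _ = scqc.classify_marker_combinations(
            self._expr(5, 0, 2), ("tcf21", "tbx18", "wt1b"), 3.0
        )
        assert cells.iloc[0]["combination"] == "tcf21"

    def test_missing_marker_rejected(self):
        with pytest.raises(KeyError):
            scqc.classify_marker_combinations(self._expr(1, 1, 1), ("nope",), 0.0)

    def test_fractions_sum_to_one_with_none(self):
        rng = np.random.default_rng(8)
        fpkm = pd.DataFrame(
            rng.poisson(1, size=(3, 60)).astype(float),
            index=["tcf21", "tbx18", "wt1b"],
            columns=[f"c{i}" for i in range(60)],
        )
        groups = pd.Series(
            ["a"] * 30 + ["b"] * 30, index=fpkm.columns
        )
        _, frac = scqc.classify_marker_combinations(
            scqc.ExpressionMatrix(fpkm), ("tcf21", "tbx18", "wt1b"), 0.0, groups
        )
        sums = frac.groupby("group")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_forty_of_hundred_triple_positive(self):
        """Counting oracle: a constructed group with exactly 40/100
        triple-positive cells yields triple fraction 0.40."""
        cols = {}
        for i in range(100):
            if i < 40:
                cols[f"c{i}"] = [1.0, 1.0, 1.0]
            else:
                cols[f"c{i}"] = [1.0, 0.0, 0.0]
        fpkm = pd.DataFrame(cols, index=["tcf21", "tbx18", "wt1b"])
        _, frac = scqc.classify_marker_combinations(
            scqc.ExpressionMatrix(fpkm), ("tcf21", "tbx18", "wt1b"), 0.0
        )
        triple = frac[frac["combination"] == "tcf21+tbx18+wt1b"].iloc[0]
        assert triple["fraction"] == pytest.approx(0.40)


class TestSimulatedCohort:
    def test_empty_wells_fail_qc_and_fractions_recover(self):
        cm, truth = simulate_count_matrix(seed=5)
        rep = scqc.qc_filter_cells(cm)
        empties = truth.loc[truth["is_empty"], "cell"]
        assert not rep.table.loc[empties, "pass"].any()
        # marker truth recovers exactly at threshold 0 among real cells
        passing = [c for c in rep.passing_samples if c in set(truth[~truth["is_empty"]]["cell"])]
        expr = scqc.compute_fpkm(
            CountMatrix(cm.counts[passing], cm.gene_length_bp)
        )
        groups = truth.set_index("cell")["group"].reindex(passing)
        cells, frac = scqc.classify_marker_combinations(
            expr, ("tcf21", "tbx18", "wt1b"), 0.0, groups
        )
        want = truth.set_index("cell")["combination"].reindex(passing)
        assert (cells["combination"] == want).all()
        # only Epi1 contains triple-positive cells in the default design
        triple = frac[frac["combination"] == "tcf21+tbx18+wt1b"]
        assert triple.loc[triple["group"] == "Epi1", "fraction"].iloc[0] > 0
        for g in ("Epi2", "Epi3"):
            assert triple.loc[triple["group"] == g, "fraction"].iloc[0] == 0
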