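"""Single-cell QC, gene filtering, FPKM and marker-combination calls.

Cells are excluded when their library size or detected-gene count falls more
than ``nmads`` median absolute deviations below the cohort median, or when
their spike-in count fraction rises more than ``nmads`` MADs above it. The
MAD uses the 1.4826 normal-consistency scaling and is computed on raw
values; both choices are configurable. Genes are kept when their mean count
across all cells reaches ``min_mean`` and they appear on no exclusion list
(mitochondrial, cell-cycle, user-supplied).

FPKM(g, s) = count / (library_size/1e6) / (gene_length/1e3); the log2
display transform (offset 1) is provided separately and never used for
classification. A marker is called positive when its FPKM exceeds the
threshold (default 0: any detected expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import CountMatrix

MAD_SCALE = 1.4826


@dataclass
class QCReport:
    table: pd.DataFrame  # per-sample: library_size, n_genes_detected, ercc_fraction, fail_reasons, pass
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def passing_samples(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])


def _mad(values: np.ndarray, scale: float = MAD_SCALE) -> float:
    med = float(np.median(values))
    return scale * float(np.median(np.abs(values - med)))


def qc_filter_cells(
    counts: CountMatrix,
    ercc_ids: Sequence[str] | None = None,
    nmads: float = 3.0,
    ercc_prefix: str = "ERCC-",
) -> QCReport:
    """Flag outlier cells by library size, detected genes and spike fraction.

    Fails ``low_libsize``/``low_genes`` below median - nmads*MAD and
    ``high_ercc`` above median + nmads*MAD, each computed over the whole
    dataset. A zero MAD degenerates the threshold to the median (warned,
    applied as stated).
    """
    if counts.counts.shape[1] < 4:
        raise ValueError("QC outlier thresholds need at least 4 samples")
    if ercc_ids is None:
        ercc_ids = [g for g in counts.gene_ids if g.startswith(ercc_prefix)]
    ercc_ids = [g for g in ercc_ids if g in counts.counts.index]

    lib = counts.library_size.astype(float)
    n_genes = (counts.counts > 0).sum(axis=0).astype(float)
    ercc_counts = counts.counts.loc[ercc_ids].sum(axis=0) if ercc_ids else 0.0
    with np.errstate(invalid="ignore"):
        ercc_frac = np.where(lib > 0, ercc_counts / lib, 1.0)
    ercc_frac = pd.Series(ercc_frac, index=lib.index, dtype=float)

    metrics = {"library_size": lib, "n_genes_detected": n_genes, "ercc_fraction": ercc_frac}
    thresholds = {}
    for name, values in metrics.items():
        mad = _mad(values.to_numpy())
        med = float(np.median(values))
        if mad == 0:
            warnings.warn(f"MAD of {name} is 0; threshold degenerates to the median")
        if name == "ercc_fraction":
            thresholds[name] = med + nmads * mad
        else:
            thresholds[name] = med - nmads * mad

    rows = []
    for s in counts.sample_ids:
        reasons = []
        if lib[s] < thresholds["library_size"]:
            reasons.append("low_libsize")
        if n_genes[s] < thresholds["n_genes_detected"]:
            reasons.append("low_genes")
        if ercc_frac[s] > thresholds["ercc_fraction"]:
            reasons.append("high_ercc")
        rows.append(
            {
                "library_size": int(lib[s]),
                "n_genes_detected": int(n_genes[s]),
                "ercc_fraction": float(ercc_frac[s]),
                "fail_reasons": ",".join(reasons),
                "pass": not reasons,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(counts.sample_ids, name="sample_id"))
    return QCReport(table, thresholds)


def filter_genes(
    counts: CountMatrix,
    min_mean: float = 0.1,
    exclusion_lists: dict[str, Sequence[str]] | None = None,
) -> CountMatrix:
    """Keep genes with mean count >= min_mean and on no exclusion list."""
    mean = counts.counts.mean(axis=1)
    keep = mean >= min_mean
    if exclusion_lists:
        for name, genes in exclusion_lists.items():
            genes = list(genes)
            unknown = [g for g in genes if g not in counts.counts.index]
            if unknown:
                warnings.warn(
                    f"exclusion list {name!r} names {len(unknown)} unknown gene(s), e.g. {unknown[0]!r}"
                )
            keep &= ~counts.counts.index.isin(genes)
    return counts.subset_genes(list(counts.counts.index[keep]))


@dataclass
class ExpressionMatrix:
    fpkm: pd.DataFrame  # genes x samples
    log2_offset: float = 1.0

    def __post_init__(self) -> None:
        vals = self.fpkm.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("FPKM values must be finite and non-negative")

    def log2(self) -> pd.DataFrame:
        """Display transform log2(FPKM + offset); never used for calling."""
        return np.log2(self.fpkm + self.log2_offset)


def compute_fpkm(counts: CountMatrix) -> ExpressionMatrix:
    lib = counts.library_size
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for sample(s) {bad[:5]}")
    if (counts.gene_length_bp <= 0).any():
        raise ValueError("gene lengths must be positive")
    fpkm = counts.counts.div(lib / 1e6, axis=1).div(counts.gene_length_bp / 1e3, axis=0)
    return ExpressionMatrix(fpkm)


def classify_marker_combinations(
    expr: ExpressionMatrix,
    markers: Sequence[str],
    threshold: float = 0.0,
    groups: pd.Series | dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every cell with its positive-marker combination.

    A marker is positive when FPKM > threshold. Returns (per-cell table,
    per-group fraction table); fractions over each group sum to 1 once the
    "none" label is included. Marker order in labels follows the *markers*
    argument.
    """
    missing = [m for m in markers if m not in expr.fpkm.index]
    if missing:
        raise KeyError(f"marker gene(s) not in matrix: {missing}")
    calls = expr.fpkm.loc[list(markers)] > threshold
    labels = []
    for s in expr.fpkm.columns:
        pos = [m for m in markers if calls.at[m, s]]
        labels.append("+".join(pos) if pos else "none")
    cell_table = pd.DataFrame(
        {m: calls.loc[m].to_numpy() for m in markers},
        index=pd.Index(expr.fpkm.columns, name="sample_id"),
    )
    cell_table["combination"] = labels
    if groups is not None:
        groups = pd.Series(groups)
        cell_table["group"] = groups.reindex(cell_table.index)
    else:
        cell_table["group"] = "all"

    combo_order = _combination_labels(markers)
    frac_rows = []
    for group, sub in cell_table.groupby("group", sort=True):
        if len(sub) == 0:
            warnings.warn(f"group {group!r} has no cells; omitted")
            continue
        for label in combo_order:
            n = int((sub["combination"] == label).sum())
            frac_rows.append(
                {"group": group, "combination": label, "n_cells": n, "fraction": n / len(sub)}
            )
    fractions = pd.DataFrame(frac_rows, columns=["group", "combination", "n_cells", "fraction"])
    return cell_table, fractions


def _combination_labels(markers: Sequence[str]) -> list[str]:
    """The 2^k - 1 non-empty subset labels (marker-argument order) plus 'none'."""
    labels = []
    k = len(markers)
    for mask in range(1, 2**k):
        subset = [markers[i] for i in range(k) if mask & (1 << i)]
        labels.append("+".join(subset))
    labels.sort(key=lambda s: (s.count("+"), s))
    return labels + ["none"]
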