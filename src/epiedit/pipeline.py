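"""End-to-end orchestration and group-comparison statistics.

``run_pipeline`` chains simulate -> genotype -> orf -> splice -> quantify ->
single-cell QC/markers -> compare, writing one TSV per stage plus a
structured log line to stderr per stage. Identical configs (same seed)
produce byte-identical tables; timestamps appear only in logs.

Group comparisons use Welch's unequal-variance t statistic with
Welch-Satterthwaite degrees of freedom and a two-sided p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import edit_genotyper as eg
from . import expr_quant as xq
from . import orf_consequence as oc
from . import scqc
from . import splice_quant as sq
from .io_core import read_alignments, read_gene_models, read_genome, read_guide_sites
from .synthetic_data import CXC_GENE, SEM_GENE, SimConfig, simulate_to_dir

logger = logging.getLogger("epiedit")


class ConfigError(ValueError):
    """Invalid run configuration (bad path or parameter)."""


@dataclass
class GroupComparison:
    group_a_values: list[float]
    group_b_values: list[float]
    t_statistic: float
    welch_df: float
    p_value: float


def welch_t(a, b) -> GroupComparison:
    """Welch's two-sided unequal-variance t-test.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b), df by the
    Welch-Satterthwaite formula, p from the t distribution. When both
    groups have zero variance and equal means the statistic degenerates to
    t = 0, p = 1 (warned via log).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        logger.warning("welch_t: zero variance in both groups; degenerate comparison")
        diff = a.mean() - b.mean()
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        return GroupComparison(list(a), list(b), t, float(na + nb - 2), 1.0 if t == 0 else 0.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return GroupComparison(list(a), list(b), float(t), float(df), p)


@dataclass
class RunConfig:
    """Paths and stage parameters for one pipeline run."""

    out_dir: str | Path = "epiedit_run"
    seed: int = 0
    # input paths; when alignments is None the toy cohort is simulated
    reference: str | None = None
    annotation: str | None = None
    alignments: str | None = None
    sites: str | None = None
    # simulation parameters (used when simulating)
    n_samples: int = 24
    depth_mrna: int = 60
    depth_amplicon: int = 30
    edited_fraction: float = 0.5
    aberrant_splice_ratio: float = 0.2
    seq_error_rate: float = 0.0
    # stage parameters
    window: int | None = None
    min_support: int = 1
    max_error_frac: float = 0.0
    nmads: float = 3.0
    marker_threshold: float = 0.0
    masked_exons: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {SEM_GENE: (2, 10)}
    )

    def validate(self) -> None:
        for name in ("reference", "annotation", "alignments", "sites"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        provided = [self.reference, self.annotation, self.alignments, self.sites]
        if any(p is not None for p in provided) and any(p is None for p in provided):
            raise ConfigError(
                "provide reference, annotation, alignments and sites together, or none"
            )
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if not 0 <= self.max_error_frac < 1:
            raise ConfigError("max_error_frac must be in [0, 1)")
        if self.window is not None and self.window < 0:
            raise ConfigError("window must be >= 0")


def _stage(name: str, **params) -> None:
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in sorted(params.items())))


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage; returns the paths of the written tables."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # --- inputs (simulated or supplied)
    if config.alignments is None:
        _stage("simulate", seed=config.seed, n_samples=config.n_samples)
        sim_dir, truth = simulate_to_dir(
            SimConfig(
                seed=config.seed,
                n_samples=config.n_samples,
                depth_mrna=config.depth_mrna,
                depth_amplicon=config.depth_amplicon,
                edited_fraction=config.edited_fraction,
                aberrant_splice_ratio=config.aberrant_splice_ratio,
                seq_error_rate=config.seq_error_rate,
            ),
            out / "sim",
        )
        ref = read_genome(sim_dir / "reference.fa")
        models = read_gene_models(sim_dir / "genes.gff")
        sites = read_guide_sites(sim_dir / "sites.tsv")
        align_dir = sim_dir / "alignments"
        written["truth"] = sim_dir / "truth_editing.tsv"
    else:
        ref = read_genome(config.reference)
        models = read_gene_models(config.annotation)
        sites = read_guide_sites(config.sites)
        align_dir = Path(config.alignments)

    if config.window is not None:
        sites = [
            type(s)(s.name, s.chrom, s.cut_pos, config.window) for s in sites
        ]
    model_by_id = {m.gene_id: m for m in models}
    coding = [m for m in models if m.cds_start is not None]

    sam_paths = sorted(align_dir.glob("*.sam"))
    if not sam_paths:
        raise ConfigError(f"no SAM files under {align_dir}")
    reads_by_sample = {
        p.stem: list(read_alignments(p, sample_id=p.stem)) for p in sam_paths
    }

    # --- genotyping
    _stage("genotype", min_support=config.min_support, max_error_frac=config.max_error_frac)
    genotypes = [
        eg.genotype_sample(
            reads, sites, ref,
            min_support=config.min_support,
            max_error_frac=config.max_error_frac,
            sample_id=sid,
        )
        for sid, reads in sorted(reads_by_sample.items())
    ]
    eg.events_table(genotypes).to_csv(out / "events.tsv", sep="\t", index=False)
    eg.genotypes_table(genotypes).to_csv(out / "genotypes.tsv", sep="\t", index=False)
    eg.summarize_cohort(genotypes).to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    written["events"] = out / "events.tsv"
    written["genotypes"] = out / "genotypes.tsv"
    written["cohort_summary"] = out / "cohort_summary.tsv"

    # --- ORF consequences of called events
    _stage("orf")
    site_by_name = {s.name: s for s in sites}
    orf_rows = []
    for g in genotypes:
        for ev in g.events:
            # large-deletion events are named "siteA--siteB"
            site_name = ev.site_name.split("--")[0]
            site = site_by_name.get(site_name)
            if site is None:
                continue
            gene = next(
                (
                    m
                    for m in coding
                    if m.chrom == site.chrom and m.span[0] <= ev.ref_span[0] <= m.span[1]
                ),
                None,
            )
            if gene is None:
                continue
            wt = oc.wildtype_variant(gene, ref)
            try:
                var = oc.apply_edit(wt, ev, gene)
            except ValueError:
                continue
            rep = oc.translate_orf(var)
            orf_rows.append(
                {
                    "sample_id": ev.sample_id,
                    "site": ev.site_name,
                    "gene_id": gene.gene_id,
                    "variant": rep.variant,
                    "protein_aa": rep.protein_length_aa,
                    "wt_aa": rep.wt_length_aa,
                    "relative_length": rep.relative_length,
                    "frameshift": rep.frameshift,
                    "premature_stop": rep.premature_stop,
                    "flags": ",".join(rep.flags),
                }
            )
    pd.DataFrame(
        orf_rows,
        columns=[
            "sample_id", "site", "gene_id", "variant", "protein_aa", "wt_aa",
            "relative_length", "frameshift", "premature_stop", "flags",
        ],
    ).to_csv(out / "orf_reports.tsv", sep="\t", index=False)
    written["orf_reports"] = out / "orf_reports.tsv"

    # --- splicing
    _stage("splice")
    splice_summaries = []
    for sid, reads in sorted(reads_by_sample.items()):
        for m in coding:
            jx = sq.extract_junctions(reads, m)
            splice_summaries.append(sq.aberrant_fraction(jx, m, "all_junctions", sid))
            if m.gene_id == CXC_GENE:
                splice_summaries.append(sq.aberrant_fraction(jx, m, ("from_exon", 1), sid))
    sq.summary_table(splice_summaries).to_csv(out / "splice_summary.tsv", sep="\t", index=False)
    written["splice_summary"] = out / "splice_summary.tsv"

    # --- quantification (masked counts; effective-length FPKM for cxcX)
    _stage("quantify", masks=config.masked_exons)
    quant_rows = []
    summaries_by = {(s.sample_id, s.gene_id, s.mode): s for s in splice_summaries}
    for sid, reads in sorted(reads_by_sample.items()):
        lib = sum(
            xq.count_reads_masked(reads, m, frozenset()) for m in models
        )
        for m in coding:
            mask = set(config.masked_exons.get(m.gene_id, ()))
            eff = None
            if m.gene_id == CXC_GENE:
                s = summaries_by.get((sid, CXC_GENE, "from_exon(1)"))
                r = s.fraction if s is not None and s.total_reads > 0 else 0.0
                full = m.transcript_length
                skipped = full - (
                    m.exon_by_index(2)[1] - m.exon_by_index(2)[0] + 1
                )
                eff = xq.effective_length(xq.EffectiveLengthSpec(full, skipped, r))
            row = xq.quantify_gene(reads, m, lib, mask, eff)
            row["sample_id"] = sid
            quant_rows.append(row)
    pd.DataFrame(quant_rows)[
        ["sample_id", "gene_id", "raw_count", "cpm", "effective_length_bp", "fpkm"]
    ].to_csv(out / "quantification.tsv", sep="\t", index=False)
    written["quantification"] = out / "quantification.tsv"

    # --- single-cell QC and marker combinations (companion count matrix)
    _stage("scqc", nmads=config.nmads)
    from .synthetic_data import simulate_count_matrix

    cm, cm_truth = simulate_count_matrix(seed=config.seed)
    qc = scqc.qc_filter_cells(cm, nmads=config.nmads)
    qc.table.to_csv(out / "qc_report.tsv", sep="\t")
    passing = cm.counts.loc[:, qc.passing_samples]
    filtered = scqc.filter_genes(
        type(cm)(passing, cm.gene_length_bp),
        exclusion_lists={"mitochondrial": [g for g in cm.gene_ids if g.startswith("mt-")]},
    )
    expr = scqc.compute_fpkm(filtered)
    groups = cm_truth.set_index("cell")["group"].reindex(expr.fpkm.columns)
    _cells, fractions = scqc.classify_marker_combinations(
        expr, ("tcf21", "tbx18", "wt1b"), config.marker_threshold, groups
    )
    fractions.to_csv(out / "marker_fractions.tsv", sep="\t", index=False)
    written["qc_report"] = out / "qc_report.tsv"
    written["marker_fractions"] = out / "marker_fractions.tsv"

    # --- group comparison: aberrant splicing, edited vs unedited samples
    _stage("compare")
    gt = eg.genotypes_table(genotypes)
    sem_sites = [s.name for s in sites if s.chrom == model_by_id[SEM_GENE].chrom] if SEM_GENE in model_by_id else []
    edited_samples = set(
        gt[(gt["status"] == "edited")]["sample_id"]
    )
    frac_by_sample = {
        s.sample_id: s.fraction
        for s in splice_summaries
        if s.gene_id == CXC_GENE and s.mode == "from_exon(1)" and s.total_reads > 0
    }
    a = [v for k, v in sorted(frac_by_sample.items()) if k in edited_samples]
    b = [v for k, v in sorted(frac_by_sample.items()) if k not in edited_samples]
    comp_rows = []
    if len(a) >= 2 and len(b) >= 2:
        c = welch_t(a, b)
        comp_rows.append(
            {
                "comparison": "cxcX_aberrant_splice_fraction_edited_vs_unedited",
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "t": c.t_statistic,
                "df": c.welch_df,
                "p_value": c.p_value,
            }
        )
    pd.DataFrame(
        comp_rows,
        columns=["comparison", "n_a", "n_b", "mean_a", "mean_b", "t", "df", "p_value"],
    ).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    written["comparisons"] = out / "comparisons.tsv"
    return written
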