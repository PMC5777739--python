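"""Desk-scale orchestration of the full concordance study.

Stages, in order: (1) purity scoring and tumor filtering; (2) FGA with a
group comparison; (3) gene-level copy-number correlations, over all genes
and over a focal-peak subset; (4) mutation matrix on the shared gene
universe, differential-mutation testing, and pairwise exclusivity testing;
(5) coverage-normalized mutation burden with a group comparison; (6) UV
signature classification. Every stage writes a TSV; a JSON summary records
the sample count entering and surviving each stage. Samples lacking a
required data type are dropped per-analysis, not globally.

All outputs are plain text with stable column names and fixed float
formatting, so a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import copy_number, io_formats, mutation_stats, purity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GroupComparison", "run_pipeline", "group_compare",
           "cluster_heatmap_order"]

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Input paths and thresholds for one pipeline run."""

    tumor_maf: str
    cell_line_maf: str
    tumor_seg: str
    cell_line_seg: str
    tumor_expression: str
    cell_line_expression: str
    gene_model: str
    stromal_set: str
    immune_set: str
    outdir: str
    focal_peaks: Optional[str] = None
    coverage_dir: Optional[str] = None

    purity_threshold: float = 0.60
    fga_threshold: float = 0.2
    min_vaf: float = 0.1
    depth_presence: int = 8
    depth_burden: int = 14
    min_mutated: int = 5
    uv_ct_threshold: float = 0.60
    uv_cctt_threshold: float = 0.05
    diff_multiplier: Optional[int] = None
    excl_multiplier: Optional[int] = None
    exclusivity_genes: Optional[list[str]] = None
    n_exclusivity_genes: int = 8
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name, lo, hi in (
            ("purity_threshold", 0.0, 1.01),
            ("min_vaf", 0.0, 1.0),
            ("uv_ct_threshold", 0.0, 1.0),
            ("uv_cctt_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.fga_threshold <= 0:
            raise ValueError("fga_threshold must be > 0")
        for name in ("depth_presence", "depth_burden", "min_mutated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "tumor_maf", "cell_line_maf", "tumor_seg", "cell_line_seg",
            "tumor_expression", "cell_line_expression", "gene_model",
            "stromal_set", "immune_set",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class GroupComparison:
    groups: dict[str, int]  # label -> n
    anova_p: float
    pairwise: list[dict] = field(default_factory=list)
    # each: {group_i, group_j, mean_difference, adjusted_p}


def group_compare(values: Sequence[float], labels: Sequence[str]) -> GroupComparison:
    """One-way ANOVA across groups plus Tukey HSD for every group pair.

    Classic (equal-variance) ANOVA; Tukey via the studentized-range
    distribution, valid for unbalanced groups. Order of samples is
    irrelevant.
    """
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: values[labels == g] for g in uniq}
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    anova_p = float(f_oneway(*[by_group[g] for g in uniq]).pvalue)
    tk = pairwise_tukeyhsd(values, labels)
    pairwise = []
    for row in tk.summary().data[1:]:
        g1, g2, meandiff, p_adj = row[0], row[1], float(row[2]), float(row[3])
        pairwise.append(
            {
                "group_i": str(g1),
                "group_j": str(g2),
                "mean_difference": meandiff,
                "adjusted_p": p_adj,
            }
        )
    return GroupComparison(
        groups={g: int(len(by_group[g])) for g in uniq},
        anova_p=anova_p,
        pairwise=pairwise,
    )


def cluster_heatmap_order(matrix: pd.DataFrame) -> tuple[list, list]:
    """Row and column orderings from Ward clustering on Euclidean distance.

    Missing values are imputed to the column mean (logged). A degenerate
    all-equal matrix returns the input order with a warning. Ties break by
    input index (scipy's ordering is deterministic for fixed input).
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("matrix must be at least 2x2")
    values = matrix.to_numpy(dtype=float).copy()
    if np.isnan(values).any():
        logger.info("imputing missing cells to column means for clustering")
        col_means = np.nanmean(values, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        nan_r, nan_c = np.where(np.isnan(values))
        values[nan_r, nan_c] = col_means[nan_c]
    if np.ptp(values) == 0:
        warnings.warn("degenerate all-equal matrix; returning input order",
                      stacklevel=2)
        return list(matrix.index), list(matrix.columns)

    def order(x: np.ndarray) -> list[int]:
        if np.ptp(x) == 0:
            return list(range(x.shape[0]))
        return [int(i) for i in leaves_list(linkage(x, method="ward"))]

    row_order = [matrix.index[i] for i in order(values)]
    col_order = [matrix.columns[i] for i in order(values.T)]
    return row_order, col_order


# ---------------------------------------------------------------------------
# run_pipeline
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False,
               index_label: Optional[str] = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FMT)


def _load_coverage(coverage_dir: Path, sample_ids: Sequence[str]):
    tracks = {}
    for sid in sample_ids:
        bed = coverage_dir / f"{sid}.bed"
        wig = coverage_dir / f"{sid}.wig"
        if bed.exists():
            tracks[sid] = io_formats.read_coverage(bed, "bed", sample_id=sid)
        elif wig.exists():
            tracks[sid] = io_formats.read_coverage(wig, "wig", sample_id=sid)
    return tracks


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the JSON-ready summary dict.

    A stage with no eligible samples is skipped with an explicit summary
    entry; downstream stages run where their inputs exist.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "thresholds": {}}

    log_lines = ["thresholds used:"]
    for key in (
        "purity_threshold", "fga_threshold", "min_vaf", "depth_presence",
        "depth_burden", "min_mutated", "uv_ct_threshold", "uv_cctt_threshold",
        "diff_multiplier", "excl_multiplier", "seed",
    ):
        val = getattr(config, key)
        summary["thresholds"][key] = val
        log_lines.append(f"  {key} = {val}")

    # ---- inputs ------------------------------------------------------------
    t_expr = io_formats.read_expression(config.tumor_expression)
    c_expr = io_formats.read_expression(config.cell_line_expression)
    stromal = purity.GeneSet.from_file(config.stromal_set)
    immune = purity.GeneSet.from_file(config.immune_set)
    t_seg = io_formats.read_seg(config.tumor_seg)
    c_seg = io_formats.read_seg(config.cell_line_seg)
    model = io_formats.read_gene_model(config.gene_model)
    t_maf = io_formats.read_maf(config.tumor_maf)
    c_maf = io_formats.read_maf(config.cell_line_maf)
    focal_genes: Optional[list[str]] = None
    if config.focal_peaks:
        _, symbols = io_formats.read_gene_set(config.focal_peaks)
        focal_genes = sorted(symbols)

    # ---- stage 1: purity ----------------------------------------------------
    t_purity = purity.add_purity(purity.estimate_scores(t_expr, stromal, immune))
    c_purity = purity.add_purity(purity.estimate_scores(c_expr, stromal, immune))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept_tumors = set(purity.filter_by_purity(t_purity, config.purity_threshold))
    pur_df = pd.concat(
        [purity.results_frame(t_purity).assign(group="tumor"),
         purity.results_frame(c_purity).assign(group="cell_line")],
        ignore_index=True,
    )
    _write_tsv(pur_df, out / "purity.tsv")
    summary["stages"]["purity"] = {
        "n_tumors_scored": len(t_purity),
        "n_cell_lines_scored": len(c_purity),
        "n_tumors_passing": len(kept_tumors),
        "skipped": False,
    }
    log_lines.append(f"tumors passing purity filter: {len(kept_tumors)}")

    # ---- stage 2: FGA -------------------------------------------------------
    t_seg_kept = [p for p in t_seg if p.sample_id in kept_tumors]
    fga_rows = []
    for profile, group in [(p, "tumor") for p in t_seg_kept] + [
        (p, "cell_line") for p in c_seg
    ]:
        r = copy_number.fga(profile, config.fga_threshold)
        fga_rows.append(
            {"sample_id": r.sample_id, "group": group, "fga": r.fga,
             "threshold": r.threshold, "total_length": r.total_length}
        )
    fga_df = pd.DataFrame(fga_rows)
    if fga_df.empty:
        summary["stages"]["fga"] = {"skipped": True, "reason": "no samples with segments"}
    else:
        _write_tsv(fga_df, out / "fga.tsv")
        stage: dict = {
            "n_tumors": int((fga_df["group"] == "tumor").sum()),
            "n_cell_lines": int((fga_df["group"] == "cell_line").sum()),
            "skipped": False,
        }
        counts = fga_df["group"].value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            gc = group_compare(fga_df["fga"], fga_df["group"])
            stage["group_comparison"] = {
                "anova_p": gc.anova_p, "groups": gc.groups, "pairwise": gc.pairwise,
            }
        summary["stages"]["fga"] = stage

    # ---- stage 3: copy-number correlation -----------------------------------
    if not t_seg_kept or not c_seg:
        summary["stages"]["cn_correlation"] = {
            "skipped": True, "reason": "a group has no purity-passing segment profiles",
        }
    else:
        t_cn = copy_number.project_segments_to_genes(t_seg_kept, model)
        c_cn = copy_number.project_segments_to_genes(c_seg, model)
        r_all, n_all = copy_number.pairwise_gene_cn_correlation(c_cn, t_cn)
        _write_tsv(r_all, out / "cn_correlation_all_genes.tsv", index=True,
                   index_label="cell_line")
        mean_all = copy_number.correlation_to_mean_profile(c_cn, t_cn)
        _write_tsv(mean_all, out / "cn_correlation_to_tumor_mean.tsv")
        stage = {
            "n_cell_lines": int(r_all.shape[0]),
            "n_tumors": int(r_all.shape[1]),
            "n_genes": int(t_cn.shape[0]),
            "skipped": False,
        }
        if focal_genes:
            r_focal, _ = copy_number.pairwise_gene_cn_correlation(
                c_cn, t_cn, gene_subset=focal_genes
            )
            _write_tsv(r_focal, out / "cn_correlation_focal_genes.tsv",
                       index=True, index_label="cell_line")
            mean_focal = copy_number.correlation_to_mean_profile(
                c_cn, t_cn, gene_subset=focal_genes
            )
            _write_tsv(mean_focal, out / "cn_correlation_focal_to_tumor_mean.tsv")
            stage["n_focal_genes"] = int(
                len(t_cn.index.intersection(pd.Index(focal_genes)))
            )
            row_order, col_order = cluster_heatmap_order(
                r_focal.fillna(0.0) if r_focal.isna().any().any() else r_focal
            )
            with (out / "cn_correlation_focal_cluster_order.txt").open("w") as fh:
                fh.write("# rows (cell lines)\n")
                fh.writelines(f"{x}\n" for x in row_order)
                fh.write("# columns (tumors)\n")
                fh.writelines(f"{x}\n" for x in col_order)
        summary["stages"]["cn_correlation"] = stage

    # ---- stage 4: mutation matrix, differential + exclusivity tests ---------
    t_filt = io_formats.filter_mutations(
        t_maf, config.min_vaf, config.depth_presence, include_synonymous=False
    )
    t_filt = [r for r in t_filt if r.sample_id in kept_tumors]
    c_filt = io_formats.filter_mutations(
        c_maf, config.min_vaf, config.depth_presence, include_synonymous=False
    )
    t_samples = sorted({r.sample_id for r in t_filt})
    c_samples = sorted({r.sample_id for r in c_filt})
    if not t_samples or not c_samples:
        summary["stages"]["mutation_tests"] = {
            "skipped": True, "reason": "a group has no qualifying mutations",
        }
    else:
        t_genes = {r.gene for r in t_filt}
        c_genes = {r.gene for r in c_filt}
        universe = sorted(t_genes & c_genes)
        t_matrix = mutation_stats.build_mutation_matrix(t_filt, universe, t_samples)
        c_matrix = mutation_stats.build_mutation_matrix(c_filt, universe, c_samples)
        diff = mutation_stats.differential_mutation_test(
            c_matrix, t_matrix,
            min_mutated=config.min_mutated,
            multiplier=config.diff_multiplier or len(universe),
        )
        if diff:
            _write_tsv(
                mutation_stats.test_results_frame(diff).rename(
                    columns={
                        "mutated_a": "mutated_cell_lines", "n_a": "n_cell_lines",
                        "mutated_b": "mutated_tumors", "n_b": "n_tumors",
                    }
                ),
                out / "differential_mutation.tsv",
            )
        excl_genes = config.exclusivity_genes
        if excl_genes is None:
            # default: the most recurrently mutated shared genes, tie-break
            # by symbol, mirroring a significantly-mutated-gene shortlist
            totals = (
                t_matrix.sum(axis=1) + c_matrix.sum(axis=1)
            ).sort_values(ascending=False, kind="stable")
            ordered = sorted(
                totals.index, key=lambda g: (-int(totals[g]), g)
            )
            excl_genes = ordered[: config.n_exclusivity_genes]
        excl_genes = [g for g in excl_genes if g in universe]
        combined = mutation_stats.build_mutation_matrix(
            t_filt + c_filt, universe, t_samples + c_samples
        )
        stage = {
            "n_shared_genes": len(universe),
            "n_tumors": len(t_samples),
            "n_cell_lines": len(c_samples),
            "n_differential_tested": len(diff),
            "skipped": False,
        }
        if len(excl_genes) >= 2:
            for label, matrix in (("tumors", t_matrix), ("cell_lines", c_matrix)):
                excl = mutation_stats.test_exclusivity_pairs(
                    matrix, excl_genes, multiplier=config.excl_multiplier
                )
                _write_tsv(
                    mutation_stats.test_results_frame(excl),
                    out / f"exclusivity_{label}.tsv",
                )
            stage["n_exclusivity_pairs"] = (
                len(excl_genes) * (len(excl_genes) - 1) // 2
            )
            stage["exclusivity_genes"] = excl_genes
        summary["stages"]["mutation_tests"] = stage

    # ---- stage 5: burden -----------------------------------------------------
    if config.coverage_dir is None:
        summary["stages"]["burden"] = {"skipped": True, "reason": "no coverage_dir"}
    else:
        covdir = Path(config.coverage_dir)
        all_ids = sorted(
            {r.sample_id for r in t_maf if r.sample_id in kept_tumors}
            | {r.sample_id for r in c_maf}
        )
        tracks = _load_coverage(covdir, all_ids)
        by_sample: dict[str, list] = {}
        tumor_ids = {r.sample_id for r in t_maf}
        for r in list(t_maf) + list(c_maf):
            by_sample.setdefault(r.sample_id, []).append(r)
        burden_rows = []
        for sid in all_ids:
            if sid not in tracks:
                continue
            breadth = mutation_stats.coverage_breadth(
                tracks[sid], min_depth=config.depth_burden
            )
            if breadth == 0:
                warnings.warn(f"{sid}: zero coverage breadth; burden undefined",
                              stacklevel=2)
                continue
            b = mutation_stats.mutation_burden(
                by_sample.get(sid, []), breadth, sample_id=sid,
                min_vaf=config.min_vaf, min_depth=config.depth_burden,
            )
            burden_rows.append(
                {
                    "sample_id": sid,
                    "group": "tumor" if sid in tumor_ids else "cell_line",
                    "n_mutations": b.n_mutations,
                    "breadth_bp": b.breadth_bp,
                    "per_mb": b.per_mb,
                    "log2_per_mb": (
                        b.log2_per_mb if b.log2_per_mb is not None else np.nan
                    ),
                }
            )
        if not burden_rows:
            summary["stages"]["burden"] = {
                "skipped": True, "reason": "no samples with coverage",
            }
        else:
            burden_df = pd.DataFrame(burden_rows)
            _write_tsv(burden_df, out / "burden.tsv")
            stage = {"n_samples": len(burden_df), "skipped": False}
            ok = burden_df.dropna(subset=["log2_per_mb"])
            counts = ok["group"].value_counts()
            if len(counts) >= 2 and (counts >= 2).all():
                gc = group_compare(ok["log2_per_mb"], ok["group"])
                stage["group_comparison"] = {
                    "anova_p": gc.anova_p, "groups": gc.groups,
                    "pairwise": gc.pairwise,
                }
            summary["stages"]["burden"] = stage

    # ---- stage 6: UV signature ------------------------------------------------
    uv_rows = []
    for records, group, keep in (
        (t_maf, "tumor", kept_tumors),
        (c_maf, "cell_line", None),
    ):
        filt = io_formats.filter_mutations(
            records, config.min_vaf, config.depth_presence, include_synonymous=True
        )
        by_sample = {}
        for r in filt:
            if keep is not None and r.sample_id not in keep:
                continue
            by_sample.setdefault(r.sample_id, []).append(r)
        for sid in sorted(by_sample):
            u = mutation_stats.uv_signature(
                by_sample[sid], sample_id=sid,
                ct_threshold=config.uv_ct_threshold,
                cctt_threshold=config.uv_cctt_threshold,
            )
            uv_rows.append(
                {
                    "sample_id": sid, "group": group,
                    "n_substitutions": u.n_substitutions,
                    "frac_ct_dipyrimidine": u.frac_ct_dipyrimidine,
                    "frac_cc_tt": u.frac_cc_tt, "is_uv": u.is_uv,
                    "n_context_unknown": u.n_context_unknown,
                }
            )
    if uv_rows:
        uv_df = pd.DataFrame(uv_rows)
        _write_tsv(uv_df, out / "uv_signature.tsv")
        summary["stages"]["uv"] = {
            "n_samples": len(uv_df),
            "n_uv_positive": int(uv_df["is_uv"].sum()),
            "skipped": False,
        }
    else:
        summary["stages"]["uv"] = {"skipped": True, "reason": "no qualifying records"}

    with (out / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with (out / "run_log.txt").open("w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary
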