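"""Copy-number concordance: segment-to-gene projection, the fraction genome
altered (FGA) statistic, and Pearson correlation of per-gene copy number
between cohorts.

FGA for a sample is

    FGA = sum_i L_i * [|CN_i| > T] / sum_i L_i

over its autosomal segments, where L_i is segment length, CN_i the
ploidy-corrected log2 ratio, and T a threshold (default 0.2 on the log2
scale; strict ">" at the boundary). FGA is invariant under subdividing a
segment into pieces with the same mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SegmentProfile

__all__ = [
    "FgaResult",
    "project_segments_to_genes",
    "fga",
    "fga_table",
    "pairwise_gene_cn_correlation",
    "correlation_to_mean_profile",
    "DEFAULT_FGA_THRESHOLD",
]

DEFAULT_FGA_THRESHOLD = 0.2
SEX_CHROMS = frozenset({"X", "Y"})
MIN_GENES_FOR_CORRELATION = 3


@dataclass(frozen=True)
class FgaResult:
    sample_id: str
    fga: float
    threshold: float
    total_length: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fga <= 1.0):
            raise ValueError(f"fga out of [0,1]: {self.fga}")
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")


def fga(
    profile: SegmentProfile,
    threshold: float = DEFAULT_FGA_THRESHOLD,
    inclusive: bool = False,
) -> FgaResult:
    """Fraction genome altered for one segmented profile.

    Only autosomal segments enter numerator and denominator. ``inclusive``
    switches the boundary comparison from strict ``>`` (default) to ``>=``.
    Segment lengths use the 1-based inclusive convention (end - start + 1).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    total = 0
    altered = 0
    for chrom, start, end, mean in profile.segments:
        if chrom in SEX_CHROMS:
            continue
        length = end - start + 1
        total += length
        hit = abs(mean) >= threshold if inclusive else abs(mean) > threshold
        if hit:
            altered += length
    if total == 0:
        raise ValueError(f"{profile.sample_id}: no autosomal segments")
    return FgaResult(profile.sample_id, altered / total, threshold, total)


def fga_table(
    profiles: Sequence[SegmentProfile],
    threshold: float = DEFAULT_FGA_THRESHOLD,
    inclusive: bool = False,
) -> pd.DataFrame:
    rows = [fga(p, threshold, inclusive) for p in profiles]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "fga": [r.fga for r in rows],
            "threshold": [r.threshold for r in rows],
            "total_length": [r.total_length for r in rows],
        }
    )


def project_segments_to_genes(
    profiles: Sequence[SegmentProfile],
    model: GeneModel,
    drop_xy: bool = True,
) -> pd.DataFrame:
    """Mean copy number per gene: genes x samples DataFrame.

    Each gene's value is the overlap-length-weighted mean of the seg_means of
    all segments intersecting its span (a gene fully inside one segment
    carries exactly that segment's value). Genes with no overlapping segment
    are NaN. X/Y genes are removed when ``drop_xy``.
    """
    if not model.entries:
        raise ValueError("empty gene model")
    entries = [
        e for e in model.entries if not (drop_xy and e[1] in SEX_CHROMS)
    ]
    genes = [e[0] for e in entries]
    samples = [p.sample_id for p in profiles]
    values = np.full((len(entries), len(samples)), np.nan)

    # genes sorted per chromosome once; segments scanned per sample
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, (_, chrom, start, end) in enumerate(entries):
        by_chrom.setdefault(chrom, []).append((start, end, gi))
    for spans in by_chrom.values():
        spans.sort()

    for sj, profile in enumerate(profiles):
        acc_w = np.zeros(len(entries))
        acc_wm = np.zeros(len(entries))
        for chrom, seg_start, seg_end, mean in profile.segments:
            spans = by_chrom.get(chrom)
            if not spans:
                continue
            for g_start, g_end, gi in spans:
                if g_start > seg_end:
                    break
                if g_end < seg_start:
                    continue
                overlap = min(g_end, seg_end) - max(g_start, seg_start) + 1
                if overlap > 0:
                    acc_w[gi] += overlap
                    acc_wm[gi] += overlap * mean
        touched = acc_w > 0
        values[touched, sj] = acc_wm[touched] / acc_w[touched]

    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)


def _pearson_pairwise_complete(
    x: np.ndarray, y: np.ndarray
) -> tuple[Optional[float], int, str]:
    """Pearson r over indices non-missing in both vectors.

    Returns (r or None, n_used, reason)."""
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < MIN_GENES_FOR_CORRELATION:
        return None, n, "too_few_genes"
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return None, n, "zero_variance"
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return max(-1.0, min(1.0, r)), n, ""


def _subset(matrix: pd.DataFrame, gene_subset: Optional[Sequence[str]]) -> pd.DataFrame:
    if gene_subset is None:
        return matrix
    keep = matrix.index.intersection(pd.Index(gene_subset))
    return matrix.loc[keep]


def pairwise_gene_cn_correlation(
    a: pd.DataFrame,
    b: pd.DataFrame,
    gene_subset: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r of per-gene copy number for every (a-sample, b-sample) pair.

    Genes are matched by symbol; each cell uses the pairwise-complete genes
    of that pair. Returns ``(r, n_genes_used)`` DataFrames with a-samples as
    rows and b-samples as columns; cells with fewer than 3 usable genes or a
    zero-variance vector are NaN (count still reported).
    """
    a = _subset(a, gene_subset)
    b = _subset(b, gene_subset)
    shared = a.index.intersection(b.index)
    if len(shared) < MIN_GENES_FOR_CORRELATION:
        raise ValueError(
            f"only {len(shared)} shared genes; need >= {MIN_GENES_FOR_CORRELATION}"
        )
    av = a.loc[shared].to_numpy(dtype=float)
    bv = b.loc[shared].to_numpy(dtype=float)
    r = np.full((av.shape[1], bv.shape[1]), np.nan)
    n_used = np.zeros((av.shape[1], bv.shape[1]), dtype=int)
    for i in range(av.shape[1]):
        for j in range(bv.shape[1]):
            rij, nij, _ = _pearson_pairwise_complete(av[:, i], bv[:, j])
            n_used[i, j] = nij
            if rij is not None:
                r[i, j] = rij
    rows, cols = list(a.columns), list(b.columns)
    return (
        pd.DataFrame(r, index=rows, columns=cols),
        pd.DataFrame(n_used, index=rows, columns=cols),
    )


def correlation_to_mean_profile(
    a: pd.DataFrame,
    b: pd.DataFrame,
    gene_subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pearson r of each a-sample against the gene-wise mean profile of b.

    The mean over b ignores missing entries per gene. Returns a DataFrame
    with columns sample_id, r, n_genes_used.
    """
    a = _subset(a, gene_subset)
    b = _subset(b, gene_subset)
    shared = a.index.intersection(b.index)
    if len(shared) < MIN_GENES_FOR_CORRELATION:
        raise ValueError(
            f"only {len(shared)} shared genes; need >= {MIN_GENES_FOR_CORRELATION}"
        )
    av = a.loc[shared].to_numpy(dtype=float)
    mean_b = np.nanmean(b.loc[shared].to_numpy(dtype=float), axis=1)
    rows = []
    for i, sample in enumerate(a.columns):
        r, n, reason = _pearson_pairwise_complete(av[:, i], mean_b)
        rows.append(
            {"sample_id": sample, "r": np.nan if r is None else r, "n_genes_used": n}
        )
    return pd.DataFrame(rows)
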