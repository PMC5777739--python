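"""Tumor-purity scoring from expression: single-sample gene-set enrichment
(ssGSEA) for stromal and immune signatures, the combined-score-to-purity
cosine transform, and purity-threshold filtering.

The combined (stromal + immune) enrichment score estimates the non-tumor
admixture of a sample; the published cosine calibration

    purity = cos(0.6049872018 + 0.0001467884 * combined_score)

converts it to an estimated tumor-cell fraction. Scoring is rank-based, so
any strictly monotone per-sample transform of expression (log, quantile)
leaves scores unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import cos, pi
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import read_gene_set

__all__ = [
    "GeneSet",
    "PurityResult",
    "ssgsea_score",
    "estimate_scores",
    "purity_from_score",
    "filter_by_purity",
    "bundled_signatures",
    "PURITY_COS_INTERCEPT",
    "PURITY_COS_SLOPE",
]

# Cosine calibration constants from the published ESTIMATE purity formula.
PURITY_COS_INTERCEPT = 0.6049872018
PURITY_COS_SLOPE = 0.0001467884

DEFAULT_ALPHA = 0.25
DEFAULT_PURITY_THRESHOLD = 0.60


@dataclass(frozen=True)
class GeneSet:
    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_file(cls, path) -> "GeneSet":
        name, symbols = read_gene_set(path)
        return cls(name, frozenset(symbols))


@dataclass
class PurityResult:
    """Per-sample enrichment scores and the derived tumor-cell fraction.

    ``purity`` is None until :func:`purity_from_score` has been applied;
    ``clamped`` flags samples whose cosine fell outside [0, 1].
    """

    sample_id: str
    stromal_score: float
    immune_score: float
    combined_score: float
    purity: Optional[float] = None
    clamped: bool = False
    n_stromal_matched: int = 0
    n_immune_matched: int = 0


def ssgsea_score(
    expr: pd.DataFrame, gene_set: GeneSet, alpha: float = DEFAULT_ALPHA
) -> pd.Series:
    """Unnormalized single-sample enrichment score per sample.

    For each sample, genes are ranked by expression (average ranks on ties,
    highest expression = highest rank). Walking the genes from highest to
    lowest rank, the score is the running sum of the difference between the
    weighted in-set empirical distribution (weights rank^alpha) and the
    unweighted out-of-set one.

    Parameters
    ----------
    expr : DataFrame, genes x samples.
    gene_set : the signature to score.
    alpha : rank-weighting exponent (> 0).

    Returns a Series indexed by sample; ``.attrs['n_matched']`` records the
    size of the set/matrix intersection.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    in_set = expr.index.isin(gene_set.symbols)
    n_matched = int(in_set.sum())
    if n_matched == 0:
        raise ValueError(
            f"gene set {gene_set.name!r} has no genes in the expression matrix"
        )
    n_genes = expr.shape[0]
    n_out = n_genes - n_matched

    values = expr.to_numpy(dtype=float)
    # average ranks, highest expression -> highest rank
    from scipy.stats import rankdata

    scores = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        order = np.argsort(-ranks, kind="stable")  # descending rank
        in_ordered = in_set[order]
        ranks_ordered = ranks[order]
        w = np.where(in_ordered, np.abs(ranks_ordered) ** alpha, 0.0)
        denom_in = w.sum()
        cdf_in = np.cumsum(w) / denom_in
        if n_out > 0:
            cdf_out = np.cumsum(~in_ordered) / n_out
        else:
            cdf_out = np.zeros(n_genes)
        scores[j] = float(np.sum(cdf_in - cdf_out))

    out = pd.Series(scores, index=expr.columns, name=gene_set.name)
    out.attrs["n_matched"] = n_matched
    return out


def estimate_scores(
    expr: pd.DataFrame,
    stromal: GeneSet,
    immune: GeneSet,
    alpha: float = DEFAULT_ALPHA,
) -> list[PurityResult]:
    """Stromal, immune, and combined enrichment scores for every sample."""
    s = ssgsea_score(expr, stromal, alpha)
    i = ssgsea_score(expr, immune, alpha)
    return [
        PurityResult(
            sample_id=str(col),
            stromal_score=float(s[col]),
            immune_score=float(i[col]),
            combined_score=float(s[col] + i[col]),
            n_stromal_matched=s.attrs["n_matched"],
            n_immune_matched=i.attrs["n_matched"],
        )
        for col in expr.columns
    ]


def purity_from_score(combined_score: float) -> tuple[float, bool]:
    """Tumor-cell fraction from the combined score via the cosine calibration.

    Returns ``(purity, clamped)``: results outside [0, 1] (cosine argument
    outside [0, pi/2]) are clamped to the boundary and flagged.
    """
    arg = PURITY_COS_INTERCEPT + PURITY_COS_SLOPE * combined_score
    raw = cos(arg)
    if raw < 0.0:
        return 0.0, True
    if raw > 1.0:
        return 1.0, True
    return raw, False


def add_purity(results: Sequence[PurityResult]) -> list[PurityResult]:
    """Fill the purity field of each result in place; returns the list."""
    for r in results:
        r.purity, r.clamped = purity_from_score(r.combined_score)
    return list(results)


def filter_by_purity(
    results: Sequence[PurityResult], threshold: float = DEFAULT_PURITY_THRESHOLD
) -> list[str]:
    """Sample ids with purity >= threshold (boundary inclusive)."""
    undefined = [r.sample_id for r in results if r.purity is None]
    if undefined:
        raise ValueError(f"purity undefined for samples: {undefined}")
    kept = [r.sample_id for r in results if r.purity >= threshold]
    if not kept:
        import warnings

        warnings.warn(
            f"no samples pass purity >= {threshold}", stacklevel=2
        )
    return kept


def results_frame(results: Sequence[PurityResult]) -> pd.DataFrame:
    """Tabular view of purity results, one row per sample."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "stromal_score": [r.stromal_score for r in results],
            "immune_score": [r.immune_score for r in results],
            "combined_score": [r.combined_score for r in results],
            "purity": [r.purity for r in results],
            "clamped": [r.clamped for r in results],
            "n_stromal_matched": [r.n_stromal_matched for r in results],
            "n_immune_matched": [r.n_immune_matched for r in results],
        }
    )


def bundled_signatures() -> tuple[GeneSet, GeneSet]:
    """The synthetic stand-in stromal and immune signature lists shipped with
    the package (see ``data/``); they mirror the 141-gene structure of the
    published signatures but are synthetic symbols paired with the synthetic
    cohort generator, not the published lists."""
    pkg = resources.files("genoconcord") / "data"
    stromal = GeneSet.from_file(pkg / "stromal_signature.synthetic.txt")
    immune = GeneSet.from_file(pkg / "immune_signature.synthetic.txt")
    return stromal, immune
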