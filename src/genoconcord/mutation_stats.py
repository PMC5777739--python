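"""Mutation-level comparative statistics.

* binary gene x sample mutation matrices (non-synonymous presence),
* differential mutation between two cohorts by the two-sided Fisher exact
  test with Bonferroni correction,
* exact mutual-exclusivity testing of gene pairs by the hypergeometric
  mid-p lower tail on the both-mutated count,
* coverage-normalized tumor mutational burden (mutations per megabase),
* UV mutational-signature classification (C>T at dipyrimidine sites >= 60%
  of substitutions, or CC>TT >= 5%).

Both exact tests are computed in log space (lgamma-based hypergeometric
terms, summed after shifting by the maximum), so p-values down to 1e-50 and
beyond are representable. The two-sided Fisher tail uses the conventional
inclusion rule: every fixed-margin table whose probability is at most the
observed table's times (1 + 1e-7) contributes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, MutationRecord, VariantClass

__all__ = [
    "ContingencyTable22",
    "TestResult",
    "BurdenResult",
    "UVResult",
    "log_hypergeom_pmf",
    "fisher_exact_two_sided",
    "exclusivity_midp",
    "build_mutation_matrix",
    "differential_mutation_test",
    "test_exclusivity_pairs",
    "coverage_breadth",
    "mutation_burden",
    "uv_signature",
]

#: relative slack for the Fisher two-sided inclusion rule (R convention)
FISHER_REL_EPS = 1e-7

PYRIMIDINES = frozenset({"C", "T"})
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class ContingencyTable22:
    """Counts of a gene pair across samples: (neither, gene2-only,
    gene1-only, both). Margins: m1 = gene1_only + both, m2 = gene2_only +
    both; n is the total."""

    neither: int
    gene2_only: int
    gene1_only: int
    both: int

    def __post_init__(self) -> None:
        for name in ("neither", "gene2_only", "gene1_only", "both"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n < 1:
            raise ValueError("table must contain at least one sample")

    @property
    def n(self) -> int:
        return self.neither + self.gene2_only + self.gene1_only + self.both

    @property
    def m1(self) -> int:
        return self.gene1_only + self.both

    @property
    def m2(self) -> int:
        return self.gene2_only + self.both


@dataclass(frozen=True)
class TestResult:
    genes: tuple[str, ...]
    table: Optional[ContingencyTable22]
    p_raw: float
    p_adjusted: float
    multiplier: int
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError(f"p_raw out of (0,1]: {self.p_raw}")
        expected = min(1.0, self.p_raw * self.multiplier)
        if not math.isclose(self.p_adjusted, expected, rel_tol=1e-12):
            raise ValueError("p_adjusted != min(1, p_raw * multiplier)")


@dataclass(frozen=True)
class BurdenResult:
    sample_id: str
    n_mutations: int
    breadth_bp: int
    per_mb: float
    log2_per_mb: Optional[float]


@dataclass(frozen=True)
class UVResult:
    sample_id: str
    n_substitutions: int
    frac_ct_dipyrimidine: float
    frac_cc_tt: float
    is_uv: bool
    n_context_unknown: int


# ---------------------------------------------------------------------------
# Exact tests in log space
# ---------------------------------------------------------------------------

def log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeometric(N population, K successes,
    n draws); -inf outside the support."""
    if k < max(0, n + K - N) or k > min(K, n):
        return -math.inf
    lg = math.lgamma
    return (
        lg(K + 1) - lg(k + 1) - lg(K - k + 1)
        + lg(N - K + 1) - lg(n - k + 1) - lg(N - K - n + k + 1)
        - (lg(N + 1) - lg(n + 1) - lg(N - n + 1))
    )


def _logsumexp(logs: Sequence[float]) -> float:
    m = max(logs)
    if m == -math.inf:
        return -math.inf
    return m + math.log(math.fsum(math.exp(x - m) for x in logs))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the probabilities of all tables with the observed margins whose
    probability is <= the observed table's (with relative slack 1e-7),
    in log space.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    row1 = a + b
    N = a + b + c + d
    col1 = a + c
    if N == 0:
        raise ValueError("empty table")
    lo = max(0, col1 - (N - row1))
    hi = min(row1, col1)
    log_obs = log_hypergeom_pmf(a, N, row1, col1)
    cutoff = log_obs + math.log1p(FISHER_REL_EPS)
    tail = [
        lp
        for k in range(lo, hi + 1)
        if (lp := log_hypergeom_pmf(k, N, row1, col1)) <= cutoff
    ]
    return min(1.0, math.exp(_logsumexp(tail)))


def exclusivity_midp(table: ContingencyTable22) -> float:
    """One-sided exact mutual-exclusivity mid-p for a gene pair.

    With margins fixed, the both-mutated count B is hypergeometric
    (population n, successes m1, draws m2); the mid-p lower tail

        p = P(B < both_observed) + 0.5 * P(B = both_observed)

    is small when the genes co-occur less than independence predicts and
    near 1 when they co-occur more. Computed in log space.
    """
    N, K, n, b = table.n, table.m1, table.m2, table.both
    lo = max(0, n + K - N)
    if b < lo or b > min(K, n):
        raise ValueError("inconsistent table: observed count outside support")
    logs = [log_hypergeom_pmf(k, N, K, n) for k in range(lo, b)]
    logs.append(log_hypergeom_pmf(b, N, K, n) + math.log(0.5))
    return min(1.0, math.exp(_logsumexp(logs)))


def bonferroni(p_raw: float, multiplier: int) -> float:
    return min(1.0, p_raw * multiplier)


# ---------------------------------------------------------------------------
# Mutation matrix and cohort tests
# ---------------------------------------------------------------------------

def build_mutation_matrix(
    records: Iterable[MutationRecord],
    genes: Sequence[str],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Boolean genes x samples presence matrix.

    A bit is set iff the sample carries >= 1 non-synonymous record in the
    gene (records are assumed already VAF/depth filtered). Genes or samples
    with no records get all-False rows/columns; records outside the given
    gene/sample universe are ignored.
    """
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols")
    gi = {g: i for i, g in enumerate(genes)}
    sj = {s: j for j, s in enumerate(samples)}
    present = np.zeros((len(genes), len(samples)), dtype=bool)
    for r in records:
        if r.is_synonymous:
            continue
        i = gi.get(r.gene)
        j = sj.get(r.sample_id)
        if i is not None and j is not None:
            present[i, j] = True
    return pd.DataFrame(
        present, index=pd.Index(list(genes), name="gene"), columns=list(samples)
    )


def differential_mutation_test(
    a: pd.DataFrame,
    b: pd.DataFrame,
    min_mutated: int = 5,
    multiplier: Optional[int] = None,
) -> list[TestResult]:
    """Per-gene two-sided Fisher test of mutation frequency between cohorts.

    ``a`` and ``b`` are boolean mutation matrices over a shared gene
    universe. Genes mutated in fewer than ``min_mutated`` samples in total
    (both cohorts combined) are skipped. Bonferroni multiplier defaults to
    the size of the shared gene universe.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between matrices")
    if multiplier is None:
        multiplier = len(shared)
    na, nb = a.shape[1], b.shape[1]
    mut_a = a.loc[shared].sum(axis=1).astype(int)
    mut_b = b.loc[shared].sum(axis=1).astype(int)
    tested = [g for g in shared if mut_a[g] + mut_b[g] >= min_mutated]
    if multiplier < len(tested):
        warnings.warn(
            f"Bonferroni multiplier {multiplier} < number of tested genes "
            f"{len(tested)}",
            stacklevel=2,
        )
    results = []
    for g in tested:
        ka, kb = int(mut_a[g]), int(mut_b[g])
        p = fisher_exact_two_sided(ka, na - ka, kb, nb - kb)
        results.append(
            TestResult(
                genes=(g,),
                table=None,
                p_raw=p,
                p_adjusted=bonferroni(p, multiplier),
                multiplier=multiplier,
                extra={"mutated_a": ka, "n_a": na, "mutated_b": kb, "n_b": nb},
            )
        )
    return results


def table_from_matrix(m: pd.DataFrame, gene1: str, gene2: str) -> ContingencyTable22:
    for g in (gene1, gene2):
        if g not in m.index:
            raise KeyError(f"gene {g!r} absent from mutation matrix")
    v1 = m.loc[gene1].to_numpy(dtype=bool)
    v2 = m.loc[gene2].to_numpy(dtype=bool)
    return ContingencyTable22(
        neither=int((~v1 & ~v2).sum()),
        gene2_only=int((~v1 & v2).sum()),
        gene1_only=int((v1 & ~v2).sum()),
        both=int((v1 & v2).sum()),
    )


def test_exclusivity_pairs(
    m: pd.DataFrame,
    genes: Sequence[str],
    multiplier: Optional[int] = None,
) -> list[TestResult]:
    """Mid-p exclusivity test for every unordered pair of ``genes``.

    k genes yield k*(k-1)/2 results; the Bonferroni multiplier defaults to
    that pair count (28 for 8 genes).
    """
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in pair list")
    n_pairs = len(genes) * (len(genes) - 1) // 2
    if multiplier is None:
        multiplier = n_pairs
    results = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            t = table_from_matrix(m, g1, g2)
            p = exclusivity_midp(t)
            results.append(
                TestResult(
                    genes=(g1, g2),
                    table=t,
                    p_raw=p,
                    p_adjusted=bonferroni(p, multiplier),
                    multiplier=multiplier,
                )
            )
    return results


def test_results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {}
        if len(r.genes) == 1:
            row["gene"] = r.genes[0]
        else:
            row["gene1"], row["gene2"] = r.genes
        if r.table is not None:
            row.update(
                neither=r.table.neither,
                gene2_only=r.table.gene2_only,
                gene1_only=r.table.gene1_only,
                both=r.table.both,
            )
        row.update(r.extra)
        row["p_raw"] = r.p_raw
        row["p_adjusted"] = r.p_adjusted
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Coverage-normalized burden
# ---------------------------------------------------------------------------

def coverage_breadth(track: CoverageTrack, min_depth: int = 14) -> int:
    """Base pairs covered: sum of interval lengths (intervals mode, spans
    half-open and already depth-thresholded) or count of positions with
    depth >= min_depth (per-position mode)."""
    if track.mode == "intervals":
        return sum(end - start for _, start, end in track.intervals)
    if track.mode == "per_position":
        return sum(1 for _, _, depth in track.positions if depth >= min_depth)
    raise ValueError(f"unknown track mode {track.mode!r}")


def mutation_burden(
    records: Iterable[MutationRecord],
    breadth_bp: int,
    sample_id: str = "",
    min_vaf: float = 0.1,
    min_depth: int = 14,
) -> BurdenResult:
    """Coverage-normalized mutation count for one sample.

    Synonymous variants, insertions, deletions, and substitutions all count
    (unlike the presence matrix). Records with unknown vaf/depth pass the
    corresponding filter. per_mb = n / (breadth_bp / 1e6); log2 is undefined
    at zero mutations.
    """
    if breadth_bp <= 0:
        raise ValueError("breadth_bp must be > 0")
    n = 0
    for r in records:
        if r.vaf is not None and r.vaf < min_vaf:
            continue
        if r.depth is not None and r.depth < min_depth:
            continue
        n += 1
    per_mb = n / (breadth_bp / 1e6)
    return BurdenResult(
        sample_id=sample_id,
        n_mutations=n,
        breadth_bp=breadth_bp,
        per_mb=per_mb,
        log2_per_mb=math.log2(per_mb) if n > 0 else None,
    )


# ---------------------------------------------------------------------------
# UV signature
# ---------------------------------------------------------------------------

def _pyrimidine_context(r: MutationRecord) -> tuple[str, str, Optional[str], Optional[str]]:
    """Strand-normalize a single-base substitution to the pyrimidine
    reference: G>A becomes C>T with complemented, swapped flanks."""
    ref, alt = r.ref_allele, r.alt_allele
    f5, f3 = r.flank5, r.flank3
    if ref in ("G", "A"):
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
        f5, f3 = (
            _COMPLEMENT.get(r.flank3) if r.flank3 else None,
            _COMPLEMENT.get(r.flank5) if r.flank5 else None,
        )
    return ref, alt, f5, f3


def uv_signature(
    records: Iterable[MutationRecord],
    sample_id: str = "",
    ct_threshold: float = 0.60,
    cctt_threshold: float = 0.05,
    either_flank: bool = True,
) -> UVResult:
    """Classify a sample's substitution spectrum as UV-driven or not.

    Substitutions are SNP and DNP records (indels excluded everywhere).
    Each single-base substitution is strand-normalized to the pyrimidine
    reference; a C>T counts toward the dipyrimidine fraction when a flanking
    base is C or T (``either_flank=False`` requires the 5' flank
    specifically). CC>TT dinucleotides (or GG>AA on the other strand) feed
    the second branch. SNP records lacking flank context are excluded from
    numerator and denominator and tallied separately.
    """
    n_subs = 0
    n_ct_dipyr = 0
    n_cctt = 0
    n_unknown = 0
    for r in records:
        if r.variant_class is VariantClass.DNP:
            n_subs += 1
            pair = (r.ref_allele, r.alt_allele)
            if pair == ("CC", "TT") or pair == ("GG", "AA"):
                n_cctt += 1
            continue
        if r.variant_class is not VariantClass.SNP:
            continue
        ref, alt, f5, f3 = _pyrimidine_context(r)
        if ref == "C" and alt == "T":
            # the dipyrimidine call needs context
            if f5 is None and f3 is None:
                n_unknown += 1
                continue
            n_subs += 1
            if either_flank:
                if (f5 in PYRIMIDINES) or (f3 in PYRIMIDINES):
                    n_ct_dipyr += 1
            else:
                if f5 in PYRIMIDINES:
                    n_ct_dipyr += 1
        else:
            n_subs += 1
    if n_subs == 0:
        return UVResult(sample_id, 0, 0.0, 0.0, False, n_unknown)
    frac_ct = n_ct_dipyr / n_subs
    frac_cctt = n_cctt / n_subs
    return UVResult(
        sample_id,
        n_subs,
        frac_ct,
        frac_cctt,
        frac_ct >= ct_threshold or frac_cctt >= cctt_threshold,
        n_unknown,
    )
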