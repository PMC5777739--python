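"""Synthetic paired tumor / cell-line cohorts with known ground truth.

The generator emulates the statistical structure the concordance pipeline
assumes in real TCGA/CCLE-style inputs:

* segmented copy-number profiles sharing planted focal amplifications and
  deletions between groups, over a Gaussian segment-mean background;
* mutation cohorts with a planted mutually exclusive driver pair, a tunable
  fraction of UV-context substitutions (C>T at dipyrimidine sites, with a
  CC>TT sub-rate), synonymous calls, and VAF/read-depth draws under which a
  known share of variants fails the standard filters;
* hybrid-capture-like coverage tracks (BED intervals for tumors, WIG depth
  tracks for cell lines) of configurable breadth over gene bodies;
* expression matrices that are convex mixtures of tumor, stromal, and immune
  archetypes with a known planted purity per sample.

The default genome is deliberately small (2 chromosomes of 1 Mb, 200 genes
of 1 kb) so a full pipeline run takes seconds; everything scales through the
config. All randomness flows from one master seed, split into independent
streams per file type, so outputs are byte-identical across reruns and
adding one generator does not perturb the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CoverageTrack,
    GeneModel,
    MutationRecord,
    SegmentProfile,
    VariantClass,
    write_bed,
    write_expression,
    write_gene_model,
    write_seg,
)

__all__ = [
    "FocalEvent",
    "ExclusivePairConfig",
    "SyntheticCohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "truth_report",
    "default_focal_events",
    "focal_events_with_shared_fraction",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NON_UV_SUBS = [("C", "A"), ("C", "G"), ("T", "A"), ("T", "C"), ("T", "G")]


@dataclass(frozen=True)
class FocalEvent:
    """A recurrent focal amplification or deletion.

    ``carrier_prob_tumor`` / ``carrier_prob_cell_line`` give the per-sample
    probability of carrying the event in each group; ``effect`` is the mean
    log2 ratio added inside the region (negative for deletions).
    """

    chrom: str
    start: int
    end: int
    effect: float
    carrier_prob_tumor: float
    carrier_prob_cell_line: float

    @property
    def direction(self) -> str:
        return "amp" if self.effect > 0 else "del"


@dataclass(frozen=True)
class ExclusivePairConfig:
    """Planted mutually exclusive driver pair.

    Each sample carries exactly one of the two genes with probability
    ``coverage_prob`` (a share ``a_fraction`` of that mass going to gene A),
    both with ``co_occurrence_prob``, and neither otherwise. The defaults
    approximate the margins of a strongly exclusive driver pair in a
    melanoma-sized cohort (roughly 74% of samples carrying one driver,
    2% carrying both).
    """

    gene_a: str = "GENE0001"
    gene_b: str = "GENE0002"
    coverage_prob: float = 0.74
    co_occurrence_prob: float = 0.02
    a_fraction: float = 0.64


@dataclass(frozen=True)
class SyntheticCohortConfig:
    seed: int
    n_tumors: int = 40
    n_cell_lines: int = 8
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    gene_length: int = 1_000
    n_background_segments: int = 4
    background_cn_sd: float = 0.05
    focal_events: Optional[tuple[FocalEvent, ...]] = None
    exclusive_pair: ExclusivePairConfig = field(default_factory=ExclusivePairConfig)
    background_mut_rate: float = 15.0  # mutations per covered Mb
    substitution_fraction: float = 0.9  # remainder split evenly INS/DEL
    synonymous_fraction: float = 0.25  # of background substitutions
    uv_weight: float = 0.65
    cctt_rate: float = 0.05  # share of UV draws emitted as CC>TT dinucleotides
    vaf_beta: tuple[float, float] = (2.0, 5.0)
    depth_nb: tuple[float, float] = (60.0, 3.0)  # mean, size
    coverage_breadth_fraction: float = 0.9
    generate_coverage: bool = True  # skip coverage tracks when not needed
    purity_levels: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
    expression_noise_sd: float = 0.25
    signature_size: int = 25

    def validate(self) -> None:
        ep = self.exclusive_pair
        if ep.coverage_prob + ep.co_occurrence_prob > 1.0:
            raise ValueError(
                "coverage_prob + co_occurrence_prob must be <= 1"
            )
        for name in ("coverage_breadth_fraction", "uv_weight", "cctt_rate",
                     "substitution_fraction", "synonymous_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not all(0.0 <= p <= 1.0 for p in self.purity_levels):
            raise ValueError("purity_levels must be fractions")
        for name in ("n_tumors", "n_cell_lines", "n_chromosomes", "n_genes",
                     "gene_length", "chrom_length", "n_background_segments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted per-sample truth, consistent with the emitted files by
    construction. ``fga_planted`` is the noise-free fraction of autosomal
    length inside carried focal events whose |effect| exceeds the threshold
    recorded in ``fga_threshold``."""

    samples: pd.DataFrame  # sample_id, group, purity, fga_planted, uv_label, exclusivity
    carrier_flags: pd.DataFrame  # sample_id x event columns (bool)
    fga_threshold: float


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    gene_model: GeneModel
    tumor_segments: list[SegmentProfile]
    cell_line_segments: list[SegmentProfile]
    tumor_mutations: list[MutationRecord]
    cell_line_mutations: list[MutationRecord]
    tumor_coverage: list[CoverageTrack]
    cell_line_coverage: list[CoverageTrack]
    tumor_expression: pd.DataFrame
    cell_line_expression: pd.DataFrame
    stromal_genes: list[str]
    immune_genes: list[str]
    focal_peak_genes: list[str]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every file in the formats the readers consume; returns the
        path of each artifact. Deterministic byte-for-byte given the seed."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["gene_model"] = out / "gene_model.tsv"
        write_gene_model(self.gene_model, paths["gene_model"])

        paths["tumor_seg"] = out / "tumors.seg"
        write_seg(self.tumor_segments, paths["tumor_seg"])
        paths["cell_line_seg"] = out / "cell_lines.seg"
        write_seg(self.cell_line_segments, paths["cell_line_seg"])

        paths["tumor_maf"] = out / "tumors.maf"
        _write_maf(self.tumor_mutations, paths["tumor_maf"])
        paths["cell_line_maf"] = out / "cell_lines.maf"
        _write_maf(self.cell_line_mutations, paths["cell_line_maf"])

        covdir = out / "coverage"
        covdir.mkdir(exist_ok=True)
        for track in self.tumor_coverage:
            p = covdir / f"{track.sample_id}.bed"
            write_bed(track, p)
            paths[f"coverage:{track.sample_id}"] = p
        for track in self.cell_line_coverage:
            p = covdir / f"{track.sample_id}.wig"
            _write_wig(track, p)
            paths[f"coverage:{track.sample_id}"] = p

        paths["tumor_expression"] = out / "expression_tumors.tsv"
        write_expression(self.tumor_expression, paths["tumor_expression"])
        paths["cell_line_expression"] = out / "expression_cell_lines.tsv"
        write_expression(self.cell_line_expression, paths["cell_line_expression"])

        for name, genes in (
            ("stromal", self.stromal_genes),
            ("immune", self.immune_genes),
            ("focal_peaks", self.focal_peak_genes),
        ):
            p = out / f"{name}.txt"
            with p.open("w") as fh:
                fh.write(f">{name}\n")
                for g in genes:
                    fh.write(g + "\n")
            paths[name] = p

        paths["truth"] = out / "truth.tsv"
        truth_report(self.truth).to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _write_maf(records: Sequence[MutationRecord], path: Path) -> None:
    cols = (
        "Hugo_Symbol\tTumor_Sample_Barcode\tChromosome\tStart_position\t"
        "Reference_Allele\tTumor_Seq_Allele2\tVariant_Classification\t"
        "Variant_Type\tt_alt_count\tt_ref_count\tFlank5\tFlank3\n"
    )
    vclass_names = {
        (VariantClass.SNP, False): "Missense_Mutation",
        (VariantClass.SNP, True): "Silent",
        (VariantClass.DNP, False): "Missense_Mutation",
        (VariantClass.INS, False): "Frame_Shift_Ins",
        (VariantClass.DEL, False): "Frame_Shift_Del",
    }
    with path.open("w") as fh:
        fh.write(cols)
        for r in records:
            alt_count = int(round((r.vaf or 0.0) * (r.depth or 0)))
            ref_count = (r.depth or 0) - alt_count
            fh.write(
                f"{r.gene}\t{r.sample_id}\t{r.chrom}\t{r.pos}\t"
                f"{r.ref_allele}\t{r.alt_allele}\t"
                f"{vclass_names[(r.variant_class, r.is_synonymous)]}\t"
                f"{r.variant_class.value}\t{alt_count}\t{ref_count}\t"
                f"{r.flank5 or ''}\t{r.flank3 or ''}\n"
            )


def _write_wig(track: CoverageTrack, path: Path) -> None:
    """fixedStep WIG; a new declaration opens at every gap or chromosome
    change."""
    with path.open("w") as fh:
        prev = None
        for chrom, pos, depth in track.positions:
            if prev is None or chrom != prev[0] or pos != prev[1] + 1:
                fh.write(f"fixedStep chrom=chr{chrom} start={pos} step=1\n")
            fh.write(f"{depth}\n")
            prev = (chrom, pos)


# ---------------------------------------------------------------------------
# default genome layout
# ---------------------------------------------------------------------------

def _build_gene_model(cfg: SyntheticCohortConfig) -> GeneModel:
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chromosomes)
    entries = []
    for gi in range(cfg.n_genes):
        chrom = str(gi // per_chrom + 1)
        slot = gi % per_chrom
        spacing = cfg.chrom_length // per_chrom
        start = slot * spacing + spacing // 4 + 1
        entries.append((f"GENE{gi + 1:04d}", chrom, start, start + cfg.gene_length - 1))
    return GeneModel(entries)


def default_focal_events(
    cfg: SyntheticCohortConfig,
    carrier_prob_tumor: float = 0.6,
    carrier_prob_cell_line: float = 0.6,
    effect: float = 1.0,
) -> tuple[FocalEvent, ...]:
    """Three alternating amp/del events per chromosome, each spanning an
    ~8% slice of the chromosome, shared between groups."""
    events = []
    k = 0
    for c in range(1, cfg.n_chromosomes + 1):
        for frac in (0.1, 0.4, 0.7):
            start = int(cfg.chrom_length * frac) + 1
            end = start + int(cfg.chrom_length * 0.08) - 1
            sign = 1.0 if k % 2 == 0 else -1.0
            events.append(
                FocalEvent(str(c), start, end, sign * effect,
                           carrier_prob_tumor, carrier_prob_cell_line)
            )
            k += 1
    return tuple(events)


def focal_events_with_shared_fraction(
    cfg: SyntheticCohortConfig,
    shared_fraction: float,
    carrier_prob: float = 0.8,
    effect: float = 1.0,
) -> tuple[FocalEvent, ...]:
    """Event list where a fraction of the default events is shared between
    tumors and cell lines and the rest alternate tumor-only / cell-line-only;
    used to study how concordance scales with shared signal."""
    base = default_focal_events(cfg, carrier_prob, carrier_prob, effect)
    n_shared = int(round(shared_fraction * len(base)))
    events = []
    for i, ev in enumerate(base):
        if i < n_shared:
            events.append(ev)
        elif (i - n_shared) % 2 == 0:
            events.append(replace(ev, carrier_prob_cell_line=0.0))
        else:
            events.append(replace(ev, carrier_prob_tumor=0.0))
    return tuple(events)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _segment_plan(cfg: SyntheticCohortConfig, events: Sequence[FocalEvent]):
    """Per-chromosome sorted breakpoints merging background boundaries with
    event boundaries. Returns {chrom: [(start, end, event_index or None)]}
    with 1-based inclusive coordinates."""
    plan: dict[str, list[tuple[int, int, Optional[int]]]] = {}
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = str(c)
        cuts = {1, cfg.chrom_length + 1}
        seg_len = cfg.chrom_length // cfg.n_background_segments
        for i in range(1, cfg.n_background_segments):
            cuts.add(i * seg_len + 1)
        ev_here = [(i, e) for i, e in enumerate(events) if e.chrom == chrom]
        for _, e in ev_here:
            cuts.add(e.start)
            cuts.add(e.end + 1)
        edges = sorted(cuts)
        pieces = []
        for s, nxt in zip(edges, edges[1:]):
            ev_idx = None
            for i, e in ev_here:
                if e.start <= s and nxt - 1 <= e.end:
                    ev_idx = i
                    break
            pieces.append((s, nxt - 1, ev_idx))
        plan[chrom] = pieces
    return plan


def _draw_depth(rng: np.random.Generator, mean: float, size: float, n: int) -> np.ndarray:
    # negative binomial parameterized by mean and size (dispersion)
    p = size / (size + mean)
    return rng.negative_binomial(size, p, n)


def _make_substitution(
    rng: np.random.Generator, uv: bool, cctt_rate: float
) -> tuple[str, str, str, str, VariantClass]:
    """(ref, alt, flank5, flank3, class) for one substitution draw.

    UV draws are C>T with at least one pyrimidine flank (emitted on either
    strand) or, at ``cctt_rate``, CC>TT dinucleotides. Non-UV draws are
    uniform over the non-C>T pyrimidine-reference substitutions.
    """
    bases = "ACGT"
    if uv:
        if rng.random() < cctt_rate:
            ref, alt = "CC", "TT"
            f5 = bases[rng.integers(4)]
            f3 = bases[rng.integers(4)]
            if rng.random() < 0.5:
                ref, alt = "GG", "AA"
                f5, f3 = _COMPLEMENT[f3], _COMPLEMENT[f5]
            return ref, alt, f5, f3, VariantClass.DNP
        ref, alt = "C", "T"
        pyr = "CT"[rng.integers(2)]
        other = bases[rng.integers(4)]
        if rng.random() < 0.5:
            f5, f3 = pyr, other
        else:
            f5, f3 = other, pyr
    else:
        ref, alt = _NON_UV_SUBS[rng.integers(len(_NON_UV_SUBS))]
        f5 = bases[rng.integers(4)]
        f3 = bases[rng.integers(4)]
    if rng.random() < 0.5:  # emit on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        f5, f3 = _COMPLEMENT[f3], _COMPLEMENT[f5]
    return ref, alt, f5, f3, VariantClass.SNP


def simulate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full paired cohort; deterministic given ``config.seed``."""
    config.validate()
    events = (
        config.focal_events
        if config.focal_events is not None
        else default_focal_events(config)
    )
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_cn, rng_mut, rng_cov, rng_expr = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    model = _build_gene_model(config)
    plan = _segment_plan(config, events)
    tumors = [f"TUMOR{i + 1:03d}" for i in range(config.n_tumors)]
    cell_lines = [f"CELL{i + 1:03d}" for i in range(config.n_cell_lines)]

    # ----- carrier assignment and exclusivity assignment -------------------
    carrier: dict[str, np.ndarray] = {}
    for group, names in (("tumor", tumors), ("cell_line", cell_lines)):
        probs = np.array(
            [
                e.carrier_prob_tumor if group == "tumor" else e.carrier_prob_cell_line
                for e in events
            ]
        )
        carrier[group] = rng_assign.random((len(names), len(events))) < probs

    ep = config.exclusive_pair
    def assign_exclusivity(n: int) -> list[str]:
        u = rng_assign.random(n)
        out = []
        for x in u:
            if x < ep.co_occurrence_prob:
                out.append("both")
            elif x < ep.co_occurrence_prob + ep.coverage_prob * ep.a_fraction:
                out.append("A")
            elif x < ep.co_occurrence_prob + ep.coverage_prob:
                out.append("B")
            else:
                out.append("neither")
        return out

    excl = {"tumor": assign_exclusivity(config.n_tumors),
            "cell_line": assign_exclusivity(config.n_cell_lines)}

    # ----- copy number ------------------------------------------------------
    def make_profiles(names: Sequence[str], flags: np.ndarray) -> list[SegmentProfile]:
        profiles = []
        for si, name in enumerate(names):
            segs = []
            for chrom in sorted(plan, key=int):
                for start, end, ev_idx in plan[chrom]:
                    mean = rng_cn.normal(0.0, config.background_cn_sd)
                    if ev_idx is not None and flags[si, ev_idx]:
                        mean += events[ev_idx].effect
                    segs.append((chrom, start, end, float(mean)))
            profiles.append(SegmentProfile(name, segs))
        return profiles

    tumor_segs = make_profiles(tumors, carrier["tumor"])
    cl_segs = make_profiles(cell_lines, carrier["cell_line"])

    # ----- coverage ---------------------------------------------------------
    cov_len = int(round(config.coverage_breadth_fraction * config.gene_length))
    gene_spans = [(g, c, s, e) for g, c, s, e in model.entries]

    def tumor_tracks(names: Sequence[str]) -> list[CoverageTrack]:
        tracks = []
        for name in names:
            ivals = [
                (chrom, start - 1, start - 1 + cov_len)
                for _, chrom, start, _ in gene_spans
                if cov_len > 0
            ]
            tracks.append(CoverageTrack(name, "intervals", intervals=ivals))
        return tracks

    def cell_tracks(names: Sequence[str]) -> list[CoverageTrack]:
        tracks = []
        mean, size = config.depth_nb
        for name in names:
            positions = []
            for _, chrom, start, end in gene_spans:
                n_cov = cov_len
                depths_hi = 14 + _draw_depth(rng_cov, mean, size, n_cov)
                depths_lo = rng_cov.integers(0, 14, end - start + 1 - n_cov)
                for off in range(end - start + 1):
                    d = depths_hi[off] if off < n_cov else depths_lo[off - n_cov]
                    positions.append((chrom, start + off, int(d)))
            tracks.append(CoverageTrack(name, "per_position", positions=positions))
        return tracks

    if config.generate_coverage:
        t_cov = tumor_tracks(tumors)
        c_cov = cell_tracks(cell_lines)
    else:
        t_cov, c_cov = [], []

    # ----- mutations --------------------------------------------------------
    covered_mb = config.n_genes * cov_len / 1e6
    a_vaf, b_vaf = config.vaf_beta
    d_mean, d_size = config.depth_nb
    pair_genes = {ep.gene_a, ep.gene_b}
    gene_lookup = {g: (c, s, e) for g, c, s, e in model.entries}
    for g in pair_genes:
        if g not in gene_lookup:
            raise ValueError(f"exclusive-pair gene {g!r} not in gene model")

    def make_mutations(names: Sequence[str], group: str) -> list[MutationRecord]:
        records: list[MutationRecord] = []
        background_genes = [g for g, *_ in model.entries if g not in pair_genes]
        for si, name in enumerate(names):
            n_mut = rng_mut.poisson(config.background_mut_rate * covered_mb)
            for _ in range(n_mut):
                gene = background_genes[rng_mut.integers(len(background_genes))]
                chrom, gstart, _ = gene_lookup[gene]
                pos = int(gstart + rng_mut.integers(max(cov_len, 1)))
                vaf = float(rng_mut.beta(a_vaf, b_vaf))
                depth = int(_draw_depth(rng_mut, d_mean, d_size, 1)[0])
                u = rng_mut.random()
                if u < config.substitution_fraction:
                    uv = rng_mut.random() < config.uv_weight
                    ref, alt, f5, f3, vc = _make_substitution(
                        rng_mut, uv, config.cctt_rate
                    )
                    synonymous = (
                        vc is VariantClass.SNP
                        and rng_mut.random() < config.synonymous_fraction
                    )
                else:
                    if rng_mut.random() < 0.5:
                        ref, alt, vc = "A", "AT", VariantClass.INS
                    else:
                        ref, alt, vc = "AT", "A", VariantClass.DEL
                    f5 = f3 = None
                    synonymous = False
                records.append(
                    MutationRecord(
                        sample_id=name, gene=gene, chrom=chrom, pos=pos,
                        ref_allele=ref, alt_allele=alt, variant_class=vc,
                        is_synonymous=synonymous, vaf=vaf,
                        depth=max(depth, 1), flank5=f5, flank3=f3,
                    )
                )
            # planted driver pair: guaranteed to survive the 0.1 VAF /
            # 14-read filters so the exclusivity pattern is preserved
            assignment = excl[group][si]
            for gene, wanted in ((ep.gene_a, ("A", "both")), (ep.gene_b, ("B", "both"))):
                if assignment in wanted:
                    chrom, gstart, _ = gene_lookup[gene]
                    records.append(
                        MutationRecord(
                            sample_id=name, gene=gene, chrom=chrom,
                            pos=int(gstart + rng_mut.integers(max(cov_len, 1))),
                            ref_allele="T", alt_allele="A",
                            variant_class=VariantClass.SNP,
                            is_synonymous=False,
                            vaf=float(0.15 + 0.7 * rng_mut.random()),
                            depth=int(20 + _draw_depth(rng_mut, d_mean, d_size, 1)[0]),
                            flank5="A", flank3="G",
                        )
                    )
        return records

    t_mut = make_mutations(tumors, "tumor")
    c_mut = make_mutations(cell_lines, "cell_line")

    # ----- expression -------------------------------------------------------
    genes = [g for g, *_ in model.entries]
    sig = config.signature_size
    n_nonpair = len(genes)
    if 2 * sig > n_nonpair - 2:
        raise ValueError("signature_size too large for gene count")
    stromal_genes = genes[-2 * sig : -sig]
    immune_genes = genes[-sig:]

    base = rng_expr.uniform(2.0, 10.0, len(genes))
    tumor_arch = base.copy()
    mix_arch = base.copy()
    idx = {g: i for i, g in enumerate(genes)}
    for g in stromal_genes:
        mix_arch[idx[g]] += 5.0
    for g in immune_genes:
        mix_arch[idx[g]] += 5.0

    def make_expression(names: Sequence[str], purities: Sequence[float]) -> pd.DataFrame:
        cols = {}
        for name, purity in zip(names, purities):
            f = 1.0 - purity
            noise = (
                rng_expr.normal(0.0, config.expression_noise_sd, len(genes))
                if config.expression_noise_sd > 0
                else 0.0
            )
            cols[name] = (1.0 - f) * tumor_arch + f * mix_arch + noise
        return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    levels = config.purity_levels
    t_purity = [levels[i % len(levels)] for i in range(config.n_tumors)]
    c_purity = [1.0] * config.n_cell_lines
    t_expr = make_expression(tumors, t_purity)
    c_expr = make_expression(cell_lines, c_purity)

    # ----- ground truth -----------------------------------------------------
    fga_threshold = 0.2
    autosome_len = config.n_chromosomes * config.chrom_length

    def planted_fga(flags: np.ndarray) -> list[float]:
        lens = np.array(
            [
                e.end - e.start + 1 if abs(e.effect) > fga_threshold else 0
                for e in events
            ]
        )
        return [(flags[si] * lens).sum() / autosome_len for si in range(flags.shape[0])]

    uv_label = config.uv_weight >= 0.60 or (
        config.uv_weight * config.cctt_rate >= 0.05
    )
    rows = []
    for group, names, purities, flags in (
        ("tumor", tumors, t_purity, carrier["tumor"]),
        ("cell_line", cell_lines, c_purity, carrier["cell_line"]),
    ):
        fgas = planted_fga(flags)
        for si, name in enumerate(names):
            rows.append(
                {
                    "sample_id": name,
                    "group": group,
                    "purity": purities[si],
                    "fga_planted": fgas[si],
                    "uv_label": uv_label,
                    "exclusivity": excl[group][si],
                }
            )
    truth_samples = pd.DataFrame(rows)
    flag_rows = np.vstack([carrier["tumor"], carrier["cell_line"]])
    carrier_df = pd.DataFrame(
        flag_rows,
        index=tumors + cell_lines,
        columns=[f"event_{i}_{e.chrom}_{e.start}_{e.direction}" for i, e in enumerate(events)],
    )
    truth = GroundTruth(truth_samples, carrier_df, fga_threshold)

    focal_peak_genes = sorted(
        g
        for g, chrom, gstart, gend in model.entries
        for e in events
        if chrom == e.chrom and gstart >= e.start and gend <= e.end
    )

    return SyntheticCohort(
        config=config,
        gene_model=model,
        tumor_segments=tumor_segs,
        cell_line_segments=cl_segs,
        tumor_mutations=t_mut,
        cell_line_mutations=c_mut,
        tumor_coverage=t_cov,
        cell_line_coverage=c_cov,
        tumor_expression=t_expr,
        cell_line_expression=c_expr,
        stromal_genes=list(stromal_genes),
        immune_genes=list(immune_genes),
        focal_peak_genes=focal_peak_genes,
        truth=truth,
    )


def truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Machine-readable ground truth, one row per sample, stable columns."""
    flags = truth.carrier_flags.copy()
    flags.insert(0, "sample_id", flags.index)
    merged = truth.samples.merge(flags, on="sample_id", how="left")
    merged["fga_threshold"] = truth.fga_threshold
    return merged
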