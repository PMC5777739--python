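"""Readers, writers, and filters for the file formats the pipeline consumes.

All coordinate and dialect decisions live here:

* SEG files and the gene model are 1-based inclusive, as distributed by the
  source projects; BED is 0-based half-open (its standard).
* Chromosome labels are normalized case-insensitively: a leading ``chr`` is
  stripped and ``23``/``24`` map to ``X``/``Y``.
* MAF columns follow TCGA spellings with CCLE fallbacks for the read-count
  columns; VAF = alt_count / (alt_count + ref_count) when a total-depth
  column is absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClass",
    "MutationRecord",
    "SegmentProfile",
    "CoverageTrack",
    "GeneModel",
    "FormatError",
    "read_maf",
    "filter_mutations",
    "read_seg",
    "write_seg",
    "read_coverage",
    "write_bed",
    "read_expression",
    "write_expression",
    "read_gene_model",
    "read_gene_set",
    "normalize_chrom",
]


class FormatError(ValueError):
    """A file violated the expected dialect (missing column, bad row...)."""


class VariantClass(str, Enum):
    SNP = "SNP"
    DNP = "DNP"  # dinucleotide substitution, needed for CC>TT counting
    INS = "INS"
    DEL = "DEL"


#: Variant_Classification values treated as synonymous (no protein change).
SYNONYMOUS_CLASSES = frozenset({"silent", "synonymous", "synonymous_variant"})

_BASES = frozenset("ACGT")


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip ``chr``, map 23/24 to X/Y."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    return c


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call.

    ``vaf`` and ``depth`` are None when the source file carried no read
    counts; ``flank5``/``flank3`` are None when no context columns exist.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    is_synonymous: bool
    vaf: Optional[float] = None
    depth: Optional[int] = None
    flank5: Optional[str] = None
    flank3: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.variant_class is VariantClass.SNP:
            if (
                len(self.ref_allele) != 1
                or len(self.alt_allele) != 1
                or self.ref_allele == self.alt_allele
                or self.ref_allele not in _BASES
                or self.alt_allele not in _BASES
            ):
                raise ValueError(
                    "SNP requires single distinct bases, got "
                    f"{self.ref_allele}>{self.alt_allele}"
                )


@dataclass
class SegmentProfile:
    """Per-sample segmented copy number: (chrom, start, end, seg_mean).

    Coordinates are 1-based inclusive; seg_mean is a ploidy-corrected log2
    ratio. Segments must not overlap within a chromosome.
    """

    sample_id: str
    segments: list[tuple[str, int, int, float]] = field(default_factory=list)

    def validate(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.segments:
            if start >= end:
                raise ValueError(
                    f"{self.sample_id}: segment start {start} >= end {end}"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1 - 1:  # 1-based inclusive overlap
                    raise ValueError(
                        f"{self.sample_id}: overlapping segments on {chrom}"
                    )


@dataclass
class CoverageTrack:
    """Sequencing coverage for one sample.

    ``intervals`` mode holds 0-based half-open (chrom, start, end) spans that
    are interpreted as already depth-thresholded (the BED convention here);
    ``per_position`` mode holds (chrom, pos, depth) triples from WIG.
    """

    sample_id: str
    mode: str  # "intervals" | "per_position"
    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    positions: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class GeneModel:
    """Gene coordinates: one (gene, chrom, start, end) per symbol, 1-based."""

    entries: list[tuple[str, str, int, int]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene, _, start, end in self.entries:
            if start >= end:
                raise ValueError(f"gene {gene}: start {start} >= end {end}")
            if gene in seen:
                raise ValueError(f"duplicate gene symbol {gene}")
            seen.add(gene)


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_MAF_COLUMN_ALIASES = {
    "sample": ["Tumor_Sample_Barcode", "sample", "Sample"],
    "gene": ["Hugo_Symbol", "gene", "Gene"],
    "chrom": ["Chromosome", "chrom", "Chr"],
    "pos": ["Start_position", "Start_Position", "Position", "pos"],
    "ref": ["Reference_Allele", "ref", "Ref"],
    "alt": ["Tumor_Seq_Allele2", "Tumor_Seq_Allele1", "alt", "Alt"],
    "varclass": ["Variant_Classification", "variant_classification"],
}
# optional columns (TCGA spelling first, CCLE fallback)
_MAF_OPTIONAL = {
    "vartype": ["Variant_Type", "variant_type"],
    "alt_count": ["t_alt_count", "alt_count", "Tumor_Alt_Count"],
    "ref_count": ["t_ref_count", "ref_count", "Tumor_Ref_Count"],
    "depth": ["t_depth", "total_reads", "depth"],
    "flank5": ["Flank5", "flank5", "ref_context_5p"],
    "flank3": ["Flank3", "flank3", "ref_context_3p"],
}

_INDEL_CLASSES_DEL = {"frame_shift_del", "in_frame_del", "del"}
_INDEL_CLASSES_INS = {"frame_shift_ins", "in_frame_ins", "ins"}


def _resolve(header: Sequence[str], aliases: Sequence[str]) -> Optional[int]:
    lowered = [h.lower() for h in header]
    for name in aliases:
        if name.lower() in lowered:
            return lowered.index(name.lower())
    return None


def _infer_variant_class(ref: str, alt: str, vartype: str, varclass: str) -> VariantClass:
    vt = vartype.upper()
    if vt in {"SNP", "SNV", "DNP", "INS", "DEL"}:
        return VariantClass("SNP" if vt == "SNV" else vt)
    vc = varclass.lower()
    if vc in _INDEL_CLASSES_DEL:
        return VariantClass.DEL
    if vc in _INDEL_CLASSES_INS:
        return VariantClass.INS
    if ref == "-" or (alt != "-" and len(alt) > len(ref)):
        return VariantClass.INS
    if alt == "-" or len(ref) > len(alt):
        return VariantClass.DEL
    if len(ref) == 2 and len(alt) == 2:
        return VariantClass.DNP
    return VariantClass.SNP


def read_maf(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-dialect mutation file into :class:`MutationRecord` rows.

    The synonymous flag is derived from the variant-classification column;
    VAF comes from alt/total read counts when present, else is left unknown;
    flanking bases come from context columns when present.
    """
    path = Path(path)
    with path.open() as fh:
        header_line = None
        for line in fh:
            if line.startswith("#"):
                continue
            header_line = line.rstrip("\n")
            break
        if header_line is None:
            raise FormatError(f"{path}: empty file, no header")
        header = header_line.split("\t")
        idx = {}
        for key, aliases in _MAF_COLUMN_ALIASES.items():
            i = _resolve(header, aliases)
            if i is None:
                raise FormatError(
                    f"{path}: missing mandatory MAF column for '{key}' "
                    f"(looked for {aliases})"
                )
            idx[key] = i
        opt = {k: _resolve(header, v) for k, v in _MAF_OPTIONAL.items()}

        records: list[MutationRecord] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")

            def get(i: Optional[int]) -> str:
                return fields[i].strip() if i is not None and i < len(fields) else ""

            try:
                varclass = get(idx["varclass"])
                ref = get(idx["ref"]).upper()
                alt = get(idx["alt"]).upper()
                vclass = _infer_variant_class(ref, alt, get(opt["vartype"]), varclass)

                vaf: Optional[float] = None
                depth: Optional[int] = None
                alt_count = get(opt["alt_count"])
                ref_count = get(opt["ref_count"])
                depth_s = get(opt["depth"])
                if depth_s:
                    depth = int(depth_s)
                if alt_count:
                    ac = int(alt_count)
                    if depth is None and ref_count:
                        depth = ac + int(ref_count)
                    if depth:
                        vaf = ac / depth

                f5 = get(opt["flank5"]).upper() or None
                f3 = get(opt["flank3"]).upper() or None
                if f5 is not None and f5 not in _BASES:
                    f5 = None
                if f3 is not None and f3 not in _BASES:
                    f3 = None

                records.append(
                    MutationRecord(
                        sample_id=get(idx["sample"]),
                        gene=get(idx["gene"]),
                        chrom=normalize_chrom(get(idx["chrom"])),
                        pos=int(get(idx["pos"])),
                        ref_allele=ref,
                        alt_allele=alt,
                        variant_class=vclass,
                        is_synonymous=varclass.lower() in SYNONYMOUS_CLASSES,
                        vaf=vaf,
                        depth=depth,
                        flank5=f5,
                        flank3=f3,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: unparseable row at line {lineno}: {exc}") from exc
    return records


def filter_mutations(
    records: Iterable[MutationRecord],
    min_vaf: float = 0.1,
    min_depth: int = 8,
    include_synonymous: bool = False,
) -> list[MutationRecord]:
    """Keep records with vaf >= min_vaf and depth >= min_depth (inclusive).

    Records with unknown vaf or depth are kept (the source file was already
    filtered upstream, as with the CCLE MAF). Synonymous records are dropped
    unless ``include_synonymous``. Order is preserved; the filter is
    idempotent.
    """
    if min_vaf < 0 or min_depth < 0:
        raise ValueError("thresholds must be non-negative")
    out = []
    for r in records:
        if r.vaf is not None and r.vaf < min_vaf:
            continue
        if r.depth is not None and r.depth < min_depth:
            continue
        if not include_synonymous and r.is_synonymous:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

def read_seg(path: str | Path) -> list[SegmentProfile]:
    """Read a 5/6-column SEG file, grouping rows by sample into profiles.

    Columns: sample, chrom, start, end, [num_probes,] seg_mean. A 6-column
    file is assumed to carry a probe count in column 5. Chromosome labels
    are normalized; profiles keep file order of first appearance.
    """
    path = Path(path)
    profiles: dict[str, SegmentProfile] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: missing SEG header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}: line {lineno}: expected >=5 columns")
            sample = fields[0]
            chrom = normalize_chrom(fields[1])
            try:
                start, end = int(fields[2]), int(fields[3])
                seg_mean = float(fields[-1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: segment start {start} >= end {end}"
                )
            profiles.setdefault(sample, SegmentProfile(sample)).segments.append(
                (chrom, start, end, seg_mean)
            )
    result = list(profiles.values())
    for p in result:
        p.validate()
    return result


def write_seg(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tSegment_Mean\n")
        for p in profiles:
            for chrom, start, end, mean in p.segments:
                fh.write(f"{p.sample_id}\t{chrom}\t{start}\t{end}\t{mean:.6g}\n")


# ---------------------------------------------------------------------------
# Coverage: BED and WIG
# ---------------------------------------------------------------------------

def read_coverage(path: str | Path, dialect: str, sample_id: Optional[str] = None) -> CoverageTrack:
    """Read a coverage track.

    ``bed`` yields an intervals-mode track (0-based half-open, already
    depth-thresholded by the producer); ``wig`` yields a per-position track
    supporting both fixedStep and variableStep declarations.
    """
    path = Path(path)
    sid = sample_id or path.stem
    if dialect == "bed":
        intervals: list[tuple[str, int, int]] = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("track", "#", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 3:
                    raise FormatError(f"{path}: line {lineno}: expected BED3")
                chrom = normalize_chrom(fields[0])
                start, end = int(fields[1]), int(fields[2])
                if start < 0 or end < 0:
                    raise FormatError(f"{path}: line {lineno}: negative coordinate")
                if start >= end:
                    raise FormatError(f"{path}: line {lineno}: start >= end")
                intervals.append((chrom, start, end))
        return CoverageTrack(sid, "intervals", intervals=intervals)
    if dialect == "wig":
        positions: list[tuple[str, int, int]] = []
        mode = None  # ("fixed", chrom, next_pos, step) | ("variable", chrom)
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith(("track", "#")):
                    continue
                if s.startswith("fixedStep"):
                    kv = dict(tok.split("=") for tok in s.split()[1:])
                    try:
                        mode = ["fixed", normalize_chrom(kv["chrom"]), int(kv["start"]), int(kv.get("step", 1))]
                    except (KeyError, ValueError) as exc:
                        raise FormatError(f"{path}: line {lineno}: malformed fixedStep: {exc}") from exc
                    if mode[2] < 1:
                        raise FormatError(f"{path}: line {lineno}: negative/zero start")
                    continue
                if s.startswith("variableStep"):
                    kv = dict(tok.split("=") for tok in s.split()[1:])
                    if "chrom" not in kv:
                        raise FormatError(f"{path}: line {lineno}: variableStep missing chrom")
                    mode = ["variable", normalize_chrom(kv["chrom"])]
                    continue
                if mode is None:
                    raise FormatError(f"{path}: line {lineno}: data before step declaration")
                if mode[0] == "fixed":
                    depth = int(float(s))
                    if depth < 0:
                        raise FormatError(f"{path}: line {lineno}: negative depth")
                    positions.append((mode[1], mode[2], depth))
                    mode[2] += mode[3]
                else:
                    fields = s.split()
                    if len(fields) != 2:
                        raise FormatError(f"{path}: line {lineno}: expected 'pos depth'")
                    pos, depth = int(fields[0]), int(float(fields[1]))
                    if pos < 1 or depth < 0:
                        raise FormatError(f"{path}: line {lineno}: bad position/depth")
                    positions.append((mode[1], pos, depth))
        return CoverageTrack(sid, "per_position", positions=positions)
    raise ValueError(f"unknown coverage dialect: {dialect!r}")


def write_bed(track: CoverageTrack, path: str | Path) -> None:
    if track.mode != "intervals":
        raise ValueError("write_bed requires an intervals-mode track")
    with Path(path).open("w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV into a DataFrame indexed by HGNC symbol.

    Tolerates one leading annotation column after the gene column. Duplicate
    gene symbols are collapsed to the row with the highest mean expression
    (logged); ragged rows or zero sample columns are errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: zero sample columns")
    # tolerate one leading non-numeric annotation column
    first = df.iloc[:, 0]
    if first.dtype == object:
        df = df.iloc[:, 1:]
        if df.shape[1] == 0:
            raise FormatError(f"{path}: zero sample columns after annotation")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows (missing values)")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        logger.info("collapsing duplicate gene symbols by max mean: %s", dupes)
        order = list(dict.fromkeys(df.index))
        df = df.assign(_mean=df.mean(axis=1)).sort_values(
            "_mean", ascending=False, kind="stable"
        )
        df = df[~df.index.duplicated(keep="first")].drop(columns="_mean").loc[order]
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


# ---------------------------------------------------------------------------
# Gene model and gene sets
# ---------------------------------------------------------------------------

def read_gene_model(path: str | Path) -> GeneModel:
    """Read a BED-like TSV of gene coordinates (gene, chrom, start, end).

    Coordinates are 1-based inclusive. A header line is detected by a
    non-numeric third column and skipped.
    """
    entries: list[tuple[str, str, int, int]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns")
            if lineno == 1:
                try:
                    int(fields[2])
                except ValueError:
                    continue  # header
            entries.append(
                (fields[0], normalize_chrom(fields[1]), int(fields[2]), int(fields[3]))
            )
    return GeneModel(entries)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        for gene, chrom, start, end in model.entries:
            fh.write(f"{gene}\t{chrom}\t{start}\t{end}\n")


def read_gene_set(path: str | Path) -> tuple[str, set[str]]:
    """Read a gene-set file: a ``>name`` or ``#name`` header line then one
    symbol per line. Returns (name, symbols)."""
    path = Path(path)
    name = path.stem
    symbols: set[str] = set()
    with path.open() as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith((">", "#")):
                name = s.lstrip(">#").strip() or name
                continue
            symbols.add(s)
    if not symbols:
        raise FormatError(f"{path}: empty gene set")
    return name, symbols
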