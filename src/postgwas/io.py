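"""Readers and writers for the external formats the tool touches.

Coordinate conventions are explicit and follow each format's published
spec: variant tables (TSV or the SNV-only VCF dialect) are 1-based;
BED and bedGraph are 0-based half-open. All internal arithmetic is
0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .pwm import BASES, PositionFrequencyMatrix, counts_to_frequencies

__all__ = [
    "GenomeSequence",
    "CandidateVariant",
    "VariantTable",
    "ScoreTrack",
    "IntervalSet",
    "RowError",
    "read_fasta",
    "read_variant_table",
    "read_jaspar",
    "read_bedgraph",
    "read_bed",
    "write_annotations",
    "write_variant_table",
]

_IUPAC = set("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class RowError:
    """A rejected input row with its provenance and reason."""

    source: str
    line: int
    reason: str

    def __str__(self) -> str:
        return f"{self.source}:{self.line}: {self.reason}"


class GenomeSequence:
    """Uppercase contig sequences over {A, C, G, T, N} with bounds-checked lookup."""

    def __init__(self, contigs: dict[str, str]):
        self.contigs = dict(contigs)

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return bases [start, end) (0-based half-open); out of bounds is an error."""
        if contig not in self.contigs:
            raise KeyError(f"contig {contig!r} not in genome")
        seq = self.contigs[contig]
        if not (0 <= start < end <= len(seq)):
            raise IndexError(
                f"window [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end]

    def base_at(self, contig: str, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self.fetch(contig, pos - 1, pos)


@dataclass(frozen=True)
class CandidateVariant:
    """One SNV with the association statistics the candidate filter needs."""

    id: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    pvalue: float
    maf: float
    info_score: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.id}: p-value {self.pvalue} outside (0, 1]")
        if not (0 <= self.maf <= 0.5):
            raise ValueError(
                f"{self.id}: MAF {self.maf} outside [0, 0.5] "
                "(must be the minor-allele frequency)"
            )
        if not (0 <= self.info_score <= 1):
            raise ValueError(f"{self.id}: info score {self.info_score} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be 1-based (got {self.pos})")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if len(allele) != 1 or allele not in "ACGT":
                raise ValueError(f"{self.id}: {name} allele {allele!r} is not a single base")


@dataclass
class VariantTable:
    """Validated SNV rows plus the per-row errors raised while reading them."""

    variants: list[CandidateVariant]
    dialect: str = "tsv"
    errors: list[RowError] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for v in self.variants:
            key = (v.contig, v.pos, v.alt)
            if key in seen:
                raise ValueError(f"duplicate variant {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (v.id, v.contig, v.pos, v.ref, v.alt, v.pvalue, v.maf, v.info_score)
                for v in self.variants
            ],
            columns=["id", "chrom", "pos", "ref", "alt", "pvalue", "maf", "info"],
        )


class ScoreTrack:
    """Sorted, non-overlapping per-contig (start, end, value) intervals.

    Coordinates are 0-based half-open; gaps mean "no data", not zero.
    """

    def __init__(self, intervals: dict[str, list[tuple[int, int, float]]]):
        self.intervals: dict[str, np.ndarray] = {}
        for contig, ivals in intervals.items():
            arr = np.array(sorted(ivals), dtype=float).reshape(-1, 3)
            for s, e in zip(arr[1:, 0], arr[:-1, 1]):
                if s < e:
                    raise ValueError(f"overlapping score intervals on {contig!r}")
            if (arr[:, 0] >= arr[:, 1]).any():
                raise ValueError(f"empty interval (start >= end) on {contig!r}")
            self.intervals[contig] = arr

    def values_over(self, contig: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are NaN."""
        out = np.full(end - start, np.nan)
        for s, e, v in self.intervals.get(contig, ()):
            lo, hi = max(int(s), start), min(int(e), end)
            if lo < hi:
                out[lo - start : hi - start] = v
        return out


class IntervalSet:
    """Per-contig (start, end) intervals; overlaps and duplicates allowed."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]]):
        self.intervals: dict[str, np.ndarray] = {}
        for contig, ivals in intervals.items():
            arr = np.array(sorted(ivals), dtype=np.int64).reshape(-1, 2)
            if (arr[:, 0] >= arr[:, 1]).any():
                raise ValueError(f"empty interval (start >= end) on {contig!r}")
            if (arr[:, 0] < 0).any():
                raise ValueError(f"negative interval start on {contig!r}")
            self.intervals[contig] = arr

    def count_overlapping(self, contig: str, start: int, end: int) -> int:
        """Intervals overlapping [start, end) by >= 1 base; duplicates each count."""
        arr = self.intervals.get(contig)
        if arr is None or len(arr) == 0:
            return 0
        return int(((arr[:, 0] < end) & (arr[:, 1] > start)).sum())

    def count_starting_in(self, contig: str, start: int, end: int) -> int:
        """Intervals whose start (5' end on the + strand) lies in [start, end)."""
        arr = self.intervals.get(contig)
        if arr is None or len(arr) == 0:
            return 0
        return int(((arr[:, 0] >= start) & (arr[:, 0] < end)).sum())


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file; contig name is the header up to the first whitespace."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in contigs:
            raise ValueError(f"{path}: duplicate contig name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(
                f"{path}: contig {name!r} contains non-IUPAC character(s) "
                f"{sorted(bad)}"
            )
        contigs[name] = seq
    if not contigs:
        raise ValueError(f"{path}: empty FASTA (no records)")
    return GenomeSequence(contigs)


_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "pvalue", "maf", "info"]


def _build_variant(
    source: str,
    line: int,
    vid: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    pvalue: float,
    maf: float,
    info: float,
    variants: list[CandidateVariant],
    errors: list[RowError],
) -> None:
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        errors.append(RowError(source, line, "indel (multi-base allele); SNV only"))
        return
    try:
        variants.append(
            CandidateVariant(vid, chrom, pos, ref, alt, pvalue, maf, info)
        )
    except ValueError as exc:
        errors.append(RowError(source, line, str(exc)))


def _read_variant_tsv(path: Path) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    variants: list[CandidateVariant] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            pos = int(row.pos)
            pvalue, maf, info = float(row.pvalue), float(row.maf), float(row.info)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}:{line}: non-numeric value in pos/pvalue/maf/info"
            ) from None
        if any(map(_is_nan, (pvalue, maf, info))):
            raise ValueError(f"{path}:{line}: non-numeric statistic")
        vid = getattr(row, "id", None) or f"{row.chrom}:{pos}:{row.ref}>{row.alt}"
        _build_variant(
            str(path), line, vid, str(row.chrom), pos, str(row.ref), str(row.alt),
            pvalue, maf, info, variants, errors,
        )
    return VariantTable(variants, dialect="tsv", errors=errors)


def _is_nan(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


def _read_variant_vcf(path: Path) -> VariantTable:
    from cyvcf2 import VCF

    variants: list[CandidateVariant] = []
    errors: list[RowError] = []
    line = 0
    for rec in VCF(str(path)):
        line += 1
        stats = {}
        for key, name in (("P", "P"), ("MAF", "MAF"), ("INFO_SCORE", "INFO_SCORE")):
            val = rec.INFO.get(key)
            if val is None:
                raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} missing INFO key {name}")
            stats[key] = float(val)
        alts = rec.ALT or []
        if len(alts) != 1:
            errors.append(RowError(str(path), line, "multi-allelic record; SNV dialect requires one ALT"))
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}>{alts[0]}"
        _build_variant(
            str(path), line, vid, rec.CHROM, rec.POS, rec.REF, alts[0],
            stats["P"], stats["MAF"], stats["INFO_SCORE"], variants, errors,
        )
    return VariantTable(variants, dialect="vcf", errors=errors)


def read_variant_table(path: str | Path, dialect: str = "tsv") -> VariantTable:
    """Read a variant summary table.

    ``dialect="tsv"`` expects header columns chrom, pos, ref, alt, pvalue,
    maf, info (an optional id column is used if present). ``dialect="vcf"``
    expects an SNV-only VCF with INFO keys P, MAF, INFO_SCORE. Rows with
    indel alleles or out-of-range statistics are rejected into
    ``VariantTable.errors``; structural problems (missing columns,
    non-numeric fields) raise.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")


def read_jaspar(path: str | Path, pseudocount: float = 0.0) -> list[PositionFrequencyMatrix]:
    """Read JASPAR-style PFM blocks into frequency matrices (file order kept)."""
    with open(path) as handle:
        try:
            records = bio_motifs.parse(handle, "jaspar")
        except Exception as exc:
            raise ValueError(f"{path}: cannot parse JASPAR PFM file: {exc}") from exc
    out: list[PositionFrequencyMatrix] = []
    seen: set[str] = set()
    for m in records:
        motif_id = m.matrix_id or m.name
        if motif_id in seen:
            raise ValueError(f"{path}: duplicate motif ID {motif_id!r}")
        seen.add(motif_id)
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T
        if (counts < 0).any():
            raise ValueError(f"{path}: motif {motif_id!r} has negative values")
        out.append(counts_to_frequencies(counts, motif_id, pseudocount=pseudocount))
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def _parse_interval_lines(path: Path, n_fields: int):
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {n_fields} tab-separated fields"
                )
            yield lineno, fields


def read_bedgraph(path: str | Path) -> ScoreTrack:
    """Read a bedGraph (0-based half-open) into a ScoreTrack.

    Unsorted input is sorted; overlapping intervals within a contig are an
    error (a per-base score track must be single-valued).
    """
    path = Path(path)
    per_contig: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, f in _parse_interval_lines(path, 4):
        start, end, value = int(f[1]), int(f[2]), float(f[3])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        per_contig.setdefault(f[0], []).append((start, end, value))
    try:
        return ScoreTrack(per_contig)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED file (0-based half-open) into an IntervalSet.

    Overlaps and duplicate lines are kept: tags are counts, not features.
    """
    path = Path(path)
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for lineno, f in _parse_interval_lines(path, 3):
        start, end = int(f[1]), int(f[2])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        per_contig.setdefault(f[0], []).append((start, end))
    return IntervalSet(per_contig)


ANNOTATION_COLUMNS = [
    "rank",
    "id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "pvalue",
    "maf",
    "info",
    "conservation",
    "dnase_count",
    "n_matches",
    "best_motif",
    "max_abs_delta_nrm",
    "best_delta_nrm",
    "best_delta_abs",
    "composite",
]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_annotations(records: Sequence, path: str | Path) -> None:
    """Write AnnotationRecords as a TSV with a fixed column order.

    Rows are sorted by rank, then contig, then position; floats are printed
    at 6 significant digits, so re-running on the same input is
    byte-identical.
    """
    ordered = sorted(
        records, key=lambda r: (r.composite_rank, r.variant.contig, r.variant.pos)
    )
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for r in ordered:
        v = r.variant
        best = r.best_hit()
        lines.append(
            "\t".join(
                _fmt(x)
                for x in (
                    r.composite_rank, v.id, v.contig, v.pos, v.ref, v.alt,
                    v.pvalue, v.maf, v.info_score,
                    r.conservation, r.dnase_count, r.n_matches,
                    best.motif_id if best else None,
                    r.max_abs_delta_nrm,
                    best.delta_nrm if best else None,
                    best.delta_abs if best else None,
                    r.composite,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as the TSV dialect (round-trips through read)."""
    with open(path, "w") as handle:
        handle.write("\t".join(["id"] + _TSV_COLUMNS) + "\n")
        for v in table:
            handle.write(
                f"{v.id}\t{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{v.pvalue:.6g}\t{v.maf:.6g}\t{v.info_score:.6g}\n"
            )
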