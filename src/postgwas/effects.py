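"""Allele-aware motif scanning around SNVs.

For each SNV, every length-L window covering the variant is extracted from
the reference genome and from the "alternative genome" in which the
reference base is replaced by the alternative allele. Both strands are
scanned (minus-strand windows are reverse-complemented). Each window pair
is scored with the information-weighted mSS, a match is called when the
mSS exceeds the threshold (strictly) on either allele, and two effect
metrics are reported with the alt-minus-ref sign convention:

    delta_nrm = mSS(alt) - mSS(ref)
    delta_abs = Score(alt) - Score(ref)

Per motif only the placement maximizing max(mSS_ref, mSS_alt) is kept by
default (ties broken toward the + strand, then the smallest window offset);
``all_placements=True`` returns every scored placement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import CandidateVariant, GenomeSequence
from .pwm import (
    DegenerateMatrixError,
    PositionFrequencyMatrix,
    absolute_score,
    matrix_similarity,
    reverse_complement,
    score_bounds,
)

MATCH_THRESHOLD = 0.8

__all__ = [
    "AlleleWindowPair",
    "MotifHitReport",
    "RefAlleleMismatch",
    "allele_windows",
    "allele_deltas",
    "scan_variant",
    "MATCH_THRESHOLD",
]


class RefAlleleMismatch(ValueError):
    """The variant's stated reference allele disagrees with the genome."""


@dataclass(frozen=True)
class AlleleWindowPair:
    """One motif-length placement over an SNV on one strand.

    ``offset`` is the SNV's 0-based index within the (strand-oriented)
    window; ref_window and alt_window differ at exactly that index.
    """

    contig: str
    snv_pos: int  # 1-based
    offset: int
    strand: str
    ref_window: str
    alt_window: str

    def __post_init__(self) -> None:
        diffs = [
            i for i, (a, b) in enumerate(zip(self.ref_window, self.alt_window)) if a != b
        ]
        if len(self.ref_window) != len(self.alt_window) or diffs != [self.offset]:
            raise ValueError(
                "ref and alt windows must differ at exactly the offset index"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class MotifHitReport:
    """Best-placement scoring of one motif against one SNV."""

    variant_id: str
    motif_id: str
    strand: str
    offset: int
    mss_ref: float
    abs_ref: float
    mss_alt: float
    abs_alt: float
    delta_nrm: float
    delta_abs: float
    is_match: bool


def allele_windows(
    genome: GenomeSequence, variant: CandidateVariant, length: int
) -> tuple[list[AlleleWindowPair], int]:
    """All length-L window pairs covering the SNV, per strand.

    Window starts run from snv_pos - L + 1 to snv_pos (1-based). Placements
    running off the contig or containing N are dropped; the second return
    value counts dropped placements (per single-strand placement).

    Raises
    ------
    RefAlleleMismatch
        If the genome base at the SNV position differs from variant.ref.
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    genome_base = genome.base_at(variant.contig, variant.pos)
    if genome_base != variant.ref:
        raise RefAlleleMismatch(
            f"{variant.id}: ref allele {variant.ref!r} != genome base "
            f"{genome_base!r} at {variant.contig}:{variant.pos}"
        )
    contig_len = len(genome.contigs[variant.contig])
    pairs: list[AlleleWindowPair] = []
    dropped = 0
    for start1 in range(variant.pos - length + 1, variant.pos + 1):  # 1-based starts
        start0 = start1 - 1
        end0 = start0 + length
        if start0 < 0 or end0 > contig_len:
            dropped += 1
            continue
        ref_win = genome.fetch(variant.contig, start0, end0)
        if "N" in ref_win or set(ref_win) - set("ACGT"):
            dropped += 1
            continue
        offset = variant.pos - start1
        alt_win = ref_win[:offset] + variant.alt + ref_win[offset + 1 :]
        pairs.append(
            AlleleWindowPair(variant.contig, variant.pos, offset, "+", ref_win, alt_win)
        )
        pairs.append(
            AlleleWindowPair(
                variant.contig,
                variant.pos,
                length - 1 - offset,
                "-",
                reverse_complement(ref_win),
                reverse_complement(alt_win),
            )
        )
    return pairs, dropped


def allele_deltas(
    pwm: PositionFrequencyMatrix, pair: AlleleWindowPair
) -> tuple[float, float]:
    """(delta_nrm, delta_abs) for one window pair; alt minus ref.

    Raises DegenerateMatrixError for uninformative motifs (mSS undefined).
    """
    delta_nrm = matrix_similarity(pwm, pair.alt_window) - matrix_similarity(
        pwm, pair.ref_window
    )
    delta_abs = absolute_score(pwm, pair.alt_window) - absolute_score(
        pwm, pair.ref_window
    )
    return delta_nrm, delta_abs


def _score_pair(
    pwm: PositionFrequencyMatrix, pair: AlleleWindowPair, threshold: float
) -> MotifHitReport:
    mss_ref = matrix_similarity(pwm, pair.ref_window)
    mss_alt = matrix_similarity(pwm, pair.alt_window)
    abs_ref = absolute_score(pwm, pair.ref_window)
    abs_alt = absolute_score(pwm, pair.alt_window)
    return MotifHitReport(
        variant_id="",
        motif_id=pwm.id,
        strand=pair.strand,
        offset=pair.offset,
        mss_ref=mss_ref,
        abs_ref=abs_ref,
        mss_alt=mss_alt,
        abs_alt=abs_alt,
        delta_nrm=mss_alt - mss_ref,
        delta_abs=abs_alt - abs_ref,
        is_match=max(mss_ref, mss_alt) > threshold,
    )


def scan_variant(
    genome: GenomeSequence,
    variant: CandidateVariant,
    motifs: list[PositionFrequencyMatrix],
    threshold: float = MATCH_THRESHOLD,
    all_placements: bool = False,
) -> list[MotifHitReport]:
    """Score every motif placement/strand over an SNV on both alleles.

    Returns one report per motif — the placement maximizing
    max(mSS_ref, mSS_alt), ties broken by + strand then smallest offset —
    or every placement when ``all_placements``. Uninformative motifs
    (degenerate score range) and motifs with no valid placement are
    skipped.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    reports: list[MotifHitReport] = []
    for pwm in motifs:
        if score_bounds(pwm).degenerate:
            continue
        pairs, _ = allele_windows(genome, variant, len(pwm))
        if not pairs:
            continue
        scored = [_score_pair(pwm, p, threshold) for p in pairs]
        if all_placements:
            chosen = scored
        else:
            best = max(
                scored,
                key=lambda r: (
                    max(r.mss_ref, r.mss_alt),
                    r.strand == "+",
                    -r.offset,
                ),
            )
            chosen = [best]
        for r in chosen:
            reports.append(
                MotifHitReport(
                    variant_id=variant.id,
                    motif_id=r.motif_id,
                    strand=r.strand,
                    offset=r.offset,
                    mss_ref=r.mss_ref,
                    abs_ref=r.abs_ref,
                    mss_alt=r.mss_alt,
                    abs_alt=r.abs_alt,
                    delta_nrm=r.delta_nrm,
                    delta_abs=r.delta_abs,
                    is_match=r.is_match,
                )
            )
    return reports
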