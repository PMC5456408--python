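"""End-to-end annotation and ranking of candidate variants.

Each filtered SNV is joined with three evidence families: windowed
conservation, DNase tag count, and per-motif allele-effect reports. The
combined order is a transparent weighted mean of per-feature fractional
ranks (higher DNase count, higher conservation and larger |delta_nrm| all
rank better); no published combination formula exists for these evidence
sources, so all raw features are always emitted alongside the composite
and the weights are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effects import MATCH_THRESHOLD, MotifHitReport, RefAlleleMismatch, scan_variant
from .io import (
    CandidateVariant,
    GenomeSequence,
    IntervalSet,
    RowError,
    ScoreTrack,
    VariantTable,
)
from .pwm import PositionFrequencyMatrix
from .sumstats import filter_candidates
from .tracks import (
    CONSERVATION_HALFWIDTH,
    DNASE_HALFWIDTH,
    conservation_score,
    dnase_score,
)

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = {"dnase": 1.0, "conservation": 1.0, "motif_delta": 1.0}

__all__ = ["AnnotationRecord", "AnnotateConfig", "annotate", "rank", "DEFAULT_WEIGHTS"]


@dataclass(frozen=True)
class AnnotationRecord:
    """A candidate variant with all its evidence and (after rank()) its rank."""

    variant: CandidateVariant
    conservation: float  # NaN = missing
    bases_covered: int
    dnase_count: int
    hits: tuple[MotifHitReport, ...]
    n_matches: int
    max_abs_delta_nrm: float
    composite: float = float("nan")
    composite_rank: int = 0

    def best_hit(self) -> MotifHitReport | None:
        """The hit with the largest |delta_nrm| (ties -> motif id)."""
        if not self.hits:
            return None
        return max(self.hits, key=lambda h: (abs(h.delta_nrm), h.motif_id))


@dataclass(frozen=True)
class AnnotateConfig:
    mss_threshold: float = MATCH_THRESHOLD
    apply_filters: bool = False
    all_placements: bool = False
    matches_only: bool = False  # keep only hits passing the match rule
    cons_halfwidth: int = CONSERVATION_HALFWIDTH
    dnase_halfwidth: int = DNASE_HALFWIDTH
    tag_mode: str = "overlap"
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))


def _annotate_one(
    variant: CandidateVariant,
    genome: GenomeSequence,
    motifs: list[PositionFrequencyMatrix],
    cons_track: ScoreTrack | None,
    tag_set: IntervalSet | None,
    cfg: AnnotateConfig,
) -> AnnotationRecord:
    if cons_track is not None:
        cons, covered = conservation_score(
            cons_track, variant.contig, variant.pos, cfg.cons_halfwidth
        )
    else:
        cons, covered = float("nan"), 0
    dnase = (
        dnase_score(tag_set, variant.contig, variant.pos, cfg.dnase_halfwidth, cfg.tag_mode)
        if tag_set is not None
        else 0
    )
    hits = scan_variant(
        genome, variant, motifs, threshold=cfg.mss_threshold,
        all_placements=cfg.all_placements,
    )
    if cfg.matches_only:
        hits = [h for h in hits if h.is_match]
    n_matches = sum(h.is_match for h in hits)
    max_delta = max((abs(h.delta_nrm) for h in hits), default=0.0)
    return AnnotationRecord(
        variant=variant,
        conservation=cons,
        bases_covered=covered,
        dnase_count=dnase,
        hits=tuple(hits),
        n_matches=n_matches,
        max_abs_delta_nrm=max_delta,
    )


def annotate(
    variants: VariantTable,
    genome: GenomeSequence,
    motifs: list[PositionFrequencyMatrix],
    cons_track: ScoreTrack | None = None,
    tag_set: IntervalSet | None = None,
    cfg: AnnotateConfig | None = None,
) -> tuple[list[AnnotationRecord], list[RowError]]:
    """Annotate (and rank) every variant; row-level problems don't stop the run.

    Returns ranked records and the row errors encountered (unknown contig,
    ref-allele mismatch against the genome).
    """
    cfg = cfg or AnnotateConfig()
    if cfg.apply_filters:
        variants = filter_candidates(variants).table
    records: list[AnnotationRecord] = []
    errors: list[RowError] = []
    for i, v in enumerate(variants):
        try:
            records.append(_annotate_one(v, genome, motifs, cons_track, tag_set, cfg))
        except (KeyError, RefAlleleMismatch) as exc:
            errors.append(RowError("variants", i + 1, str(exc)))
            logger.warning("skipping %s: %s", v.id, exc)
    if records:
        records = rank(records, cfg.weights)
    return records, errors


def rank(
    records: list[AnnotationRecord],
    weights: dict[str, float] | None = None,
) -> list[AnnotationRecord]:
    """Assign composite ranks from weighted per-feature fractional ranks.

    Per feature, records get fractional (mean-of-ties) ranks with 1 = best:
    higher dnase_count, higher conservation and higher max|delta_nrm| rank
    better; missing conservation ranks worst. The composite is the weighted
    mean of the fractional ranks; the final order breaks composite ties by
    p-value ascending, then contig, then position. A feature missing in
    every record is dropped from the composite with a warning.
    """
    if not records:
        raise ValueError("rank() needs at least one record")
    weights = dict(weights or DEFAULT_WEIGHTS)
    feats = pd.DataFrame(
        {
            "dnase": [float(r.dnase_count) for r in records],
            "conservation": [r.conservation for r in records],
            "motif_delta": [r.max_abs_delta_nrm for r in records],
        }
    )
    parts: list[pd.Series] = []
    wsum = 0.0
    for name, w in weights.items():
        if name not in feats.columns:
            raise ValueError(f"unknown feature weight {name!r}")
        if w == 0:
            continue
        col = feats[name]
        if col.isna().all():
            logger.warning("feature %r missing in all records; dropped from composite", name)
            continue
        parts.append(w * col.rank(ascending=False, method="average", na_option="bottom"))
        wsum += w
    if not parts:
        composite = pd.Series(1.0, index=feats.index)
    else:
        composite = sum(parts) / wsum
    order = sorted(
        range(len(records)),
        key=lambda i: (
            composite[i],
            records[i].variant.pvalue,
            records[i].variant.contig,
            records[i].variant.pos,
            records[i].variant.alt,
        ),
    )
    ranked = [
        replace(records[i], composite=float(composite[i]), composite_rank=k + 1)
        for k, i in enumerate(order)
    ]
    return ranked
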