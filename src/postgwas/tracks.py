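"""Windowed track annotations per variant.

Two window scores are computed around each candidate SNV:

* conservation — the mean of a per-base conservation track (e.g. phastCons)
  over positions -10..+10 relative to the variant (21 bases, clipped at
  contig ends). Bases without track data are excluded from both numerator
  and denominator — a gap in phastCons means "no alignment", not score 0 —
  and a fully uncovered window yields a missing value.
* DNase hypersensitivity — the number of sequencing-tag intervals in the
  -100..+100 window (201 bases). ``tag_mode="overlap"`` (default) counts
  tags overlapping the window by >= 1 base; ``tag_mode="start"`` counts
  tags whose interval start falls inside the window. Duplicate tags each
  count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import IntervalSet, ScoreTrack

CONSERVATION_HALFWIDTH = 10
DNASE_HALFWIDTH = 100

__all__ = [
    "WindowScore",
    "conservation_score",
    "dnase_score",
    "CONSERVATION_HALFWIDTH",
    "DNASE_HALFWIDTH",
]


@dataclass(frozen=True)
class WindowScore:
    variant_id: str
    conservation: float  # NaN when no track base overlaps the window
    bases_covered: int
    dnase_count: int

    def __post_init__(self) -> None:
        if self.dnase_count < 0:
            raise ValueError("dnase_count must be >= 0")
        if math.isnan(self.conservation) != (self.bases_covered == 0):
            raise ValueError("conservation is missing iff no base is covered")


def _window(pos: int, halfwidth: int) -> tuple[int, int]:
    """0-based half-open window for 1-based pos +/- halfwidth, clipped at 0."""
    return max(pos - 1 - halfwidth, 0), pos + halfwidth


def conservation_score(
    track: ScoreTrack, contig: str, pos: int, halfwidth: int = CONSERVATION_HALFWIDTH
) -> tuple[float, int]:
    """Mean track value over pos +/- halfwidth (1-based, inclusive).

    Returns (mean, bases_covered); mean is NaN when no base has data.
    """
    start, end = _window(pos, halfwidth)
    values = track.values_over(contig, start, end)
    covered = int(np.count_nonzero(~np.isnan(values)))
    if covered == 0:
        return float("nan"), 0
    return float(np.nanmean(values)), covered


def dnase_score(
    tags: IntervalSet,
    contig: str,
    pos: int,
    halfwidth: int = DNASE_HALFWIDTH,
    tag_mode: str = "overlap",
) -> int:
    """Tag count over pos +/- halfwidth (1-based, inclusive)."""
    start, end = _window(pos, halfwidth)
    if tag_mode == "overlap":
        return tags.count_overlapping(contig, start, end)
    if tag_mode == "start":
        return tags.count_starting_in(contig, start, end)
    raise ValueError(f"unknown tag_mode {tag_mode!r} (expected 'overlap' or 'start')")
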