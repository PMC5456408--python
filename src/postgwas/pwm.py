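"""Information-weighted position-weight-matrix scoring.

The scoring model follows the MATCH family of motif scanners: each motif
column ``i`` of a position frequency matrix ``f[i, B]`` is weighted by its
information content

    I(i) = sum_B f[i, B] * log2(4 * f[i, B])        (bits; 0 <= I <= 2)

and a window of bases ``b_1..b_L`` receives the absolute score

    Score = sum_i I(i) * f[i, b_i].

The normalized matrix similarity score (mSS) rescales the absolute score
into [0, 1] by the motif's attainable minimum and maximum:

    mSS = (Score - min_score) / (max_score - min_score),

so the consensus window scores exactly 1 and the anti-consensus exactly 0.
Columns with zero frequencies use the limit convention 0 * log2(0) = 0, so
unsmoothed count matrices remain finite; a pseudocount is available but not
applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "PositionFrequencyMatrix",
    "ScoreBounds",
    "DegenerateMatrixError",
    "counts_to_frequencies",
    "information_vector",
    "absolute_score",
    "score_bounds",
    "matrix_similarity",
    "reverse_complement_pwm",
    "reverse_complement",
    "consensus",
]


class DegenerateMatrixError(ValueError):
    """mSS is undefined: the motif's score range is empty (max == min)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """A motif as per-position base frequencies.

    ``freqs`` has shape (L, 4) with columns ordered A, C, G, T; every row
    sums to 1 (within 1e-9) and entries are non-negative.
    """

    id: str
    freqs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError(f"motif {self.id!r}: frequency matrix must be L x 4")
        if (f < 0).any():
            raise ValueError(f"motif {self.id!r}: negative frequencies")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.id!r}: rows must sum to 1")
        object.__setattr__(self, "freqs", f)

    def __len__(self) -> int:
        return self.freqs.shape[0]


@dataclass(frozen=True)
class ScoreBounds:
    min_score: float
    max_score: float

    def __post_init__(self) -> None:
        if self.min_score > self.max_score:
            raise ValueError("min_score > max_score")

    @property
    def degenerate(self) -> bool:
        return self.max_score == self.min_score


def counts_to_frequencies(
    count_matrix: np.ndarray, motif_id: str = "", pseudocount: float = 0.0
) -> PositionFrequencyMatrix:
    """Convert an L x 4 count (or frequency) matrix to column frequencies.

    f[i, B] = (c[i, B] + pseudocount) / sum_B (c[i, B] + pseudocount)
    """
    c = np.asarray(count_matrix, dtype=float)
    if c.ndim != 2 or c.shape[1] != 4:
        raise ValueError("count matrix must be L x 4 (columns A, C, G, T)")
    if (c < 0).any():
        raise ValueError("negative counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = c + pseudocount
    totals = c.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.flatnonzero(totals == 0)[0])
        raise ValueError(
            f"motif {motif_id!r}: position {bad + 1} has zero total count and "
            "zero pseudocount"
        )
    return PositionFrequencyMatrix(motif_id, c / totals[:, None])


def information_vector(pwm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-column information content I(i) = sum_B f log2(4f), in bits."""
    f = pwm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * np.log2(4.0 * f)
    terms[f == 0] = 0.0  # lim x->0 of x log2(4x)
    return terms.sum(axis=1)


def _window_indices(pwm: PositionFrequencyMatrix, window: str) -> np.ndarray:
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != motif length {len(pwm)}"
        )
    try:
        return np.fromiter((BASE_INDEX[b] for b in window), dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"window contains non-ACGT base {exc.args[0]!r}") from exc


def absolute_score(pwm: PositionFrequencyMatrix, window: str) -> float:
    """Information-weighted match score Score = sum_i I(i) f[i, b_i]."""
    idx = _window_indices(pwm, window)
    info = information_vector(pwm)
    return float((info * pwm.freqs[np.arange(len(pwm)), idx]).sum())


def score_bounds(pwm: PositionFrequencyMatrix) -> ScoreBounds:
    """Attainable score range: per column, the best (worst) base wins."""
    info = information_vector(pwm)
    return ScoreBounds(
        min_score=float((info * pwm.freqs.min(axis=1)).sum()),
        max_score=float((info * pwm.freqs.max(axis=1)).sum()),
    )


def matrix_similarity(pwm: PositionFrequencyMatrix, window: str) -> float:
    """Min-max-normalized match score (mSS) in [0, 1].

    Raises
    ------
    DegenerateMatrixError
        If the motif is uninformative (max_score == min_score), where mSS
        is undefined rather than 0.
    """
    bounds = score_bounds(pwm)
    if bounds.degenerate:
        raise DegenerateMatrixError(
            f"motif {pwm.id!r}: score range is empty (uninformative matrix)"
        )
    score = absolute_score(pwm, window)
    return (score - bounds.min_score) / (bounds.max_score - bounds.min_score)


def reverse_complement_pwm(pwm: PositionFrequencyMatrix) -> PositionFrequencyMatrix:
    """Reverse column order and swap base channels A<->T, C<->G (involution)."""
    return PositionFrequencyMatrix(pwm.id, pwm.freqs[::-1, ::-1].copy())


def consensus(pwm: PositionFrequencyMatrix) -> str:
    """Highest-frequency base per column (ties -> first of A, C, G, T)."""
    return "".join(BASES[i] for i in pwm.freqs.argmax(axis=1))
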