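import math
from itertools import product

import numpy as np
import pytest

from postgwas import CandidateVariant, GenomeSequence, PositionFrequencyMatrix

BASES = "ACGT"
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Independent brute-force oracle: naive per-column loops, no numpy broadcasting,
# kept deliberately separate from the implementation under test.
# ---------------------------------------------------------------------------

def naive_information(column) -> float:
    total = 0.0
    for f in column:
        if f > 0:
            total += f * math.log2(4 * f)
    return total


def naive_score(freqs, window: str) -> float:
    score = 0.0
    for i, base in enumerate(window):
        score += naive_information(freqs[i]) * freqs[i][BASES.index(base)]
    return score


def naive_bounds(freqs):
    length = len(freqs)
    best = max(naive_score(freqs, "".join(w)) for w in product(BASES, repeat=length))
    worst = min(naive_score(freqs, "".join(w)) for w in product(BASES, repeat=length))
    return worst, best


def naive_mss(freqs, window: str) -> float:
    worst, best = naive_bounds(freqs)
    return (naive_score(freqs, window) - worst) / (best - worst)


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def naive_best_placement(genome_seq: str, pos: int, ref: str, alt: str, freqs):
    """Enumerate every placement and strand; return the best (max mSS either allele).

    Mirrors the documented tie-break: highest max(mss_ref, mss_alt), then +
    strand, then smallest offset.
    """
    length = len(freqs)
    assert genome_seq[pos - 1] == ref
    alt_seq = genome_seq[: pos - 1] + alt + genome_seq[pos:]
    candidates = []
    for start1 in range(pos - length + 1, pos + 1):
        start0 = start1 - 1
        if start0 < 0 or start0 + length > len(genome_seq):
            continue
        ref_win = genome_seq[start0 : start0 + length]
        alt_win = alt_seq[start0 : start0 + length]
        if set(ref_win + alt_win) - set(BASES):
            continue
        offset = pos - start1
        for strand, rw, aw, off in (
            ("+", ref_win, alt_win, offset),
            ("-", revcomp(ref_win), revcomp(alt_win), length - 1 - offset),
        ):
            mss_r, mss_a = naive_mss(freqs, rw), naive_mss(freqs, aw)
            candidates.append(
                (max(mss_r, mss_a), strand == "+", -off, strand, off, mss_r, mss_a)
            )
    if not candidates:
        return None
    return max(candidates)


def random_pwm(rng: np.random.Generator, length: int) -> np.ndarray:
    """Dirichlet rows: a generic random frequency matrix."""
    return rng.dirichlet(np.ones(4) * rng.uniform(0.3, 2.0), size=length)


# ---------------------------------------------------------------------------
# Shared scenes
# ---------------------------------------------------------------------------

@pytest.fixture
def two_col_motif() -> PositionFrequencyMatrix:
    """The 0.7/0.1 A-then-C motif used throughout the worked examples."""
    return PositionFrequencyMatrix(
        "AC_motif", np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]])
    )


@pytest.fixture
def ttaat_scene(two_col_motif):
    """Contig TTAAT with an A->C SNV at position 4."""
    genome = GenomeSequence({"chrT": "TTAAT"})
    variant = CandidateVariant("v1", "chrT", 4, "A", "C", 1e-6, 0.3, 0.9)
    return genome, variant, two_col_motif
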