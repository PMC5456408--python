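"""Deterministic synthetic data: toy genomes, planted motifs, tracks, cohorts.

Everything the annotation tool consumes can be generated here with a single
integer seed, so the whole pipeline is testable without any download. Each
generator derives its own named pseudo-random stream from the master seed
(``numpy`` SeedSequence spawning keyed by a label), so adding one fixture
never shifts the random draws of another.

The cohort simulator is the synthetic twin of a replication-cohort summary
row: given a true allelic odds ratio and a control minor-allele frequency
it solves odds(f_case) = OR * odds(f_ctrl) for the case frequency and draws
binomial allele counts (two alleles per subject).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import CandidateVariant, GenomeSequence, IntervalSet, ScoreTrack
from .pwm import BASES, PositionFrequencyMatrix, consensus, information_vector, reverse_complement

TAG_LENGTH = 36  # typical DNase-seq read length; only overlap counts matter

__all__ = [
    "CohortDraw",
    "make_genome",
    "make_pwm",
    "plant_motif",
    "make_disrupting_snv",
    "make_tracks",
    "simulate_cohort",
    "write_fixture_dir",
    "TAG_LENGTH",
]


def _rng(seed: int, label: str) -> np.random.Generator:
    """A named sub-stream of the master seed (stable across processes)."""
    key = zlib.crc32(label.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def make_genome(
    length: int, gc_fraction: float = 0.5, seed: int = 0, contig: str = "chrT"
) -> GenomeSequence:
    """I.i.d. random contig with P(G) + P(C) = gc_fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= gc_fraction <= 1):
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = _rng(seed, f"genome:{contig}")
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    bases = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
    return GenomeSequence({contig: "".join(bases)})


def make_pwm(
    length: int, sharpness: float = 0.85, seed: int = 0, motif_id: str = "M1"
) -> PositionFrequencyMatrix:
    """Random motif: each column puts ``sharpness`` mass on one random base."""
    if not (0.25 < sharpness <= 1.0):
        raise ValueError("sharpness must be in (0.25, 1]")
    rng = _rng(seed, f"pwm:{motif_id}")
    f = np.full((length, 4), (1 - sharpness) / 3)
    f[np.arange(length), rng.integers(0, 4, size=length)] = sharpness
    return PositionFrequencyMatrix(motif_id, f)


def plant_motif(
    genome: GenomeSequence, pwm: PositionFrequencyMatrix, pos: int, strand: str = "+"
) -> GenomeSequence:
    """Write the motif consensus into the genome at 1-based ``pos``.

    On the minus strand the reverse complement of the consensus is written,
    so a minus-strand scan sees the consensus. The planted window has
    mSS = 1 by construction.
    """
    (contig,) = genome.contigs
    seq = genome.contigs[contig]
    word = consensus(pwm)
    if strand == "-":
        word = reverse_complement(word)
    elif strand != "+":
        raise ValueError("strand must be + or -")
    start0 = pos - 1
    if start0 < 0 or start0 + len(word) > len(seq):
        raise ValueError(f"motif does not fit at position {pos}")
    return GenomeSequence({contig: seq[:start0] + word + seq[start0 + len(word) :]})


def make_disrupting_snv(
    pwm: PositionFrequencyMatrix,
    planted_pos: int,
    contig: str = "chrT",
    strand: str = "+",
    pvalue: float = 1e-6,
    maf: float = 0.25,
    info_score: float = 0.95,
) -> CandidateVariant:
    """The positive control: an SNV at the motif's most informative column.

    The reference allele is the planted consensus base and the alternative
    is the lowest-frequency base of that column, so the alt allele is
    guaranteed to lower the match score (delta_nrm < 0).
    """
    info = information_vector(pwm)
    freqs = pwm.freqs
    unique_max = np.array(
        [np.count_nonzero(freqs[i] == freqs[i].max()) == 1 for i in range(len(pwm))]
    )
    candidates = np.flatnonzero(unique_max & (info > 0))
    if candidates.size == 0:
        raise ValueError("motif has no informative column with a unique best base")
    col = int(candidates[np.argmax(info[candidates])])
    ref = BASES[int(freqs[col].argmax())]
    alt = BASES[int(freqs[col].argmin())]
    if strand == "-":
        # the genome carries the reverse complement of the consensus
        from .pwm import reverse_complement as _rc

        pos = planted_pos + (len(pwm) - 1 - col)
        ref, alt = _rc(ref), _rc(alt)
    else:
        pos = planted_pos + col
    return CandidateVariant(
        id=f"snv_{contig}_{pos}",
        contig=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        pvalue=pvalue,
        maf=maf,
        info_score=info_score,
    )


def make_tracks(
    genome: GenomeSequence,
    tag_density: float,
    conserved_intervals: list[tuple[int, int]],
    seed: int = 0,
    conserved_value: float = 0.9,
    background_value: float = 0.1,
) -> tuple[ScoreTrack, IntervalSet]:
    """Synthetic conservation track and DNase tag set for a one-contig genome.

    Conservation is ``conserved_value`` inside the stated 0-based half-open
    intervals and ``background_value`` elsewhere (full coverage). Tags of
    length 36 are dropped at Poisson(tag_density per 100 bp) with uniform
    starts.
    """
    if tag_density < 0:
        raise ValueError("tag_density must be >= 0")
    (contig,) = genome.contigs
    length = len(genome.contigs[contig])
    # conservation: merge the piecewise-constant profile into intervals
    boundaries = {0, length}
    for s, e in conserved_intervals:
        if not (0 <= s < e <= length):
            raise ValueError(f"conserved interval ({s}, {e}) outside contig")
        boundaries.update((s, e))
    cuts = sorted(boundaries)
    cons: list[tuple[int, int, float]] = []
    for s, e in zip(cuts[:-1], cuts[1:]):
        inside = any(cs <= s and e <= ce for cs, ce in conserved_intervals)
        cons.append((s, e, conserved_value if inside else background_value))
    rng = _rng(seed, f"tags:{contig}")
    n_tags = rng.poisson(tag_density * length / 100.0)
    tags: list[tuple[int, int]] = []
    if n_tags > 0:
        starts = np.sort(rng.integers(0, max(length - TAG_LENGTH, 1), size=n_tags))
        tags = [(int(s), int(s) + TAG_LENGTH) for s in starts]
    return ScoreTrack({contig: cons}), IntervalSet({contig: tags} if tags else {})


@dataclass(frozen=True)
class CohortDraw:
    """Observed allele frequencies and the underlying 2x2 allele counts."""

    maf_case_observed: float
    maf_ctrl_observed: float
    counts: tuple[int, int, int, int]  # minor/major alleles in cases, controls
    f_case_true: float


def case_frequency(true_or: float, maf_ctrl: float) -> float:
    """Case allele frequency solving odds(f_case) = OR * odds(maf_ctrl)."""
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    if not (0 < maf_ctrl < 0.5):
        raise ValueError("maf_ctrl must be in (0, 0.5)")
    odds = true_or * maf_ctrl / (1 - maf_ctrl)
    return odds / (1 + odds)


def simulate_cohort(
    true_or: float, maf_ctrl: float, n_case: int, n_ctrl: int, seed: int = 0
) -> CohortDraw:
    """Draw one case/control cohort at a known allelic odds ratio.

    Allele counts are binomial with 2n draws per group (two alleles per
    subject, Hardy-Weinberg allele counting).
    """
    f_case = case_frequency(true_or, maf_ctrl)
    rng = _rng(seed, "cohort")
    a = int(rng.binomial(2 * n_case, f_case))
    c = int(rng.binomial(2 * n_ctrl, maf_ctrl))
    b = 2 * n_case - a
    d = 2 * n_ctrl - c
    return CohortDraw(
        maf_case_observed=a / (2 * n_case),
        maf_ctrl_observed=c / (2 * n_ctrl),
        counts=(a, b, c, d),
        f_case_true=f_case,
    )


def write_fixture_dir(
    out_dir: str | Path,
    seed: int = 0,
    genome_length: int = 2000,
    motif_length: int = 8,
    n_decoys: int = 8,
    tag_density: float = 0.5,
) -> dict[str, Path]:
    """Write a ready-to-annotate fixture set (FASTA, TSV, JASPAR, bedGraph, BED).

    One strong motif is planted mid-contig with a disrupting SNV inside a
    conserved, tag-enriched region; decoy SNVs are scattered over the rest
    of the contig. Returns the paths written, keyed by role.
    """
    from .io import write_variant_table, VariantTable

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed, "fixture-dir")

    genome = make_genome(genome_length, 0.45, seed=seed)
    pwm = make_pwm(motif_length, sharpness=0.9, seed=seed, motif_id="PLANTED")
    planted_pos = genome_length // 2
    genome = plant_motif(genome, pwm, planted_pos)
    snv = make_disrupting_snv(pwm, planted_pos)

    (contig,) = genome.contigs
    conserved = [(planted_pos - 30, planted_pos + motif_length + 30)]
    cons_track, bg_tags = make_tracks(genome, tag_density, conserved, seed=seed)
    # enrich tags around the planted site
    extra = [
        (planted_pos - 60 + int(o), planted_pos - 60 + int(o) + TAG_LENGTH)
        for o in rng.integers(0, 90, size=25)
    ]
    all_tags = list(map(tuple, bg_tags.intervals.get(contig, []))) + extra
    tags = IntervalSet({contig: [(int(s), int(e)) for s, e in all_tags]})

    variants = [snv]
    taken = {snv.pos}
    while len(variants) < n_decoys + 1:
        pos = int(rng.integers(motif_length + 1, genome_length - motif_length))
        if abs(pos - planted_pos) < 200 or pos in taken:
            continue
        ref = genome.base_at(contig, pos)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        variants.append(
            CandidateVariant(
                id=f"decoy_{pos}", contig=contig, pos=pos, ref=ref, alt=str(alt),
                pvalue=float(rng.uniform(1e-6, 9e-5)), maf=0.2, info_score=0.9,
            )
        )
        taken.add(pos)

    paths = {
        "genome": out / "genome.fa",
        "variants": out / "variants.tsv",
        "motifs": out / "motifs.jaspar",
        "conservation": out / "conservation.bedGraph",
        "dnase": out / "tags.bed",
    }
    paths["genome"].write_text(f">{contig}\n{genome.contigs[contig]}\n")
    write_variant_table(VariantTable(sorted(variants, key=lambda v: v.pos)), paths["variants"])
    _write_jaspar(pwm, paths["motifs"])
    with open(paths["conservation"], "w") as fh:
        for s, e, v in cons_track.intervals[contig]:
            fh.write(f"{contig}\t{int(s)}\t{int(e)}\t{v:g}\n")
    with open(paths["dnase"], "w") as fh:
        for s, e in tags.intervals[contig]:
            fh.write(f"{contig}\t{int(s)}\t{int(e)}\n")
    return paths


def _write_jaspar(pwm: PositionFrequencyMatrix, path: Path, scale: int = 100) -> None:
    """Write a motif as a JASPAR-format count block (frequencies x scale)."""
    counts = np.rint(pwm.freqs * scale).astype(int)
    with open(path, "w") as fh:
        fh.write(f">{pwm.id} {pwm.id}\n")
        for j, base in enumerate(BASES):
            row = " ".join(str(c) for c in counts[:, j])
            fh.write(f"{base}  [ {row} ]\n")
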