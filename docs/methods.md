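# Methods

## Motif model and scoring

A motif is a position frequency matrix (PFM) `f[i,B]`, rows summing to 1
over B ∈ {A, C, G, T}. Each column is weighted by its information content
in bits,

    I(i) = Σ_B f[i,B] · log2(4 f[i,B]),

which is 0 for a uniform column and 2 for a fully conserved one. A window
of bases `b_1…b_L` receives the information-weighted match score
`Score = Σ_i I(i) · f[i, b_i]`, and the normalized matrix similarity score
(mSS) rescales it by the motif's attainable extremes,

    mSS = (Score − min) / (max − min),
    min = Σ_i I(i) · min_B f[i,B],   max = Σ_i I(i) · max_B f[i,B],

so the consensus window scores exactly 1 and the anti-consensus exactly 0.
This is plain min–max normalization over the full motif length; the MATCH
family's optional core-pentamer pre-filter and per-matrix cut-off profiles
are deliberately omitted — a single global match threshold is used
instead, so the core step would add nothing but configuration surface.

Numerical conventions:

* `0 · log2(0) := 0` by the limit, so unsmoothed count matrices with zero
  cells give finite information. A pseudocount is exposed
  (`counts_to_frequencies(..., pseudocount=...)`, default 0) for users who
  prefer smoothing; changing it changes I(i) and therefore mSS.
* A motif whose score range is empty (max = min, e.g. an all-uniform
  matrix) has no defined mSS. It raises a typed error in the scoring API
  and is skipped with a warning during scanning — never silently scored 0.
* Matrix rows must sum to 1 within 1e-9; strand symmetry
  (`Score(f, w) = Score(rc(f), rc(w))`) holds to 1e-12 and is enforced by
  property tests.

## Allele-aware scanning

For an SNV at 1-based position p and a motif of length L, every window
start from p−L+1 to p is considered on both strands (minus-strand windows
are reverse-complemented, which is equivalent to scanning the
reverse-complemented motif). For each placement the reference window and
the alternative window (reference base replaced by the alternative allele)
are scored; windows running off the contig or containing N are dropped and
counted. A match is called for a motif when mSS strictly exceeds the
threshold (default 0.8) on either allele at some placement.

Per motif, one report is kept by default: the placement maximizing
max(mSS_ref, mSS_alt), with ties broken toward the + strand and then the
smallest offset of the SNV inside the window. Both deltas are computed at
that jointly best placement — not at separately best per-allele
placements — so the comparison is like-for-like; `all_placements=True`
(CLI `--all-placements`) emits every placement for users who want the
alternative. The sign convention is alt minus ref: a negative `delta_nrm`
means the alternative allele weakens the predicted binding site.

## Window annotations

* Conservation: mean of a per-base track over the 21 bases p−10…p+10,
  clipped at contig ends. Track gaps are excluded from numerator and
  denominator rather than imputed as 0 — in phastCons-style tracks a gap
  means "no alignment", not "score 0". This choice changes ranks for
  variants in sparsely covered regions, so it is a documented default, not
  an implementation detail. A fully uncovered window yields a missing
  value.
* DNase: the number of tag intervals over the 201 bases p−100…p+100. "Tags
  in the window" is ambiguous between any-overlap and 5′-start-in-window;
  any-overlap is the default because it is strand-free and monotone in the
  window width, and `tag_mode="start"` is the alternative. Duplicate tags
  each count — they are sequencing reads, not merged features.

## Candidate filter and ranking

The filter keeps rows with discovery p < 10⁻⁴ AND MAF > 0.005 AND
imputation info score > 0.5, all strict, preserving order and counting
exclusions per reason.

No published formula combines the evidence families into a single rank, so
the composite is deliberately transparent: per feature (DNase count,
conservation, max |delta_nrm|), records receive fractional (mean-of-ties)
ranks with 1 best, higher raw values ranking better and missing
conservation ranking worst; the composite is the weighted mean of those
ranks (default weights 1:1:1, configurable), and residual ties are broken
by p-value, then contig, then position, then allele, making the output a
deterministic permutation of the input regardless of input order. A
feature that is missing in every record is dropped from the composite with
a warning. All raw feature values are always written to the output table,
so any other weighting can be recomputed from it. Chromatin-state evidence
(Roadmap-style segmentations) is not scored: no computable rule is
available, and inventing one would change ranks silently.

## Summary statistics

* Crude allelic OR: from case/control minor-allele frequencies,
  OR = odds(f_case)/odds(f_ctrl). The SE uses the Woolf formula
  √(1/a+1/b+1/c+1/d) on the 2×2 allele-count table (two alleles per
  subject; counts rounded to the nearest integer when reconstructed from
  printed frequencies). Published GWAS ORs are typically
  covariate-adjusted score-test estimates, so the crude OR matches the
  printed value only where adjustment changed nothing at the printed
  precision — the package asserts equality only for such rows.
* CI↔SE: se = (ln hi − ln lo)/(2·1.96). The 95% quantile 1.96 is
  hard-coded (reporting convention) so CI→SE→CI round trips are exact.
* Fixed-effects inverse-variance meta-analysis on log odds ratios:
  weights 1/SE², combined lnOR the weighted mean, combined SE 1/√Σw,
  two-sided normal p. Combining estimates whose SEs were recovered from
  printed (2-decimal) CIs reproduces a published combined OR only
  approximately; the package asserts the combination lies within the range
  of study ORs, never equality. Random-effects models and heterogeneity
  statistics are out of scope.

## Synthetic fixtures

The generator emulates the inputs the annotation tool expects at toy
scale: i.i.d. random contigs with a chosen GC fraction; sharp random
motifs (one base per column carrying `sharpness` mass, default 0.85–0.9);
a consensus planted at a known position (mSS = 1 by construction); a
disrupting SNV at the motif's most informative column with the
lowest-frequency base as the alternative allele (delta_nrm < 0
guaranteed); a two-level conservation profile (0.9 in designated
intervals, 0.1 elsewhere); Poisson-placed 36-bp tags (a typical DNase-seq
read length; only overlap counts matter); and case/control cohorts drawn
binomially at a known allelic odds ratio (case frequency solves
odds(f_case) = OR·odds(f_ctrl); defaults 2000/2000 subjects, control
MAF 0.30, OR 1.3 in the calibration run).

Each generator draws from its own named substream of one master integer
seed (SeedSequence spawn keys derived from a CRC of the label), so outputs
are byte-reproducible and adding a fixture never shifts another's draws.

What the fixtures do **not** emulate: linkage disequilibrium between
variants, imputation error, GC- or mappability-biased tag placement,
realistic conservation autocorrelation, and motif clustering in real
promoters. Passing the end-to-end benchmark therefore shows the pipeline
ranks a true positive above independent decoys under clean evidence — not
that it resolves correlated variants in an LD block.

## Problem sizes and determinism

The test and benchmark sizes are chosen so the full suite runs in well
under a minute: exhaustive oracles enumerate all 4^L windows for motif
lengths ≤ 6 (200 random motifs); symmetry properties are checked on 1000
random triples at 1e-12; the CI-coverage calibration uses 1000 replicates
of 2000/2000 cohorts (expected coverage 93–97%); the end-to-end benchmark
uses 100 random 1.2-kb decoy configurations. Everything is seeded; the
CLI annotation path is fully deterministic, and re-running any command on
the same inputs is byte-identical.

## Known limitations

* SNVs only — indels and multi-nucleotide variants are rejected at input.
* Single match threshold for all motifs; no per-matrix calibrated cut-offs
  and no motif-score p-values.
* bedGraph only for conservation (no bigWig/fixed-step wiggle); plain-text
  BED for tags.
* Ranking is within the supplied table; per-locus grouping is not
  implemented.
* The per-study association test (covariate-adjusted score test) is not
  re-implemented; this package covers the arithmetic downstream of
  published summary statistics.
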