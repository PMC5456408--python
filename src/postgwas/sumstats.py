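"""Candidate filtering and summary-statistics arithmetic.

Covers three things a GWAS summary table makes checkable without genotype
data:

* the candidate filter (discovery p < 1e-4, MAF > 0.005, info score > 0.5;
  all strict),
* crude allelic odds ratios from printed minor-allele frequencies and
  sample counts, with Woolf (log) standard errors from the reconstructed
  2x2 allele-count table, and
* fixed-effects inverse-variance meta-analysis of per-study log odds
  ratios (weights 1/SE^2), as implemented in METAL.

The per-study association tests themselves (covariate-adjusted score
tests) are not re-implemented; a crude allelic OR equals the published OR
only when covariates changed nothing at the printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import VariantTable

P_MAX = 1e-4
MAF_MIN = 0.005
INFO_MIN = 0.5
_Z95 = 1.96  # conventional 95% normal quantile, kept fixed for exact CI<->SE round trips

__all__ = [
    "EffectEstimate",
    "MetaResult",
    "FilterResult",
    "filter_candidates",
    "allelic_or",
    "ci_to_se",
    "estimate_from_ci",
    "meta_fixed",
    "P_MAX",
    "MAF_MIN",
    "INFO_MIN",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One study's odds ratio on the log scale with its standard error."""

    label: str
    ln_or: float
    se_ln_or: float

    def __post_init__(self) -> None:
        if not (self.se_ln_or > 0 and math.isfinite(self.se_ln_or)):
            raise ValueError(f"{self.label}: SE must be positive and finite")
        if not math.isfinite(self.ln_or):
            raise ValueError(f"{self.label}: non-finite lnOR")

    @property
    def or_value(self) -> float:
        return math.exp(self.ln_or)

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            math.exp(self.ln_or - _Z95 * self.se_ln_or),
            math.exp(self.ln_or + _Z95 * self.se_ln_or),
        )


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects inverse-variance combination of study estimates."""

    combined: EffectEstimate
    weights: dict[str, float]
    z: float
    p_two_sided: float

    def summary(self) -> str:
        lines = [
            f"{'study':<20}{'weight':>12}{'rel_weight':>12}",
        ]
        total = sum(self.weights.values())
        for label, w in self.weights.items():
            lines.append(f"{label:<20}{w:>12.4g}{w / total:>12.2%}")
        lo, hi = self.combined.ci95
        lines.append("-" * 44)
        lines.append(
            f"combined OR {self.combined.or_value:.4g} "
            f"(95% CI {lo:.4g}-{hi:.4g}), z = {self.z:.4g}, "
            f"p = {self.p_two_sided:.3g}"
        )
        return "\n".join(lines)


@dataclass
class FilterResult:
    """Survivors of the candidate filter plus per-reason exclusion counts."""

    table: VariantTable
    n_input: int
    excluded: dict[str, int] = field(default_factory=dict)


def filter_candidates(
    table: VariantTable,
    p_max: float = P_MAX,
    maf_min: float = MAF_MIN,
    info_min: float = INFO_MIN,
) -> FilterResult:
    """Keep rows with p < p_max AND maf > maf_min AND info > info_min.

    All comparisons are strict, so rows sitting exactly on a threshold are
    dropped. Input order is preserved; exclusion reasons are counted (a row
    failing several tests counts once per failed test).
    """
    kept = []
    excluded = {"pvalue": 0, "maf": 0, "info": 0}
    for v in table:
        ok = True
        if not v.pvalue < p_max:
            excluded["pvalue"] += 1
            ok = False
        if not v.maf > maf_min:
            excluded["maf"] += 1
            ok = False
        if not v.info_score > info_min:
            excluded["info"] += 1
            ok = False
        if ok:
            kept.append(v)
    return FilterResult(
        table=VariantTable(kept, dialect=table.dialect),
        n_input=len(table),
        excluded=excluded,
    )


def allelic_or(
    maf_case: float,
    n_case: int,
    maf_ctrl: float,
    n_ctrl: int,
    label: str = "",
) -> EffectEstimate:
    """Crude allelic odds ratio from allele frequencies and subject counts.

    The OR is the odds ratio of the frequencies themselves,
    OR = (f_case / (1 - f_case)) / (f_ctrl / (1 - f_ctrl)); the SE uses the
    Woolf formula sqrt(1/a + 1/b + 1/c + 1/d) on allele counts (two alleles
    per subject) rounded to the nearest integer.
    """
    for f, name in ((maf_case, "maf_case"), (maf_ctrl, "maf_ctrl")):
        if not (0 < f < 1):
            raise ValueError(f"{name} = {f} gives a degenerate 2x2 table")
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("sample sizes must be positive")
    ln_or = math.log(maf_case / (1 - maf_case)) - math.log(maf_ctrl / (1 - maf_ctrl))
    a = round(2 * n_case * maf_case)  # minor alleles, cases
    b = 2 * n_case - a
    c = round(2 * n_ctrl * maf_ctrl)  # minor alleles, controls
    d = 2 * n_ctrl - c
    if min(a, b, c, d) == 0:
        raise ValueError("an allele-count cell rounded to zero; table degenerate")
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(label=label, ln_or=ln_or, se_ln_or=se)


def ci_to_se(low: float, high: float) -> float:
    """SE of lnOR recovered from a printed 95% CI: (ln high - ln low) / (2 * 1.96)."""
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    return (math.log(high) - math.log(low)) / (2 * _Z95)


def estimate_from_ci(label: str, or_value: float, low: float, high: float) -> EffectEstimate:
    """Build an EffectEstimate from a printed OR and its 95% CI."""
    if or_value <= 0:
        raise ValueError("OR must be positive")
    return EffectEstimate(label=label, ln_or=math.log(or_value), se_ln_or=ci_to_se(low, high))


def meta_fixed(estimates: list[EffectEstimate], label: str = "combined") -> MetaResult:
    """Fixed-effects inverse-variance meta-analysis.

    weights w_k = 1/SE_k^2; combined lnOR = sum(w lnOR)/sum(w);
    combined SE = 1/sqrt(sum w); z = lnOR/SE; two-sided normal p.
    """
    if not estimates:
        raise ValueError("meta_fixed needs at least one estimate")
    weights = {e.label or f"study{i+1}": 1.0 / e.se_ln_or**2 for i, e in enumerate(estimates)}
    if len(weights) != len(estimates):
        raise ValueError("study labels must be unique")
    w = np.array([1.0 / e.se_ln_or**2 for e in estimates])
    ln_ors = np.array([e.ln_or for e in estimates])
    ln_or = float((w * ln_ors).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = ln_or / se
    p = float(2 * stats.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return MetaResult(
        combined=EffectEstimate(label=label, ln_or=ln_or, se_ln_or=se),
        weights=weights,
        z=z,
        p_two_sided=p,
    )
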