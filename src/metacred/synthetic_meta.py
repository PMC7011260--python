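"""Synthetic case-control meta-analysis catalogues with known truth.

Each variant is simulated at the allele level: control minor-allele counts
are Binomial(2n, f) draws at the population minor allele frequency f, and
case counts are Binomial(2n, f_case) draws at the frequency implied by the
true allelic odds ratio,

    f_case = OR * f/(1-f) / (1 + OR * f/(1-f)).

Per-study 2x2 allele tables are pooled by fixed-effect inverse-variance
meta-analysis of the log odds ratio (Woolf SEs, 0.5 continuity correction
on any zero cell) into a single pooled OR/CI/P record of the same shape as
a published meta-analysis row, so the whole credibility pipeline can be
exercised end to end against catalogues whose true effects are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from . import cred_stats
from .assoc_io import MetaAnalysisRecord, RecordCatalog

__all__ = [
    "TwoByTwoTable",
    "SimulationSpec",
    "SimulatedCatalog",
    "case_allele_frequency",
    "simulate_study",
    "pool_fixed_effect",
    "simulate_catalog",
]


class TwoByTwoTable(NamedTuple):
    """Allele-count table of one case-control study."""

    case_minor: int
    case_major: int
    control_minor: int
    control_major: int

    @property
    def odds_ratio(self) -> float:
        a, b, c, d = self._corrected()
        return (a * d) / (b * c)

    @property
    def log_or(self) -> float:
        return math.log(self.odds_ratio)

    @property
    def se_log_or(self) -> float:
        """Woolf standard error with continuity correction when needed."""
        a, b, c, d = self._corrected()
        return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)

    def _corrected(self) -> tuple[float, float, float, float]:
        cells = (self.case_minor, self.case_major,
                 self.control_minor, self.control_major)
        if any(x == 0 for x in cells):
            return tuple(x + 0.5 for x in cells)
        return tuple(float(x) for x in cells)


def case_allele_frequency(maf: float, true_or: float) -> float:
    """Case minor-allele frequency implied by an allelic odds ratio."""
    if not (0.0 < maf < 1.0):
        raise ValueError(f"maf must lie in (0, 1), got {maf}")
    if true_or <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {true_or}")
    odds = true_or * maf / (1.0 - maf)
    return odds / (1.0 + odds)


def simulate_study(
    maf: float,
    true_or: float,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
) -> TwoByTwoTable:
    """Draw one case-control study's allele-count table."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("subject counts must be positive")
    f_case = case_allele_frequency(maf, true_or)
    case_minor = int(rng.binomial(2 * n_cases, f_case))
    control_minor = int(rng.binomial(2 * n_controls, maf))
    return TwoByTwoTable(
        case_minor=case_minor,
        case_major=2 * n_cases - case_minor,
        control_minor=control_minor,
        control_major=2 * n_controls - control_minor,
    )


def pool_fixed_effect(
    studies: Sequence[TwoByTwoTable],
    *,
    author: str = "synthetic",
    year: int = 2020,
    gene: str = "GENE",
    variant: str = "rs0",
    comparison: str = "minor vs. major",
    study_type: str = "gwas",
    maf: float | None = None,
    ci_level: float = 0.95,
) -> MetaAnalysisRecord:
    """Inverse-variance fixed-effect pooling of per-study log odds ratios.

    Pooled ln OR is the precision-weighted mean with weights ``1/SE_i^2``;
    the pooled SE is ``(sum of weights)**-0.5``.  Returns a fully populated
    association record whose CI and two-sided P come from the pooled
    normal approximation.
    """
    if not studies:
        raise ValueError("at least one study is required for pooling")
    weights = np.array([1.0 / t.se_log_or ** 2 for t in studies])
    thetas = np.array([t.log_or for t in studies])
    pooled_theta = float(np.sum(weights * thetas) / np.sum(weights))
    pooled_se = float(np.sum(weights) ** -0.5)
    z = cred_stats.normal_quantile(0.5 + ci_level / 2.0)
    effect = cred_stats.z_and_p(math.exp(pooled_theta), pooled_se)
    n_cases = sum((t.case_minor + t.case_major) // 2 for t in studies)
    n_controls = sum((t.control_minor + t.control_major) // 2 for t in studies)
    return MetaAnalysisRecord(
        author=author, year=year, gene=gene, variant=variant,
        comparison=comparison,
        odds_ratio=math.exp(pooled_theta),
        ci_lower=math.exp(pooled_theta - z * pooled_se),
        ci_upper=math.exp(pooled_theta + z * pooled_se),
        ci_level=ci_level,
        p_value=min(effect.p_two_sided, 1.0) if effect.p_two_sided > 0 else None,
        study_type=study_type,
        n_cases=n_cases, n_controls=n_controls, n_studies=len(studies),
        maf=maf,
    )


def _as_range(value) -> tuple[int, int]:
    if isinstance(value, int):
        return (value, value)
    lo, hi = value
    return (int(lo), int(hi))


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for a synthetic meta-analysis catalogue.

    ``fraction_true`` of the variants carry the spec's true odds ratio
    (fixed, or log-normal on the OR scale when ``true_or_sigma`` > 0); the
    remainder are null (OR = 1).  Ranges are inclusive.
    """

    n_variants: int = 100
    fraction_true: float = 0.1
    true_or: float = 1.5
    true_or_sigma: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    studies_per_variant: int | tuple[int, int] = 5
    cases_per_study: int | tuple[int, int] = 2000
    controls_per_study: int | tuple[int, int] = 2000
    study_type_label: str = "gwas"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ValueError("n_variants must be positive")
        if not (0.0 <= self.fraction_true <= 1.0):
            raise ValueError("fraction_true must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie within (0, 1)")
        for name in ("studies_per_variant", "cases_per_study",
                     "controls_per_study"):
            lo, hi = _as_range(getattr(self, name))
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}")


class SimulatedCatalog(NamedTuple):
    """A pooled catalogue plus the per-variant generative truth."""

    catalog: RecordCatalog
    truth: dict  # variant label -> {"true_or": float, "is_null": bool, "maf": float}


def simulate_catalog(spec: SimulationSpec) -> SimulatedCatalog:
    """Generate a catalogue of pooled records, reproducible from the seed.

    The first ``round(fraction_true * n_variants)`` variants are
    associated; the rest are null.  Truth labels are returned alongside
    the catalogue for operating-characteristic evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    n_true = round(spec.fraction_true * spec.n_variants)
    records = []
    truth: dict[str, dict] = {}
    for i in range(spec.n_variants):
        is_null = i >= n_true
        if is_null:
            true_or = 1.0
        elif spec.true_or_sigma > 0.0:
            true_or = float(np.exp(rng.normal(math.log(spec.true_or),
                                              spec.true_or_sigma)))
        else:
            true_or = spec.true_or
        maf_lo, maf_hi = spec.maf_range
        maf = float(rng.uniform(maf_lo, maf_hi))
        k_lo, k_hi = _as_range(spec.studies_per_variant)
        n_studies = int(rng.integers(k_lo, k_hi + 1))
        studies = []
        for _ in range(n_studies):
            nc_lo, nc_hi = _as_range(spec.cases_per_study)
            nn_lo, nn_hi = _as_range(spec.controls_per_study)
            n_cases = int(rng.integers(nc_lo, nc_hi + 1))
            n_controls = int(rng.integers(nn_lo, nn_hi + 1))
            studies.append(simulate_study(maf, true_or, n_cases, n_controls, rng))
        variant = f"rs{1000000 + i}"
        records.append(pool_fixed_effect(
            studies, gene=f"GENE{i}", variant=variant,
            study_type=spec.study_type_label, maf=maf,
        ))
        truth[variant] = {"true_or": true_or, "is_null": is_null, "maf": maf}
    catalog = RecordCatalog(records=tuple(records),
                            provenance=f"simulated(seed={spec.seed})")
    return SimulatedCatalog(catalog=catalog, truth=truth)
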