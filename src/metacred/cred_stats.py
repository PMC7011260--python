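"""Core credibility statistics for pooled genetic-association estimates.

Given a pooled odds ratio and its confidence interval, this module
reconstructs the standard error of the log odds ratio, the Wald Z statistic
and a two-sided P value, and evaluates two post-hoc credibility measures
over a grid of prior probabilities:

* **FPRP** (false-positive report probability): the probability that a
  statistically significant association is a false positive, given a prior
  probability ``pi`` of a true association, the observed P value and the
  statistical power to detect an odds ratio of a specified size::

      FPRP = p * (1 - pi) / (p * (1 - pi) + power * pi)

* **BFDP** (Bayesian false discovery probability): the posterior
  probability of the null hypothesis computed from an approximate Bayes
  factor under normal approximations, with data variance ``V = se**2`` and
  prior variance ``W`` chosen so that the 97.5th percentile of the prior on
  the odds ratio under the alternative equals ``prior_or_bound``::

      ABF  = sqrt((V + W) / V) * exp(-z**2 * W / (2 * (V + W)))
      BFDP = ABF * PO / (ABF * PO + 1),   PO = (1 - pi) / pi

Everything is evaluated in log space so that associations with |Z| of 50 or
more (GWAS-scale evidence) yield finite, correctly ordered probabilities
instead of underflowing to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import log_expit

__all__ = [
    "EffectSummary",
    "BfdpValue",
    "CredibilityConfig",
    "CredibilityProfile",
    "OBS_PRIORS",
    "GWAS_PRIORS",
    "DETECTION_ORS",
    "se_from_ci",
    "z_and_p",
    "power_to_detect",
    "fprp",
    "bfdp",
    "evaluate_profile",
]

#: Medium/low prior-probability levels used for candidate-gene SNPs.
OBS_PRIORS: tuple[float, float] = (0.05, 0.001)
#: Medium/low prior-probability levels used for GWAS SNPs.
GWAS_PRIORS: tuple[float, float] = (0.001, 1e-6)
#: Odds ratios at which statistical power is evaluated inside the FPRP.
DETECTION_ORS: tuple[float, float] = (1.2, 1.5)


def normal_quantile(q: float) -> float:
    """Standard-normal quantile (inverse CDF)."""
    return float(stats.norm.ppf(q))


def se_from_ci(or_: float, lower: float, upper: float, level: float = 0.95) -> float:
    """Standard error of ln(OR) reconstructed from a symmetric Wald CI.

    ``se = (ln upper - ln lower) / (2 * z)`` with ``z`` the two-sided
    normal quantile for the interval's confidence ``level``.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"ci level must lie in (0, 1), got {level}")
    if or_ <= 0.0 or lower <= 0.0 or upper <= 0.0:
        raise ValueError("odds ratio and CI bounds must all be positive")
    if lower >= upper:
        raise ValueError(f"ci_lower ({lower}) must be below ci_upper ({upper})")
    z = normal_quantile(0.5 + level / 2.0)
    return (math.log(upper) - math.log(lower)) / (2.0 * z)


@dataclass(frozen=True)
class EffectSummary:
    """Log odds ratio, its standard error, Wald Z and two-sided P.

    ``log_p`` is the natural log of the two-sided P value; it stays finite
    for |Z| far beyond the point where ``p_two_sided`` underflows.
    """

    log_or: float
    se: float
    z: float
    p_two_sided: float
    log_p: float

    @property
    def log10_p(self) -> float:
        return self.log_p / math.log(10.0)


def z_and_p(or_: float, se: float) -> EffectSummary:
    """Wald Z and two-sided P for a pooled odds ratio.

    The P value is computed through the log of the normal survival
    function, so ``log_p`` is exact even when ``p_two_sided`` underflows.
    """
    if se <= 0.0:
        raise ValueError(f"se must be positive, got {se}")
    if or_ <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {or_}")
    log_or = math.log(or_)
    z = log_or / se
    log_p = math.log(2.0) + float(stats.norm.logsf(abs(z)))
    # p = 1 exactly at z = 0 (logsf(0) = log(1/2)).
    return EffectSummary(log_or=log_or, se=se, z=z,
                         p_two_sided=math.exp(log_p), log_p=log_p)


def power_to_detect(
    detection_or: float,
    se: float,
    *,
    alpha_mode: str = "observed_p",
    alpha: float = 0.05,
    observed_z: float | None = None,
) -> float:
    """Power to detect an odds ratio of ``detection_or`` at the given SE.

    With ``theta1 = ln(detection_or)`` and critical value ``c`` the power is
    ``Phi(theta1/se - c) + Phi(-theta1/se - c)``.  ``c`` is the fixed-level
    two-sided critical value ``z_{1-alpha/2}`` when ``alpha_mode='fixed'``,
    or the observed |Z| when ``alpha_mode='observed_p'`` (the convention of
    the original FPRP proposal, where significance is assessed at the
    observed P value itself).
    """
    if se <= 0.0:
        raise ValueError(f"se must be positive, got {se}")
    if detection_or <= 1.0:
        raise ValueError(f"detection odds ratio must exceed 1, got {detection_or}")
    if alpha_mode == "fixed":
        if not (0.0 < alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        c = normal_quantile(1.0 - alpha / 2.0)
    elif alpha_mode == "observed_p":
        if observed_z is None:
            raise ValueError("observed_z is required when alpha_mode='observed_p'")
        c = abs(observed_z)
    else:
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    theta1 = math.log(detection_or)
    shift = theta1 / se
    return float(stats.norm.cdf(shift - c) + stats.norm.cdf(-shift - c))


def fprp(
    p_value: float,
    power: float,
    prior: float,
    *,
    log_p: float | None = None,
) -> float | None:
    """False-positive report probability, evaluated in log space.

    Returns ``p(1-pi) / (p(1-pi) + power*pi)``.  Pass ``log_p`` (natural
    log of the P value) to keep the ratio defined when ``p_value``
    underflows to zero.  The degenerate case where both the P value and the
    power are exactly zero has no defined value and returns ``None`` —
    mirroring spreadsheet implementations that fail on the normal-quantile
    inversion for extreme inputs rather than report a number.
    """
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must lie in (0, 1), got {prior}")
    if not (0.0 <= power <= 1.0):
        raise ValueError(f"power must lie in [0, 1], got {power}")
    if p_value < 0.0 or p_value > 1.0:
        raise ValueError(f"p_value must lie in [0, 1], got {p_value}")
    lp = log_p if log_p is not None else (
        math.log(p_value) if p_value > 0.0 else -math.inf)
    if power == 0.0 and lp == -math.inf:
        return None
    if power == 0.0:
        return 1.0
    log_num = lp + math.log1p(-prior)
    log_den = np.logaddexp(log_num, math.log(power) + math.log(prior))
    return float(math.exp(log_num - log_den))


class BfdpValue(NamedTuple):
    """A BFDP together with its natural log (finite for extreme evidence)."""

    value: float
    log: float

    @property
    def log10(self) -> float:
        return self.log / math.log(10.0)


def bfdp(
    log_or: float,
    se: float,
    prior: float,
    prior_or_bound: float = 1.5,
) -> BfdpValue:
    """Bayesian false discovery probability via the approximate Bayes factor.

    The prior on the log odds ratio under the alternative is normal with
    mean zero and variance ``W`` such that its 97.5th percentile on the OR
    scale equals ``prior_or_bound``.  The logistic transform of
    ``log ABF + log prior-odds`` is taken through :func:`log_expit`, so the
    returned log stays finite for |Z| of 50 and beyond.
    """
    if se <= 0.0:
        raise ValueError(f"se must be positive, got {se}")
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must lie in (0, 1), got {prior}")
    if prior_or_bound <= 1.0:
        raise ValueError(f"prior_or_bound must exceed 1, got {prior_or_bound}")
    v = se * se
    w = (math.log(prior_or_bound) / normal_quantile(0.975)) ** 2
    z = log_or / se
    log_bf = 0.5 * math.log((v + w) / v) - z * z * w / (2.0 * (v + w))
    log_prior_odds = math.log1p(-prior) - math.log(prior)
    logit = log_bf + log_prior_odds
    log_value = float(log_expit(logit))
    return BfdpValue(value=math.exp(log_value), log=log_value)


@dataclass(frozen=True)
class CredibilityConfig:
    """Conventions and thresholds for a credibility evaluation.

    Parameters
    ----------
    priors
        Prior probabilities of a true association (default: the candidate
        SNP levels 0.05 / 0.001; GWAS evaluations use 0.001 / 1e-6).
    detection_ors
        Odds ratios at which power is evaluated inside the FPRP.
    fprp_threshold, bfdp_threshold
        Noteworthiness cut-offs: FPRP < 0.2, BFDP < 0.8.
    bfdp_prior_or_bound
        97.5th percentile of the prior on the OR under the alternative.
    fprp_alpha_mode
        'observed_p' evaluates power at the observed |Z| (the original FPRP
        convention); 'fixed' uses the two-sided critical value for
        ``fixed_alpha``.
    p_source
        'ci' reconstructs the observed P from the OR/CI (default);
        'printed' uses the record's published P value when available.
    """

    priors: tuple[float, ...] = OBS_PRIORS
    detection_ors: tuple[float, ...] = DETECTION_ORS
    fprp_threshold: float = 0.2
    bfdp_threshold: float = 0.8
    bfdp_prior_or_bound: float = 1.5
    fprp_alpha_mode: str = "observed_p"
    fixed_alpha: float = 0.05
    p_source: str = "ci"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not self.priors:
            raise ValueError("at least one prior is required")
        for pi in self.priors:
            if not (0.0 < pi < 1.0):
                raise ValueError(f"priors must lie in (0, 1), got {pi}")
        for or1 in self.detection_ors:
            if or1 <= 1.0:
                raise ValueError(f"detection ORs must exceed 1, got {or1}")
        for name in ("fprp_threshold", "bfdp_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.bfdp_prior_or_bound <= 1.0:
            raise ValueError("bfdp_prior_or_bound must exceed 1")
        if self.fprp_alpha_mode not in ("observed_p", "fixed"):
            raise ValueError(f"unknown fprp_alpha_mode {self.fprp_alpha_mode!r}")
        if self.p_source not in ("ci", "printed"):
            raise ValueError(f"unknown p_source {self.p_source!r}")

    @classmethod
    def for_study_type(cls, study_type: str, **overrides) -> "CredibilityConfig":
        """Default configuration with priors chosen per study type."""
        priors = GWAS_PRIORS if study_type == "gwas" else OBS_PRIORS
        overrides.setdefault("priors", priors)
        return cls(**overrides)


@dataclass(frozen=True)
class CredibilityProfile:
    """Full FPRP/BFDP evaluation of one association record.

    ``fprp`` maps ``(prior, detection_or)`` to a probability (or ``None``
    when undefined); ``bfdp`` maps each prior to a :class:`BfdpValue`;
    ``power`` maps each detection OR to the power used in the FPRP.
    """

    record: object
    effect: EffectSummary
    power: Mapping[float, float]
    fprp: Mapping[tuple[float, float], float | None]
    bfdp: Mapping[float, BfdpValue]
    config: CredibilityConfig
    p_used: float = field(default=math.nan)

    def noteworthy_fprp(self, prior: float, detection_or: float) -> bool:
        """FPRP below threshold at the grid point; undefined is never noteworthy."""
        value = self.fprp[(prior, detection_or)]
        return value is not None and value < self.config.fprp_threshold

    def noteworthy_bfdp(self, prior: float) -> bool:
        return self.bfdp[prior].value < self.config.bfdp_threshold

    def noteworthy_any(self, prior: float, detection_or: float | None = None) -> bool:
        """Noteworthy by FPRP (any detection OR, or the one given) or by BFDP."""
        ors = self.config.detection_ors if detection_or is None else (detection_or,)
        if any(self.noteworthy_fprp(prior, or1) for or1 in ors):
            return True
        return self.noteworthy_bfdp(prior)


def evaluate_profile(record, config: CredibilityConfig) -> CredibilityProfile:
    """Evaluate the FPRP grid, BFDP values and power for one record.

    Protective odds ratios (OR < 1) are handled through |Z|, which is
    equivalent to inverting the OR and mirroring its CI bounds, so the
    profile is symmetric under OR <-> 1/OR.
    """
    se = se_from_ci(record.odds_ratio, record.ci_lower, record.ci_upper,
                    getattr(record, "ci_level", config.ci_level))
    effect = z_and_p(record.odds_ratio, se)
    abs_z = abs(effect.z)

    printed_p = getattr(record, "p_value", None)
    if config.p_source == "printed" and printed_p is not None:
        p_used = float(printed_p)
        log_p_used = math.log(p_used)
        # Critical value consistent with the P value actually plugged in.
        z_for_power = float(stats.norm.isf(p_used / 2.0))
    else:
        p_used = effect.p_two_sided
        log_p_used = effect.log_p
        z_for_power = abs_z

    power = {
        or1: power_to_detect(
            or1, se,
            alpha_mode=config.fprp_alpha_mode,
            alpha=config.fixed_alpha,
            observed_z=z_for_power,
        )
        for or1 in config.detection_ors
    }
    fprp_grid = {
        (pi, or1): fprp(p_used, power[or1], pi, log_p=log_p_used)
        for pi in config.priors
        for or1 in config.detection_ors
    }
    bfdp_values = {
        pi: bfdp(abs(effect.log_or), se, pi, config.bfdp_prior_or_bound)
        for pi in config.priors
    }
    return CredibilityProfile(
        record=record, effect=effect, power=power,
        fprp=fprp_grid, bfdp=bfdp_values, config=config, p_used=p_used,
    )
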