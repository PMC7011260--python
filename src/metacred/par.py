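"""Population attributable risk from allele frequency and odds ratio.

The per-variant PAR uses Levin's allele-frequency form

    PAR = f (OR - 1) / (f (OR - 1) + 1)

with ``f`` the minor allele frequency.  For protective alleles (OR < 1)
the signed value is negative; published attributable-risk tables print the
magnitude, so :func:`single_par` returns ``|PAR|`` and the signed value
remains available through :func:`single_par_signed`.

The joint contribution of a set of (assumed independent) variants is
combined multiplicatively through the complements.  The conventional joint
PAR is ``1 - prod(1 - PAR_i)``; published synopses have also reported the
bare complement product ``prod(1 - PAR_i)`` under the "joint PAR" label,
so :func:`joint_par` returns both and downstream reports label the
complement product as "as-published".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from . import assoc_io

__all__ = [
    "single_par",
    "single_par_signed",
    "joint_par",
    "ParResult",
    "par_table",
    "ParSelection",
    "select_par_set",
]


def single_par_signed(maf: float, or_: float) -> float:
    """Signed Levin attributable risk; negative for protective alleles."""
    if not (0.0 < maf < 1.0):
        raise ValueError(f"maf must lie in (0, 1), got {maf}")
    if or_ <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {or_}")
    excess = maf * (or_ - 1.0)
    denom = excess + 1.0
    if denom <= 0.0:
        raise ValueError(
            f"degenerate attributable-risk denominator for maf={maf}, OR={or_}")
    return excess / denom


def single_par(maf: float, or_: float) -> float:
    """Magnitude of the attributable risk, ``|f(OR-1)| / (f(OR-1) + 1)``."""
    return abs(single_par_signed(maf, or_))


class JointPar(NamedTuple):
    """Both joint-combination conventions over a set of per-variant PARs."""

    complement_product: float    # prod(1 - PAR_i): the "as-published" form
    one_minus_product: float     # 1 - prod(1 - PAR_i): conventional joint PAR
    n_snps: int


def joint_par(pars: Sequence[float]) -> JointPar:
    """Combine per-variant PARs multiplicatively through their complements."""
    pars = list(pars)
    if not pars:
        raise ValueError("joint PAR requires at least one per-variant PAR")
    for p in pars:
        if not (0.0 <= p < 1.0):
            raise ValueError(f"each PAR must lie in [0, 1), got {p}")
    product = math.prod(1.0 - p for p in pars)
    return JointPar(complement_product=product,
                    one_minus_product=1.0 - product,
                    n_snps=len(pars))


@dataclass(frozen=True)
class ParResult:
    """Per-variant attributable risks and their joint combination.

    ``per_snp`` maps each variant label to a dict with keys ``maf``,
    ``or``, ``par`` (magnitude, fraction in [0,1)) and ``par_signed``.
    """

    per_snp: Mapping[str, Mapping[str, float]]
    joint_complement_product: float
    joint_one_minus_product: float
    n_snps: int

    def __post_init__(self) -> None:
        assert abs(self.joint_one_minus_product
                   - (1.0 - self.joint_complement_product)) < 1e-15


def par_table(records: Iterable) -> ParResult:
    """Per-variant and joint PAR over records carrying a MAF.

    Records without a MAF raise ``ValueError`` — use
    :func:`select_par_set` first to partition them out.
    """
    per_snp: dict[str, dict[str, float]] = {}
    pars: list[float] = []
    for rec in records:
        if rec.maf is None:
            raise ValueError(f"record {rec.variant} has no MAF")
        signed = single_par_signed(rec.maf, rec.odds_ratio)
        par = abs(signed)
        label = f"{rec.gene}/{rec.variant}"
        per_snp[label] = {"maf": rec.maf, "or": rec.odds_ratio,
                          "par": par, "par_signed": signed}
        pars.append(par)
    joint = joint_par(pars)
    return ParResult(per_snp=per_snp,
                     joint_complement_product=joint.complement_product,
                     joint_one_minus_product=joint.one_minus_product,
                     n_snps=joint.n_snps)


class ParSelection(NamedTuple):
    """Noteworthy variants selected for the joint-PAR combination."""

    variants: list[tuple[str, str]]      # all noteworthy (gene, variant) keys
    records: list                        # one record per variant, with MAF
    missing_maf: list[tuple[str, str]]   # noteworthy but unusable (no MAF)


def select_par_set(
    profiles: Iterable,
    prior: float,
    detection_or: float = 1.5,
    fprp_threshold: float = 0.2,
    bfdp_threshold: float = 0.8,
    *,
    source: str = "recomputed",
) -> ParSelection:
    """Select the noteworthy variant set for a joint-PAR combination.

    A variant qualifies when any of its genetic-model rows has
    ``FPRP(prior, detection_or) < fprp_threshold`` or
    ``BFDP(prior) < bfdp_threshold``.  With ``source='recomputed'`` the
    thresholds apply to the profiles' own statistics; with
    ``source='printed'`` they apply to the published cells carried in each
    record's ``printed_stats`` (an absent cell — printed "–" — is never
    noteworthy).  One record per variant is kept (the first qualifying
    row); variants whose records carry no MAF are reported separately.
    """
    if source not in ("recomputed", "printed"):
        raise ValueError(f"unknown source {source!r}")
    fkey = assoc_io.fprp_key(detection_or, prior)
    bkey = assoc_io.bfdp_key(prior)

    chosen: dict[tuple[str, str], object] = {}
    for prof in profiles:
        rec = prof.record
        if source == "recomputed":
            hit = (prof.noteworthy_fprp(prior, detection_or)
                   or prof.noteworthy_bfdp(prior))
        else:
            stats = rec.printed_stats
            hit = (stats.get(fkey, math.inf) < fprp_threshold
                   or stats.get(bkey, math.inf) < bfdp_threshold)
        if hit and rec.variant_key not in chosen:
            chosen[rec.variant_key] = rec

    with_maf = [rec for rec in chosen.values() if rec.maf is not None]
    missing = [key for key, rec in chosen.items() if rec.maf is None]
    return ParSelection(variants=list(chosen), records=with_maf,
                        missing_maf=missing)
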