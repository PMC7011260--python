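"""Association-record data model, TSV readers/writers and bundled fixtures.

One :class:`MetaAnalysisRecord` holds a single pooled association result —
a variant, the allele or genotype comparison, the pooled odds ratio with
its confidence interval and P value, and study metadata.  Catalogues of
records are read from delimited text with a mandatory header row; cells
printed as "–", "" or "NA" become absent values.  Any column that is not a
core field is retained verbatim in ``printed_stats`` so that published
FPRP/BFDP/PAR cells travel with the record they belong to.

Six transcriptions of published summary tables ship with the package as
TSV resources (``table1`` … ``table6``): the significant observational and
GWAS association tables, their subtype and ethnicity subgroup tables, and
the attributable-risk table with minor allele frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from . import cred_stats

__all__ = [
    "MetaAnalysisRecord",
    "RecordCatalog",
    "InputSchemaError",
    "RecordValidationError",
    "FIXTURE_NAMES",
    "read_catalog",
    "write_catalog",
    "load_fixture",
    "deduplicate",
    "filter_significant",
    "fprp_key",
    "bfdp_key",
]

STUDY_TYPES = ("observational", "gwas")
SUBTYPES = ("overall", "MA", "MO")
FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "table5", "table6")

#: Tokens that mark an absent cell in delimited input.
MISSING_TOKENS = frozenset({"", "-", "–", "—", "na", "n/a", "nan", "none"})

OBS_ALPHA_DEFAULT = 0.05
GWAS_ALPHA_DEFAULT = 5e-8


class InputSchemaError(ValueError):
    """A mandatory column is missing or the header cannot be interpreted."""


class RecordValidationError(ValueError):
    """A row violates a record invariant; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)


def fprp_key(detection_or: float, prior: float) -> str:
    """Canonical printed-stats key for an FPRP cell, e.g. ``fprp_1.2_1e-06``."""
    return f"fprp_{detection_or:g}_{prior:g}"


def bfdp_key(prior: float) -> str:
    """Canonical printed-stats key for a BFDP cell, e.g. ``bfdp_0.001``."""
    return f"bfdp_{prior:g}"


@dataclass(frozen=True)
class MetaAnalysisRecord:
    """One pooled association result from a meta-analysis.

    ``printed_stats`` maps a column label (e.g. ``fprp_1.5_0.05``,
    ``bfdp_0.001``, ``par_percent``) to the value printed in the source
    table; a label absent from the mapping marks a cell that was printed as
    "–" (not computable) or not printed at all.
    """

    author: str
    year: int
    gene: str
    variant: str
    comparison: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    study_type: str
    ethnicity: str = "Overall"
    subtype: str = "overall"
    n_cases: int = 0
    n_controls: int = 0
    ci_level: float = 0.95
    p_value: float | None = None
    n_studies: int | None = None
    maf: float | None = None
    venice_grades: str | None = None
    venice_credibility: str | None = None
    printed_stats: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0 or self.ci_lower <= 0 or self.ci_upper <= 0:
            raise RecordValidationError(
                f"{self.variant}: OR and CI bounds must be positive "
                f"(got OR={self.odds_ratio}, CI {self.ci_lower}-{self.ci_upper})")
        if not (self.ci_lower < self.odds_ratio < self.ci_upper):
            raise RecordValidationError(
                f"{self.variant}: point estimate {self.odds_ratio} must lie "
                f"inside its CI ({self.ci_lower}-{self.ci_upper})")
        if not (0.0 < self.ci_level < 1.0):
            raise RecordValidationError(
                f"{self.variant}: ci_level must lie in (0, 1), got {self.ci_level}")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise RecordValidationError(
                f"{self.variant}: p_value must lie in (0, 1], got {self.p_value}")
        if self.maf is not None and not (0.0 < self.maf < 1.0):
            raise RecordValidationError(
                f"{self.variant}: maf must lie in (0, 1), got {self.maf}")
        if self.study_type not in STUDY_TYPES:
            raise RecordValidationError(
                f"{self.variant}: study_type must be one of {STUDY_TYPES}, "
                f"got {self.study_type!r}")
        if self.subtype not in SUBTYPES:
            raise RecordValidationError(
                f"{self.variant}: subtype must be one of {SUBTYPES}, "
                f"got {self.subtype!r}")
        if self.n_cases < 0 or self.n_controls < 0:
            raise RecordValidationError(
                f"{self.variant}: case/control counts must be non-negative")
        object.__setattr__(self, "printed_stats", dict(self.printed_stats))

    # -- derived views -------------------------------------------------

    @property
    def dedup_key(self) -> tuple[str, str, str, str, str]:
        return (self.variant, self.comparison, self.study_type,
                self.subtype, self.ethnicity)

    @property
    def variant_key(self) -> tuple[str, str]:
        """Identity of the genetic variant across genetic-model rows."""
        return (self.gene, self.variant)

    @property
    def sample_size(self) -> int:
        return self.n_cases + self.n_controls

    def ci_excludes_null(self, *, boundary_excludes: bool = True) -> bool:
        """Whether the printed CI excludes OR = 1.

        Printed bounds are rounded; with ``boundary_excludes`` (default) a
        bound printed exactly as 1 counts as excluding the null, matching
        how published significance tables treat e.g. "1.03 (1.00–1.06)".
        """
        if boundary_excludes:
            return self.ci_lower >= 1.0 or self.ci_upper <= 1.0
        return self.ci_lower > 1.0 or self.ci_upper < 1.0

    def effective_p(self) -> float:
        """Published P value, or one reconstructed from the OR/CI."""
        if self.p_value is not None:
            return self.p_value
        se = cred_stats.se_from_ci(self.odds_ratio, self.ci_lower,
                                   self.ci_upper, self.ci_level)
        return cred_stats.z_and_p(self.odds_ratio, se).p_two_sided


@dataclass(frozen=True)
class RecordCatalog:
    """An ordered collection of association records with provenance."""

    records: tuple[MetaAnalysisRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MetaAnalysisRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def variants(self) -> list[tuple[str, str]]:
        """Unique (gene, variant) keys in first-seen order."""
        seen: dict[tuple[str, str], None] = {}
        for rec in self.records:
            seen.setdefault(rec.variant_key)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_record_to_row(r) for r in self.records])


# -- delimited text I/O ------------------------------------------------

_CORE_FIELDS = [f.name for f in fields(MetaAnalysisRecord)
                if f.name != "printed_stats"]

_ALIASES = {
    "or": "odds_ratio",
    "odds ratio": "odds_ratio",
    "lower": "ci_lower",
    "upper": "ci_upper",
    "p": "p_value",
    "pvalue": "p_value",
    "p-value": "p_value",
    "cases": "n_cases",
    "controls": "n_controls",
    "studies": "n_studies",
    "venice": "venice_grades",
    "credibility": "venice_credibility",
}

_MANDATORY = ("author", "year", "gene", "variant", "comparison",
              "odds_ratio", "ci_lower", "ci_upper", "study_type")

_INT_FIELDS = {"year", "n_cases", "n_controls", "n_studies"}
_FLOAT_FIELDS = {"odds_ratio", "ci_lower", "ci_upper", "ci_level",
                 "p_value", "maf"}


def _clean(cell) -> str | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.lower() in MISSING_TOKENS:
        return None
    return text


def read_catalog(
    path: str | Path,
    *,
    sep: str = "\t",
    aliases: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> RecordCatalog:
    """Read a delimited association table into a :class:`RecordCatalog`.

    Header names are matched case-insensitively against the record fields
    (with a configurable alias map); unknown columns become entries in
    ``printed_stats``.  Scientific-notation P values such as ``5.6E-49``
    parse as floats.  Raises :class:`InputSchemaError` for a missing
    mandatory column and :class:`RecordValidationError` (with the 0-based
    data row index) for an unparseable or invariant-violating row.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    alias_map = {**_ALIASES, **{k.lower(): v for k, v in (aliases or {}).items()}}

    colmap: dict[str, str] = {}   # original header -> canonical field or stat label
    for col in frame.columns:
        key = col.strip().lower()
        canon = alias_map.get(key, key)
        colmap[col] = canon if canon in _CORE_FIELDS else col.strip()

    present = set(colmap.values())
    for name in _MANDATORY:
        if name not in present:
            raise InputSchemaError(
                f"{path.name}: missing mandatory column {name!r}")

    records: list[MetaAnalysisRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        kwargs: dict = {}
        stats_map: dict[str, float] = {}
        for col, value in zip(frame.columns, row):
            target = colmap[col]
            cell = _clean(value)
            if target in _CORE_FIELDS:
                if cell is None:
                    continue
                try:
                    if target in _INT_FIELDS:
                        kwargs[target] = int(float(cell.replace(",", "")))
                    elif target in _FLOAT_FIELDS:
                        kwargs[target] = float(cell)
                    else:
                        kwargs[target] = cell
                except ValueError as exc:
                    raise RecordValidationError(
                        f"cannot parse {target}={cell!r}", row=idx) from exc
            else:
                if cell is None:
                    continue
                try:
                    stats_map[target] = float(cell)
                except ValueError as exc:
                    raise RecordValidationError(
                        f"cannot parse printed stat {target}={cell!r}",
                        row=idx) from exc
        try:
            records.append(MetaAnalysisRecord(printed_stats=stats_map, **kwargs))
        except RecordValidationError as exc:
            raise RecordValidationError(str(exc), row=idx) from None
        except TypeError as exc:
            raise RecordValidationError(f"incomplete row: {exc}", row=idx) from None
    return RecordCatalog(records=tuple(records),
                         provenance=provenance or str(path))


def _format(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _record_to_row(rec: MetaAnalysisRecord) -> dict:
    row = {name: getattr(rec, name) for name in _CORE_FIELDS}
    row.update(rec.printed_stats)
    return row


def write_catalog(catalog: RecordCatalog, path: str | Path, *, sep: str = "\t") -> Path:
    """Write a catalog as delimited text; floats round-trip bit-identically."""
    path = Path(path)
    stat_cols: dict[str, None] = {}
    for rec in catalog:
        for key in rec.printed_stats:
            stat_cols.setdefault(key)
    columns = _CORE_FIELDS + list(stat_cols)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(columns) + "\n")
        for rec in catalog:
            row = _record_to_row(rec)
            fh.write(sep.join(_format(row.get(col)) for col in columns) + "\n")
    return path


def load_fixture(name: str) -> RecordCatalog:
    """Load one of the bundled published-table transcriptions.

    ``table1``/``table2`` are the significant observational and GWAS
    association tables with their printed FPRP/BFDP columns; ``table3``–
    ``table5`` are the subtype and ethnicity subgroup tables; ``table6``
    is the attributable-risk table with MAF and printed PAR columns.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    ref = resources.files(__package__).joinpath(f"fixtures/{name}.tsv")
    with resources.as_file(ref) as path:
        return read_catalog(path, provenance=f"fixture:{name}")


# -- deduplication and significance filtering --------------------------

def deduplicate(catalog: RecordCatalog) -> RecordCatalog:
    """Keep one record per (variant, comparison, study type, subtype, ethnicity).

    When several meta-analyses report the same comparison, the most recent
    one wins; ties on year are broken by the larger total sample size, and
    remaining ties keep the first-seen record with a warning.
    """
    best: dict[tuple, MetaAnalysisRecord] = {}
    order: list[tuple] = []
    for rec in catalog:
        key = rec.dedup_key
        if key not in best:
            best[key] = rec
            order.append(key)
            continue
        incumbent = best[key]
        if rec.year > incumbent.year:
            best[key] = rec
        elif rec.year == incumbent.year:
            if rec.sample_size > incumbent.sample_size:
                best[key] = rec
            elif rec.sample_size == incumbent.sample_size:
                warnings.warn(
                    f"duplicate records for {key} with identical year and "
                    f"sample size; keeping the first-seen record",
                    stacklevel=2)
    return RecordCatalog(records=tuple(best[k] for k in order),
                         provenance=catalog.provenance)


def filter_significant(
    catalog: RecordCatalog,
    obs_alpha: float = OBS_ALPHA_DEFAULT,
    gwas_alpha: float = GWAS_ALPHA_DEFAULT,
    *,
    boundary_excludes: bool = True,
) -> RecordCatalog:
    """Retain records that are statistically significant for their study type.

    A record is kept when its P value (published, or reconstructed from the
    OR/CI when absent) is strictly below the threshold for its study type
    — ``obs_alpha`` for observational meta-analyses, ``gwas_alpha`` for
    GWAS — AND its confidence interval excludes the null.
    """
    for name, alpha in (("obs_alpha", obs_alpha), ("gwas_alpha", gwas_alpha)):
        if not (0.0 < alpha < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {alpha}")
    kept = []
    for rec in catalog:
        alpha = gwas_alpha if rec.study_type == "gwas" else obs_alpha
        if not rec.ci_excludes_null(boundary_excludes=boundary_excludes):
            continue
        if rec.effective_p() < alpha:
            kept.append(rec)
    return RecordCatalog(records=tuple(kept), provenance=catalog.provenance)
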