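"""Venice-criteria grading of cumulative epidemiological evidence.

Cumulative evidence for a genetic association is graded A (strong),
B (moderate) or C (weak) on three parameters — amount of evidence,
replication of the association, and protection from bias — and the grade
triplet maps to a credibility level: all A is high credibility, a mix of A
and B is intermediate, and one or more C grades is low.  Bias cannot be
graded mechanically from summary rows and is always supplied editorially.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "GRADES",
    "CREDIBILITY_LEVELS",
    "VeniceAssessment",
    "parse_grade_string",
    "grade_amount",
    "grade_replication",
    "combine_grades",
    "assess_record",
]

GRADES = ("A", "B", "C", "NA")
CREDIBILITY_LEVELS = ("high", "intermediate", "low", "NA")

_GRADE_SPLIT = re.compile(r"\+")


def parse_grade_string(text: str) -> tuple[str, str, str]:
    """Parse a grade triplet such as ``"A + C + C"`` (whitespace-tolerant).

    Returns the grades in order (amount, replication, bias).  Raises
    ``ValueError`` naming the offending token for malformed input.
    """
    tokens = [tok.strip() for tok in _GRADE_SPLIT.split(text)]
    if len(tokens) != 3:
        raise ValueError(
            f"expected three '+'-separated grades, got {text!r}")
    for tok in tokens:
        if tok.upper() not in GRADES:
            raise ValueError(f"unknown grade token {tok!r} in {text!r}")
    a, r, b = (tok.upper() for tok in tokens)
    return a, r, b


def grade_amount(n_minor_group: int, thresholds: tuple[int, int] = (1000, 100)) -> str:
    """Grade the amount of evidence from the minor-group subject count.

    With default thresholds ``(1000, 100)``: A above 1000, B between 100
    and 1000 inclusive, C below 100.
    """
    if n_minor_group < 0:
        raise ValueError("count must be non-negative")
    upper, lower = max(thresholds), min(thresholds)
    if n_minor_group > upper:
        return "A"
    if n_minor_group >= lower:
        return "B"
    return "C"


def grade_replication(i_squared: float | None,
                      thresholds: tuple[float, float] = (25.0, 50.0)) -> str:
    """Grade replication from the heterogeneity statistic I² (percent).

    With default thresholds ``(25, 50)``: A below 25, B from 25 to 50
    inclusive, C above 50.  A missing I² yields the NA grade.
    """
    if i_squared is None:
        return "NA"
    if not (0.0 <= i_squared <= 100.0):
        raise ValueError(f"I-squared must lie in [0, 100], got {i_squared}")
    lower, upper = min(thresholds), max(thresholds)
    if i_squared < lower:
        return "A"
    if i_squared <= upper:
        return "B"
    return "C"


def combine_grades(amount: str, replication: str, bias: str) -> str:
    """Map a grade triplet to a credibility level.

    All three A -> ``high``; any C -> ``low`` (a weak grade is decisive
    even when another grade is missing); any NA without a C -> ``NA``;
    otherwise (A/B mix) -> ``intermediate``.  Order-insensitive.
    """
    grades = [amount.upper(), replication.upper(), bias.upper()]
    for g in grades:
        if g not in GRADES:
            raise ValueError(f"unknown grade {g!r}")
    if "C" in grades:
        return "low"
    if "NA" in grades:
        return "NA"
    if all(g == "A" for g in grades):
        return "high"
    return "intermediate"


@dataclass(frozen=True)
class VeniceAssessment:
    """A/B/C grades for the three Venice parameters and their credibility."""

    amount_grade: str
    replication_grade: str
    bias_grade: str

    @property
    def credibility(self) -> str:
        return combine_grades(self.amount_grade, self.replication_grade,
                              self.bias_grade)


def assess_record(record) -> VeniceAssessment | None:
    """Build an assessment from a record's grade string, if it has one."""
    text = getattr(record, "venice_grades", None)
    if text is None:
        return None
    amount, replication, bias = parse_grade_string(text)
    return VeniceAssessment(amount, replication, bias)
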