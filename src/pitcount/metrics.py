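"""Sample-level pitted-RBC biomarkers and splenic-function calls.

%PIT — the percentage of counted RBCs bearing at least one pit — is the
surrogate biomarker of splenic filtration function; the morphometrics
(pits per pitted cell, maximum pits in one cell, mean pit size as a
percentage of the affected cell's area) describe how pitting presents.
The two published diagnostic rules are implemented exactly as printed:
Rogers (1970s): %PIT ≥ 3.5 → loss of splenic function; El Hoss (2018):
%PIT < 1.2 → normal, %PIT > 4.5 → absent, otherwise indeterminate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .postprocess import ObjectTable

__all__ = [
    "SampleResult",
    "DiagnosisRule",
    "SpleenStatus",
    "UndefinedPercentPitError",
    "pit_count_percent",
    "pit_morphometrics",
    "classify_splenic_function",
    "summarize_sample",
    "ROGERS_1970S",
    "EL_HOSS_2018",
    "DEFAULT_MIN_CELLS",
]

#: Minimum cells for a reliable manual-style count.
DEFAULT_MIN_CELLS = 500

ROGERS_LOSS_GE = 3.5
EL_HOSS_NORMAL_LT = 1.2
EL_HOSS_ABSENT_GT = 4.5


class SpleenStatus(str, enum.Enum):
    NORMAL = "normal"
    INDETERMINATE = "indeterminate"
    LOSS_OF_FUNCTION = "loss_of_function"
    ABSENT = "absent"


@dataclass(frozen=True)
class DiagnosisRule:
    """A named threshold rule mapping %PIT to a splenic-function status."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in ("rogers_1970s", "el_hoss_2018"):
            raise ValueError(f"unknown diagnosis rule {self.name!r}")


ROGERS_1970S = DiagnosisRule("rogers_1970s")
EL_HOSS_2018 = DiagnosisRule("el_hoss_2018")


class UndefinedPercentPitError(ValueError):
    """%PIT is undefined (no counted cells) where a value is required."""


@dataclass
class SampleResult:
    """Per-sample biomarkers; fields are None when undefined (empty
    denominator)."""

    n_cells_counted: int
    n_pitted: int
    percent_pit: float | None
    mean_pits_per_pitted_cell: float | None = None
    max_pits_in_one_cell: int | None = None
    mean_pit_size_percent_of_cell: float | None = None
    exclusions: dict[str, int] = field(default_factory=dict)
    sufficient_count: bool = False
    spleen_status: SpleenStatus | None = None


def pit_count_percent(table: ObjectTable, min_cells: int = DEFAULT_MIN_CELLS) -> SampleResult:
    """%PIT over the included cells of a filtered table.

    A cell is pitted iff it has at least one pit; the denominator is the
    included cells only.  An empty denominator yields ``percent_pit=None``
    and ``sufficient_count=False``.
    """
    included = table.included()
    n = len(included)
    n_pitted = sum(1 for r in included if r.pitted)
    percent = 100.0 * n_pitted / n if n > 0 else None
    return SampleResult(
        n_cells_counted=n,
        n_pitted=n_pitted,
        percent_pit=percent,
        exclusions=table.exclusion_tally(),
        sufficient_count=n >= min_cells,
    )


def pit_morphometrics(
    table: ObjectTable, pit_size_average: str = "per_pit"
) -> tuple[float | None, int | None, float | None]:
    """(mean pits per pitted cell, max pits in one cell, mean pit size %).

    Mean pit size is each pit's area as a percentage of its cell's area,
    averaged per pit by default; ``pit_size_average="per_cell"`` first
    averages within each pitted cell.  All fields are None when no
    included cell is pitted (max is None when there are no included
    cells at all).
    """
    if pit_size_average not in ("per_pit", "per_cell"):
        raise ValueError("pit_size_average must be 'per_pit' or 'per_cell'")
    included = table.included()
    if not included:
        return None, None, None
    pitted = [r for r in included if r.pitted]
    max_pits = max(r.pit_count for r in included)
    if not pitted:
        return None, max_pits, None
    mean_pits = sum(r.pit_count for r in pitted) / len(pitted)
    if pit_size_average == "per_pit":
        fractions = [
            100.0 * a / r.area_um2 for r in pitted for a in r.pit_areas_um2
        ]
    else:
        fractions = [
            100.0 * sum(a / r.area_um2 for a in r.pit_areas_um2) / r.pit_count
            for r in pitted
        ]
    mean_size = sum(fractions) / len(fractions)
    return mean_pits, max_pits, mean_size


def classify_splenic_function(
    percent_pit: float | None, rule: DiagnosisRule | str = EL_HOSS_2018
) -> SpleenStatus:
    """Apply a published %PIT threshold rule, boundaries exactly as
    printed (≥ 3.5; < 1.2; > 4.5) with no epsilon fuzzing."""
    if percent_pit is None:
        raise UndefinedPercentPitError(
            "cannot classify splenic function: %PIT is undefined (no counted cells)"
        )
    if isinstance(rule, str):
        rule = DiagnosisRule(rule)
    if rule.name == "rogers_1970s":
        return (
            SpleenStatus.LOSS_OF_FUNCTION
            if percent_pit >= ROGERS_LOSS_GE
            else SpleenStatus.NORMAL
        )
    if percent_pit < EL_HOSS_NORMAL_LT:
        return SpleenStatus.NORMAL
    if percent_pit > EL_HOSS_ABSENT_GT:
        return SpleenStatus.ABSENT
    return SpleenStatus.INDETERMINATE


def summarize_sample(
    table: ObjectTable,
    min_cells: int = DEFAULT_MIN_CELLS,
    rule: DiagnosisRule | str | None = EL_HOSS_2018,
    pit_size_average: str = "per_pit",
) -> SampleResult:
    """Full per-sample summary: %PIT, morphometrics, splenic-function call."""
    result = pit_count_percent(table, min_cells=min_cells)
    mean_pits, max_pits, mean_size = pit_morphometrics(table, pit_size_average)
    result.mean_pits_per_pitted_cell = mean_pits
    result.max_pits_in_one_cell = max_pits
    result.mean_pit_size_percent_of_cell = mean_size
    if rule is not None and result.percent_pit is not None:
        result.spleen_status = classify_splenic_function(result.percent_pit, rule)
    return result
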