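"""BLOKS-style size binning and longitudinal change classification.

The relative lesion involvement is binned into the four BLOKS size groups
(none, <10%, 10-25%, >25% of the analysed subregion) mapped to grades 0-3.
A follow-up change in relative involvement is called significant — progression
or regression — when it exceeds the baseline 95% limits of agreement, used as
the minimal detectable change (MDC).
"""

from __future__ import annotations

from dataclasses import dataclass

BIN_LABELS = {0: "none", 1: "<10%", 2: "10-25%", 3: ">25%"}


@dataclass(frozen=True)
class BloksGrade:
    grade: int
    bin_label: str

    def __post_init__(self) -> None:
        if BIN_LABELS.get(self.grade) != self.bin_label:
            raise ValueError(f"grade {self.grade} does not match bin {self.bin_label!r}")


@dataclass(frozen=True)
class ChangeAssessment:
    baseline_percent: float
    followup_percent: float
    delta: float
    classification: str  # regression | stable | progression


def grade_bloks(relative_percent: float) -> BloksGrade:
    """Bin a relative involvement percentage into BLOKS grades 0-3.

    Grade 0 is reserved for exactly zero measured lesion ("none"); the
    boundary values fall into the closed middle bin, i.e. [10, 25] -> grade 2,
    consistent with the printed "<10%" being strict.
    """
    if not 0 <= relative_percent <= 100:
        raise ValueError(f"relative percent {relative_percent} outside [0, 100]")
    if relative_percent == 0:
        grade = 0
    elif relative_percent < 10:
        grade = 1
    elif relative_percent <= 25:
        grade = 2
    else:
        grade = 3
    return BloksGrade(grade=grade, bin_label=BIN_LABELS[grade])


def classify_change(
    baseline: float, followup: float, limits: tuple[float, float]
) -> ChangeAssessment:
    """Classify a baseline-to-follow-up change against MDC limits.

    ``limits`` are the (lower, upper) 95% limits of agreement of baseline
    measurements, in percentage points, straddling zero.  Progression iff
    delta strictly exceeds the upper limit; regression iff delta falls
    strictly below the lower limit; otherwise stable.  Degenerate (0, 0)
    limits are admitted — perfect baseline agreement makes every nonzero
    change significant.
    """
    lower, upper = limits
    if not lower <= 0 <= upper:
        raise ValueError(f"limits must straddle zero; got {limits}")
    delta = followup - baseline
    if delta > upper:
        classification = "progression"
    elif delta < lower:
        classification = "regression"
    else:
        classification = "stable"
    return ChangeAssessment(
        baseline_percent=baseline,
        followup_percent=followup,
        delta=delta,
        classification=classification,
    )
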