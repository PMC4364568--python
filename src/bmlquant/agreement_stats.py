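"""Reliability and responsiveness statistics.

Bland-Altman analysis of paired measurements (two readers, two occasions, or
two methods): bias = mean difference, its 95% CI via the t distribution, and
the 95% limits of agreement bias +/- 1.96*SD of the differences.  The baseline
limits of agreement double as the minimal detectable change for longitudinal
classification.  Spearman rank correlation and Student's t-test cover the
method-comparison and reference-threshold contrasts.

Difference direction is value_a - value_b throughout (reader 1 - reader 2,
method CAS - MS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

LOA_MULTIPLIER = 1.96  # conventional Bland-Altman normal quantile


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired values per subject, e.g. two readers' relative BML percents."""

    records: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("need at least 2 paired records")
        for rec in self.records:
            if len(rec) != 3 or not np.isfinite(rec[1]) or not np.isfinite(rec[2]):
                raise ValueError(f"malformed record {rec!r}")

    @classmethod
    def from_arrays(cls, a: Sequence[float], b: Sequence[float],
                    ids: Sequence[str] | None = None) -> "PairedMeasurements":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("value arrays must have equal length")
        if ids is None:
            ids = [str(i) for i in range(len(a))]
        return cls(tuple((str(s), float(x), float(y)) for s, x, y in zip(ids, a, b)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedMeasurements":
        """Read a CSV with columns subject_id, value_a, value_b."""
        df = pd.read_csv(path)
        missing = {"subject_id", "value_a", "value_b"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV {path} missing columns {sorted(missing)}")
        return cls.from_arrays(df["value_a"], df["value_b"], df["subject_id"].astype(str))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def values_a(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def values_b(self) -> np.ndarray:
        return np.array([r[2] for r in self.records])

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    sd_diff: float
    ci_bias: tuple[float, float]
    loa: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "ci_bias": list(self.ci_bias),
            "loa": list(self.loa),
            "n": self.n,
        }


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    ci: tuple[float, float]
    p_value: float
    n: int


def bland_altman(pairs: PairedMeasurements) -> AgreementResult:
    """Bias, 95% CI of the bias, and 95% limits of agreement of a-b."""
    d = pairs.differences
    n = pairs.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = LOA_MULTIPLIER * sd
    t_crit = float(sps.t.ppf(0.975, n - 1))
    ci_half = t_crit * sd / np.sqrt(n)
    return AgreementResult(
        bias=bias,
        sd_diff=sd,
        ci_bias=(bias - ci_half, bias + ci_half),
        loa=(bias - half, bias + half),
        n=n,
    )


def limits_as_mdc(result: AgreementResult) -> tuple[float, float]:
    """Baseline limits of agreement, verbatim, as the minimal detectable
    change interval for :func:`bmlquant.grading_change.classify_change`."""
    return result.loa


def spearman_correlation(pairs: PairedMeasurements) -> SpearmanResult:
    """Spearman rank correlation (average ranks on ties, two-sided p via the
    t approximation)."""
    if pairs.n < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    a, b = pairs.values_a, pairs.values_b
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.spearmanr(a, b)
    return SpearmanResult(rho=float(res.statistic), p_value=float(res.pvalue), n=pairs.n)


def compare_means_ttest(
    sample_a: Sequence[float], sample_b: Sequence[float], paired: bool = False
) -> TTestResult:
    """Student's t comparison of two samples with a 95% CI of the difference.

    Paired uses the within-pair differences; unpaired uses the classic pooled
    variance (not Welch).  A degenerate zero-variance comparison of identical
    samples is reported as difference 0, p = 1, with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        d = a - b
        n = len(d)
        mean_d = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0:
            warnings.warn("zero variance of paired differences; p set to 1", stacklevel=2)
            return TTestResult(mean_d, (mean_d, mean_d), 1.0, n)
        t_crit = float(sps.t.ppf(0.975, n - 1))
        half = t_crit * sd / np.sqrt(n)
        p = float(sps.ttest_rel(a, b).pvalue)
        return TTestResult(mean_d, (mean_d - half, mean_d + half), p, n)
    n1, n2 = len(a), len(b)
    mean_d = float(a.mean() - b.mean())
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        warnings.warn("zero pooled variance; p set to 1", stacklevel=2)
        return TTestResult(mean_d, (mean_d, mean_d), 1.0, n1 + n2)
    se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    t_crit = float(sps.t.ppf(0.975, n1 + n2 - 2))
    p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    return TTestResult(mean_d, (mean_d - t_crit * se, mean_d + t_crit * se), p, n1 + n2)


def bland_altman_plot(pairs: PairedMeasurements, result: AgreementResult | None = None,
                      ax=None):
    """Basic Bland-Altman scatter: mean vs difference with bias and LoA lines."""
    import matplotlib.pyplot as plt

    if result is None:
        result = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots()
    means = (pairs.values_a + pairs.values_b) / 2
    ax.scatter(means, pairs.differences, s=14)
    ax.axhline(result.bias, color="k", lw=1)
    for lim in result.loa:
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of paired measurements")
    ax.set_ylabel("difference (a - b)")
    return ax
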