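"""Ancillary paired analyses: baseline correction, outlier exclusion and
normality-gated paired tests for cortisol and subjective-rating data."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "baseline_correct",
    "outlier_exclude_3p5sd",
    "PairedTestReport",
    "normality_gated_paired_test",
]

logger = logging.getLogger(__name__)


def baseline_correct(
    before: np.ndarray | pd.Series, after: np.ndarray | pd.Series
) -> np.ndarray:
    """Per-subject delta = after - before; subjects missing either value are
    dropped with a logged warning."""
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("before/after must be aligned per subject")
    ok = np.isfinite(b) & np.isfinite(a)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.warning("dropping %d subject(s) missing a paired value", n_drop)
    return a[ok] - b[ok]


def outlier_exclude_3p5sd(values: np.ndarray, n_sd: float = 3.5) -> np.ndarray:
    """Leave-one-out high-outlier rule.

    ``values`` is (n_subjects,) or (n_subjects, n_measures). A subject is
    excluded when its minimum value exceeds the mean + ``n_sd`` standard
    deviations of all OTHER subjects' values. Applied once, no iteration.
    Returns a boolean inclusion mask over subjects.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    n = v.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    include = np.ones(n, dtype=bool)
    for i in range(n):
        others = np.delete(v, i, axis=0).ravel()
        mu, sd = others.mean(), others.std(ddof=1)
        if sd > 0 and v[i].min() > mu + n_sd * sd:
            include[i] = False
    if (~include).any():
        logger.info("excluded %d subject(s) by the %.1f-SD rule", int((~include).sum()), n_sd)
    return include


@dataclass
class PairedTestReport:
    branch: str  # "paired_t" | "wilcoxon" | "no_variation"
    shapiro_p: float | None
    statistic: float | None
    p: float | None
    n: int

    def describe(self) -> str:
        if self.branch == "no_variation":
            return f"n={self.n}: all paired differences are zero; no test performed"
        test = "paired t-test" if self.branch == "paired_t" else "Wilcoxon signed-rank"
        shape = "normal" if self.branch == "paired_t" else "non-normal"
        return (
            f"n={self.n}: differences {shape} by Shapiro-Wilk "
            f"(p={self.shapiro_p:.3g}); {test}: statistic={self.statistic:.4g}, "
            f"p={self.p:.4g}"
        )


def normality_gated_paired_test(
    a: np.ndarray, b: np.ndarray, alpha_normality: float = 0.05
) -> PairedTestReport:
    """Shapiro-Wilk on paired differences decides the test: normal
    differences get a paired t-test, non-normal a Wilcoxon signed-rank."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must be aligned")
    if len(a) < 4:
        raise ValueError("need at least 4 pairs")
    d = b - a
    if np.allclose(d, 0):
        return PairedTestReport("no_variation", None, None, None, len(d))
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= alpha_normality:
        res = stats.ttest_rel(b, a)
        return PairedTestReport("paired_t", sw_p, float(res.statistic), float(res.pvalue), len(d))
    stat, p = stats.wilcoxon(b, a)
    return PairedTestReport("wilcoxon", sw_p, float(stat), float(p), len(d))
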