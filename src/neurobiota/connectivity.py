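"""Task-related ROI-to-ROI functional connectivity.

Sub-cluster mean timecourses are linearly detrended and band-pass filtered
(0.008-0.09 Hz), then correlated pairwise under condition weights — the
rectified, normalised HRF-convolved indicator of the condition of interest
(ME), so that volumes acquired during and shortly after emotion-matching
blocks dominate the correlation. Correlations are Fisher z-transformed,
contrasted between interventions with a paired t-test per ROI pair, and
thresholded with seed-level Benjamini-Hochberg FDR: BH is applied within
each seed's row of the pair matrix and a pair is significant if it
survives in at least one of its two rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .paradigm import (
    Condition,
    HRFParams,
    RegressorSeries,
    TaskDesign,
    convolve_regressor,
    hrf_kernel,
    sample_indicator,
)

__all__ = [
    "denoise_series",
    "condition_weights",
    "weighted_correlation",
    "fisher_z",
    "inverse_fisher_z",
    "connectivity_matrix",
    "ContrastResult",
    "paired_roi_contrast",
    "seed_level_fdr",
]

logger = logging.getLogger(__name__)

BAND_LO_HZ = 0.008
BAND_HI_HZ = 0.09


def denoise_series(
    s: RegressorSeries,
    band_lo: float = BAND_LO_HZ,
    band_hi: float = BAND_HI_HZ,
    order: int = 2,
) -> RegressorSeries:
    """Linear detrend followed by zero-phase Butterworth band-pass."""
    nyquist = 0.5 / s.tr_s
    if not 0 < band_lo < band_hi < nyquist:
        raise ValueError(
            f"band ({band_lo}, {band_hi}) Hz outside (0, Nyquist={nyquist:.4f}) Hz"
        )
    if len(s) < 16:
        raise ValueError("series too short to filter (need >= 16 volumes)")
    x = signal.detrend(s.values, type="linear")
    sos = signal.butter(order, [band_lo / nyquist, band_hi / nyquist], btype="bandpass", output="sos")
    y = signal.sosfiltfilt(sos, x)
    return RegressorSeries(y, s.tr_s, label=s.label)


def condition_weights(
    design: TaskDesign,
    condition: Condition | str = Condition.ME,
    tr_s: float = 2.5,
    n_volumes: int = 192,
    hrf: HRFParams | None = None,
) -> RegressorSeries:
    """HRF weighting vector for condition-specific connectivity.

    The condition indicator is HRF-convolved, negative values are clipped
    to zero, and the result is normalised to sum 1 so it can serve as
    observation weights in :func:`weighted_correlation`.
    """
    ind = sample_indicator(design, condition, tr_s, n_volumes)
    conv = convolve_regressor(ind, hrf_kernel(hrf, tr_s))
    w = np.clip(conv.values, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"condition {Condition(condition).value} yields all-zero weights")
    return RegressorSeries(w / total, tr_s, label=f"w({Condition(condition).value})")


def weighted_correlation(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Pearson correlation under observation weights summing to 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and w must have equal lengths")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    mx = w @ x
    my = w @ y
    cov = w @ ((x - mx) * (y - my))
    vx = w @ ((x - mx) ** 2)
    vy = w @ ((y - my) ** 2)
    if vx <= 0 or vy <= 0:
        warnings.warn("zero weighted variance; correlation undefined", RuntimeWarning)
        return np.nan
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilising transform z = atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z: float | np.ndarray) -> float | np.ndarray:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def connectivity_matrix(
    timecourses: list[RegressorSeries],
    weights: np.ndarray,
    denoise: bool = True,
) -> np.ndarray:
    """Symmetric ROI x ROI Fisher-z matrix from weighted correlations.

    The diagonal is NaN (self-connectivity is undefined).
    """
    series = [denoise_series(s) if denoise else s for s in timecourses]
    n = len(series)
    z = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            r = weighted_correlation(series[i].values, series[j].values, weights)
            # guard: numerically perfect correlations would map to +-inf
            r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
            z[i, j] = z[j, i] = np.arctanh(r)
    return z


@dataclass
class ContrastResult:
    """Paired intervention contrast over all ROI pairs."""

    t: np.ndarray  # (n_roi, n_roi), NaN diagonal
    p: np.ndarray
    n_subjects: int
    fdr_q: np.ndarray | None = None
    significant_pairs: list[tuple[int, int]] | None = None


def paired_roi_contrast(
    z_prob: list[np.ndarray], z_plac: list[np.ndarray]
) -> ContrastResult:
    """Per-pair paired t statistic on Fisher-z differences
    (probiotic - placebo) with df = n_subjects - 1."""
    if len(z_prob) != len(z_plac):
        raise ValueError("subject lists differ in length between conditions")
    n = len(z_prob)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    diffs = np.stack(z_prob) - np.stack(z_plac)  # (S, R, R)
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & np.isfinite(mean)
    t = np.where(zero_var, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(np.isnan(t), np.nan, p)
    if zero_var.any():
        logger.warning("%d pairs had zero difference variance; reported t=0", int(zero_var.sum() // 2))
    return ContrastResult(t=t, p=p, n_subjects=n)


def seed_level_fdr(result: ContrastResult, q: float = 0.05) -> ContrastResult:
    """Seed-level BH FDR on the pair p matrix.

    BH is applied separately within each seed's row (n_roi - 1 tests). A
    pair is significant if it survives in at least one of its two rows; the
    reported q is the smaller of the two row-wise adjusted values.
    """
    p = result.p
    n = p.shape[0]
    if p.shape[0] != p.shape[1]:
        raise ValueError("p matrix must be square")
    row_q = np.full_like(p, np.nan, dtype=float)
    row_sig = np.zeros_like(p, dtype=bool)
    for i in range(n):
        cols = np.array([j for j in range(n) if j != i])
        pi = p[i, cols]
        ok = np.isfinite(pi)
        if not ok.any():
            continue
        rej, adj, _, _ = multipletests(pi[ok], alpha=q, method="fdr_bh")
        row_q[i, cols[ok]] = adj
        row_sig[i, cols[ok]] = rej
    fdr_q = np.fmin(row_q, row_q.T)
    sig = row_sig | row_sig.T
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if sig[i, j]]
    result.fdr_q = fdr_q
    result.significant_pairs = pairs
    return result


def contrast_table(
    result: ContrastResult, roi_ids: list | None = None
) -> pd.DataFrame:
    """Upper-triangle pair table mirroring a connectivity results listing."""
    n = result.t.shape[0]
    ids = roi_ids if roi_ids is not None else list(range(n))
    rows = []
    sig = set(result.significant_pairs or [])
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                {
                    "roi_a": ids[i],
                    "roi_b": ids[j],
                    "t": result.t[i, j],
                    "p": result.p[i, j],
                    "fdr_q": None if result.fdr_q is None else result.fdr_q[i, j],
                    "significant": (i, j) in sig,
                }
            )
    return pd.DataFrame(rows)
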