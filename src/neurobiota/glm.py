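"""Per-voxel general linear model of task-evoked BOLD activity.

The session model relates each voxel's signal y to an intercept, a linear
drift, unconvolved instruction/fixation indicators, and HRF-convolved task
components:

    y = b0 + b1*t + b2*INSTR + b3*FIX + b4*(ME+MS) + b5*(ME-MS) + err

b4 carries the average response to both matching conditions, while b5 — the
ME-MS contrast — isolates the emotional-processing response and is the
coefficient tested throughout. Group fits pool subjects in one fixed-effects
regression with a per-subject intercept, a rigid correction for individual
mean signal level that keeps the time course intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import (
    Condition,
    HRFParams,
    TaskDesign,
    convolve_regressor,
    hrf_kernel,
    sample_indicator,
)

__all__ = [
    "BoldImage",
    "StatMap",
    "StatKind",
    "DESIGN_COLUMNS",
    "build_design_matrix",
    "fit_voxelwise_glm",
    "fit_multisubject_glm",
    "bonferroni_threshold",
    "fit_region_glm",
    "GLMResult",
]

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ("intercept", "drift_t", "INSTR", "FIX", "ME_plus_MS", "ME_minus_MS")


class StatKind(str, Enum):
    beta = "beta"
    t = "t"
    p = "p"
    neglog10p = "neglog10p"
    mask = "mask"


@dataclass
class BoldImage:
    """4-D BOLD series (x, y, z, time) with affine and repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class StatMap:
    """3-D statistic map defined inside a boolean mask."""

    data: np.ndarray
    kind: StatKind
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")
        self.kind = StatKind(self.kind)
        self.affine = np.asarray(self.affine, dtype=float)

    def neglog10(self) -> "StatMap":
        """Convert a p map to -log10(p), the form written to NIfTI."""
        if self.kind is not StatKind.p:
            raise ValueError("neglog10 applies to p maps only")
        out = np.zeros_like(self.data, dtype=float)
        out[self.mask] = -np.log10(np.clip(self.data[self.mask], 1e-300, 1.0))
        return StatMap(out, StatKind.neglog10p, self.mask, self.affine)


@dataclass
class GLMResult:
    """Beta maps plus t and two-sided p maps for the ME-MS contrast."""

    betas: dict[str, StatMap]
    t_map: StatMap
    p_map: StatMap
    df: int
    zero_variance_voxels: np.ndarray  # (n, 3) voxel indices flagged in QC


def build_design_matrix(
    design: TaskDesign,
    tr_s: float,
    n_volumes: int,
    hrf: HRFParams | None = None,
) -> pd.DataFrame:
    """Assemble the six-column session design matrix.

    Columns: intercept, drift_t (volume index scaled to [0, 1]), unconvolved
    INSTR and FIX indicators, and the HRF-convolved ME+MS and ME-MS
    components.
    """
    if design.total_duration_s > n_volumes * tr_s + 1e-9:
        raise ValueError(
            f"design covers {design.total_duration_s} s > acquisition "
            f"{n_volumes * tr_s} s"
        )
    kernel = hrf_kernel(hrf, tr_s)
    conv = {}
    for cond in (Condition.ME, Condition.MS):
        ind = sample_indicator(design, cond, tr_s, n_volumes)
        conv[cond] = convolve_regressor(ind, kernel).values
    X = pd.DataFrame(
        {
            "intercept": np.ones(n_volumes),
            "drift_t": np.arange(n_volumes) / max(n_volumes - 1, 1),
            "INSTR": sample_indicator(design, Condition.INSTR, tr_s, n_volumes).values,
            "FIX": sample_indicator(design, Condition.FIX, tr_s, n_volumes).values,
            "ME_plus_MS": conv[Condition.ME] + conv[Condition.MS],
            "ME_minus_MS": conv[Condition.ME] - conv[Condition.MS],
        }
    )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"design matrix rank {rank} < {X.shape[1]}; most collinear pair: "
            f"{X.columns[i]!r} ~ {X.columns[j]!r} (|r|={abs(corr[i, j]):.4f})"
        )
    return X


def _ols_contrast(
    Y: np.ndarray, X: np.ndarray, contrast_idx: int, df: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS over voxels (rows of Y): betas, t, p for one coefficient.

    Returns (beta_all, t, p, resid_var, zero_var_mask)."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T  # (p, V)
    resid = Y.T - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    var5 = sigma2 * XtX_inv[contrast_idx, contrast_idx]
    zero_var = np.ptp(Y, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[contrast_idx] / np.sqrt(var5)
    t = np.where(var5 > 0, t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    t[zero_var] = 0.0
    p[zero_var] = 1.0
    return beta, t, p, sigma2, zero_var


def _pack_maps(
    shape: tuple[int, ...],
    mask: np.ndarray,
    affine: np.ndarray,
    beta: np.ndarray,
    t: np.ndarray,
    p: np.ndarray,
    beta_names: list[str],
    df: int,
    zero_var: np.ndarray,
) -> GLMResult:
    def to_map(vec: np.ndarray, kind: StatKind, fill: float = 0.0) -> StatMap:
        vol = np.full(shape, fill, dtype=float)
        vol[mask] = vec
        return StatMap(vol, kind, mask, affine)

    betas = {name: to_map(beta[i], StatKind.beta) for i, name in enumerate(beta_names)}
    coords = np.argwhere(mask)[zero_var]
    if len(coords):
        logger.warning("QC: %d zero-variance voxels set to p=1", len(coords))
    return GLMResult(
        betas=betas,
        t_map=to_map(t, StatKind.t),
        p_map=to_map(p, StatKind.p, fill=1.0),
        df=df,
        zero_variance_voxels=coords,
    )


def fit_voxelwise_glm(bold: BoldImage, X: pd.DataFrame, mask: np.ndarray) -> GLMResult:
    """Ordinary least squares per masked voxel; t and two-sided p for the
    ME-MS coefficient with df = n_volumes - 6.

    Zero-variance voxels get p = 1 and are flagged, not raised.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    Xa = X.to_numpy(dtype=float)
    if bold.n_volumes != Xa.shape[0]:
        raise ValueError(
            f"BOLD has {bold.n_volumes} volumes but design has {Xa.shape[0]} rows"
        )
    Y = bold.data[mask].astype(float)  # (V, T)
    df = Xa.shape[0] - Xa.shape[1]
    c_idx = list(X.columns).index("ME_minus_MS")
    beta, t, p, _, zero_var = _ols_contrast(Y, Xa, c_idx, df)
    return _pack_maps(
        mask.shape, mask, bold.affine, beta, t, p, list(X.columns), df, zero_var
    )


def _stack_multisubject_design(X: pd.DataFrame, n_subjects: int) -> tuple[np.ndarray, int]:
    """Concatenated design with one intercept per subject replacing the
    common intercept; remaining columns shared across subjects."""
    n = X.shape[0]
    shared = X.drop(columns="intercept").to_numpy(dtype=float)
    k_shared = shared.shape[1]
    big = np.zeros((n_subjects * n, n_subjects + k_shared))
    for s in range(n_subjects):
        rows = slice(s * n, (s + 1) * n)
        big[rows, s] = 1.0
        big[rows, n_subjects:] = shared
    c_idx = n_subjects + list(X.drop(columns="intercept").columns).index("ME_minus_MS")
    return big, c_idx


def fit_multisubject_glm(
    bolds: list[BoldImage], X: pd.DataFrame, mask: np.ndarray
) -> GLMResult:
    """Pooled fixed-effects GLM across subjects with per-subject intercepts.

    All subjects must share grid, affine and TR. df = S*n - (S + 5).
    """
    if not bolds:
        raise ValueError("no subjects")
    ref = bolds[0]
    for b in bolds[1:]:
        if b.data.shape[:3] != ref.data.shape[:3] or not np.allclose(b.affine, ref.affine):
            raise ValueError("subjects differ in grid or affine")
        if not np.isclose(b.tr_s, ref.tr_s):
            raise ValueError("subjects differ in TR")
    mask = np.asarray(mask, dtype=bool)
    S = len(bolds)
    big, c_idx = _stack_multisubject_design(X, S)
    Y = np.concatenate([b.data[mask].astype(float) for b in bolds], axis=1)  # (V, S*n)
    df = big.shape[0] - big.shape[1]
    beta, t, p, _, zero_var = _ols_contrast(Y, big, c_idx, df)
    names = [f"intercept_s{i}" for i in range(S)] + [
        c for c in X.columns if c != "intercept"
    ]
    return _pack_maps(mask.shape, mask, ref.affine, beta, t, p, names, df, zero_var)


def bonferroni_threshold(pmap: StatMap, alpha: float, m: int) -> StatMap:
    """Boolean map of voxels with p < alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    sig = np.zeros(pmap.data.shape, dtype=float)
    sig[pmap.mask] = pmap.data[pmap.mask] < alpha / m
    return StatMap(sig, StatKind.mask, pmap.mask, pmap.affine)


def fit_region_glm(
    bolds: list[BoldImage],
    X: pd.DataFrame,
    atlas: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Region-averaged pooled GLM with Bonferroni over the number of labels.

    Each atlas label's mean timecourse per subject is fit with the same
    pooled fixed-effects model as :func:`fit_multisubject_glm`. Empty labels
    are skipped with a warning. Returns a table with per-region ME-MS beta,
    t, p and Bonferroni significance at ``alpha`` over the tested labels.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != bolds[0].data.shape[:3]:
        raise ValueError("atlas grid does not match BOLD grid")
    labels = [int(v) for v in np.unique(atlas) if v > 0]
    rows = []
    kept_labels = []
    series = []
    for lab in labels:
        region = atlas == lab
        if not region.any():
            logger.warning("atlas label %d is empty; skipped", lab)
            continue
        kept_labels.append(lab)
        series.append(
            np.stack([b.data[region].mean(axis=0) for b in bolds])  # (S, T)
        )
    S = len(bolds)
    big, c_idx = _stack_multisubject_design(X, S)
    df = big.shape[0] - big.shape[1]
    m = len(kept_labels)
    for lab, ts in zip(kept_labels, series):
        Y = ts.reshape(1, -1)  # (1, S*T)
        beta, t, p, _, _ = _ols_contrast(Y, big, c_idx, df)
        rows.append(
            {
                "label": lab,
                "beta_me_minus_ms": beta[c_idx, 0],
                "t": t[0],
                "p": p[0],
                "significant_bonferroni": bool(p[0] < alpha / m),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_m"] = m
    return out
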