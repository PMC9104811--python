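"""Crossover intervention analysis of sub-cluster mean timecourses.

Each subject is scanned once after placebo and once after probiotic
intervention. Stacking both sessions' mean timecourses of a sub-cluster
yields a long table on which the intervention model is fit:

    y = b0 + b1*t + b2*INSTR + b3*FIX + b4*(ME+MS) + b5*(ME-MS)
        + b6*TREAT + b7*TREAT*(ME-MS) + err

with subject-level random effects on b4, b5, b6 and b7 (independent
variance components). b7 — the treatment x (ME-MS) interaction — is the
quantity of interest: b7 > 0 means a larger emotional-attention response
under probiotic than placebo. Inference on b7 uses a Wald test from the
REML fit.

The module also screens many sub-cluster results at the nominal,
Bonferroni and FDR tiers and provides the paired t-test power / sample
size computation used to plan such a crossover study.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import VCSpec
from scipy import stats

from .microbiome import bh_fdr

__all__ = [
    "MixedModelResult",
    "assemble_long_table",
    "fit_intervention_model",
    "screen_subclusters",
    "paired_t_power",
    "compute_sample_size",
]

logger = logging.getLogger(__name__)

FIXED_TERMS = ("drift_t", "INSTR", "FIX", "ME_plus_MS", "ME_minus_MS", "TREAT", "TREAT_x_MM")
RANDOM_TERMS = ("ME_plus_MS", "ME_minus_MS", "TREAT", "TREAT_x_MM")
FALLBACK_RANDOM_TERMS = ("ME_minus_MS", "TREAT_x_MM")


@dataclass
class MixedModelResult:
    """REML fit of the intervention model for one sub-cluster."""

    fixed: pd.Series
    se: pd.Series
    random_variances: dict[str, float]
    interaction_p: float
    effect_size: float  # b7 / SE(b7)
    converged: bool
    used_fallback: bool = False

    @property
    def interaction_estimate(self) -> float:
        return float(self.fixed["TREAT_x_MM"])


def assemble_long_table(
    timecourses: dict[tuple[str, int], np.ndarray],
    metadata: pd.DataFrame,
    X: pd.DataFrame,
) -> pd.DataFrame:
    """Stack per subject x session mean timecourses into a long table.

    ``timecourses`` maps (subject_id, session) to a signal vector aligned
    with the rows of the session design matrix ``X``. ``metadata`` must
    contain columns subject, session and treatment (0 = placebo,
    1 = probiotic). Subjects missing either session are excluded with a
    logged warning.
    """
    meta = metadata.set_index(["subject", "session"])
    sessions_per_subject = metadata.groupby("subject")["session"].nunique()
    complete = sessions_per_subject[sessions_per_subject == 2].index
    dropped = sorted(set(metadata["subject"]) - set(complete))
    if dropped:
        logger.warning("excluding %d subject(s) missing a session: %s", len(dropped), dropped)
    n = X.shape[0]
    design = X.drop(columns="intercept", errors="ignore").reset_index(drop=True)
    frames = []
    for (subject, session), series in sorted(timecourses.items()):
        if subject not in complete:
            continue
        series = np.asarray(series, dtype=float)
        if len(series) != n:
            raise ValueError(
                f"series for {subject} session {session} has {len(series)} "
                f"volumes but design has {n} rows"
            )
        block = design.copy()
        block.insert(0, "signal", series)
        block.insert(0, "volume_index", np.arange(n))
        block.insert(0, "treatment", int(meta.loc[(subject, session), "treatment"]))
        block.insert(0, "session", session)
        block.insert(0, "subject", subject)
        frames.append(block)
    tbl = pd.concat(frames, ignore_index=True)
    tbl["TREAT"] = tbl["treatment"].astype(float)
    tbl["TREAT_x_MM"] = tbl["TREAT"] * tbl["ME_minus_MS"]
    return tbl


def _fit_mixedlm(tbl: pd.DataFrame, random_terms: tuple[str, ...]):
    # built from arrays (not a formula) so repeated fits stay cheap
    groups = tbl["subject"].to_numpy()
    labels = np.unique(groups)
    mats = [
        [tbl.loc[groups == g, [t]].to_numpy() for g in labels] for t in random_terms
    ]
    vc = VCSpec(
        names=list(random_terms),
        colnames=[[[t]] * len(labels) for t in random_terms],
        mats=mats,
    )
    exog = tbl[list(FIXED_TERMS)].copy()
    exog.insert(0, "Intercept", 1.0)
    model = sm.MixedLM(
        tbl["signal"].to_numpy(),
        exog,
        groups=groups,
        exog_re=np.empty((len(tbl), 0)),  # no random intercept; vc terms only
        exog_vc=vc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not res.converged:
            # derivative-free restart rescues most boundary cases
            res = model.fit(reml=True, method="powell", maxiter=2000)
    return res


def fit_intervention_model(
    tbl: pd.DataFrame,
    random_terms: tuple[str, ...] = RANDOM_TERMS,
) -> MixedModelResult:
    """REML mixed-effects fit with diagonal subject-level random slopes.

    Random effects are independent variance components on the ME+MS, ME-MS,
    TREAT and TREAT x (ME-MS) columns. On non-convergence the model is
    refit with random effects on ME-MS and the interaction only, and the
    result is flagged.
    """
    if tbl["subject"].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    res = _fit_mixedlm(tbl, random_terms)
    used_fallback = False
    if not res.converged:
        logger.warning("mixed model did not converge; refitting reduced random structure")
        res = _fit_mixedlm(tbl, FALLBACK_RANDOM_TERMS)
        used_fallback = True
    fixed = res.fe_params.copy()
    se_s = res.bse_fe.reindex(fixed.index)
    z = fixed["TREAT_x_MM"] / se_s["TREAT_x_MM"]
    p = float(2.0 * stats.norm.sf(abs(z)))
    vcomp = dict(zip(res.model.exog_vc.names, np.maximum(res.vcomp, 0.0)))
    return MixedModelResult(
        fixed=fixed,
        se=se_s,
        random_variances=vcomp,
        interaction_p=max(p, np.finfo(float).tiny),
        effect_size=float(z),
        converged=bool(res.converged),
        used_fallback=used_fallback,
    )


def screen_subclusters(
    results: pd.DataFrame,
    alpha: float = 0.05,
    n_rois: int = 10,
) -> pd.DataFrame:
    """Three-tier multiplicity report over per-sub-cluster interaction tests.

    ``results`` needs an ``interaction_p`` column. Adds nominal
    significance, Bonferroni over all sub-clusters tested, Bonferroni over
    the predefined ROI count, and BH FDR values.
    """
    if results.empty:
        raise ValueError("no results to screen")
    out = results.copy()
    m = len(out)
    p = out["interaction_p"].to_numpy(dtype=float)
    out["significant_nominal"] = p < alpha
    out["significant_bonferroni_all"] = p < alpha / m
    out["significant_bonferroni_rois"] = p < alpha / max(n_rois, 1)
    out["fdr_q"] = bh_fdr(p)
    out.attrs["n_subclusters"] = m
    out.attrs["n_rois"] = n_rois
    return out


def paired_t_power(n: int, dz: float, alpha: float) -> float:
    """Power of a two-sided paired t-test at effect size dz (Cohen's dz)
    via the noncentral t distribution."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = dz * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def compute_sample_size(
    dz: float,
    alpha: float = 0.05,
    n_tests: int = 1,
    power: float = 0.80,
    n_max: int = 100_000,
) -> int:
    """Smallest n with paired t-test power >= target at Bonferroni-corrected
    two-sided alpha / n_tests."""
    if dz <= 0:
        raise ValueError("dz must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    a = alpha / n_tests
    for n in range(2, n_max + 1):
        if paired_t_power(n, dz, a) >= power:
            return n
    raise ValueError(f"power {power} unattainable with n <= {n_max}")
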