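"""Crossover differential-abundance and diversity analysis of taxa counts.

Fecal 16S count tables (one sample per subject x treatment x timepoint)
are aggregated to a taxonomic rank, filtered on prevalence (taxa absent in
more than 85% of samples are dropped), and tested taxon by taxon with a
zero-inflated negative binomial (ZINB) regression

    y ~ ZINB(mu, k, pi),  log mu = b0 + b1*TREAT + b2*TIME
                                   + b3*TREAT*TIME + offset(log library size)

where TREAT in {placebo, probiotics}, TIME in {before, after} and the
interaction b3 — nonzero only for probiotics-after samples — captures the
differential post-treatment effect of the probiotic versus placebo. The
zero-inflation component is intercept-only. Wald p-values for b3 are
corrected across taxa with Benjamini-Hochberg FDR.

Diversity: Shannon (natural log) and Simpson (1 - sum p^2) alpha
diversity with paired Wilcoxon / Friedman tests, and Bray-Curtis
dissimilarity embedded by classical principal coordinate analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.discrete.discrete_model import NegativeBinomial

__all__ = [
    "RANKS",
    "TaxaTable",
    "ZINBFit",
    "aggregate_rank",
    "normalize_library",
    "prevalence_filter",
    "fit_zinb_interaction",
    "differential_abundance",
    "bh_fdr",
    "alpha_diversity",
    "beta_diversity_pcoa",
    "diversity_tests",
]

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxaTable:
    """Taxa x samples count matrix with taxonomy and sample metadata.

    ``counts``: DataFrame indexed by taxon id, columns = sample ids.
    ``taxonomy``: Series of semicolon-separated lineages (domain..species),
    aligned with the count index.
    ``sample_meta``: DataFrame indexed by sample id with columns subject,
    TREAT ('placebo'/'probiotics') and TIME ('before'/'after').
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.taxonomy.index):
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, counts_path, meta_path) -> None:
        wide = self.counts.copy()
        wide.insert(0, "taxonomy", self.taxonomy)
        wide.to_csv(counts_path, sep="\t")
        self.sample_meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "TaxaTable":
        wide = pd.read_csv(counts_path, sep="\t", index_col=0)
        taxonomy = wide.pop("taxonomy")
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts=wide, taxonomy=taxonomy, sample_meta=meta)


def _rank_label(lineage: str, level: int, rank: str) -> str:
    parts = [p.strip() for p in str(lineage).split(";")]
    if level < len(parts) and parts[level]:
        return parts[level]
    return f"unclassified_{rank}"


def aggregate_rank(tbl: TaxaTable, rank: str) -> TaxaTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Taxa unclassified at that rank are pooled into an explicit
    ``unclassified_<rank>`` bucket. Library sizes are preserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid: {', '.join(RANKS)}")
    level = RANKS.index(rank)
    labels = tbl.taxonomy.map(lambda s: _rank_label(s, level, rank))
    counts = tbl.counts.groupby(labels).sum()
    lineages = {}
    for taxon, label in labels.items():
        parts = [p.strip() for p in str(tbl.taxonomy[taxon]).split(";")][: level + 1]
        parts += [""] * (level + 1 - len(parts))
        lineages.setdefault(label, ";".join(parts))
    taxonomy = pd.Series({lab: lineages[lab] for lab in counts.index}, name="taxonomy")
    return TaxaTable(counts=counts, taxonomy=taxonomy, sample_meta=tbl.sample_meta)


def normalize_library(tbl: TaxaTable, target: str | float = "median") -> TaxaTable:
    """Total-sum scaling of every sample to a common library size
    (the median library by default). Proportions within a sample are
    unchanged; output counts are real-valued."""
    sizes = tbl.library_sizes
    zero = sizes[sizes == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    target_size = float(np.median(sizes)) if target == "median" else float(target)
    scaled = tbl.counts * (target_size / sizes)
    return replace(tbl, counts=scaled)


def prevalence_filter(
    tbl: TaxaTable, max_absent_frac: float = 0.85
) -> tuple[TaxaTable, pd.DataFrame]:
    """Drop taxa absent in strictly more than ``max_absent_frac`` of samples.

    Returns the filtered table and a summary of removed taxa (per-group
    prevalence) for checking that removals follow no specific pattern.
    """
    if not 0 < max_absent_frac < 1:
        raise ValueError("max_absent_frac must lie in (0, 1)")
    absent = (tbl.counts == 0).mean(axis=1)
    removed = absent.index[absent > max_absent_frac]
    kept = absent.index[absent <= max_absent_frac]
    groups = tbl.sample_meta["TREAT"].astype(str) + "/" + tbl.sample_meta["TIME"].astype(str)
    summary_rows = []
    for taxon in removed:
        present = tbl.counts.loc[taxon] > 0
        row = {"taxon": taxon, "absent_frac": float(absent[taxon])}
        for g in sorted(groups.unique()):
            cols = groups[groups == g].index
            row[f"prevalence_{g}"] = float(present[cols].mean())
        summary_rows.append(row)
    if len(removed):
        logger.info("prevalence filter removed %d/%d taxa", len(removed), len(absent))
    filtered = replace(
        tbl, counts=tbl.counts.loc[kept], taxonomy=tbl.taxonomy.loc[kept]
    )
    return filtered, pd.DataFrame(summary_rows)


@dataclass
class ZINBFit:
    """One taxon's interaction fit."""

    coefficients: pd.Series
    se: pd.Series
    zero_inflation_prob: float
    dispersion_alpha: float
    interaction_p: float
    converged: bool
    nb_fallback: bool = False
    loglike: float = np.nan


def _design_from_meta(meta: pd.DataFrame) -> pd.DataFrame:
    treat = (meta["TREAT"].astype(str) == "probiotics").astype(float)
    time = (meta["TIME"].astype(str) == "after").astype(float)
    return pd.DataFrame(
        {
            "const": 1.0,
            "TREAT": treat,
            "TIME": time,
            "TREAT_x_TIME": treat * time,
        },
        index=meta.index,
    )


def fit_zinb_interaction(
    y: np.ndarray | pd.Series,
    meta: pd.DataFrame,
    library_sizes: np.ndarray | pd.Series | None = None,
    round_counts: bool = False,
) -> ZINBFit:
    """Maximum-likelihood ZINB fit of one taxon's counts.

    Count-model covariates: intercept, TREAT, TIME, TREAT x TIME, plus a
    log-library-size offset (centred on the median library). The
    zero-inflation component is intercept-only with a logit link. The
    two-sided Wald p for the interaction coefficient is returned. If the
    estimated zero-inflation probability collapses to the zero boundary or
    the ZINB fit fails, the model is refit as a plain negative binomial and
    flagged.

    ``round_counts`` rounds real-valued (pre-normalised) inputs so a count
    likelihood applies; the recommended route is raw counts + offset.
    """
    y = np.asarray(y, dtype=float)
    if round_counts:
        y = np.round(y)
    if not np.allclose(y, np.round(y)):
        raise ValueError("counts must be integers (use round_counts for normalized tables)")
    y = y.astype(int)
    if len(y) < 8:
        raise ValueError("need at least 8 samples")
    X = _design_from_meta(meta)
    for col in ("TREAT", "TIME"):
        if X[col].nunique() < 2:
            raise ValueError(f"{col} has a single level")
    if library_sizes is not None:
        ls = np.asarray(library_sizes, dtype=float)
        if (ls <= 0).any():
            raise ValueError("library sizes must be positive")
        offset = np.log(ls) - np.log(np.median(ls))
    else:
        offset = np.zeros(len(y))

    names = list(X.columns)
    exog = X.to_numpy()

    def _nb_fallback() -> ZINBFit:
        nb = NegativeBinomial(y, exog, offset=offset, loglike_method="nb2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = nb.fit(disp=0, maxiter=200)
            except Exception:
                return _failed()
        if not np.all(np.isfinite(res.bse[: len(names)])):
            return _failed()
        coef = pd.Series(res.params[: len(names)], index=names)
        se = pd.Series(res.bse[: len(names)], index=names)
        zi = coef["TREAT_x_TIME"] / se["TREAT_x_TIME"]
        return ZINBFit(
            coefficients=coef,
            se=se,
            zero_inflation_prob=0.0,
            dispersion_alpha=float(res.params[-1]),
            interaction_p=float(2 * stats.norm.sf(abs(zi))),
            converged=bool(res.mle_retvals.get("converged", True)),
            nb_fallback=True,
            loglike=float(res.llf),
        )

    def _failed() -> ZINBFit:
        nan = pd.Series(np.nan, index=names)
        return ZINBFit(nan, nan, np.nan, np.nan, np.nan, converged=False, nb_fallback=True)

    model = ZeroInflatedNegativeBinomialP(
        y, exog, exog_infl=np.ones((len(y), 1)), offset=offset, p=2
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
        except Exception:
            res = None
    if res is None or not np.all(np.isfinite(res.params)):
        return _nb_fallback()
    pi = float(stats.logistic.cdf(res.params[0]))
    k = 1 + len(names)  # infl const + count params; last param is alpha
    bse = res.bse
    if pi < 1e-4 or not np.all(np.isfinite(bse[1:k])):
        return _nb_fallback()
    coef = pd.Series(res.params[1:k], index=names)
    se = pd.Series(bse[1:k], index=names)
    zi = coef["TREAT_x_TIME"] / se["TREAT_x_TIME"]
    return ZINBFit(
        coefficients=coef,
        se=se,
        zero_inflation_prob=pi,
        dispersion_alpha=float(res.params[-1]),
        interaction_p=float(2 * stats.norm.sf(abs(zi))),
        converged=bool(res.mle_retvals.get("converged", True)),
        nb_fallback=False,
        loglike=float(res.llf),
    )


def differential_abundance(
    tbl: TaxaTable,
    use_offset: bool = True,
) -> pd.DataFrame:
    """ZINB interaction test per taxon with BH FDR across taxa.

    Expects a raw-count table (offset handles library size). Returns a
    table with the interaction estimate, SE, p, FDR q and fit flags, sorted
    by q then p.
    """
    lib = tbl.library_sizes if use_offset else None
    rows = []
    for taxon in tbl.counts.index:
        try:
            fit = fit_zinb_interaction(
                tbl.counts.loc[taxon], tbl.sample_meta.loc[tbl.counts.columns], lib
            )
        except ValueError as e:
            logger.warning("taxon %s skipped: %s", taxon, e)
            continue
        rows.append(
            {
                "taxon": taxon,
                "taxonomy": tbl.taxonomy.get(taxon, ""),
                "beta_interaction": float(fit.coefficients["TREAT_x_TIME"]),
                "se": float(fit.se["TREAT_x_TIME"]),
                "p": fit.interaction_p,
                "zero_inflation": fit.zero_inflation_prob,
                "converged": fit.converged,
                "nb_fallback": fit.nb_fallback,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["fdr_q", "p"]).reset_index(drop=True)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaN entries propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] <= 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def alpha_diversity(counts: np.ndarray | pd.Series, index: str = "shannon") -> float:
    """Shannon H = -sum p ln p (natural log) or Simpson 1 - sum p^2."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    p = c[c > 0] / total
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    if index == "simpson":
        return float(1.0 - (p**2).sum())
    raise ValueError(f"unknown index {index!r}; valid: shannon, simpson")


def beta_diversity_pcoa(
    tbl: TaxaTable,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Bray-Curtis dissimilarities embedded by classical PCoA.

    Returns (distance matrix, coordinates, eigenvalues). Negative
    eigenvalues of the double-centred Gram matrix are reported as-is; axes
    are returned only for positive eigenvalues.
    """
    samples = list(tbl.counts.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    D = squareform(pdist(tbl.counts.to_numpy().T, metric="braycurtis"))
    J = np.eye(len(samples)) - np.ones((len(samples), len(samples))) / len(samples)
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    dist_df = pd.DataFrame(D, index=samples, columns=samples)
    coord_df = pd.DataFrame(
        coords, index=samples, columns=[f"PCo{i+1}" for i in range(int(pos.sum()))]
    )
    return dist_df, coord_df, evals


def diversity_tests(alpha_values: pd.DataFrame) -> pd.DataFrame:
    """Paired before/after Wilcoxon per intervention plus a Friedman test
    across the four treatment x time cells.

    ``alpha_values`` needs columns subject, TREAT, TIME, value with every
    subject measured in all four cells.
    """
    wide = alpha_values.pivot_table(
        index="subject", columns=["TREAT", "TIME"], values="value"
    )
    expected = {
        (t, ti)
        for t in alpha_values["TREAT"].unique()
        for ti in ("before", "after")
    }
    if len(expected) < 4 or set(wide.columns) != expected:
        raise ValueError(
            "broken pairing; incomplete treatment x time cells: "
            f"have {sorted(wide.columns)}"
        )
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"broken pairing; incomplete subjects: {missing}")
    rows = []
    for treat in wide.columns.get_level_values(0).unique():
        before = wide[(treat, "before")]
        after = wide[(treat, "after")]
        diff = after - before
        if np.allclose(diff, 0):
            rows.append({"test": f"wilcoxon_{treat}", "statistic": 0.0, "p": 1.0})
            continue
        stat, p = stats.wilcoxon(before, after)
        rows.append({"test": f"wilcoxon_{treat}", "statistic": float(stat), "p": float(p)})
    cells = [wide[c].to_numpy() for c in wide.columns]
    if all(np.allclose(c, cells[0]) for c in cells[1:]):
        rows.append({"test": "friedman", "statistic": 0.0, "p": 1.0})
    else:
        stat, p = stats.friedmanchisquare(*cells)
        rows.append({"test": "friedman", "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)
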