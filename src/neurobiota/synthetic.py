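"""Ground-truthed synthetic data for every stage of the pipeline.

Three generators emulate the study's data-generating processes:

* a multi-subject crossover BOLD study on a small isotropic grid with
  planted cluster activations (ME-MS amplitude and a treatment x (ME-MS)
  interaction amplitude per blob), per-subject random effects, linear
  drift and white Gaussian noise;
* a space-filling synthetic atlas (nearest-seed-point regions) standing in
  for an anatomical parcellation;
* paired two-treatment x two-timepoint zero-inflated negative binomial
  taxa count tables with planted interaction taxa;
* paired measurements (cortisol/VAS stand-ins) with a chosen noise family.

All generators are pure functions of their spec plus seed and return the
ground truth needed to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .glm import BoldImage
from .microbiome import TaxaTable
from .paradigm import HRFParams, TaskDesign, build_eat_design
from .glm import build_design_matrix

__all__ = [
    "BoldSimSpec",
    "CountSimSpec",
    "box_blob",
    "simulate_bold_study",
    "simulate_atlas",
    "simulate_intervention_series",
    "simulate_taxa_counts",
    "simulate_paired_measures",
]

DEFAULT_TR_S = 2.5
DEFAULT_N_VOLUMES = 192


def box_blob(origin: tuple[int, int, int], shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel coordinates of a rectangular blob."""
    gi, gj, gk = np.meshgrid(
        *[np.arange(o, o + s) for o, s in zip(origin, shape)], indexing="ij"
    )
    return np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1)


def _default_blobs() -> list[tuple[np.ndarray, float, float]]:
    # two well-separated 40-voxel (2x4x5) blobs; (coords, beta5, beta7)
    return [
        (box_blob((3, 3, 3), (2, 4, 5)), 2.0, 0.3),
        (box_blob((13, 12, 11), (2, 4, 5)), 2.0, 0.3),
    ]


@dataclass
class BoldSimSpec:
    """Parameters of the crossover BOLD study generator.

    ``planted_clusters`` is a list of (voxel coords, beta5 amplitude,
    beta7 amplitude). ``subject_sd`` gives the between-subject SDs of the
    (ME+MS, ME-MS, TREAT, TREAT x (ME-MS)) slopes.
    """

    shape: tuple[int, int, int] = (20, 20, 20)
    tr_s: float = DEFAULT_TR_S
    n_volumes: int = DEFAULT_N_VOLUMES
    n_subjects: int = 12
    planted_clusters: list[tuple[np.ndarray, float, float]] = field(
        default_factory=_default_blobs
    )
    baseline: float = 100.0
    drift_slope: float = 1.0
    beta4: float = 1.0
    beta6: float = 0.0
    noise_sd: float = 1.0
    subject_sd: tuple[float, float, float, float] = (0.5, 0.3, 0.5, 0.0)
    voxel_size_mm: float = 3.0
    hrf: HRFParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        upper = np.array(self.shape)
        for coords, b5, b7 in self.planted_clusters:
            coords = np.asarray(coords)
            if (coords < 0).any() or (coords >= upper).any():
                raise ValueError("planted blob extends outside the grid")
            if not (np.isfinite(b5) and np.isfinite(b7)):
                raise ValueError("blob amplitudes must be finite")


def _crossover_metadata(n_subjects: int) -> pd.DataFrame:
    """Balanced crossover: first half gets placebo in session 1."""
    rows = []
    for i in range(n_subjects):
        arm = i % 2  # alternate arms for balance
        for session in (1, 2):
            treat = arm if session == 1 else 1 - arm
            rows.append(
                {"subject": f"sub-{i:02d}", "session": session, "treatment": treat}
            )
    return pd.DataFrame(rows)


def simulate_bold_study(
    spec: BoldSimSpec, design: TaskDesign | None = None
) -> tuple[dict[tuple[str, int], BoldImage], pd.DataFrame, dict]:
    """Generate per subject x session BOLD images plus ground truth.

    The signal at a planted voxel follows the intervention model: baseline
    + drift + (b4 + b4_i)*(ME+MS) + (b5 + b5_i + (b7 + b7_i)*TREAT)*(ME-MS)
    + (b6 + b6_i)*TREAT + white noise; voxels outside blobs carry baseline,
    drift and noise only.

    Returns (images keyed by (subject, session), metadata, truth dict with
    the blob masks, amplitudes, subject effects and the design matrix).
    """
    rng = np.random.default_rng(spec.seed)
    design = design or build_eat_design()
    X = build_design_matrix(design, spec.tr_s, spec.n_volumes, spec.hrf)
    drift = X["drift_t"].to_numpy()
    me_plus = X["ME_plus_MS"].to_numpy()
    me_minus = X["ME_minus_MS"].to_numpy()
    meta = _crossover_metadata(spec.n_subjects)
    sd4, sd5, sd6, sd7 = spec.subject_sd
    subj_ids = meta["subject"].unique()
    effects = pd.DataFrame(
        {
            "subject": subj_ids,
            "b4": rng.normal(0, sd4, len(subj_ids)),
            "b5": rng.normal(0, sd5, len(subj_ids)),
            "b6": rng.normal(0, sd6, len(subj_ids)),
            "b7": rng.normal(0, sd7, len(subj_ids)),
        }
    )
    eff = effects.set_index("subject")
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    images: dict[tuple[str, int], BoldImage] = {}
    base = spec.baseline + spec.drift_slope * drift
    for row in meta.itertuples():
        treat = row.treatment
        vol = np.empty((*spec.shape, spec.n_volumes), dtype=np.float32)
        background = base + (spec.beta6 + eff.loc[row.subject, "b6"]) * treat
        vol[...] = background.astype(np.float32)
        for coords, b5, b7 in spec.planted_clusters:
            c = np.asarray(coords)
            task = (spec.beta4 + eff.loc[row.subject, "b4"]) * me_plus + (
                b5 + eff.loc[row.subject, "b5"] + (b7 + eff.loc[row.subject, "b7"]) * treat
            ) * me_minus
            vol[c[:, 0], c[:, 1], c[:, 2], :] += task.astype(np.float32)
        vol += rng.normal(0, spec.noise_sd, vol.shape).astype(np.float32)
        images[(row.subject, row.session)] = BoldImage(vol, affine, spec.tr_s)
    truth = {
        "blobs": [
            {"coords": np.asarray(c), "beta5": b5, "beta7": b7}
            for c, b5, b7 in spec.planted_clusters
        ],
        "subject_effects": effects,
        "design_matrix": X,
        "seed": spec.seed,
    }
    return images, meta, truth


def simulate_atlas(
    shape: tuple[int, int, int], n_regions: int, seed: int = 0
) -> np.ndarray:
    """Space-filling integer parcellation: every voxel gets the label of its
    nearest of ``n_regions`` random seed points (labels 1..n_regions)."""
    n_voxels = int(np.prod(shape))
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > n_voxels:
        raise ValueError(f"n_regions={n_regions} exceeds voxel count {n_voxels}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_voxels, size=n_regions, replace=False)
    seeds = np.stack(np.unravel_index(flat, shape), axis=1)
    grid = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    _, nearest = cKDTree(seeds).query(grid)
    return (nearest + 1).reshape(shape).astype(np.int32)


def simulate_intervention_series(
    n_subjects: int = 12,
    beta5: float = 1.0,
    beta7: float = 0.3,
    beta4: float = 1.0,
    beta6: float = 0.5,
    baseline: float = 100.0,
    drift_slope: float = 1.0,
    subject_sd: tuple[float, float, float, float] = (0.5, 0.3, 0.5, 0.0),
    noise_sd: float = 1.0,
    tr_s: float = DEFAULT_TR_S,
    n_volumes: int = DEFAULT_N_VOLUMES,
    design: TaskDesign | None = None,
    hrf: HRFParams | None = None,
    seed: int = 0,
) -> tuple[dict[tuple[str, int], np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Generate sub-cluster mean timecourses directly from the intervention
    model — the region-level counterpart of :func:`simulate_bold_study`.

    Returns (timecourses keyed by (subject, session), metadata, design
    matrix) ready for ``assemble_long_table``.
    """
    rng = np.random.default_rng(seed)
    design = design or build_eat_design()
    X = build_design_matrix(design, tr_s, n_volumes, hrf)
    drift = X["drift_t"].to_numpy()
    me_plus = X["ME_plus_MS"].to_numpy()
    me_minus = X["ME_minus_MS"].to_numpy()
    meta = _crossover_metadata(n_subjects)
    sd4, sd5, sd6, sd7 = subject_sd
    series: dict[tuple[str, int], np.ndarray] = {}
    for subject in meta["subject"].unique():
        b4, b5, b6, b7 = (
            rng.normal(0, sd4),
            rng.normal(0, sd5),
            rng.normal(0, sd6),
            rng.normal(0, sd7),
        )
        for session in (1, 2):
            treat = int(
                meta.query("subject == @subject and session == @session")["treatment"].iloc[0]
            )
            y = (
                baseline
                + drift_slope * drift
                + (beta4 + b4) * me_plus
                + (beta5 + b5 + (beta7 + b7) * treat) * me_minus
                + (beta6 + b6) * treat
                + rng.normal(0, noise_sd, n_volumes)
            )
            series[(subject, session)] = y
    return series, meta, X


def _default_taxonomy(i: int) -> str:
    return (
        f"Bacteria;Phylum_{i % 4};Class_{i % 6};Order_{i % 10};"
        f"Family_{i % 15};Genus_{i % 25};Species_{i}"
    )


@dataclass
class CountSimSpec:
    """Parameters of the paired zero-inflated taxa count generator.

    Each subject contributes 4 samples (2 treatments x 2 timepoints).
    ``planted_taxa`` lists (taxon index, interaction log fold effect).
    """

    n_subjects: int = 22
    n_taxa: int = 40
    baseline_logmean_mu: float = 3.0
    baseline_logmean_sd: float = 1.5
    dispersion: float = 1.0  # NB size k; variance = mu + mu^2 / k
    zero_inflation: float = 0.15
    beta_treat: float = 0.0
    beta_time: float = 0.0
    planted_taxa: list[tuple[int, float]] = field(default_factory=list)
    library_size_range: tuple[int, int] = (15_000, 45_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for idx, _ in self.planted_taxa:
            if not 0 <= idx < self.n_taxa:
                raise ValueError(f"planted taxon index {idx} out of range")


def simulate_taxa_counts(spec: CountSimSpec) -> tuple[TaxaTable, pd.DataFrame]:
    """Draw a crossover taxa count table from the ZINB generative model.

    log-mean = taxon baseline + b1*TREAT + b2*TIME + b3*TREAT*TIME
    + log(library/median library); counts are NB draws zeroed with
    probability pi. Returns the table and a truth dict with per-taxon
    effects and the drawn library sizes.
    """
    rng = np.random.default_rng(spec.seed)
    planted = dict(spec.planted_taxa)
    base = rng.normal(spec.baseline_logmean_mu, spec.baseline_logmean_sd, spec.n_taxa)
    rows = []
    meta_rows = []
    sample_ids = []
    libs = []
    for s in range(spec.n_subjects):
        for treat_name, treat in (("placebo", 0), ("probiotics", 1)):
            for time_name, time in (("before", 0), ("after", 1)):
                sid = f"S{s:02d}_{treat_name}_{time_name}"
                sample_ids.append(sid)
                libs.append(rng.integers(*spec.library_size_range))
                meta_rows.append(
                    {
                        "sample": sid,
                        "subject": f"S{s:02d}",
                        "TREAT": treat_name,
                        "TIME": time_name,
                        "_treat": treat,
                        "_time": time,
                    }
                )
    libs = np.array(libs, dtype=float)
    lib_factor = np.log(libs) - np.log(np.median(libs))
    meta = pd.DataFrame(meta_rows).set_index("sample")
    counts = np.zeros((spec.n_taxa, len(sample_ids)), dtype=np.int64)
    k = spec.dispersion
    for t in range(spec.n_taxa):
        b3 = planted.get(t, 0.0)
        logmu = (
            base[t]
            + spec.beta_treat * meta["_treat"].to_numpy()
            + spec.beta_time * meta["_time"].to_numpy()
            + b3 * (meta["_treat"] * meta["_time"]).to_numpy()
            + lib_factor
        )
        mu = np.exp(logmu)
        draw = rng.negative_binomial(k, k / (k + mu))
        if spec.zero_inflation > 0:
            draw = np.where(rng.random(len(mu)) < spec.zero_inflation, 0, draw)
        counts[t] = draw
    index = [f"taxon_{t:03d}" for t in range(spec.n_taxa)]
    table = TaxaTable(
        counts=pd.DataFrame(counts, index=index, columns=sample_ids),
        taxonomy=pd.Series([_default_taxonomy(t) for t in range(spec.n_taxa)], index=index),
        sample_meta=meta.drop(columns=["_treat", "_time"]),
    )
    truth = {
        "taxa": pd.DataFrame(
            {
                "taxon": index,
                "baseline_logmean": base,
                "beta_interaction": [planted.get(t, 0.0) for t in range(spec.n_taxa)],
            }
        ),
        "library_sizes": pd.Series(libs, index=sample_ids, name="library_size"),
        "seed": spec.seed,
    }
    return table, truth


def simulate_paired_measures(
    n_subjects: int,
    effect: float,
    sd: float,
    distribution: str = "normal",
    baseline_mu: float = 10.0,
    baseline_sd: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired before/after measurements with a planted shift.

    ``distribution`` chooses the noise family of the paired differences:
    'normal' or 'lognormal' (right-skewed, mean-centred).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    a = rng.normal(baseline_mu, baseline_sd, n_subjects)
    if distribution == "normal":
        noise = rng.normal(0, sd, n_subjects)
    elif distribution == "lognormal":
        raw = rng.lognormal(0.0, 1.0, n_subjects)
        noise = sd * (raw - np.exp(0.5))
    else:
        raise ValueError(f"unknown distribution {distribution!r}; valid: normal, lognormal")
    b = a + effect + noise
    return pd.DataFrame(
        {"subject": [f"S{i:02d}" for i in range(n_subjects)], "value_a": a, "value_b": b}
    )
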