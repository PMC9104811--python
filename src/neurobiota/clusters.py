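"""Atlas-resolved sub-cluster definition from ME-MS significance maps.

Voxels whose ME-MS p-value falls below a nominal threshold are grouped by
density-based clustering (DBSCAN, eps = 1.5 voxels, minPts = 10) in voxel
index space; eps = 1.5 links face and edge neighbours but not corner
neighbours. Clusters spanning several atlas regions are split into
sub-clusters, each confined to a single region; each sub-cluster gets a
peak (the most significant voxel) and a mean timecourse used downstream by
the intervention and connectivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .glm import BoldImage, StatMap
from .paradigm import RegressorSeries

__all__ = [
    "SubCluster",
    "threshold_pmap",
    "dbscan_voxels",
    "split_by_atlas",
    "find_peak",
    "extract_mean_timecourse",
    "assert_isotropic",
    "subcluster_table",
]

logger = logging.getLogger(__name__)

DEFAULT_EPS = 1.5
DEFAULT_MIN_PTS = 10


@dataclass
class SubCluster:
    """Voxels of one cluster restricted to a single atlas region."""

    voxels: np.ndarray  # (n, 3) int indices
    atlas_label: int
    peak_ijk: tuple[int, int, int] | None = None
    peak_xyz: tuple[float, float, float] | None = None
    size_mm3: float | None = None
    min_p: float | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def assert_isotropic(affine: np.ndarray, tol: float = 1e-3) -> float:
    """Voxel-space clustering assumes an isotropic grid; reject otherwise.

    Returns the (scalar) voxel edge length in mm.
    """
    zooms = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    if np.ptp(zooms) > tol:
        raise ValueError(
            f"anisotropic voxel grid {zooms}; resample to an isotropic grid "
            "(e.g. 3x3x3 mm) before clustering"
        )
    return float(zooms[0])


def threshold_pmap(pmap: StatMap, p_crit: float) -> np.ndarray:
    """Voxel indices with p strictly below ``p_crit`` (inside the mask)."""
    if not 0 < p_crit < 1:
        raise ValueError("p_crit must lie in (0, 1)")
    hit = pmap.mask & (pmap.data < p_crit)
    return np.argwhere(hit)


def dbscan_voxels(
    coords: np.ndarray,
    eps: float = DEFAULT_EPS,
    min_pts: int = DEFAULT_MIN_PTS,
) -> list[np.ndarray]:
    """DBSCAN over voxel index coordinates with Euclidean distance.

    A core voxel needs >= ``min_pts`` voxels (itself included) within
    ``eps``. Noise voxels are discarded. Coordinates are sorted
    lexicographically first so border-point assignment is deterministic.
    Clusters are returned sorted by size, largest first.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    coords = np.asarray(coords, dtype=int)
    if coords.size == 0:
        return []
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    coords = coords[order]
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords.astype(float))
    clusters = [coords[labels == k] for k in range(labels.max() + 1)]
    # size-descending; ties broken by smallest first voxel for determinism
    clusters.sort(key=lambda c: (-len(c), tuple(c[0])))
    return clusters


def split_by_atlas(cluster: np.ndarray, atlas: np.ndarray) -> list[SubCluster]:
    """Partition a cluster's voxels by atlas label; background (label <= 0)
    voxels are dropped with a warning."""
    cluster = np.asarray(cluster, dtype=int)
    atlas = np.asarray(atlas)
    labels = atlas[cluster[:, 0], cluster[:, 1], cluster[:, 2]]
    n_bg = int((labels <= 0).sum())
    if n_bg:
        logger.warning("dropping %d cluster voxels on atlas background", n_bg)
    out = []
    for lab in np.unique(labels[labels > 0]):
        out.append(SubCluster(voxels=cluster[labels == lab], atlas_label=int(lab)))
    return out


def find_peak(sc: SubCluster, pmap: StatMap) -> tuple[int, int, int]:
    """The sub-cluster voxel with minimum p; ties resolved by lowest
    (i, j, k) in lexicographic order."""
    v = sc.voxels
    p = pmap.data[v[:, 0], v[:, 1], v[:, 2]]
    best = p.min()
    tied = v[p == best]
    order = np.lexsort((tied[:, 2], tied[:, 1], tied[:, 0]))
    peak = tuple(int(x) for x in tied[order[0]])
    sc.peak_ijk = peak
    sc.min_p = float(best)
    return peak


def extract_mean_timecourse(bold: BoldImage, sc: SubCluster) -> RegressorSeries:
    """Mean BOLD signal across the sub-cluster's voxels at each volume."""
    v = sc.voxels
    if (v < 0).any() or (v >= np.array(bold.data.shape[:3])).any():
        raise ValueError("sub-cluster voxels outside the BOLD grid")
    series = bold.data[v[:, 0], v[:, 1], v[:, 2]].mean(axis=0)
    return RegressorSeries(series, bold.tr_s, label=f"region{sc.atlas_label}")


def annotate(sc: SubCluster, pmap: StatMap, affine: np.ndarray) -> SubCluster:
    """Fill peak, world coordinates and volume on a sub-cluster in place."""
    find_peak(sc, pmap)
    ijk = np.array([*sc.peak_ijk, 1.0])
    sc.peak_xyz = tuple(float(x) for x in (np.asarray(affine) @ ijk)[:3])
    edge = assert_isotropic(affine)
    sc.size_mm3 = sc.n_voxels * edge**3
    return sc


def subcluster_table(subclusters: list[SubCluster]) -> pd.DataFrame:
    """Tabular summary: label, size, peak indices and world coordinates, min p."""
    rows = []
    for sc in subclusters:
        pi, pj, pk = sc.peak_ijk if sc.peak_ijk else (None, None, None)
        px, py, pz = sc.peak_xyz if sc.peak_xyz else (None, None, None)
        rows.append(
            {
                "atlas_label": sc.atlas_label,
                "n_voxels": sc.n_voxels,
                "size_mm3": sc.size_mm3,
                "peak_i": pi,
                "peak_j": pj,
                "peak_k": pk,
                "peak_x_mm": px,
                "peak_y_mm": py,
                "peak_z_mm": pz,
                "min_p": sc.min_p,
            }
        )
    return pd.DataFrame(rows)


def cluster_label_volume(
    subclusters: list[SubCluster], shape: tuple[int, int, int]
) -> np.ndarray:
    """Integer volume with sub-cluster ordinal (1-based) at each voxel."""
    vol = np.zeros(shape, dtype=np.int32)
    for idx, sc in enumerate(subclusters, start=1):
        v = sc.voxels
        vol[v[:, 0], v[:, 1], v[:, 2]] = idx
    return vol
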