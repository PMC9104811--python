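"""NIfTI and configuration I/O."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .glm import BoldImage, StatMap
from .paradigm import HRFParams

__all__ = [
    "read_bold",
    "read_volume",
    "write_nifti",
    "PipelineConfig",
]


def read_bold(path: str | Path) -> BoldImage:
    """Read a 4-D BOLD NIfTI; TR is taken from the header's time zoom."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4-D BOLD, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldImage(data=data, affine=img.affine, tr_s=tr_s)


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D volume (mask, atlas or stat map); returns (data, affine)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got shape {data.shape}")
    return data, img.affine


def _load(path: str | Path):
    try:
        return nib.load(str(path))
    except Exception as e:  # nibabel raises several header error types
        raise ValueError(f"cannot read NIfTI {path}: {e}") from e


def write_nifti(
    obj: BoldImage | StatMap | np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    tr_s: float | None = None,
) -> None:
    """Write an image as NIfTI-1.

    Stat maps go out as 32-bit float with their own affine; integer arrays
    (atlas/cluster labels) keep an integer dtype; BOLD keeps its TR in the
    header time zoom.
    """
    if isinstance(obj, BoldImage):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = obj.tr_s
        img.header.set_zooms(zooms)
    elif isinstance(obj, StatMap):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.affine)
    else:
        arr = np.asarray(obj)
        if affine is None:
            raise ValueError("affine required for raw arrays")
        dtype = np.int32 if np.issubdtype(arr.dtype, np.integer) else np.float32
        img = nib.Nifti1Image(arr.astype(dtype), affine)
        if arr.ndim == 4 and tr_s:
            zooms = list(img.header.get_zooms())
            zooms[3] = tr_s
            img.header.set_zooms(zooms)
    nib.save(img, str(path))


@dataclass
class PipelineConfig:
    """All pipeline parameters with the study's printed defaults.

    Round-trips losslessly through YAML; a stable hash of the contents is
    embedded in every output for provenance.
    """

    # paths (None = simulate inputs)
    bold_dir: str | None = None
    atlas_path: str | None = None
    mask_path: str | None = None
    counts_path: str | None = None
    out_dir: str = "neurobiota_out"
    # stage parameters
    p_crit: float = 1e-6  # nominal voxel threshold (printed value was 1e-50)
    eps: float = 1.5
    min_pts: int = 10
    band_lo_hz: float = 0.008
    band_hi_hz: float = 0.09
    q_fdr: float = 0.05
    max_absent_frac: float = 0.85
    alpha: float = 0.05
    n_rois: int = 10
    hrf: dict = field(default_factory=lambda: asdict(HRFParams()))
    # synthetic-study knobs
    n_subjects: int = 12
    n_regions: int = 24
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hrf_params(self) -> HRFParams:
        return HRFParams(**self.hrf)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
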