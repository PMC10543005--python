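"""Neuromarker and ROI responses from contrast maps.

A *signature score* is the masked dot product of a participant's contrast map
with a multivariate weight map; an *ROI response* is the arithmetic mean of
the contrast over a region mask; a *local pattern response* restricts the dot
product to one labelled subregion of the signature.  For negative-weight
subregions a more positive response corresponds to deactivation of the
underlying voxels — the sign convention is carried in the record.

Maps and signatures must live on the same voxel grid: there is no implicit
resampling anywhere in this module (a silent regrid would change every dot
product).  An explicit, user-invoked :func:`regrid` utility is provided for
the rare case where resampling is genuinely wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VolumeMap",
    "SignatureMap",
    "GridMismatchError",
    "signature_score",
    "roi_mean",
    "local_pattern_response",
    "zscore_within",
    "regrid",
    "load_volume",
    "load_signature",
]


class GridMismatchError(ValueError):
    """Shapes or affines differ between a map and a signature/ROI."""


@dataclass
class VolumeMap:
    """A masked 3-D volume with its affine."""

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3 or self.mask.shape != self.values.shape:
            raise ValueError("values must be 3-D with a mask of the same shape")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside the mask")


@dataclass
class SignatureMap(VolumeMap):
    """Weight volume with an integer subregion atlas and per-label signs."""

    subregions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    subregion_signs: dict[int, int] = field(default_factory=dict)

    # alias: the volume's values are the pattern weights
    @property
    def weights(self) -> np.ndarray:
        return self.values

    def __post_init__(self) -> None:
        super().__post_init__()
        self.subregions = np.asarray(self.subregions)
        if self.subregions.shape != self.values.shape:
            raise ValueError("subregion atlas must match the weight grid")
        if np.any((self.subregions > 0) & ~self.mask):
            raise ValueError("subregions must lie inside the signature mask")
        for label, sign in self.subregion_signs.items():
            w = self.values[self.subregions == label]
            if w.size and np.min(sign * w) < 0:
                raise ValueError(f"subregion {label} weights contradict its sign")

    def labels(self) -> list[int]:
        return sorted(int(l) for l in np.unique(self.subregions) if l != 0)


def _check_same_grid(a: VolumeMap, b: VolumeMap, atol: float = 1e-4) -> None:
    if a.values.shape != b.values.shape:
        raise GridMismatchError(
            f"grid shapes differ: {a.values.shape} vs {b.values.shape}"
        )
    if not np.allclose(a.affine, b.affine, atol=atol):
        raise GridMismatchError("affines differ beyond tolerance; no silent resampling")


def signature_score(vmap: VolumeMap, signature: SignatureMap) -> float:
    """Dot product of the map with the signature over the joint mask."""
    _check_same_grid(vmap, signature)
    joint = vmap.mask & signature.mask
    if not joint.any():
        raise ValueError("map and signature masks do not intersect")
    return float(
        np.sum(vmap.values[joint].astype(float) * signature.values[joint].astype(float))
    )


def roi_mean(vmap: VolumeMap, roi_mask: np.ndarray) -> float:
    """Mean contrast value over the ROI voxels inside the map mask."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != vmap.values.shape:
        raise GridMismatchError("ROI mask shape does not match the map grid")
    joint = roi_mask & vmap.mask
    if not joint.any():
        raise ValueError("ROI does not intersect the map mask")
    return float(np.mean(vmap.values[joint].astype(float)))


def local_pattern_response(vmap: VolumeMap, signature: SignatureMap, label: int) -> float:
    """Dot product restricted to one labelled signature subregion.

    For a negative-weight subregion a more positive response means the
    underlying activity is more *negative* (deactivation).
    """
    _check_same_grid(vmap, signature)
    if label not in signature.labels():
        raise KeyError(f"unknown subregion label {label!r}")
    sel = (signature.subregions == label) & vmap.mask
    if not sel.any():
        raise ValueError(f"subregion {label} does not intersect the map mask")
    return float(
        np.sum(vmap.values[sel].astype(float) * signature.values[sel].astype(float))
    )


def zscore_within(
    records: pd.DataFrame,
    group_keys: list[str],
    value_col: str = "score",
    out_col: str | None = None,
) -> pd.DataFrame:
    """Standardize ``value_col`` to mean 0 / sample SD 1 within each group.

    Sample SD uses the n-1 denominator.  A group with fewer than two distinct
    values cannot be standardized and raises, naming the group.
    """
    out_col = out_col or value_col
    result = records.copy()

    def _z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            key = records.loc[s.index[0], group_keys].tolist()
            raise ValueError(f"constant group {dict(zip(group_keys, key))}: cannot z-score")
        return (s - s.mean()) / sd

    result[out_col] = records.groupby(group_keys, sort=False)[value_col].transform(_z)
    return result


def regrid(vmap: VolumeMap, target: VolumeMap, order: int = 1) -> VolumeMap:
    """Explicitly resample ``vmap`` onto ``target``'s grid (never implicit).

    ``order`` 0 = nearest neighbour, 1 = trilinear.  Values outside the
    source grid become 0 and fall outside the resampled mask.
    """
    from scipy.ndimage import map_coordinates

    src_inv = np.linalg.inv(vmap.affine)
    tgt_shape = target.values.shape
    ijk = np.indices(tgt_shape).reshape(3, -1)
    homog = np.vstack([ijk, np.ones(ijk.shape[1])])
    src_ijk = (src_inv @ target.affine @ homog)[:3]

    values = map_coordinates(
        np.asarray(vmap.values, float), src_ijk, order=order, mode="constant", cval=0.0
    ).reshape(tgt_shape)
    mask = (
        map_coordinates(
            vmap.mask.astype(float), src_ijk, order=0, mode="constant", cval=0.0
        ).reshape(tgt_shape)
        > 0.5
    )
    warnings.warn("explicit regrid applied; dot products are not preserved", stacklevel=2)
    return VolumeMap(values=values, affine=target.affine.copy(), mask=mask)


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path: str | Path, mask: np.ndarray | None = None) -> VolumeMap:
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj, dtype=np.float32)
    if mask is None:
        mask = np.isfinite(values) & (values != 0)
        if not mask.any():
            mask = np.isfinite(values)
    return VolumeMap(values=values, affine=np.asarray(img.affine), mask=mask)


def load_signature(directory: str | Path, name: str = "signature") -> SignatureMap:
    """Load weights + atlas + legend written by ``synth.write_signature``."""
    import json

    import nibabel as nib

    directory = Path(directory)
    w_img = nib.load(str(directory / f"{name}_weights.nii"))
    atlas = np.asanyarray(
        nib.load(str(directory / f"{name}_atlas.nii")).dataobj
    ).astype(np.int16)
    legend = json.loads((directory / f"{name}_legend.json").read_text())
    weights = np.asanyarray(w_img.dataobj, dtype=np.float32)
    return SignatureMap(
        values=weights,
        affine=np.asarray(w_img.affine),
        mask=atlas > 0,
        subregions=atlas,
        subregion_signs={int(k): int(v) for k, v in legend.items()},
    )
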