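"""Correlation-based QC maps: global correlation (GCOR), corr_brain, radial
correlation (radcor), seed-based correlation, and mask Dice overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import Dataset3D, Dataset4D, Mask3D

log = logging.getLogger(__name__)

__all__ = [
    "CorrMap",
    "compute_gcor",
    "compute_corr_brain",
    "compute_radcor",
    "compute_seed_corr",
    "dice_coefficient",
    "DEFAULT_RADCOR_FWHM",
]

DEFAULT_RADCOR_FWHM = 20.0  # mm

# default transparent / range thresholds for rendering correlation maps
CORR_THRESHOLD = 0.3
CORR_RANGE = 0.6


@dataclass
class CorrMap:
    """A 3D correlation map with rendering metadata."""

    values: np.ndarray
    kind: str  # corr_brain | radcor | seed
    affine: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    seed_coord: tuple | None = None  # mm
    stage: str = ""
    render: dict = field(default_factory=lambda: {
        "threshold": CORR_THRESHOLD, "range": CORR_RANGE})

    def as_dataset(self) -> Dataset3D:
        return Dataset3D(self.values, self.voxel_size, self.affine)


def _unit_series(dset: Dataset4D, mask: Mask3D):
    """Demeaned, unit-norm in-mask series plus the kept-voxel mask rows."""
    data = dset.values[mask.values].astype(float)  # (n_vox, T)
    data = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((data ** 2).sum(axis=1))
    keep = norms > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("excluding %d zero-variance voxels", n_dropped)
    return data[keep] / norms[keep, None], keep


def compute_gcor(dset: Dataset4D, mask: Mask3D) -> float:
    """Global correlation: the average of all pairwise correlations of
    in-mask series (self-pairs included).

    Computed as the squared norm of the mean of the demeaned, unit-norm
    series, an O(N*T) identity for the O(N^2) definition.
    """
    if dset.n_volumes < 3:
        raise ValueError("need at least 3 volumes for GCOR")
    unit, keep = _unit_series(dset, mask)
    if unit.shape[0] < 2:
        raise ValueError("need at least 2 in-mask voxels with nonzero variance")
    gmean = unit.mean(axis=0)
    return float((gmean ** 2).sum())


def _corr_with(dset: Dataset4D, mask: Mask3D, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of every in-mask voxel's series with ``ref``;
    zero-variance voxels get value 0."""
    data = dset.values[mask.values].astype(float)
    data = data - data.mean(axis=1, keepdims=True)
    ref = np.asarray(ref, float)
    ref = ref - ref.mean()
    refn = np.sqrt((ref ** 2).sum())
    norms = np.sqrt((data ** 2).sum(axis=1))
    out = np.zeros(data.shape[0])
    ok = (norms > 0) & (refn > 0)
    out[ok] = (data[ok] @ ref) / (norms[ok] * refn)
    vol = np.zeros(mask.shape)
    vol[mask.values] = np.clip(out, -1.0, 1.0)
    return vol


def compute_corr_brain(errts: Dataset4D, mask: Mask3D) -> CorrMap:
    """Correlation of each residual series with the in-mask mean residual."""
    gmean = errts.values[mask.values].mean(axis=0)
    vol = _corr_with(errts, mask, gmean)
    return CorrMap(vol, kind="corr_brain", affine=errts.affine,
                   voxel_size=errts.voxel_size, stage="regress")


def compute_radcor(dset: Dataset4D, mask: Mask3D,
                   fwhm: float = DEFAULT_RADCOR_FWHM, stage: str = "") -> CorrMap:
    """Radial correlation: each voxel's correlation with a Gaussian-weighted
    (FWHM in mm, default 20) average of its in-mask neighborhood.

    Smoothing is renormalized by the smoothed mask so edge voxels are not
    diluted by out-of-mask zeros; the center voxel is included in its own
    neighborhood average.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if fwhm < min(dset.voxel_size):
        log.warning("radcor fwhm %.3g mm below one voxel: near self-correlation", fwhm)
    sigma_vox = [fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
                 for v in dset.voxel_size]
    m = mask.values.astype(float)
    # zero-padded convolution so the mask-renormalized ratio is exactly the
    # Gaussian-weighted average over in-mask voxels (no boundary reflection)
    sm_mask = gaussian_filter(m, sigma_vox, mode="constant", cval=0.0)
    T = dset.n_volumes
    neigh = np.zeros_like(dset.values, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        for t in range(T):
            sm = gaussian_filter(dset.values[..., t] * m, sigma_vox,
                                 mode="constant", cval=0.0)
            neigh[..., t] = np.where(sm_mask > 1e-12, sm / sm_mask, 0.0)
    data = dset.values[mask.values].astype(float)
    ref = neigh[mask.values]
    data = data - data.mean(axis=1, keepdims=True)
    ref = ref - ref.mean(axis=1, keepdims=True)
    dn = np.sqrt((data ** 2).sum(axis=1))
    rn = np.sqrt((ref ** 2).sum(axis=1))
    ok = (dn > 0) & (rn > 0)
    r = np.zeros(data.shape[0])
    r[ok] = (data[ok] * ref[ok]).sum(axis=1) / (dn[ok] * rn[ok])
    vol = np.zeros(dset.shape[:3])
    vol[mask.values] = np.clip(r, -1.0, 1.0)
    return CorrMap(vol, kind="radcor", affine=dset.affine,
                   voxel_size=dset.voxel_size, stage=stage)


def compute_seed_corr(dset: Dataset4D, mask: Mask3D, seed_mm) -> CorrMap:
    """Correlation of every in-mask voxel with the series at a seed location
    given in mm; a seed falling outside the mask snaps to the nearest in-mask
    voxel (logged)."""
    inv = np.linalg.inv(dset.affine)
    ijk = (inv @ np.append(np.asarray(seed_mm, float), 1.0))[:3]
    ijk = np.round(ijk).astype(int)
    ijk = np.clip(ijk, 0, np.array(dset.shape[:3]) - 1)
    if not mask.values[tuple(ijk)]:
        coords = np.argwhere(mask.values)
        d2 = ((coords - ijk) ** 2).sum(axis=1)
        ijk = coords[np.argmin(d2)]
        log.warning("seed outside mask; snapped to nearest in-mask voxel %s", tuple(ijk))
    seed_series = dset.values[tuple(ijk) + (slice(None),)]
    vol = _corr_with(dset, mask, seed_series)
    return CorrMap(vol, kind="seed", affine=dset.affine,
                   voxel_size=dset.voxel_size,
                   seed_coord=tuple(dset.ijk_to_mm(ijk)))


def dice_coefficient(a: Mask3D, b: Mask3D) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|); two empty masks are an error."""
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValueError("both masks empty")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)
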