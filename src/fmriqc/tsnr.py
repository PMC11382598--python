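"""Temporal signal-to-noise maps at processing stages and the per-ROI
shape/TSNR table with graded warnings.

TSNR is mean(signal series) / sd(noise series) per voxel.  What counts as
signal and noise depends on the stage: after volume registration the signal
is the full series and the noise its detrended version; after regression the
signal is the full series and the noise the residual (errts) series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_cdt

from .io import Dataset3D, Dataset4D, Mask3D
from .warns import WarnLevel

__all__ = [
    "TsnrMap",
    "ROITableRow",
    "DEFAULT_ROI_WARN_THRESHOLDS",
    "compute_tsnr",
    "roi_depth",
    "roi_stats_table",
    "assign_roi_warn_levels",
]


@dataclass
class TsnrMap:
    values: np.ndarray
    stage: str  # volreg | regress
    affine: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    signal_source: str = ""
    noise_source: str = ""

    def as_dataset(self) -> Dataset3D:
        return Dataset3D(self.values, self.voxel_size, self.affine)


@dataclass
class ROITableRow:
    """Per-region shape and TSNR summary."""

    label: str
    nvox: int
    nzer: int
    dvox: int
    tmin: float
    t25: float
    tmed: float
    t75: float
    tmax: float
    max_depth_coord: tuple = (0.0, 0.0, 0.0)  # mm
    warns: dict = field(default_factory=dict)  # metric -> WarnLevel

    def __post_init__(self):
        if self.nzer > self.nvox:
            raise ValueError("nzer cannot exceed nvox")
        q = (self.tmin, self.t25, self.tmed, self.t75, self.tmax)
        if not all(a <= b + 1e-9 for a, b in zip(q, q[1:])):
            raise ValueError("TSNR quartiles must be nondecreasing")
        if self.nvox > 0 and self.dvox < 1:
            raise ValueError("dvox must be >= 1 for a nonempty ROI")


def compute_tsnr(signal: Dataset4D, noise: Dataset4D, mask: Mask3D,
                 stage: str = "regress") -> TsnrMap:
    """Voxelwise mean(signal)/sd(noise); zero-sd voxels get value 0."""
    if stage not in ("volreg", "regress"):
        raise ValueError("stage must be 'volreg' or 'regress'")
    if signal.shape != noise.shape:
        raise ValueError("signal and noise grids must match")
    mean = signal.values.mean(axis=3)
    sd = noise.values.std(axis=3, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsnr = np.where(sd > 0, mean / sd, 0.0)
    tsnr = np.where(mask.values, tsnr, 0.0)
    return TsnrMap(values=tsnr, stage=stage, affine=signal.affine,
                   voxel_size=signal.voxel_size)


def roi_depth(roi: Mask3D):
    """Maximum face-connected erosion depth of an ROI, and its location.

    Boundary voxels (face-adjacent to outside, including the volume edge)
    have depth 1; dvox is the maximum depth, i.e. the number of successive
    face-erosions needed to empty the ROI.  Ties break to the smallest index
    order; the location is reported in mm via the affine.
    """
    if not roi.values.any():
        raise ValueError("empty ROI")
    padded = np.pad(roi.values, 1)
    # city-block distance to background == face-connected erosion depth
    depth = distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1, 1:-1]
    dvox = int(depth.max())
    idx = np.unravel_index(int(np.argmax(depth)), depth.shape)
    mm = tuple((roi.affine @ np.append(np.asarray(idx, float), 1.0))[:3])
    return dvox, {"index": tuple(int(i) for i in idx), "mm": mm}


def roi_stats_table(tsnr: TsnrMap, atlas: Dataset3D,
                    labels: dict | None = None) -> list[ROITableRow]:
    """One ROITableRow per nonzero atlas label.

    nzer counts voxels whose TSNR is exactly 0 (masked-out or failed
    voxels); quartiles are over all ROI voxels, zeros included.
    """
    if atlas.shape != tsnr.values.shape:
        raise ValueError("atlas must be on the TSNR grid")
    lab = np.asarray(atlas.values).astype(int)
    ids = sorted(int(v) for v in np.unique(lab) if v != 0)
    if not ids:
        raise ValueError("empty atlas (no nonzero labels)")
    rows = []
    for rid in ids:
        sel = lab == rid
        vals = tsnr.values[sel]
        dvox, loc = roi_depth(Mask3D(sel.astype(int), tsnr.voxel_size, tsnr.affine))
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        name = labels.get(rid, f"ROI_{rid:03d}") if labels else f"ROI_{rid:03d}"
        rows.append(ROITableRow(
            label=name, nvox=int(sel.sum()), nzer=int((vals == 0).sum()),
            dvox=dvox, tmin=float(q[0]), t25=float(q[1]), tmed=float(q[2]),
            t75=float(q[3]), tmax=float(q[4]), max_depth_coord=loc["mm"]))
    return rows


# Directions of concern: small ROIs, many zero voxels, shallow ROIs, low
# TSNR, steep TSNR drop-off.  The cutoffs themselves are local heuristics
# and overridable per metric.
DEFAULT_ROI_WARN_THRESHOLDS = {
    # metric: [(cut, level), ...] ordered from mildest to most severe
    "nvox": [(20, WarnLevel.mild), (10, WarnLevel.medium), (5, WarnLevel.severe)],
    "zero_frac": [(0.1, WarnLevel.mild), (0.25, WarnLevel.medium),
                  (0.5, WarnLevel.severe)],
    "dvox": [(3, WarnLevel.mild), (2, WarnLevel.medium)],
    "t75": [(50, WarnLevel.mild), (30, WarnLevel.medium), (15, WarnLevel.severe)],
    "slope": [(0.75, WarnLevel.mild), (1.0, WarnLevel.medium),
              (1.5, WarnLevel.severe)],
}

# metrics where *smaller* values are worse
_DECREASING = {"nvox", "dvox", "t75"}


def assign_roi_warn_levels(row: ROITableRow,
                           thresholds: dict | None = None) -> ROITableRow:
    """Grade each shape/TSNR metric of a row with a warning level.

    Metrics: small nvox, high nzer/nvox, small dvox, low t75, and a high
    interquartile slope (t75 - t25) / tmed.  Warn levels are monotone
    nondecreasing as each metric degrades.
    """
    thr = dict(DEFAULT_ROI_WARN_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    metrics = {
        "nvox": row.nvox,
        "zero_frac": row.nzer / row.nvox if row.nvox else 1.0,
        "dvox": row.dvox,
        "t75": row.t75,
    }
    if row.tmed == 0:
        slope_level = WarnLevel.severe  # cannot divide; degenerate ROI
    else:
        metrics["slope"] = (row.t75 - row.t25) / row.tmed
        slope_level = None
    warns = {}
    for name, value in metrics.items():
        level = WarnLevel.none
        for cut, lev in thr[name]:
            hit = value < cut if name in _DECREASING else value > cut
            if hit:
                level = lev
        warns[name] = level
    warns["slope"] = slope_level if slope_level is not None else warns["slope"]
    row.warns = warns
    return row
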