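"""Artifact detectors and the graded warning system of the "warns" block:
left-right flip checking via a local Pearson correlation cost, through-slice
variance-line detection, presteady-state detection, and warning aggregation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Dataset3D, Dataset4D, Mask3D
from .timeseries import detrend_dataset

__all__ = [
    "WarnLevel",
    "WarnItem",
    "FlipResult",
    "lpc_cost",
    "check_flip",
    "find_variance_lines",
    "check_presteady",
    "max_warn_level",
]


class WarnLevel(enum.IntEnum):
    """Graded warning severity with its report display color."""

    none = 0
    undecided = 1
    mild = 2
    medium = 3
    severe = 4

    @property
    def color(self) -> str:
        return _LEVEL_COLORS[self]


_LEVEL_COLORS = {
    WarnLevel.none: "#00cc00",       # green
    WarnLevel.undecided: "#ffff00",  # yellow
    WarnLevel.mild: "#ffb2b2",       # light pink
    WarnLevel.medium: "#ff7373",     # darker pink
    WarnLevel.severe: "#ff0000",     # bright red
}


@dataclass
class WarnItem:
    name: str
    level: WarnLevel
    message: str
    payload: dict = field(default_factory=dict)

    def to_json(self):
        return {"name": self.name, "level": self.level.name,
                "message": self.message, "payload": self.payload}


@dataclass
class FlipResult:
    cost_asis: float
    cost_flipped: float
    guess: str  # NO_FLIP | DO_FLIP | UNDECIDED


def lpc_cost(a: Dataset3D, b: Dataset3D, mask: Mask3D, block_radius: int = 2) -> float:
    """Local Pearson correlation cost between two volumes on a shared grid.

    In-mask voxels are partitioned into non-overlapping cubic blocks of edge
    2*block_radius + 1; per block with at least 8 in-mask voxels the Pearson
    correlation r of the two intensity patterns is computed, and

        cost = - sum_b w_b * sign(r_b) * r_b**2 / sum_b w_b

    with w_b the block voxel count.  Lower is a better match; bounded in
    [-1, 1]; identical inputs give -1.
    """
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("volumes and mask must share a grid")
    edge = 2 * block_radius + 1
    av, bv, mv = np.asarray(a.values, float), np.asarray(b.values, float), mask.values
    nx, ny, nz = av.shape
    num = 0.0
    den = 0.0
    for i0 in range(0, nx, edge):
        for j0 in range(0, ny, edge):
            for k0 in range(0, nz, edge):
                sel = mv[i0:i0 + edge, j0:j0 + edge, k0:k0 + edge]
                w = int(sel.sum())
                if w < 8:
                    continue
                x = av[i0:i0 + edge, j0:j0 + edge, k0:k0 + edge][sel]
                y = bv[i0:i0 + edge, j0:j0 + edge, k0:k0 + edge][sel]
                xd = x - x.mean()
                yd = y - y.mean()
                sx = np.sqrt((xd ** 2).sum())
                sy = np.sqrt((yd ** 2).sum())
                if sx == 0 or sy == 0:
                    continue
                r = float((xd * yd).sum() / (sx * sy))
                num += w * np.sign(r) * r * r
                den += w
    if den == 0:
        raise ValueError("no valid blocks for LPC cost")
    return -num / den


def _lr_axis(affine: np.ndarray) -> int:
    """Array axis most aligned with the world left-right (x) direction."""
    rot = np.asarray(affine)[:3, :3]
    comp = np.abs(rot[0, :])
    if comp.max() < 1e-9:
        raise ValueError("left-right axis not identifiable from affine")
    return int(np.argmax(comp))


def check_flip(epi_vol: Dataset3D, anat: Dataset3D, mask: Mask3D,
               block_radius: int = 2, margin: float = 0.02):
    """Compare the LPC cost of the EPI as-is vs. mirrored left-right.

    DO_FLIP when the mirrored cost beats the as-is cost by more than a
    relative margin (default 2%), NO_FLIP for the reverse, UNDECIDED within
    the margin.  A DO_FLIP guess raises a severe warning.
    """
    axis = _lr_axis(epi_vol.affine)
    flipped = Dataset3D(np.flip(epi_vol.values, axis=axis).copy(),
                        epi_vol.voxel_size, epi_vol.affine)
    cost_asis = lpc_cost(epi_vol, anat, mask, block_radius)
    cost_flip = lpc_cost(flipped, anat, mask, block_radius)
    scale = max(abs(cost_asis), abs(cost_flip), 1e-6)
    if cost_flip < cost_asis - margin * scale:
        guess = "DO_FLIP"
        level = WarnLevel.severe
        msg = "left-right flipped EPI matches the anatomical better"
    elif cost_asis < cost_flip - margin * scale:
        guess = "NO_FLIP"
        level = WarnLevel.none
        msg = "EPI-anatomical left-right orientation consistent"
    else:
        guess = "UNDECIDED"
        level = WarnLevel.undecided
        msg = "left-right flip check inconclusive (costs within margin)"
    result = FlipResult(cost_asis=cost_asis, cost_flipped=cost_flip, guess=guess)
    item = WarnItem(name="flip check", level=level, message=msg,
                    payload={"cost_asis": cost_asis, "cost_flipped": cost_flip,
                             "guess": guess})
    return result, item


def find_variance_lines(dset: Dataset4D, mask: Mask3D, factor: float = 2.5,
                        min_frac: float = 0.5, order: int | None = None):
    """Detect narrow through-slice columns of anomalously high temporal
    variance (a scanner artifact).

    Per voxel the series is polynomially detrended; for each in-plane column
    (i, j) covered by at least ``min_frac`` of slices in-mask, the column
    score is the median over its in-mask slices of the temporal sd.  Columns
    scoring above ``factor`` times the median in-mask column score are
    flagged; face-adjacent flagged columns merge into clusters and each
    cluster reports its peak location (index and mm).
    """
    if dset.n_volumes < 20:
        raise ValueError("need at least 20 volumes for variance-line detection")
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    resid = detrend_dataset(dset.values, dset.run_lengths, dset.tr, order=order)
    sd = resid.std(axis=3, ddof=1)
    nz = m.shape[2]
    counts = m.sum(axis=2)
    valid = counts >= min_frac * nz
    sd_masked = np.where(m, sd, np.nan)
    score = np.full(m.shape[:2], np.nan)
    if valid.any():
        score[valid] = np.nanmedian(sd_masked[valid], axis=1)
    ref = np.nanmedian(score[valid]) if valid.any() else np.nan
    if not np.isfinite(ref) or ref <= 0:
        return [], WarnItem("variance lines", WarnLevel.none,
                            "no valid columns for variance-line check")
    flagged = valid & (score > factor * ref)

    # merge face-adjacent flagged (i, j) columns into clusters
    from scipy.ndimage import label as cc_label
    lab, n_clusters = cc_label(flagged)
    records = []
    for c in range(1, n_clusters + 1):
        ii, jj = np.where(lab == c)
        rel = score[ii, jj] / ref
        peak = int(np.argmax(rel))
        i, j = int(ii[peak]), int(jj[peak])
        k = int(np.argmax(np.where(m[i, j], sd[i, j], -np.inf)))
        mm = dset.ijk_to_mm((i, j, k))
        records.append({
            "columns": [(int(a), int(b)) for a, b in zip(ii, jj)],
            "peak_index": (i, j, k),
            "peak_mm": tuple(float(v) for v in mm),
            "relative_score": float(rel[peak]),
        })
    records.sort(key=lambda r: -r["relative_score"])
    if not records:
        level = WarnLevel.none
        msg = "no variance lines detected"
    elif len(records) >= 3 or max(r["relative_score"] for r in records) > 2 * factor:
        level = WarnLevel.severe
        msg = f"{len(records)} variance line cluster(s) detected"
    else:
        level = WarnLevel.medium
        msg = f"{len(records)} variance line cluster(s) detected"
    item = WarnItem("variance lines", level, msg,
                    payload={"n_clusters": len(records), "clusters": records})
    return records, item


def check_presteady(dset: Dataset4D, mask: Mask3D, presteady_factor: float = 1.05):
    """Count initial consecutive volumes whose in-mask mean intensity exceeds
    the first run's 10%-trimmed mean by more than ``presteady_factor``.

    The trimmed mean keeps an intensity inflation at the start of the run
    from biasing its own baseline.  A nonzero count is a medium warning.
    """
    if dset.n_volumes < 10:
        raise ValueError("need at least 10 volumes for presteady check")
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    rl = dset.run_lengths[0]
    means = dset.values[m][:, :rl].mean(axis=0)
    base = stats.trim_mean(means, 0.1)
    count = 0
    for t in range(rl):
        if means[t] > presteady_factor * base:
            count += 1
        else:
            break
    level = WarnLevel.medium if count > 0 else WarnLevel.none
    msg = (f"{count} apparent presteady-state volume(s) at the start of run 1"
           if count else "no presteady-state volumes detected")
    item = WarnItem("presteady state", level, msg, payload={"count": count})
    return count, item


def max_warn_level(items) -> WarnLevel:
    """Maximum warning level over a list of items; empty list -> none."""
    level = WarnLevel.none
    for it in items:
        if it.level > level:
            level = it.level
    return level
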