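"""Motion Euclidean norm, voxelwise outlier fractions, min-outlier volume
selection, censor construction, and before/after-censoring summaries.

The motion magnitude per volume is the Euclidean norm ("enorm") of the
forward differences of the six rigid-body parameters (3 rotations in degrees,
3 translations in mm), reset to zero at the first volume of every run.
Rotations and translations enter unscaled, following the common AFNI
convention; on a ~50 mm-radius head one degree of rotation is roughly one mm
of surface displacement, so the mixed units are comparable in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io import Dataset4D, Mask3D, ReviewDict, sig6
from .timeseries import detrend_dataset, polort_for_run

__all__ = [
    "MotionParams",
    "CensorVector",
    "DistributionStats",
    "DEFAULT_ENORM_LIMIT",
    "DEFAULT_OUTLIER_LIMIT",
    "compute_enorm",
    "compute_outlier_fraction",
    "select_min_outlier_volume",
    "build_censor",
    "censor_summary",
    "distribution_stats",
]

DEFAULT_ENORM_LIMIT = 0.3    # mm-equivalent
DEFAULT_OUTLIER_LIMIT = 0.05  # fraction of in-mask voxels


@dataclass
class MotionParams:
    """Per-volume rigid-body motion estimates: T x 6 (rot deg, trans mm)."""

    values: np.ndarray
    run_lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 6:
            raise ValueError(f"expected 6 motion columns, got {self.values.shape[1]}")
        if not self.run_lengths:
            self.run_lengths = [self.values.shape[0]]
        if sum(self.run_lengths) != self.values.shape[0]:
            raise ValueError("run_lengths must sum to the number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass
class CensorVector:
    """Binary keep/censor decision per volume (1 = keep)."""

    keep: np.ndarray
    limits: dict = field(default_factory=lambda: {
        "enorm_limit": DEFAULT_ENORM_LIMIT,
        "outlier_limit": DEFAULT_OUTLIER_LIMIT,
    })

    def __post_init__(self):
        arr = np.asarray(self.keep)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("keep values must be 0 or 1")
        self.keep = arr.astype(int)
        for k, v in self.limits.items():
            if v <= 0:
                raise ValueError(f"limit {k} must be positive")

    @property
    def n_total(self) -> int:
        return self.keep.size

    @property
    def n_censored(self) -> int:
        return int((self.keep == 0).sum())

    @property
    def censored_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep == 0)


@dataclass
class DistributionStats:
    """Five-number summary, before censoring (bc) and after censoring (ac)."""

    bc: tuple
    ac: tuple | None  # None when every volume is censored

    def __post_init__(self):
        for stats in (self.bc, self.ac):
            if stats is None:
                continue
            if not all(a <= b + 1e-12 for a, b in zip(stats, stats[1:])):
                raise ValueError("five-number summary must be nondecreasing")


def compute_enorm(mp: MotionParams) -> np.ndarray:
    """Euclidean norm of the forward differences of the motion parameters.

    Zero at the first volume of every run.
    """
    e = np.zeros(mp.n_volumes)
    start = 0
    for rl in mp.run_lengths:
        block = mp.values[start:start + rl]
        d = np.diff(block, axis=0)
        e[start + 1:start + rl] = np.sqrt((d ** 2).sum(axis=1))
        start += rl
    return e


def compute_outlier_fraction(dset: Dataset4D, mask: Mask3D) -> np.ndarray:
    """Per-volume fraction of in-mask voxels that are outliers in their own
    detrended series.

    Per voxel and run, the series is detrended with Legendre polynomials of
    order 1 + floor(run_seconds / 150); a residual is an outlier when its
    magnitude about the residual median exceeds
    q * 1.4826 * MAD, with q the normal quantile at tail p = 0.001 / (2 T)
    Bonferroni-style in the run length T.
    """
    if dset.n_volumes < 10:
        raise ValueError("need at least 10 volumes for outlier detection")
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    data = dset.values[m]  # (n_vox, T)
    frac = np.zeros(dset.n_volumes)
    start = 0
    for rl in dset.run_lengths:
        order = polort_for_run(rl, dset.tr)
        resid = detrend_dataset(data[:, start:start + rl], [rl], dset.tr, order=order)
        med = np.median(resid, axis=1, keepdims=True)
        dev = np.abs(resid - med)
        madn = 1.4826 * np.median(dev, axis=1, keepdims=True)
        q = norm.ppf(1.0 - 0.001 / (2.0 * rl))
        out = dev > q * madn
        # zero-variance voxels (madn == 0) can never be outliers
        out[np.ravel(madn == 0)] = False
        frac[start:start + rl] = out.mean(axis=0)
        start += rl
    return frac


def select_min_outlier_volume(outfrac: np.ndarray, censorable_prefix: int = 0) -> int:
    """Index of the volume with minimal outlier fraction (ties -> earliest).

    ``censorable_prefix`` volumes at the start (e.g., presteady-state ones)
    are excluded from consideration.
    """
    outfrac = np.asarray(outfrac, dtype=float)
    if outfrac.size == 0:
        raise ValueError("empty outlier series")
    sub = outfrac[censorable_prefix:]
    return int(np.argmin(sub)) + censorable_prefix


def build_censor(enorm, outfrac, limits=None, extend_previous: bool = True,
                 run_lengths=None) -> CensorVector:
    """Censor volumes whose enorm or outlier fraction exceed their limits.

    With ``extend_previous`` (default on), the volume preceding an
    enorm-censored one within the same run is censored too: enorm measures a
    between-pair difference, so both members of the pair are suspect.
    """
    enorm = np.asarray(enorm, dtype=float)
    outfrac = np.asarray(outfrac, dtype=float)
    if enorm.shape != outfrac.shape:
        raise ValueError("enorm and outlier series must have equal length")
    limits = dict(limits or {})
    limits.setdefault("enorm_limit", DEFAULT_ENORM_LIMIT)
    limits.setdefault("outlier_limit", DEFAULT_OUTLIER_LIMIT)
    if limits["enorm_limit"] <= 0 or limits["outlier_limit"] <= 0:
        raise ValueError("censor limits must be positive")
    T = enorm.size
    run_lengths = list(run_lengths) if run_lengths else [T]
    censored = np.zeros(T, dtype=bool)
    start = 0
    for rl in run_lengths:
        for t in range(start, start + rl):
            if enorm[t] > limits["enorm_limit"]:
                censored[t] = True
                if extend_previous and t - 1 >= start:
                    censored[t - 1] = True
            if outfrac[t] > limits["outlier_limit"]:
                censored[t] = True
        start += rl
    return CensorVector(keep=(~censored).astype(int), limits=limits)


def censor_summary(cv: CensorVector, run_lengths=None) -> ReviewDict:
    """Censor counts and fractions as a review-dictionary fragment."""
    T = cv.n_total
    run_lengths = list(run_lengths) if run_lengths else [T]
    if sum(run_lengths) != T:
        raise ValueError("run_lengths inconsistent with censor length")
    ncen = cv.n_censored
    rd = ReviewDict()
    rd["num runs found"] = len(run_lengths)
    rd["num TRs per run"] = run_lengths if len(run_lengths) > 1 else run_lengths[0]
    per_run_applied = []
    per_run_frac = []
    start = 0
    for rl in run_lengths:
        kept = int(cv.keep[start:start + rl].sum())
        per_run_applied.append(kept)
        per_run_frac.append(sig6((rl - kept) / rl))
        start += rl
    rd["num TRs per run (applied)"] = (per_run_applied if len(run_lengths) > 1
                                       else per_run_applied[0])
    rd["fraction censored per run"] = (per_run_frac if len(run_lengths) > 1
                                       else per_run_frac[0])
    rd["TRs total (uncensored)"] = T
    rd["TRs total"] = T - ncen
    rd["TRs censored"] = ncen
    # printed at 6 decimals (the per-run line above keeps 6 significant digits)
    rd["censor fraction"] = round(ncen / T, 6)
    return rd


def distribution_stats(series, cv: CensorVector) -> DistributionStats:
    """Five-number summaries before (BC) and after (AC) censoring.

    Quartiles use linear interpolation.  AC is None (flagged) when every
    volume is censored.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")

    def five(x):
        return tuple(np.percentile(x, [0, 25, 50, 75, 100]))

    bc = five(series)
    kept = series[cv.keep.astype(bool)]
    ac = five(kept) if kept.size else None
    return DistributionStats(bc=bc, ac=ac)
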