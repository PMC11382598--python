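"""Synthetic phantom generation with machine-readable ground truth.

Generates anatomical/EPI phantom pairs, toy atlases, motion traces, and
stimulus timings so that every detector in the toolkit can be exercised with
known answers, without downloading any data.  The phantoms are statistical
stand-ins, not physical MR simulations: an ellipsoidal three-tissue "brain"
with a deliberate left-right asymmetry, Gaussian temporal noise, polynomial
drift, and injected artifacts (motion spikes, through-slice variance lines,
shared network time courses, presteady-state intensity inflation, left-right
flips).

All generation is a pure function of the spec, including its ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter1d

from .io import Dataset3D, Dataset4D, Mask3D
from .motion import (MotionParams, DEFAULT_ENORM_LIMIT)
from .timeseries import legendre_basis

__all__ = [
    "SimSpec",
    "TruthRecord",
    "make_phantom_anat",
    "make_toy_atlas",
    "simulate_motion_params",
    "simulate_epi",
    "phantom_suite",
    "demo_spec",
]

_FACE = np.zeros((3, 3, 3), dtype=bool)
_FACE[1, 1, 1] = _FACE[0, 1, 1] = _FACE[2, 1, 1] = True
_FACE[1, 0, 1] = _FACE[1, 2, 1] = _FACE[1, 1, 0] = _FACE[1, 1, 2] = True


@dataclass
class SimSpec:
    """Phantom study conditions.

    Defaults describe a small but realistic single-run acquisition:
    32 x 32 x 20 voxels at 2.5 mm isotropic, TR 2 s, 200 volumes, baseline
    1000 with temporal noise sd 10 (whole-brain TSNR ~ 100).  Artifact lists
    are empty by default; the clean phantom is the null condition detectors
    must stay silent on.
    """

    dims: tuple = (32, 32, 20)
    voxel_size: tuple = (2.5, 2.5, 2.5)
    tr: float = 2.0
    n_volumes: int = 200
    n_runs: int = 1
    baseline_mean: float = 1000.0
    noise_sd: float = 10.0
    epi_contrast: float = 0.10   # fractional tissue contrast of the EPI baseline
    drift_amplitude: float = 5.0
    drift_order: int = 2
    motion_base_amp: float = 0.02
    motion_spikes: list = field(default_factory=list)   # [(t, magnitude mm)]
    variance_lines: list = field(default_factory=list)  # [(i, j, scale)]
    networks: list = field(default_factory=list)        # [{label, seed, radius_vox, amplitude}]
    roi_tsnr: dict = field(default_factory=dict)        # label(int) -> target TSNR
    hrf: str = "gamma"
    stim_onsets: dict = field(default_factory=dict)     # label -> onset seconds
    stim_durations: dict = field(default_factory=dict)
    flip: bool = False
    presteady_n: int = 0
    presteady_factor: float = 1.15
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_volumes < 10:
            raise ValueError("n_volumes must be >= 10")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for t, mag in self.motion_spikes:
            if not (0 <= t < self.n_volumes):
                raise ValueError(f"spike time {t} outside [0, {self.n_volumes})")
            if mag < 0:
                raise ValueError("spike magnitudes must be >= 0")
        for i, j, s in self.variance_lines:
            if not (0 <= i < self.dims[0] and 0 <= j < self.dims[1]):
                raise ValueError(f"variance-line column ({i}, {j}) outside grid")
            if s <= 0:
                raise ValueError("variance-line scales must be positive")
        for net in self.networks:
            seed = net["seed"]
            if not all(0 <= s < d for s, d in zip(seed, self.dims)):
                raise ValueError(f"network seed {seed} outside grid")
            if net.get("radius_vox", 2) >= min(self.dims) // 2:
                raise ValueError("network radius exceeds grid")
        if self.n_volumes % self.n_runs:
            raise ValueError("n_volumes must divide evenly into n_runs")

    @property
    def run_lengths(self) -> list[int]:
        return [self.n_volumes // self.n_runs] * self.n_runs

    @property
    def affine(self) -> np.ndarray:
        # grid centered at world origin, axes aligned with (x, y, z)
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = [-(d - 1) / 2.0 * v for d, v in zip(self.dims, self.voxel_size)]
        return aff


@dataclass
class TruthRecord:
    """Ground truth actually injected into a simulated EPI."""

    motion: MotionParams
    expected_censored: list
    variance_line_cols: list
    network_seeds: list   # [{label, seed, voxels, course}]
    roi_tsnr: dict
    flip_applied: bool
    presteady_n: int
    rng_seed: int

    def to_json(self, path):
        obj = {
            "motion": self.motion.values.tolist(),
            "run_lengths": self.motion.run_lengths,
            "expected_censored": [int(t) for t in self.expected_censored],
            "variance_line_cols": [[int(i), int(j), float(s)]
                                   for i, j, s in self.variance_line_cols],
            "network_seeds": [
                {"label": n["label"], "seed": [int(v) for v in n["seed"]],
                 "voxels": [[int(a) for a in v] for v in n["voxels"]],
                 "course": [float(v) for v in n["course"]]}
                for n in self.network_seeds],
            "roi_tsnr": {str(k): float(v) for k, v in self.roi_tsnr.items()},
            "flip_applied": bool(self.flip_applied),
            "presteady_n": int(self.presteady_n),
            "rng_seed": int(self.rng_seed),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _ellipsoid_rho(dims):
    """Normalized ellipsoidal radius on the grid (<= 1 inside the brain)."""
    center = (np.asarray(dims) - 1) / 2.0
    semi = 0.42 * np.asarray(dims)
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return np.sqrt(rho2)


def _sphere(dims, center, radius):
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def make_phantom_anat(spec: SimSpec):
    """Ellipsoidal three-tissue anatomical phantom with a deliberate
    left-right asymmetry (an exterior lobe plus internal nodules on one
    hemisphere, for flip testing).  Returns (Dataset3D, Mask3D) where the
    mask is the phantom support.
    """
    dims = tuple(spec.dims)
    if min(dims) < 16:
        raise ValueError("phantom dims must be >= 16 per axis")
    nx, ny, nz = dims
    rho = _ellipsoid_rho(dims)
    ellipsoid = rho <= 1.0
    vals = np.zeros(dims)
    vals[rho <= 1.0] = 400.0    # outer shell ("CSF/GM")
    vals[rho <= 0.80] = 700.0   # mid tissue
    vals[rho <= 0.45] = 1000.0  # inner tissue ("WM")
    center = (np.asarray(dims) - 1) / 2.0
    # exterior lobe on the +x hemisphere
    lobe = _sphere(dims, center + [0.32 * nx, 0, 0], 0.16 * nx)
    vals[lobe & ~ellipsoid] = 800.0
    # bright nodule, +x interior
    bright = _sphere(dims, center + [0.18 * nx, 0.10 * ny, 0], 0.10 * nx)
    vals[bright & ellipsoid] = 1200.0
    # dark nodule, -x interior
    dark = _sphere(dims, center + [-0.20 * nx, -0.08 * ny, 0.05 * nz], 0.10 * nx)
    vals[dark & ellipsoid] = 450.0
    mask = ellipsoid | lobe
    aff = spec.affine
    return (Dataset3D(vals, spec.voxel_size, aff),
            Mask3D(mask.astype(int), spec.voxel_size, aff))


def make_toy_atlas(mask: Mask3D, n_roi: int, rng_seed: int = 0) -> Dataset3D:
    """Partition the mask into n_roi contiguous, disjoint, nonempty integer-
    labeled regions (label 0 = background) by farthest-point seeding followed
    by simultaneous face-connected region growth."""
    if n_roi < 2:
        raise ValueError("n_roi must be >= 2")
    coords = np.argwhere(mask.values)
    if coords.shape[0] < 8 * n_roi:
        raise ValueError("mask too small to host that many regions")
    rng = np.random.default_rng(rng_seed)
    seeds = [coords[rng.integers(coords.shape[0])]]
    for _ in range(n_roi - 1):
        d = np.stack([np.abs(coords - s).sum(axis=1) for s in seeds]).min(axis=0)
        seeds.append(coords[int(np.argmax(d))])
    labels = np.zeros(mask.shape, dtype=int)
    for idx, s in enumerate(seeds, start=1):
        labels[tuple(s)] = idx
    changed = True
    while changed:
        changed = False
        for idx in range(1, n_roi + 1):
            grow = binary_dilation(labels == idx, structure=_FACE)
            grow &= mask.values & (labels == 0)
            if grow.any():
                labels[grow] = idx
                changed = True
    return Dataset3D(labels, mask.voxel_size, mask.affine)


def _expected_censored(spec: SimSpec, enorm_limit: float) -> list:
    """Volumes a default censor pass must remove, from the spike list alone.

    A one-volume spike of magnitude m produces enorm = m at the spike time
    (unless it starts a run) and at the following volume; with the default
    extend-previous rule the preceding volume is censored too.
    """
    runs = spec.run_lengths
    starts = np.cumsum([0] + runs[:-1])
    cens = set()
    for t, mag in spec.motion_spikes:
        if mag <= enorm_limit:
            continue
        r = int(np.searchsorted(starts, t, side="right")) - 1
        s, e = starts[r], starts[r] + runs[r]
        hit = set()
        if t > s:
            hit.add(t)
        if t + 1 < e:
            hit.add(t + 1)
        for c in list(hit):
            if c - 1 >= s:
                hit.add(c - 1)
        cens |= hit
    return sorted(cens)


def simulate_motion_params(spec: SimSpec) -> MotionParams:
    """Six-column motion trace: slow sinusoidal baseline plus the listed
    one-volume spikes (applied to translation columns)."""
    rng = np.random.default_rng(spec.rng_seed + 1)
    T = spec.n_volumes
    t = np.arange(T)
    vals = np.zeros((T, 6))
    if spec.motion_base_amp > 0:
        for c in range(6):
            freq = rng.uniform(0.005, 0.02)
            phase = rng.uniform(0, 2 * np.pi)
            vals[:, c] = spec.motion_base_amp * np.sin(2 * np.pi * freq * t + phase)
    for idx, (ts, mag) in enumerate(spec.motion_spikes):
        vals[ts, 3 + idx % 3] += mag
    return MotionParams(vals, run_lengths=spec.run_lengths)


def simulate_epi(spec: SimSpec, anat: Dataset3D = None, mask: Mask3D = None,
                 atlas: Dataset3D = None):
    """Simulate a 4D EPI phantom and the TruthRecord of injected artifacts.

    The EPI baseline carries a scaled copy of the anatomical tissue contrast
    (in-mask mean exactly ``baseline_mean``), plus per-run polynomial drift,
    Gaussian noise (per-ROI rescaled to hit any TSNR targets), and the
    requested artifacts.
    """
    if anat is None or mask is None:
        anat, mask = make_phantom_anat(spec)
    if atlas is None and spec.roi_tsnr:
        atlas = make_toy_atlas(mask, len(spec.roi_tsnr), rng_seed=spec.rng_seed)
    rng = np.random.default_rng(spec.rng_seed)
    dims = tuple(spec.dims)
    T = spec.n_volumes
    m = mask.values

    a_in = anat.values[m]
    contrast = (a_in - a_in.mean())
    peak = np.abs(contrast).max()
    base = np.full(dims, 20.0)
    base[m] = spec.baseline_mean * (1.0 + spec.epi_contrast * contrast / peak)

    # per-voxel noise sd, with per-ROI override to hit TSNR targets
    sd_field = np.full(dims, 2.0)
    sd_field[m] = spec.noise_sd
    if spec.roi_tsnr:
        lab = atlas.values.astype(int)
        for roi_label, target in spec.roi_tsnr.items():
            sd_field[lab == int(roi_label)] = spec.baseline_mean / float(target)

    data = np.empty(dims + (T,))
    data[:] = base[..., None]

    # polynomial drift, per run, shared across in-mask voxels
    start = 0
    for rl in spec.run_lengths:
        basis = legendre_basis(rl, spec.drift_order)
        coefs = spec.drift_amplitude * rng.uniform(-1, 1, spec.drift_order)
        drift = basis[:, 1:] @ coefs
        data[m, start:start + rl] += drift
        start += rl

    noise = rng.standard_normal(dims + (T,)) * sd_field[..., None]
    for i, j, scale in spec.variance_lines:
        noise[i, j, :, :] *= scale
    data += noise

    # shared network time courses
    net_truth = []
    for net in spec.networks:
        course = gaussian_filter1d(rng.standard_normal(T), sigma=2.0)
        course = (course - course.mean()) / course.std()
        amp = net.get("amplitude") or 2.0 * spec.noise_sd
        seed = tuple(int(v) for v in net["seed"])
        radius = net.get("radius_vox", 2)
        region = _sphere(dims, seed, radius) & m
        data[region] += amp * course
        net_truth.append({"label": net.get("label", "network"),
                          "seed": seed,
                          "voxels": [tuple(int(a) for a in v)
                                     for v in np.argwhere(region)],
                          "course": course})

    # motion spikes: whole-volume intensity scaling + one-voxel shift
    for ts, mag in spec.motion_spikes:
        if mag > 0:
            data[..., ts] = np.roll(data[..., ts], 1, axis=0) * 1.02

    if spec.presteady_n:
        data[m, :spec.presteady_n] *= spec.presteady_factor

    if spec.flip:
        data = np.flip(data, axis=0).copy()

    mp = simulate_motion_params(spec)
    truth = TruthRecord(
        motion=mp,
        expected_censored=_expected_censored(spec, DEFAULT_ENORM_LIMIT),
        variance_line_cols=list(spec.variance_lines),
        network_seeds=net_truth,
        roi_tsnr=dict(spec.roi_tsnr),
        flip_applied=spec.flip,
        presteady_n=spec.presteady_n,
        rng_seed=spec.rng_seed,
    )
    epi = Dataset4D(data, spec.voxel_size, spec.tr, spec.affine,
                    run_lengths=spec.run_lengths)
    return epi, truth


def phantom_suite(spec: SimSpec) -> dict:
    """Generate the full set of phantom inputs for one synthetic subject."""
    anat, mask = make_phantom_anat(spec)
    atlas = make_toy_atlas(mask, max(len(spec.roi_tsnr), 4), rng_seed=spec.rng_seed)
    epi, truth = simulate_epi(spec, anat, mask, atlas)
    return {"spec": spec, "anat": anat, "mask": mask, "atlas": atlas,
            "epi": epi, "truth": truth, "motion": truth.motion}


def demo_spec(rng_seed: int = 0, **overrides) -> SimSpec:
    """Study conditions for the worked demonstration subject: two motion
    spikes above the censor limit, one variance line, three network seeds
    named after the canonical resting-state trio, four ROI TSNR targets, and
    a two-class block-design timing."""
    dims = overrides.pop("dims", (32, 32, 20))
    n_volumes = overrides.pop("n_volumes", 200)
    tr = overrides.pop("tr", 2.0)
    cx, cy, cz = [d // 2 for d in dims]
    run_s = n_volumes * tr
    defaults = dict(
        dims=dims,
        n_volumes=n_volumes,
        tr=tr,
        motion_spikes=[(int(0.3 * n_volumes), 1.0), (int(0.75 * n_volumes), 0.8)],
        variance_lines=[(cx - 6, cy + 4, 5.0)],
        networks=[
            {"label": "DMN", "seed": (cx - 5, cy - 5, cz), "radius_vox": 2},
            {"label": "visual", "seed": (cx + 5, cy + 4, cz - 2), "radius_vox": 2},
            {"label": "auditory", "seed": (cx - 4, cy + 5, cz + 2), "radius_vox": 2},
        ],
        roi_tsnr={1: 120.0, 2: 90.0, 3: 150.0, 4: 60.0},
        stim_onsets={"vis": [0.05 * run_s, 0.35 * run_s, 0.65 * run_s],
                     "aud": [0.20 * run_s, 0.50 * run_s, 0.80 * run_s]},
        stim_durations={"vis": 20.0, "aud": 20.0},
        rng_seed=rng_seed,
    )
    defaults.update(overrides)
    return SimSpec(**defaults)


def write_stim_timing(onsets: dict, path_prefix):
    """Write stimulus timing text files: one row of onset seconds per run."""
    paths = []
    for label, times in onsets.items():
        p = f"{path_prefix}_{label}.txt"
        with open(p, "w") as fh:
            fh.write(" ".join(f"{t:g}" for t in times) + "\n")
        paths.append(p)
    return paths
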