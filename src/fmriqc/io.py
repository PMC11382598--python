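"""Core gridded-data and tabular types, plus readers/writers for the standard
formats the toolkit touches: NIfTI-1 volumes, AFNI-style ".1D" text matrices,
and colon-separated / flat-JSON review dictionaries.

Array index order is (x, y, z, t) throughout.  Voxel coordinates are reported
0-based in index space, with world mm positions obtained through the affine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Dataset3D",
    "Dataset4D",
    "Mask3D",
    "Matrix1D",
    "ReviewDict",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_matrix_1d",
    "write_matrix_1d",
    "read_review_dict",
    "write_review_dict",
    "sig6",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not satisfy its format contract."""


def sig6(x):
    """Round a float to 6 significant digits (the precision used on write).

    Integers pass through unchanged so counts stay exact.
    """
    if isinstance(x, (int, np.integer)) and not isinstance(x, bool):
        return int(x)
    return float(f"{float(x):.6g}")


def _format_value(v) -> str:
    if isinstance(v, (int, np.integer)) and not isinstance(v, bool):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.6g}"
    return str(v)


def _parse_token(tok: str):
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        return tok


# ---------------------------------------------------------------------------
# gridded types
# ---------------------------------------------------------------------------

def _check_affine(affine):
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class Dataset3D:
    """A single gridded volume (anatomical, atlas, statistic map, ...)."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("Dataset3D requires a 3D array with all dims >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.values.shape

    def ijk_to_mm(self, ijk):
        ijk = np.asarray(ijk, dtype=float)
        return tuple((self.affine @ np.append(ijk, 1.0))[:3])


@dataclass
class Dataset4D:
    """A 4D EPI time series on a regular grid.

    ``run_lengths`` partitions the time axis into acquisition runs; most
    temporal operations (detrending, forward differences) respect run
    boundaries.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    tr: float
    affine: np.ndarray
    run_lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4 or min(self.values.shape) < 1:
            raise ValueError("Dataset4D requires a 4D array with all dims >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.affine = _check_affine(self.affine)
        if not self.run_lengths:
            self.run_lengths = [self.values.shape[3]]
        if sum(self.run_lengths) != self.values.shape[3]:
            raise ValueError("run_lengths must sum to the time dimension")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_volumes(self) -> int:
        return self.values.shape[3]

    def volume(self, t: int) -> Dataset3D:
        return Dataset3D(self.values[..., t], self.voxel_size, self.affine)

    def ijk_to_mm(self, ijk):
        ijk = np.asarray(ijk, dtype=float)
        return tuple((self.affine @ np.append(ijk, 1.0))[:3])


@dataclass
class Mask3D:
    """A binary mask on a dataset grid (1 = inside)."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = None

    def __post_init__(self):
        arr = np.asarray(self.values)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = arr.astype(bool)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class Matrix1D:
    """A whitespace-separated numeric text matrix (rows = time)."""

    values: np.ndarray
    column_labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.column_labels is not None and len(self.column_labels) != self.values.shape[1]:
            raise ValueError("column_labels length must match column count")

    @property
    def shape(self):
        return self.values.shape


# ---------------------------------------------------------------------------
# review dictionary
# ---------------------------------------------------------------------------

class ReviewDict:
    """Ordered label -> value record of subject QC quantities.

    Values are scalars, strings, or lists of scalars.  Labels are unique;
    unknown labels read from disk are preserved verbatim.
    """

    def __init__(self, entries=None):
        self._d: dict = {}
        if entries:
            items = entries.items() if isinstance(entries, dict) else entries
            for k, v in items:
                self[k] = v

    def __setitem__(self, label, value):
        if isinstance(value, (list, tuple)):
            value = [_parse_token(v) if isinstance(v, str) else v for v in value]
            for v in value:
                if isinstance(v, float) and not np.isfinite(v):
                    raise ValueError(f"non-finite value for label {label!r}")
        elif isinstance(value, (float, np.floating)) and not np.isfinite(value):
            raise ValueError(f"non-finite value for label {label!r}")
        self._d[str(label)] = value

    def __getitem__(self, label):
        return self._d[label]

    def __contains__(self, label):
        return label in self._d

    def __iter__(self):
        return iter(self._d)

    def __len__(self):
        return len(self._d)

    def __eq__(self, other):
        if not isinstance(other, ReviewDict):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def __repr__(self):
        return f"ReviewDict({list(self._d.items())!r})"

    def keys(self):
        return self._d.keys()

    def items(self):
        return self._d.items()

    def get(self, label, default=None):
        return self._d.get(label, default)

    def merge(self, other: "ReviewDict") -> "ReviewDict":
        """Merge in another fragment; colliding labels are an error."""
        clash = set(self._d) & set(other.keys())
        if clash:
            raise ValueError(f"label collision on merge: {sorted(clash)}")
        out = ReviewDict(list(self.items()) + list(other.items()))
        return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path):
    """Read a NIfTI-1 file into a Dataset3D or Dataset4D.

    The repetition time comes from the header time step; a nonpositive time
    step falls back to 1.0 s with a logged warning.
    """
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt or non-NIfTI input
        raise FormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if any(not np.isfinite(v) or v <= 0 for v in voxel_size):
        raise FormatError(f"{path}: non-finite or nonpositive voxel sizes {voxel_size}")
    affine = img.affine
    if data.ndim == 3:
        return Dataset3D(data, voxel_size, affine)
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not np.isfinite(tr) or tr <= 0:
            log.warning("%s: header time step %r invalid, defaulting tr to 1.0 s", path, tr)
            tr = 1.0
        return Dataset4D(data, voxel_size, tr, affine)
    raise FormatError(f"{path}: expected a 3D or 4D volume, got {data.ndim}D")


def write_volume(dset, path):
    """Write a Dataset3D/Dataset4D (or Mask3D as uint8) to NIfTI-1."""
    if isinstance(dset, Mask3D):
        img = nib.Nifti1Image(dset.values.astype(np.uint8), dset.affine)
    else:
        img = nib.Nifti1Image(np.asarray(dset.values), dset.affine)
        if isinstance(dset, Dataset4D):
            zooms = list(dset.voxel_size) + [dset.tr]
            img.header.set_zooms(zooms)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# ".1D" matrices
# ---------------------------------------------------------------------------

_LABEL_TAG = "# ColumnLabels ="


def read_matrix_1d(path) -> Matrix1D:
    """Read an AFNI-style ".1D" whitespace-separated numeric text matrix.

    Lines starting with "#" are comments; a comment "# ColumnLabels = a ; b"
    supplies column labels.
    """
    rows = []
    labels = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if stripped.startswith(_LABEL_TAG):
                    labels = [s.strip().strip('"')
                              for s in stripped[len(_LABEL_TAG):].split(";")]
                continue
            toks = stripped.split()
            try:
                row = [float(t) for t in toks]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric token at line {lineno}") from exc
            if rows and len(row) != len(rows[0]):
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} columns, expected {len(rows[0])})")
            rows.append(row)
    if not rows:
        return Matrix1D(np.empty((0, 0)), labels)
    return Matrix1D(np.asarray(rows), labels)


def write_matrix_1d(mat: Matrix1D, path):
    with open(path, "w") as fh:
        if mat.column_labels:
            fh.write(f'{_LABEL_TAG} {" ; ".join(mat.column_labels)}\n')
        for row in mat.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# review dictionaries
# ---------------------------------------------------------------------------

def read_review_dict(path, dialect: str = "colon") -> ReviewDict:
    """Read a review dictionary: "label : value(s)" lines or a flat JSON object.

    File order is preserved; multi-token colon values become lists of scalars.
    Duplicate labels are an error.
    """
    rd = ReviewDict()
    if dialect == "json":
        with open(path) as fh:
            obj = json.load(fh)
        if not isinstance(obj, dict):
            raise FormatError(f"{path}: expected a flat JSON object")
        for k, v in obj.items():
            if k in rd:
                raise FormatError(f"{path}: duplicate label {k!r}")
            rd[k] = v
        return rd
    if dialect != "colon":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if ":" not in stripped:
                raise FormatError(f"{path}: line without ':' separator: {stripped!r}")
            label, _, raw = stripped.partition(":")
            label = label.strip()
            if label in rd:
                raise FormatError(f"{path}: duplicate label {label!r}")
            toks = raw.split()
            if len(toks) == 0:
                rd[label] = ""
            elif len(toks) == 1:
                rd[label] = _parse_token(toks[0])
            else:
                parsed = [_parse_token(t) for t in toks]
                if all(isinstance(p, str) for p in parsed):
                    rd[label] = raw.strip()
                else:
                    rd[label] = parsed
    return rd


def write_review_dict(rd: ReviewDict, path, dialect: str = "colon"):
    """Write a ReviewDict; floats are printed to 6 significant digits in both
    dialects so the two representations of one dictionary compare equal."""
    if dialect == "json":
        obj = {}
        for k, v in rd.items():
            if isinstance(v, list):
                obj[k] = [sig6(x) if isinstance(x, (int, float, np.number)) else x for x in v]
            elif isinstance(v, (int, float, np.number)) and not isinstance(v, bool):
                obj[k] = sig6(v)
            else:
                obj[k] = v
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
            fh.write("\n")
        return
    if dialect != "colon":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for k, v in rd.items():
            if isinstance(v, list):
                val = " ".join(_format_value(x) for x in v)
            else:
                val = _format_value(v)
            fh.write(f"{k} : {val}\n")
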