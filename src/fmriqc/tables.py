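"""Single-subject review-dictionary assembly, group tabulation, criterion-
based outlier/keeper filtering, and the raw-header consistency scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .io import ReviewDict

__all__ = [
    "Criterion",
    "GroupTable",
    "MISSING",
    "build_ss_review",
    "build_group_table",
    "filter_report",
    "gtkyd_scan",
]

MISSING = "NA"

_OPS = ("VARY", "EQ", "GT", "LT", "GE", "LE", "SHOW")


@dataclass
class Criterion:
    """One filtering criterion: a review label, an operator, and (for the
    comparison operators) a value."""

    label: str
    op: str
    value: object = None

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        needs_value = self.op in ("EQ", "GT", "LT", "GE", "LE")
        if needs_value and self.value is None:
            raise ValueError(f"operator {self.op} requires a comparison value")
        if not needs_value and self.value is not None:
            raise ValueError(f"operator {self.op} takes no comparison value")

    @classmethod
    def parse(cls, text: str) -> "Criterion":
        """Parse a "LABEL OP [VALUE]" string (label may be quoted)."""
        text = text.strip()
        if text.startswith(("'", '"')):
            quote = text[0]
            end = text.index(quote, 1)
            label = text[1:end]
            rest = text[end + 1:].split()
        else:
            parts = text.split()
            label, rest = parts[0], parts[1:]
        if not rest:
            raise ValueError(f"no operator in criterion {text!r}")
        op = rest[0]
        value = None
        if len(rest) > 1:
            raw = " ".join(rest[1:]).strip("'\"")
            try:
                value = int(raw)
            except ValueError:
                try:
                    value = float(raw)
                except ValueError:
                    value = raw
        return cls(label=label, op=op, value=value)


@dataclass
class GroupTable:
    """One row per subject; columns in first-seen key order, subject id first."""

    df: pd.DataFrame

    @property
    def subjects(self) -> list:
        return list(self.df["subject"])

    def to_tsv(self, path, sep="\t"):
        self.df.to_csv(path, sep=sep, index=False)


def build_ss_review(fragments, software: dict | None = None) -> ReviewDict:
    """Merge review fragments from the QC modules into one dictionary.

    Fragment labels must not collide.  Software identification fields go
    first, mirroring the layout of the single-subject review text file.
    """
    out = ReviewDict()
    if software:
        for k, v in software.items():
            out[k] = v
    for frag in fragments:
        out = out.merge(frag)
    return out


def _expand(rd: ReviewDict) -> dict:
    """Flatten list-valued entries into suffixed columns."""
    flat = {}
    for k, v in rd.items():
        if isinstance(v, list):
            for i, x in enumerate(v):
                flat[f"{k}[{i}]"] = x
        else:
            flat[k] = v
    return flat


def build_group_table(dicts, subject_ids=None) -> GroupTable:
    """Tabulate ReviewDicts: columns follow first-seen order across inputs;
    cells missing for a subject get the sentinel, never silently dropped."""
    dicts = list(dicts)
    if not dicts:
        raise ValueError("need at least one review dict")
    if subject_ids is None:
        subject_ids = [d.get("subject ID", f"subj{i:03d}") for i, d in enumerate(dicts)]
    flats = [_expand(d) for d in dicts]
    columns = ["subject"]
    for f in flats:
        for k in f:
            if k not in columns:
                columns.append(k)
    rows = []
    for sid, f in zip(subject_ids, flats):
        rows.append([sid] + [f.get(c, MISSING) for c in columns[1:]])
    return GroupTable(pd.DataFrame(rows, columns=columns))


def _values_for(cell):
    """A cell's comparable values; list cells compare elementwise."""
    return list(cell) if isinstance(cell, (list, tuple)) else [cell]


def _num_eq(a, b, rtol=1e-9):
    return np.isclose(float(a), float(b), rtol=rtol, atol=0.0)


def _evaluate(op, cell_value, ref):
    """Evaluate one criterion on one cell value; type mismatches are errors."""
    is_num = isinstance(cell_value, (int, float, np.number)) and not isinstance(cell_value, bool)
    if op == "EQ":
        if is_num and isinstance(ref, (int, float)):
            return bool(_num_eq(cell_value, ref))
        return str(cell_value) == str(ref)
    if op == "VARY":
        if is_num and isinstance(ref, (int, float, np.number)):
            return not bool(_num_eq(cell_value, ref))
        return str(cell_value) != str(ref)
    if not is_num or not isinstance(ref, (int, float)):
        raise TypeError(f"operator {op} needs numeric operands, got "
                        f"{cell_value!r} vs {ref!r}")
    x, r = float(cell_value), float(ref)
    return {"GT": x > r, "LT": x < r, "GE": x >= r, "LE": x <= r}[op]


def _columns_for_label(df, label):
    cols = [c for c in df.columns if c == label or c.startswith(f"{label}[")]
    if not cols:
        raise KeyError(f"criterion label {label!r} not found in table")
    return cols


def filter_report(table: GroupTable, criteria, show_keepers: bool = False) -> GroupTable:
    """Report subjects matching (or, with show_keepers, failing) criteria.

    A subject appears when at least one comparison criterion evaluates True;
    VARY compares against the first subject's value (exact for strings,
    relative tolerance 1e-9 for reals).  In the output, only the values that
    triggered plus any SHOW columns are populated.  show_keepers inverts the
    selection to subjects with no True comparisons.
    """
    df = table.df
    comps = [c for c in criteria if c.op != "SHOW"]
    shows = [c for c in criteria if c.op == "SHOW"]
    # resolve criterion labels to (possibly expanded) columns up-front
    col_map = {c.label: _columns_for_label(df, c.label) for c in criteria}
    out_cols = ["subject"]
    for c in comps + shows:
        for col in col_map[c.label]:
            if col not in out_cols:
                out_cols.append(col)
    rows = []
    for _, row in df.iterrows():
        triggered = {}
        any_true = False
        for c in comps:
            for col in col_map[c.label]:
                cell = row[col]
                if isinstance(cell, str) and cell == MISSING:
                    continue
                ref = (df[col].iloc[0] if c.op == "VARY" else c.value)
                if _evaluate(c.op, cell, ref):
                    any_true = True
                    triggered[col] = cell
        selected = (not any_true) if show_keepers else any_true
        if not selected:
            continue
        rec = {"subject": row["subject"]}
        rec.update(triggered if not show_keepers else {})
        for c in shows:
            for col in col_map[c.label]:
                rec[col] = row[col]
        rows.append([rec.get(c, MISSING) for c in out_cols])
    return GroupTable(pd.DataFrame(rows, columns=out_cols))


def _scan_one(path) -> ReviewDict:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    rd = ReviewDict()
    rd["file"] = str(path)
    dims = list(data.shape[:3])
    rd["matrix dims"] = dims
    rd["voxel sizes"] = [round(float(z), 6) for z in zooms[:3]]
    rd["TR"] = round(float(zooms[3]), 6) if data.ndim > 3 and len(zooms) > 3 else 0
    rd["num volumes"] = int(data.shape[3]) if data.ndim > 3 else 1
    rd["orientation"] = "".join(nib.aff2axcodes(img.affine))
    rd["datum"] = str(np.asarray(img.dataobj).dtype)
    rd["min value"] = float(data.min())
    rd["max value"] = float(data.max())
    return rd


def gtkyd_scan(paths):
    """"Getting to know your data": per-dataset header/value properties plus
    a variability report flagging any property that differs from the first
    dataset.  Unreadable files become error rows; the scan continues.
    """
    dicts = []
    ids = []
    for p in paths:
        ids.append(str(p))
        try:
            dicts.append(_scan_one(p))
        except Exception as exc:
            rd = ReviewDict()
            rd["file"] = str(p)
            rd["error"] = f"{type(exc).__name__}: {exc}"
            dicts.append(rd)
    table = build_group_table(dicts, subject_ids=ids)
    prop_cols = [c for c in table.df.columns if c not in ("subject", "file")]
    criteria = [Criterion(label=c.split("[")[0], op="VARY") for c in prop_cols]
    # dedupe labels expanded from list-valued properties
    seen = set()
    uniq = []
    for c in criteria:
        if c.label not in seen:
            seen.add(c.label)
            uniq.append(c)
    report = filter_report(table, uniq)
    return table, report
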