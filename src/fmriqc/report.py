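"""Static HTML QC report assembly: montages, percentile/alpha thresholding,
grayplots, edge overlays, warn coloring, jump anchors, and the
ratings/comments JSON.

The report is a self-contained, relocatable directory (index.html + media/
PNGs + JSON sidecars) with one anchor per QC block.  Ratings are applied
through :func:`ratings_io` (or the ``apqc rate`` subcommand), which writes
the same JSON schema an interactive reviewer would produce, so the shareable
artifact needs no web stack.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sstats
from scipy.ndimage import binary_erosion

from .io import Dataset3D, Dataset4D, Mask3D, ReviewDict, write_review_dict
from .warns import WarnLevel, max_warn_level

__all__ = [
    "RenderSpec",
    "RatingRecord",
    "QC_BLOCKS",
    "RATING_SYMBOLS",
    "select_montage_slices",
    "apply_alpha_threshold",
    "render_grayplot",
    "render_edge_overlay",
    "assemble_report",
    "ratings_io",
]

# fixed block order of the report
QC_BLOCKS = ["vorig", "ve2a", "va2t", "vstat", "mot", "mecho", "regr",
             "radcor", "warns", "qsumm"]

RATING_SYMBOLS = {"good": "+", "bad": "X", "other": "?", "none": ""}
_SYMBOL_WORDS = {v: k for k, v in RATING_SYMBOLS.items()}


@dataclass
class RenderSpec:
    """Colorbar and thresholding rules for overlay rendering."""

    cbar_max_percentile: float = 99.0   # in whole-brain mask
    fstat_thr_percentile: float = 90.0  # in whole-brain mask
    t_p_two_sided: float = 0.001
    corr_threshold: float = 0.3
    corr_range: float = 0.6
    grayplot_p_two_sided: float = 0.001
    automask_frac: float = 0.25         # of the 98th-percentile intensity

    def __post_init__(self):
        for p in (self.cbar_max_percentile, self.fstat_thr_percentile):
            if not (0 < p < 100):
                raise ValueError("percentiles must lie in (0, 100)")

    def t_threshold(self, df: int) -> float:
        """Two-sided t threshold at the configured p, for df degrees of freedom."""
        return float(sstats.t.ppf(1.0 - self.t_p_two_sided / 2.0, df))

    def grayplot_z(self) -> float:
        """Two-sided normal quantile bounding the grayplot grayscale range."""
        return float(sstats.norm.ppf(1.0 - self.grayplot_p_two_sided / 2.0))


@dataclass
class RatingRecord:
    """Per-block rating (good/bad/other/none) and free comment."""

    ratings: dict = field(default_factory=dict)   # block -> rating word
    comments: dict = field(default_factory=dict)  # block -> comment


def select_montage_slices(vol: Dataset3D, axis: int = 2, n_slices: int = 6,
                          automask_frac: float = 0.25):
    """Evenly spaced slice indices within a light automask of the FOV.

    The automask keeps voxels above ``automask_frac`` of the 98th-percentile
    intensity; slices are spread over the automask's extent along the axis.
    Returns (indices, mm labels).  An empty automask falls back to the full
    extent.
    """
    vals = np.abs(np.asarray(vol.values, float))
    thr = automask_frac * np.percentile(vals, 98)
    auto = vals > thr
    if auto.any():
        axes = tuple(a for a in range(3) if a != axis)
        prof = auto.any(axis=axes)
        lo, hi = int(np.argmax(prof)), len(prof) - 1 - int(np.argmax(prof[::-1]))
    else:
        lo, hi = 0, vol.shape[axis] - 1
    if n_slices == 1:
        idx = np.array([(lo + hi) // 2])
    else:
        idx = np.unique(np.round(np.linspace(lo, hi, n_slices)).astype(int))
    labels = []
    for i in idx:
        ijk = [0.0, 0.0, 0.0]
        ijk[axis] = float(i)
        mm = vol.ijk_to_mm(ijk)[axis]
        labels.append(f"{mm:.1f} mm")
    return idx, labels


def apply_alpha_threshold(overlay: np.ndarray, threshold: float):
    """Transparent ("highlighting") thresholding of an overlay volume.

    Opacity is 1 at |v| >= threshold and falls off quadratically below it:
    alpha = (|v| / thr)**2.  Suprathreshold regions are outlined ("boxed").
    The overlay is deliberately not restricted to a brain mask.  Returns
    (alpha, boxed) arrays of the overlay's shape.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    v = np.abs(np.asarray(overlay, float))
    alpha = np.minimum((v / threshold) ** 2, 1.0)
    supra = v >= threshold
    boxed = supra & ~binary_erosion(supra)
    return alpha, boxed


def render_grayplot(dset: Dataset4D, mask: Mask3D, enorm=None, outfrac=None,
                    spec: RenderSpec | None = None, out_png=None):
    """Carpet plot of Z-scored in-mask series, rows ordered by decreasing
    |correlation| with the first principal component of the in-mask data;
    grayscale clipped at the two-sided p = 0.001 normal quantile.

    Returns (image matrix in display order, row ordering of in-mask voxels).
    """
    spec = spec or RenderSpec()
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    data = dset.values[m].astype(float)
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=0, keepdims=True)
    ok = np.ravel(sd > 0)
    if not ok.any():
        raise ValueError("degenerate (constant) dataset")
    z = np.zeros_like(data)
    z[ok] = (data[ok] - mean[ok]) / sd[ok]
    # leading principal time course from the T x T covariance of z
    cov = z.T @ z
    w, v = np.linalg.eigh(cov)
    pc = v[:, -1]
    corr = z @ pc / (np.linalg.norm(pc) * np.maximum(
        np.sqrt((z ** 2).sum(axis=1)), 1e-12))
    order = np.argsort(-np.abs(corr), kind="stable")
    img = z[order]
    zmax = spec.grayplot_z()
    img = np.clip(img, -zmax, zmax)
    if out_png is not None:
        nrow = 3 if enorm is not None else 1
        fig, axes = plt.subplots(nrow, 1, figsize=(8, 5), sharex=True,
                                 gridspec_kw={"height_ratios": [1, 1, 4][:nrow]})
        axes = np.atleast_1d(axes)
        if enorm is not None:
            axes[0].plot(enorm, lw=0.8, color="tab:blue")
            axes[0].set_ylabel("enorm")
            axes[1].plot(outfrac, lw=0.8, color="tab:orange")
            axes[1].set_ylabel("outlier\nfrac")
        axes[-1].imshow(img, aspect="auto", cmap="gray", vmin=-zmax, vmax=zmax,
                        interpolation="nearest")
        axes[-1].set_xlabel("volume")
        axes[-1].set_ylabel("voxels (PC-ordered)")
        fig.savefig(out_png, dpi=90)
        plt.close(fig)
    return img, order


def render_edge_overlay(base: Dataset3D, edges_src: Dataset3D):
    """Gradient-magnitude edges of one volume, for drawing over another on a
    shared grid.  The threshold is a fixed fraction of the robust (98th
    percentile) gradient maximum, so every strong tissue boundary survives
    regardless of how much of the volume is flat.

    Returns the boolean edge mask.
    """
    if base.shape != edges_src.shape:
        raise ValueError("grid mismatch between base and edge source")
    g = np.gradient(np.asarray(edges_src.values, float))
    gmag = np.sqrt(sum(gi ** 2 for gi in g))
    nz = gmag[gmag > 0]
    if nz.size == 0:
        return np.zeros(base.shape, dtype=bool)
    thr = 0.25 * np.percentile(nz, 98)
    return gmag > thr


# ---------------------------------------------------------------------------
# montage and report assembly
# ---------------------------------------------------------------------------

def _save_montage(path, base: Dataset3D, overlay=None, alpha=None, boxed=None,
                  edge=None, n_slices=6, title="", vmin=None, vmax=None,
                  overlay_range=None):
    idx, labels = select_montage_slices(base, axis=2, n_slices=n_slices)
    n = len(idx)
    fig, axes = plt.subplots(1, n, figsize=(1.8 * n, 2.2))
    axes = np.atleast_1d(axes)
    for ax, k, lab in zip(axes, idx, labels):
        sl = np.asarray(base.values, float)[:, :, k].T
        ax.imshow(sl, cmap="gray", origin="lower", vmin=vmin, vmax=vmax,
                  interpolation="nearest")
        if overlay is not None:
            ov = np.asarray(overlay, float)[:, :, k].T
            a = alpha[:, :, k].T if alpha is not None else np.ones_like(ov)
            rng = overlay_range or np.abs(ov).max() or 1.0
            rgba = plt.get_cmap("coolwarm")((ov / rng + 1) / 2)
            rgba[..., 3] = a
            ax.imshow(rgba, origin="lower", interpolation="nearest")
            if boxed is not None:
                yy, xx = np.where(boxed[:, :, k].T)
                ax.plot(xx, yy, ".k", ms=0.8)
        if edge is not None:
            em = edge[:, :, k].T
            rgba = np.zeros(em.shape + (4,))
            rgba[em] = (1.0, 0.85, 0.1, 1.0)
            ax.imshow(rgba, origin="lower", interpolation="nearest")
        ax.set_title(f"z={lab}", fontsize=6)
        ax.axis("off")
    if title:
        fig.suptitle(title, fontsize=8)
    fig.savefig(path, dpi=90)
    plt.close(fig)


def _plot_series(path, series_dict, censored=None, limits=None, title=""):
    fig, ax = plt.subplots(figsize=(8, 2.2))
    for lab, y in series_dict.items():
        ax.plot(y, lw=0.9, label=lab)
    if censored is not None:
        for t in censored:
            ax.axvspan(t - 0.5, t + 0.5, color="red", alpha=0.3, lw=0)
    if limits:
        for lv in limits:
            ax.axhline(lv, color="k", ls="--", lw=0.7)
    ax.legend(fontsize=6, loc="upper right")
    ax.set_xlabel("volume")
    if title:
        ax.set_title(title, fontsize=8)
    fig.savefig(path, dpi=90)
    plt.close(fig)


def _review_html_table(rd: ReviewDict) -> str:
    rows = []
    for k, v in rd.items():
        if isinstance(v, list):
            v = " ".join(str(x) for x in v)
        rows.append(f"<tr><td>{html.escape(str(k))}</td>"
                    f"<td>{html.escape(str(v))}</td></tr>")
    return "<table class='qtable'>" + "".join(rows) + "</table>"


_CSS = """
body { background: #101010; color: #e8e8e8; font-family: sans-serif; margin: 0; }
.menu { position: sticky; top: 0; background: #000; padding: 6px; z-index: 9; }
.menu a { color: #ffd700; margin-right: 10px; text-decoration: none; font-weight: bold; }
.block { padding: 12px 18px; border-bottom: 1px solid #333; }
.block h2 { color: #ffd700; }
img { max-width: 100%; }
.qtable td { border: 1px solid #444; padding: 2px 8px; font-family: monospace; }
.warn-item { margin: 4px 0; padding: 4px 8px; }
"""


def _warns_label_style(level: WarnLevel) -> str:
    # lowest three levels color the text; medium/severe invert to colored bg
    if level >= WarnLevel.medium:
        return f"color:#000;background:{level.color};padding:1px 4px;"
    return f"color:{level.color};"


def assemble_report(out_dir, subject: str, blocks: dict,
                    review: ReviewDict | None = None,
                    warn_items=None) -> Path:
    """Assemble the QC blocks into a portable static HTML directory.

    ``blocks`` maps block name -> list of HTML fragments (typically produced
    by the pipeline; image sources must be relative paths under media/).
    Missing optional blocks render a placeholder note; the warns label in the
    top menu is colored by the maximum warning level; qsumm embeds the full
    review dictionary.  Only relative paths are written, so the directory can
    be moved and viewed anywhere.
    """
    out_dir = Path(out_dir)
    (out_dir / "media").mkdir(parents=True, exist_ok=True)
    warn_items = warn_items or []
    top_level = max_warn_level(warn_items)
    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'>",
             f"<title>QC: {html.escape(subject)}</title>",
             f"<style>{_CSS}</style></head><body>"]
    menu = ["<div class='menu'>"]
    for b in QC_BLOCKS:
        style = _warns_label_style(top_level) if b == "warns" else ""
        menu.append(f"<a href='#{b}' style='{style}'>{b}</a>")
    menu.append(f"<span style='float:right'>subject: {html.escape(subject)}</span></div>")
    parts.append("".join(menu))
    for b in QC_BLOCKS:
        parts.append(f"<div class='block' id='{b}'><h2>{b}</h2>")
        content = blocks.get(b)
        if b == "qsumm" and review is not None:
            parts.append(_review_html_table(review))
        elif b == "warns":
            if warn_items:
                for it in warn_items:
                    parts.append(
                        f"<div class='warn-item' style='{_warns_label_style(it.level)}'>"
                        f"[{it.level.name}] {html.escape(it.name)}: "
                        f"{html.escape(it.message)}</div>")
            else:
                parts.append("<p>no warnings</p>")
            if content:
                parts.extend(content)
        elif content:
            parts.extend(content)
        elif b == "mecho":
            parts.append("<p>single-echo acquisition: no multi-echo "
                         "combination to review</p>")
        else:
            parts.append("<p>not available for this processing</p>")
        parts.append("</div>")
    parts.append("</body></html>")
    (out_dir / "index.html").write_text("".join(parts))
    # ratings stub + review JSON so group filtering can pick up FINAL ratings
    ratings_path = out_dir / f"apqc_{subject}.json"
    if not ratings_path.exists():
        stub = {b: {"rating": "none", "comment": ""} for b in QC_BLOCKS + ["FINAL"]}
        ratings_path.write_text(json.dumps(stub, indent=1))
    if review is not None:
        write_review_dict(review, out_dir / f"out.ss_review.{subject}.json",
                          dialect="json")
    return out_dir / "index.html"


def ratings_io(report_dir, subject: str, updates: RatingRecord | None = None
               ) -> RatingRecord:
    """Read, and optionally update, the ratings/comments JSON of a report.

    Symbols and words interconvert via the fixed mapping good=+, bad=X,
    other=?.  Adding a comment to an unrated block automatically applies a
    rating of "other".  Updates are merged into the subject's review JSON
    (key "FINAL rating" etc.) so group filtering can use them.
    """
    report_dir = Path(report_dir)
    path = report_dir / f"apqc_{subject}.json"
    obj = json.loads(path.read_text()) if path.exists() else {}
    valid = set(QC_BLOCKS) | {"FINAL"}
    if updates is not None:
        for block in list(updates.ratings) + list(updates.comments):
            if block not in valid:
                raise KeyError(f"unknown QC block {block!r}")
        for block, rating in updates.ratings.items():
            word = _SYMBOL_WORDS.get(rating, rating)
            if word not in RATING_SYMBOLS:
                raise ValueError(f"unknown rating {rating!r}")
            obj.setdefault(block, {"rating": "none", "comment": ""})
            obj[block]["rating"] = word
        for block, comment in updates.comments.items():
            obj.setdefault(block, {"rating": "none", "comment": ""})
            obj[block]["comment"] = comment
            if comment and obj[block].get("rating", "none") == "none":
                obj[block]["rating"] = "other"
        path.write_text(json.dumps(obj, indent=1))
        # merge into review JSON
        review_path = report_dir / f"out.ss_review.{subject}.json"
        if review_path.exists():
            review = json.loads(review_path.read_text())
            for block, entry in obj.items():
                key = "FINAL rating" if block == "FINAL" else f"QC rating ({block})"
                review[key] = entry["rating"]
                if entry.get("comment"):
                    ckey = ("FINAL comment" if block == "FINAL"
                            else f"QC comment ({block})")
                    review[ckey] = entry["comment"]
            review_path.write_text(json.dumps(review, indent=1) + "\n")
    record = RatingRecord()
    for block, entry in obj.items():
        record.ratings[block] = entry.get("rating", "none")
        if entry.get("comment"):
            record.comments[block] = entry["comment"]
    return record
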