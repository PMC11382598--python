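"""Regression-model QC: idealized stimulus responses, temporal degree-of-
freedom accounting (including the cost of bandpassing), per-stimulus censor
fractions, and design-matrix collinearity warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Matrix1D, ReviewDict, sig6
from .motion import CensorVector
from .warns import WarnItem, WarnLevel

__all__ = [
    "IdealResponse",
    "DFSummary",
    "build_ideal_response",
    "gamma_hrf",
    "count_bandpass_regressors",
    "df_accounting",
    "stim_censor_fractions",
    "cormat_warnings",
    "DEFAULT_COLLINEARITY_GRADES",
]


@dataclass
class IdealResponse:
    """Per-stimulus convolved regressors plus their summed series."""

    series: np.ndarray  # (T, n_stim)
    labels: list[str]

    def __post_init__(self):
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if len(self.labels) != self.series.shape[1]:
            raise ValueError("one label per stimulus column required")

    @property
    def summed(self) -> np.ndarray:
        return self.series.sum(axis=1)

    @property
    def n_stim(self) -> int:
        return self.series.shape[1]


@dataclass
class DFSummary:
    """Temporal degree-of-freedom bookkeeping: total = censored + used + left."""

    total: int
    censored: int
    used_by_regressors: int
    left: int
    final_fraction: float
    warn: WarnItem | None = None

    def __post_init__(self):
        if self.total != self.censored + self.used_by_regressors + self.left:
            raise ValueError("DF conservation violated")
        if not (0.0 <= self.final_fraction <= 1.0):
            raise ValueError("final_fraction must be in [0, 1]")

    def as_review_fragment(self) -> ReviewDict:
        rd = ReviewDict()
        rd["degrees of freedom used"] = self.used_by_regressors
        rd["degrees of freedom left"] = self.left
        rd["final DF fraction"] = round(self.final_fraction, 6)
        return rd


def gamma_hrf(t: np.ndarray, peak: float = 4.5, power: float = 5.0) -> np.ndarray:
    """Unit-peak gamma-variate response kernel (t/p)^q exp(q - q t / p)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (t[pos] / peak) ** power * np.exp(power - power * t[pos] / peak)
    return out


def build_ideal_response(onsets: dict, durations: dict, hrf: str, tr: float,
                         T: int) -> IdealResponse:
    """Convolve stimulus timing with a unit-peak response kernel at TR.

    ``onsets`` maps stimulus label -> onset seconds; ``durations`` gives the
    boxcar duration per label.  Kernels: "gamma" (gamma-variate), "block"
    (the boxcar itself), "identity" (a single-sample impulse).
    """
    labels = list(onsets)
    run_end = T * tr
    cols = []
    t_axis = np.arange(T) * tr
    if hrf == "gamma":
        kernel = gamma_hrf(np.arange(0, 30.0 + tr, tr))
    elif hrf in ("block", "identity"):
        kernel = np.array([1.0])
    else:
        raise ValueError(f"unknown hrf {hrf!r}")
    for lab in labels:
        box = np.zeros(T)
        dur = durations.get(lab, 0.0) if isinstance(durations, dict) else durations
        for on in onsets[lab]:
            if on < 0 or on >= run_end:
                raise ValueError(f"onset {on} s outside run [0, {run_end}) for {lab!r}")
            sel = (t_axis >= on) & (t_axis <= on + max(dur, tr / 2))
            box[sel] = 1.0
        conv = np.convolve(box, kernel)[:T]
        peak = np.abs(conv).max()
        cols.append(conv / peak if peak > 0 else conv)
    return IdealResponse(series=np.column_stack(cols), labels=labels)


def count_bandpass_regressors(T: int, tr: float, band) -> int:
    """Number of Fourier regressors removed by bandpassing to [fbot, ftop] Hz.

    DFT frequencies f_k = k / (T * tr) for k = 1..floor(T/2); each
    out-of-band frequency costs 2 DFs (sine and cosine), except the Nyquist
    bin for even T which costs 1.  DC is excluded (handled by the drift
    model).  Band endpoints are inclusive.
    """
    fbot, ftop = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= fbot < ftop):
        raise ValueError("need 0 <= fbot < ftop")
    if ftop > nyquist + 1e-12:
        raise ValueError(f"ftop {ftop} above Nyquist {nyquist}")
    n = 0
    for k in range(1, T // 2 + 1):
        f = k / (T * tr)
        if fbot <= f <= ftop:
            continue
        is_nyquist = (T % 2 == 0) and (k == T // 2)
        n += 1 if is_nyquist else 2
    return n


def df_accounting(T: int, n_censored: int, n_motion: int = 0, n_drift: int = 0,
                  n_stim: int = 0, n_bandpass: int = 0) -> DFSummary:
    """Account for temporal DFs consumed by censoring and regressors.

    left = T - censored - (motion + drift + stim + bandpass).  A negative
    remainder raises a severe warning and clamps the fraction at 0 rather
    than failing.
    """
    counts = (n_censored, n_motion, n_drift, n_stim, n_bandpass)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    used = n_motion + n_drift + n_stim + n_bandpass
    left = T - n_censored - used
    warn = None
    if left < 0:
        warn = WarnItem("degrees of freedom", WarnLevel.severe,
                        f"model consumes {n_censored + used} DFs but only "
                        f"{T} available", payload={"deficit": -left})
        frac = 0.0
    else:
        frac = left / T
    return DFSummary(total=T, censored=n_censored, used_by_regressors=used,
                     left=T - n_censored - used, final_fraction=frac, warn=warn)


def stim_censor_fractions(ideal: IdealResponse, cv: CensorVector,
                          tol: float = 1e-6):
    """Per stimulus: fraction of response volumes (nonzero ideal) censored.

    Fractions are rounded to 3 decimals for reporting.  A stimulus with no
    response volumes gets fraction None and a severe warning; a fully
    censored stimulus is also severe.
    """
    if ideal.series.shape[0] != cv.n_total:
        raise ValueError("ideal response and censor lengths must match")
    censored = cv.keep == 0
    fractions = []
    counts = []
    ncens = []
    warns = []
    for j, lab in enumerate(ideal.labels):
        resp = np.abs(ideal.series[:, j]) > tol
        n_resp = int(resp.sum())
        counts.append(n_resp)
        if n_resp == 0:
            fractions.append(None)
            ncens.append(0)
            warns.append(WarnItem(f"stimulus {lab!r} response", WarnLevel.severe,
                                  "stimulus has no response volumes"))
            continue
        n_c = int((resp & censored).sum())
        ncens.append(n_c)
        frac = round(n_c / n_resp, 3)
        fractions.append(frac)
        if n_c == n_resp:
            warns.append(WarnItem(f"stimulus {lab!r} censoring", WarnLevel.severe,
                                  "all response volumes censored"))
    return {"labels": list(ideal.labels), "n_response": counts,
            "n_censored": ncens, "fractions": fractions, "warnings": warns}


DEFAULT_COLLINEARITY_GRADES = [(0.4, WarnLevel.mild), (0.6, WarnLevel.medium),
                               (0.9, WarnLevel.severe)]


def cormat_warnings(design: Matrix1D, grades=None) -> list[WarnItem]:
    """Warn on highly correlated design-matrix column pairs.

    All pairs with |r| at or above the lowest grade are listed, level graded
    by |r|; identical columns reach |r| = 1 and are severe.  Constant columns
    are flagged separately (correlation undefined).
    """
    grades = grades or DEFAULT_COLLINEARITY_GRADES
    X = design.values
    if X.shape[1] < 2:
        raise ValueError("need at least 2 design columns")
    labels = design.column_labels or [f"col{j}" for j in range(X.shape[1])]
    items = []
    Xd = X - X.mean(axis=0)
    norms = np.sqrt((Xd ** 2).sum(axis=0))
    for j in np.flatnonzero(norms == 0):
        items.append(WarnItem(f"constant regressor {labels[j]!r}",
                              WarnLevel.medium,
                              "design column has zero variance"))
    for i in range(X.shape[1]):
        for j in range(i + 1, X.shape[1]):
            if norms[i] == 0 or norms[j] == 0:
                continue
            r = float(Xd[:, i] @ Xd[:, j] / (norms[i] * norms[j]))
            level = WarnLevel.none
            for cut, lev in grades:
                if abs(r) >= cut:
                    level = lev
            if level > WarnLevel.none:
                items.append(WarnItem(
                    f"collinearity {labels[i]!r} vs {labels[j]!r}", level,
                    f"design columns correlated at r = {r:.4f}",
                    payload={"pair": (labels[i], labels[j]), "r": r}))
    return items
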