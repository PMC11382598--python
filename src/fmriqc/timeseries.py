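"""Shared temporal helpers: Legendre-polynomial detrending applied per run.

The slow-drift model follows the common convention of one polynomial order
per 150 s of run duration, on top of a linear term: order = 1 + floor(D/150)
for a run lasting D seconds.
"""

from __future__ import annotations

import numpy as np

__all__ = ["polort_for_run", "legendre_basis", "detrend_series", "detrend_dataset"]


def polort_for_run(run_len: int, tr: float) -> int:
    """Polynomial order used for detrending a run of run_len volumes at tr s."""
    return 1 + int(run_len * tr // 150)


def legendre_basis(n: int, order: int) -> np.ndarray:
    """Legendre polynomials P_0..P_order sampled on n points over [-1, 1].

    Returns an (n, order+1) design matrix.
    """
    x = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    cols = []
    for k in range(order + 1):
        c = np.zeros(k + 1)
        c[k] = 1.0
        cols.append(np.polynomial.legendre.legval(x, c))
    return np.column_stack(cols)


def detrend_series(arr: np.ndarray, order: int) -> np.ndarray:
    """Remove a Legendre polynomial fit from each row of an (n_series, T) array."""
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    T = arr.shape[1]
    order = min(order, T - 1)
    basis = legendre_basis(T, order)
    coef, *_ = np.linalg.lstsq(basis, arr.T, rcond=None)
    return arr - (basis @ coef).T


def detrend_dataset(values: np.ndarray, run_lengths, tr: float,
                    order: int | None = None) -> np.ndarray:
    """Detrend a (..., T) array run by run; order defaults to the duration rule."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    start = 0
    for rl in run_lengths:
        ord_run = polort_for_run(rl, tr) if order is None else order
        block = values[..., start:start + rl].reshape(-1, rl)
        out[..., start:start + rl] = detrend_series(block, ord_run).reshape(
            values.shape[:-1] + (rl,))
        start += rl
    return out
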