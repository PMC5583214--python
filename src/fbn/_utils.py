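"""Shared constants and small helpers."""

from __future__ import annotations

import numpy as np

#: Entries with absolute value at or below this are treated as structural zeros
#: (proximal solvers produce exact zeros, but text round-trips leave float dust).
ZERO_TOL = 1e-12

#: Significant digits used for all text output; chosen so write/read round-trips
#: are stable at test tolerances.
PRINT_PRECISION = 10


def as_matrix(W) -> np.ndarray:
    """Return the underlying n×n ndarray of a ConnectivityMatrix or array-like."""
    values = getattr(W, "W", W)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        from .errors import DimensionError

        raise DimensionError(f"expected a square matrix, got shape {arr.shape}")
    return arr


def check_symmetric(W: np.ndarray, tol: float = 1e-10) -> bool:
    return bool(np.max(np.abs(W - W.T), initial=0.0) <= tol)
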