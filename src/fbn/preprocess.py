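"""Column standardization: centering plus unit-Euclidean-norm scaling.

Each ROI time course x_i is replaced by (x_i − x̄_i)/‖x_i − x̄_i‖₂.  With this
convention (unit norm, not unit variance) the Gram matrix XᵀX is exactly the
Pearson correlation matrix, which is what the matrix-optimization estimators
in :mod:`fbn.estimators` assume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DegenerateColumnError, ParameterError
from .io_formats import TimeSeriesMatrix

__all__ = ["StandardizedTimeSeries", "standardize_columns"]


@dataclass
class StandardizedTimeSeries:
    """A t×n matrix whose columns are centered with unit Euclidean norm.

    ``degenerate_columns`` lists indices of constant ROIs mapped to zero
    under ``degenerate_policy="zero"``; such columns violate the unit-norm
    invariant by construction and are flagged rather than hidden.
    """

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    degenerate_columns: tuple[int, ...] = ()
    standardized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{k + 1}" for k in range(self.values.shape[1])]

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def to_timeseries(self) -> TimeSeriesMatrix:
        return TimeSeriesMatrix(
            values=self.values.copy(),
            roi_labels=list(self.roi_labels),
            subject_id=self.subject_id,
        )


def standardize_columns(
    X, degenerate_policy: str = "error"
) -> StandardizedTimeSeries:
    """Center each column and scale it to unit Euclidean norm.

    Parameters
    ----------
    X
        A :class:`~fbn.io_formats.TimeSeriesMatrix` or a t×n array.
    degenerate_policy
        What to do with a constant column (zero norm after centering):
        ``"error"`` (default) aborts naming the ROI — a silently zeroed
        column would shift downstream feature ranks invisibly; ``"zero"``
        maps it to all-zeros and records a warning.
    """
    if degenerate_policy not in ("error", "zero"):
        raise ParameterError(f"unknown degenerate_policy {degenerate_policy!r}")
    if isinstance(X, StandardizedTimeSeries):
        values = X.values
        labels = list(X.roi_labels)
        sid = X.subject_id
    elif isinstance(X, TimeSeriesMatrix):
        values = X.values
        labels = list(X.roi_labels)
        sid = X.subject_id
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise ContractError("expected a 2-D time-series matrix")
        labels = [f"ROI_{k + 1}" for k in range(values.shape[1])]
        sid = ""
    t, n = values.shape
    if t < 2:
        raise ContractError(f"need at least 2 time points, got {t}")

    centered = values - values.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0)
    scale = max(1.0, float(np.abs(values).max(initial=0.0)))
    degenerate = np.flatnonzero(norms <= 1e-12 * scale * np.sqrt(t))
    if degenerate.size:
        names = [labels[k] for k in degenerate]
        if degenerate_policy == "error":
            raise DegenerateColumnError(
                f"constant ROI column(s) with zero norm after centering: {names}"
            )
        warnings.warn(
            f"degenerate ROI column(s) mapped to zero: {names}",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = norms.copy()
    safe[degenerate] = 1.0
    out = centered / safe
    out[:, degenerate] = 0.0
    return StandardizedTimeSeries(
        values=out,
        roi_labels=labels,
        subject_id=sid,
        degenerate_columns=tuple(int(k) for k in degenerate),
    )
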