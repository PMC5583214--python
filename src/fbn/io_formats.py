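"""Text I/O for ROI time series, connectivity matrices and cohort manifests.

All formats are plain UTF-8 delimited text with "." as the decimal separator:

* time series — one row per time point, one column per ROI, optional single
  header row of ROI labels;
* networks — either a full n×n table with a label header ("matrix") or a
  3-column edge list over the strictly-upper triangle ("edge_list");
* cohort manifests — delimited table with header columns
  ``subject_id``, ``path``, ``label``.

Orientation is fixed as rows=time, columns=ROI; a ``transpose`` flag is
available but never inferred, because silently guessing the orientation
corrupts every downstream correlation.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from ._utils import PRINT_PRECISION, ZERO_TOL
from .errors import DimensionError, FormatError, ParseError

__all__ = [
    "TimeSeriesMatrix",
    "CohortEntry",
    "CohortManifest",
    "read_timeseries",
    "write_timeseries",
    "read_network",
    "read_edge_list",
    "write_network",
    "read_cohort_manifest",
    "write_cohort_manifest",
    "DEFAULT_LABEL_MAP",
]

#: Documented mapping from raw manifest label tokens (lowercased) to the
#: canonical {positive, negative} pair. "positive" is the patient group.
DEFAULT_LABEL_MAP = {
    "positive": "positive",
    "pos": "positive",
    "1": "positive",
    "patient": "positive",
    "case": "positive",
    "asd": "positive",
    "negative": "negative",
    "neg": "negative",
    "0": "negative",
    "control": "negative",
    "nc": "negative",
    "hc": "negative",
}


@dataclass
class TimeSeriesMatrix:
    """A t×n matrix of ROI signals for one subject (rows=time, columns=ROI)."""

    values: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("time series must be a 2-D matrix")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise DimensionError(
                f"need at least 2 time points and 2 ROIs, got {t}×{n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("time series contains non-finite entries")
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{k + 1}" for k in range(n)]
        if len(self.roi_labels) != n:
            raise DimensionError(
                f"{len(self.roi_labels)} labels for {n} columns"
            )

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CohortEntry:
    subject_id: str
    path: str
    label: str  # "positive" or "negative"


@dataclass
class CohortManifest:
    entries: list[CohortEntry]

    def __post_init__(self) -> None:
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise FormatError(f"duplicate subject_id(s) in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    @property
    def subject_ids(self) -> list[str]:
        return [e.subject_id for e in self.entries]


def _rows_from_file(path: str, delimiter: str) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delimiter) if row]
    # tolerate repeated whitespace delimiters ("1  2") producing empty tokens
    return [[tok for tok in row if tok.strip() != ""] for row in rows]


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_timeseries(
    path: str,
    delimiter: str = "\t",
    transpose: bool = False,
    subject_id: str | None = None,
) -> TimeSeriesMatrix:
    """Read a delimited time-series table (rows=time, columns=ROI).

    A single leading row whose cells are not all numeric is taken as the ROI
    label header; otherwise labels default to ``ROI_1 … ROI_n``.
    """
    rows = _rows_from_file(path, delimiter)
    if not rows:
        raise FormatError(f"{path}: empty file")
    labels: list[str] = []
    if not all(_is_float(tok) for tok in rows[0]):
        labels = [tok.strip() for tok in rows[0]]
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: header but no data rows")
    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=float)
    for r, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged table — data row {r + 1} has {len(row)} "
                f"cells, expected {width}"
            )
        for c, tok in enumerate(row):
            try:
                data[r, c] = float(tok)
            except ValueError:
                col = labels[c] if labels else f"column {c + 1}"
                raise ParseError(
                    f"{path}: non-numeric cell {tok!r} at data row "
                    f"{r + 1}, {col}"
                ) from None
    if transpose:
        data = data.T
        labels = []
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise DimensionError(
            f"{path}: need ≥2 time points and ≥2 ROIs, got "
            f"{data.shape[0]}×{data.shape[1]}"
        )
    sid = subject_id or os.path.splitext(os.path.basename(path))[0]
    return TimeSeriesMatrix(values=data, roi_labels=labels, subject_id=sid)


def _fmt(x: float, precision: int) -> str:
    return f"{x:.{precision}g}"


def write_timeseries(
    ts: TimeSeriesMatrix,
    path: str,
    delimiter: str = "\t",
    precision: int = PRINT_PRECISION,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(ts.roi_labels) + "\n")
        for row in ts.values:
            fh.write(delimiter.join(_fmt(v, precision) for v in row) + "\n")


def write_network(
    W,
    path: str,
    fmt: str = "matrix",
    roi_labels: list[str] | None = None,
    delimiter: str = "\t",
    zero_tol: float = ZERO_TOL,
    precision: int = PRINT_PRECISION,
) -> None:
    """Write a connectivity matrix as a full table or an upper-triangle edge list.

    The edge list has one line per unordered pair (i<j) with |W_ij| > zero_tol,
    columns: label_i, label_j, weight.
    """
    arr = np.asarray(getattr(W, "W", W), dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise DimensionError(f"network must be square, got shape {arr.shape}")
    n = arr.shape[0]
    labels = roi_labels or getattr(W, "roi_labels", None) or [
        f"ROI_{k + 1}" for k in range(n)
    ]
    if len(labels) != n:
        raise DimensionError(f"{len(labels)} labels for {n} nodes")
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "matrix":
            fh.write(delimiter.join(labels) + "\n")
            for row in arr:
                fh.write(
                    delimiter.join(_fmt(v, precision) for v in row) + "\n"
                )
        elif fmt == "edge_list":
            for i in range(n):
                for j in range(i + 1, n):
                    if abs(arr[i, j]) > zero_tol:
                        fh.write(
                            delimiter.join(
                                [labels[i], labels[j], _fmt(arr[i, j], precision)]
                            )
                            + "\n"
                        )
        else:
            raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str, delimiter: str = "\t"):
    """Read a full-matrix network file; returns (W, roi_labels)."""
    rows = _rows_from_file(path, delimiter)
    if not rows:
        raise FormatError(f"{path}: empty file")
    labels = [tok.strip() for tok in rows[0]]
    n = len(labels)
    if len(rows) - 1 != n:
        raise FormatError(
            f"{path}: {n} labels but {len(rows) - 1} matrix rows"
        )
    W = np.empty((n, n), dtype=float)
    for r, row in enumerate(rows[1:]):
        if len(row) != n:
            raise FormatError(f"{path}: ragged matrix row {r + 1}")
        W[r] = [float(tok) for tok in row]
    return W, labels


def read_edge_list(
    path: str, roi_labels: list[str], delimiter: str = "\t"
) -> np.ndarray:
    """Reconstruct a symmetric matrix from a 3-column edge list."""
    index = {lab: k for k, lab in enumerate(roi_labels)}
    n = len(roi_labels)
    W = np.zeros((n, n), dtype=float)
    for r, row in enumerate(_rows_from_file(path, delimiter)):
        if len(row) != 3:
            raise FormatError(f"{path}: edge line {r + 1} has {len(row)} cells")
        a, b, w = row
        try:
            i, j = index[a], index[b]
        except KeyError as exc:
            raise ParseError(f"{path}: unknown ROI label {exc} on line {r + 1}")
        W[i, j] = W[j, i] = float(w)
    return W


def read_cohort_manifest(
    path: str,
    delimiter: str = "\t",
    label_map: dict[str, str] | None = None,
    require_files: bool = True,
) -> CohortManifest:
    """Read a subject manifest; labels normalized via ``DEFAULT_LABEL_MAP``.

    Relative subject paths are resolved against the manifest's directory.
    """
    label_map = label_map or DEFAULT_LABEL_MAP
    base = os.path.dirname(os.path.abspath(path))
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty manifest")
        missing = {"subject_id", "path", "label"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
        entries = []
        for row in reader:
            sid = row["subject_id"].strip()
            token = row["label"].strip().lower()
            if token not in label_map:
                raise ParseError(
                    f"{path}: unknown label {row['label']!r} for subject {sid}"
                )
            p = row["path"].strip()
            if not os.path.isabs(p):
                p = os.path.join(base, p)
            if require_files and not os.path.exists(p):
                raise FormatError(
                    f"{path}: time-series file missing for subject {sid}: {p}"
                )
            entries.append(CohortEntry(sid, p, label_map[token]))
    if not entries:
        raise FormatError(f"{path}: manifest has no subjects")
    return CohortManifest(entries)


def write_cohort_manifest(
    manifest: CohortManifest, path: str, delimiter: str = "\t"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(["subject_id", "path", "label"]) + "\n")
        for e in manifest.entries:
            fh.write(delimiter.join([e.subject_id, e.path, e.label]) + "\n")
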