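"""Vectorized spectrograms and Standard Normal Variate preprocessing.

Each sample's time-frequency power matrix is read row by row, left to
right, into a single feature row (row-major flattening), so element
``(i, j)`` of the grid lands at column ``i * n_bins + j``.  Rows are
stacked into a samples x variables matrix — 262,144 variables at the
default 256 x 1024 grid.  The grid shape is retained so loading maps can
be projected back onto the time-frequency plane unambiguously.

SNV normalizes each row (sample) independently to mean 0 and standard
deviation 1.  The SD denominator is the sample SD (n-1) by default;
with 262,144 variables the n vs n-1 distinction is negligible, but it is
exposed for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AssemblyError, ParseError, ShapeError, ZeroVarianceError
from .spectro import Spectrogram

__all__ = [
    "FeatureMatrix",
    "vectorize",
    "unvectorize",
    "assemble",
    "snv",
    "save_feature_matrix",
    "load_feature_matrix",
]


@dataclass
class FeatureMatrix:
    """Samples x variables matrix with per-row identities and labels."""

    values: np.ndarray
    sample_ids: list[str]
    grid_shape: tuple[int, int]
    group_labels: list[str] | None = None
    snv_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("feature matrix must be 2-D")
        n_rows, n_cols = self.values.shape
        if n_cols != self.grid_shape[0] * self.grid_shape[1]:
            raise ShapeError(
                f"column count {n_cols} != product of grid_shape {self.grid_shape}"
            )
        if len(self.sample_ids) != n_rows:
            raise ShapeError("sample_ids length must equal the number of rows")
        if self.group_labels is not None and len(self.group_labels) != n_rows:
            raise ShapeError("group_labels length must equal the number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def vectorize(spec: Spectrogram) -> np.ndarray:
    """Flatten a spectrogram row-major into one feature row."""
    return np.asarray(spec.power, dtype=np.float64).reshape(-1)


def unvectorize(row: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Invert :func:`vectorize`: reshape a feature row back onto the grid."""
    row = np.asarray(row)
    if row.size != grid_shape[0] * grid_shape[1]:
        raise ShapeError(
            f"row of length {row.size} does not match grid_shape {grid_shape}"
        )
    return row.reshape(grid_shape)


def assemble(specs: Sequence[Spectrogram]) -> FeatureMatrix:
    """Stack vectorized spectrograms into one feature matrix.

    Row order follows input order; sample ids must be unique and all
    spectrograms must share one grid shape.
    """
    specs = list(specs)
    if not specs:
        raise AssemblyError("cannot assemble an empty list of spectrograms")
    grid_shape = specs[0].shape
    for s in specs[1:]:
        if s.shape != grid_shape:
            raise AssemblyError(
                f"heterogeneous spectrogram shapes: {grid_shape} vs {s.shape} "
                f"(sample {s.sample_id!r})"
            )
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AssemblyError(f"duplicate sample ids: {dupes}")
    labels = [getattr(s, "group_label", None) for s in specs]
    values = np.vstack([vectorize(s) for s in specs])
    group_labels = (
        [str(l) for l in labels] if all(l is not None for l in labels) else None
    )
    return FeatureMatrix(
        values=values, sample_ids=ids, grid_shape=grid_shape,
        group_labels=group_labels,
    )


def snv(matrix: FeatureMatrix, ddof: int = 1) -> FeatureMatrix:
    """Standard Normal Variate transform: each row to mean 0, SD 1."""
    X = matrix.values
    means = X.mean(axis=1, keepdims=True)
    sds = X.std(axis=1, ddof=ddof, keepdims=True)
    bad = np.flatnonzero(sds.ravel() == 0)
    if bad.size:
        names = [matrix.sample_ids[i] for i in bad]
        raise ZeroVarianceError(f"constant row(s), cannot SNV-normalize: {names}")
    return replace(matrix, values=(X - means) / sds, snv_applied=True)


def save_feature_matrix(matrix: FeatureMatrix, npz_path: str | Path,
                        sidecar_path: str | Path | None = None) -> Path:
    """Persist to a binary array container plus a delimited sidecar table."""
    npz_path = Path(npz_path)
    np.savez(
        npz_path,
        values=matrix.values,
        sample_ids=np.asarray(matrix.sample_ids),
        group_labels=np.asarray(
            matrix.group_labels if matrix.group_labels is not None else []
        ),
        grid_shape=np.asarray(matrix.grid_shape),
        snv_applied=np.bool_(matrix.snv_applied),
    )
    if sidecar_path is not None:
        df = pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "group_label": matrix.group_labels
                if matrix.group_labels is not None
                else [""] * matrix.n_samples,
                "row_index": np.arange(matrix.n_samples),
                "grid_rows": matrix.grid_shape[0],
                "grid_cols": matrix.grid_shape[1],
                "snv_applied": matrix.snv_applied,
            }
        )
        df.to_csv(sidecar_path, index=False)
    return npz_path


def load_feature_matrix(npz_path: str | Path) -> FeatureMatrix:
    try:
        with np.load(npz_path, allow_pickle=False) as z:
            labels = [str(x) for x in z["group_labels"]]
            return FeatureMatrix(
                values=z["values"],
                sample_ids=[str(x) for x in z["sample_ids"]],
                grid_shape=tuple(int(v) for v in z["grid_shape"]),
                group_labels=labels or None,
                snv_applied=bool(z["snv_applied"]),
            )
    except (KeyError, OSError, ValueError) as exc:
        raise ParseError(f"{npz_path}: not a valid feature-matrix archive ({exc})") from exc
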