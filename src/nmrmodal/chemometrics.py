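"""NIPALS PCA, two-class PLS-DA, and correlation-loading maps.

The data matrix here is very wide (a handful of serum samples by 262,144
time-frequency variables), and only a few latent components are ever
needed, so both models are fit with NIPALS — the classic one-component-
at-a-time power iteration with deflation — rather than a full SVD.

PCA
    Columns are mean-centered internally.  Component extraction repeats
    (with ``t`` a score column, ``p`` a unit-norm loading column):

        p <- X't / (t't);  p <- p / ||p||;  t <- X p

    until ``t`` stabilizes, then deflates ``X <- X - t p'``.  The
    explained-variance fraction of a component is ``t't`` over the total
    centered sum of squares.

PLS-DA
    The two class labels are coded as a single -1/+1 dummy response
    ``y`` (mean-centered), then PLS1 NIPALS runs

        w <- X'y / ||X'y||;  t <- X w;  q <- y't / t't;  p <- X't / t't

    followed by deflation of both ``X`` and ``y``.  Factor-1 scores are
    oriented so the positively coded class has the higher mean score.

Correlation loadings
    For a chosen score column, the correlation loading of variable ``j``
    is the plain Pearson correlation between the scores and column ``j``
    of the (preprocessed) data matrix, back-projected onto the
    time-frequency grid.  Cells with zero variance across samples (e.g.
    all-zero spectrogram cells) are undefined (NaN) and never enter the
    threshold mask.  Cells at or above the magnitude threshold (default
    0.4) are the variables deemed relevant to the separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ClassCountError,
    DegenerateScoresError,
    InvalidParameterError,
    RankError,
)
from .features import FeatureMatrix, unvectorize

__all__ = [
    "PCAResult",
    "PLSDAResult",
    "CorrelationLoadingMap",
    "pca_fit",
    "plsda_fit",
    "correlation_loadings",
    "threshold_mask",
    "export_model",
    "export_loading_map",
]

DEFAULT_LOADING_THRESHOLD = 0.4


@dataclass
class PCAResult:
    """Scores, unit-norm loadings and explained-variance fractions."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    column_means: np.ndarray
    n_components: int
    n_iterations: list[int]
    sample_ids: list[str] | None = None


@dataclass
class PLSDAResult:
    """PLS1 discriminant model: T, P, W, q and the class coding."""

    x_scores: np.ndarray
    x_loadings: np.ndarray
    x_weights: np.ndarray
    y_loadings: np.ndarray
    class_coding: dict[str, float]
    n_factors: int
    column_means: np.ndarray
    y_mean: float
    n_iterations: list[int]
    sample_ids: list[str] | None = None

    def factor1_labels(self) -> list[str]:
        """Class assignment of each training sample by Factor-1 score sign."""
        inv = {v: k for k, v in self.class_coding.items()}
        return [inv[1.0] if s > 0 else inv[-1.0] for s in self.x_scores[:, 0]]


@dataclass
class CorrelationLoadingMap:
    """Pearson correlations on the time-frequency grid, plus mask."""

    r_values: np.ndarray
    threshold: float = DEFAULT_LOADING_THRESHOLD

    @property
    def mask(self) -> np.ndarray:
        return threshold_mask(self, self.threshold)


def _as_values(matrix: FeatureMatrix | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values, matrix.sample_ids
    return np.asarray(matrix, dtype=np.float64), None


def _flip_to_positive_max(loading: np.ndarray) -> float:
    """Sign making the largest-magnitude loading element positive."""
    j = int(np.argmax(np.abs(loading)))
    return 1.0 if loading[j] >= 0 else -1.0


def pca_fit(
    matrix: FeatureMatrix | np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> PCAResult:
    """Fit PCA by NIPALS with internal column mean-centering.

    Components are extracted in order of decreasing variance; each
    loading column has unit norm and is sign-fixed so its largest-
    magnitude element is positive.  Non-convergence within ``max_iter``
    emits a warning rather than failing silently.
    """
    X, sample_ids = _as_values(matrix)
    n, p = X.shape
    if n < 2:
        raise RankError("PCA needs at least 2 samples")
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise RankError(
            f"n_components={n_components} outside [1, min(n-1, p)={max_rank}]"
        )
    means = X.mean(axis=0)
    Xc = X - means
    total_ss = float(np.sum(Xc * Xc))
    if total_ss == 0.0:
        raise RankError("data matrix has zero variance after centering")

    scores = np.empty((n, n_components))
    loadings = np.empty((p, n_components))
    explained = np.empty(n_components)
    iters: list[int] = []
    for c in range(n_components):
        # start from the column with the largest residual variance
        t = Xc[:, int(np.argmax(np.sum(Xc * Xc, axis=0)))].copy()
        if not np.any(t):
            t = Xc[:, 0] + 1e-30
        it = 0
        for it in range(1, max_iter + 1):
            pvec = Xc.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = Xc @ pvec
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        else:
            warnings.warn(
                f"PCA component {c + 1} did not converge in {max_iter} iterations",
                stacklevel=2,
            )
        sign = _flip_to_positive_max(pvec)
        pvec *= sign
        t *= sign
        scores[:, c] = t
        loadings[:, c] = pvec
        explained[c] = (t @ t) / total_ss
        iters.append(it)
        Xc = Xc - np.outer(t, pvec)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=explained,
        column_means=means,
        n_components=n_components,
        n_iterations=iters,
        sample_ids=sample_ids,
    )


def plsda_fit(
    matrix: FeatureMatrix,
    n_factors: int = 2,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    labels: list[str] | None = None,
) -> PLSDAResult:
    """Fit a two-class PLS-DA model (PLS1 NIPALS on a -1/+1 dummy).

    The alphabetically first label is coded -1, the second +1.  Factor-1
    scores are oriented so the +1 class has the higher mean score;
    further factors are sign-fixed by their loading columns.
    """
    X, sample_ids = _as_values(matrix)
    if labels is None:
        if not isinstance(matrix, FeatureMatrix) or matrix.group_labels is None:
            raise ClassCountError("PLS-DA requires group labels")
        labels = matrix.group_labels
    if len(labels) != X.shape[0]:
        raise ClassCountError("labels length must equal the number of samples")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ClassCountError(
            f"PLS-DA is a 2-class model; got {len(classes)} class(es): {classes}"
        )
    counts = {c: labels.count(c) for c in classes}
    for c, k in counts.items():
        if k == 1:
            warnings.warn(f"class {c!r} has a single sample", stacklevel=2)
    n = X.shape[0]
    if not 1 <= n_factors <= n - 1:
        raise RankError(f"n_factors={n_factors} outside [1, n-1={n - 1}]")

    coding = {classes[0]: -1.0, classes[1]: 1.0}
    y_raw = np.array([coding[l] for l in labels])
    y_mean = float(y_raw.mean())
    y = y_raw - y_mean
    means = X.mean(axis=0)
    Xc = X - means

    p_vars = X.shape[1]
    T = np.empty((n, n_factors))
    P = np.empty((p_vars, n_factors))
    W = np.empty((p_vars, n_factors))
    q = np.empty(n_factors)
    iters: list[int] = []
    for f in range(n_factors):
        # PLS1: with a univariate response the weight vector is closed-form,
        # one pass per factor (the inner loop converges immediately).
        w = Xc.T @ y
        wnorm = np.linalg.norm(w)
        if wnorm == 0:
            raise RankError(
                f"response carries no covariance with X at factor {f + 1}"
            )
        w /= wnorm
        t = Xc @ w
        tt = float(t @ t)
        qf = float(y @ t) / tt
        pvec = Xc.T @ t / tt
        if f == 0:
            # orient Factor-1 so the +1-coded class scores higher on average
            pos = y_raw > 0
            sign = 1.0 if t[pos].mean() >= t[~pos].mean() else -1.0
        else:
            sign = _flip_to_positive_max(pvec)
        # flipping w and t flips q and p consistently: t q stays invariant
        w *= sign
        t *= sign
        qf *= sign
        pvec *= sign
        T[:, f] = t
        W[:, f] = w
        P[:, f] = pvec
        q[f] = qf
        iters.append(1)
        Xc = Xc - np.outer(t, pvec)
        y = y - qf * t
    return PLSDAResult(
        x_scores=T,
        x_loadings=P,
        x_weights=W,
        y_loadings=q,
        class_coding=coding,
        n_factors=n_factors,
        column_means=means,
        y_mean=y_mean,
        n_iterations=iters,
        sample_ids=sample_ids,
    )


def correlation_loadings(
    matrix: FeatureMatrix | np.ndarray,
    scores_column: np.ndarray,
    grid_shape: tuple[int, int] | None = None,
    threshold: float = DEFAULT_LOADING_THRESHOLD,
) -> CorrelationLoadingMap:
    """Pearson correlation of one score column with every variable.

    Computed against the matrix as passed in — normally the preprocessed
    (SNV) matrix the model was fit on.  Zero-variance variables get NaN.
    """
    X, _ = _as_values(matrix)
    s = np.asarray(scores_column, dtype=np.float64)
    if s.shape != (X.shape[0],):
        raise InvalidParameterError(
            f"scores length {s.shape} does not match {X.shape[0]} samples"
        )
    s_c = s - s.mean()
    s_norm = np.linalg.norm(s_c)
    if s_norm == 0:
        raise DegenerateScoresError("score column is constant")
    Xc = X - X.mean(axis=0)
    col_norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ s_c) / (col_norms * s_norm)
    r[col_norms == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)
    if grid_shape is None:
        if isinstance(matrix, FeatureMatrix):
            grid_shape = matrix.grid_shape
        else:
            raise InvalidParameterError("grid_shape required for a bare array")
    return CorrelationLoadingMap(r_values=unvectorize(r, grid_shape), threshold=threshold)


def threshold_mask(
    cmap: CorrelationLoadingMap, threshold: float = DEFAULT_LOADING_THRESHOLD
) -> np.ndarray:
    """Boolean grid: True where ``|r| >= threshold`` and r is defined."""
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError(f"threshold must lie in (0, 1], got {threshold}")
    r = cmap.r_values
    with np.errstate(invalid="ignore"):
        return np.isfinite(r) & (np.abs(r) >= threshold)


# ---------------------------------------------------------------------------
# Exports: score scatter plots, loading heat maps, delimited tables
# ---------------------------------------------------------------------------


def _axis_prefix(result: PCAResult | PLSDAResult) -> str:
    return "PC" if isinstance(result, PCAResult) else "Factor"


def _scores_of(result: PCAResult | PLSDAResult) -> np.ndarray:
    return result.scores if isinstance(result, PCAResult) else result.x_scores


def export_model(
    result: PCAResult | PLSDAResult,
    score_plot_path: str | Path | None = None,
    tables_dir: str | Path | None = None,
    component_pair: tuple[int, int] = (1, 2),
    group_labels: list[str] | None = None,
) -> list[Path]:
    """Write a score scatter plot and delimited score/variance tables.

    ``component_pair`` is 1-based, e.g. ``(1, 5)`` for a PC-1/PC-5 plot.
    """
    scores = _scores_of(result)
    n_comp = scores.shape[1]
    ci, cj = component_pair
    if not (1 <= ci <= n_comp and 1 <= cj <= n_comp):
        raise IndexError(
            f"component pair {component_pair} out of range for {n_comp} components"
        )
    prefix = _axis_prefix(result)
    written: list[Path] = []

    if tables_dir is not None:
        tables_dir = Path(tables_dir)
        tables_dir.mkdir(parents=True, exist_ok=True)
        ids = result.sample_ids or [f"s{i}" for i in range(scores.shape[0])]
        df = pd.DataFrame(
            scores, columns=[f"{prefix}-{i + 1}" for i in range(n_comp)]
        )
        df.insert(0, "sample_id", ids)
        if group_labels is not None:
            df.insert(1, "group_label", group_labels)
        score_table = tables_dir / "scores.tsv"
        df.to_csv(score_table, sep="\t", index=False, float_format="%.12g")
        written.append(score_table)
        if isinstance(result, PCAResult):
            ev = pd.DataFrame(
                {
                    "component": np.arange(1, n_comp + 1),
                    "explained_variance_fraction": result.explained_variance_fraction,
                }
            )
            ev_table = tables_dir / "explained_variance.tsv"
            ev.to_csv(ev_table, sep="\t", index=False, float_format="%.12g")
            written.append(ev_table)

    if score_plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        xs, ys = scores[:, ci - 1], scores[:, cj - 1]
        if group_labels is not None:
            for g in sorted(set(group_labels)):
                sel = [i for i, l in enumerate(group_labels) if l == g]
                ax.scatter(xs[sel], ys[sel], label=g, alpha=0.8)
            ax.legend(frameon=False)
        else:
            ax.scatter(xs, ys, alpha=0.8)
        ax.axhline(0, lw=0.5, color="gray")
        ax.axvline(0, lw=0.5, color="gray")
        ax.set_xlabel(f"{prefix}-{ci}")
        ax.set_ylabel(f"{prefix}-{cj}")
        ax.set_title(f"{prefix}-{ci}/{prefix}-{cj} score plot")
        fig.tight_layout()
        fig.savefig(score_plot_path, dpi=150)
        plt.close(fig)
        written.append(Path(score_plot_path))
    return written


def export_loading_map(
    cmap: CorrelationLoadingMap,
    plot_path: str | Path | None = None,
    ascii_path: str | Path | None = None,
) -> list[Path]:
    """Write the correlation-loading map as a diverging heat map and ASCII.

    Cells above the magnitude threshold saturate toward red (+) or blue
    (-); sub-threshold cells are washed out.
    """
    written: list[Path] = []
    if ascii_path is not None:
        np.savetxt(ascii_path, cmap.r_values, fmt="%.8g", delimiter=" ")
        written.append(Path(ascii_path))
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        display = np.where(cmap.mask, cmap.r_values, np.nan_to_num(cmap.r_values) * 0.15)
        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(
            display, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1,
            interpolation="nearest", origin="upper",
        )
        fig.colorbar(im, ax=ax, label="correlation loading r")
        ax.set_xlabel("frequency bin")
        ax.set_ylabel("time frame")
        ax.set_title(f"correlation loadings, |r| >= {cmap.threshold:g} highlighted")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        written.append(Path(plot_path))
    return written
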