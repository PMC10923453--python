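"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain, slow, textbook code —
explicit double sums and explicit iteration loops — so it shares no code
path with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def stft_brute_force(
    x: np.ndarray, window: np.ndarray, hop: int, n_fft: int, centered: bool = True
) -> np.ndarray:
    """Direct double-sum STFT: frame m, bin f, no FFT anywhere."""
    x = np.asarray(x, dtype=np.complex128)
    M = len(window)
    L = M - hop
    k = (len(x) - L) // hop
    out = np.zeros((k, n_fft), dtype=np.complex128)
    for m in range(k):
        for f in range(n_fft):
            acc = 0.0 + 0.0j
            for n in range(M):
                acc += window[n] * x[m * hop + n] * np.exp(-2j * np.pi * f * n / n_fft)
            out[m, f] = acc
    if centered:
        out = np.fft.fftshift(out, axes=1)
    return out


def pca_eig(X: np.ndarray, n_components: int):
    """PCA by dense eigendecomposition of the covariance (scatter) matrix.

    Returns (scores, loadings, explained_fraction) with loading columns
    sign-fixed so their largest-magnitude element is positive.
    """
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    V = evecs[:, :n_components].copy()
    for c in range(n_components):
        j = np.argmax(np.abs(V[:, c]))
        if V[j, c] < 0:
            V[:, c] = -V[:, c]
    T = Xc @ V
    return T, V, evals[:n_components] / total


def pls1_nipals_textbook(X: np.ndarray, y: np.ndarray, n_factors: int):
    """Classic PLS1 NIPALS recursion with explicit per-factor loops.

    y is the already-coded univariate response.  Returns (T, P, W, q)
    without any sign convention applied.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n, p = Xc.shape
    T = np.zeros((n, n_factors))
    P = np.zeros((p, n_factors))
    W = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    for a in range(n_factors):
        w = np.zeros(p)
        for j in range(p):
            for i in range(n):
                w[j] += Xc[i, j] * yc[i]
        w = w / np.sqrt(np.sum(w * w))
        t = Xc @ w
        tt = float(t @ t)
        qa = float(yc @ t) / tt
        pvec = (Xc.T @ t) / tt
        T[:, a] = t
        P[:, a] = pvec
        W[:, a] = w
        q[a] = qa
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
    return T, P, W, q


def align_signs(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Return B with each column flipped to best match the sign of A's."""
    out = B.copy()
    for c in range(A.shape[1]):
        if np.dot(A[:, c], B[:, c]) < 0:
            out[:, c] = -out[:, c]
    return out
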