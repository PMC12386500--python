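"""Kernel-algorithm PLS1 regression of spectra on days in vitro.

The fit operates on the cross-product statistics A = Xc'Xc and s = Xc'y
(Dayal & MacGregor kernel formulation of PLS1), which is algebraically
equivalent to NIPALS with explicit X deflation.  Cross-validation uses
random segments, optionally grouped so that all technical replicates of a
biological sample stay in one segment (no leakage between train and test).

Sign convention: factor-1 scores correlate positively with y, so a positive
regression coefficient marks spectral variables that characterize late
differentiation.  Note that on second-derivative spectra an absorption band
is a negative-going feature, so a band whose amplitude *rises* with y gets a
*negative* beta at its center; :func:`beta_peaks` handles this inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "PLSMetrics", "CVScheme", "fit_pls", "cross_validate", "beta_peaks"]


@dataclass
class PLSModel:
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray   # (p, k) weight vectors (unit norm)
    P: np.ndarray   # (p, k) X-loadings
    q: np.ndarray   # (k,) y-loadings
    R: np.ndarray   # (p, k) rotations: T = Xc @ R on the *original* X
    T: np.ndarray   # (n, k) scores
    B: np.ndarray   # (p, k): column k-1 = coefficients using the first k factors
    n_factors: int

    def predict(self, X: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        k = self.n_factors if n_factors is None else n_factors
        if not 1 <= k <= self.n_factors:
            raise ValueError(f"n_factors must be in [1, {self.n_factors}]")
        return (np.asarray(X, float) - self.x_mean) @ self.B[:, k - 1] + self.y_mean


@dataclass
class PLSMetrics:
    """Per-factor-count calibration and cross-validation figures of merit."""

    factors: np.ndarray           # 1..K
    rmsec: np.ndarray
    rmsecv: np.ndarray
    correlation_cal: np.ndarray
    correlation_val: np.ndarray
    chosen_k: int
    predictions_cv: np.ndarray = field(repr=False, default=None)  # (n, K) pooled


@dataclass(frozen=True)
class CVScheme:
    """Random-segment cross-validation plan."""

    n_segments: int = 10
    grouping: str = "by_bio_rep"  # or "by_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if self.grouping not in ("by_sample", "by_bio_rep"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


def fit_pls(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSModel:
    """PLS1 via the kernel algorithm on X'X and X'y.

    Factors are extracted until ``n_factors`` or until the residual
    covariance X'y vanishes (rank exhausted), whichever comes first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("y is constant")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(f"n_factors must be in [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if not np.any(Xc):
        raise ValueError("X has zero variance")

    A = Xc.T @ Xc
    s = Xc.T @ yc
    s0_norm = np.linalg.norm(s)

    W, P, R, qs = [], [], [], []
    for _ in range(n_factors):
        s_norm = np.linalg.norm(s)
        if s_norm <= 1e-12 * max(s0_norm, 1.0):
            break  # residual X-y covariance exhausted
        w = s / s_norm
        tt = float(w @ A @ w)
        if tt <= 0:
            break
        p_load = (A @ w) / tt
        q_k = float(s @ w) / tt
        # rotation so scores can be formed from the un-deflated X
        r = w.copy()
        for p_j, r_j in zip(P, R):
            r -= float(p_j @ w) * r_j
        W.append(w)
        P.append(p_load)
        R.append(r)
        qs.append(q_k)
        # deflate the cross-product statistics
        s = s - p_load * (q_k * tt)
        A = A - tt * np.outer(p_load, p_load)

    if not W:
        raise ValueError("no PLS factor could be extracted")
    W = np.column_stack(W)
    P = np.column_stack(P)
    R = np.column_stack(R)
    q = np.asarray(qs)
    # factor 1 of PLS1 always has q_1 = |X'y| / t't >= 0, i.e. scores already
    # correlate positively with y; flip defensively if a later refactoring
    # ever changes that.
    if q[0] < 0:
        W[:, 0] *= -1
        P[:, 0] *= -1
        R[:, 0] *= -1
        q[0] *= -1
    T = Xc @ R
    B = np.cumsum(R * q, axis=1)
    return PLSModel(x_mean, y_mean, W, P, q, R, T, B, W.shape[1])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _segments(n: int, groups, scheme: CVScheme) -> list[np.ndarray]:
    rng = np.random.default_rng(scheme.seed)
    if scheme.grouping == "by_bio_rep":
        if groups is None:
            raise ValueError("grouping='by_bio_rep' requires a groups array")
        uniq = list(dict.fromkeys(groups))  # stable order
        order = rng.permutation(len(uniq))
        seg_of_group = {uniq[j]: i % scheme.n_segments for i, j in enumerate(order)}
        assign = np.array([seg_of_group[g] for g in groups])
    else:
        assign = rng.permutation(n) % scheme.n_segments
    return [np.flatnonzero(assign == s) for s in range(scheme.n_segments)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    scheme: CVScheme,
    max_factors: int,
    groups=None,
) -> PLSMetrics:
    """Segmented cross-validation of the kernel PLS1 fit.

    RMSECV(k) pools squared held-out prediction errors over all samples;
    correlation_val(k) is the Pearson correlation of pooled predictions with
    y.  ``chosen_k`` is the smallest k whose RMSECV lies within 2% of the
    global minimum.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    segments = [seg for seg in _segments(n, groups, scheme) if len(seg)]

    full = fit_pls(X, y, max_factors)
    K = full.n_factors
    pred_cv = np.full((n, K), np.nan)
    for seg in segments:
        train = np.setdiff1d(np.arange(n), seg)
        if np.unique(y[train]).size < 2:
            raise ValueError("a training fold has constant y")
        m = fit_pls(X[train], y[train], min(K, len(train) - 1, X.shape[1]))
        for k in range(1, K + 1):
            pred_cv[seg, k - 1] = m.predict(X[seg], min(k, m.n_factors))

    factors = np.arange(1, K + 1)
    rmsec = np.empty(K)
    corr_cal = np.empty(K)
    rmsecv = np.empty(K)
    corr_val = np.empty(K)
    for k in factors:
        fit_pred = full.predict(X, k)
        rmsec[k - 1] = float(np.sqrt(np.mean((y - fit_pred) ** 2)))
        corr_cal[k - 1] = _pearson(fit_pred, y)
        cv = pred_cv[:, k - 1]
        rmsecv[k - 1] = float(np.sqrt(np.mean((y - cv) ** 2)))
        corr_val[k - 1] = _pearson(cv, y)

    chosen = int(factors[np.flatnonzero(rmsecv <= 1.02 * rmsecv.min())[0]])
    return PLSMetrics(factors, rmsec, rmsecv, corr_cal, corr_val, chosen, pred_cv)


def beta_peaks(
    model: PLSModel,
    factor: int,
    band_library,
    wavenumbers: np.ndarray,
    spectrum_mode: str = "second_derivative",
    min_prominence: float = 0.05,
    max_distance: float = 12.0,
) -> list[tuple[float, int, str]]:
    """Local extrema of the factor-k regression coefficients, with band labels.

    Returns (wavenumber, sign, band_name) triples where sign +1 marks
    variables characterizing high y (late DIV) and -1 low y.  In
    ``second_derivative`` mode the attribution sign is the *negative* of the
    coefficient extremum's sign, because absorption bands are negative-going
    there (a deepening minimum, i.e. a growing band, pairs with beta < 0).
    Extrema below ``min_prominence`` of the maximum |beta| are ignored;
    bands further than ``max_distance`` cm^-1 away are labeled "unassigned".
    """
    if not 1 <= factor <= model.n_factors:
        raise ValueError(f"factor must be in [1, {model.n_factors}]")
    if spectrum_mode not in ("raw", "second_derivative"):
        raise ValueError(f"unknown spectrum_mode {spectrum_mode!r}")
    beta = model.B[:, factor - 1]
    nu = np.asarray(wavenumbers, float)
    flip = -1 if spectrum_mode == "second_derivative" else 1
    thresh = min_prominence * np.max(np.abs(beta)) if len(beta) else 0.0

    peaks = []
    for i in range(1, len(beta) - 1):
        if abs(beta[i]) < thresh:
            continue
        if beta[i] > beta[i - 1] and beta[i] > beta[i + 1]:
            sign = 1
        elif beta[i] < beta[i - 1] and beta[i] < beta[i + 1]:
            sign = -1
        else:
            continue
        name = "unassigned"
        best = max_distance
        for b in band_library:
            d = abs(b.center - nu[i])
            if d <= best:
                best = d
                name = b.name
        peaks.append((float(nu[i]), flip * sign, name))
    return peaks
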