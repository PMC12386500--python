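"""PCA-based outlier screening and technical-replicate aggregation.

Outliers are flagged by the dual Hotelling T^2 / Q-residual criterion on a
mean-centered PCA of baseline-corrected, area-normalized region spectra:
T^2 measures distance inside the retained score space (limit from the
F-distribution), Q the residual off the model plane (limit from the
Jackson-Mudholkar approximation).  Nothing is removed silently; removal is
a separate, explicit step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import Spectrum, spectra_to_matrix

__all__ = [
    "PCAResult",
    "OutlierReport",
    "fit_pca",
    "detect_outliers",
    "apply_outlier_removal",
    "aggregate_technical",
]


@dataclass
class PCAResult:
    mean: np.ndarray               # per-wavenumber center
    components: np.ndarray         # (k, p), orthonormal rows
    scores: np.ndarray             # (n, k)
    explained_variance: np.ndarray  # (k,), eigenvalues of sample covariance
    all_eigenvalues: np.ndarray    # full spectrum, for residual limits
    n_components: int

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        k = self.n_components if k is None else k
        return self.mean + self.scores[:, :k] @ self.components[:k]


def _as_matrix(spectra) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        return np.asarray(spectra, dtype=float)
    _, X, _ = spectra_to_matrix(list(spectra))
    return X


def fit_pca(spectra, n_components: int) -> PCAResult:
    """Mean-centered PCA by singular value decomposition."""
    X = _as_matrix(spectra)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X - mean, full_matrices=False)
    eig = S**2 / (n - 1)
    k = n_components
    return PCAResult(
        mean=mean,
        components=Vt[:k],
        scores=(U[:, :k] * S[:k]),
        explained_variance=eig[:k],
        all_eigenvalues=eig,
        n_components=k,
    )


@dataclass
class OutlierReport:
    sample_ids: list
    t2: np.ndarray
    q: np.ndarray
    flagged: np.ndarray          # bool; flagged <=> t2 > t2_limit or q > q_limit
    t2_limit: float
    q_limit: float
    n_components: int
    alpha: float

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "t2": self.t2,
                "q": self.q,
                "t2_limit": self.t2_limit,
                "q_limit": self.q_limit,
                "flagged": self.flagged,
            }
        )


def _choose_n_components(eig: np.ndarray, target: float = 0.95, cap: int = 10) -> int:
    total = eig.sum()
    if total <= 0:
        return 1
    cum = np.cumsum(eig) / total
    k = int(np.searchsorted(cum, target) + 1)
    return max(1, min(k, cap, len(eig)))


def _jackson_mudholkar_limit(residual_eig: np.ndarray, alpha: float) -> float:
    """Q-statistic control limit from the residual eigenvalue spectrum."""
    th1 = residual_eig.sum()
    th2 = (residual_eig**2).sum()
    th3 = (residual_eig**3).sum()
    if th1 <= 0 or th2 <= 0:
        return np.inf
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = sps.norm.ppf(1.0 - alpha)
    inner = z * np.sqrt(2.0 * th2 * h0**2) / th1 + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2
    if inner <= 0:
        return np.inf
    return float(th1 * inner ** (1.0 / h0))


def detect_outliers(
    spectra,
    n_components: int | None = None,
    alpha: float = 0.01,
    variance_target: float = 0.95,
    max_components: int = 10,
) -> OutlierReport:
    """Flag spectra whose T^2 or Q exceeds its (1 - alpha) control limit.

    With ``n_components=None`` the model order is the smallest k explaining
    ``variance_target`` of the variance, capped at ``max_components``.
    Degenerate (zero-variance) data yields infinite limits and no flags.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    X = _as_matrix(spectra)
    n = X.shape[0]
    full = fit_pca(X, min(n - 1, X.shape[1]))
    eig = full.all_eigenvalues
    k = n_components if n_components is not None else _choose_n_components(
        eig, variance_target, max_components
    )
    if not 1 <= k <= len(eig):
        raise ValueError(f"n_components must be in [1, {len(eig)}]")

    scores = full.scores[:, :k]
    lam = eig[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = np.where(lam > 1e-30, scores**2 / lam, 0.0).sum(axis=1)
    resid = (X - full.mean) - scores @ full.components[:k]
    q = (resid**2).sum(axis=1)

    if np.all(lam <= 1e-30) or n <= k:
        t2_limit = np.inf
    else:
        t2_limit = k * (n - 1) / (n - k) * sps.f.ppf(1.0 - alpha, k, n - k)
    q_limit = _jackson_mudholkar_limit(eig[k:], alpha)

    flagged = (t2 > t2_limit) | (q > q_limit)
    ids = (
        [s.meta.get("sample_id", i) for i, s in enumerate(spectra)]
        if not isinstance(spectra, np.ndarray)
        else list(range(n))
    )
    return OutlierReport(ids, t2, q, flagged, float(t2_limit), float(q_limit), k, alpha)


def apply_outlier_removal(spectra: list[Spectrum], report: OutlierReport) -> list[Spectrum]:
    """Drop the flagged spectra (explicit removal step; order preserved)."""
    return [s for s, f in zip(spectra, report.flagged) if not f]


def aggregate_technical(spectra: list[Spectrum]) -> list[Spectrum]:
    """Point-wise mean over technical replicates within each (DIV, bio_rep).

    The output spectrum carries ``n_averaged`` in its metadata.  A cell with
    zero surviving spectra cannot occur here (groups are formed from what is
    present), but incomplete metadata raises.
    """
    groups: dict[tuple, list[Spectrum]] = {}
    for s in spectra:
        try:
            key = (s.meta["div"], s.meta["bio_rep"])
        except KeyError as e:
            raise ValueError(f"spectrum metadata missing {e} for technical aggregation")
        groups.setdefault(key, []).append(s)
    out = []
    for (div, bio), members in sorted(groups.items()):
        if not members:
            raise ValueError(f"no surviving spectra for DIV {div}, bio_rep {bio}")
        nu = members[0].wavenumbers
        mean_a = np.mean([m.absorbance for m in members], axis=0)
        out.append(
            Spectrum(
                nu.copy(),
                mean_a,
                {
                    "sample_id": f"DIV{div:02d}_B{bio}",
                    "div": div,
                    "bio_rep": bio,
                    "n_averaged": len(members),
                },
            )
        )
    return out
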