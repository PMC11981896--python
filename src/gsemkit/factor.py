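"""Exploratory factor analysis of genetic correlation matrices.

The follow-up factor analysis asks which clusters of risk factors share
genetic variance: the number of factors is chosen with the Kaiser rule
(eigenvalues of the unreduced correlation matrix > 1), factors are extracted
by principal-axis / iterated-communality factoring and obliquely rotated
(varimax followed by a promax power-4 transformation) so that factors may
correlate.  The confirmatory model is then built from the rotated pattern by
keeping every standardized loading >= 0.30; variables with no loading above
the cutoff are excluded from the CFA and reported.

Genetic correlation matrices estimated by block jackknife are routinely
indefinite; :func:`nearest_psd` projects onto the PSD cone (eigenvalue floor
1e-6) before extraction and reports the Frobenius distance moved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

from .sem import SemModel
from .sumstats import InputError

__all__ = ["EfaResult", "kaiser_n_factors", "efa", "cfa_from_efa", "nearest_psd"]


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InputError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise InputError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise InputError("correlation matrix must have unit diagonal")
    return R


def kaiser_n_factors(R: np.ndarray) -> int:
    """Number of eigenvalues of R strictly greater than 1 (Kaiser rule).

    Applied to the unreduced correlation matrix; the strict inequality means
    an identity matrix retains zero factors.
    """
    R = _check_corr(R)
    return int(np.sum(np.linalg.eigvalsh(R) > 1.0))


def nearest_psd(R: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the PSD cone with an eigenvalue floor.

    Returns the projected matrix (diagonal restored to 1) and the Frobenius
    distance from the input.
    """
    R = np.asarray(R, dtype=float)
    w, Q = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() >= floor:
        return R, 0.0
    out = (Q * np.maximum(w, floor)) @ Q.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out, float(np.linalg.norm(out - R, "fro"))


def _varimax(L: np.ndarray, normalize: bool = True,
             tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Classic pairwise varimax with Kaiser row normalization.

    The explicit per-pair angle update escapes the symmetric stationary
    points where gradient-projection rotation can stall.
    """
    X = L.copy()
    p, k = X.shape
    if k == 1:
        return X
    if normalize:
        h = np.sqrt((X ** 2).sum(axis=1))
        h[h == 0] = 1.0
        X = X / h[:, None]
    for _ in range(max_iter):
        change = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = X[:, i], X[:, j]
                u = x ** 2 - y ** 2
                v = 2 * x * y
                num = 2 * (u * v).sum() - 2 * u.sum() * v.sum() / p
                den = (u ** 2 - v ** 2).sum() - (u.sum() ** 2 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                change = max(change, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                X[:, [i, j]] = X[:, [i, j]] @ np.array([[c, -s], [s, c]])
        if change < tol:
            break
    if normalize:
        X = X * h[:, None]
    return X


def _promax(X: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique transformation of a varimax solution.

    Regresses the varimax loadings onto their |.|^power simple-structure
    target; returns (pattern matrix, factor correlation matrix).
    """
    if X.shape[1] == 1:
        return X, np.eye(1)
    Q = X * np.abs(X) ** (power - 1)
    U = np.linalg.lstsq(X, Q, rcond=None)[0]
    d = np.sqrt(np.diag(np.linalg.inv(U.T @ U)))
    U = U * d
    return X @ U, np.linalg.inv(U.T @ U)


@dataclass
class EfaResult:
    """Oblique EFA solution: standardized pattern loadings, factor
    correlations, and the fraction of total variance captured by the common
    factors (mean communality)."""

    n_factors: int
    loadings: pd.DataFrame  # variables x factors
    factor_correlations: np.ndarray
    variance_explained: float
    smoothing_distance: float = 0.0

    @property
    def variables(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def factors(self) -> list[str]:
        return list(self.loadings.columns)


def efa(R: np.ndarray, n_factors: int, variables: list[str] | None = None,
        psd_floor: float = 1e-6) -> EfaResult:
    """Principal-axis EFA with promax oblique rotation.

    Deterministic for a given input: no random starts, and each factor's
    column sign is fixed so that its largest-magnitude loading is positive.
    ``variance_explained`` is the mean communality under the oblique solution
    (diagonal of L Phi L' averaged over variables).
    """
    R = _check_corr(R)
    p = R.shape[0]
    if not (1 <= n_factors < p):
        raise InputError(f"n_factors must be in [1, {p - 1}]")
    if variables is None:
        variables = [f"V{i + 1}" for i in range(p)]
    R_psd, dist = nearest_psd(R, floor=psd_floor)

    fa = Factor(corr=R_psd, n_factor=n_factors, method="pa", smc=True).fit()
    unrotated = np.asarray(fa.loadings)
    pattern, phi = _promax(_varimax(unrotated))

    # deterministic sign: largest-|loading| entry of each factor positive
    for j in range(n_factors):
        i_max = int(np.argmax(np.abs(pattern[:, j])))
        if pattern[i_max, j] < 0:
            pattern[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    np.fill_diagonal(phi, 1.0)

    communalities = np.einsum("ij,jk,ik->i", pattern, phi, pattern)
    var_explained = float(np.clip(communalities.mean(), 0.0, 1.0))
    factors = [f"F{j + 1}" for j in range(n_factors)]
    return EfaResult(
        n_factors=n_factors,
        loadings=pd.DataFrame(pattern, index=list(variables), columns=factors),
        factor_correlations=phi,
        variance_explained=var_explained,
        smoothing_distance=dist,
    )


def cfa_from_efa(efa_result: EfaResult, cutoff: float = 0.30) -> tuple[SemModel, list[str]]:
    """Confirmatory model from thresholded EFA loadings.

    Emits a loading path for every |pattern loading| >= ``cutoff``, free
    correlations between all retained factors, and free residual variances
    (added automatically at fit time).  Returns the model and the list of
    excluded variables (no loading above the cutoff) — e.g. a genetically
    distinct trait that fails to load on any shared factor.
    """
    L = efa_result.loadings
    keep_mask = L.abs() >= cutoff
    excluded = [v for v in L.index if not keep_mask.loc[v].any()]
    if len(excluded) == len(L.index):
        raise InputError("all variables fall below the loading cutoff")
    lines = []
    kept_factors = []
    for f in L.columns:
        indicators = [v for v in L.index if keep_mask.loc[v, f]]
        if not indicators:
            continue
        kept_factors.append(f)
        lines.append(f"{f} =~ " + " + ".join(indicators))
    for i, f1 in enumerate(kept_factors):
        for f2 in kept_factors[i + 1:]:
            lines.append(f"{f1} ~~ {f2}")
    return SemModel.from_text("\n".join(lines)), excluded
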