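"""Rank/empirical-CDF machinery, Gaussian-copula normalization and Gaussian entropy.

The central primitive of the package: replace each variable by the inverse
standard-normal CDF of its rescaled ranks.  The transform preserves the
empirical copula (the joint rank structure) exactly while forcing perfect
standard-normal marginals, so any quantity computed from the transformed data
that is a difference of entropies (MI, CMI, ...) depends only on the
dependence structure and is invariant to strictly monotonic transforms of the
raw marginals.

Entropies of the transformed data are evaluated with the closed-form Gaussian
expression H = (1/2) log2[(2*pi*e)^k |Sigma|], optionally with the analytic
small-sample correction that removes the bias of the sample log-determinant
(see :func:`gaussian_entropy`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri, psi

__all__ = [
    "InfoValue",
    "GaussianModel",
    "rank_ecdf",
    "copula_normalize",
    "gaussian_entropy",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class InfoValue:
    """An information quantity in bits.

    ``bits`` may be negative: interaction information is signed, and
    bias-corrected estimates of null quantities fluctuate around zero.
    """

    bits: float
    estimator: str = ""
    bias_corrected: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.bits):
            raise ValueError(f"non-finite information value: {self.bits!r}")

    def __float__(self) -> float:
        return float(self.bits)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f", estimator={self.estimator!r}" if self.estimator else ""
        bc = ", bias_corrected=True" if self.bias_corrected else ""
        return f"InfoValue({self.bits:.6g} bits{tag}{bc})"


@dataclass(frozen=True)
class GaussianModel:
    """Sufficient statistics of a Gaussian fit: covariance, N and k."""

    covariance: np.ndarray
    n_samples: int
    dim: int

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (self.dim, self.dim):
            raise ValueError(
                f"covariance shape {cov.shape} does not match dim={self.dim}"
            )
        if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        object.__setattr__(self, "covariance", cov)

    @classmethod
    def fit(cls, x: np.ndarray) -> "GaussianModel":
        """Estimate about the sample mean with divisor N-1."""
        x = as_samples(x)
        n, k = x.shape
        xc = x - x.mean(axis=0)
        cov = (xc.T @ xc) / (n - 1)
        return cls(covariance=cov, n_samples=n, dim=k)


def as_samples(x: np.ndarray, min_samples: int = 1) -> np.ndarray:
    """Coerce input to a finite 2-D float array of shape (N, k).

    1-D vectors become single-column matrices; complex input is split into
    real/imaginary columns (the package-wide convention for spectral data).
    """
    x = np.asarray(x)
    if np.iscomplexobj(x):
        x = np.column_stack([x.real.ravel(), x.imag.ravel()]) if x.ndim == 1 else \
            np.concatenate([x.real, x.imag], axis=-1)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"expected a vector or 2-D sample matrix, got shape {x.shape}")
    if x.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.shape[0]}")
    if not np.isfinite(x).all():
        raise ValueError("sample matrix contains non-finite entries")
    return x


def rank_ecdf(x: np.ndarray) -> np.ndarray:
    """Empirical-CDF values rank(x_i)/(N+1), strictly inside (0, 1).

    Ties are broken deterministically by original sample index (ordinal
    ranking); a warning is emitted because the method assumes continuous data.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("rank_ecdf requires at least one sample")
    if not np.isfinite(x).all():
        raise ValueError("rank_ecdf input contains non-finite entries")
    n = x.size
    n_tied = n - np.unique(x).size
    if n_tied > 0:
        warnings.warn(
            f"rank_ecdf: {n_tied}/{n} tied samples ({100.0 * n_tied / n:.1f}%); "
            "proceeding with ordinal tie-break by sample index",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    return ranks / (n + 1)


def copula_normalize(x: np.ndarray) -> np.ndarray:
    """Gaussian-copula normalization, applied independently to each column.

    Each column of the output, when sorted, equals the fixed grid
    Phi^{-1}(i/(N+1)), i = 1..N; the joint rank structure of the input is
    preserved exactly.
    """
    x = as_samples(x, min_samples=3)
    n, k = x.shape
    if n <= k:
        warnings.warn(
            f"copula_normalize: N={n} samples for k={k} dimensions; "
            "downstream covariance will be singular or ill-conditioned",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.empty_like(x)
    for j in range(k):
        out[:, j] = ndtri(rank_ecdf(x[:, j]))
    return out


def _logdet_cholesky(cov: np.ndarray) -> float:
    """log|Sigma| via Cholesky; raises a diagnostic error on non-PD input."""
    try:
        chol = np.linalg.cholesky(cov)
        d = np.diag(chol)
        # near-singular matrices can pass Cholesky on rounding noise alone;
        # a vanishing pivot ratio marks numerically collinear columns
        if (d.min() / d.max()) ** 2 < 1e-12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # locate the first failing leading minor for the error message
        k = cov.shape[0]
        bad = k
        for i in range(1, k + 1):
            try:
                np.linalg.cholesky(cov[:i, :i])
            except np.linalg.LinAlgError:
                bad = i
                break
        raise np.linalg.LinAlgError(
            f"covariance matrix is singular / not positive definite "
            f"(first failing leading minor at dimension {bad}); "
            "this usually signals collinear input columns"
        ) from None
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def gaussian_entropy(
    x: np.ndarray | GaussianModel, bias_correct: bool = False
) -> InfoValue:
    """Closed-form Gaussian (differential) entropy in bits.

    Without correction::

        H = 1/(2 ln 2) * ln[(2 pi e)^k |Sigma|]

    With ``bias_correct=True`` the analytic expectation of the sample
    log-determinant bias is removed::

        H = 1/(2 ln 2) * ( ln[(2 pi e)^k |Sigma|]
                           - k ln(2/(N-1)) - sum_{i=1}^{k} psi((N-i)/2) )

    which makes the estimate unbiased for Gaussian samples (the correction
    is exact for the log-determinant of a Wishart-distributed sample
    covariance).  Requires N > k + 1 so every digamma argument is positive.
    """
    if isinstance(x, GaussianModel):
        model = x
    else:
        model = GaussianModel.fit(x)
    cov, n, k = model.covariance, model.n_samples, model.dim
    h_nats = 0.5 * (_logdet_cholesky(cov) + k * np.log(2.0 * np.pi * np.e))
    if bias_correct:
        if n <= k + 1:
            raise ValueError(
                f"bias correction requires N > k + 1 (got N={n}, k={k})"
            )
        i = np.arange(1, k + 1)
        h_nats -= 0.5 * (k * np.log(2.0 / (n - 1)) + np.sum(psi((n - i) / 2.0)))
    return InfoValue(
        bits=h_nats / _LN2, estimator="gaussian", bias_corrected=bias_correct
    )
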