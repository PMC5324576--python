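"""Amplitude/direction decomposition of vector signals and derivative augmentation.

Complex spectral coefficients (real/imaginary pairs), planar magnetic-field
gradients or any d-dimensional vector response can be fed to the copula MI
estimators either whole (as a d-dimensional variable), or split into an
amplitude channel (row norms) and a direction channel (rows normalized onto
the unit sphere).  Keeping phase as a 2-D point on the unit circle avoids all
circular-variable issues (no wrap-around, no arbitrary branch cut), and by
the data-processing inequality the normalization cannot leak amplitude
information into the direction channel.

Amplitude vs power is irrelevant downstream: squaring is monotone on
non-negative values, and the copula estimators are rank statistics.
"""

from __future__ import annotations

import warnings

import numpy as np

from .copula import as_samples

__all__ = ["amplitude", "direction", "derivative_augment"]

_EPS_SCALE = 1e3  # zero-amplitude threshold = _EPS_SCALE * machine epsilon


def _as_vectors(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v)
    if np.iscomplexobj(v) and v.ndim == 1:
        v = np.column_stack([v.real, v.imag])
    v = as_samples(v)
    if v.shape[1] < 2:
        raise ValueError("vector samples need at least 2 components")
    return v


def amplitude(v: np.ndarray) -> np.ndarray:
    """Euclidean row norms of a vector sample, as an (N, 1) column.

    Accepts a complex vector or an N x d real matrix.  Zero rows are kept
    (with a warning), since amplitude 0 is a legitimate value; only the
    direction is undefined there.
    """
    v = _as_vectors(v)
    amp = np.linalg.norm(v, axis=1, keepdims=True)
    n_zero = int(np.sum(amp[:, 0] <= _EPS_SCALE * np.finfo(float).eps))
    if n_zero:
        warnings.warn(
            f"amplitude: {n_zero} zero-amplitude rows; their phase/direction "
            "is undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    return amp


def direction(
    v: np.ndarray, on_zero: str = "drop", return_mask: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Rows normalized to the unit sphere: the direction-only channel.

    Rows with norm below a machine-epsilon-scaled threshold have no defined
    direction; policy ``on_zero='drop'`` removes them (with a warning),
    ``'error'`` raises.  With ``return_mask=True`` also returns the boolean
    keep-mask so labels/stimuli can be subset consistently.
    """
    v = _as_vectors(v)
    norms = np.linalg.norm(v, axis=1)
    keep = norms > _EPS_SCALE * np.finfo(float).eps
    if not keep.all():
        n_bad = int((~keep).sum())
        if on_zero == "error":
            raise ValueError(f"{n_bad} rows have (near-)zero norm; direction undefined")
        if on_zero != "drop":
            raise ValueError(f"unknown on_zero policy {on_zero!r}")
        warnings.warn(
            f"direction: dropping {n_bad} (near-)zero-norm rows",
            RuntimeWarning,
            stacklevel=2,
        )
    dirs = v[keep] / norms[keep, None]
    if return_mask:
        return dirs, keep
    return dirs


def derivative_augment(r: np.ndarray) -> np.ndarray:
    """Augment trials x time data with the central-difference temporal derivative.

    Returns trials x time x 2 with channel 0 the raw value and channel 1 the
    derivative (x_{t+1} - x_{t-1})/2, one-sided at the endpoints.  A bivariate
    (value, gradient) response removes the artifactual MI dips that occur
    where a stimulus modulation changes sign (the raw-value correlation
    crosses zero while the gradient modulation peaks).
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 2:
        raise ValueError("expected a trials x time matrix")
    if r.shape[1] < 3:
        raise ValueError("need at least 3 time points for a central difference")
    grad = np.gradient(r, axis=1)  # central differences, one-sided at the ends
    return np.stack([r, grad], axis=2)
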