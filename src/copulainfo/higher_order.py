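"""Higher-order information quantities built on the copula MI primitives.

- interaction information (II): signed overlap of the stimulus information in
  two responses; negative = redundancy, positive = synergy,
- normalized redundancy: -II as a percentage of its tightest upper bound,
- directed information (DI, a.k.a. transfer entropy): time-lagged CMI
  I(X_t1; Y_t2 | Y_t1),
- directed feature information (DFI): the part of DI attributable to a given
  stimulus feature (DI minus stimulus-conditioned DI),
- novel information over time: I(S; R_t | R_{t-1}, anchors),
- pairwise temporal interaction matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .copula import InfoValue, as_samples, copula_normalize
from .discrete import gcmi_cd
from .gaussian import gccmi_ccc, gcmi_cc

__all__ = [
    "LagSpec",
    "Redundancy",
    "interaction_information",
    "normalized_redundancy",
    "directed_information",
    "directed_feature_information",
    "novel_information",
    "pairwise_interaction_matrix",
]


@dataclass(frozen=True)
class LagSpec:
    """Source-target offset (in samples) and embedding depth for DI/DFI.

    ``lag`` is the offset t2 - t1 between the source past and the target
    present; ``embedding`` is the number of consecutive past samples used for
    both the source window and the target's own past.
    """

    lag: int
    embedding: int = 1

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be a positive sample offset")
        if self.embedding < 1:
            raise ValueError("embedding must be >= 1")


def _unique_columns(a: np.ndarray) -> np.ndarray:
    """Drop exactly duplicated columns (keeping first occurrences).

    A variable stacked with an exact copy of itself has a singular joint
    covariance, but the duplicate carries no additional information; removing
    it realizes the degenerate limit (e.g. I(R,R;S) = I(R;S)) instead of
    failing on a collinear matrix.  Only bit-identical columns are removed;
    merely correlated columns are genuine dimensions.

    Columns are returned in a canonical (byte-lexicographic) order: entropy
    is invariant to column permutation, and the canonical order makes
    quantities like interaction information bit-exactly symmetric in their
    response arguments.
    """
    cols = {a[:, j].tobytes(): j for j in range(a.shape[1] - 1, -1, -1)}
    keep = [cols[key] for key in sorted(cols)]
    return a[:, keep]


def _is_discrete(s: np.ndarray) -> bool:
    s = np.asarray(s)
    return s.ndim == 1 and np.issubdtype(s.dtype, np.integer)


def _mi_xs(x: np.ndarray, s: np.ndarray, bias_correct: bool) -> float:
    """MI between continuous x and stimulus s (dispatching on s's type)."""
    if _is_discrete(s):
        return gcmi_cd(x, s, bias_correct=bias_correct).bits
    return gcmi_cc(x, s, bias_correct=bias_correct).bits


def _cmi_sx_given_z(
    x: np.ndarray, s: np.ndarray, z: np.ndarray, bias_correct: bool
) -> float:
    """I(S; X | Z) for continuous x, z and discrete-or-continuous s.

    For discrete s the chain rule I(S;X|Z) = I(S;X,Z) - I(S;Z) reduces the
    conditional to two mixed-MI terms.  Columns of x that exactly duplicate a
    conditioning column contribute nothing given z and are dropped; if
    nothing remains the conditional MI is 0 by definition.
    """
    x = as_samples(x)
    z = _unique_columns(as_samples(z))
    z_cols = {z[:, j].tobytes() for j in range(z.shape[1])}
    fresh = [j for j in range(x.shape[1]) if x[:, j].tobytes() not in z_cols]
    if not fresh:
        return 0.0
    x = x[:, fresh]
    if _is_discrete(s):
        joint = gcmi_cd(np.hstack([x, z]), s, bias_correct=bias_correct).bits
        return joint - gcmi_cd(z, s, bias_correct=bias_correct).bits
    return gccmi_ccc(x, s, z, bias_correct=bias_correct).bits


def interaction_information(
    r1: np.ndarray, r2: np.ndarray, s: np.ndarray, bias_correct: bool = True
) -> InfoValue:
    """Interaction information II = I(R1,R2;S) - I(R1;S) - I(R2;S), in bits.

    Additivity of MI means the sum of the two single-response terms counts
    the shared (overlapping) stimulus information twice, while the joint term
    counts it once; the difference is therefore signed: negative values are
    redundancy (shared information), positive values synergy.  Symmetric in
    (r1, r2).  ``s`` may be continuous or an integer label vector.

    The responses are copula-normalized up front (the transform is
    idempotent, so the downstream estimators leave them unchanged); exact
    duplicates between the two responses -- including monotone transforms of
    the same column, which normalize identically -- are dropped from the
    joint term, realizing I(R,R;S) = I(R;S) so a fully redundant copy yields
    II = -I(R1;S).
    """
    cr1 = copula_normalize(r1)
    cr2 = copula_normalize(r2)
    joint = _mi_xs(_unique_columns(np.hstack([cr1, cr2])), s, bias_correct)
    i1 = _mi_xs(cr1, s, bias_correct)
    i2 = _mi_xs(cr2, s, bias_correct)
    return InfoValue(
        bits=joint - (i1 + i2),
        estimator="interaction_information",
        bias_corrected=bias_correct,
    )


@dataclass(frozen=True)
class Redundancy:
    """Normalized redundancy: 100*(-II)/min{I(S;R1), I(S;R2), I(R1;R2)}.

    ``percent`` is NaN when the bound is degenerate (denominator ~ 0);
    ``synergy`` flags a positive II (reported as 0% redundancy).
    """

    percent: float
    synergy: bool
    ii_bits: float
    bound_bits: float


def normalized_redundancy(
    r1: np.ndarray, r2: np.ndarray, s: np.ndarray, bias_correct: bool = True
) -> Redundancy:
    """Redundancy between two responses about ``s`` as a bounded percentage."""
    r1 = as_samples(r1, min_samples=3)
    r2 = as_samples(r2, min_samples=3)
    ii = interaction_information(r1, r2, s, bias_correct=bias_correct).bits
    i1 = _mi_xs(r1, s, bias_correct)
    i2 = _mi_xs(r2, s, bias_correct)
    try:
        i12 = gcmi_cc(r1, r2, bias_correct=bias_correct).bits
    except np.linalg.LinAlgError:
        i12 = float("inf")  # deterministically related responses
    bound = min(i1, i2, i12)
    if ii > 0:
        return Redundancy(percent=0.0, synergy=True, ii_bits=ii, bound_bits=bound)
    if bound <= 1e-12:
        return Redundancy(
            percent=float("nan"), synergy=False, ii_bits=ii, bound_bits=bound
        )
    return Redundancy(
        percent=100.0 * (-ii) / bound, synergy=False, ii_bits=ii, bound_bits=bound
    )


def _embed(series: np.ndarray, times: np.ndarray, lag: int, m: int) -> np.ndarray:
    """Stack m consecutive lagged copies series[t-lag-j], j=0..m-1, as columns."""
    series = as_samples(series)
    cols = [series[times - lag - j] for j in range(m)]
    return np.hstack(cols)


def _lag_windows(
    x: np.ndarray, y: np.ndarray, spec: LagSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = as_samples(x)
    y = as_samples(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("series must have equal length")
    t_total = y.shape[0]
    start = spec.lag + spec.embedding - 1
    times = np.arange(start, t_total)
    kdim = x.shape[1] * spec.embedding + y.shape[1] * (spec.embedding + 1)
    if times.size < max(10, kdim + 2):
        raise ValueError(
            f"series too short for lag={spec.lag}, embedding={spec.embedding}: "
            f"{times.size} usable samples"
        )
    y_now = y[times]
    y_past = _embed(y, times, spec.lag, spec.embedding)
    x_past = _embed(x, times, spec.lag, spec.embedding)
    return x_past, y_now, y_past, times


def directed_information(
    x: np.ndarray, y: np.ndarray, lag: LagSpec | int
) -> InfoValue:
    """Directed information (transfer entropy) from ``x`` to ``y``, in bits.

    I(X_{t-lag}; Y_t | Y_{t-lag}) over sliding-window samples: the
    time-lagged dependence of the target on the source over and above the
    target's own self-predictability.  Non-negative up to estimator
    fluctuation; the information-theoretic analogue of Granger causality.
    """
    spec = LagSpec(lag) if isinstance(lag, int) else lag
    x_past, y_now, y_past, _ = _lag_windows(x, y, spec)
    di = gccmi_ccc(x_past, y_now, y_past, bias_correct=True)
    return InfoValue(bits=di.bits, estimator="directed_information", bias_corrected=True)


def directed_feature_information(
    x: np.ndarray, y: np.ndarray, s: np.ndarray, lag: LagSpec | int
) -> InfoValue:
    """DFI = DI(x -> y) - DI(x -> y | S): stimulus-specific communication.

    The portion of the directed information from ``x`` to ``y`` that is
    redundant with the stimulus feature ``s`` (a series aligned to the same
    time axis).  The stimulus is conditioned at the *source* times t - lag,
    i.e. aligned with the source window: that is the feature content the
    source carried when the communicated activity left it.  Signed; a
    constant ``s`` gives exactly 0 since conditioning on a constant changes
    nothing.
    """
    spec = LagSpec(lag) if isinstance(lag, int) else lag
    x_past, y_now, y_past, times = _lag_windows(x, y, spec)
    s = np.asarray(s)
    if s.shape[0] != np.asarray(y).shape[0]:
        raise ValueError("stimulus series must be aligned with the time axis of y")
    s_mat = as_samples(s.astype(float) if _is_discrete(s) else s)
    s_src = _embed(s_mat, times, spec.lag, spec.embedding)
    di = gccmi_ccc(x_past, y_now, y_past, bias_correct=True).bits
    if np.ptp(s_src, axis=0).max() == 0.0:
        # constant stimulus: the conditioned term coincides with DI
        return InfoValue(0.0, "directed_feature_information", True)
    di_s = gccmi_ccc(
        x_past, y_now, np.hstack([y_past, s_src]), bias_correct=True
    ).bits
    return InfoValue(di - di_s, "directed_feature_information", True)


def _time_slab(r: np.ndarray, t: int) -> np.ndarray:
    """Per-time-point response matrix from trials x time (x features) data."""
    if r.ndim == 2:
        return r[:, t : t + 1]
    return r[:, t, :]


def novel_information(
    r: np.ndarray,
    s: np.ndarray,
    accumulate: bool = False,
    anchor_times: tuple[int, ...] = (),
    bias_correct: bool = True,
) -> np.ndarray:
    """New stimulus information arriving at each time point, in bits.

    For t >= 1 computes I(S; R_t | R_{t-1}); when ``accumulate`` is set, the
    responses at the caller-supplied ``anchor_times`` (< t) are added to the
    conditioning set so that information redundant with those earlier peaks
    is not counted again.  The first time point carries plain MI.

    ``r`` is trials x time, or trials x time x d for multivariate per-time
    responses (e.g. value + temporal derivative).
    """
    r = np.asarray(r, dtype=float)
    if r.ndim not in (2, 3):
        raise ValueError("response must be trials x time (x features)")
    n_time = r.shape[1]
    kdim = 1 if r.ndim == 2 else r.shape[2]
    out = np.empty(n_time)
    out[0] = _mi_xs(_time_slab(r, 0), s, bias_correct)
    for t in range(1, n_time):
        cond = [_time_slab(r, t - 1)]
        if accumulate:
            cond += [_time_slab(r, a) for a in anchor_times if a < t - 1]
        z = np.hstack(cond)
        if z.shape[1] + kdim + 2 >= r.shape[0]:
            raise ValueError(
                f"conditioning set dimension {z.shape[1]} too high for "
                f"{r.shape[0]} trials at time {t}"
            )
        out[t] = _cmi_sx_given_z(_time_slab(r, t), s, z, bias_correct)
    return out


def pairwise_interaction_matrix(
    r: np.ndarray, s: np.ndarray, bias_correct: bool = True
) -> np.ndarray:
    """Signed interaction information for every pair of time points (bits).

    Symmetric time x time matrix; the diagonal holds -I(R_t;S), the
    self-redundancy of each time point.  Negative off-diagonal entries mean
    two time points carry overlapping stimulus information; positive entries
    mean their joint readout is synergistic.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim not in (2, 3):
        raise ValueError("response must be trials x time (x features)")
    n_time = r.shape[1]
    cslabs = [copula_normalize(_time_slab(r, t)) for t in range(n_time)]
    mi_t = np.array([_mi_xs(c, s, bias_correct) for c in cslabs])
    out = np.diag(-mi_t)
    for i in range(n_time):
        for j in range(i + 1, n_time):
            joint = _mi_xs(
                _unique_columns(np.hstack([cslabs[i], cslabs[j]])), s, bias_correct
            )
            out[i, j] = out[j, i] = joint - mi_t[i] - mi_t[j]
    return out
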