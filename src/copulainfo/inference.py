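"""Mass-univariate permutation testing with maximum-statistics FWER control.

The observed statistic (by default copula MI, computed without bias
correction -- only the null ordering matters and the correction adds
variance) is evaluated independently for every cell of an analysis grid
(e.g. channels x time points).  A null distribution is built by recomputing
the full map under permutations of the stimulus -- plain label permutation
for exchangeable trials, or blockwise / circular-shift permutation for
autocorrelated series -- and taking the maximum over the grid for each
permutation.  Thresholding the observed map at the (1-alpha) percentile of
these maxima controls the family-wise error rate at alpha over the whole
grid.

The built-in estimators ("gcmi_cd", "gcmi_cc") use a vectorized path: the
copula transform of each cell is computed once (it does not depend on the
stimulus ordering) and per-permutation maps reduce to per-class variances or
correlations across the whole grid at once.  Arbitrary estimator callables
are supported through a generic per-cell path that gives identical results
for the built-ins (asserted in the test suite).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtri

from .discrete import validate_labels

__all__ = [
    "PermutationResult",
    "permute_labels",
    "permute_blocks",
    "max_stat_threshold",
    "run_mass_univariate",
]

_LN2 = np.log(2.0)


def permute_labels(y: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Seeded uniform random permutation of a label vector (or sample matrix rows)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(y)
    return y[rng.permutation(y.shape[0])]


def _block_index(n: int, block_length: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Permutation index for blockwise / circular-shift schemes.

    Blocks are contiguous; an incomplete trailing block is kept as its own
    (shorter) block rather than discarded.
    """
    if block_length is None or block_length < 1:
        raise ValueError("block_length must be a positive integer")
    if block_length > n:
        raise ValueError(f"block_length={block_length} exceeds series length {n}")
    if mode == "circular_shift":
        shift = int(rng.integers(n))
        return np.roll(np.arange(n), shift)
    if mode != "block":
        raise ValueError(f"unknown mode {mode!r}")
    starts = np.arange(0, n, block_length)
    if starts.size < 2:
        raise ValueError("series must contain at least 2 blocks")
    blocks = [np.arange(s, min(s + block_length, n)) for s in starts]
    order = rng.permutation(len(blocks))
    return np.concatenate([blocks[i] for i in order])


def permute_blocks(
    series: np.ndarray,
    block_length: int,
    mode: str = "block",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permute a series while preserving within-block temporal structure.

    ``mode='block'`` reorders contiguous blocks of ``block_length`` samples;
    ``mode='circular_shift'`` rotates the whole series by a random offset.
    Both preserve autocorrelation at lags shorter than the block length, so
    the permutation null retains the chance-coincidence structure that
    autocorrelated signals produce.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    series = np.asarray(series)
    idx = _block_index(series.shape[0], block_length, mode, rng)
    return series[idx]


def max_stat_threshold(null_max: np.ndarray, alpha: float) -> float:
    """FWER threshold: the ceil((1-alpha)*(n_perm+1))-th order statistic of the null maxima.

    The ``+1`` counts the observed (identity) permutation, mirroring the
    permutation p-value convention p = (r+1)/(n_perm+1); exceeding this order
    statistic is equivalent to p <= alpha, which guarantees a family-wise
    error rate of floor(alpha*(n_perm+1))/(n_perm+1) <= alpha under
    exchangeability (the plain ceil((1-alpha)*n_perm) convention is slightly
    anticonservative at small permutation counts).  alpha = 1 returns the
    minimum of the null.  A warning is emitted when fewer than 1/alpha
    permutations are available to estimate the tail.
    """
    null_max = np.asarray(null_max, dtype=float).ravel()
    if null_max.size == 0:
        raise ValueError("empty null distribution")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if null_max.size < 1.0 / alpha:
        warnings.warn(
            f"only {null_max.size} permutations for alpha={alpha}; "
            "at least 1/alpha are recommended",
            RuntimeWarning,
            stacklevel=2,
        )
    k = int(np.ceil((1.0 - alpha) * (null_max.size + 1)))
    k = min(max(k, 1), null_max.size)
    return float(np.sort(null_max)[k - 1])


@dataclass
class PermutationResult:
    """Observed statistic map, permutation null maxima, threshold and mask."""

    observed: np.ndarray
    null_max: np.ndarray
    threshold: float
    mask: np.ndarray
    alpha: float
    n_perm: int
    seed: int | None
    scheme: str
    estimator: str
    block_length: int | None = None
    axes: tuple[str, ...] = field(default_factory=tuple)

    def save(self, outdir: str | Path, stem: str = "result") -> tuple[Path, Path]:
        """Write the map as TSV (grid coords, statistic, mask) plus a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tsv = outdir / f"{stem}_map.tsv"
        coords = np.indices(self.observed.shape).reshape(self.observed.ndim, -1).T
        names = self.axes or tuple(f"axis{i}" for i in range(self.observed.ndim))
        with open(tsv, "w") as fh:
            fh.write("\t".join([*names, "statistic", "significant"]) + "\n")
            for c, v, m in zip(coords, self.observed.ravel(), self.mask.ravel()):
                fh.write(
                    "\t".join(str(int(i)) for i in c)
                    + f"\t{v:.17g}\t{int(m)}\n"
                )
        sidecar = outdir / f"{stem}.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "alpha": self.alpha,
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                    "scheme": self.scheme,
                    "estimator": self.estimator,
                    "block_length": self.block_length,
                    "threshold": self.threshold,
                    "null_max": [float(v) for v in self.null_max],
                    "grid_shape": list(self.observed.shape),
                },
                fh,
                indent=1,
            )
        return tsv, sidecar


def _copula_columns(a: np.ndarray) -> np.ndarray:
    """Column-wise copula normalization of an (N, cells) matrix, vectorized.

    Same ordinal tie-break as the scalar path; no small-N warning, because
    the columns here are independent analyses, not joint dimensions.
    """
    n = a.shape[0]
    order = np.argsort(a, axis=0, kind="stable")
    ranks = np.empty_like(a, dtype=float)
    np.put_along_axis(ranks, order, np.arange(1, n + 1, dtype=float)[:, None], axis=0)
    return ndtri(ranks / (n + 1))


def _cd_map(cx: np.ndarray, y: np.ndarray, m: int) -> np.ndarray:
    """Uncorrected 1-D discrete-continuous copula MI for every column of cx."""
    n = cx.shape[0]
    log_var_u = np.log(cx.var(axis=0, ddof=1))
    acc = np.zeros(cx.shape[1])
    for c in range(m):
        xc = cx[y == c]
        acc += (xc.shape[0] / n) * np.log(xc.var(axis=0, ddof=1))
    return 0.5 * (log_var_u - acc) / _LN2


def _cc_map(cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    """Uncorrected 1-D continuous-continuous copula MI for every column of cx."""
    cxd = cx - cx.mean(axis=0)
    cyd = cy - cy.mean()
    r = (cxd.T @ cyd) / np.sqrt((cxd**2).sum(axis=0) * (cyd**2).sum())
    return -0.5 * np.log1p(-(r**2)) / _LN2


def _perm_index(
    n: int, scheme: str, block_length: int | None, rng: np.random.Generator
) -> np.ndarray:
    if scheme == "labels":
        return rng.permutation(n)
    if scheme in ("block", "circular_shift"):
        return _block_index(n, block_length, scheme, rng)
    raise ValueError(f"unknown permutation scheme {scheme!r}")


def run_mass_univariate(
    data: np.ndarray,
    y: np.ndarray,
    estimator="gcmi_cd",
    scheme: str = "labels",
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | None = None,
    block_length: int | None = None,
    axes: tuple[str, ...] = (),
) -> PermutationResult:
    """Mass-univariate copula-MI analysis with max-statistics FWER control.

    Parameters
    ----------
    data
        Trials x grid array; the grid may be multi-dimensional
        (e.g. trials x channels x time points).
    y
        Integer class labels (estimator "gcmi_cd"), a continuous feature
        (estimator "gcmi_cc"), or whatever the estimator callable expects.
    estimator
        "gcmi_cd", "gcmi_cc", or a callable ``f(cell_values, y) -> float``
        applied per grid cell.
    scheme
        "labels" (full permutation of y), "block" or "circular_shift"
        (autocorrelation-preserving permutation of y; requires
        ``block_length`` for "block").
    """
    data = np.asarray(data, dtype=float)
    if data.ndim < 2:
        raise ValueError("data must be trials x grid")
    n = data.shape[0]
    grid_shape = data.shape[1:]
    flat = data.reshape(n, -1)
    rng = np.random.default_rng(seed)
    if scheme == "circular_shift" and block_length is None:
        block_length = 1  # unused by the shift itself, validated for "block"

    if estimator == "gcmi_cd":
        yv, m = validate_labels(np.asarray(y), min_per_class=3)
        if yv.shape[0] != n:
            raise ValueError("label vector length must match the trial count")
        cx = _copula_columns(flat)
        observed = _cd_map(cx, yv, m)
        null_max = np.empty(n_perm)
        for p in range(n_perm):
            yp = yv[_perm_index(n, scheme, block_length, rng)]
            null_max[p] = _cd_map(cx, yp, m).max()
        est_name = "gcmi_cd"
    elif estimator == "gcmi_cc":
        yc = np.asarray(y, dtype=float).ravel()
        if yc.shape[0] != n:
            raise ValueError("feature vector length must match the trial count")
        cx = _copula_columns(flat)
        cy = _copula_columns(yc[:, None])[:, 0]
        observed = _cc_map(cx, cy)
        null_max = np.empty(n_perm)
        for p in range(n_perm):
            cyp = cy[_perm_index(n, scheme, block_length, rng)]
            null_max[p] = _cc_map(cx, cyp).max()
        est_name = "gcmi_cc"
    elif callable(estimator):
        y_arr = np.asarray(y)

        def _apply(yy: np.ndarray) -> np.ndarray:
            out = np.empty(flat.shape[1])
            for j in range(flat.shape[1]):
                try:
                    out[j] = float(estimator(flat[:, j], yy))
                except Exception as err:
                    coord = np.unravel_index(j, grid_shape)
                    raise RuntimeError(
                        f"estimator failed at grid cell {coord}: {err}"
                    ) from err
            return out

        observed = _apply(y_arr)
        null_max = np.empty(n_perm)
        for p in range(n_perm):
            yp = y_arr[_perm_index(n, scheme, block_length, rng)]
            null_max[p] = _apply(yp).max()
        est_name = getattr(estimator, "__name__", "custom")
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    threshold = max_stat_threshold(null_max, alpha)
    observed = observed.reshape(grid_shape)
    return PermutationResult(
        observed=observed,
        null_max=null_max,
        threshold=threshold,
        mask=observed > threshold,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
        estimator=est_name,
        block_length=block_length,
        axes=tuple(axes),
    )
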