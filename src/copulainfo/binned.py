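"""Binned (discrete) reference estimators: the baseline the copula method improves on.

Equipopulated quantization, plug-in entropy/MI, the Miller-Madow bias
correction, and the bridge between MI and the likelihood-ratio (G) test of
independence: G = 2 N ln(2) I, chi-square distributed with
df = (|R|-1)(|S|-1) under independence.  That same null expectation,
df / (2 N ln 2) bits, is what the Miller-Madow correction subtracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .copula import InfoValue
from .discrete import validate_labels

__all__ = [
    "ContingencyTable",
    "quantize_equipopulated",
    "entropy_plugin",
    "mi_plugin",
    "g_test",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Joint count table of two discrete variables."""

    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def df(self) -> int:
        r, s = self.counts.shape
        return (r - 1) * (s - 1)

    @classmethod
    def from_labels(cls, x: np.ndarray, y: np.ndarray) -> "ContingencyTable":
        x, mx = validate_labels(x)
        y, my = validate_labels(y)
        if x.shape[0] != y.shape[0]:
            raise ValueError("label vectors must have equal length")
        counts = np.zeros((mx, my), dtype=np.int64)
        np.add.at(counts, (x, y), 1)
        return cls(counts=counts)


def quantize_equipopulated(x: np.ndarray, nbins: int) -> np.ndarray:
    """Quantize by empirical quantile membership into near-equal-occupancy bins.

    Label of sample i is floor(rank_i * nbins / N) with ordinal ranks (ties
    broken by original sample index), so bin counts never differ by more than
    one and the labels are invariant to strictly monotone transforms of x.
    A warning is emitted when tied values straddle a bin boundary, since the
    quantiles are then degenerate and the split of the tie is arbitrary.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    if n < nbins:
        raise ValueError(f"need at least nbins={nbins} samples, got {n}")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite entries")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    labels = (ranks * nbins) // n
    # degenerate quantiles: identical values assigned to different bins
    srt = np.argsort(x, kind="stable")
    same_value = np.diff(x[srt]) == 0
    straddles = same_value & (np.diff(labels[srt]) != 0)
    if straddles.any():
        warnings.warn(
            "quantize_equipopulated: tied values straddle a bin boundary; "
            "quantiles are degenerate and the tie split is by sample index",
            RuntimeWarning,
            stacklevel=2,
        )
    return labels


def entropy_plugin(p: np.ndarray) -> float:
    """Plug-in (maximum-likelihood) entropy in bits, with 0*log(0) = 0.

    ``p`` may be a probability array (any shape; must sum to 1) or an integer
    label vector, in which case empirical frequencies are used.
    """
    p = np.asarray(p)
    if p.ndim == 1 and np.issubdtype(p.dtype, np.integer):
        _, counts = np.unique(p, return_counts=True)
        p = counts / counts.sum()
    else:
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must be non-negative and sum to 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def _mi_from_table(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    return entropy_plugin(px) + entropy_plugin(py) - entropy_plugin(p.ravel())


def mi_plugin(
    x: np.ndarray, y: np.ndarray, correction: str = "none"
) -> InfoValue:
    """Plug-in MI between two discrete variables, in bits.

    ``correction='miller_madow'`` subtracts the expected null bias
    (|R|-1)(|S|-1)/(2 N ln 2) bits, the mean of the chi-square null
    distribution of the G statistic expressed on the MI scale.
    """
    if correction not in ("none", "miller_madow"):
        raise ValueError(f"unknown correction {correction!r}")
    table = ContingencyTable.from_labels(x, y)
    bits = _mi_from_table(table.counts)
    corrected = correction == "miller_madow"
    if corrected:
        bits -= table.df / (2.0 * table.n * _LN2)
    return InfoValue(bits=bits, estimator="mi_plugin", bias_corrected=corrected)


def g_test(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Likelihood-ratio (G) test of independence between two label vectors.

    G = 2 N ln(2) I_plugin(bits); under independence G ~ chi-square with
    df = (|R|-1)(|S|-1).  Returns ``{'G', 'df', 'p'}``.
    """
    table = ContingencyTable.from_labels(x, y)
    counts = table.counts
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("a full row/column of the table has zero expected count")
    g = 2.0 * table.n * _LN2 * _mi_from_table(counts)
    return {
        "G": float(g),
        "df": int(table.df),
        "p": float(stats.chi2.sf(g, table.df)),
    }
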