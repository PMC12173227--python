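"""Nonequilibrium metrics: gEC asymmetry and time-series irreversibility.

Two complementary views of how far a model is from detailed balance:

* **Asymmetry count** — structural: the number of region pairs whose two
  directed gEC weights differ by at least a threshold gamma.
* **Irreversibility** — dynamical (the INSIDEOUT construction): compare
  the lagged correlations of the forward and the time-reversed signal;
  their squared discrepancy, after the variance-stabilizing map
  ``FS = 0.5 * log(1 - r^2)``, quantifies the arrow of time.  For a
  reversible (equilibrium) process the two agree and the index is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CouplingMatrix, SignalPanel

__all__ = [
    "AsymmetryResult",
    "IrreversibilityResult",
    "asymmetry_count",
    "calibrate_gamma",
    "irreversibility",
]

DEFAULT_GAMMA = 0.12
GAMMA_GRID_STEP = 0.005


@dataclass
class AsymmetryResult:
    count: int
    gamma: float
    binarized: np.ndarray  # symmetric 0/1 matrix of above-threshold pairs


@dataclass
class IrreversibilityResult:
    value: float
    fs_forward: np.ndarray
    fs_reversed: np.ndarray
    lag_samples: int


def _weights(gec) -> np.ndarray:
    if isinstance(gec, CouplingMatrix):
        return gec.weights
    w = np.asarray(gec, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("gec must be a square matrix")
    return w


def asymmetry_count(gec, gamma: float = DEFAULT_GAMMA) -> AsymmetryResult:
    """Number of node pairs whose directed weights differ by >= gamma.

    The binarized matrix is ``A_ij = 1`` iff ``|w_ij - w_ji| >= gamma``;
    the count is ``sum(A) / 2`` (each unordered pair once).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    w = _weights(gec)
    binarized = (np.abs(w - w.T) >= gamma).astype(int)
    np.fill_diagonal(binarized, 0)
    return AsymmetryResult(
        count=int(binarized.sum()) // 2, gamma=gamma, binarized=binarized
    )


def calibrate_gamma(gecs: list, step: float = GAMMA_GRID_STEP) -> float:
    """Largest grid-aligned gamma keeping every gEC's count nonzero.

    The threshold is chosen on a grid of spacing ``step`` as the largest
    value for which every supplied gEC still has at least one
    asymmetric pair.  That is simply the minimum over gECs of the maximum
    pairwise weight gap, floored to the grid.
    """
    if not gecs:
        raise ValueError("need at least one gEC")
    max_gaps = []
    for g in gecs:
        w = _weights(g)
        gap = float(np.max(np.abs(w - w.T)))
        if gap == 0:
            raise ValueError("a perfectly symmetric gEC admits no threshold")
        max_gaps.append(gap)
    k = int(np.floor(min(max_gaps) / step * (1 + 1e-12) + 1e-12))
    gamma = k * step
    # grid multiples can land one ulp above the true gap; step down an
    # ulp before conceding a whole grid step
    def _ok(g):
        return all(asymmetry_count(m, g).count >= 1 for m in gecs)

    if not _ok(gamma) and _ok(np.nextafter(gamma, 0)):
        gamma = float(np.nextafter(gamma, 0))
    while gamma >= step and not _ok(gamma):
        k -= 1
        gamma = k * step
    if gamma < step:
        raise ValueError(
            f"smallest maximum asymmetry {min(max_gaps):.4g} is below one "
            f"grid step ({step}); no positive grid threshold works"
        )
    return float(gamma)


def _lagged_corr(values: np.ndarray, lag: int) -> np.ndarray:
    """r[i, j] = Pearson correlation of x_i(t) with x_j(t + lag)."""
    t = values.shape[1]
    a = values[:, : t - lag]
    b = values[:, lag:]
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return az @ bz.T / (t - lag)


def irreversibility(
    panel: SignalPanel | np.ndarray, lag_samples: int = 1
) -> IrreversibilityResult:
    """Arrow-of-time index of a multivariate series.

    ``FS_f = 0.5 log(1 - r_f^2)`` with ``r_f`` the forward lagged
    correlation matrix, ``FS_r`` its analogue on the time-reversed
    series, and the index is the mean over all N^2 entries of
    ``(FS_f - FS_r)^2``.  Exactly zero for data statistically symmetric
    under time reversal; always nonnegative.
    """
    values = panel.values if isinstance(panel, SignalPanel) else np.asarray(panel, float)
    n, t = values.shape
    lag = int(lag_samples)
    if not 1 <= lag < t / 2:
        raise ValueError(f"lag_samples must satisfy 1 <= lag < T/2, got {lag}")
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(
            f"zero-variance regions: {np.flatnonzero(sd == 0).tolist()}"
        )
    r_f = _lagged_corr(values, lag)
    r_r = _lagged_corr(values[:, ::-1], lag)
    for name, r in (("forward", r_f), ("reversed", r_r)):
        sat = np.abs(r) >= 1.0
        if sat.any():
            i, j = np.argwhere(sat)[0]
            raise ValueError(
                f"|{name} lagged correlation| = 1 at entry ({i}, {j}); "
                "log term diverges"
            )
    fs_f = 0.5 * np.log1p(-(r_f**2))
    fs_r = 0.5 * np.log1p(-(r_r**2))
    value = float(np.mean((fs_f - fs_r) ** 2))
    return IrreversibilityResult(
        value=value, fs_forward=fs_f, fs_reversed=fs_r, lag_samples=lag
    )
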