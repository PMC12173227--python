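"""Linear approximation of the Hopf network: analytic covariances.

Linearizing the Stuart-Landau equations at the origin (dropping the cubic
terms, valid for a < 0 where the origin is the attractor) yields a
multivariate Ornstein-Uhlenbeck process dX = A X dt + beta dW on the
stacked state X = (x_1..x_N, y_1..y_N).  Its stationary covariance solves
the continuous Lyapunov equation

    A S + S A^T + Q = 0,        Q = beta^2 I,

and the lagged covariance follows from the matrix exponential,
<X(t+tau) X(t)^T> = expm(A tau) S.  This gives the model-side lagged
covariance of the fitting loop in microseconds instead of a stochastic
simulation, and makes the fit deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .core import LaggedCovariance
from .hopf import HopfParams

__all__ = [
    "LinearModel",
    "StabilityError",
    "build_linear_model",
    "stationary_covariance",
    "analytic_lagged_covariance",
]


class StabilityError(ValueError):
    pass


@dataclass
class LinearModel:
    """Drift matrix A (2N x 2N) and diffusion Q = beta^2 I of the OU model."""

    jacobian: np.ndarray
    noise_cov: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.jacobian.shape[0] // 2


def build_linear_model(params: HopfParams) -> LinearModel:
    """Assemble and stability-check the linearized drift.

    The x-block Jacobian has row j: ``a_j - G * sum_i C_ij`` on the
    diagonal and ``G * C_ij`` as the coefficient of x_i, i.e. the
    diffusive coupling ``G sum_i C_ij (x_i - x_j)`` differentiated at the
    origin; the y-block is identical, and the two are coupled by the
    rotation ``-diag(omega)`` / ``+diag(omega)``.

    Raises :class:`StabilityError` when any eigenvalue of A has a
    nonnegative real part (e.g. a node with a >= 0, where the origin is
    no longer the attractor).
    """
    n = params.n_regions
    W = params.C.weights
    col_sum = W.sum(axis=0)
    # row j, column i: d(x_j)/d(x_i) = G * C[i, j] for i != j
    Dxx = params.G * W.T + np.diag(params.a - params.G * col_sum)
    Om = np.diag(params.omega)
    A = np.block([[Dxx, -Om], [Om, Dxx]])
    max_re = float(np.max(np.linalg.eigvals(A).real))
    if max_re >= 0:
        raise StabilityError(
            f"linearized model unstable: max Re(eigenvalue) = {max_re:.4g}"
        )
    Q = params.beta**2 * np.eye(2 * n)
    return LinearModel(jacobian=A, noise_cov=Q)


def stationary_covariance(model: LinearModel) -> np.ndarray:
    """Stationary covariance S solving A S + S A^T + Q = 0 (2N x 2N)."""
    S = solve_continuous_lyapunov(model.jacobian, -model.noise_cov)
    S = 0.5 * (S + S.T)
    resid = model.jacobian @ S + S @ model.jacobian.T + model.noise_cov
    if not np.isfinite(S).all() or np.max(np.abs(resid)) > 1e-6:
        raise np.linalg.LinAlgError("Lyapunov solve failed to converge")
    return S


def analytic_lagged_covariance(
    model: LinearModel, tau_seconds: float, lag_samples: int = 1
) -> LaggedCovariance:
    """Model-side analogue of :func:`neqbrain.signal_prep.lagged_covariance`.

    Returns the x-x block of the stationary correlation (``corr0``) and of
    the lagged covariance ``<x_i(t) x_j(t + tau)>``, both normalized by
    the stationary standard deviations so they live on the z-scored scale
    of the empirical estimator.  ``lag_samples`` is carried along for
    bookkeeping (``tau_seconds`` is normally ``lag_samples * tr``).
    """
    if tau_seconds < 0:
        raise ValueError("tau_seconds must be >= 0")
    n = model.n_regions
    S = stationary_covariance(model)
    # <X(t+tau) X(t)^T> = expm(A tau) S; entry (i, j) of the *lagged*
    # matrix we report is <x_i(t) x_j(t+tau)> = [expm(A tau) S]_{ji},
    # i.e. S @ expm(A tau)^T.
    M = expm(model.jacobian * tau_seconds)
    full = S @ M.T
    Sxx = S[:n, :n]
    Lxx = full[:n, :n]
    d = np.sqrt(np.diag(Sxx))
    norm = np.outer(d, d)
    return LaggedCovariance(
        corr0=Sxx / norm, cov_lag=Lxx / norm, lag_samples=lag_samples
    )
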