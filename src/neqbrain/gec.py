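"""Generative effective connectivity (gEC) inference.

The gEC is the directed coupling matrix C for which the linearized Hopf
model reproduces a panel's empirical zero-lag and time-lagged
covariances.  It is fitted with a heuristic delta rule: at each iteration
the analytic model covariances are computed (module
:mod:`neqbrain.linear_hopf`), and every masked off-diagonal weight moves
a small step in the direction of the remaining covariance discrepancy,

    w_ij <- clip(w_ij + lr * [(corr0_emp - corr0_mod)
                              + (cov_lag_emp - cov_lag_mod)]_ij, 0, cap),

until the error has stagnated.  Because the lagged covariance is
asymmetric, the two directions of a structural connection converge to
different weights; that asymmetry is the quantity the downstream
nonequilibrium metrics consume.

Cohorts are fitted hierarchically: first one gEC per group against the
group-averaged covariances (initialized at the structural scaffold), then
one gEC per subject against the subject's own covariances, initialized at
the group solution.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import CouplingMatrix, LaggedCovariance, SignalPanel
from .linear_hopf import StabilityError, analytic_lagged_covariance, build_linear_model
from .signal_prep import lagged_covariance

__all__ = [
    "FitConfig",
    "FitTrace",
    "fit_objective",
    "fit_gec",
    "average_lagged_covariances",
    "fit_group_then_individual",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the delta-rule fit.

    The stop rule mirrors the qualitative "error has stagnated"
    criterion: stop when the relative improvement over the last
    ``stall_window`` iterations falls below ``stall_tol``.  ``weight_cap``
    bounds every weight; with diffusive coupling and G = 1 it keeps the
    fitted models comfortably inside the stable regime and fixes the
    scale on which the asymmetry threshold gamma is interpreted.
    ``use_corr0=False`` matches the lagged covariance alone.
    """

    learning_rate: float = 1e-3
    max_iter: int = 10_000
    stall_window: int = 100
    stall_tol: float = 1e-5
    weight_cap: float = 0.2
    lag_samples: int = 1
    use_corr0: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_cap <= 0:
            raise ValueError("weight_cap must be positive")
        if self.max_iter < 1 or self.stall_window < 1:
            raise ValueError("max_iter and stall_window must be >= 1")


@dataclass
class FitTrace:
    """Per-iteration objective values of one fit."""

    errors: np.ndarray
    final_error: float
    iterations_run: int
    converged: bool


def fit_objective(
    empirical: LaggedCovariance, model_cov: LaggedCovariance
) -> float:
    """Mean squared covariance mismatch.

    Off-diagonal entries of the zero-lag correlation and *all* entries of
    the lagged covariance contribute with equal weight.
    """
    if empirical.corr0.shape != model_cov.corr0.shape:
        raise ValueError("shape mismatch between empirical and model covariances")
    if empirical.lag_samples != model_cov.lag_samples:
        raise ValueError("lag mismatch between empirical and model covariances")
    n = empirical.n_regions
    off = ~np.eye(n, dtype=bool)
    sq = np.sum((empirical.corr0 - model_cov.corr0)[off] ** 2)
    sq += np.sum((empirical.cov_lag - model_cov.cov_lag) ** 2)
    return float(sq / (off.sum() + n * n))


def _model_cov(params, weights, mask, tau, lag):
    model = build_linear_model(
        params.with_coupling(CouplingMatrix(weights=weights, mask=mask))
    )
    return analytic_lagged_covariance(model, tau, lag_samples=lag)


def fit_gec(
    empirical: LaggedCovariance,
    init: CouplingMatrix,
    params,
    config: FitConfig = FitConfig(),
) -> tuple[CouplingMatrix, FitTrace]:
    """Fit a gEC to one set of empirical covariances.

    ``params`` supplies the node parameters (a, omega, G, beta, tr); its
    coupling matrix is replaced by the evolving weights.  The model lag
    ``tau = lag_samples * tr`` matches the empirical estimator's lag.
    The fit is fully deterministic.
    """
    if empirical.n_regions != init.n_regions:
        raise ValueError("empirical covariance and init coupling sizes differ")
    mask = init.mask
    tau = config.lag_samples * params.tr
    lag = config.lag_samples
    upd_mask = mask & ~np.eye(init.n_regions, dtype=bool)

    weights = init.weights.copy()
    prev_weights: np.ndarray | None = None
    step: np.ndarray | None = None
    errors: list[float] = []
    converged = False
    best_err = np.inf
    best_weights = weights
    for _ in range(config.max_iter):
        # diffusive coupling with nonnegative weights is provably stable,
        # but guard anyway: halve the previous step until the model
        # stabilizes again.
        for _retry in range(20):
            try:
                mod = _model_cov(params, weights, mask, tau, lag)
                break
            except StabilityError:
                if prev_weights is None:
                    raise
                log.warning("unstable update at iteration %d; halving step", len(errors))
                step = 0.5 * step
                weights = np.where(
                    upd_mask,
                    np.clip(prev_weights + step, 0, config.weight_cap),
                    prev_weights,
                )
        else:
            raise StabilityError("update kept the model unstable after 20 halvings")

        err = fit_objective(empirical, mod)
        if not np.isfinite(err):
            raise FloatingPointError("non-finite fit error; aborting")
        errors.append(err)
        if err < best_err:
            best_err = err
            best_weights = weights

        w = config.stall_window
        if len(errors) > w:
            ref = errors[-1 - w]
            improvement = (ref - errors[-1]) / max(ref, 1e-300)
            if improvement < config.stall_tol:
                converged = True
                break

        delta = empirical.cov_lag - mod.cov_lag
        if config.use_corr0:
            delta = delta + (empirical.corr0 - mod.corr0)
        step = config.learning_rate * delta
        prev_weights = weights
        weights = np.where(
            upd_mask, np.clip(weights + step, 0, config.weight_cap), weights
        )

    # the delta rule is a heuristic, not strict descent: keep the best
    # iterate so warm-started fits can never end worse than they began
    trace = FitTrace(
        errors=np.asarray(errors),
        final_error=best_err,
        iterations_run=len(errors),
        converged=converged,
    )
    return CouplingMatrix(weights=best_weights, mask=mask.copy()), trace


def average_lagged_covariances(covs: list[LaggedCovariance]) -> LaggedCovariance:
    """Entrywise average, used to build group-level fitting targets."""
    if not covs:
        raise ValueError("no covariances to average")
    lag = covs[0].lag_samples
    if any(c.lag_samples != lag for c in covs):
        raise ValueError("covariances have differing lags")
    return LaggedCovariance(
        corr0=np.mean([c.corr0 for c in covs], axis=0),
        cov_lag=np.mean([c.cov_lag for c in covs], axis=0),
        lag_samples=lag,
    )


def fit_group_then_individual(
    panels: list[SignalPanel],
    sc: CouplingMatrix,
    params,
    config: FitConfig = FitConfig(),
) -> tuple[dict[str, tuple[CouplingMatrix, FitTrace]], dict[str, CouplingMatrix]]:
    """Hierarchical cohort fit.

    Panels are grouped by ``state_label``.  Per group, the subjects'
    empirical covariances are averaged and a group gEC is fitted starting
    from the structural scaffold ``sc``; each subject's gEC is then
    fitted against that subject's own covariances starting from the group
    solution.  Panels are used as given: apply any band-pass intended
    for the covariance targets before calling.

    Returns ``(per_subject, per_group)`` where ``per_subject`` maps
    subject id to ``(gec, trace)``.
    """
    by_group: dict[str, list[SignalPanel]] = defaultdict(list)
    for p in panels:
        by_group[p.state_label].append(p)
    for label, members in by_group.items():
        if not members:
            raise ValueError(f"group {label!r} has no subjects")
    seen: set[str] = set()
    for p in panels:
        if p.subject_id in seen:
            raise ValueError(f"duplicate subject_id {p.subject_id!r}")
        seen.add(p.subject_id)

    per_subject: dict[str, tuple[CouplingMatrix, FitTrace]] = {}
    per_group: dict[str, CouplingMatrix] = {}
    for label, members in by_group.items():
        covs = {
            p.subject_id: lagged_covariance(p, config.lag_samples) for p in members
        }
        group_target = average_lagged_covariances(list(covs.values()))
        group_gec, _ = fit_gec(group_target, sc, params, config)
        per_group[label] = group_gec
        for p in members:
            per_subject[p.subject_id] = fit_gec(
                covs[p.subject_id], group_gec, params, config
            )
    return per_subject, per_group
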