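"""State-transition perturbational complexity for simulated fMRI (sfPCI).

The response window of an in-silico perturbation is decomposed by PCA
(regions as variables); the principal components that explain 99% of the
response variance define a low-dimensional state space, and the baseline
window is projected into the same space (same mean, same loadings).  Per
component, the number of state transitions (NST) is counted on both
windows: pairwise sample distances are thresholded at epsilon and the
resulting recurrence rows are scanned for value changes, giving a
per-sample transition rate.  The sfPCI is the summed (over components)
excess of response transitions over baseline transitions, maximized over
an epsilon scan and floored at zero, scaled by the response length so the
number is a transition *count*.

The absolute magnitude of the index depends on the perturbation protocol
and the scan grid; only orderings and correlations across models are
meaningful, which is how the index is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hopf import PerturbationRecord

__all__ = [
    "PCIConfig",
    "PCIResult",
    "select_components",
    "count_state_transitions",
    "st_pci",
]


@dataclass(frozen=True)
class PCIConfig:
    """Knobs of the state-transition complexity index.

    var_threshold
        Cumulative explained-variance fraction deciding how many response
        principal components are retained (0.99 by default).
    n_thresholds
        Size of the epsilon scan grid, log-spaced between the 1st and
        99th percentile of the pooled baseline/response distance
        distribution of each component.
    max_components
        Hard cap on retained components (None: no cap).
    min_snr
        Minimum response-to-baseline RMS ratio for a component to
        contribute: components whose response amplitude does not exceed
        the unperturbed fluctuations carry no stimulus-evoked signal and
        would only accumulate positive noise through the epsilon
        maximization.
    base_weight
        Factor multiplying the baseline transition rate before
        differencing; values above 1 penalize components whose baseline
        is already transition-rich.
    """

    var_threshold: float = 0.99
    n_thresholds: int = 10
    max_components: int | None = None
    min_snr: float = 1.1
    base_weight: float = 1.2

    def __post_init__(self) -> None:
        if not 0 < self.var_threshold <= 1:
            raise ValueError("var_threshold must be in (0, 1]")
        if self.n_thresholds < 2:
            raise ValueError("n_thresholds must be >= 2")
        if self.min_snr < 0 or self.base_weight <= 0:
            raise ValueError("min_snr must be >= 0 and base_weight > 0")


@dataclass
class PCIResult:
    value: float
    n_components: int
    per_component: np.ndarray  # Delta-NST per retained component
    node: int                  # perturbed region


def select_components(
    record: PerturbationRecord, config: PCIConfig = PCIConfig()
) -> tuple[int, np.ndarray, np.ndarray]:
    """PCA of the response; both windows projected onto its axes.

    Returns ``(k, response_scores, baseline_scores)`` with score arrays of
    shape ``(k, T_window)``.  ``k`` is the smallest number of response
    principal components reaching ``var_threshold`` cumulative explained
    variance (capped at ``max_components``).  The baseline is expressed in
    the response's state space: the response mean is subtracted from it
    and the response loadings applied.
    """
    resp = record.response.values
    base = record.baseline.values
    if resp.shape[1] < 2:
        raise ValueError("response needs at least 2 timepoints")
    mu = resp.mean(axis=1, keepdims=True)
    centered = resp - mu
    # rows = timepoints, columns = regions
    _, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("response window has zero variance")
    cumfrac = np.cumsum(var) / total
    k = int(np.searchsorted(cumfrac, config.var_threshold - 1e-12) + 1)
    k = min(k, len(s))
    if config.max_components is not None:
        k = min(k, config.max_components)
    axes = vt[:k]  # (k, n_regions)
    response_scores = axes @ centered
    baseline_scores = axes @ (base - mu)
    return k, response_scores, baseline_scores


def count_state_transitions(score_series: np.ndarray, epsilon: float) -> float:
    """Per-sample state-transition rate of a 1-D score series.

    Build the pairwise distance matrix ``D_ts = |y_t - y_s|``, binarize at
    ``epsilon`` (distance > epsilon means "different state"), and average
    over reference samples t the number of value changes along each
    thresholded row, divided by the series length.
    """
    y = np.asarray(score_series, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("series must have at least 2 samples")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    tm = np.abs(y[:, None] - y[None, :]) > epsilon
    changes = (tm[:, 1:] != tm[:, :-1]).sum(axis=1)
    return float(changes.mean() / y.size)


def _pair_distances(y: np.ndarray) -> np.ndarray:
    d = np.abs(y[:, None] - y[None, :])
    iu = np.triu_indices(y.size, k=1)
    return d[iu]


def st_pci(
    record: PerturbationRecord, config: PCIConfig = PCIConfig()
) -> PCIResult:
    """State-transition PCI of one perturbation record.

    Per retained component, epsilon is scanned over ``n_thresholds``
    log-spaced values between the 1st and 99th percentile of the pooled
    baseline/response pairwise-distance distribution; the component
    contributes ``max(0, max_eps(NST_response - base_weight * NST_baseline))``,
    and only if its response RMS exceeds ``min_snr`` times its baseline
    RMS (components without stimulus-evoked signal are discarded).  The
    total is scaled by the response length, making values comparable
    across window lengths.
    """
    k, resp_scores, base_scores = select_components(record, config)
    t_resp = resp_scores.shape[1]
    per_component = np.zeros(k)
    resp_rms = np.sqrt(np.mean(resp_scores**2, axis=1))
    base_rms = np.sqrt(np.mean(base_scores**2, axis=1))
    for c in range(k):
        if resp_rms[c] <= config.min_snr * base_rms[c]:
            continue  # no stimulus-evoked signal on this axis
        pooled = np.concatenate(
            [_pair_distances(resp_scores[c]), _pair_distances(base_scores[c])]
        )
        hi = float(np.percentile(pooled, 99))
        if hi <= 0:
            continue  # both windows constant on this axis
        lo = float(np.percentile(pooled, 1))
        lo = max(lo, hi * 1e-6)
        best = 0.0
        for eps in np.geomspace(lo, hi, config.n_thresholds):
            diff = count_state_transitions(
                resp_scores[c], eps
            ) - config.base_weight * count_state_transitions(base_scores[c], eps)
            best = max(best, diff)
        per_component[c] = best
    return PCIResult(
        value=float(t_resp * per_component.sum()),
        n_components=k,
        per_component=per_component,
        node=record.protocol.node,
    )
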