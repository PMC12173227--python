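"""Stochastic integration of the coupled Stuart-Landau (Hopf) network.

Each region j follows the normal form of a supercritical Hopf bifurcation
in Cartesian coordinates (x_j, y_j):

    dx_j = [(a_j - x_j^2 - y_j^2) x_j - w_j y_j + G sum_i C_ij (x_i - x_j)] dt
           + beta dW
    dy_j = [(a_j - x_j^2 - y_j^2) y_j + w_j x_j + G sum_i C_ij (y_i - y_j)] dt
           + beta dW

with a_j the bifurcation parameter (a < 0: noisy damped oscillation;
a > 0: limit cycle of radius sqrt(a)), w_j the intrinsic angular
frequency, G a global coupling gain and C the directed coupling matrix
(entry (i, j): source i -> target j).  Integration is Euler-Maruyama with
independent Gaussian noise per node and component; the x components,
subsampled at the output interval ``tr`` after a burn-in, emulate the
BOLD-like signal.

A perturbation run switches one node's bifurcation parameter to a
positive value partway through a single continuous integration, splitting
the output into a baseline and a response window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import CouplingMatrix, SignalPanel

__all__ = [
    "HopfParams",
    "PerturbationProtocol",
    "PerturbationRecord",
    "IntegrationError",
    "simulate",
    "simulate_perturbed",
]

# |x| beyond this aborts the integration: the attractors of interest have
# radius sqrt(a) <= O(1), so reaching it means numerical blow-up.
BLOWUP_BOUND = 1e3


class IntegrationError(RuntimeError):
    pass


@dataclass
class HopfParams:
    """Full parameterization of one network simulation."""

    a: np.ndarray          # per-node bifurcation parameter
    omega: np.ndarray      # per-node intrinsic angular frequency, rad/s
    C: CouplingMatrix
    G: float = 1.0
    beta: float = 0.02
    dt: float = 0.1        # integrator step, s
    tr: float = 2.0        # output sampling interval, s
    burn_in: float = 200.0  # seconds discarded before sampling
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.C.n_regions
        self.a = np.broadcast_to(np.asarray(self.a, dtype=float), (n,)).copy()
        self.omega = np.broadcast_to(
            np.asarray(self.omega, dtype=float), (n,)
        ).copy()
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        steps = self.tr / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(f"tr={self.tr} is not an integer multiple of dt={self.dt}")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.C.n_regions

    @property
    def steps_per_sample(self) -> int:
        return round(self.tr / self.dt)

    def with_coupling(self, C: CouplingMatrix) -> "HopfParams":
        return replace(self, C=C)


@dataclass
class PerturbationProtocol:
    """One in-silico stimulation: which node, how strongly, for how long."""

    node: int
    a_pert: float = 0.2
    baseline_len: int = 100
    response_len: int = 100

    def __post_init__(self) -> None:
        if self.a_pert <= 0:
            raise ValueError("a_pert must be positive (pushes the node past the bifurcation)")
        if self.baseline_len < 8 or self.response_len < 8:
            raise ValueError("baseline_len and response_len must be >= 8 samples")


@dataclass
class PerturbationRecord:
    """Baseline and response windows from one perturbation run."""

    baseline: SignalPanel
    response: SignalPanel
    protocol: PerturbationProtocol

    def __post_init__(self) -> None:
        if self.baseline.n_regions != self.response.n_regions:
            raise ValueError("baseline/response region counts differ")
        if self.baseline.tr != self.response.tr:
            raise ValueError("baseline/response tr differ")
        if self.baseline.n_samples != self.protocol.baseline_len:
            raise ValueError("baseline length does not match protocol")
        if self.response.n_samples != self.protocol.response_len:
            raise ValueError("response length does not match protocol")


def _steps_numpy(x, y, a, omega, WT, col_sum, G, dt, noise_x, noise_y):
    """Advance ``noise_x.shape[0]`` Euler-Maruyama steps in place."""
    for s in range(noise_x.shape[0]):
        r2 = x * x + y * y
        cx = G * (WT @ x - col_sum * x)
        cy = G * (WT @ y - col_sum * y)
        dx = (a - r2) * x - omega * y + cx
        dy = (a - r2) * y + omega * x + cy
        x += dt * dx + noise_x[s]
        y += dt * dy + noise_y[s]


try:  # jitted kernel when numba is available; numpy loop otherwise
    from numba import njit

    _steps_kernel = njit(cache=True)(_steps_numpy)
except ImportError:  # pragma: no cover
    _steps_kernel = _steps_numpy


class _Integrator:
    """Stateful Euler-Maruyama stepper so runs can be chained continuously.

    Noise is pre-drawn in blocks (already scaled by ``beta * sqrt(dt)``)
    and the arithmetic is delegated to a compiled kernel; the draw order
    is fixed, so output is reproducible for a given seed.
    """

    _BLOCK = 2048  # steps integrated per kernel call when not recording

    def __init__(self, params: HopfParams, x0=None, y0=None):
        self.p = params
        n = params.n_regions
        self.x = np.zeros(n) if x0 is None else np.array(x0, dtype=float)
        self.y = np.zeros(n) if y0 is None else np.array(y0, dtype=float)
        self.rng = np.random.default_rng(params.seed)
        self.WT = np.ascontiguousarray(params.C.weights.T)
        self.col_sum = params.C.weights.sum(axis=0)  # sum_i C_ij per target j
        self.noise_scale = params.beta * np.sqrt(params.dt)
        self.step_count = 0

    def _noise(self, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
        n = self.p.n_regions
        if self.noise_scale > 0:
            block = self.noise_scale * self.rng.standard_normal((2, n_steps, n))
            return block[0], block[1]
        zeros = np.zeros((n_steps, n))
        return zeros, zeros

    def _check(self) -> None:
        if not np.isfinite(self.x).all() or np.max(np.abs(self.x)) > BLOWUP_BOUND:
            raise IntegrationError(
                f"|x| exceeded {BLOWUP_BOUND} at step {self.step_count}"
            )

    def run(self, n_steps: int, a: np.ndarray, record_every: int = 0) -> np.ndarray | None:
        """Advance ``n_steps``; optionally record x every ``record_every`` steps.

        Recording happens *after* each block of ``record_every`` steps, so
        the first recorded sample already reflects the supplied ``a``.
        """
        p = self.p
        a = np.asarray(a, dtype=float)
        out = None
        if record_every:
            out = np.empty((p.n_regions, n_steps // record_every))
            for k in range(n_steps // record_every):
                nx, ny = self._noise(record_every)
                _steps_kernel(
                    self.x, self.y, a, p.omega, self.WT, self.col_sum,
                    p.G, p.dt, nx, ny,
                )
                self.step_count += record_every
                self._check()
                out[:, k] = self.x
        else:
            done = 0
            while done < n_steps:
                chunk = min(self._BLOCK, n_steps - done)
                nx, ny = self._noise(chunk)
                _steps_kernel(
                    self.x, self.y, a, p.omega, self.WT, self.col_sum,
                    p.G, p.dt, nx, ny,
                )
                done += chunk
                self.step_count += chunk
                self._check()
        return out


def _region_ids(n: int) -> list[str]:
    return [f"R{i:03d}" for i in range(n)]


def simulate(
    params: HopfParams,
    n_samples: int,
    x0: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    subject_id: str = "",
    state_label: str = "",
) -> SignalPanel:
    """Integrate the resting network and return x sampled at ``tr``.

    Identical ``params`` (including seed) give bit-identical output.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    it = _Integrator(params, x0=x0, y0=y0)
    burn_steps = round(params.burn_in / params.dt)
    if burn_steps:
        it.run(burn_steps, params.a)
    spp = params.steps_per_sample
    values = it.run(n_samples * spp, params.a, record_every=spp)
    return SignalPanel(
        values=values,
        tr=params.tr,
        region_ids=_region_ids(params.n_regions),
        subject_id=subject_id,
        state_label=state_label,
    )


def simulate_perturbed(
    params: HopfParams,
    protocol: PerturbationProtocol,
    x0: np.ndarray | None = None,
    y0: np.ndarray | None = None,
) -> PerturbationRecord:
    """One continuous run: resting baseline, then a perturbed response.

    After the burn-in, ``baseline_len`` samples are recorded with all
    nodes at their resting bifurcation parameters; then the target node's
    parameter is switched to ``a_pert`` and ``response_len`` samples are
    recorded.  The response starts at the switch.
    """
    n = params.n_regions
    if not 0 <= protocol.node < n:
        raise ValueError(f"node {protocol.node} out of range for {n} regions")
    it = _Integrator(params, x0=x0, y0=y0)
    burn_steps = round(params.burn_in / params.dt)
    if burn_steps:
        it.run(burn_steps, params.a)
    spp = params.steps_per_sample
    base = it.run(protocol.baseline_len * spp, params.a, record_every=spp)
    a_pert = params.a.copy()
    a_pert[protocol.node] = protocol.a_pert
    resp = it.run(protocol.response_len * spp, a_pert, record_every=spp)
    ids = _region_ids(n)
    return PerturbationRecord(
        baseline=SignalPanel(values=base, tr=params.tr, region_ids=ids),
        response=SignalPanel(values=resp, tr=params.tr, region_ids=list(ids)),
        protocol=protocol,
    )
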