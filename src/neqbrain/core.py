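"""Core data containers shared across the pipeline.

Three objects move between stages: :class:`SignalPanel` (a region x time
matrix of BOLD-like samples), :class:`CouplingMatrix` (directed coupling
weights under a symmetric structural mask), and :class:`LaggedCovariance`
(the zero-lag correlation together with the covariance at a small time lag,
the quantity the model-fitting stage matches).

Panels and coupling matrices round-trip through plain TSV matrices with a
JSON sidecar holding the metadata, so cohorts can be inspected with any
spreadsheet tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SignalPanel", "CouplingMatrix", "LaggedCovariance"]


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {arr.shape}")
    return arr


@dataclass
class SignalPanel:
    """A parcellated multivariate time series.

    Parameters
    ----------
    values
        Array of shape ``(n_regions, n_samples)``; one row per region.
    tr
        Sampling interval (repetition time) in seconds.
    region_ids
        Ordered region labels; defaults to ``R000 .. R{N-1}``.
    subject_id, state_label
        Free-form identifiers carried through the pipeline (e.g. the
        consciousness state: CNT/MCS/UWS or W/N3).
    """

    values: np.ndarray
    tr: float
    region_ids: list[str] = field(default_factory=list)
    subject_id: str = ""
    state_label: str = ""

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "values")
        n, t = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if not np.isfinite(self.values).all():
            raise ValueError("panel contains non-finite values")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if not self.region_ids:
            self.region_ids = [f"R{i:03d}" for i in range(n)]
        if len(self.region_ids) != n:
            raise ValueError(
                f"{len(self.region_ids)} region labels for {n} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "SignalPanel":
        """Copy of this panel with new sample values, same metadata."""
        return SignalPanel(
            values=values,
            tr=self.tr,
            region_ids=list(self.region_ids),
            subject_id=self.subject_id,
            state_label=self.state_label,
        )

    # ---- serialization -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write values as TSV plus a ``.json`` metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t")
        sidecar = {
            "tr": self.tr,
            "subject_id": self.subject_id,
            "state_label": self.state_label,
            "region_ids": self.region_ids,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalPanel":
        path = Path(path)
        values = np.loadtxt(path, delimiter="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values=values, **meta)


@dataclass
class CouplingMatrix:
    """Directed, nonnegative coupling weights under a symmetric mask.

    Entry ``weights[i, j]`` is the influence of source region ``i`` on
    target region ``j``.  The mask is the undirected structural scaffold:
    weights may only be nonzero where the mask is true, but the two
    directions of a masked pair are free to differ — that difference is
    the asymmetry the downstream metrics quantify.
    """

    weights: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.weights = _as_2d_float(self.weights, "weights")
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError(f"weights must be square, got {self.weights.shape}")
        if self.mask.shape != (n, n):
            raise ValueError("mask shape does not match weights")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("mask diagonal must be zero")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(self.weights[~self.mask] != 0):
            raise ValueError("weights must be zero off-mask")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray) -> "CouplingMatrix":
        return CouplingMatrix(weights=weights, mask=self.mask.copy())

    def to_tsv(self, path: str | Path, **extra_meta) -> None:
        path = Path(path)
        np.savetxt(path, self.weights, delimiter="\t")
        sidecar = {"mask": self.mask.astype(int).tolist(), **extra_meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CouplingMatrix":
        path = Path(path)
        weights = np.loadtxt(path, delimiter="\t")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(weights=weights, mask=np.asarray(meta["mask"], dtype=bool))


@dataclass
class LaggedCovariance:
    """Zero-lag correlation and lagged covariance of a panel.

    ``corr0`` is the ordinary Pearson correlation matrix.  ``cov_lag[i, j]``
    is the covariance of region ``i`` at time ``t`` with region ``j`` at
    ``t + lag``, computed on z-scored signals, so its entries are lagged
    correlations; it is generally asymmetric, and that asymmetry encodes
    the directed flow the model fitting recovers.
    """

    corr0: np.ndarray
    cov_lag: np.ndarray
    lag_samples: int

    def __post_init__(self) -> None:
        self.corr0 = _as_2d_float(self.corr0, "corr0")
        self.cov_lag = _as_2d_float(self.cov_lag, "cov_lag")
        if self.corr0.shape != self.cov_lag.shape:
            raise ValueError("corr0 and cov_lag shapes differ")
        if int(self.lag_samples) < 1:
            raise ValueError(f"lag_samples must be >= 1, got {self.lag_samples}")
        self.lag_samples = int(self.lag_samples)

    @property
    def n_regions(self) -> int:
        return self.corr0.shape[0]
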