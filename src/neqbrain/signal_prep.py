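"""Band-pass filtering, intrinsic-frequency estimation, lagged covariances.

These are the shared preprocessing steps applied to every panel before
model fitting: restrict the signal to the slow oscillatory band
(0.04-0.07 Hz by default), estimate each region's intrinsic angular
frequency from the spectral peak in that band, and summarize the panel by
its zero-lag correlation plus one-lag covariance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import LaggedCovariance, SignalPanel

__all__ = [
    "BandSpec",
    "bandpass_filter",
    "estimate_peak_frequencies",
    "lagged_covariance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification in Hz.

    ``filter_order`` is the Butterworth order per pass; filtering is
    applied forward and backward (zero phase), doubling the effective
    order.
    """

    f_low: float = 0.04
    f_high: float = 0.07
    filter_order: int = 2

    def validate_for(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if not (0.0 < self.f_low < self.f_high < nyquist):
            raise ValueError(
                f"band [{self.f_low}, {self.f_high}] Hz infeasible at "
                f"tr={tr} s (Nyquist {nyquist:.4g} Hz)"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.f_low + self.f_high)


def _design_sos(band: BandSpec, tr: float) -> np.ndarray:
    return sps.butter(
        band.filter_order,
        [band.f_low, band.f_high],
        btype="bandpass",
        fs=1.0 / tr,
        output="sos",
    )


def min_samples_for(band: BandSpec, tr: float) -> int:
    """Minimum panel length for stable zero-phase filtering.

    The forward-backward pass pads by three times the effective filter
    length; we require the series to be strictly longer than that pad.
    """
    sos = _design_sos(band, tr)
    return 3 * (2 * sos.shape[0] + 1)


def bandpass_filter(panel: SignalPanel, band: BandSpec) -> SignalPanel:
    """Zero-phase band-pass filter each region; output is demeaned.

    Constant (zero-variance) regions pass through as ~0 signals and are
    reported in the log rather than raised, since the DC component lies
    outside any valid band.
    """
    band.validate_for(panel.tr)
    t_min = min_samples_for(band, panel.tr)
    if panel.n_samples <= t_min:
        raise ValueError(
            f"panel has {panel.n_samples} samples; band {band} at "
            f"tr={panel.tr} needs more than {t_min}"
        )
    sos = _design_sos(band, panel.tr)
    demeaned = panel.values - panel.values.mean(axis=1, keepdims=True)
    const = np.ptp(panel.values, axis=1) == 0
    if const.any():
        log.warning(
            "constant regions %s pass the band-pass as ~0 signals",
            [panel.region_ids[i] for i in np.flatnonzero(const)],
        )
    filtered = sps.sosfiltfilt(sos, demeaned, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return panel.with_values(filtered)


def bandpass_gain(band: BandSpec, tr: float, freq_hz: float) -> float:
    """Amplitude gain of the (two-pass) filter at ``freq_hz``."""
    sos = _design_sos(band, tr)
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=1.0 / tr)
    return float(np.abs(h[0]) ** 2)  # forward and backward pass


def estimate_peak_frequencies(
    panels: list[SignalPanel], band: BandSpec
) -> np.ndarray:
    """Per-region intrinsic angular frequency, averaged across panels.

    For each panel and region the periodogram peak inside the band is
    located; peak frequencies are averaged across panels per region and
    returned as angular frequencies ``2*pi*f`` (rad/s).  Regions with a
    flat in-band spectrum fall back to the band midpoint.
    """
    if not panels:
        raise ValueError("need at least one panel")
    n = panels[0].n_regions
    tr = panels[0].tr
    for p in panels:
        if p.n_regions != n or p.tr != tr:
            raise ValueError("all panels must share n_regions and tr")
    band.validate_for(tr)

    peaks = np.zeros((len(panels), n))
    for k, p in enumerate(panels):
        freqs, power = sps.periodogram(
            p.values, fs=1.0 / tr, detrend="constant", axis=1
        )
        in_band = (freqs >= band.f_low) & (freqs <= band.f_high)
        if not in_band.any():
            raise ValueError("frequency grid has no point inside the band")
        fb = freqs[in_band]
        pb = power[:, in_band]
        idx = np.argmax(pb, axis=1)
        flat = np.ptp(pb, axis=1) <= 0
        if flat.any():
            log.warning(
                "flat in-band spectrum for regions %s; using band midpoint",
                np.flatnonzero(flat).tolist(),
            )
        peaks[k] = np.where(flat, band.midpoint, fb[idx])
    return 2.0 * np.pi * peaks.mean(axis=0)


def lagged_covariance(panel: SignalPanel, lag_samples: int = 1) -> LaggedCovariance:
    """Zero-lag correlation and lag-``lag_samples`` covariance of a panel.

    Signals are z-scored per region first, so ``cov_lag`` entries are
    lagged correlations on the same scale as ``corr0``; only the
    ``T - lag`` overlapping samples contribute to each lagged entry.
    """
    t = panel.n_samples
    lag = int(lag_samples)
    if not 1 <= lag < t / 2:
        raise ValueError(f"lag_samples must satisfy 1 <= lag < T/2, got {lag}")
    sd = panel.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [panel.region_ids[i] for i in dead]
        raise ValueError(f"zero-variance regions: {names}")
    z = (panel.values - panel.values.mean(axis=1, keepdims=True)) / sd[:, None]
    corr0 = np.corrcoef(panel.values)
    cov_lag = z[:, : t - lag] @ z[:, lag:].T / (t - lag)
    return LaggedCovariance(corr0=corr0, cov_lag=cov_lag, lag_samples=lag)
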