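"""Aperiodic (1/f^chi) parameterization of EEG power spectra.

The aperiodic component of a neural power spectrum follows
``P(f) = 10**offset / f**chi``: in log-log coordinates a straight line with
slope ``-chi`` (the exponent) and intercept ``offset`` at log10 f = 0
(i.e. 1 Hz).  Estimation is a robust iterative regression: ordinary least
squares in log-log space, then oscillatory peaks — points with large
*positive* residuals — are excluded and the line refit until the excluded
set stabilizes.  Spectra come from Welch's method on the broadband
(re-referenced, otherwise unfiltered) epochs; parameters are fit per
channel and epoch so their distributions feed the group statistics, then
averaged globally and per scalp region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EpochSet
from .montage import REGIONS, Montage

DEFAULT_FIT_RANGE: tuple[float, float] = (1.0, 40.0)


@dataclass(frozen=True)
class Spectrum:
    """A one-sided power spectral density (uV^2/Hz) on a frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.ndim != 1 or p.shape[-1] != f.size:
            raise ValueError("power's last axis must match freqs")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(p)):
            raise ValueError("power must be finite")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class AperiodicFit:
    """Fitted 1/f^chi parameters: offset (log10 power at 1 Hz), exponent
    chi >= 0 typically, and the RMSE of the retained points in log10 space."""

    offset: float
    exponent: float
    fit_error: float
    fit_range: tuple[float, float]


def welch_psd(
    series: np.ndarray,
    fs: float,
    window_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
) -> Spectrum:
    """Welch average modified periodogram (Hamming window), one-sided
    density.  With the 2-s window and 50% overlap, an 8-s epoch yields 7
    averaged segments at 0.5 Hz resolution.  Works on the last axis of any
    shape."""
    series = np.asarray(series, dtype=float)
    nper = int(round(window_seconds * fs))
    if nper > series.shape[-1]:
        raise ValueError("window longer than series")
    freqs, power = signal.welch(
        series,
        fs=fs,
        window="hamming",
        nperseg=nper,
        noverlap=int(round(nper * overlap_fraction)),
        detrend="constant",
        axis=-1,
    )
    return Spectrum(freqs=freqs, power=power)


def fit_aperiodic(
    spectrum: Spectrum,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    peak_threshold: float = 2.5,
    max_iter: int = 10,
) -> AperiodicFit:
    """Robust log-log line fit with iterative oscillatory-peak exclusion.

    1. OLS of log10 P on log10 f over ``fit_range``;
    2. exclude points whose residual exceeds ``peak_threshold`` times the
       residual SD — positive residuals only, i.e. peaks;
    3. refit; iterate until the excluded set stops changing (<= ``max_iter``
       rounds).

    Raises on non-positive power in range, fewer than 10 points in range,
    or fewer than 5 points surviving exclusion.
    """
    if spectrum.power.ndim != 1:
        raise ValueError("fit_aperiodic expects a single spectrum")
    lo, hi = fit_range
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if sel.sum() < 10:
        raise ValueError(f"fewer than 10 frequency points in {fit_range}")
    f = spectrum.freqs[sel]
    p = spectrum.power[sel]
    if np.any(p <= 0):
        raise ValueError("non-positive power inside the fit range")
    x = np.log10(f)
    y = np.log10(p)

    keep = np.ones(x.size, dtype=bool)
    slope = intercept = 0.0
    for _ in range(max_iter):
        slope, intercept = np.polyfit(x[keep], y[keep], 1)
        resid = y - (intercept + slope * x)
        sd = resid[keep].std()
        new_keep = resid <= peak_threshold * max(sd, 1e-15)
        if new_keep.sum() < 5:
            raise ValueError("degenerate fit: fewer than 5 points after exclusion")
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    resid = y[keep] - (intercept + slope * x[keep])
    return AperiodicFit(
        offset=float(intercept),
        exponent=float(-slope),
        fit_error=float(np.sqrt(np.mean(resid**2))),
        fit_range=(float(lo), float(hi)),
    )


@dataclass
class AperiodicResult:
    """Per-epoch, per-channel aperiodic fits for one recording."""

    offset: np.ndarray  # (epoch, channel)
    exponent: np.ndarray
    fit_error: np.ndarray
    channel_labels: tuple[str, ...]
    fit_range: tuple[float, float]

    def parameter(self, name: str) -> np.ndarray:
        if name not in ("offset", "exponent"):
            raise ValueError(f"unknown aperiodic parameter {name!r}")
        return getattr(self, name)


def aperiodic_per_epoch(
    epochs: EpochSet,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    window_seconds: float = 2.0,
    overlap_fraction: float = 0.5,
) -> AperiodicResult:
    """Welch spectrum then robust aperiodic fit, per channel and epoch.

    The input should be the broadband re-referenced epochs, not a band
    output."""
    spec = welch_psd(epochs.data, epochs.fs, window_seconds, overlap_fraction)
    n_ep, n_ch = epochs.n_epochs, epochs.n_channels
    off = np.empty((n_ep, n_ch))
    expo = np.empty((n_ep, n_ch))
    err = np.empty((n_ep, n_ch))
    for e in range(n_ep):
        for c in range(n_ch):
            fit = fit_aperiodic(
                Spectrum(spec.freqs, spec.power[e, c]), fit_range=fit_range
            )
            off[e, c] = fit.offset
            expo[e, c] = fit.exponent
            err[e, c] = fit.fit_error
    return AperiodicResult(
        offset=off,
        exponent=expo,
        fit_error=err,
        channel_labels=epochs.channel_labels,
        fit_range=fit_range,
    )


def aggregate_aperiodic(
    result: AperiodicResult, montage: Montage, parameter: str
) -> tuple[np.ndarray, dict[str, np.ndarray | None]]:
    """Global (mean over channels) and per-region per-epoch series for one
    parameter.  Regions with no channel present map to ``None``."""
    values = result.parameter(parameter)
    global_series = values.mean(axis=1)
    idx = {lab: i for i, lab in enumerate(result.channel_labels)}
    regional: dict[str, np.ndarray | None] = {}
    for region in REGIONS:
        members = [idx[l] for l in montage.channels_in(region) if l in idx]
        regional[region] = values[:, members].mean(axis=1) if members else None
    return global_series, regional
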