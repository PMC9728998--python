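"""Common-average referencing and the five-band frequency-domain filter bank.

The processing order is fixed: epochs are first re-referenced to the common
average of all scalp channels, then decomposed into the five canonical
rhythms (delta 0.5-3, theta 3-8, alpha 8-12, beta 12-30, gamma 30-50 Hz).
Filters are applied in the frequency domain as a real (zero-phase) magnitude
response: unity in the passband, zero beyond the transition bands, with a
raised-cosine taper across each transition.  Transition widths are
band-specific: 1/2 Hz (low/high) for delta, 2/3 for theta, 3/4 for alpha,
4/5 for beta and 3/3 for gamma.  The delta low-side taper would extend below
0 Hz; it is truncated there and the DC bin is always zeroed (epochs are
demeaned per channel before filtering anyway).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EpochSet

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    passband: tuple[float, float]
    transition_low: float
    transition_high: float

    def __post_init__(self) -> None:
        low, high = self.passband
        if not 0 < low < high:
            raise ValueError(f"invalid passband {self.passband} for {self.name}")
        if self.transition_low <= 0 or self.transition_high <= 0:
            raise ValueError("transition widths must be positive")


CANONICAL_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", (0.5, 3.0), 1.0, 2.0),
    "theta": BandDefinition("theta", (3.0, 8.0), 2.0, 3.0),
    "alpha": BandDefinition("alpha", (8.0, 12.0), 3.0, 4.0),
    "beta": BandDefinition("beta", (12.0, 30.0), 4.0, 5.0),
    "gamma": BandDefinition("gamma", (30.0, 50.0), 3.0, 3.0),
}


def common_average_reference(epochs: EpochSet, allow_partial: bool = False) -> EpochSet:
    """Re-reference every sample to the mean over all scalp channels.

    After referencing, the channel mean at each sample of each epoch is zero
    (idempotent).  Auxiliary polygraphy channels are untouched.  By default
    a full 61-channel montage is required; pass ``allow_partial=True`` to
    reference whatever channels are present.
    """
    if epochs.n_channels != 61 and not allow_partial:
        raise ValueError(
            f"common average expects the 61-channel montage, got "
            f"{epochs.n_channels} channels (allow_partial=True to override)"
        )
    return epochs.with_data(epochs.data - epochs.data.mean(axis=1, keepdims=True))


def band_filter_response(
    band: BandDefinition, n_samples: int, fs: float
) -> np.ndarray:
    """Real magnitude response of ``band`` on the length-``n_samples`` rFFT grid.

    Unity over the passband, raised-cosine over each transition band, zero
    elsewhere; DC is always zero.  The same response applies to negative
    frequencies by conjugate symmetry of the real FFT.
    """
    low, high = band.passband
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"{band.name} passband reaches Nyquist ({nyq} Hz)")
    if high + band.transition_high > nyq:
        raise ValueError(
            f"{band.name} upper transition ({high}+{band.transition_high} Hz) "
            f"exceeds Nyquist ({nyq} Hz)"
        )
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    resp = np.zeros_like(freqs)
    lo_edge = max(low - band.transition_low, 0.0)
    hi_edge = high + band.transition_high

    resp[(freqs >= low) & (freqs <= high)] = 1.0
    rising = (freqs > lo_edge) & (freqs < low)
    if low > lo_edge:
        resp[rising] = 0.5 * (
            1 - np.cos(np.pi * (freqs[rising] - (low - band.transition_low))
                       / band.transition_low)
        )
    falling = (freqs > high) & (freqs < hi_edge)
    resp[falling] = 0.5 * (
        1 + np.cos(np.pi * (freqs[falling] - high) / band.transition_high)
    )
    resp[0] = 0.0
    return resp


def apply_band_filter(epochs: EpochSet, band: BandDefinition) -> EpochSet:
    """Zero-phase bandpass: demean each epoch/channel, multiply its spectrum
    by the band's real magnitude response, transform back.

    Epochs are filtered independently (they are non-contiguous selections
    from the recording), and output length equals input length.
    """
    x = epochs.data
    if not np.all(np.isfinite(x)):
        raise ValueError("epochs contain non-finite samples")
    resp = band_filter_response(band, epochs.n_samples, epochs.fs)
    spec = np.fft.rfft(x - x.mean(axis=-1, keepdims=True), axis=-1)
    out = np.fft.irfft(spec * resp, n=epochs.n_samples, axis=-1)
    return epochs.with_data(out)


def extract_band_stack(
    epochs: EpochSet,
    bands: dict[str, BandDefinition] | None = None,
    allow_partial: bool = False,
) -> dict[str, EpochSet]:
    """Common-average reference, then every canonical band filter.

    Returns ``{band name -> EpochSet}`` in canonical band order; each output
    has the same shape as the input.
    """
    bands = bands if bands is not None else CANONICAL_BANDS
    ref = common_average_reference(epochs, allow_partial=allow_partial)
    return {name: apply_band_filter(ref, bd) for name, bd in bands.items()}
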