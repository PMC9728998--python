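"""Synthetic resting-EEG cohorts with known connectivity and spectral truth.

The study design this package analyses — 61-channel, 1024-Hz resting EEG,
20 artifact-free 8-s epochs per session, recorded before and one year after
VNS implantation — is emulated here with fully known ground truth:

* a 1/f^chi aperiodic background per channel, synthesized by inverse
  spectral shaping (amplitude spectrum = square root of the target power
  law, independently randomized phases), so the target offset/exponent are
  exact in expectation;
* band-limited oscillations whose instantaneous phase difference across a
  channel pair follows a von Mises law with a chosen mean lag and
  concentration, giving a closed numerical oracle (:func:`expected_pli`)
  for the phase lag index the analysis should measure;
* zero-lag "volume conduction" mixing, which changes spectra but must not
  create PLI;
* a clinical cohort layer that draws monthly seizure rates, applies per-group
  seizure reductions (responders >= 50%), and injects the group-signed
  pre-to-post shifts in PLI and aperiodic parameters, with the aperiodic
  shift optionally coupled linearly to each subject's Labar index so that
  outcome correlation is recoverable.

All generators take explicit seeds (or numpy Generators); there is no
global random state.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import integrate, optimize, special

from .io import EpochSet
from .montage import DEFAULT_61_LABELS
from .preprocess import BAND_ORDER, CANONICAL_BANDS

__all__ = [
    "AperiodicSpec",
    "CouplingSpec",
    "DiffuseCoupling",
    "SimulationConfig",
    "CohortSpec",
    "SimulatedSubject",
    "band_center",
    "expected_pli",
    "generate_aperiodic_background",
    "generate_coupled_phase_pair",
    "generate_coupled_oscillation",
    "mix_volume_conduction",
    "generate_epoch_set",
    "generate_cohort",
    "balanced_labels",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def band_center(band: str) -> float:
    """Carrier frequency used for a band's oscillation (passband midpoint,
    e.g. 10 Hz for alpha)."""
    low, high = CANONICAL_BANDS[band].passband
    return 0.5 * (low + high)


# --------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class AperiodicSpec:
    """Target 1/f^chi background: ``power(f) = 10**offset / f**exponent``
    (one-sided density, uV^2/Hz; offset is log10 power at 1 Hz)."""

    offset: float
    exponent: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.offset):
            raise ValueError("offset must be finite")
        if not (math.isfinite(self.exponent) and self.exponent >= 0):
            raise ValueError("exponent must be finite and >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """A phase-coupled channel pair in one band.

    The instantaneous phase difference (first minus second channel) is
    von Mises with mean ``lag_delta`` and concentration ``jitter_kappa``
    (kappa = 0 means a uniform phase difference; a nonzero lag is required
    for the expected PLI to be positive)."""

    channel_pair: tuple[str, str]
    band: str
    lag_delta: float
    jitter_kappa: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.band not in CANONICAL_BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if not (-math.pi < self.lag_delta <= math.pi):
            raise ValueError("lag_delta must lie in (-pi, pi]")
        if self.jitter_kappa < 0:
            raise ValueError("jitter_kappa must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class DiffuseCoupling:
    """Scalp-wide coupling in one band: every channel carries the band's
    common oscillation at a fixed channel-specific lag.

    ``snr`` is the oscillation RMS relative to the channel's aperiodic
    background RMS within the band's passband, and is the knob that sets
    the measured PLI level: the band-limited background acts as phase noise
    on the coupled carrier, approximately von Mises with concentration
    ``snr**2`` on each pair's phase difference.  ``kappa``, if given, adds
    an extra per-channel, per-epoch constant von Mises lag jitter
    (session-to-session variability; it does not affect within-epoch PLI).
    ``lag_offsets`` fixes the per-channel lags (radians), otherwise they
    are drawn uniformly in ``(-lag_spread/2, lag_spread/2)``.
    """

    band: str
    snr: float = 2.0
    kappa: float | None = None
    lag_spread: float = math.pi
    lag_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.band not in CANONICAL_BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """One subject-session recording: epochs x channels x samples."""

    n_channels: int = 61
    fs: float = 1024.0
    epoch_seconds: float = 8.0
    n_epochs: int = 20
    aperiodic: AperiodicSpec | tuple[AperiodicSpec, ...] = AperiodicSpec(1.4, 2.0)
    couplings: tuple[CouplingSpec, ...] = ()
    diffuse: tuple[DiffuseCoupling, ...] = ()
    leakage: float = 0.0
    seed: int = 0
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n_samp = self.epoch_seconds * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_seconds * fs must be an integer sample count")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must lie in [0, 1)")
        labels = self.resolve_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels")
        if isinstance(self.aperiodic, tuple) and len(self.aperiodic) != self.n_channels:
            raise ValueError("need one AperiodicSpec per channel")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.fs))

    def resolve_labels(self) -> tuple[str, ...]:
        if self.channel_labels is not None:
            if len(self.channel_labels) != self.n_channels:
                raise ValueError("channel_labels length != n_channels")
            return tuple(self.channel_labels)
        if self.n_channels <= len(DEFAULT_61_LABELS):
            return DEFAULT_61_LABELS[: self.n_channels]
        return tuple(f"ch{i}" for i in range(self.n_channels))

    def channel_specs(self) -> tuple[AperiodicSpec, ...]:
        if isinstance(self.aperiodic, AperiodicSpec):
            return (self.aperiodic,) * self.n_channels
        return tuple(self.aperiodic)


# --------------------------------------------------------------------------
# PLI oracle


def expected_pli(lag_delta: float, jitter_kappa: float) -> float:
    """Expected PLI of a pair whose phase difference is
    von Mises(``lag_delta``, ``jitter_kappa``).

    Returns ``|P(dphi in (0, pi)) - P(dphi in (-pi, 0))|`` by numeric
    integration of the wrapped density.  kappa = 0 (uniform) or a zero lag
    both give 0.
    """
    if jitter_kappa < 0:
        raise ValueError("jitter_kappa must be >= 0")
    if jitter_kappa == 0 or lag_delta in (0.0, math.pi, -math.pi):
        # uniform difference, or a density symmetric about 0 (mod 2*pi)
        return 0.0

    norm = 2.0 * math.pi * special.i0e(jitter_kappa)

    def dens(x: float) -> float:
        # i0e-scaled to stay finite at large kappa
        return math.exp(jitter_kappa * (math.cos(x - lag_delta) - 1.0)) / norm

    p_pos, _ = integrate.quad(dens, 0.0, math.pi, limit=200)
    p_neg, _ = integrate.quad(dens, -math.pi, 0.0, limit=200)
    return abs(p_pos - p_neg)


def expected_global_pli(kappa: float, lag_spread: float = math.pi) -> float:
    """Expected mean pair PLI under the diffuse coupling model.

    Channel lags are uniform on ``(-lag_spread/2, lag_spread/2)``, so a
    pair's mean lag is triangular on ``(-lag_spread, lag_spread)``; the
    pair's phase difference scatters around it with effective von Mises
    concentration ``kappa``.  Averages :func:`expected_pli` over the
    triangular lag density by numeric integration.
    """
    s = lag_spread

    def integrand(d: float) -> float:
        tri = (s - abs(d)) / s**2  # triangular density on (-s, s)
        return tri * expected_pli(d, kappa)

    val, _ = integrate.quad(integrand, -s, s, limit=100)
    return val


# --------------------------------------------------------------------------
# Signal generators


def generate_aperiodic_background(
    spec: AperiodicSpec,
    fs: float,
    n_samples: int,
    seed: int | np.random.Generator,
    synth_band: tuple[float, float] = (0.5, 70.0),
) -> np.ndarray:
    """One channel of 1/f^chi background by inverse spectral shaping.

    The one-sided power density over the synthesis band (default 0.5-70 Hz,
    mirroring the acquisition bandpass) is exactly
    ``10**offset / f**exponent``; phases are independently uniform, so the
    series is a stationary Gaussian-like surrogate with exact spectral
    control and zero mean.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    lo = max(synth_band[0], freqs[1] * 0.999)
    hi = min(synth_band[1], fs / 2.0)
    sel = (freqs >= lo) & (freqs <= hi)
    target = np.zeros_like(freqs)
    target[sel] = 10.0 ** spec.offset / freqs[sel] ** spec.exponent
    amp = np.sqrt(target * fs * n_samples / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    z = amp * np.exp(1j * phases)
    z[0] = 0.0
    if n_samples % 2 == 0:
        z[-1] = z[-1].real  # Nyquist bin must be real
    return np.fft.irfft(z, n=n_samples)


def generate_coupled_phase_pair(
    coupling: CouplingSpec,
    fs: float,
    n_samples: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase series of the two coupled channels.

    The difference ``phi1 - phi2`` is i.i.d. von Mises(``lag_delta``,
    ``jitter_kappa``) across samples (kappa >= 1e4 is treated as a constant
    lag), riding on a common carrier at the band's center frequency.
    """
    rng = _rng(seed)
    t = np.arange(n_samples) / fs
    carrier = 2.0 * np.pi * band_center(coupling.band) * t
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    phi1 = carrier + phi0
    if coupling.jitter_kappa >= 1e4:
        jitter = np.zeros(n_samples)
    else:
        jitter = rng.vonmises(0.0, coupling.jitter_kappa, size=n_samples)
    phi2 = phi1 - coupling.lag_delta - jitter
    return phi1, phi2


def generate_coupled_oscillation(
    coupling: CouplingSpec,
    fs: float,
    n_samples: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two band-limited series whose phase difference follows the coupling's
    von Mises law (cosines of :func:`generate_coupled_phase_pair`)."""
    phi1, phi2 = generate_coupled_phase_pair(coupling, fs, n_samples, seed)
    return coupling.amplitude * np.cos(phi1), coupling.amplitude * np.cos(phi2)


def mix_volume_conduction(epochs: EpochSet, leakage: float) -> EpochSet:
    """Zero-lag convex mixing of each channel with the mean of the others.

    Emulates instantaneous volume conduction: spectra change, but no phase
    lag is introduced, so PLI between independent sources must stay ~0.
    """
    if not 0 <= leakage < 1:
        raise ValueError("leakage must lie in [0, 1)")
    if leakage == 0:
        return epochs
    x = epochs.data
    n_ch = x.shape[1]
    total = x.sum(axis=1, keepdims=True)
    others_mean = (total - x) / (n_ch - 1)
    return epochs.with_data((1.0 - leakage) * x + leakage * others_mean)


def _band_rms(spec: AperiodicSpec, band: str) -> float:
    """RMS of the aperiodic background restricted to a band's passband
    (analytic integral of the power law)."""
    low, high = CANONICAL_BANDS[band].passband
    a = 10.0 ** spec.offset
    e = spec.exponent
    if abs(e - 1.0) < 1e-12:
        power = a * math.log(high / low)
    else:
        power = a * (high ** (1 - e) - low ** (1 - e)) / (1 - e)
    return math.sqrt(max(power, 1e-300))


def generate_epoch_set(config: SimulationConfig) -> EpochSet:
    """Simulate one recording session.

    Per epoch and channel: aperiodic background, plus any pairwise
    couplings, plus any diffuse band couplings; finally zero-lag leakage
    mixing.  Deterministic under a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.resolve_labels()
    specs = config.channel_specs()
    n_ep, n_ch, n_s = config.n_epochs, config.n_channels, config.n_samples
    fs = config.fs
    label_idx = {lab: i for i, lab in enumerate(labels)}

    # per-set fixed structure: diffuse lag offsets and amplitudes
    diffuse_lags: list[np.ndarray] = []
    diffuse_amps: list[np.ndarray] = []
    for dc in config.diffuse:
        if dc.lag_offsets is not None:
            lags = np.asarray(dc.lag_offsets, dtype=float)
            if lags.size != n_ch:
                raise ValueError("lag_offsets length != n_channels")
        else:
            lags = rng.uniform(-dc.lag_spread / 2, dc.lag_spread / 2, n_ch)
        diffuse_lags.append(lags)
        amps = np.array(
            [math.sqrt(2.0) * dc.snr * _band_rms(s, dc.band) for s in specs]
        )
        diffuse_amps.append(amps)

    t = np.arange(n_s) / fs
    data = np.empty((n_ep, n_ch, n_s))
    for e in range(n_ep):
        for c in range(n_ch):
            data[e, c] = generate_aperiodic_background(specs[c], fs, n_s, rng)
        for dc, lags, amps in zip(config.diffuse, diffuse_lags, diffuse_amps):
            carrier = 2.0 * np.pi * band_center(dc.band) * t + rng.uniform(
                0.0, 2.0 * np.pi
            )
            for c in range(n_ch):
                phase_lag = lags[c]
                if dc.kappa is not None and dc.kappa < 1e4:
                    # constant within the epoch: session variability only
                    phase_lag += rng.vonmises(0.0, dc.kappa)
                data[e, c] += amps[c] * np.cos(carrier + phase_lag)
        for cs in config.couplings:
            i = label_idx[cs.channel_pair[0]]
            j = label_idx[cs.channel_pair[1]]
            x1, x2 = generate_coupled_oscillation(cs, fs, n_s, rng)
            data[e, i] += x1
            data[e, j] += x2

    out = EpochSet(data=data, fs=fs, channel_labels=labels)
    return mix_volume_conduction(out, config.leakage)


# --------------------------------------------------------------------------
# Cohort layer


#: Pre-implantation global PLI levels the generator aims for, per band
#: (responder pre-implantation means where reported; interpolated for
#: theta/beta, which showed no effect).
DEFAULT_PLI_BASELINE: Mapping[str, float] = {
    "delta": 0.18,
    "theta": 0.16,
    "alpha": 0.15,
    "beta": 0.12,
    "gamma": 0.08,
}

#: Group-signed pre-to-post target changes: responders lose delta/gamma PLI,
#: gain alpha, and both aperiodic parameters drop; non-responders show no
#: PLI change but offset/exponent rise.
DEFAULT_FEATURE_SHIFT: Mapping[str, Mapping[str, float]] = {
    "R": {
        "pli_delta": -0.01,
        "pli_alpha": +0.03,
        "pli_gamma": -0.01,
        "offset": -0.1,
        "exponent": -0.1,
    },
    "NR": {"offset": +0.2, "exponent": +0.2},
}

DEFAULT_BASELINE: Mapping[str, Mapping[str, float]] = {
    "R": {"offset": 1.4, "exponent": 2.0},
    "NR": {"offset": 1.7, "exponent": 2.2},
}


@dataclass(frozen=True)
class CohortSpec:
    """A pre/post VNS cohort with known seizure outcomes and feature shifts.

    Seizure rates are log-normal; responders draw a seizure reduction in
    ``responder_reduction_range`` (Labar index = 100 x reduction >= 50),
    non-responders in ``nonresponder_reduction_range`` (< 50).  Aperiodic
    pre-to-post shifts are, when ``outcome_coupling`` is on, linear in the
    subject's Labar index and anchored so the two group means equal the
    per-group ``feature_shift`` values — giving both the group-signed
    effects and a negative variation-vs-Labar correlation.
    """

    n_responders: int = 5
    n_nonresponders: int = 5
    pre_rate_lognormal: tuple[float, float] = (1.5, 1.2)  # mean, sd of log rate
    responder_reduction_range: tuple[float, float] = (0.5, 1.0)
    nonresponder_reduction_range: tuple[float, float] = (-0.3, 0.5)
    feature_shift: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_FEATURE_SHIFT.items()}
    )
    baseline: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_BASELINE.items()}
    )
    pli_baseline: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLI_BASELINE)
    )
    between_subject_sd: Mapping[str, float] = field(
        default_factory=lambda: {"offset": 0.35, "exponent": 0.2}
    )
    channel_sd: float = 0.1
    shift_noise_sd: float = 0.05
    outcome_coupling: bool = True
    n_channels: int = 61
    fs: float = 1024.0
    epoch_seconds: float = 8.0
    n_epochs: int = 20
    leakage: float = 0.2
    channel_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("both groups need at least one subject")
        lo, hi = self.responder_reduction_range
        if lo < 0.5:
            raise ValueError("responder reductions must be >= 0.5 (Labar >= 50)")
        if self.nonresponder_reduction_range[1] > 0.5:
            raise ValueError("non-responder reductions must stay < 0.5")


@dataclass
class SimulatedSubject:
    """One simulated patient: seizure diary plus paired recordings."""

    subject_id: str
    group: str  # "R" or "NR"
    pre_rate: float
    post_rate: float
    labar: float
    epochs_pre: EpochSet
    epochs_post: EpochSet
    truth: dict = field(default_factory=dict)


@functools.lru_cache(maxsize=256)
def _snr_for_pli(target: float, lag_spread: float = math.pi) -> float:
    """Oscillation-to-background SNR whose expected global PLI is ``target``
    under the diffuse model (effective pair concentration kappa = snr**2,
    inverted through the numeric oracle).  The mapping is approximate —
    background phase noise is narrowband, not i.i.d. — but monotone, which
    is what the group comparisons rely on."""
    target = min(max(target, 1e-3), 0.99)

    def f(log_k: float) -> float:
        return expected_global_pli(math.exp(log_k), lag_spread) - target

    log_k = optimize.brentq(f, math.log(1e-4), math.log(1e4))
    return math.sqrt(math.exp(log_k))


def balanced_labels(n_per_region: int) -> tuple[str, ...]:
    """A reduced montage with ``n_per_region`` channels in each of the five
    regions, for desk-scale simulations (e.g. 2 -> F3,F4,T7,T8,C3,C4,P3,P4,
    O1,O2)."""
    order = {
        "frontal": ["F3", "F4", "Fz", "F7", "F8", "Fp1", "Fp2"],
        "temporal": ["T7", "T8", "FT7", "FT8", "TP7", "TP8"],
        "central": ["C3", "C4", "Cz", "FC3", "FC4", "C5"],
        "parietal": ["P3", "P4", "Pz", "CP3", "CP4", "P7"],
        "occipital": ["O1", "O2", "Oz", "PO3", "PO4", "PO7"],
    }
    if n_per_region > 6:
        raise ValueError("at most 6 channels per region in the reduced montage")
    out: list[str] = []
    for region in ("frontal", "temporal", "central", "parietal", "occipital"):
        out.extend(order[region][:n_per_region])
    return tuple(out)


def generate_cohort(spec: CohortSpec) -> list[SimulatedSubject]:
    """Simulate the full cohort: seizure diaries, Labar indices and paired
    pre/post epoch sets carrying the group-signed feature shifts."""
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    groups = ["R"] * spec.n_responders + ["NR"] * spec.n_nonresponders

    # anchor points for the Labar-linear aperiodic shift
    r_mid = 100.0 * np.mean(spec.responder_reduction_range)
    nr_mid = 100.0 * np.mean(spec.nonresponder_reduction_range)

    subjects: list[SimulatedSubject] = []
    for k, group in enumerate(groups):
        sub_seed = root.spawn(1)[0]
        srng = np.random.default_rng(sub_seed)
        mu, sd = spec.pre_rate_lognormal
        pre_rate = float(np.round(srng.lognormal(mu, sd), 2))
        lo, hi = (
            spec.responder_reduction_range
            if group == "R"
            else spec.nonresponder_reduction_range
        )
        reduction = srng.uniform(lo, hi)
        post_rate = float(np.round(pre_rate * (1.0 - reduction), 2))
        labar = -100.0 * (post_rate - pre_rate) / pre_rate

        shifts = dict(spec.feature_shift.get(group, {}))
        ap_shift: dict[str, float] = {}
        for param in ("offset", "exponent"):
            s_r = spec.feature_shift.get("R", {}).get(param, 0.0)
            s_nr = spec.feature_shift.get("NR", {}).get(param, 0.0)
            if spec.outcome_coupling and r_mid != nr_mid:
                base = s_nr + (s_r - s_nr) * (labar - nr_mid) / (r_mid - nr_mid)
            else:
                base = shifts.get(param, 0.0)
            ap_shift[param] = base + srng.normal(0.0, spec.shift_noise_sd)

        # per-channel aperiodic truth (channel deviations shared pre/post)
        base = spec.baseline[group]
        n_ch = spec.n_channels
        subj_offset = base["offset"] + srng.normal(0, spec.between_subject_sd["offset"])
        subj_exponent = max(
            0.2,
            base["exponent"] + srng.normal(0, spec.between_subject_sd["exponent"]),
        )
        ch_dev_off = srng.normal(0, spec.channel_sd, n_ch)
        ch_dev_exp = srng.normal(0, spec.channel_sd, n_ch)
        ap_pre = tuple(
            AperiodicSpec(subj_offset + ch_dev_off[c],
                          max(0.1, subj_exponent + ch_dev_exp[c]))
            for c in range(n_ch)
        )
        ap_post = tuple(
            AperiodicSpec(s.offset + ap_shift["offset"],
                          max(0.1, s.exponent + ap_shift["exponent"]))
            for s in ap_pre
        )

        # diffuse band couplings; lags fixed per subject, snr per session
        lag_sets = {
            b: tuple(srng.uniform(-math.pi / 2, math.pi / 2, n_ch))
            for b in BAND_ORDER
        }
        snr_pre = {b: _snr_for_pli(spec.pli_baseline[b]) for b in BAND_ORDER}
        snr_post = {
            b: _snr_for_pli(spec.pli_baseline[b] + shifts.get(f"pli_{b}", 0.0))
            for b in BAND_ORDER
        }

        def _config(session_seed: int, ap, snrs) -> SimulationConfig:
            return SimulationConfig(
                n_channels=n_ch,
                fs=spec.fs,
                epoch_seconds=spec.epoch_seconds,
                n_epochs=spec.n_epochs,
                aperiodic=ap,
                diffuse=tuple(
                    DiffuseCoupling(band=b, snr=snrs[b], lag_offsets=lag_sets[b])
                    for b in BAND_ORDER
                ),
                leakage=spec.leakage,
                seed=session_seed,
                channel_labels=spec.channel_labels,
            )

        seeds = sub_seed.generate_state(2) % (2**31 - 1)
        pre = generate_epoch_set(_config(int(seeds[0]), ap_pre, snr_pre))
        post = generate_epoch_set(_config(int(seeds[1]), ap_post, snr_post))
        sid = f"S{k + 1:02d}"
        pre = replace(pre, subject_id=sid, session="pre")
        post = replace(post, subject_id=sid, session="post")

        subjects.append(
            SimulatedSubject(
                subject_id=sid,
                group=group,
                pre_rate=pre_rate,
                post_rate=post_rate,
                labar=labar,
                epochs_pre=pre,
                epochs_post=post,
                truth={
                    "aperiodic_pre": ap_pre,
                    "aperiodic_post": ap_post,
                    "aperiodic_shift": ap_shift,
                    "snr_pre": snr_pre,
                    "snr_post": snr_post,
                },
            )
        )
    return subjects
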