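"""Phase lag index (PLI) per channel pair, epoch and band, with global,
regional and channel-level aggregation.

PLI quantifies the asymmetry of the distribution of instantaneous phase
differences between two signals:

    PLI = | mean_t sign( wrap(phi_a(t) - phi_b(t)) ) |

with the difference wrapped to (-pi, pi] and sign(0) = 0, so an exactly
zero (volume-conduction-like) lag contributes nothing.  PLI is 0 for no
consistent lagged coupling and 1 for a perfectly consistent nonzero lag,
and is invariant to channel amplitude scaling.

Aggregation follows the three spatial scales of the analysis: the global
value is the mean over all unordered channel pairs within an epoch, the
regional value averages only within-region pairs, and the channel value
averages all pairs that include the channel of interest.  The per-epoch
distributions are retained — they are the statistical unit downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .io import EpochSet
from .montage import REGIONS, Montage, region_pair_indices


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2.0 * np.pi)


def instantaneous_phase(band_epochs: EpochSet) -> np.ndarray:
    """Analytic-signal phase per epoch/channel/sample, radians in (-pi, pi].

    The input should be narrowband (a band-filter output).  A constant
    (zero-variance) channel has no defined phase and raises.
    """
    x = band_epochs.data
    flat = np.ptp(x, axis=-1) < 1e-300
    if np.any(flat):
        e, c = np.argwhere(flat)[0]
        raise ValueError(
            f"constant channel (epoch {e}, channel "
            f"{band_epochs.channel_labels[c]}): phase undefined"
        )
    return np.angle(hilbert(x, axis=-1))


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI between two phase series."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    if phase_a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.sign(wrap_phase(phase_a - phase_b)))))


def pli_matrix(phases: np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal PLI matrix for one epoch.

    ``phases`` is (channel, sample); a 61-channel epoch yields 1830
    independent pair values mirrored across the diagonal.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise ValueError("phases must be (n_channels >= 2, n_samples)")
    n_ch = phases.shape[0]
    mat = np.zeros((n_ch, n_ch))
    for i in range(n_ch - 1):
        d = wrap_phase(phases[i + 1 :] - phases[i])
        vals = np.abs(np.sign(d).mean(axis=-1))
        mat[i, i + 1 :] = vals
        mat[i + 1 :, i] = vals
    return mat


def pli_matrices(phases: np.ndarray) -> np.ndarray:
    """PLI matrices for a stack of epochs, (epoch, channel, channel)."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 3:
        raise ValueError("phases must be (epoch, channel, sample)")
    return np.stack([pli_matrix(p) for p in phases])


@dataclass
class ConnectivityResult:
    """Per-epoch PLI matrices for one band plus the channel labels that
    index them."""

    band: str
    matrices: np.ndarray  # (epoch, channel, channel)
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrices
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (epoch, channel, channel)")
        if m.shape[1] != len(self.channel_labels):
            raise ValueError("label count mismatch")


def compute_connectivity(band_epochs: EpochSet, band: str) -> ConnectivityResult:
    """Instantaneous phases then pairwise PLI for every epoch of one band."""
    phases = instantaneous_phase(band_epochs)
    return ConnectivityResult(
        band=band,
        matrices=pli_matrices(phases),
        channel_labels=band_epochs.channel_labels,
    )


def _upper_mean(mats: np.ndarray) -> np.ndarray:
    n = mats.shape[1]
    iu = np.triu_indices(n, k=1)
    return mats[:, iu[0], iu[1]].mean(axis=1)


def aggregate_global(result: ConnectivityResult) -> np.ndarray:
    """Per-epoch mean PLI over all unordered channel pairs."""
    if result.matrices.shape[0] < 1:
        raise ValueError("need at least one epoch")
    return _upper_mean(result.matrices)


def aggregate_region(
    result: ConnectivityResult, montage: Montage
) -> dict[str, np.ndarray | None]:
    """Per-epoch mean PLI over within-region pairs, per region.

    Regions with fewer than two channels in the result have no within-region
    pair and map to ``None`` (undefined, flagged rather than averaged)."""
    out: dict[str, np.ndarray | None] = {}
    for region in REGIONS:
        pairs = region_pair_indices(montage, region, result.channel_labels)
        if not pairs:
            out[region] = None
            continue
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        out[region] = result.matrices[:, ii, jj].mean(axis=1)
    return out


def aggregate_channel(result: ConnectivityResult) -> np.ndarray:
    """Per-epoch, per-channel mean of all pairs including that channel:
    row mean excluding the diagonal.  The channel values average back to
    the global value exactly."""
    mats = result.matrices
    n = mats.shape[1]
    if n < 2:
        raise ValueError("need at least 2 channels")
    return mats.sum(axis=2) / (n - 1)
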