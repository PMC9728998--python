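"""EEG epoch containers and EDF / internal-store input-output.

The working unit everywhere in the package is the :class:`EpochSet`: a
(epoch x channel x sample) tensor of scalp voltages in microvolts together
with the sampling rate, ordered channel labels and subject/session tags.
Recordings arrive as European Data Format (EDF) files — read here through
MNE — or through the package's own store, a ``.npz`` array container with a
JSON metadata sidecar that round-trips floats exactly (EDF is 16-bit
quantized and kept as the interchange format only).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import normalize_label

_AUX_MARKERS = ("ECG", "EKG", "EMG", "EOG", "CHIN", "NECK")


@dataclass
class EpochSet:
    """Artifact-free EEG epochs for one subject and session.

    Parameters
    ----------
    data:
        ``(n_epochs, n_channels, n_samples)`` array, microvolts.
    fs:
        Sampling rate in Hz.
    channel_labels:
        One label per channel, same order as axis 1 of ``data``.
    subject_id, session:
        Provenance tags; ``session`` is ``"pre"`` or ``"post"`` when the
        epochs belong to a pre/post-implantation comparison.
    aux:
        Non-EEG polygraphy channels (ECG, EMG ...) kept out of every scalp
        computation, as ``label -> (n_epochs, n_samples)`` arrays.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    session: str = ""
    aux: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epoch, channel, sample)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=np.asarray(data, dtype=float))


def _split_aux(labels: list[str]) -> tuple[list[int], list[int]]:
    eeg, aux = [], []
    for i, lab in enumerate(labels):
        if any(m in lab.upper() for m in _AUX_MARKERS):
            aux.append(i)
        else:
            eeg.append(i)
    return eeg, aux


def read_edf(
    path: str | Path,
    epoch_seconds: float = 8.0,
    subject_id: str = "",
    session: str = "",
    expected_labels: tuple[str, ...] | None = None,
) -> EpochSet:
    """Read an EDF file into an :class:`EpochSet`.

    The continuous record is cut into consecutive non-overlapping epochs of
    ``epoch_seconds`` (a trailing remainder is dropped).  Channel labels are
    normalized to modern 10-10 names; channels whose labels mark them as
    polygraphy (ECG/EMG/EOG) are separated into ``aux``.  If
    ``expected_labels`` is given and some are missing, a warning listing
    them is emitted.
    """
    import warnings

    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # malformed header, empty file ...
        raise OSError(f"cannot read EDF file {path}: {exc}") from exc

    fs = float(raw.info["sfreq"])
    labels = [normalize_label(ch) for ch in raw.ch_names]
    eeg_idx, aux_idx = _split_aux(labels)
    if not eeg_idx:
        raise OSError(f"{path} contains no EEG channels")

    if expected_labels is not None:
        have = {labels[i] for i in eeg_idx}
        missing = [l for l in expected_labels if normalize_label(l) not in have]
        if missing:
            warnings.warn(
                f"EDF {path.name} is missing {len(missing)} montage channels: "
                f"{missing}",
                stacklevel=2,
            )

    sig = raw.get_data() * 1e6  # MNE loads volts; the package works in uV
    n_per = int(round(epoch_seconds * fs))
    n_ep = sig.shape[1] // n_per
    if n_ep < 1:
        raise OSError(f"{path} shorter than one {epoch_seconds}-s epoch")
    sig = sig[:, : n_ep * n_per]

    def _epoched(rows: np.ndarray) -> np.ndarray:
        return rows.reshape(rows.shape[0], n_ep, n_per).transpose(1, 0, 2)

    eeg = _epoched(sig[eeg_idx])
    aux = {
        labels[i]: _epoched(sig[[i]])[:, 0, :] for i in aux_idx
    }
    return EpochSet(
        data=eeg,
        fs=fs,
        channel_labels=tuple(labels[i] for i in eeg_idx),
        subject_id=subject_id,
        session=session,
        aux=aux,
    )


# --------------------------------------------------------------------------
# EDF writing.  EDF is a fixed-layout ASCII-header + int16 format; nothing in
# the installed stack writes it, so a minimal single-purpose writer lives
# here: one data record per second, 16-bit quantization over each channel's
# physical range.


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(epochs: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` to a 16-bit EDF file.

    Epochs are concatenated back into one continuous signal.  ``fs`` must be
    a positive integer (EDF stores integer samples per 1-s record).
    Quantization error is bounded by half the physical range divided by
    2^15 per channel.
    """
    path = Path(path)
    fs = int(round(epochs.fs))
    if abs(fs - epochs.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")

    sig = epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)
    aux_labels = list(epochs.aux)
    if aux_labels:
        aux_sig = np.stack([epochs.aux[l].reshape(-1) for l in aux_labels])
        sig = np.vstack([sig, aux_sig])
    labels = list(epochs.channel_labels) + aux_labels

    n_rec = sig.shape[1] // fs
    sig = sig[:, : n_rec * fs]
    ns = sig.shape[0]

    pmin = sig.min(axis=1)
    pmax = sig.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((sig - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(epochs.subject_id or "X", 80),
            _pad(f"Startdate X {epochs.session or 'X'}", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_pad(l, 16) for l in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad("uV", 8) for _ in labels),
            b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmin),
            b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmax),
            b"".join(_pad(str(dmin), 8) for _ in labels),
            b"".join(_pad(str(dmax), 8) for _ in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad(str(fs), 8) for _ in labels),
            b"".join(_pad("", 32) for _ in labels),
        ]
    )
    records = digital.reshape(ns, n_rec, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(records.tobytes())
    return path


# --------------------------------------------------------------------------
# Internal store: exact float round-trip per subject/session.


def save_store(epochs: EpochSet, path: str | Path) -> Path:
    """Save to the internal store (``.npz`` + JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"data": epochs.data}
    for lab, arr in epochs.aux.items():
        arrays[f"aux__{lab}"] = arr
    np.savez_compressed(path, **arrays)
    meta = {
        "fs": epochs.fs,
        "channel_labels": list(epochs.channel_labels),
        "subject_id": epochs.subject_id,
        "session": epochs.session,
        "aux_labels": list(epochs.aux),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_store(path: str | Path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with np.load(path) as npz:
        data = npz["data"]
        aux = {lab: npz[f"aux__{lab}"] for lab in meta["aux_labels"]}
    return EpochSet(
        data=data,
        fs=meta["fs"],
        channel_labels=tuple(meta["channel_labels"]),
        subject_id=meta["subject_id"],
        session=meta["session"],
        aux=aux,
    )
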