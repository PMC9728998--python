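"""Config-driven orchestration: simulate -> preprocess -> features -> stats.

A run is described by a YAML config (cohort/simulation parameters plus
analysis options), executed deterministically under its seed, and leaves
behind the result tables (epoch-level features, pre/post comparisons,
outcome correlations, cohort diary) plus a manifest with a config snapshot
and SHA-256 checksums of every output, so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .aperiodic import DEFAULT_FIT_RANGE, aggregate_aperiodic, aperiodic_per_epoch
from .connectivity import (
    aggregate_channel,
    aggregate_global,
    aggregate_region,
    compute_connectivity,
)
from .io import EpochSet
from .montage import Montage
from .preprocess import CANONICAL_BANDS, common_average_reference, extract_band_stack
from .simulate import CohortSpec, SimulatedSubject, balanced_labels, generate_cohort
from .stats import classify_responder, compare_groups, correlate_with_outcome, labar_index

log = logging.getLogger("vnseeg")

SCALES = ("global", "regional", "channel")


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs."""

    seed: int = 0
    outdir: str = "vnseeg_run"
    simulation: Mapping = field(default_factory=dict)
    scales: tuple[str, ...] = ("global", "regional")
    unit_mode: str = "pooled"
    channel_family_per_region: bool = False
    alpha: float = 0.05
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE
    welch_window_seconds: float = 2.0
    welch_overlap: float = 0.5
    save_epochs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        analysis = raw.pop("analysis", {})
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in {**raw, **analysis}.items() if k in known}
        if "scales" in kwargs:
            kwargs["scales"] = tuple(kwargs["scales"])
        if "fit_range" in kwargs:
            kwargs["fit_range"] = tuple(kwargs["fit_range"])
        return cls(**kwargs)

    def to_cohort_spec(self) -> CohortSpec:
        sim = dict(self.simulation)
        k = sim.pop("channels_per_region", None)
        if k is not None:
            labels = balanced_labels(int(k))
            sim["channel_labels"] = labels
            sim["n_channels"] = len(labels)
        if "channel_labels" in sim and sim["channel_labels"] is not None:
            sim["channel_labels"] = tuple(sim["channel_labels"])
        sim.setdefault("seed", self.seed)
        return CohortSpec(**sim)


def validate_config(config: RunConfig) -> list[str]:
    """Aggregated, human-readable config problems (empty list = ok)."""
    errors: list[str] = []
    if not 0 < config.alpha < 1:
        errors.append(f"alpha must be in (0,1), got {config.alpha}")
    if config.unit_mode not in ("pooled", "subject"):
        errors.append(f"unknown unit_mode {config.unit_mode!r}")
    for s in config.scales:
        if s not in SCALES:
            errors.append(f"unknown scale {s!r}")
    try:
        spec = config.to_cohort_spec()
    except (TypeError, ValueError) as exc:
        errors.append(f"simulation config invalid: {exc}")
        return errors
    nyq = spec.fs / 2.0
    for band in CANONICAL_BANDS.values():
        if band.passband[1] + band.transition_high > nyq:
            errors.append(
                f"{band.name} band does not fit below Nyquist ({nyq} Hz) "
                f"at fs={spec.fs}"
            )
    lo, hi = config.fit_range
    if not 0 < lo < hi <= nyq:
        errors.append(f"fit_range {config.fit_range} invalid for fs={spec.fs}")
    return errors


# --------------------------------------------------------------------------
# Feature extraction


def extract_session_features(
    epochs: EpochSet,
    montage: Montage | None = None,
    scales: Sequence[str] = ("global", "regional"),
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    welch_window_seconds: float = 2.0,
    welch_overlap: float = 0.5,
    group: str = "",
) -> pd.DataFrame:
    """Epoch-level long-format feature table for one recording session:
    PLI per band and aperiodic offset/exponent, at the requested spatial
    scales."""
    montage = montage or Montage.from_labels(epochs.channel_labels)
    allow_partial = epochs.n_channels != 61
    rows: list[dict] = []
    base = {
        "subject": epochs.subject_id,
        "group": group,
        "session": epochs.session,
    }

    def emit(measure, scale, unit, variable, series):
        for e, v in enumerate(series):
            rows.append(
                {**base, "measure": measure, "scale": scale, "unit": unit,
                 "variable": variable, "epoch": e, "value": float(v)}
            )

    band_stack = extract_band_stack(epochs, allow_partial=allow_partial)
    for band, band_epochs in band_stack.items():
        conn = compute_connectivity(band_epochs, band)
        if "global" in scales:
            emit("pli", "global", "global", band, aggregate_global(conn))
        if "regional" in scales:
            for region, series in aggregate_region(conn, montage).items():
                if series is not None:
                    emit("pli", "regional", region, band, series)
        if "channel" in scales:
            per_channel = aggregate_channel(conn)
            for c, lab in enumerate(conn.channel_labels):
                emit("pli", "channel", lab, band, per_channel[:, c])

    broadband = common_average_reference(epochs, allow_partial=allow_partial)
    ap = aperiodic_per_epoch(
        broadband,
        fit_range=fit_range,
        window_seconds=welch_window_seconds,
        overlap_fraction=welch_overlap,
    )
    for param in ("offset", "exponent"):
        glob, regional = aggregate_aperiodic(ap, montage, param)
        if "global" in scales:
            emit("aperiodic", "global", "global", param, glob)
        if "regional" in scales:
            for region, series in regional.items():
                if series is not None:
                    emit("aperiodic", "regional", region, param, series)
        if "channel" in scales:
            vals = ap.parameter(param)
            for c, lab in enumerate(ap.channel_labels):
                emit("aperiodic", "channel", lab, param, vals[:, c])
    return pd.DataFrame(rows)


def cohort_feature_table(
    subjects: Sequence[SimulatedSubject], config: RunConfig
) -> pd.DataFrame:
    frames = []
    for s in subjects:
        for epochs in (s.epochs_pre, s.epochs_post):
            log.info("features: subject %s session %s (%d epochs, %d channels)",
                     s.subject_id, epochs.session, epochs.n_epochs,
                     epochs.n_channels)
            frames.append(
                extract_session_features(
                    epochs,
                    scales=config.scales,
                    fit_range=config.fit_range,
                    welch_window_seconds=config.welch_window_seconds,
                    welch_overlap=config.welch_overlap,
                    group=s.group,
                )
            )
    return pd.concat(frames, ignore_index=True)


def cohort_table(subjects: Sequence[SimulatedSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject": s.subject_id,
                "group": s.group,
                "pre_rate": s.pre_rate,
                "post_rate": s.post_rate,
                "labar": s.labar,
            }
            for s in subjects
        ]
    )


def clinical_outcome_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Labar index and responder classification from a seizure-diary table
    with ``pre_rate`` / ``post_rate`` columns."""
    out = cohort.copy()
    out["labar"] = [
        labar_index(p, q) for p, q in zip(out["pre_rate"], out["post_rate"])
    ]
    cls = [classify_responder(v) for v in out["labar"]]
    out["group"] = [c[0] for c in cls]
    out["bucket"] = [c[1] for c in cls]
    return out


# --------------------------------------------------------------------------
# Full run


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: RunConfig) -> dict:
    """Simulate the cohort, extract features, run the statistics, write all
    tables and the manifest.  Deterministic under ``config.seed``."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spec = config.to_cohort_spec()
    log.info("simulate: %d+%d subjects, %d channels, fs=%g",
             spec.n_responders, spec.n_nonresponders, spec.n_channels, spec.fs)
    subjects = generate_cohort(spec)

    if config.save_epochs:
        from .io import save_store

        for s in subjects:
            for ep in (s.epochs_pre, s.epochs_post):
                save_store(ep, outdir / "store" / f"{s.subject_id}_{ep.session}.npz")

    cohort = cohort_table(subjects)
    features = cohort_feature_table(subjects, config)
    comparisons = compare_groups(
        features,
        alpha=config.alpha,
        unit_mode=config.unit_mode,
        channel_family_per_region=config.channel_family_per_region,
    )
    correlations = correlate_with_outcome(cohort, features)

    paths = {}
    for name, df in (
        ("cohort", cohort),
        ("features", features),
        ("comparisons", comparisons),
        ("correlations", correlations),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    manifest = {
        "version": __version__,
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
        "config": {
            **{
                f.name: getattr(config, f.name)
                for f in dataclasses.fields(RunConfig)
                if f.name != "simulation"
            },
            "simulation": dict(config.simulation),
        },
        "outputs": {name: _sha256(p) for name, p in paths.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "cohort": cohort,
        "features": features,
        "comparisons": comparisons,
        "correlations": correlations,
        "manifest": manifest,
    }
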