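"""61-channel 10-10 scalp montage and its partition into lobar regions.

Every regional aggregation in the package (PLI within-region pair averages,
per-region aperiodic means) is driven by the :class:`Montage` defined here:
61 electrode labels of the International 10-10 system assigned to exactly one
of five scalp regions (frontal, temporal, central, parietal, occipital) by a
prefix rule.  The rule is the standard lobar convention; an alternative
partition can be supplied via :meth:`Montage.from_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

REGIONS: tuple[str, ...] = ("frontal", "temporal", "central", "parietal", "occipital")

#: 61 scalp labels of the 10-10 system, anterior to posterior, left to right.
DEFAULT_61_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Older 10-20 dialect names mapped onto modern 10-10 labels.
LABEL_ALIASES: Mapping[str, str] = {
    "T3": "T7",
    "T4": "T8",
    "T5": "P7",
    "T6": "P8",
}

# Longest-prefix-first so FT/TP/FC/CP/PO win over their single-letter parents.
# Midline "z" electrodes carry the same letter prefix and need no special case.
_PREFIX_REGIONS: tuple[tuple[str, str], ...] = (
    ("FP", "frontal"),
    ("AF", "frontal"),
    ("FT", "temporal"),
    ("TP", "temporal"),
    ("FC", "central"),
    ("CP", "parietal"),
    ("PO", "occipital"),
    ("F", "frontal"),
    ("T", "temporal"),
    ("C", "central"),
    ("P", "parietal"),
    ("O", "occipital"),
    ("I", "occipital"),
)

_CANONICAL = {lab.upper(): lab for lab in DEFAULT_61_LABELS}


def normalize_label(label: str) -> str:
    """Normalize an electrode label: trim, strip an ``EEG`` prefix and a
    reference suffix, resolve 10-20 aliases, and canonicalize case."""
    lab = label.strip()
    if lab.upper().startswith("EEG"):
        lab = lab[3:].strip()
    lab = lab.split("-")[0].strip()  # "Fp1-REF" -> "Fp1"
    lab = LABEL_ALIASES.get(lab.upper().capitalize(), LABEL_ALIASES.get(lab, lab))
    return _CANONICAL.get(lab.upper(), lab)


def region_for_label(label: str) -> str:
    """Scalp region of a 10-10 label via the longest-prefix rule."""
    up = normalize_label(label).upper()
    for prefix, region in _PREFIX_REGIONS:
        if up.startswith(prefix):
            return region
    raise ValueError(f"label {label!r} matches no scalp-region prefix")


@dataclass(frozen=True)
class Montage:
    """An ordered electrode set with a total region assignment."""

    labels: tuple[str, ...]
    region_of: Mapping[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in montage")
        missing = [l for l in self.labels if l not in self.region_of]
        if missing:
            raise ValueError(f"labels without region assignment: {missing}")
        bad = {r for r in self.region_of.values()} - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")

    @classmethod
    def from_labels(
        cls, labels: Iterable[str], region_of: Mapping[str, str] | None = None
    ) -> "Montage":
        labels = tuple(normalize_label(l) for l in labels)
        if region_of is None:
            region_of = {l: region_for_label(l) for l in labels}
        return cls(labels=labels, region_of=dict(region_of))

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def channels_in(self, region: str) -> list[str]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
        return [l for l in self.labels if self.region_of[l] == region]

    def index_of(self, label: str) -> int:
        return self.labels.index(normalize_label(label))


def default_montage() -> Montage:
    """The 61-channel 10-10 montage with the standard lobar partition."""
    return Montage.from_labels(DEFAULT_61_LABELS)


def region_channel_pairs(
    montage: Montage, region: str
) -> list[tuple[str, str]]:
    """All unordered channel pairs lying entirely within ``region``.

    A singleton region yields an empty list; regional PLI aggregation must
    treat that as undefined rather than silently averaging nothing.
    """
    members = montage.channels_in(region)
    return list(combinations(members, 2))


def region_pair_indices(
    montage: Montage, region: str, labels: Sequence[str] | None = None
) -> list[tuple[int, int]]:
    """Index pairs of within-region channels relative to ``labels``
    (defaults to the montage's own ordering)."""
    labels = list(labels) if labels is not None else list(montage.labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    out = []
    for a, b in region_channel_pairs(montage, region):
        if a in idx and b in idx:
            i, j = idx[a], idx[b]
            out.append((min(i, j), max(i, j)))
    return out
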