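"""Electrode montage: lead numbering, names and anatomical regions.

The default montage is the 22-lead clinical scalp layout used throughout
this package: the 19 standard 10/20 electrodes plus the mastoid references
``m1``/``m2`` and the additional fronto-central lead ``Afz``.  Lead numbers
are 1-based and fixed, so every downstream report can refer to a channel
either by name (``Cz``) or by its lead number (12).

Regions follow the 10/20 letter convention (F* frontal, T* temporal,
C* central, P* parietal, O* occipital, mastoids as reference).  They are
used for reporting only, never for computation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

__all__ = [
    "ChannelRecord",
    "Montage",
    "UnknownChannelError",
    "default_montage",
    "resolve_channel",
]

REGIONS = frozenset(
    {"frontal", "temporal", "central", "parietal", "occipital", "reference"}
)

#: Prefixes commonly prepended by clinical EDF exporters.
_NAME_PREFIXES = ("eeg ", "eeg-", "eeg_")
#: Reference suffixes commonly appended by clinical EDF exporters.
_NAME_SUFFIXES = ("-ref", "-le", "-avg", "-a1", "-a2")


class UnknownChannelError(KeyError):
    """Raised when a channel label cannot be resolved against a montage."""

    def __init__(self, label: str, valid: list[str]):
        self.label = label
        self.valid = valid
        super().__init__(
            f"unknown channel {label!r}; valid names: {', '.join(valid)}"
        )


@dataclass(frozen=True)
class ChannelRecord:
    """One electrode: 1-based lead number, label and anatomical region."""

    index: int
    name: str
    region: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"lead index must be >= 1, got {self.index}")
        if self.region not in REGIONS:
            raise ValueError(
                f"region {self.region!r} not one of {sorted(REGIONS)}"
            )


def _normalize(label: str) -> str:
    """Case-fold and strip common exporter prefixes/suffixes from a label."""
    s = label.strip().lower()
    for pre in _NAME_PREFIXES:
        if s.startswith(pre):
            s = s[len(pre):]
            break
    for suf in _NAME_SUFFIXES:
        if s.endswith(suf):
            s = s[: -len(suf)]
            break
    return s.strip()


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout with unique, case-normalized names."""

    channels: tuple[ChannelRecord, ...]
    name: str = "10/20+mastoids"
    _by_norm: dict[str, ChannelRecord] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        by_norm: dict[str, ChannelRecord] = {}
        for pos, ch in enumerate(self.channels, start=1):
            if ch.index != pos:
                raise ValueError(
                    f"channel {ch.name!r} has index {ch.index}, "
                    f"expected position {pos}"
                )
            key = ch.name.lower()
            if key in by_norm:
                raise ValueError(f"duplicate channel name {ch.name!r}")
            by_norm[key] = ch
        object.__setattr__(self, "_by_norm", by_norm)

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self) -> Iterator[ChannelRecord]:
        return iter(self.channels)

    @property
    def names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def by_index(self, index: int) -> ChannelRecord:
        """Look up a channel by its 1-based lead number."""
        if not 1 <= index <= len(self.channels):
            raise IndexError(
                f"lead index {index} outside [1, {len(self.channels)}]"
            )
        return self.channels[index - 1]

    def to_csv(self, path) -> None:
        """Serialize as index,name,region CSV."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "name", "region"])
            for ch in self.channels:
                w.writerow([ch.index, ch.name, ch.region])


def _load_bundled() -> tuple[ChannelRecord, ...]:
    src = resources.files("seiznet.data").joinpath("montage_1020.csv")
    with src.open("r") as fh:
        rows = list(csv.DictReader(fh))
    return tuple(
        ChannelRecord(int(r["index"]), r["name"], r["region"]) for r in rows
    )


def default_montage() -> Montage:
    """The 22-lead montage: leads 1..22 = m1, F7, T3, T5, Fp1, F3, C3, P3,
    O1, Afz, Fz, Cz, Pz, Fp2, F4, C4, P4, O2, m2, F8, T4, T6."""
    return Montage(channels=_load_bundled())


def resolve_channel(montage: Montage, label: str) -> ChannelRecord:
    """Resolve a free-text channel label against a montage.

    Matching is case-insensitive and tolerant of common EDF exporter
    decorations (``"EEG Cz-REF"`` resolves to ``Cz``).

    Raises
    ------
    UnknownChannelError
        If no montage channel matches after normalization.
    ValueError
        If the label is empty.
    """
    if not label or not label.strip():
        raise ValueError("channel label must be nonempty")
    key = _normalize(label)
    rec = montage._by_norm.get(key)
    if rec is None:
        raise UnknownChannelError(label, montage.names)
    return rec
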