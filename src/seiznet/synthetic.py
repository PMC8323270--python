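"""Surrogate multichannel EEG with known period-dependent coupling.

Real long-term seizure recordings are clinical data and rarely shareable, so
every downstream stage is exercised on surrogate EEG whose ground-truth
coupling structure is known.  Each channel is driven by an independent
second-order autoregressive oscillator with a spectral peak in the alpha
band (10 Hz at the default 256 Hz sampling rate); observed channels are
linear mixtures

    x_i(t) = u_i(t) + sum_j C_ij u_j(t) + noise,

where C is the period's symmetric coupling matrix (zero diagonal, entries in
[0, 1]).  Linear mixing of Gaussian sources keeps an analytic mutual-
information reference available: for a single coupled pair with coefficient
c, corr(x_i, x_j) = 2c / (1 + c^2) and MI = -0.5 log2(1 - rho^2).

The default seizure schedule has five periods (interictal, preictal, early
ictal, late ictal, postictal) whose structure mimics the reported dynamics
of focal seizures:

* interictal — a ring-lattice: each lead couples to its neighbours within
  ring distance 2 on the montage ordering.  Modular, high clustering,
  longer paths.
* preictal — the lattice persists while a designated focus lead (T3, the
  left mid-temporal electrode) grows four long-range chords and the diffuse
  background rises: paths start to shorten.
* ictal (early, late) — local lattice organization dissolves: couplings
  concentrate on the focus, now coupled to every lead, and on a layer of
  long-range chords (ring distances 7 and 9, a triangle-free chord set).
  The resulting hub-plus-shortcuts graph has minimal path length and low
  clustering.
* postictal — the lattice returns and the background decays toward baseline.

Mean off-diagonal coupling is strictly ordered
interictal < postictal < preictal < ictal, matching the reported period
ordering of EEG synchronization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .montage import Montage, default_montage

__all__ = [
    "SchedulePeriod",
    "CouplingSchedule",
    "SyntheticRecording",
    "default_seizure_schedule",
    "simulate",
    "write_recording",
    "labels_to_segments",
    "DEFAULT_FOCUS",
]

DEFAULT_FOCUS = "T3"
ICTAL_LABELS = ("ictal_early", "ictal_late")


def is_ictal(label: str) -> bool:
    """True for within-seizure period labels."""
    return label.startswith("ictal")


@dataclass(frozen=True)
class SchedulePeriod:
    label: str
    duration_s: float
    coupling: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coupling, dtype=float)
        object.__setattr__(self, "coupling", c)
        if self.duration_s <= 0:
            raise ValueError(f"period {self.label!r}: duration must be > 0")
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError(f"period {self.label!r}: coupling must be square")
        if not np.allclose(c, c.T):
            raise ValueError(f"period {self.label!r}: coupling must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError(f"period {self.label!r}: diagonal must be zero")
        if c.min() < 0 or c.max() > 1:
            raise ValueError(f"period {self.label!r}: entries must be in [0, 1]")

    def mean_offdiag(self) -> float:
        n = self.coupling.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(self.coupling[iu].mean())


@dataclass(frozen=True)
class CouplingSchedule:
    """Ordered periods with coupling matrices, plus signal parameters."""

    periods: tuple[SchedulePeriod, ...]
    sampling_rate: float = 256.0
    noise_sd: float = 0.2
    window_length_s: float = 20.0
    focus_channel: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.periods:
            raise ValueError("schedule needs at least one period")
        sides = {p.coupling.shape[0] for p in self.periods}
        if len(sides) != 1:
            raise ValueError("coupling matrices have differing sizes")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        total = sum(p.duration_s for p in self.periods)
        if total < self.window_length_s:
            raise ValueError(
                f"total duration {total}s shorter than one "
                f"{self.window_length_s}s window"
            )

    @property
    def n_channels(self) -> int:
        return self.periods[0].coupling.shape[0]

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.periods)

    def segments(self) -> list[tuple[float, float, str]]:
        """(start_s, end_s, label) for each period."""
        out, t = [], 0.0
        for p in self.periods:
            out.append((t, t + p.duration_s, p.label))
            t += p.duration_s
        return out


def _ring_lattice_pairs(n: int, reach: int = 2) -> list[tuple[int, int]]:
    pairs = []
    for i in range(n):
        for step in range(1, reach + 1):
            j = (i + step) % n
            pairs.append((min(i, j), max(i, j)))
    return sorted(set(pairs))


def _chord_pairs(n: int, distances: tuple[int, ...] = (7, 9)
                 ) -> list[tuple[int, int]]:
    """Long-range ring chords.  For n=22 and distances {7, 9} no triple of
    chord distances sums to 0 mod n, so the chord graph is triangle-free."""
    pairs = []
    for i in range(n):
        for step in distances:
            j = (i + step) % n
            pairs.append((min(i, j), max(i, j)))
    return sorted(set(pairs))


def default_seizure_schedule(baseline: float = 0.05,
                             ictal: float = 0.6,
                             window_length: float = 20.0,
                             montage: Optional[Montage] = None,
                             sampling_rate: float = 256.0,
                             noise_sd: float = 0.2,
                             focus: str = DEFAULT_FOCUS) -> CouplingSchedule:
    """Five-period schedule realizing the seizure coupling dynamics.

    ``baseline`` is the diffuse interictal background coupling and ``ictal``
    the peak focus coupling; all other levels interpolate between them (see
    module docstring).  Each period spans an integer number of windows:
    interictal 4, preictal 3, early/late ictal 2 each, postictal 3.
    """
    if not 0 <= baseline <= ictal <= 1:
        raise ValueError(
            f"need 0 <= baseline <= ictal <= 1, got {baseline}, {ictal}"
        )
    mont = montage or default_montage()
    n = len(mont)
    focus_idx = None
    if focus is not None:
        focus_idx = next(
            (k for k, ch in enumerate(mont) if ch.name.lower() == focus.lower()),
            None,
        )
        if focus_idx is None:
            raise ValueError(f"focus channel {focus!r} not in montage")
    d = ictal - baseline
    lattice = _ring_lattice_pairs(n, reach=2)
    chords = _chord_pairs(n)
    focus_chords = ([p for p in chords if focus_idx in p]
                    if focus_idx is not None else [])

    def mat(bg: float, pair_vals: list[tuple[list[tuple[int, int]], float]],
            hub_val: Optional[float] = None) -> np.ndarray:
        c = np.full((n, n), bg)
        np.fill_diagonal(c, 0.0)
        for pairs, val in pair_vals:
            for i, j in pairs:
                c[i, j] = c[j, i] = val
        if hub_val is not None and focus_idx is not None:
            for j in range(n):
                if j != focus_idx:
                    v = max(c[focus_idx, j], hub_val)
                    c[focus_idx, j] = c[j, focus_idx] = v
        return np.clip(c, 0.0, 1.0)

    wl = float(window_length)
    lat = baseline + 2 / 3 * d
    pre_pairs = [(lattice, lat)]
    if focus_chords:
        pre_pairs.append((focus_chords, baseline + 0.7 * d))
    periods = (
        SchedulePeriod("interictal", 4 * wl,
                       mat(baseline, [(lattice, lat)])),
        SchedulePeriod("preictal", 3 * wl,
                       mat(baseline + 0.1 * d, pre_pairs)),
        SchedulePeriod("ictal_early", 2 * wl,
                       mat(baseline + 0.15 * d,
                           [(chords, baseline + 0.6 * d)], hub_val=ictal)),
        SchedulePeriod("ictal_late", 2 * wl,
                       mat(baseline + 0.12 * d,
                           [(chords, baseline + 0.55 * d)],
                           hub_val=baseline + 0.85 * d)),
        SchedulePeriod("postictal", 3 * wl,
                       mat(baseline + 0.05 * d,
                           [(lattice, baseline + 0.55 * d)])),
    )
    return CouplingSchedule(periods=periods, sampling_rate=sampling_rate,
                            noise_sd=noise_sd, window_length_s=wl,
                            focus_channel=focus)


@dataclass
class SyntheticRecording:
    """Generated EEG: channels x time samples plus labels and ground truth."""

    samples: np.ndarray
    sampling_rate: float
    montage: Montage
    labels: np.ndarray  # per-sample period label (unicode array)
    truth: CouplingSchedule

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def segments(self) -> list[tuple[float, float, str]]:
        return labels_to_segments(self.labels, self.sampling_rate)


def labels_to_segments(labels: np.ndarray,
                       sampling_rate: float) -> list[tuple[float, float, str]]:
    """Compress per-sample labels into (start_s, end_s, label) runs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(s / sampling_rate, e / sampling_rate, str(labels[s]))
            for s, e in zip(starts, ends)]


# AR(2) oscillator: poles at r * exp(+-2*pi*i*f0/fs)
_AR_POLE_RADIUS = 0.95
_AR_PEAK_HZ = 10.0
_BURN_IN = 512


def _ar2_sources(n_channels: int, n_samples: int, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    a1 = 2 * _AR_POLE_RADIUS * np.cos(2 * np.pi * _AR_PEAK_HZ / fs)
    a2 = -_AR_POLE_RADIUS**2
    e = rng.standard_normal((n_channels, n_samples + _BURN_IN))
    u = np.empty_like(e)
    u[:, 0] = e[:, 0]
    u[:, 1] = a1 * u[:, 0] + e[:, 1]
    for t in range(2, u.shape[1]):
        u[:, t] = a1 * u[:, t - 1] + a2 * u[:, t - 2] + e[:, t]
    u = u[:, _BURN_IN:]
    # normalize each source to unit variance so coupling entries are comparable
    sd = u.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return u / sd


def simulate(schedule: CouplingSchedule, montage: Optional[Montage] = None,
             seed: int = 0) -> SyntheticRecording:
    """Generate one recording from a coupling schedule, reproducibly.

    The same (schedule, montage, seed) triple yields bit-identical samples.
    """
    mont = montage or default_montage()
    if len(mont) != schedule.n_channels:
        raise ValueError(
            f"montage has {len(mont)} channels, schedule expects "
            f"{schedule.n_channels}"
        )
    fs = schedule.sampling_rate
    rng = np.random.default_rng(seed)
    counts = [int(round(p.duration_s * fs)) for p in schedule.periods]
    n_total = sum(counts)
    u = _ar2_sources(len(mont), n_total, fs, rng)
    noise = (schedule.noise_sd * rng.standard_normal(u.shape)
             if schedule.noise_sd > 0 else 0.0)

    x = np.empty_like(u)
    labels = np.empty(n_total, dtype=object)
    t0 = 0
    for p, cnt in zip(schedule.periods, counts):
        block = u[:, t0:t0 + cnt]
        mix = np.eye(len(mont)) + p.coupling
        x[:, t0:t0 + cnt] = mix @ block
        labels[t0:t0 + cnt] = p.label
        t0 += cnt
    x = x + noise
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("synthetic recording contains non-finite values")
    return SyntheticRecording(samples=x, sampling_rate=fs, montage=mont,
                              labels=np.array(labels, dtype=str),
                              truth=schedule)


def write_recording(rec: SyntheticRecording, path) -> tuple[Path, Path]:
    """Write a recording as CSV (header = montage names, one row per sample)
    with a JSON sidecar holding the sampling rate, period segments and the
    ground-truth coupling schedule.  Returns (csv_path, sidecar_path).

    EDF output is not supported (no EDF writer backend); EDF files are
    accepted on the *read* side of the pipeline.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raise ValueError(
            "EDF writing is unsupported; use a .csv path (EDF is accepted "
            "for reading)"
        )
    try:
        header = ",".join(rec.montage.names)
        np.savetxt(path, rec.samples.T, delimiter=",", header=header,
                   comments="", fmt="%.8g")
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".labels.json")
    payload = {
        "sampling_rate": rec.sampling_rate,
        "segments": [
            {"start_s": s, "end_s": e, "label": lab}
            for s, e, lab in rec.segments()
        ],
        "truth": {
            "noise_sd": rec.truth.noise_sd,
            "focus_channel": rec.truth.focus_channel,
            "periods": [
                {
                    "label": p.label,
                    "duration_s": p.duration_s,
                    "mean_offdiag_coupling": p.mean_offdiag(),
                    "coupling": np.round(p.coupling, 6).tolist(),
                }
                for p in rec.truth.periods
            ],
        },
    }
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path, sidecar
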