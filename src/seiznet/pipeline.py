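"""End-to-end orchestration: recording -> windows -> MI -> networks -> reports.

The pipeline consumes a multichannel recording (EDF or CSV, or an in-memory
synthetic recording), cuts it into non-overlapping 20 s windows aligned to
period boundaries, estimates the per-window MI matrix with a shared
embedding, builds the mean-MI-thresholded network per window, and emits the
per-period summaries, the gated statistical comparison, topology-index
trajectories, the core-node ranking and the top-k/propagation-path reports.
All outputs are flat CSV/TSV/JSON/GraphML files keyed by window_id and
period; identical config + seed gives byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from . import brain_network as bn
from .montage import Montage, default_montage, resolve_channel
from .mutual_information import (GridSpec, MIMatrix, PeriodComparison,
                                 PeriodSummary, compare_periods, mi_matrix,
                                 period_summary)
from .phase_space import EmbeddingParams, choose_delay, choose_dimension
from .synthetic import SyntheticRecording

log = logging.getLogger("seiznet")

__all__ = [
    "EEGWindow",
    "RunConfig",
    "PipelineResult",
    "MissingChannelError",
    "read_recording",
    "window_recording",
    "run_pipeline",
    "write_bundle",
]

PERIOD_LABELS = {"awake", "sleep", "interictal", "preictal", "ictal",
                 "postictal"}


class MissingChannelError(ValueError):
    """A montage channel is absent from the input file."""

    def __init__(self, missing: list[str], path=None):
        self.missing = missing
        where = f" in {path}" if path else ""
        super().__init__(
            f"missing montage channel(s){where}: {', '.join(missing)}"
        )


@dataclass(frozen=True)
class EEGWindow:
    """One fixed-length multichannel segment with montage and period label."""

    samples: np.ndarray  # channels x window samples
    start_time: float
    period: str
    window_id: int
    montage: Montage
    sampling_rate: float

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    ``embedding="auto"`` selects the delay by the first auto-MI minimum and
    the dimension by FNN, per channel, then takes the channel median so all
    channels share one (l, m) pair.  ``threshold_rule`` is "window_mean"
    (per-window mean of off-diagonal MI) or "global_mean" (one threshold
    from all windows pooled).
    """

    window_length_s: float = 20.0
    embedding: Union[str, EmbeddingParams] = "auto"
    max_lag: int = 50
    max_dim: int = 5
    grid: GridSpec = field(default_factory=GridSpec)
    threshold_rule: str = "window_mean"
    top_k: int = 20
    activation_quantile: float = 0.75
    alpha: float = 0.05
    seed: int = 0
    csv_sampling_rate: Optional[float] = None
    max_windows_per_segment: int = 6

    def __post_init__(self) -> None:
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.threshold_rule not in ("window_mean", "global_mean"):
            raise ValueError(f"unknown threshold_rule {self.threshold_rule!r}")
        if self.top_k < 1 or self.max_windows_per_segment < 1:
            raise ValueError("top_k and max_windows_per_segment must be >= 1")
        if not 0 <= self.activation_quantile <= 1:
            raise ValueError("activation_quantile must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.embedding, EmbeddingParams):
            d["embedding"] = {"delay_l": self.embedding.delay_l,
                              "dim_m": self.embedding.dim_m}
        d["grid"] = {"cell_budget": self.grid.cell_budget,
                     "mode": self.grid.mode}
        return d


def read_recording(path, montage: Optional[Montage] = None,
                   sampling_rate: Optional[float] = None,
                   ) -> tuple[np.ndarray, float]:
    """Read an EDF or CSV recording; channels returned in montage order.

    EDF channel labels and CSV headers are resolved case-insensitively with
    exporter prefix/suffix stripping, so a file may store channels in any
    order and under decorated names.  The sampling rate comes from the EDF
    header; CSV requires ``sampling_rate``.
    """
    mont = montage or default_montage()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = raw.ch_names
        data = raw.get_data()
        rate = float(raw.info["sfreq"])
    else:
        df = pd.read_csv(path)
        names = list(df.columns)
        data = df.to_numpy(dtype=float).T
        if sampling_rate is None:
            raise ValueError("CSV input requires an explicit sampling_rate")
        rate = float(sampling_rate)

    by_channel: dict[int, int] = {}
    for col, label in enumerate(names):
        try:
            rec = resolve_channel(mont, label)
        except (KeyError, ValueError):
            continue  # non-montage channel (e.g. ECG): ignored
        by_channel[rec.index] = col
    missing = [ch.name for ch in mont if ch.index not in by_channel]
    if missing:
        raise MissingChannelError(missing, path)
    rows = [by_channel[ch.index] for ch in mont]
    return np.ascontiguousarray(data[rows]), rate


def window_recording(samples: np.ndarray, sampling_rate: float,
                     segments: Sequence[tuple[float, float, str]],
                     config: Optional[RunConfig] = None,
                     montage: Optional[Montage] = None) -> list[EEGWindow]:
    """Cut a labeled recording into non-overlapping fixed-length windows.

    Windows are aligned to each labeled segment's start, so none straddles a
    period boundary; the sub-window remainder of each segment is dropped (and
    logged).  At most ``max_windows_per_segment`` windows are kept per
    segment, mirroring the 2-6 segments analyzed per seizure episode.
    """
    cfg = config or RunConfig()
    mont = montage or default_montage()
    wl = int(round(cfg.window_length_s * sampling_rate))
    windows: list[EEGWindow] = []
    wid = 0
    for start_s, end_s, label in segments:
        i0 = int(round(start_s * sampling_rate))
        i1 = min(int(round(end_s * sampling_rate)), samples.shape[1])
        n_fit = (i1 - i0) // wl
        if n_fit == 0:
            log.warning("segment %r [%g, %g)s shorter than one %gs window; "
                        "dropped", label, start_s, end_s, cfg.window_length_s)
            continue
        n_used = min(n_fit, cfg.max_windows_per_segment)
        dropped = (i1 - i0) - n_used * wl
        if dropped > 0:
            log.info("segment %r: dropped %.1fs remainder", label,
                     dropped / sampling_rate)
        for k in range(n_used):
            a = i0 + k * wl
            windows.append(EEGWindow(
                samples=samples[:, a:a + wl], start_time=a / sampling_rate,
                period=label, window_id=wid, montage=mont,
                sampling_rate=sampling_rate,
            ))
            wid += 1
    return windows


def _auto_embedding(windows: list[EEGWindow], cfg: RunConfig) -> EmbeddingParams:
    """Shared (l, m): per-channel choices on one representative window,
    median across channels."""
    w = windows[len(windows) // 2]
    delays, dims = [], []
    for ch in range(w.samples.shape[0]):
        x = w.samples[ch]
        if np.ptp(x) == 0:
            continue
        l = choose_delay(x, max_lag=cfg.max_lag)
        m = choose_dimension(x, l, max_dim=cfg.max_dim)
        delays.append(l)
        dims.append(m)
    if not delays:
        raise ValueError("all channels constant; cannot choose embedding")
    return EmbeddingParams(delay_l=int(np.median(delays)),
                           dim_m=int(np.median(dims)))


@dataclass
class PipelineResult:
    """Everything one run computes, ready for writing or inspection."""

    config: RunConfig
    embedding: EmbeddingParams
    windows: list[EEGWindow]
    matrices: list[MIMatrix]
    summaries: list[PeriodSummary]
    comparison: Optional[PeriodComparison]
    networks: list[bn.BrainNetwork]
    trajectory: bn.MetricTrajectory
    core_report: bn.CoreNodeReport
    path: bn.PropagationPath
    top_edges: list[list[tuple[int, int, float]]]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.summaries])

    def metrics_frame(self) -> pd.DataFrame:
        t = self.trajectory
        return pd.DataFrame({
            "window_id": t.window_ids, "period": t.periods,
            "mean_degree": t.mean_degree,
            "avg_path_length": t.avg_path_length,
            "avg_clustering": t.avg_clustering,
            "n_edges": t.n_edges,
            "connected_pair_fraction": t.connected_pair_fraction,
        })


def run_pipeline(recording: Union[SyntheticRecording, str, Path],
                 config: Optional[RunConfig] = None,
                 segments: Optional[Sequence[tuple[float, float, str]]] = None,
                 montage: Optional[Montage] = None,
                 out_dir: Optional[Union[str, Path]] = None) -> PipelineResult:
    """Run the full analysis; optionally write the output bundle.

    ``recording`` is a SyntheticRecording or a path to an EDF/CSV file (the
    latter requires ``segments`` with the period annotation, and CSV also
    needs ``config.csv_sampling_rate``).
    """
    cfg = config or RunConfig()
    if isinstance(recording, SyntheticRecording):
        mont = recording.montage
        samples, rate = recording.samples, recording.sampling_rate
        segs = segments or recording.segments()
    else:
        mont = montage or default_montage()
        samples, rate = read_recording(recording, mont,
                                       sampling_rate=cfg.csv_sampling_rate)
        if segments is None:
            raise ValueError("file input requires period-label segments")
        segs = list(segments)

    windows = window_recording(samples, rate, segs, cfg, mont)
    if not windows:
        raise ValueError("no complete window in any labeled segment")
    log.info("stage windows: %d windows", len(windows))

    emb = (cfg.embedding if isinstance(cfg.embedding, EmbeddingParams)
           else _auto_embedding(windows, cfg))
    log.info("stage embedding: l=%d m=%d", emb.delay_l, emb.dim_m)

    matrices = [
        mi_matrix(w.samples, emb, channel_names=mont.names, grid_spec=cfg.grid,
                  window_id=w.window_id, period=w.period)
        for w in windows
    ]
    log.info("stage MI: %d matrices", len(matrices))

    summaries = period_summary(matrices)
    samples_by_period: dict[str, np.ndarray] = {}
    for m in matrices:
        samples_by_period.setdefault(m.period, []).append(m.offdiag())
    samples_by_period = {p: np.concatenate(v)
                         for p, v in samples_by_period.items()}
    comparison = None
    if len(samples_by_period) >= 2:
        comparison = compare_periods(samples_by_period, alpha=cfg.alpha)

    global_thr = None
    if cfg.threshold_rule == "global_mean":
        global_thr = float(np.mean(np.concatenate(
            [m.offdiag() for m in matrices])))
    networks = [bn.build_network(m, threshold=global_thr) for m in matrices]
    log.info("stage networks: %d graphs", len(networks))

    trajectory = bn.metric_trajectory(networks)
    core_report = bn.core_nodes(networks)
    tops = [bn.top_k_edges(m, cfg.top_k) for m in matrices]
    path = bn.propagation_path(networks, quantile=cfg.activation_quantile,
                               top_k=cfg.top_k)

    result = PipelineResult(
        config=cfg, embedding=emb, windows=windows, matrices=matrices,
        summaries=summaries, comparison=comparison, networks=networks,
        trajectory=trajectory, core_report=core_report, path=path,
        top_edges=tops,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def _json_default(o):
    if isinstance(o, (np.integer, np.floating, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_bundle(result: PipelineResult, out_dir: Union[str, Path]) -> Path:
    """Write the flat output bundle; deterministic byte-for-byte."""
    out = Path(out_dir)
    (out / "mi").mkdir(parents=True, exist_ok=True)
    (out / "networks").mkdir(exist_ok=True)
    names = result.matrices[0].channel_names

    # per-window MI matrices (channel-name header/rows) + long form
    long_rows = []
    for m in result.matrices:
        df = pd.DataFrame(m.values, index=names, columns=names)
        df.to_csv(out / "mi" / f"window_{m.window_id:03d}.csv",
                  float_format="%.10g")
        for i, j, w in m.pair_items():
            long_rows.append((names[i], names[j], _fmt(w), m.window_id,
                              m.period))
    pd.DataFrame(long_rows, columns=["chan_a", "chan_b", "mi_bits",
                                     "window_id", "period"]).to_csv(
        out / "mi_long.tsv", sep="\t", index=False)

    # networks: edge lists + GraphML
    edge_rows = []
    for net in result.networks:
        g = net.to_networkx(weighted=True)
        nx.relabel_nodes(g, dict(enumerate(net.node_names)), copy=False)
        nx.write_graphml(g, out / "networks" / f"window_{net.window_id:03d}.graphml")
        for (i, j), w in sorted(net.edges.items()):
            edge_rows.append((net.node_names[i], net.node_names[j], _fmt(w),
                              1, net.window_id, net.period))
    pd.DataFrame(edge_rows, columns=["chan_a", "chan_b", "mi_bits", "binary",
                                     "window_id", "period"]).to_csv(
        out / "edges.csv", index=False)

    result.summary_frame().to_csv(out / "period_summary.csv", index=False,
                                  float_format="%.10g")
    result.metrics_frame().to_csv(out / "metrics.csv", index=False,
                                  float_format="%.10g")

    core = result.core_report
    pd.DataFrame({
        "rank": range(1, len(core.ranking) + 1),
        "channel": [core.node_names[i] for i in core.ranking],
        "lead_number": [i + 1 for i in core.ranking],
        "total_degree": [int(core.total_degree[i]) for i in core.ranking],
    }).to_csv(out / "core_nodes.csv", index=False)

    top_rows = []
    for m, tops in zip(result.matrices, result.top_edges):
        for rank, (i, j, w) in enumerate(tops, start=1):
            top_rows.append((m.window_id, m.period, rank, names[i], names[j],
                             _fmt(w)))
    pd.DataFrame(top_rows, columns=["window_id", "period", "rank", "chan_a",
                                    "chan_b", "mi_bits"]).to_csv(
        out / "top_edges.csv", index=False)

    path_payload = {
        "activation_quantile": result.path.quantile,
        "rule": "first window where binary degree is nonzero and reaches "
                "the window's degree quantile (package-defined rule)",
        "activations": [
            {"window_id": a.window_id, "window_pos": a.window_pos,
             "channel": names[a.channel], "lead_number": a.channel + 1,
             "degree": a.degree,
             "strongest_partner": (names[a.strongest_partner]
                                   if a.strongest_partner is not None else None),
             "strongest_mi_bits": (round(a.strongest_mi, 10)
                                   if np.isfinite(a.strongest_mi) else None)}
            for a in result.path.activations
        ],
    }
    with open(out / "propagation_path.json", "w") as fh:
        json.dump(path_payload, fh, indent=1, sort_keys=True,
                  default=_json_default)

    if result.comparison is not None:
        comp = result.comparison
        stats_payload = {
            "parametric": comp.parametric,
            "omnibus": {"name": comp.omnibus_name,
                        "statistic": round(comp.omnibus_statistic, 10),
                        "p": comp.omnibus_p},
            "normality_p": {k: (None if not np.isfinite(v) else v)
                            for k, v in comp.normality_p.items()},
            "levene_p": (None if not np.isfinite(comp.levene_p)
                         else comp.levene_p),
            "alpha": comp.alpha,
            "pairwise": [dataclasses.asdict(t) for t in comp.pairwise],
        }
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_payload, fh, indent=1, sort_keys=True,
                      default=_json_default)
        (out / "stats.txt").write_text(comp.to_text() + "\n")

    provenance = {
        "config": result.config.to_dict(),
        "embedding": {"delay_l": result.embedding.delay_l,
                      "dim_m": result.embedding.dim_m},
        "counts": {
            "windows": len(result.windows),
            "mi_matrices": len(result.matrices),
            "networks": len(result.networks),
            "periods": len(result.summaries),
            "activations": len(result.path.activations),
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True,
                  default=_json_default)
    return out
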