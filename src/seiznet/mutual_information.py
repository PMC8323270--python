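"""Histogram (plug-in) mutual information between embedded EEG channels.

The synchronization index between two leads is the Shannon mutual
information of their phase-space trajectories,

    MI(S, Q) = H(S) + H(Q) - H(S, Q)   [bits],

estimated by discretizing each embedded trajectory onto an equal-width grid
spanning the window's observed range, counting cell occupancies and applying
the plug-in entropy formula.  The per-channel cell budget defaults to
``ceil(n_points ** (1/3))`` capped at 32; for an m-dimensional embedding the
budget is split evenly across axes (per-axis bins = ``floor(budget**(1/m))``,
at least 2).  For m > 2 the joint histogram over full embedded vectors would
be hopelessly sparse at window sizes of a few thousand points, so MI is
computed on the first embedding component of each channel (the embedding is
still used for delay selection).  An equal-frequency ("quantile") partition
is available as the adaptive alternative to the fixed grid.

Per-period summaries (mean MI, SD, coefficient of variation) and the
normality-gated ANOVA / Kruskal-Wallis comparison of periods live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .phase_space import EmbeddedSeries, EmbeddingParams

__all__ = [
    "GridSpec",
    "DiscreteDistribution",
    "MIMatrix",
    "PeriodSummary",
    "PairwiseTest",
    "PeriodComparison",
    "entropy",
    "joint_entropy",
    "discretize",
    "pairwise_mi",
    "mi_matrix",
    "mi_bias_bound",
    "period_summary",
    "compare_periods",
]


@dataclass(frozen=True)
class GridSpec:
    """Discretization rule for one channel's embedded trajectory.

    cell_budget: total cells per channel; ``None`` means the default
        ``min(32, ceil(n_points ** (1/3)))``.
    mode: ``"width"`` for equal-width bins over the observed range,
        ``"quantile"`` for equal-frequency (adaptive) bins.
    """

    cell_budget: Optional[int] = None
    mode: str = "width"

    def __post_init__(self) -> None:
        if self.mode not in ("width", "quantile"):
            raise ValueError(f"unknown binning mode {self.mode!r}")
        if self.cell_budget is not None and self.cell_budget < 2:
            raise ValueError("cell_budget must be >= 2")

    def budget_for(self, n_points: int) -> int:
        if self.cell_budget is not None:
            return self.cell_budget
        return min(32, int(np.ceil(n_points ** (1 / 3))))


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probabilities over occupied grid cells (sum to 1)."""

    probabilities: np.ndarray
    grid_spec: Optional[GridSpec] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.size and (p < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if p.size and abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")


def entropy(dist: DiscreteDistribution | np.ndarray) -> float:
    """Shannon entropy -sum p log2 p in bits; empty distribution -> 0."""
    p = (dist.probabilities if isinstance(dist, DiscreteDistribution)
         else np.asarray(dist, dtype=float))
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-np.sum(p * np.log2(p)))


def joint_entropy(joint: DiscreteDistribution | np.ndarray) -> float:
    """Joint Shannon entropy over the product grid, in bits."""
    return entropy(joint)


def _axis_bins(budget: int, dim: int) -> int:
    return max(2, int(budget ** (1 / dim)))


def discretize(points: np.ndarray, spec: GridSpec) -> tuple[np.ndarray, int]:
    """Map trajectory points to integer cell codes.

    Returns (codes, n_cells) where codes[t] is the flat grid-cell index of
    point t and n_cells the total cell count of the grid.  Equal-width bins
    span each axis's observed range; constant axes collapse to one bin.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array (n_points, dim)")
    n, dim = pts.shape
    bins = _axis_bins(spec.budget_for(n), dim)
    codes = np.zeros(n, dtype=np.int64)
    for ax in range(dim):
        x = pts[:, ax]
        if spec.mode == "quantile":
            edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
            ax_codes = np.searchsorted(edges, x, side="right")
        else:
            lo, hi = x.min(), x.max()
            if hi == lo:
                ax_codes = np.zeros(n, dtype=np.int64)
            else:
                ax_codes = np.floor((x - lo) / (hi - lo) * bins).astype(np.int64)
                ax_codes[ax_codes == bins] = bins - 1  # right edge inclusive
        codes = codes * bins + ax_codes
    return codes, bins**dim


def _effective_points(e: EmbeddedSeries) -> np.ndarray:
    # m > 2: sparse product grids carry no signal at these window sizes;
    # fall back to the first embedding component (see module docstring).
    pts = e.points
    return pts[:, :1] if pts.shape[1] > 2 else pts


def _mi_from_codes(ca: np.ndarray, cb: np.ndarray,
                   na_cells: int, nb_cells: int) -> tuple[float, float, float]:
    """(MI, H_a, H_b) in bits from per-point cell codes of the two channels."""
    n = ca.size
    joint = np.bincount(ca * nb_cells + cb, minlength=na_cells * nb_cells)
    joint = joint[joint > 0] / n
    pa = np.bincount(ca, minlength=na_cells) / n
    pb = np.bincount(cb, minlength=nb_cells) / n
    h_a = entropy(pa)
    h_b = entropy(pb)
    h_ab = entropy(joint)
    return max(h_a + h_b - h_ab, 0.0), h_a, h_b


def mi_bias_bound(n_points: int, cells_a: int, cells_b: int) -> float:
    """Miller-Madow-style expected plug-in MI bias, in bits.

    Used as the principled "near zero" tolerance for independent channels:
    the plug-in estimate of zero MI has expectation approximately
    (cells_a - 1)(cells_b - 1) / (2 n ln 2).
    """
    return (cells_a - 1) * (cells_b - 1) / (2 * n_points * np.log(2))


def pairwise_mi(a: EmbeddedSeries, b: EmbeddedSeries,
                grid_spec: Optional[GridSpec] = None) -> float:
    """Mutual information between two embedded channels, in bits.

    Both trajectories must have the same point count and dimension.  The
    estimate is clipped at zero from below.  A too-sparse grid (fewer points
    than cells) triggers a warning but is still computed.
    """
    spec = grid_spec or GridSpec()
    if a.n_points != b.n_points:
        raise ValueError(
            f"embedded series lengths differ: {a.n_points} vs {b.n_points}"
        )
    if a.points.shape[1] != b.points.shape[1]:
        raise ValueError("embedded series dimensions differ")
    pa, pb = _effective_points(a), _effective_points(b)
    ca, na = discretize(pa, spec)
    cb, nb = discretize(pb, spec)
    if a.n_points < max(na, nb):
        warnings.warn(
            f"histogram sparser than data: {a.n_points} points on "
            f"{max(na, nb)} cells; MI estimate will be strongly biased",
            stacklevel=2,
        )
    # canonical argument order -> bit-identical result under swap
    if ca.tobytes() > cb.tobytes():
        ca, cb, na, nb = cb, ca, nb, na
    mi, _, _ = _mi_from_codes(ca, cb, na, nb)
    return mi


@dataclass
class MIMatrix:
    """Symmetric channel x channel mutual-information matrix for one window.

    The diagonal holds each channel's marginal entropy H(i); off-diagonal
    entries are pairwise MI in bits.
    """

    values: np.ndarray
    channel_names: list[str]
    window_id: Optional[int] = None
    period: Optional[str] = None
    params: Optional[EmbeddingParams] = None
    grid_spec: Optional[GridSpec] = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i < j) MI values, each unordered pair once."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]

    def pair_items(self):
        """Yield (i, j, mi) over unordered pairs, 0-based, i < j."""
        for i, j in combinations(range(self.n_channels), 2):
            yield i, j, float(self.values[i, j])


def mi_matrix(channels: Sequence[np.ndarray] | np.ndarray,
              params: EmbeddingParams,
              channel_names: Optional[Sequence[str]] = None,
              grid_spec: Optional[GridSpec] = None,
              window_id: Optional[int] = None,
              period: Optional[str] = None) -> MIMatrix:
    """Pairwise MI matrix of one multichannel window.

    Each channel is delay-embedded with the shared ``params``, discretized
    once, and every unordered pair's MI is computed from the cached cell
    codes, so the matrix is symmetric by construction.
    """
    from .phase_space import embed  # local import to avoid cycle at module load

    arr = [np.asarray(c, dtype=float).ravel() for c in channels]
    if len(arr) < 2:
        raise ValueError("need at least 2 channels")
    lengths = {a.size for a in arr}
    if len(lengths) != 1:
        raise ValueError(f"channels have unequal lengths: {sorted(lengths)}")
    names = list(channel_names) if channel_names is not None else [
        f"ch{i}" for i in range(len(arr))
    ]
    spec = grid_spec or GridSpec()

    codes, cells, ents = [], [], []
    for name, x in zip(names, arr):
        try:
            e = embed(x, params)
            c, k = discretize(_effective_points(e), spec)
        except Exception as exc:  # attach channel context
            raise type(exc)(f"channel {name!r}: {exc}") from exc
        codes.append(c)
        cells.append(k)
        ents.append(entropy(np.bincount(c, minlength=k) / c.size))

    n = len(arr)
    values = np.zeros((n, n))
    np.fill_diagonal(values, ents)
    for i, j in combinations(range(n), 2):
        mi, _, _ = _mi_from_codes(codes[i], codes[j], cells[i], cells[j])
        values[i, j] = values[j, i] = mi
    return MIMatrix(values=values, channel_names=names, window_id=window_id,
                    period=period, params=params, grid_spec=spec)


@dataclass(frozen=True)
class PeriodSummary:
    """Per-period MI statistics: mean, SD and coefficient of variation (%)."""

    period: str
    mean_mi: float
    sd_mi: float
    coefficient_of_variation: float
    n_windows: int
    n_values: int


def period_summary(matrices: Sequence[MIMatrix],
                   labels: Optional[Sequence[str]] = None
                   ) -> list[PeriodSummary]:
    """Pool all off-diagonal MI values per period; CV = 100 * sd / mean.

    Periods appear in first-encounter order.  ``labels`` overrides the
    matrices' own period attributes when given.
    """
    if labels is None:
        labels = [m.period for m in matrices]
    if len(labels) != len(matrices):
        raise ValueError("labels and matrices differ in length")
    by_period: dict[str, list[np.ndarray]] = {}
    n_windows: dict[str, int] = {}
    for m, lab in zip(matrices, labels):
        if lab is None:
            raise ValueError("matrix without a period label")
        by_period.setdefault(lab, []).append(m.offdiag())
        n_windows[lab] = n_windows.get(lab, 0) + 1
    out = []
    for period, chunks in by_period.items():
        vals = np.concatenate(chunks)
        if vals.size == 0:
            raise ValueError(f"period {period!r} has no MI values")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        cv = 100.0 * sd / mean if mean > 0 else float("nan")
        out.append(PeriodSummary(period, mean, sd, cv,
                                 n_windows[period], int(vals.size)))
    return out


@dataclass(frozen=True)
class PairwiseTest:
    """One pairwise comparison row of the test report."""

    period_a: str
    period_b: str
    statistic: float
    p_value: float
    p_holm: float
    significant: bool  # raw p < alpha


@dataclass
class PeriodComparison:
    """Gated group comparison of per-period MI samples.

    Normality (Shapiro-Wilk) and homoscedasticity (Levene) are tested per
    group at the same alpha; if both hold, one-way ANOVA with pairwise
    t tests is used, otherwise Kruskal-Wallis with pairwise Mann-Whitney U.
    Significance is flagged on raw p-values at alpha; Holm-adjusted values
    are reported alongside.
    """

    parametric: bool
    omnibus_name: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[PairwiseTest]
    alpha: float
    normality_p: dict[str, float] = field(default_factory=dict)
    levene_p: float = float("nan")

    def to_text(self) -> str:
        """Render the pairwise grid as a plain-text table."""
        lines = [
            f"omnibus: {self.omnibus_name} stat={self.omnibus_statistic:.4f} "
            f"p={self.omnibus_p:.4g} "
            f"({'parametric' if self.parametric else 'nonparametric'} branch)",
            f"{'pair':<28}{'stat':>10}{'p':>12}{'p_holm':>12}  sig(a={self.alpha})",
        ]
        for t in self.pairwise:
            mark = "*" if t.significant else ""
            lines.append(
                f"{t.period_a + ' vs ' + t.period_b:<28}"
                f"{t.statistic:>10.4f}{t.p_value:>12.4g}{t.p_holm:>12.4g}  {mark}"
            )
        return "\n".join(lines)


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    k = len(pvals)
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def compare_periods(samples: dict[str, np.ndarray],
                    alpha: float = 0.05) -> PeriodComparison:
    """Compare per-period MI samples with the gated parametric/nonparametric
    strategy described on :class:`PeriodComparison`.

    ``samples`` maps period label -> 1-D array of MI values (e.g. all
    off-diagonal entries of that period's windows).
    """
    periods = list(samples)
    groups = [np.asarray(samples[p], dtype=float).ravel() for p in periods]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError(
            "need >= 2 periods with >= 2 values each; got sizes "
            f"{ {p: g.size for p, g in zip(periods, groups)} }"
        )

    normality_p: dict[str, float] = {}
    normal = True
    for p, g in zip(periods, groups):
        if g.size < 3 or np.ptp(g) == 0:
            # Shapiro is undefined here; treat as failing the gate.
            normality_p[p] = float("nan")
            normal = False
        else:
            sw = stats.shapiro(g[:5000])
            normality_p[p] = float(sw.pvalue)
            normal = normal and sw.pvalue > alpha
    try:
        levene_p = float(stats.levene(*groups).pvalue)
    except Exception:
        levene_p = float("nan")
    homoscedastic = np.isfinite(levene_p) and levene_p > alpha
    parametric = normal and homoscedastic

    degenerate = np.ptp(np.concatenate(groups)) == 0
    if degenerate:
        om = None
        omnibus_name = "one-way ANOVA" if parametric else "Kruskal-Wallis"
    elif parametric:
        om = stats.f_oneway(*groups)
        omnibus_name = "one-way ANOVA"
    else:
        om = stats.kruskal(*groups)
        omnibus_name = "Kruskal-Wallis"
    om_stat = float(om.statistic) if om is not None else 0.0
    om_p = float(om.pvalue) if om is not None else 1.0

    rows = []
    raw = []
    for (pa, ga), (pb, gb) in combinations(zip(periods, groups), 2):
        if np.ptp(np.concatenate([ga, gb])) == 0:
            stat, p = 0.0, 1.0  # identical constant samples: no evidence
        elif parametric:
            r = stats.ttest_ind(ga, gb)
            stat, p = float(r.statistic), float(r.pvalue)
        else:
            r = stats.mannwhitneyu(ga, gb, alternative="two-sided")
            stat, p = float(r.statistic), float(r.pvalue)
        rows.append((pa, pb, stat, p))
        raw.append(p)
    holm = _holm(raw)
    pairwise = [
        PairwiseTest(pa, pb, stat, p, ph, p < alpha)
        for (pa, pb, stat, p), ph in zip(rows, holm)
    ]
    return PeriodComparison(
        parametric=parametric, omnibus_name=omnibus_name,
        omnibus_statistic=om_stat, omnibus_p=om_p, pairwise=pairwise,
        alpha=alpha, normality_p=normality_p, levene_p=levene_p,
    )
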