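# Methods

## Problem and model

Epileptic seizures reorganize the functional coupling between brain regions.
`seiznet` quantifies that reorganization from multichannel scalp EEG as a
*dynamic brain network*: the recording is cut into non-overlapping 20 s
windows, the pairwise synchronization between leads is estimated per window,
each window's synchronization matrix is binarized into a graph, and the
graph's topology indices are followed across the seizure course
(interictal → preictal → ictal → postictal).

### Synchronization index

The synchronization between two leads is their Shannon mutual information
computed on phase-space-reconstructed trajectories rather than on raw
samples.  Each channel x is delay-embedded,

    X_t = (x_t, x_{t+l}, ..., x_{t+(m-1)l}),

with delay `l` (samples) and dimension `m`; a series of length N yields
exactly N − (m−1)·l points.  Both trajectories are discretized on a grid
spanning the window's observed range, and

    MI(S, Q) = H(S) + H(Q) − H(S, Q)   [bits],

with H the plug-in (histogram) entropy, −Σ p log₂ p.  MI is clipped at zero
against floating-point negatives; the matrix diagonal carries the marginal
entropies, and MI(S, S) = H(S) exactly.

### Network construction

Within each window, the threshold is the arithmetic mean of the off-diagonal
MI entries of that window ("uniform MI of all channels"); an edge joins two
leads iff their MI *strictly* exceeds it, so an all-equal matrix yields an
empty graph.  MI weights are retained, so the binary and weighted views
coexist.  A whole-recording (global-mean) threshold is available via
`RunConfig(threshold_rule="global_mean")`.

### Topology indices

Per window: node degree and its distribution; average shortest-path length
in hops; average local clustering coefficient (nodes of degree < 2
contribute 0).  Disconnected node pairs are excluded from the path-length
mean — the connected-pair fraction is reported alongside so the exclusion is
visible — and an edgeless window carries NaN as the undefined-metric marker.
Core nodes are ranked by total binary degree summed over every window of
every period, ties broken by montage position.  The per-window top-20
strongest MI pairs and an activation rule operationalize the propagation
path: a lead "activates" in the first window where its binary degree is
nonzero and reaches the window's activation quantile (default 0.75, upper
interpolation, taken over participating nodes so a lone hub activates alone
while a uniform graph activates everyone).  The activation rule is this
package's own formalization of a narrative concept and is labeled as such in
the outputs.

### Statistics

Per-period samples are all upper-triangle MI values of that period's
windows.  Normality (Shapiro–Wilk, per group; groups with n < 3 or zero
range fail the gate) and homoscedasticity (Levene) are tested at α = 0.05;
if both hold, one-way ANOVA with pairwise t tests, otherwise
Kruskal–Wallis with pairwise Mann–Whitney U.  Significance is flagged on
raw p-values at α; Holm-adjusted values are reported alongside.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| window length | 20 s | the segment length used for the per-window analysis |
| embedding delay l | auto | first minimum of the lagged auto-MI curve; a flat valley returns its median lag (a pure sine then yields the quarter period) |
| embedding dimension m | auto (cap 5) | false-nearest-neighbour criterion, tolerance 0.05 |
| cell budget | ⌈n^⅓⌉, cap 32 | total histogram cells **per channel**; per-axis bins = ⌊budget^(1/m)⌋, min 2 |
| binning mode | equal-width | "quantile" (equal-frequency) available as the adaptive alternative |
| threshold | window mean | mean off-diagonal MI of the same window, strict inequality |
| top-k edges | 20 | strongest-pair subnetwork size |
| activation quantile | 0.75 | degree quantile for the propagation-path rule |
| α | 0.05 | significance level for the gate and the tests |

One (l, m) pair is shared by all channels (median of per-channel choices on
a representative window) so the pairwise matrix is symmetric by
construction.  For m > 2 the product grid over full embedded vectors would
be hopelessly sparse at ~5000 points per window, so MI is computed on the
first embedding component of each channel; the embedding still governs
delay/dimension selection.  The per-channel cell *budget* (rather than
per-axis bin count) keeps joint histograms populated at m = 2.

Numerical determinism: pairwise MI canonicalizes its argument order by the
discretized code bytes, making MI(a, b) and MI(b, a) bit-identical; all
tie-breaks (top-k, core-node ranking, activation order) are lexicographic in
montage position; output files format floats at fixed precision, so a rerun
with the same config and seed is byte-identical.

The "near zero" tolerance for independent channels is the Miller–Madow-style
expected plug-in bias (K_a−1)(K_b−1)/(2n ln 2) bits — a principled,
sample-size-aware floor rather than an arbitrary epsilon.

## Surrogate EEG generator

Clinical long-term recordings are not shareable, so the pipeline is
validated on surrogate EEG with known coupling structure.  Channels are
independent AR(2) oscillators (spectral peak 10 Hz, pole radius 0.95,
sampling 256 Hz, unit variance) mixed linearly per period,
x = (I + C)u + noise (sd 0.2), where C is the period's symmetric coupling
matrix.  Linear Gaussian mixing gives an analytic MI reference: a single
pair coupled at c has corr = 2c/(1+c²) and MI = −½log₂(1−ρ²), which the
estimator tests use as an oracle.

The default schedule has five periods sized in whole windows (interictal 4,
preictal 3, early/late ictal 2 each, postictal 3; 280 s total), with
baseline coupling 0.05 and peak 0.6:

* **interictal** — ring-lattice: every lead coupled to its neighbours
  within ring distance 2 on the montage ordering (modular: high clustering,
  longer paths);
* **preictal** — lattice plus four long-range chords from the focus lead
  (T3) and a slightly raised background (paths begin to shorten);
* **ictal** — the lattice dissolves; coupling concentrates on the focus,
  now coupled to every lead, plus a chord layer at ring distances {7, 9}.
  For 22 nodes no triple of {±7, ±9} chords closes a triangle, so the
  thresholded graph is a hub with triangle-free shortcuts: minimal path
  length, clustering below the interictal level;
* **postictal** — lattice returns, background decays toward baseline.

Mean off-diagonal coupling is strictly ordered interictal < postictal <
preictal < ictal, the reported ordering of seizure-period EEG
synchronization, and the topology dynamics above (path-length minimum in
ictal, clustering dip with postictal recovery) follow from the structure,
not from tuned constants.

What the generator does **not** emulate: volume conduction, artifacts (eye
blinks, muscle), spike-wave morphology, 24 h nonstationarity, and awake/sleep
vigilance states.  Passing tests therefore demonstrate that the estimator
and network machinery recover known coupling structure and its dynamics —
not that clinical recordings would show the same effect sizes.  Absolute MI
magnitudes depend on binning and embedding settings and on the data itself;
only orderings and qualitative dynamics are asserted.

## Problem sizes

The validation suite runs the full pipeline on 14-window surrogate
recordings (22 channels, 256 Hz, 280 s) over 10 independent seeds with
majority aggregation — the package's chosen trade-off between seed coverage
and a test suite that stays interactive.  Estimator oracles use n = 5000
Gaussian pairs (20 replicates) and 1000 random small windows for the matrix
invariants.

## Known limitations

* EDF files are read (via mne) but not written; the native output format is
  CSV plus a JSON sidecar for labels and ground truth.
* Raw samples are consumed as-is: no filtering, re-referencing or artifact
  rejection is applied before windowing.
* The propagation-path activation rule is one reasonable formalization of a
  narrative description; alternative rules (e.g. weighted strength) would
  order activations differently.
* Average path length over connected pairs only is not comparable across
  graphs with very different connected fractions; the fraction is reported
  so users can check it.
* The histogram MI estimator is biased upward for independent channels and
  downward for strongly dependent Gaussian pairs (binning loss); both biases
  are quantified in the tests.
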