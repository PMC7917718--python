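# Methods

This note documents the models and numerical choices behind `caldynet`:
what the synthetic generator simulates, how events and networks are
measured, which parameters matter, and what the recovery benchmarks do
and do not demonstrate.

## 1. The analysis pipeline

### Preprocessing (ΔF/F₀)

Raw fluorescence is converted to fluctuations against a running
baseline: F₀(t) is the 20th percentile of F in a centred 60 s window
(`baseline_percentile`, `baseline_window_s`), and the output is
(F − F₀)/F₀. The running percentile absorbs slow drift and bleaching
trends by construction, and the ratio makes the signal invariant to any
positive rescaling of the raw intensities (gain, laser power). The
percentile must be < 50 so that F₀ tracks the quiet part of the trace;
the cost is a small positive offset of the resulting ΔF/F₀ signal
(the baseline sits below the median of the noise), which the event
detector removes by re-centring on the median (below). A window much
shorter than 60 s starts eating into 10–15 s calcium events; much
longer windows track drift poorly.

### Event detection

Detection operates per cell on the ΔF/F₀ signal after light smoothing
(moving average, `smooth_window_s` = 1.5 s = 3 frames at 2 frames/s) and
median re-centring. The noise scale is σ = 1.4826·MAD of the smoothed
signal — robust to the events themselves at moderate activity levels.
Detection is two-threshold (hysteresis):

* candidate excursions are contiguous runs above min(`seg_k`, `k_mad`)·σ
  (`seg_k` default 3.0);
* a run is accepted as an oscillation when its peak exceeds `k_mad`·σ
  (default 3.0);
* event boundaries are the crossings of `offset_fraction`·peak (default
  0.5, i.e. half-height) nearest the peak, located with sub-frame linear
  interpolation;
* events with half-height duration < `min_duration_s` (default 1.5 s)
  are discarded. Reported amplitude is the raw (unsmoothed) peak.

Two choices deserve comment. *Half-height boundaries*: measuring
duration where the signal crosses a fixed detection threshold makes the
measured duration depend on the ratio of event amplitude to noise (the
decay tail crosses a low threshold much later than a high one); at
half-height the duration estimate is nearly independent of the
threshold, with a residual bias of roughly +1 s for a 0.5-amplitude
plateau with 0.5 s rise / 3 s decay kinetics — under 10% of a typical
12 s oscillation. *Hysteresis*: if the segmentation level moved with
`k_mad`, a stricter threshold could cut one oscillation into several
short runs at noise dips, so the event count would not be monotone in
`k_mad`. With the segmentation level capped at `seg_k`·σ, raising
`k_mad` beyond `seg_k` only removes events. Conversely, at very low
thresholds two events separated by a shallow trough can merge into one
run; this count-reducing merge is intrinsic to every run-based detector
and is why the monotonicity benchmark uses sparse, well-separated
events.

### Activity statistics

* **Active cells %** — cells with ≥ 1 detected oscillation / all cells × 100.
* **Frequency** — oscillations per minute, averaged over *active* cells
  only. Averaging over all cells would conflate a drop in per-cell
  frequency with a drop in the active fraction; both conventions are
  trivially computable from the event table, and the active-cell
  convention is the package default.
* **Duration** — mean half-height duration over all events.

Statistics that are undefined on an empty event table (frequency,
duration) are reported as NaN, never as 0, so that group averages are
not silently biased.

### Network reconstruction

The correlation matrix is the plain product-moment (Pearson)
correlation of the ΔF/F₀ fluctuations over the full recording; constant
traces (silent cells) have undefined correlation and are excluded from
edges. A *functional connection* is a pair with ρ > `threshold`
(default 0.3, strict, applied to the signed coefficient so
anticorrelated pairs never connect). The cross-correlation delay τᵢⱼ is
the lag maximizing the biased normalized cross-correlation within
±`max_lag_s` (default 10 s), ties broken toward zero lag, refined by a
parabolic fit through the peak and its two neighbours (the refinement
vanishes for symmetric peaks, so exact frame shifts remain exact; it
removes the ±0.25 s quantization error at 2 frames/s that would
otherwise bias speed estimates).

The four-measure panel:

* **Mean adjacent-cell correlation** — mean ρ over all *neighbouring*
  pairs (centroid distance ≤ r₁+r₂+`contact_margin_um`, default margin
  2 µm to absorb centroid/radius estimation error). All neighbouring
  pairs count, not only supra-threshold ones; restricting to edges
  would bias the measure upward exactly in the damaged conditions where
  it is most informative. The median [Q1; Q3] is reported alongside.
* **Connections per cell** — mean degree 2E/N.
* **% correlated connections** — 100·E/(N(N−1)/2); 0 iff the edge set
  is empty, 100 iff complete.
* **Propagation speed** — mean of dᵢⱼ/|τᵢⱼ| over edges with
  |τ| ≥ `min_abs_lag_s` (default 0.5 s, one frame). Near-zero lags carry
  no timing information and would produce unbounded ratios; the number
  of excluded edges is reported. Because the ratio uses the straight
  (Euclidean) inter-soma distance while the wave travels along the
  network, the measure is a faithful speed only where propagation paths
  are close to straight; see §3.

### Group statistics

Viability per imaging field is 100·(1 − dead/total); groups are
summarized as mean ± SEM. ΔΔCt: per sample ΔCt = Ct(target) −
Ct(reference); per group ΔΔCt = mean ΔCt − mean ΔCt(control); fold
change 2^(−ΔΔCt), so the control group is exactly 1. Per-sample fold
changes against the control mean provide the SEM. Comparisons use the
two-sided Mann–Whitney U test or one-way ANOVA with Tukey's HSD for the
pairwise p-values; significance at p < 0.05; degenerate (all-identical)
samples get p = 1 with a warning rather than an error. Quartiles use
the linear-interpolation (type-7) convention throughout. No multiple-
testing correction is applied beyond Tukey's own familywise control —
a deliberate mirror of common practice in this literature, and a known
limitation.

## 2. The synthetic recording generator

The generator emulates what the analysis needs to be sensitive to, not
cellular biophysics.

* **Geometry** — `n_cells` somas of radius 5 µm placed uniformly at
  random without overlap in a `field_width_um` × `field_height_um`
  rectangle (default 450 × 450 µm, a 20× confocal field).
* **Ground-truth network** — each pair is independently an edge with
  probability `conn_base_prob`·exp(−d/`conn_decay_um`). Defaults
  (0.6, 50 µm) give a mean degree ≈ 2.3 at 50 cells, chosen so the
  intact preset's observed per-cell oscillation frequency lands near
  the ~1.4 osc/min scale typical of healthy cultures.
* **Events** — a subset of exactly round(`active_fraction`·N) cells is
  active. Initiator cells fire as independent Poisson processes at
  `event_rate_per_min`; each event carries a duration drawn from
  N(`event_duration_mean_s`, `event_duration_sd_s`²) (default 12 ± 3 s)
  and propagates along ground-truth edges with per-hop delay = edge
  length / `wave_speed_um_s` (default 40 µm/s). Propagation can be hop-
  limited (`max_hops`, default 1), thinned (`transmission_prob`) and
  amplitude-damped per hop (`propagation_attenuation`). Overlapping
  deliveries to one cell merge into a single longer oscillation.
  Optionally a small set of pacemakers (`n_pacemakers`) initiates all
  events, either random cells or the most upstream cell of the giant
  component (`pacemaker_mode="edge"`), which produces a directed
  travelling wave.
* **Fluorescence** — each event contributes a transient with a
  saturating-exponential rise (`rise_tau_s` = 0.5 s) toward
  `amplitude_dff`·baseline during the plateau and an exponential decay
  (`decay_tau_s` = 3 s) after it; traces are baseline (100 a.u.) +
  linear drift (`drift_per_min`, default 0.5%/min) + transients +
  i.i.d. Gaussian noise (`noise_sd_dff`·baseline, default SNR 5).
  Kinetic constants are generic fast-rise/slow-decay values for
  high-affinity green calcium dyes; nothing downstream depends on their
  exact values. Optionally the traces are rasterized into a TIFF stack
  (uniform disks per soma) to exercise the ROI-extraction path.
* **Condition presets** — `"intact"`, `"gd"`, `"hypoxia"` set the
  programmed active fraction (0.61 / 0.47 / 0.36) and proportionally
  scaled initiation rates (0.40 / 0.29 / 0.13 min⁻¹), mirroring the
  *ordering* of healthy vs glucose-deprived vs hypoxic cultures. They
  make no claim about reproducing measured effect sizes.

What the generator does **not** model: calcium stores and channel
kinetics, dye saturation and photobleaching (beyond linear drift),
motion artifacts, cell-type heterogeneity (neurons vs astrocytes),
refractoriness, and amplitude variability across events. Consequently,
passing recovery benchmarks demonstrates that the pipeline's estimators
are correct and well-calibrated *for data matching these assumptions*;
they do not certify performance on recordings with strong bleaching,
movement, or saturated indicators.

## 3. Recovery benchmarks (frozen scenarios)

`caldynet.benchmarks` fixes four scenarios; their parameters are part
of the experimental design, chosen from the analysis below and then
frozen.

* **Network recovery** — 20 cells, fully active, rate 0.6 min⁻¹,
  1800 s recordings, wave speed 100 µm/s, per-hop attenuation 0.6,
  amplitude 0.85 (so even propagated events keep SNR ≥ 5 over the 0.1
  noise). Design rationale: (i) with 12-s-autocorrelated signals a
  600 s recording gives chance correlations with sd ≈ 0.14, far too
  wide for a 0.3 cutoff — 1800 s brings false-positive pairs to a
  negligible rate; (ii) without attenuation, a pair sharing a common
  neighbour inherits about half the correlation of a directly coupled
  pair, which is not separable at any single threshold — per-hop
  damping (a standard property of regenerative calcium waves) pushes
  common-neighbour pairs to ≈ 0.15 while direct pairs sit ≈ 0.5.
  Pooled over 20 cultures, precision and recall against the true edge
  set both exceed 0.9.
* **Dynamics recovery** — 20 cells, active fraction 0.6, initiation
  rate 0.15 min⁻¹, 900 s, SNR 5. Detected active %, frequency and mean
  duration are compared with the statistics of the ground-truth event
  trains (which include propagated events), isolating detection error
  from simulation stochasticity; relative errors stay within 10%.
* **Wave-speed recovery** — 15 cells on a quasi-line (40 µm spacing,
  ±5 µm jitter) wired as a chain, one pacemaker at the upstream end,
  low noise. The propagation-speed measure recovers the programmed
  40 µm/s within a few percent. The chain geometry is deliberate: in a
  random 2-D field, parallel branches of the propagation tree create
  correlated pairs whose delay difference is much smaller than their
  separation, inflating d/|τ| by 50% or more on unlucky layouts. That
  is a geometric property of the measure itself (it assumes straight
  propagation paths), not an estimator bug, and users should read the
  speed panel with that caveat in mind.
* **Calibration / ordering** — the Mann–Whitney wrapper's empirical
  type-I error over 2000 null simulations (n = 10 per group) stays
  within [0.03, 0.07] at nominal 0.05 (the exact U test is mildly
  conservative at these sample sizes); and across 10 seeds the presets
  order intact > GD > hypoxia in active %, mean overall correlation and
  % correlated connections. The *mean* correlation is used for the
  ordering because with realistically sparse connectivity the all-pairs
  median is ≈ 0 in every condition; the median [Q1; Q3] is still the
  reported summary statistic in the metrics panel.

## 4. Degenerate inputs and numerical conventions

* Constant traces: NaN correlation, excluded from edges and summaries.
* No events: activity statistics NaN (not 0); empty event table is a
  valid detection result.
* No neighbouring pairs / no edge with usable lag: the corresponding
  measure is NaN with a warning, never silently 0.
* Correlation matrices are symmetrized exactly ((C+Cᵀ)/2) and clipped
  to [−1, 1]; the diagonal is 1 by convention.
* Lag ties break toward the smallest |τ|; the lag matrix is exactly
  antisymmetric.
* All generators are driven by `numpy.random.Generator` seeded from the
  configuration; a fixed seed reproduces cell maps, ground truth,
  traces and every downstream artifact bit-for-bit. Pipeline runs
  record the seed and a configuration hash in their manifest, and
  figures are rendered from the saved tables, never from in-memory
  state.

## 5. Known limitations

* The propagation-speed measure divides straight-line distance by path
  delay; it underestimates speed on curved paths and can overestimate
  it when parallel branches synchronize distant cells (§3).
* MAD-based thresholds assume the trace is quiet most of the time; at
  occupancy ≳ 50% both σ and the running baseline are biased and
  durations shrink (visible under the saturated intact preset at high
  connectivity).
* Frequency is averaged over active cells; cultures differing only in
  silent-cell count will differ in active % but not frequency.
* The ΔΔCt implementation assumes equal amplification efficiency of
  target and reference genes.
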