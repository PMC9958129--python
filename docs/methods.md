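# Methods

`nociquant` quantifies five kinds of recordings that arise when a descending
pain-modulation circuit is probed with optogenetics: stimulus-locked spinal
wind-up electrophysiology, midbrain single-unit responses to a light epoch,
fluorescent neuropeptide-sensor photometry, patch-clamp excitability, and
small behavioral/histological scores. Each stage is paired with a synthetic
generator that produces data with known ground truth, so every estimator in
the package can be checked by parameter recovery. This note documents the
models, the defaults and their units, the numerical choices, and what the
synthetic tests do and do not establish about real recordings.

## Wind-up quantification (`fiber_windup`)

**Model.** A wide-dynamic-range (WDR) dorsal-horn neuron is driven by 1 Hz
electrical shocks of its hind-paw receptive field. Spikes are attributed to
afferent fiber classes by their conduction latency after each shock, with
half-open windows in ms: A-beta [0, 20), A-delta [20, 90), C [90, 300),
C-fiber post-discharge [300, 800). Repeated C-strength stimulation produces
wind-up: the per-shock nociceptive spike count ramps to a plateau. An
intervention (here, an optogenetically driven peptide release upstream) shows
up as a slow multiplicative suppression of the C/post-discharge discharge.

**Procedure.**

1. `build_raster` bins each spike by latency to the latest shock at or
   before it (1-ms bins, 0–800 ms). Spikes later than 800 ms but before the
   next shock are counted and reported (`n_unassigned`), not dropped.
2. `count_c_window` sums bins in [90, 800) ms per trial — the nociceptive
   (C + post-discharge) count.
3. `normalize_windup` smooths the per-trial counts with a centered 21-trial
   moving average (1 Hz shocks make trials and seconds interchangeable);
   edge windows are truncated means. The maximal moving-mean window defines
   100 % activity (ties to the earliest window); the whole smoothed trace is
   expressed in percent of it. The moving-mean maximum is exactly 100 by
   construction and the trace is invariant under scaling the counts.
4. `percent_reduction` is 100 minus the trace minimum among trials whose
   shock time falls in the analysis window (defaults 140–180 s and
   570–600 s after light onset). Trials during stimulation pauses are
   absent, not zero.
5. `wu_latency_metrics` reports the times of the moving-mean maximum, the
   post-plateau minimum, and the first crossing of their midpoint. The
   minimum search stays within the contiguous stimulation series that holds
   the maximum — across a pause wind-up dissipates and is re-induced, so
   post-plateau kinetics are not comparable across series.

**Raster smoothing.** `smooth_raster` (display smoothing for averaged
rasters) applies a separable truncated Gaussian with unit sum, sd 20 samples
per axis, truncated at 100 samples along the latency axis and 20 along the
trial axis. The sd's units are not uniquely determined by the convention the
method descends from ("standard deviation = 20" with 100 ms × 20 ms
windows); we interpret it as samples at 1-ms binning and expose all three
numbers in the API. Edges are handled by renormalizing the kernel over its
valid support, so a constant raster is reproduced exactly and interior
impulses conserve mass. The quantitative pipeline (steps 1–5) does not pass
through this smoothing.

**Control-arm drift.** With a plateau of ~12 nociceptive spikes/trial, the
21-trial moving mean has a relative sd of ~6 %. Normalizing by the *maximum*
window and then taking a *minimum* inside a 40-trial window are extreme-value
statistics, so even suppression-free recordings show a positive "reduction"
of roughly 20 % (noise-free recovery is exactly 0; quadrupling the counts
halves the drift, confirming the 1/sqrt(rate) scaling). Real control
recordings of this kind behave the same way. Recovered suppression is
therefore biased upward by a few percentage points at the paper-scale effect
size (0.61 recovers as ~0.65).

## Single-unit light responses (`unit_response`)

**Normalization.** The spike train is binned at 1 s, convolved with a
unit-sum Gaussian (width 10 s, sd 5 s, edge-renormalized). The baseline mean
rate over −100–0 s relative to light onset (BSmean) defines 0 %. The largest
absolute 21-s moving mean of (FR − BSmean) within the 0–300 s response
window defines ±100 %, positive when the extremum exceeds BSmean. The
extremum search is confined to the response window (config-exposed). Adding
a constant to the rate leaves the percent trace unchanged, and the in-window
extremum of the moving-mean percent is exactly ±100.

**Responder criterion (declared, not reconstructed).** The underlying
experimental reports do not state a quantitative rule for "responded"; ours
is: a unit is *excited* when the 21-s moving-mean deviation exceeds
+3 × (baseline SD) continuously for at least 5 s inside the response window,
*inhibited* for the mirrored rule, else *none*. The baseline SD is measured
on the **unsmoothed** 1-s binned rate over the baseline window: the smoothed
trace's own SD shrinks with the kernel and made stationary units cross the
threshold spuriously, while the raw-rate SD gives the criterion the scale of
the unit's actual count noise. Both the multiplier and the duration are
config-exposed. At the recorded effect sizes (~1 → ~17.7 Hz excited,
~26 → ~7 Hz inhibited, stationary otherwise) classification is 100 % correct
on synthetic populations, and the default 82-unit mixture reproduces a
21 / 2 / 59 split.

**Latencies.** Onset is the first time the criterion is met (clipped at 0),
peak the moving-mean extremum, offset the first return below criterion after
the peak, censored at 300 s. The centered 21-s moving average and the 5-s
kernel lead a true rate step by up to ~12 s, so onsets are systematically
early by that amount — an inherent property of centered smoothing, visible
in the synthetic recovery tests. Population quantiles are (Q1, median, Q3)
with linear interpolation between order statistics (fractional ranks
`p·(n−1)`), so printed quantiles are reproducible on any list.

## Sensor photometry (`grab_sensor`)

**Bleach model.** F_bleach(t) = a·exp(−t/τ) + c, fitted by least squares to
samples outside an excluded window (default: the stimulation epoch). The fit
is linear in (a, c) at fixed τ, so a deterministic τ grid
{30, 100, 300, 600, 1200, 3000, 10000} s with the exact linear solution at
each point seeds a bounded nonlinear refinement — no random initialization,
bit-reproducible results. A constant trace fits with a ≈ 0 and τ pinned at
the grid top, flagged via `tau_at_bound`. An offset-free variant
(`with_offset=False`) is available; τ beyond ~2 recording lengths is weakly
identified whenever an offset is also estimated.

Because the evoked transient outlasts the stimulation pulse by minutes,
closed-form recovery requires excluding the whole post-onset segment from
the fit (`exclude=(stim_onset, end)`); the default exclusion reproduces the
practical situation in which residual signal slightly biases the baseline.

**QC (declared rule).** A recording is discarded when the fit-region
residual RMS exceeds 3× the pre-stimulation noise estimate (RMS of
pre-stimulation residuals), or when τ is pinned at a grid bound with a large
residual — the signature of a stimulation artifact disrupting the fit. The
multiplier is config-exposed; the original discard rule is unstated, so this
is the package's own criterion.

**Quantification.** `detrend` returns (F − bleach)/bleach (ΔF/F0 against the
fitted baseline; scale-invariant) or the raw difference F − bleach via
`mode="raw"` — published deltas of this kind are in raw a.u., so both are
provided. `delta_metrics` reports post − pre differences of the window
maximum and the trapezoid AUC over 300-s windows flanking the stimulation
onset; release therefore comes out positive. Null traces (no transient) give
raw-mode deltas exactly centered on 0; in ratio mode delta_max carries a
small positive bias because the bleach denominator is smaller in the post
window — the null-centering check uses raw mode for this reason.

## Patch-clamp metrics (`patch_metrics`)

Epoch AP frequency is the spike count in a half-open labelled epoch divided
by its duration. First-spike latency (FSL) is the delay from a 50-pA step
onset to the first spike; cells that never fire during the step are missing,
and missing cells are excluded rather than classed. A cell is "decreased"
when baseline − agonist FSL > 10 ms (strict), "increased" for the mirror
(reported as its own class rather than folded into "unchanged", since a
threshold-sized increase is a different observation), else "unchanged".

## Small quantifications (`quant_misc`)

Colocalization percentages are 100·numerator/denominator with a half-up
one-decimal display value alongside full precision. The per-slice
fiber-vs-cell correlation is a Pearson r with R², the least-squares slope of
cells on fibers, and a two-sided p from the exact t transform. The
conditioned-place-preference change score is
(paired_post − unpaired_post) − (paired_hab − unpaired_hab), in seconds; it
is zero for symmetric occupancy and invariant to additive constants.

## Rank tests (`stats_core`)

Mann–Whitney U, Wilcoxon signed-rank, Friedman, Kruskal–Wallis and Welch's
heteroscedastic ANOVA, with exact small-sample null distributions:

* ties get midranks everywhere; signed-rank zeros are dropped (and counted);
* the exact method enumerates group-label arrangements (U), sign patterns
  (W, n ≤ 20) or within-block permutations (Friedman) whenever the total
  number of arrangements is ≤ 10⁶, using the observed midranks, so tied
  configurations are exact too;
* two-sided p doubles the smaller one-sided tail, capped at 1 (the common
  convention for discrete nulls; alternatives exist and would differ in the
  last digit for asymmetric tie patterns);
* larger samples use the normal approximation with tie correction (U, W) or
  the chi-square / F reference distributions (Friedman, Kruskal–Wallis,
  Welch with Welch–Satterthwaite degrees of freedom).

U is reported as the smaller orientation (both retained); W as the smaller
signed-rank sum. With two groups Welch's W equals the squared Welch t.
Post-hoc multiple-comparison families are deliberately out of scope.

## Synthetic generators (`synthgen`)

All generators draw from `numpy.random.default_rng([seed, object_index])` —
one stream per simulated object, so outputs are bit-identical under a fixed
seed and independent of generation order.

**WDR recording.** Per trial and fiber class, the spike count is Poisson
with uniform latency inside the class window (the analysis only ever uses
window membership, so the within-window shape is deliberately
assumption-free). The C/post-discharge intensity is scaled by a linear
wind-up ramp (from 0.2 of plateau over 30 trials — wind-up is maximal ~30 s
after stimulation onset) and by a suppression envelope
(1 − e^{−Δ/40 s})·e^{−Δ/1500 s} after light onset (trial 40), normalized to
unit peak so the trough intensity is exactly (1 − suppression_fraction) ×
plateau; the peak falls at ≈146 s, inside the 140–180 s analysis window,
and meaningful suppression persists at 570–600 s. Default rates
(spikes/trial at plateau): A-beta 2, A-delta 2, C 8, post-discharge 4.
Default protocol: 350 trials at 1 Hz in two series (290 shocks, a 300-s
pause with no trials across which the ramp restarts, 60 more shocks); the
suppression envelope runs on the absolute clock. Trial-to-trial counts are
independent — real wind-up has serial dependence whose structure is not
reported, so recovery results bound sampling error, not autocorrelation
effects.

**Unit population.** Class counts are the largest-remainder rounding of the
(excited, inhibited, none) mixture, default (21, 2, 59)/82. Units are
piecewise-homogeneous Poisson: excited units step from 1.05 Hz to 17.65 Hz
between a lognormal onset (median 4 s, sigma 1.2) and offset (median 250 s,
sigma 0.35) after light onset; inhibited units mirror (25.83 → 6.95 Hz);
"none" units are stationary at 5 Hz. Real units ramp rather than step and
have non-Poisson variability; the generator tests the classifier's
operating point, not its robustness to bursting.

**Sensor trace.** F(t) = f0·e^{−t/τ} + c + A·k(t − t_stim) + artifact +
Gaussian noise, sampled at 2 Hz for 630 s with stimulation at 300 s for
30 s (a 5-min baseline, as in the imaging protocol emulated). k is a
difference of exponentials (rise 5 s, decay 60 s) normalized to unit peak so
A is the peak height above baseline. Defaults: f0 = 10, τ = 600 s, c = 2,
A = 8, noise sd 0.3, artifact 0. The ground-truth record keeps the bleach
and noiseless traces so every downstream metric has an analytic target.

**Patch cell.** Epoch-labelled Poisson spiking (defaults 0.573 / 1.045 /
0.514 Hz over three 300-s epochs) plus FSL values (129.31 / 41.42 ms) with
optional Gaussian jitter.

## Problem sizes used in the recovery checks

The shipped tests and `scripts/acceptance.py` use 200 simulated WDR
recordings per arm, a 100-unit population (plus the default 82), 100 null
sensor traces, and enumeration oracles up to 10 observations — sizes at
which the Monte-Carlo error of every asserted mean is several times smaller
than the tolerance it is checked against.

## Known limitations

* The wind-up percent-reduction estimator inherits extreme-value bias from
  max-normalization and window minima (quantified above); comparisons
  between arms are unaffected in ordering but absolute reductions are
  inflated by a few points at realistic rates.
* Responder classification and photometry QC are declared criteria, not
  reconstructions of unpublished rules; both are config-exposed.
* Onset latencies are systematically early by up to half the moving-average
  window plus the kernel sd.
* The bleach τ is weakly identified when the recording is much shorter than
  τ and an offset is estimated; the τ-grid multi-start keeps the fit
  deterministic but cannot create information that is not in the trace.
* Repeated-measures ANOVA and multiple-comparison post-hocs are out of
  scope; use an established statistics package downstream.
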