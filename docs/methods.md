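# Methods

This note records the models implemented in `optomap`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want written
down.

## The measurement problem

A mapping experiment probes one candidate presynaptic cell at a time: a
10 ms spiral photostimulus is aimed at an opsin-expressing soma while
1–4 patched neurons are held in current clamp (near −70 mV for
excitatory mapping, −55 mV for inhibitory mapping, where IPSPs are
hyperpolarizing). Unlike paired recording, there is no record of the
presynaptic spike, so three separate inferences substitute for it:

1. Did the targeted cell fire? (photostimulus characterization)
2. Did anything *else* fire? (off-target activation model)
3. Did the patched cell receive a stimulus-locked PSP? (detection and
   classification)

## PSP detection by exponential deconvolution

A PSP decaying with time constant τ becomes a brief impulse under

    D(t) = V(t) + τ · dV/dt,

so peaks of `D` localize PSP onsets even when a second PSP rides on the
first's decay. Defaults: τ = 20 ms (a typical pyramidal-cell membrane
time constant); detection threshold 5× the SD of `D` in a 20 ms
pre-stimulus window; search window 0–50 ms post-stimulus; measurement
window from the first threshold crossing to 20 ms later, truncated at
the inter-peak minimum of `D` when multiple PSPs are present. Sweep QC
drops trials whose 50 ms pre-stimulus mean is >5 mV off the holding
target or that drift >1 mV across that window (assessed by the fitted
linear trend, which is robust to membrane noise); baselining subtracts
the median of the 20 ms pre-stimulus window.

Numerical choices:

- Derivative by central differences (one-sided at the edges):
  second-order accurate and symmetric, and `D` is exactly linear in `V`.
- The detection/feature path applies a 1 ms boxcar to the trace before
  the derivative. τ·dV/dt amplifies high-frequency membrane noise
  (at 10 kHz sampling a 0.1 mV Ornstein–Uhlenbeck baseline produces
  multi-mV derivative noise), and 1 ms is short relative to every rise
  time modeled here. `deconvolve` itself stays unsmoothed so the
  operator remains exact on analytic traces.
- Deconvolved peaks without a genuine valley between them (inter-peak
  minimum above half the smaller peak) are merged: residual noise
  wiggles on a single PSP's rise must not split its measurement window.
- Ties at the peak take the first maximum; window boundaries round to
  the nearest sample; traces are analyzed at native sampling rate.
- Amplitude = peak of the average trace in the window; CV = SD/mean of
  per-sweep peaks in the same window; 20–80% rise time by linear
  interpolation, reported only above 0.1 mV (smaller responses are too
  easily contaminated by spontaneous events). One polarity-agnostic
  pipeline serves EPSPs and IPSPs; inhibitory traces are sign-flipped
  before detection.

For paired-pulse ratios, each sweep is deconvolved individually (this
removes temporal summation of the second PSP on the first's decay), the
per-window deconvolved peaks are averaged across sweeps, and PPR =
second/first. When τ is not supplied it is chosen from {5, 10, 15, 20} ms
to minimize |mean of D| in the 10 ms after the second peak — the
automated version of adjusting τ until the deconvolved trace neither
overshoots nor undershoots the baseline (faster τ suits fast-spiking
interneuron targets). Population PPR summaries keep only estimated
inter-PSP intervals of 5–10 ms.

## Classification

The SVM pathway standardizes eleven response features (peak, peak time,
across-sweep SD at the peak, baseline SD, deconvolved peak/time/SD,
3×/5×-SD crossing counts of the deconvolved average, and mean/SD of
per-sweep 3×-SD crossings) and fits an RBF-kernel support-vector
classifier (C = 1, scaled gamma) on a seeded 40–60 train/test split;
excitatory and inhibitory datasets are fit separately.

The z-score pathway is annotation-free: post-stimulus peak of the
average response divided by its 20 ms baseline SD, thresholded at the
99th percentile of the matching *pre*-stimulus statistic (window 70–20 ms
before the stimulus) over the whole dataset — so on pure noise exactly
~1% of pairs exceed the threshold by construction. The threshold is
computed per dataset and per polarity; the comparison is strict
(`post_z > threshold`).

Direct-stimulation artifacts (opsin-positive patched cells) are flagged
when the detected depolarization onset falls within 1 ms of the stimulus
onset — a monosynaptic PSP cannot arrive before the photo-evoked spike
latency plus synaptic delay. Flagged pairs leave every
connection-probability denominator.

## Photostimulus resolution and off-target activation

Spike probability versus offset is fit per axis with
`p(d) = A·exp(−d²/2σ²)`, A ∈ (0, 1], centered at zero with no baseline
term; radial-grid spokes are averaged per distance before fitting, and
jitter uses the sample (n−1) SD of first-spike latencies. FWHM is
reported as 2√(2 ln 2)·σ exactly.

Off-target exposure combines two maps on a common (lateral, axial) grid
of 10 µm × 10 µm bins:

- *Neighbors per targeted cell*: for each bin, pair counts are divided
  by the number of seed cells whose full annulus × symmetric axial slab
  fits inside the imaged volume. This edge correction keeps the estimate
  unbiased for seeds near boundaries (unimaged neighbors outside the
  volume would otherwise deflate it); the targeted cell is excluded from
  its own counts.
- *Activation probability* under the min rule: a neighbor at combined
  offsets is assigned the lower of the two per-axis Gaussian
  probabilities. The surface is evaluated on a 1 µm lattice and averaged
  within bins; at zero offset the probability is 1.

Their elementwise product summed over bins estimates off-target cells
per stimulus. The homogeneous-density variant integrates the min-rule
surface over all space; the radial integral has a closed form at fixed
axial offset (min(g_r, g_z) splits at r* with both pieces analytic), so
only the axial integral needs quadrature (relative tolerance 1e-6). At
68,000 cells/mm³ and a 24/66 µm FWHM stimulus this evaluates to ≈4.7
cells per stimulus. The response model `P_response = 1 − (1 − P)^n`
connects activated-cell counts to measured response rates.

## Connectivity statistics

Connection probabilities use half-open 100 µm distance bins (along
presynaptic pia distance, |horizontal offset|, or 3D distance) with
equal-tailed Jeffreys Beta(found+½, probed−found+½) 95% intervals
(boundary convention: lower bound 0 at zero found, upper bound 1 at
found = probed). Minimum-probed drawing thresholds (20 by default, 10
for the sparser inhibitory datasets) are presentation flags only — the
counts are always reported. Fisher exact tests are two-sided by the
classical minimum-likelihood rule; zero-margin tables give p = 1.
Benjamini–Hochberg adjustment is the standard step-up with cumulative
minimum. The cross-method comparison regresses optogenetic on
paired-recording probabilities with unweighted OLS. Dunn's post hoc test
(after Kruskal–Wallis) is implemented directly — pooled mid-rank z
statistics with tie correction, Holm-adjusted by default.

## Motif analysis

Convergence counts the connected (2 presyn → 1 postsyn) pairs per
patched cell; divergence the connected (1 presyn → 2 postsyn) pairs per
photostimulated cell, both as unordered completions summed over cells.
The bootstrap null estimates each probed pair's connection probability
from its (|horizontal| × presynaptic-pia × subclass) bin — 100 µm ×
100 µm bins, zero-found bins contributing probability 0 (an optional
Laplace-smoothing flag defaults off) — then redraws every pair's
Bernoulli outcome independently, keeping geometry and subclasses fixed.
One-sided p = fraction of simulations with at least the observed count;
counts above all simulations report "<1/n_simulations".

Because the default table is estimated from the dataset it is tested
against, the simulated edge total is pinned to the observed total and
null p-values concentrate mildly around 0.5: the test is *conservative*
for detecting motif excess (it never manufactures significance).
`bootstrap_motif_test` accepts an externally supplied per-pair
probability table; under the generating model the exceedance p-values
are exactly uniform, which is how calibration is verified. At sparse,
study-like connectivity (~8%, 6 recorded cells, 100 candidates), a
planted hub wired to every recorded cell is detected (p < 0.05) with
power >0.9.

Completed-motif curves report P(cell j connected | cell i connected)
per distance bin with Jeffreys intervals, enumerating both orders of
every pair; the divergence variant can restrict cell j to L2/3
pyramidal cells when compared against an overall connection
probability. A caution for calibration checks: ordered pairs reuse each
completing edge, so per-bin variability exceeds the plain binomial —
the clustered variance uses the edge multiplicities. Amplitude
correlations across convergent/divergent pairs enter double-plotted
(each unordered pair once in each orientation) so the i/j assignment is
arbitrary; significance uses the number of unique unordered pairs.

## Intrinsic features and interneuron classes

From a −130…250 pA (20 pA step, 1 s) family at a −70 mV baseline:
input resistance from the OLS slope of steady-state deflection versus
current over hyperpolarizing steps; membrane time constant from
exponential fits to the charging phase, excluding the weakest
hyperpolarizing step (too easily corrupted by background synaptic
activity); capacitance = τ/R; sag = (peak − steady state)/peak on the
−130 pA step; AP waveform features (FWHM at half height above
threshold, upstroke/downstroke ratio, peak, trough, height) from the
first spike at rheobase; firing rate and adaptation index (mean
normalized successive ISI difference) from the step 40 pA above
rheobase; f-I slope by OLS over suprathreshold steps.

Interneurons are clustered on the z-scored 14-feature matrix with a
3-component Gaussian mixture. Covariance is diagonal (reg_covar 1e-3):
with a few tens of cells per class a full 14×14 covariance per component
is degenerate and unstable, while the diagonal model recovers ≥95% of
labels on populations sampled at the published class means/SDs. The fit
uses canonically sorted rows and assigns by per-row prediction, making
the labeling invariant to recording order; Ward agglomerative clustering
is available behind a flag. Components map to classes by signature:
narrowest AP FWHM → FSI, largest sag among the rest → putative Sst,
remainder (high input resistance) → putative VIP.

## Synthetic data: what it emulates, and what it does not

All generators draw from named substreams of one integer seed, so any
stage can be regenerated independently and reruns are byte-identical.

- **Cell maps**: homogeneous Poisson point processes per layer slab
  (layer boundaries 0/80/330/480/750/1000 µm from the pia, half-open
  bins). Real labeled-cell maps show clustering and laminar density
  gradients within layers; none of that is modeled.
- **Networks**: independent Bernoulli edges from a distance kernel
  (default 0.3·exp(−d/150 µm)). Real connectivity has subclass structure
  and (per the motif results) hub-like deviations — which is exactly
  what the motif machinery is meant to detect, so the generator's
  independence is a feature for calibration, and hubs are planted
  explicitly in power tests.
- **Photoresponses**: per sweep, a spike count (default P(1,2,3 spikes)
  = 0.8/0.15/0.05) and a jittered first-spike latency (5 ± 0.5 ms)
  drive difference-of-exponential PSPs (rise/decay 1.5/18 ms for
  pyramidal targets, chosen to land in the measured 20–80% rise range;
  0.8/8 ms suits fast-spiking targets) with binomially sampled quantal
  content — n_sites × release_prob × quantal_size sets the mean and
  √((1−p)/(Np)) the CV, reproducing the inverse CV–amplitude relation.
  Noise is an Ornstein–Uhlenbeck process (5 ms correlation, 0.1 mV SD
  default) plus Poisson spontaneous PSPs (0.2 Hz default — the
  spontaneous rate is a free parameter, not a measured one) and, for
  opsin-positive patched cells, a direct artifact starting exactly at
  stimulus onset (0.23 mV default). Opsin photocurrent kinetics and
  conductance-based membrane dynamics are not modeled.
- **Intrinsic sweeps**: leaky-RC charging with an optional sag
  relaxation (the sag excess is scaled so the realized peak matches the
  requested sag ratio exactly) and regular-with-adaptation spike trains
  whose piecewise-linear AP waveform realizes the requested FWHM and
  upstroke/downstroke ratio.

Passing recovery tests on these fixtures shows the *estimators* are
correct and calibrated at realistic noise levels; it does not certify
performance against biological nuisances the generator omits (bursting,
correlated spontaneous activity, electrode drift beyond a linear ramp,
dendritic filtering differences between subclasses).

## Problem sizes used in tests and the acceptance script

Recovery and calibration measurements run at sizes chosen to keep the
whole suite fast while leaving clear statistical margin: amplitude
recovery on 100 pairs × 20 sweeps at 0.1 mV noise, with per-pair mean
amplitudes log-normal around 0.5 mV (the canonical measured connection
amplitude; the criterion is scale-sensitive since the absolute noise
floor is fixed); quantal CV on 1000 sweeps; z-score false positives on
600 noise-only pairs; bootstrap calibration over 200 replicate datasets
× 200 simulations; planted-hub power over 25 replicates; oracle
equalities (Fisher enumeration, Benjamini–Hochberg definition) on 500
random instances each. The acceptance script reruns all of the above
from scratch plus every published-count statistic; it completes in well
under a minute on one CPU.

## Known limitations

- The bootstrap motif test with the default plug-in probability table is
  conservative (see above); published per-line motif p-values also
  depend on the study's full geometry and are not desk-reproducible.
- The deconvolution threshold (5×SD) limits detection to roughly
  >0.15 mV responses at 0.1 mV baseline noise and 10–20 sweeps — the
  z-score and SVM pathways have similar floors, which is a property of
  the measurement, not the implementation.
- Sweep I/O uses a plain HDF5 container (one group per probed pair);
  loaders for archive-specific electrophysiology formats are out of
  scope, and cell positions enter as annotated coordinate tables, never
  from images.
- Fisher tests on tables larger than 2×2 (used in some low-count
  figure comparisons) are not implemented; the k×2 chi-squared is.
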