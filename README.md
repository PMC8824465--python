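# optomap

Analysis pipeline for synaptic-connectivity mapping by two-photon
optogenetic stimulation combined with whole-cell patch-clamp recording.

In these experiments, opsin-expressing candidate presynaptic neurons
(labeled by subclass-specific Cre lines) are photostimulated one at a
time while 1–4 postsynaptic cells are recorded in current clamp. Each
(photostimulated cell, patched cell) pair is a *probed connection*; the
analysis must decide whether a stimulus-locked postsynaptic potential
(PSP) occurred, quantify it, and turn thousands of such probes into
connection probabilities, spatial profiles, and higher-order wiring
statistics — while accounting for the finite spatial resolution of the
photostimulus, which can activate off-target neighbors.

`optomap` implements that computational chain, plus seeded synthetic-data
generators that emulate the statistical structure of the recordings so
every stage is testable without any raw data:

- **PSP detection and quantification** by exponential deconvolution
  `D(t) = V(t) + τ·dV/dt` (τ = 20 ms): peaks of `D` above 5× its baseline
  SD within 0–50 ms of the stimulus define measurement windows; the
  pipeline reports amplitude, CV across sweeps, 20–80% rise time,
  paired-pulse ratio (summation-corrected through per-sweep
  deconvolution), and run-down.
- **Connection classification** by an RBF-kernel SVM on eleven response
  features, or by an annotation-independent z-score rule thresholded at
  the 99th percentile of pre-stimulus z-scores (false-positive rate 1%
  by construction); direct-stimulation artifacts in opsin-positive
  patched cells (onset coincident with the stimulus) are excluded from
  probability denominators.
- **Photostimulus characterization**: minimum power for 10/10 spiking,
  first-spike latency and jitter, and Gaussian fits
  `p(d) = A·exp(−d²/2σ²)` of spike probability versus lateral/axial
  offset, with FWHM = 2√(2 ln 2)·σ.
- **Off-target activation model**: edge-corrected 2D histograms of
  labeled neighbors per targeted cell × a min-rule activation-probability
  map (a neighbor at combined offsets gets the *lower* of the two
  per-axis Gaussian probabilities), summed to expected off-target cells
  per stimulus; an analytic homogeneous-density variant; and the response
  model `P_response = 1 − (1 − P_connection)^n`.
- **Connectivity statistics**: distance-binned connection probabilities
  with 95% Jeffreys (Beta(½,½)) intervals, two-sided Fisher exact and
  chi-squared contingency tests, Benjamini–Hochberg FDR adjustment,
  Cohen's d, Kruskal–Wallis with Dunn's post hoc, and a cross-method
  (optogenetics vs paired recordings) comparison with Pearson correlation
  and OLS regression.
- **Motif analysis**: convergence (2 presyn → 1 postsyn) and divergence
  (1 presyn → 2 postsyn) counts against a bootstrap null that redraws
  every probed pair at its (horizontal × pia-depth × subclass)-binned
  connection probability; completed-motif conditional probabilities
  P(j connected | i connected); double-plotted amplitude correlations.
- **Intrinsic electrophysiology**: the standard 14-feature
  characterization from current-step families, and Gaussian-mixture
  clustering of interneurons into FSI / putative VIP / putative Sst.

## Worked example

Simulate a small mapping experiment (3 patched L2/3 cells, 40
photostimulated Rorb-labeled cells, 10 sweeps per probe), run detection
and classification, and bin connection probability by the presynaptic
cell's distance from the pia:

```python
import numpy as np
from optomap import synthetic, psp, classify, stats

cfg = synthetic.ExperimentConfig(
    experiment_id="demo", cre_line="Rorb", n_patched=3, n_stim_cells=40,
    n_sweeps=10, base_connection_prob=0.3, connection_length_scale=150.0,
)
dataset, truth = synthetic.gen_experiment(cfg, seed=7)

for pair in dataset.pairs:
    pair.psp_metrics = psp.analyze_pair(pair.epochs)

zpairs = [classify.zscore_pair(p.epochs) for p in dataset.pairs]
flags, thr = classify.zscore_classifier(zpairs)
truth_flags = np.array([p.connected == "connected" for p in dataset.pairs])

print(f"probed pairs:            {len(dataset.pairs)}")
print(f"ground-truth connections: {truth_flags.sum()}")
print(f"deconvolution detections: {sum(p.psp_metrics is not None for p in dataset.pairs)}")
print(f"z-score threshold:        {thr:.2f}")
print(f"z-score agreement:        {np.mean(flags == truth_flags):.3f}")

frame = dataset.to_frame()
for b in stats.binned_connection_probability(frame, axis="pia", min_probed=10):
    print(f"pia {b.bin_lo:4.0f}-{b.bin_hi:4.0f} um: {b.found:2d}/{b.probed:2d}"
          f" = {b.probability:.2f}  (95% CI {b.jeffreys_lo:.2f}-{b.jeffreys_hi:.2f})")
```

Output:

```
probed pairs:            120
ground-truth connections: 11
deconvolution detections: 8
z-score threshold:        8.48
z-score agreement:        0.983
pia    0- 100 um:  0/ 6 = 0.00  (95% CI 0.00-0.33)
pia  100- 200 um:  1/15 = 0.07  (95% CI 0.01-0.27)
pia  200- 300 um:  4/27 = 0.15  (95% CI 0.05-0.31)
pia  300- 400 um:  5/36 = 0.14  (95% CI 0.06-0.28)
pia  400- 500 um:  0/18 = 0.00  (95% CI 0.00-0.13)
pia  500- 600 um:  1/18 = 0.06  (95% CI 0.01-0.23)
```

Of 120 probed pairs, 11 are connected in the ground-truth network; the
deconvolution path finds the 8 whose amplitudes clear the 5×SD threshold
at this noise level, and the z-score classifier agrees with ground truth
on 98.3% of pairs. Each distance bin reports found/probed with its
Jeffreys interval — the shape of the generating distance kernel is
already visible at this small scale.

The same stages are available as a CLI (`optomap simulate | detect |
classify | resolution | offtarget | stats | motifs | intrinsics |
report`), all wired to a single `--seed`.

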