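"""Connection classification: response features, SVM, z-score rule, artifacts.

Three complementary pathways decide whether a probed pair is connected:

- an SVM trained on labeled examples of the eleven response features
  (peak/timing/variance statistics of the average and deconvolved
  responses),
- an annotation-independent z-score rule — the post-stimulus peak of the
  average response in units of its baseline SD, thresholded at the 99th
  percentile of the matching *pre*-stimulus statistic across the whole
  dataset (pinning the false-positive rate at 1% by construction),
- a direct-artifact filter for opsin-positive patched cells, whose
  photo-evoked depolarization starts coincident with the stimulus rather
  than after a synaptic delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data_model import TraceEpoch
from .psp import (
    DeconvolutionParams,
    average_epoch,
    baseline_subtract,
    deconvolve_epoch,
    detect_psp_window,
)

#: Window definitions (ms relative to stimulus onset).
POST_WINDOW = (0.0, 50.0)
PRE_WINDOW = (-70.0, -20.0)
BASELINE_WINDOW = (-20.0, 0.0)

#: Latency margin below which a depolarization counts as a direct artifact.
ARTIFACT_ONSET_MARGIN_MS = 1.0


@dataclass
class ResponseFeatures:
    """The eleven photoresponse features used by the trained classifier."""

    peak: float
    time_of_peak: float
    sd_at_peak_time: float
    baseline_sd: float
    deconvolved_peak: float
    time_of_deconvolved_peak: float
    deconvolved_baseline_sd: float
    n_crossings_3sd: float
    n_crossings_5sd: float
    mean_per_sweep_crossings_3sd: float
    sd_per_sweep_crossings: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass
class ZScorePair:
    """Post- and pre-stimulus peak z-scores of one average photoresponse."""

    post_z: float
    pre_z: float


def _count_upward_crossings(x: np.ndarray, level: float) -> int:
    above = x >= level
    return int(np.sum(above[1:] & ~above[:-1]) + (1 if above[0] else 0))


def extract_features(
    epochs: Sequence[TraceEpoch],
    polarity: str = "positive",
    tau: float = 20.0,
    smooth_ms: float = 1.0,
) -> ResponseFeatures:
    """Compute the eleven classifier features for one probed pair.

    Features are measured in a 50 ms post-stimulus window; baseline SDs in
    the 20 ms before the stimulus. Per-sweep SD features are NaN with
    fewer than two sweeps.
    """
    baselined = [baseline_subtract(e) for e in epochs]
    if polarity == "negative":
        for b in baselined:
            b.voltage = -b.voltage
    avg = average_epoch(baselined)
    post = avg.window_slice(*POST_WINDOW)
    base = avg.window_slice(*BASELINE_WINDOW)

    seg = avg.voltage[post]
    ipk = int(np.argmax(seg))
    peak = float(seg[ipk])
    time_of_peak = ipk * avg.dt_ms
    stack = np.stack([b.voltage for b in baselined])
    sd_at_peak = (
        float(np.std(stack[:, post.start + ipk], ddof=1))
        if len(baselined) >= 2
        else float("nan")
    )
    baseline_sd = float(np.std(avg.voltage[base]))

    dec = deconvolve_epoch(avg, tau, smooth_ms)
    dseg = dec[post]
    dpk = int(np.argmax(dseg))
    dec_sd = float(np.std(dec[base]))
    n3 = _count_upward_crossings(dseg, 3.0 * dec_sd)
    n5 = _count_upward_crossings(dseg, 5.0 * dec_sd)

    per_sweep = []
    for b in baselined:
        d = deconvolve_epoch(b, tau, smooth_ms)
        sd_i = float(np.std(d[base]))
        per_sweep.append(_count_upward_crossings(d[post], 3.0 * sd_i))
    per_sweep = np.asarray(per_sweep, dtype=float)

    return ResponseFeatures(
        peak=peak,
        time_of_peak=time_of_peak,
        sd_at_peak_time=sd_at_peak,
        baseline_sd=baseline_sd,
        deconvolved_peak=float(dseg[dpk]),
        time_of_deconvolved_peak=dpk * avg.dt_ms,
        deconvolved_baseline_sd=dec_sd,
        n_crossings_3sd=float(n3),
        n_crossings_5sd=float(n5),
        mean_per_sweep_crossings_3sd=float(np.mean(per_sweep)),
        sd_per_sweep_crossings=(
            float(np.std(per_sweep, ddof=1)) if per_sweep.size >= 2 else float("nan")
        ),
    )


def zscore_pair(epochs: Sequence[TraceEpoch], polarity: str = "positive") -> ZScorePair:
    """Peak-over-baseline-SD statistics in the post and pre windows."""
    baselined = [baseline_subtract(e) for e in epochs]
    if polarity == "negative":
        for b in baselined:
            b.voltage = -b.voltage
    avg = average_epoch(baselined)
    sd = float(np.std(avg.voltage[avg.window_slice(*BASELINE_WINDOW)]))
    if sd == 0:
        return ZScorePair(post_z=float("inf"), pre_z=0.0)
    post = float(np.max(np.abs(avg.voltage[avg.window_slice(*POST_WINDOW)])))
    pre = float(np.max(np.abs(avg.voltage[avg.window_slice(*PRE_WINDOW)])))
    return ZScorePair(post_z=post / sd, pre_z=pre / sd)


def zscore_classifier(
    zpairs: Sequence[ZScorePair], percentile: float = 99.0
) -> tuple[np.ndarray, float]:
    """Annotation-independent classification of a whole dataset.

    The threshold is the empirical ``percentile`` of all pre-stimulus
    z-scores (computed per dataset and per polarity); a pair is connected
    iff its post-stimulus z strictly exceeds the threshold. Returns
    (connected flags, threshold).
    """
    if len(zpairs) < 100:
        warnings.warn(
            "fewer than 100 pairs: the percentile threshold is coarse", stacklevel=2
        )
    pre = np.array([z.pre_z for z in zpairs])
    post = np.array([z.post_z for z in zpairs])
    threshold = float(np.percentile(pre, percentile))
    return post > threshold, threshold


def train_classifier(
    features: np.ndarray,
    labels: Sequence[bool],
    split_fraction: float = 0.4,
    seed: int = 0,
):
    """Train the SVM connection classifier; report held-out accuracy.

    ``split_fraction`` of the examples (seeded shuffle) train an
    RBF-kernel support-vector classifier on standardized features; the
    rest measure accuracy. Excitatory and inhibitory datasets should be
    trained separately. Returns (fitted pipeline, held-out accuracy).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(y.size)
    n_train = max(int(round(split_fraction * y.size)), 2)
    # make sure both classes appear in the training split
    while len(set(y[order[:n_train]])) < 2:
        order = rng.permutation(y.size)
    train, test = order[:n_train], order[n_train:]
    model = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale"))
    model.fit(X[train], y[train])
    accuracy = float(np.mean(model.predict(X[test]) == y[test])) if test.size else 1.0
    return model, accuracy


def flag_direct_artifact(
    epochs: Sequence[TraceEpoch],
    opsin_positive_post: bool,
    margin_ms: float = ARTIFACT_ONSET_MARGIN_MS,
    params: DeconvolutionParams | None = None,
) -> bool:
    """Flag responses whose depolarization onset coincides with the stimulus.

    Only opsin-positive patched cells can produce direct artifacts; pairs
    flagged here must leave connection-probability denominators.
    """
    if not opsin_positive_post:
        return False
    baselined = [baseline_subtract(e) for e in epochs]
    avg = average_epoch(baselined)
    windows = detect_psp_window(avg, params)
    if not windows:
        return False
    return windows[0][0] <= margin_ms
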