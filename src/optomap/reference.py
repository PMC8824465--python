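"""Published reference inputs for mouse V1 connectivity comparisons.

These tables are *inputs* to the statistics modules — printed counts from
the cross-method comparison of two-photon optogenetic mapping against
multicellular paired recordings in mouse primary visual cortex, the
results-level contingency comparisons, and population means/SDs of
intrinsic electrophysiological properties of L2/3 cell classes. They let
the contingency, multiple-comparison, regression, and clustering
machinery be exercised end-to-end on real counts.
"""

from __future__ import annotations

import pandas as pd

#: Cross-method comparison: found/probed counts per connection class and
#: 3D intersomatic distance range, for paired recordings and 2P optogenetics.
METHOD_COMPARISON_COUNTS = pd.DataFrame(
    [
        # class, distance, paired found, paired probed, opto found, opto probed
        ("Exc. to exc.", "0-100", 8, 135, 12, 205),
        ("Exc. to exc.", "100-200", 2, 48, 3, 312),
        ("Exc. to Pvalb", "0-100", 13, 28, 19, 41),
        ("Exc. to Pvalb", "100-200", 8, 27, 9, 60),
        ("Exc. to VIP", "0-100", 6, 25, 7, 24),
        ("Exc. to VIP", "100-200", 4, 28, 0, 11),
        ("Sst to exc.", "0-100", 9, 38, 45, 101),
        ("Sst to exc.", "100-200", 6, 22, 38, 167),
        ("Sst to Pvalb", "0-100", 8, 36, 2, 12),
        ("Sst to Pvalb", "100-200", 4, 35, 4, 26),
        ("Pvalb to exc.", "0-100", 17, 31, 17, 50),
        ("Pvalb to exc.", "100-200", 9, 30, 18, 96),
        ("Pvalb to Pvalb", "0-100", 30, 82, 6, 17),
        ("Pvalb to Pvalb", "100-200", 32, 102, 14, 35),
    ],
    columns=[
        "connection_class",
        "distance_um",
        "paired_found",
        "paired_probed",
        "opto_found",
        "opto_probed",
    ],
)

#: Results-level contingency comparisons: (found1, probed1, found2, probed2).
#: The Sst Ai167-vs-AAV L4 comparison uses the denominators consistent with
#: the published percentages (10.5% = 2/19, 6.0% → 266 probed).
CONTINGENCY_COMPARISONS = {
    "rorb_l4_vs_l5": (148, 1511, 71, 1028),
    "l5_rorb_vs_l5_tlx3": (71, 1028, 61, 1052),
    "sst_ai167_vs_aav_l4": (2, 19, 51, 248),
    "pvalb_vs_sst_intralaminar": (35, 156, 60, 211),
    "l5_pvalb_vs_l5_sst": (2, 259, 16, 266),
    "penk_to_fsi_vs_pc": (19, 41, 12, 205),
    "penk_to_vip_vs_pc": (7, 24, 12, 205),
}

#: Recurrent excitatory connectivity vs 3D distance: chi-squared statistic
#: printed for the Penk dataset (df = 2) and the positive-predictive-value
#: counts for optically identified connections verified by patching.
PENK_CHI2_STAT = 11.8
PENK_CHI2_DF = 2
VERIFIED_EXCITATORY = (11, 12)  # verified / tested by subsequent patching
VERIFIED_INHIBITORY = (22, 22)

#: Population intrinsic properties (mean, SD) of L2/3 cell classes.
INTRINSIC_POPULATIONS = {
    "L2/3 PC": {
        "v_rest": (-72.8, 6.7),
        "input_resistance": (90.3, 31.5),
        "tau": (14.4, 4.3),
        "capacitance": (171.0, 58.0),
        "sag": (0.032, 0.027),
        "rheobase": (171.0, 75.0),
        "ap_fwhm": (1.37, 0.31),
        "upstroke_downstroke_ratio": (4.30, 0.68),
        "ap_peak": (40.6, 8.0),
        "ap_trough": (-48.4, 4.9),
        "ap_height": (89.0, 10.1),
        "avg_firing_rate": (7.78, 2.36),
        "adaptation": (0.090, 0.079),
        "f_i_slope": (0.12, 0.06),
    },
    "FSI": {
        "v_rest": (-68.2, 7.3),
        "input_resistance": (92.4, 33.8),
        "tau": (6.5, 1.8),
        "capacitance": (80.0, 44.0),
        "sag": (0.062, 0.042),
        "rheobase": (268.0, 119.0),
        "ap_fwhm": (0.62, 0.17),
        "upstroke_downstroke_ratio": (1.72, 0.23),
        "ap_peak": (19.5, 7.9),
        "ap_trough": (-53.0, 5.16),
        "ap_height": (72.5, 10.2),
        "avg_firing_rate": (30.9, 10.8),
        "adaptation": (0.008, 0.021),
        "f_i_slope": (0.66, 0.19),
    },
    "putative VIP": {
        "v_rest": (-62.6, 10.5),
        "input_resistance": (174.0, 64.3),
        "tau": (9.9, 4.3),
        "capacitance": (56.0, 15.0),
        "sag": (0.117, 0.068),
        "rheobase": (126.0, 77.0),
        "ap_fwhm": (1.25, 0.29),
        "upstroke_downstroke_ratio": (3.36, 0.58),
        "ap_peak": (27.5, 12.7),
        "ap_trough": (-51.0, 2.8),
        "ap_height": (78.5, 13.1),
        "avg_firing_rate": (15.5, 11.3),
        "adaptation": (0.044, 0.083),
        "f_i_slope": (0.20, 0.11),
    },
    "putative Sst": {
        "v_rest": (-61.8, 4.6),
        "input_resistance": (199.0, 57.0),
        "tau": (16.8, 4.3),
        "capacitance": (87.0, 20.0),
        "sag": (0.16, 0.096),
        "rheobase": (129.0, 52.0),
        "ap_fwhm": (0.79, 0.14),
        "upstroke_downstroke_ratio": (2.10, 0.36),
        "ap_peak": (24.0, 13.4),
        "ap_trough": (-52.7, 5.2),
        "ap_height": (76.7, 17.0),
        "avg_firing_rate": (15.6, 6.6),
        "adaptation": (0.081, 0.090),
        "f_i_slope": (0.29, 0.11),
    },
}

#: Per-axis activation probabilities of the worked min-rule example
#: (Tlx3:AAV resolution fits evaluated at 10 µm lateral / 10 µm axial).
MIN_RULE_EXAMPLE = {"lateral_p_at_10um": 0.18, "axial_p_at_10um": 0.83}
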