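"""Published cluster summaries from the concurrent tDCS-fMRI study of MS
patients and healthy controls that this pipeline reimplements.

Each table lists the significant clusters of one group-level contrast: cluster
extent in voxels, the group-mean normalized fALFF per condition (arbitrary
units after rank-Gaussian standardization), the printed percentage change /
relative difference, the peak t-statistic and the FDR-corrected cluster p.
These serve as worked-example inputs for the reporting formulas and for the
section-total aggregation; the underlying MRI data are not public.
"""

from __future__ import annotations

import pandas as pd

_COLS = ["region", "section", "voxels", "mean_a", "mean_b", "pct_printed", "t_stat"]

#: Phase contrast (during vs pre) in healthy controls.
#: mean_a = pre-stimulation mean, mean_b = during-stimulation mean.
HC_PHASE_CONTRAST = pd.DataFrame(
    [
        ["Pre and Postcentral Gyri Right", "increase", 1877, 0.019201, 0.368802, 90.10288, 9.66],
        ["Inferior Temporal Gyrus Right", "increase", 1013, -0.32587, 0.001911, 98.8342, 10.14],
        ["Precuneus Cortex", "increase", 271, 0.119524, 0.443586, 57.54851, 6.76],
        ["Temporal Pole Right", "increase", 240, -0.42706, -0.05268, 78.0369, 7.25],
        ["Supramarginal Gyrus Right", "increase", 219, 0.391473, 0.707374, 28.74843, 7.18],
        ["Middle Frontal Gyrus Right", "increase", 209, -0.14105, 0.231028, 24.18118, 6.76],
        ["Brain Stem", "decrease", 3909, -0.23085, -0.66331, 48.36413, -5.52],
        ["Occipital Pole Bilateral", "decrease", 1557, 0.815443, 0.434038, 30.525, -4.85],
        ["Anterior Cingulate Gyrus", "decrease", 444, 0.090492, -0.29264, 52.76195, -7.39],
    ],
    columns=_COLS,
)

#: Phase contrast in MS patients at the baseline visit.
MS_BASELINE_PHASE_CONTRAST = pd.DataFrame(
    [
        ["Cuneal Cortex Bilateral", "increase", 1172, 0.429658, 0.866538, 33.70483, 4.88],
        ["Superior Parietal Lobule Left", "increase", 433, -0.59321, -0.15992, 57.5313, 7.28],
        ["Lateral Occipital Cortex Left", "increase", 332, 0.106048, 0.485274, 64.13187, 8.92],
        ["Caudate Right", "increase", 265, -0.51554, -0.09985, 67.5479, 6.57],
        ["Inferior Temporal Gyrus Right", "increase", 230, -0.32848, 0.089951, 57.0058, 5.96],
        ["Superior Lateral Occipital Cortex Left", "increase", 221, -0.21563, 0.194086, 5.25928, 5.62],
        ["Middle Temporal Gyrus Right", "decrease", 427, 0.250174, -0.16139, 21.571, -9.92],
        ["Superior/Middle Frontal Gyrus Left", "decrease", 403, 0.545782, 0.092736, 70.9526, -5.36],
        ["Middle Temporal Gyrus Left", "decrease", 380, 0.465669, 0.025445, 89.6379, -8.65],
        ["Superior/Middle Frontal Gyrus Right", "decrease", 375, 0.481211, 0.052951, 80.1742, -6.11],
        ["Inferior Temporal Gyrus Right", "decrease", 365, 0.320968, -0.17819, 28.6043, -7.96],
        ["Superior Frontal Gyrus Right", "decrease", 234, 0.410741, -0.05509, 76.3488, -6.22],
        ["Posterior Cingulate Gyrus", "decrease", 217, -0.22283, -0.70026, 51.72135, -5.37],
    ],
    columns=_COLS,
)

#: Phase contrast in MS patients at the follow-up visit.
MS_FOLLOWUP_PHASE_CONTRAST = pd.DataFrame(
    [
        ["Inferior Lateral Occipital / Temporal Occipital Cortex Left", "increase", 437, 0.118253, 0.481962, 60.59631, 5.80],
        ["Temporal Pole / Inferior Frontal Gyrus Right", "increase", 428, -0.28435, 0.110447, 44.0492, 9.57],
        ["Insular Cortex / Putamen / Amygdala Right", "increase", 307, -0.56942, -0.18799, 50.3599, 12.81],
        ["Cerebellum Right", "increase", 267, -0.02321, 0.323126, 86.59579, 9.31],
        ["Occipital Pole Right", "increase", 236, 0.434013, 0.809296, 30.18424, 5.04],
        ["Inferior Frontal Gyrus Left", "increase", 232, 0.093637, 0.474607, 67.04334, 6.18],
        ["Hippocampus Right", "increase", 225, -0.8762, -0.46149, 31.0015, 9.05],
        ["Middle/Inferior Frontal Gyrus Right", "increase", 209, -0.19298, 0.21055, 4.355137, 6.51],
        ["Temporal Pole / Insular Cortex Left", "increase", 191, -0.53496, -0.13044, 60.7937, 7.60],
        ["Cuneal Cortex Right", "decrease", 627, 1.17035, 0.827826, -17.1418, -7.27],
        ["Superior/Middle Frontal Gyrus Left", "decrease", 309, 0.269823, -0.13118, -34.5747, -6.27],
        ["Lateral Occipital Cortex / Angular Gyrus Right", "decrease", 283, 0.92414, 0.572967, -23.4568, -6.09],
        ["Precuneus Cortex / Superior Parietal Lobule Right", "decrease", 254, 0.732296, 0.385454, -31.0304, -8.81],
        ["Posterior Cingulate Gyrus", "decrease", 248, 0.427365, 0.071968, -71.1742, -8.29],
    ],
    columns=_COLS,
)

#: Visit contrast in MS patients (follow-up vs baseline), split by phase.
#: mean_a = baseline mean, mean_b = follow-up mean; section marks the phase
#: in which the cluster was found, with the sign of the change.
MS_VISIT_CONTRAST = pd.DataFrame(
    [
        ["Precuneus Cortex Right / Cuneal Cortex Bilateral", "pre_increase", 498, 0.457145, 1.012112, 37.77192, 4.46],
        ["Lingual / Occipital Fusiform / Inferior Lateral Occipital Right", "pre_increase", 346, -0.17168, 0.367106, 36.27264, 4.78],
        ["Post and Precentral Gyri Right", "pre_increase", 327, -0.16212, 0.308116, 31.04644, 7.65],
        ["Frontal Pole / Middle / Inferior Frontal Gyrus Right", "pre_decrease", 385, 0.265931, -0.38734, 18.58469, -6.45],
        ["Frontal Pole / Superior Frontal Gyrus Left", "dur_decrease", 370, 0.297546, -0.43713, 18.99966, -5.55],
        ["Middle/Inferior Frontal Gyrus Left", "dur_decrease", 362, 0.145045, -0.54301, 57.83924, -4.63],
    ],
    columns=_COLS,
)

#: Group contrast (HC vs MS) at baseline, split by phase.
#: mean_a = HC mean, mean_b = MS mean.
GROUP_CONTRAST = pd.DataFrame(
    [
        ["Anterior Cingulate Gyrus / Thalamus Bilateral", "pre", 3346, 0.159017278, -0.463121198, 48.880423, 6.13],
        ["Insular Cortex / Frontal Operculum Right", "pre", 1231, 0.097547268, -0.520021303, 68.409251, 5.10],
        ["Insular Cortex / Inferior Frontal Gyrus Left", "pre", 1158, 0.097244857, -0.492867159, 67.041899, 6.03],
        ["Posterior Inferior Temporal Gyrus Left", "pre", 518, 1.026043849, 0.457400933, 38.3325974, 5.63],
        ["Anterior Parahippocampal Gyrus Right", "pre", 494, 1.027096386, 0.433568696, 40.6340712, 4.79],
        ["Occipital Pole Right", "pre", 409, -0.290480644, -0.990572217, 54.649702, 3.42],
        ["Insular Cortex / Heschl's Gyrus Left", "pre", 336, 0.747053189, 0.154194933, 65.7819131, 4.94],
        ["Inferior Temporal Gyrus Right", "pre", 323, 0.719479415, 0.156920041, 64.189836, 5.53],
        ["Precuneous / Cuneal Cortex", "pre", 252, 0.441386577, -0.098704592, 63.4489146, 4.38],
        ["Posterior Inferior Temporal Gyrus Left", "during", 1553, -0.6197054, -0.1267058, 66.0493289, -8.43],
        ["Anterior Middle Temporal Gyrus Right", "during", 830, -0.7224977, -0.2598023, 47.1032603, -7.71],
        ["Superior Lateral Occipital Cortex Right", "during", 581, -0.1409356, 0.37347333, 45.204852, -7.16],
        ["Cerebellum", "during", 427, -0.682366, -0.044775, 87.6846512, -3.60],
        ["Paracingulate Gyrus Left", "during", 406, -0.8173234, -0.3373407, 41.5690316, -6.75],
        ["Supplementary Motor Cortex Right", "during", 377, -0.3995375, 0.05429481, 76.0727417, -8.13],
        ["Middle Temporal Gyrus Right", "during", 332, 0.0917993, 0.65752227, 75.498024, -6.49],
        ["Putamen Left", "during", 281, -0.7584529, -0.3172187, 41.019413, -6.27],
        ["Precuneus Cortex", "during", 263, 0.19427928, 0.7033319, 56.71193, -5.66],
        ["Cerebellum", "during", 262, -0.3793384, 0.06941254, 69.0641142, -5.59],
        ["Parietal Operculum Cortex Left", "during", 254, -0.235471, 0.30670603, 13.138704, -6.01],
    ],
    columns=_COLS,
)
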