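"""Previously reported values for the petunia sterilization experiment.

These are the published model-comparison metrics, optimization outcomes
and sensitivity ranks for this dataset.  They are used only by the run
report to show deltas (reproduced - reported); no computation reads them.
"""

# (model, response, subset) -> (R2, RMSE, MBE)
REPORTED_METRICS = {
    ("MLP", "contamination", "train"): (0.890, 15.948, -2.272),
    ("MLP", "contamination", "test"): (0.844, 20.645, -3.565),
    ("MLP", "germination", "train"): (0.846, 15.383, 1.699),
    ("MLP", "germination", "test"): (0.794, 17.219, 1.956),
    ("GRNN", "contamination", "train"): (0.954, 11.632, 1.572),
    ("GRNN", "contamination", "test"): (0.886, 14.836, -2.735),
    ("GRNN", "germination", "train"): (0.941, 10.724, -1.182),
    ("GRNN", "germination", "test"): (0.841, 14.026, 1.898),
    ("RBF", "contamination", "train"): (0.944, 13.737, 2.024),
    ("RBF", "contamination", "test"): (0.863, 18.370, -3.870),
    ("RBF", "germination", "train"): (0.913, 11.569, -1.237),
    ("RBF", "germination", "test"): (0.800, 15.369, 2.870),
}

# disinfectant -> (concentration, time_min, contamination %, germination %)
REPORTED_OPTIMA = {
    "CaClO2": (8.73, 13.54, 4.27, 90.63),
    "NaOCl": (1.89, 11.97, 8.03, 76.27),
    "HgCl2": (5.03, 4.77, 7.36, 72.03),
    "H2O2": (16.35, 18.44, 1.33, 77.73),
    "NWCNFe": (8.59, 16.19, 33.07, 56.78),
    "MWCNT": (35.63, 9.93, 45.63, 41.07),
}

# response -> feature -> (VSR, rank)
REPORTED_SENSITIVITY = {
    "contamination": {
        "NaOCl": (3.63, 2), "CaClO2": (2.76, 4), "HgCl2": (2.96, 3),
        "H2O2": (1.36, 6), "NWCNFe": (1.14, 7), "MWCNT": (1.83, 5),
        "time_min": (3.73, 1),
    },
    "germination": {
        "NaOCl": (1.94, 2), "CaClO2": (1.72, 3), "HgCl2": (1.11, 5),
        "H2O2": (1.36, 4), "NWCNFe": (1.01, 6), "MWCNT": (0.80, 7),
        "time_min": (2.07, 1),
    },
}
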