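"""Reference one-vs-rest confusion counts for three benchmark classifiers.

Each row: (classifier, level, TN, TP, FN, FP, accuracy, sensitivity,
specificity, F1) with the metric values printed at two decimals.  Used as
worked examples for the metric algebra and macro summaries.
"""

REFERENCE_ROWS = [
    ("KNN", "I", 532, 183, 1, 8, 0.99, 0.99, 0.99, 0.98),
    ("KNN", "II", 573, 126, 16, 9, 0.97, 0.83, 0.98, 0.91),
    ("KNN", "III", 521, 172, 9, 22, 0.96, 0.95, 0.96, 0.92),
    ("KNN", "IV", 506, 203, 14, 1, 0.98, 0.94, 0.99, 0.96),
    ("SVM", "I", 1396, 359, 41, 34, 0.96, 0.90, 0.98, 0.91),
    ("SVM", "II", 1349, 354, 71, 56, 0.93, 0.83, 0.96, 0.85),
    ("SVM", "III", 1324, 421, 23, 62, 0.95, 0.95, 0.96, 0.91),
    ("SVM", "IV", 1261, 536, 25, 8, 0.98, 0.96, 0.99, 0.97),
    ("GB", "I", 282, 80, 0, 0, 1.00, 1.00, 1.00, 1.00),
    ("GB", "II", 268, 87, 3, 4, 0.98, 0.97, 0.99, 0.96),
    ("GB", "III", 286, 67, 6, 3, 0.98, 0.92, 0.99, 0.94),
    ("GB", "IV", 240, 118, 1, 3, 0.99, 0.99, 0.99, 0.98),
]

# Cells whose printed value is inconsistent with the row's own counts
# (KNN II sensitivity prints 0.83 but 126/142 = 0.89; KNN IV specificity
# prints 0.99 but 506/507 = 1.00 at two decimals). The counts are
# authoritative; these cells are skipped when comparing.
INCONSISTENT_CELLS = {("KNN", "II", "sensitivity"), ("KNN", "IV", "specificity")}

# Total evaluated rows per classifier's dataset.
DATASET_SIZES = {"KNN": 724, "SVM": 1830, "GB": 362}

# Cumulative (macro) reference values.
MACRO_ACCURACY = {"KNN": 0.97, "SVM": 0.96, "GB": 0.99}
MACRO_SENSITIVITY_KNN = 0.94
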