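"""Reference cross-tabulations from a published 447-case thyroid FNA cohort.

These counts document the system's original clinical validation: structure-
level RBF results on 20,614 training / 20,710 test structures, and
patient-level results of the numeric (cut 37 nuclei) and percent (cut 51%)
case classifiers on 224 training / 223 test patients.  They serve as inputs
for regression-testing the metrics module — the raw counts are exact, so
every derived index is exactly recomputable — and as documentation constants;
the underlying per-nucleus data are not distributed.
"""

from __future__ import annotations

from .metrics import ConfusionMatrix

__all__ = [
    "NUCLEUS_CM",
    "CASE_CM",
    "REFERENCE_CASE_THRESHOLDS",
    "SENSITIVITY_COUNTS",
]

# Structure-level (nucleus + colloid) confusion matrices, malignant positive.
NUCLEUS_CM: dict[str, ConfusionMatrix] = {
    "train": ConfusionMatrix(tp=6090, fp=716, tn=12517, fn=1291),
    "test": ConfusionMatrix(tp=5978, fp=1335, tn=12028, fn=1369),
}
NUCLEUS_CM["combined"] = NUCLEUS_CM["train"] + NUCLEUS_CM["test"]

# Patient-level confusion matrices per case classifier.
CASE_CM: dict[tuple[str, str], ConfusionMatrix] = {
    ("numeric", "train"): ConfusionMatrix(tp=73, fp=8, tn=137, fn=6),
    ("numeric", "test"): ConfusionMatrix(tp=73, fp=9, tn=134, fn=7),
    ("percent", "train"): ConfusionMatrix(tp=75, fp=6, tn=139, fn=4),
    ("percent", "test"): ConfusionMatrix(tp=76, fp=7, tn=136, fn=4),
}
for _mode in ("numeric", "percent"):
    CASE_CM[(_mode, "combined")] = (
        CASE_CM[(_mode, "train")] + CASE_CM[(_mode, "test")]
    )

# Case thresholds selected on the original training cohort (documentation
# constants: they derive from undistributed data and are not re-derivable).
REFERENCE_CASE_THRESHOLDS = {"numeric": 37, "percent": 51.0}

# Train-vs-test structure-level sensitivity comparison: (x, class n, whole-set n).
SENSITIVITY_COUNTS = {
    "train": (6090, 7381, 20614),
    "test": (5978, 7347, 20710),
}
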