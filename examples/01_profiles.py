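"""Assay selection and profile padding.

Builds a small assay panel, applies the quality cascade (best model per
target, best phenotypic model per project, very-high-quality unannotated
models), then zero-pads a profile to the conditioning width.
"""

import numpy as np

from pdiff.profiles import AssayRecord, pad_profile, select_assays

assays = [
    AssayRecord("KINASE-A1", 0.55, "target_annotated", target_id="ABL1"),
    AssayRecord("KINASE-A2", 0.72, "target_annotated", target_id="ABL1"),
    AssayRecord("KINASE-B1", 0.45, "target_annotated", target_id="BRAF"),
    AssayRecord("PHENO-P1", 0.62, "project_annotated", project_id="PROJ-9"),
    AssayRecord("PHENO-P2", 0.41, "project_annotated", project_id="PROJ-9"),
    AssayRecord("MISC-U1", 0.95, "unannotated"),
    AssayRecord("MISC-U2", 0.85, "unannotated"),
    AssayRecord("WEAK-T1", 0.20, "target_annotated", target_id="EGFR"),
]

selected = select_assays(assays, r2_min=0.3, r2_hq=0.9)
print("selected assays:", selected)
# One assay per target (the higher-r2 ABL1 model wins), one per project,
# and only the r2>0.9 unannotated assay survive; the r2=0.2 model is dropped.

profile = np.random.default_rng(0).normal(5.5, 1.0, len(selected))
padded = pad_profile(profile, width=16)
print(f"profile of {len(profile)} pAC50 values padded to width {len(padded)};")
print("trailing zeros:", int((padded == 0)[len(profile):].sum()))
# The padded vector is what conditions the image generator's cross-attention.
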