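"""Classify cognitive groups from connectivity features under nested
leave-one-out cross-validation.

For each held-out subject the features are re-ranked on the training
subjects only, and a linear C-SVM is trained on the top-k features for
k = 1..K_max.  On a cohort whose groups differ only through non-linear
couplings, eMIC features should out-classify PCC features.
"""

import numpy as np

from nlfc import (
    ClassifierSpec,
    average_accuracy,
    compute_features,
    contrast_scenario,
    generate_cohort,
    loocv_curve,
)

cohort = generate_cohort(contrast_scenario("nonlinear", seed=7))
codes = cohort.group_codes()
mask = np.isin(codes, (1, 2))  # CN vs MCI carries the full planted effect
spec = ClassifierSpec(scaling="zscore")

for method in ("pcc", "emic"):
    x = compute_features(cohort, method)
    curve = loocv_curve(x[mask], codes[mask], spec)
    per_k = ", ".join(f"k={k + 1}: {a:.2f}" for k, a in enumerate(curve.accuracy))
    print(
        f"{method:>4}: {per_k}  ->  average accuracy "
        f"{average_accuracy(curve):.3f}  (sens {curve.sensitivity.mean():.2f}, "
        f"spec {curve.specificity.mean():.2f})"
    )
# PCC cannot see the symmetric couplings, so it hovers near the 21/37
# majority rate; eMIC separates the groups essentially perfectly.
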