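"""Rank connectivity features by between-group discrepancy and select the
top 1%.

Each of the R(R-1)/2 region-pair eMIC values is scored with the
cross-group Kendall statistic tau = (n_c - n_d) / (m * n) for the CN vs
MCI contrast; the top-1% (ceiling) features become the selection budget,
and the regions of highest degree in the selected-edge graph are the
candidate significant ROIs.
"""

import numpy as np

from nlfc import (
    compute_features,
    contrast_scenario,
    generate_cohort,
    rank_features,
    select_top_fraction,
    significant_rois,
)

cohort = generate_cohort(contrast_scenario("nonlinear", seed=7))
codes = cohort.group_codes()
mask = np.isin(codes, (1, 2))
features = compute_features(cohort, "emic")

table = rank_features(features[mask], codes[mask], contrast=(1, 2))
selected = select_top_fraction(table, 0.01)
rois, edges = significant_rois(selected, cohort.n_regions, cohort.region_labels)

print(f"{features.shape[1]} features; selected top {selected.size}")
print(table.to_frame(cohort.region_labels).iloc[table.ranking[:4]])
print("highest-degree regions in the selected graph:", rois)
# The planted coupled pairs (R000-R001 etc.) carry |tau| = 1 — complete
# cross-group separation — and dominate both the ranking and the ROI list.
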