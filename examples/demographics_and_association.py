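"""Demographic group comparisons and connectivity-MMSE association.

Sex distributions are compared with the uncorrected Pearson chi-square,
ages with the two-sample t-test, and a planted connectivity feature is
correlated against MMSE across all subjects.
"""

import numpy as np

from nlfc import (
    chi_square_2x2,
    compute_features,
    contrast_scenario,
    fc_mmse_correlation,
    feature_index,
    generate_cohort,
    two_sample_ttest,
)

# Sex tables (female/male) of a 21/16/13 cohort.
tables = {
    "CN vs MCI": [[10, 11], [10, 6]],
    "CN vs dementia": [[10, 11], [5, 8]],
    "MCI vs dementia": [[10, 6], [5, 8]],
}
for name, t in tables.items():
    stat, p = chi_square_2x2(t)
    print(f"sex {name:>16}: chi2 = {stat:.3f}, p = {p:.3f}")

cohort = generate_cohort(contrast_scenario("nonlinear", seed=7))
codes = cohort.group_codes()
ages = np.array([s.age for s in cohort.subjects])
t, df, p = two_sample_ttest(ages[codes == 1], ages[codes == 2])
print(f"age CN vs MCI: t = {t:.2f}, d.f. = {df:.0f}, p = {p:.3f}")

# A planted feature's eMIC tracks group, and group tracks MMSE, so the
# feature should correlate with the cognitive score across all 50 subjects.
features = compute_features(cohort, "emic")
k = feature_index(0, 1, cohort.n_regions)
rec = fc_mmse_correlation(features[:, k], cohort.mmse_scores())
print(f"eMIC(R000,R001) vs MMSE: r = {rec.r:+.3f}, p = {rec.p:.2e}, "
      f"significant at 0.05: {rec.significant}")
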