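# nlfc — linear and non-linear functional connectivity for cognitive-level classification

`nlfc` is a Python library for asking whether the *non-linear* component of
resting-state functional connectivity (FC) carries information about
cognitive impairment that the usual linear measure misses.  It targets the
three-level setting used in white-matter-disease cohorts — cognitively
normal (CN), mild cognitive impairment (MCI) and dementia, defined from the
MMSE screen (28–30, 23–27, <23) — and provides every stage of the analysis
as composable functions plus a thin CLI.

## The measures and the procedure

For each subject, an R×T region-by-time matrix yields an R×R FC matrix
under three pairwise dependence measures:

- **PCC** — Pearson's correlation, ρ = cov(X,Y)/(σ_X σ_Y), the linear measure;
- **MIC** — the maximal information coefficient
  `MIC = max_{p·q ≤ B} I*(p,q) / log2 min(p,q)` with budget `B = n^0.6`,
  where `I*(p,q)` is the largest mutual information over p×q grids drawn on
  the scatterplot (grid search by exact dynamic programming over one axis,
  with exhaustive row-partition enumeration where feasible and
  equal-frequency partitioning otherwise);
- **eMIC** — the non-linear residual `MIC − ρ²`.

The R(R−1)/2 upper-triangle FC values are features.  For a two-group
contrast each feature is scored with the cross-group Kendall statistic
`τ = (n_c − n_d)/(m·n)` over all m·n cross-group subject pairs, features are
ranked by |τ|, and the top 1% (ceiling: 6,670 features at R = 116 → 67)
form the selection budget.  Classification uses a linear C-SVM under
leave-one-out cross-validation with the ranking recomputed inside every
training fold, for incremental feature counts k = 1..K_max; accuracy,
sensitivity and specificity (positive class = more impaired group) are
averaged over k.

Because cohorts of this kind are rarely deposited, the package includes a
seeded synthetic-cohort generator that plants linear and non-linear
(quadratic/sine/absolute-value) couplings between regions with
group-dependent strengths, so the whole pipeline can be exercised and
calibrated end to end.

## Worked example

`examples/classification_curve.py` builds a 21/16/13 cohort (R = 20,
T = 230) whose CN and MCI groups differ **only** through non-linear
couplings, then runs the nested LOOCV curve for PCC and eMIC features:

```
 pcc: k=1: 0.24, k=2: 0.22  ->  average accuracy 0.230  (sens 0.03, spec 0.38)
emic: k=1: 1.00, k=2: 1.00  ->  average accuracy 1.000  (sens 1.00, spec 1.00)
```

The planted dependence is symmetric about the driver's mean, so PCC
features contain no group signal and the classifier hovers at (here,
below) chance, while eMIC features separate the groups perfectly.
`examples/connectivity_measures.py` shows the same effect at the level of
a single pair — `PCC = +0.082, MIC = 0.678, eMIC = +0.671` for a coupled
pair versus `MIC = 0.166` for a null pair at T = 230 — and the other
example scripts cover cohort simulation, feature ranking/ROI extraction,
and the demographic statistics (e.g. sex tables 10/11 vs 10/6 vs 5/8 give
uncorrected chi-square p-values 0.368, 0.601, 0.198).

A full run with artifacts and a checksummed manifest:

```bash
nlfc run --config examples/config.yaml
```

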