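# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `nlfc`, in the order the pipeline runs them.

## Cohort model and preprocessing scope

A subject is an R×T matrix of region-averaged signal; a cohort attaches a
cognitive group (CN/MCI/dementia coded 1/2/3), an MMSE score, age and sex
to each subject.  Group codes derive from MMSE by the standard screening
cuts — 28–30 CN, 23–27 MCI, below 23 dementia — applied as inclusive
integer ranges; scores outside 0–30 are rejected.

Only two preprocessing steps are in scope, because everything upstream
(registration, slice timing, smoothing) is assumed done by standard
neuroimaging tooling: discarding the first volumes of a run (the
steady-state convention: 240 acquired → 230 retained at the default
10-volume discard) and parcellation averaging, the arithmetic mean of all
voxels sharing an atlas label at each time point.  Parcellation averaging
is linear by construction, which the suite asserts.

## Connectivity measures

**PCC.**  ρ = cov(X,Y)/(σ_X σ_Y) via `numpy.corrcoef`; the ratio is
normalisation-free.  Zero-variance input raises a `DegenerateSeriesError`;
the matrix assembler catches it, substitutes 0 and logs the region, so one
flat region cannot abort a cohort run.

**MIC.**  For series of length n, the resolution budget is
`B = max(floor(n^0.6), 4)` — the floor at 4 guarantees the smallest (2×2)
grid is always admissible, which a bare `floor(n^0.6)` does not below
n = 11.  For every grid shape (p columns, q rows) with p·q ≤ B, the
characteristic-matrix entry is the maximal grid mutual information
(base-2, so entries are exactly normalised by `log2 min(p,q)`) over grids
of that shape; MIC is the maximum entry.  The search fixes rows and
optimises columns exactly by dynamic programming over clump boundaries
(the objective is additive over columns), with these rules:

- cuts may fall only strictly between distinct data values, so tied values
  share a bin;
- at most `cmax`·(column budget) clumps are handed to the DP (adjacent
  clumps are merged proportionally); `cmax` defaults to 5;
- row partitions: when a shape admits at most 32 legal row partitions the
  search enumerates them all, making it exact for that shape (in
  particular for every n ≤ 12 fixture, where B = 4 allows only 2×2
  grids); otherwise it uses the single near-equal-frequency partition,
  the standard large-sample heuristic;
- both orientations are evaluated and merged cell-wise; the per-shape
  value is monotone in the allowed column count (a grid with ≤ p columns).

`brute_force_mic` enumerates every admissible grid for n ≤ 12 and is the
independent upper-bound oracle; the suite asserts dominance on random
fixtures and equality on monotone data (where MIC = 1 analytically).  The
DP kernels are numba-compiled; one pair at T = 230 costs ~0.7 ms, so a
50-subject, 20-region cohort's eMIC matrix set takes a few seconds.

**eMIC.**  `MIC − ρ²`, not clamped: finite-sample negatives (when ρ²
exceeds the MIC estimate) are retained and meaningful.  Diagonals are 1
for PCC/MIC and 0 for eMIC; they are never features, so the convention has
no downstream effect.

Null behaviour at T = 230: independent Gaussian pairs give median
MIC ≈ 0.20 and median |ρ| ≈ 0.05 (regression-tested), so planted effects
must clear ~0.2, not 0.

## Feature discrepancy and selection

Features are the R(R−1)/2 upper-triangle entries in row-major order
(`k = i·R − i(i+1)/2 + (j−i−1)`).  The cross-group Kendall statistic for a
contrast (lower group code first) counts, over all m·n cross-group subject
pairs, those whose feature ordering matches the group-code ordering minus
those opposing it, divided by m·n; ties count as neither but stay in the
denominator.  Positive τ therefore means "increases with impairment".
Ranking is by |τ| descending with ties broken by ascending feature index
(stable sort); selection keeps the top `ceil(fraction·N)` features
(fraction 0.01 by default: 67 of 6,670 at R = 116).  Significant ROIs are
the `top_k` (default 4) highest-degree nodes of the selected-edge graph,
ties again by ascending region index.

## Classification

A linear C-SVM (scikit-learn `SVC`, C = 1) under leave-one-out
cross-validation: for each held-out subject the Kendall ranking is
recomputed on the training subjects only, and for k = 1..K_max the SVM is
trained on the top-k training features and predicts the held-out subject
on those same features.  K_max defaults to the selection budget (2 at
R = 20; 67 at R = 116).  Accuracy per k is the fraction of correct
held-out predictions; sensitivity and specificity take the more-impaired
group as positive; all three are summarised as unweighted means over k.  A
decision value of exactly 0 resolves toward the positive class and is
logged.  Everything is deterministic for a fixed cohort and spec.

**Feature scaling.**  The library default is no scaling, matching common
SVM-toolkit defaults.  The benchmark protocol (`nlfc.benchmarks`) instead
z-scores features with training-fold statistics, and this matters:
small-range features (eMIC values span ~0.2) make the margin penalty of
any separating hyperplane exceed the slack cost of the majority-class
solution at C = 1, so the unscaled k = 1 SVM degenerates to majority
voting — which under leave-one-out on near-balanced groups is wrong almost
every time.  Z-scoring restores scale-invariance of the procedure; the
choice is recorded in every exported curve's metadata.

## Synthetic cohorts

Each region's base series is i.i.d. standard normal plus optional shared
latent factors (loading sd 0.5).  A coupling (i → j, transfer f, per-group
strength a_g) replaces region j by `a_g · z(f(z(base_i))) + ε`,
ε ~ N(0, noise_sd²), where z(·) is per-subject standardisation — applied to
the driver so strengths are comparable across transfers, and to the
transfer output so a_g is the signal amplitude against the noise floor.
Transfers: linear, quadratic, sine(πz), absolute value; all but the linear
one are (near-)orthogonal to a linear readout, which is what makes a
planted effect invisible to PCC but visible to MIC.  MMSE is uniform on
each group's defining range (dementia 16–22, matching a moderate-impairment
clinic mean of ~19); ages are group-wise normal (means 58.8/64.2/65.0, sds
8.8/11.0/13.3) and sex Bernoulli (female 10/21, 10/16, 5/13), so
demographic-table statistics can be exercised end to end.  Per-subject
strength jitter is available but defaults to 0.  Seeding uses
`SeedSequence.spawn`, so cohorts are bitwise reproducible and subjects are
independent streams.

Study conditions, chosen once: group sizes 21/16/13, T = 230, R = 20 for
benchmark cohorts; noise_sd 0.3; linear strength 0.9 and non-linear
strength 1.0; six coupled pairs (~3% of edges — a focal alteration);
per-group strength profile (s, 0, s/2) so the 1-vs-2 contrast carries the
full effect.  What the generator does *not* emulate: hemodynamics,
autocorrelated BOLD noise, motion, spatial structure, site effects, or
within-group heterogeneity of coupling topology.  Passing benchmarks
therefore show that the pipeline recovers the kinds of dependence it is
built for at realistic sample sizes and run lengths — not that real
cohorts of this size would classify this well.

## Benchmark calibration and a known bias

The planted-effect benchmark behaves as designed: with only non-linear
couplings distinguishing the contrasted groups, eMIC features classify
essentially perfectly while PCC features sit at or below chance; with a
linear separator planted instead, both feature sets exceed 0.9 average
accuracy (PCC through the correlation itself, eMIC through the ρ²
depression it induces).

The permuted-label null calibration deserves honesty: nested feature
selection inside leave-one-out is *pessimistically* biased under the null.
The selected features are exactly those on which the training groups
spuriously separate, the held-out subject regresses toward the overall
mean, and with balanced groups the prediction is wrong slightly more than
half the time.  At the benchmark conditions (20 replicates of 10+10
subjects, R = 20, T = 230) the long-run mean accuracy is ≈ 0.45, sitting
at the lower edge of the binomial 95% band for 400 pooled predictions;
individual 20-replicate means scatter roughly 0.37–0.53 because fold
predictions are correlated, so the pooled-binomial band is
anti-conservative.  The calibration check is kept in its standard form,
but a mean a few points below 0.5 is expected behaviour of the procedure,
not leakage — leakage would bias it *above* chance, and the dedicated
sentinel-feature test shows none.

## Statistics

Sex distributions use the uncorrected Pearson chi-square on 2×2 counts
(1 d.f.); the uncorrected form is deliberate and regression-tested against
the canonical 21/16/13 cohort tables (p = 0.368, 0.601, 0.198).
Continuous demographics use the two-sample t-test, pooled variant by
default with Welch available; printed summary statistics generally cannot
be inverted to recover exact p-values, so none are asserted.  FC–MMSE
association is the Pearson correlation across subjects with the two-sided
t-based p-value (n−2 d.f.) and a strict p < 0.05 significance flag; no
multiple-testing correction is applied across selected features, matching
the exploratory character of the association tables.

## Numerical and interface choices

Base-2 logarithms throughout the information-theoretic code (the base
cancels in MIC but fixes bit-exact tests); 0·log 0 ≡ 0; mutual information
clamped at 0 against float error.  All artifacts are plain text (TSV
matrices, CSV tables, JSON manifests) written with round-trip-exact float
formatting, and the pipeline manifest checksums every artifact so a run is
verifiable byte-for-byte from config + seed.  Per-subject FC computation
may be distributed with joblib; results are independent of worker count
(tested).
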