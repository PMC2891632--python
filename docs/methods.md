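# Methods

## The index and what it claims

The Shields index summarises three histological measurements of a
primary cutaneous melanoma into a single prognostic score for
metastasis within five years of excision:

    index = LVD^2 x invasion x thickness

- **LVD** — epi-tumoural lymphatic vessel density, vessels/mm²,
  counted in a 350 µm border around the tumour (the *total* variant)
  or in the three subjectively densest regions (*hot-spot* variant).
  LVD is squared because it is the component most strongly associated
  with metastasis.
- **invasion** — 2 if tumour cells are seen inside a lymphatic vessel
  (LVI), 1 otherwise.
- **thickness** — Breslow thickness in mm.

The index is analysed on the log10 scale, where the validation cohort
separates into group means of 2.43 (metastatic) versus 1.77
(non-metastatic), and thresholded at **2.1** (strict exceedance) for
binary prediction. The raw index is treated as a unitless score; a
zero index (only possible at LVD = 0) has an undefined log and is
always classified negative and ranked lowest.

## Cohort model and inclusion criteria

Patients enter analysis if they were clear of metastases at excision,
invasive (not in situ), non-ulcerated, with Breslow thickness < 8 mm
and an assessable LVD; non-metastatic patients must additionally carry
more than 60 months of follow-up, since a "control" is only a control
if metastasis had five years to appear (cases qualify by their event —
the validation cohort's cases average 53 months of follow-up, below
the control threshold). Thickness exactly 8.0 mm is excluded (the
strict `< 8 mm` reading of the inclusion rule). Each excluded record
is tallied once under the first matching reason in the fixed order
*metastatic at excision → in situ → thickness → ulceration →
follow-up → missing LVD*; the source descriptions list exclusions
without precedence, and a fixed order makes tallies deterministic and
the filter idempotent.

## Synthetic cohorts

No patient-level data from the validation registry are deposited, so
the generator emulates the cohort's *published group structure*:

| component | model | metastatic | non-metastatic |
|---|---|---|---|
| LVD (vessels/mm²) | Gamma, moment-matched | 10.24 (5.54) | 6.52 (3.82) |
| LVI | Bernoulli | 38/45 | 26/57 |
| thickness (mm) | Gamma, resampled if ≥ 8 | 2.36 (1.55) | 1.93 (1.37) |
| follow-up (months) | Normal, truncated at 0 | 53 (36) | 92 (36) |
| n | — | 45 | 57 |

Gamma marginals were chosen because dermal LVD is reported as
non-negative and right-skewed ("Poisson-like", reference dermis mean
10.6 ± 0.67 mm⁻², range 0–25.1), and because the choice is
independently checkable: under independent components,
E[log₁₀ index] = 2·E[log₁₀ LVD] + p·log₁₀2 + E[log₁₀ T] with
E[log X] = ψ(k) + ln θ for a Gamma(k, θ). The defaults give 2.414 /
1.776 against the published 2.43 / 1.77 — agreement to ~0.02 that was
computed from the closed form before any simulation.

Components are independent within a patient by default; the joint
distribution is not published. Independence implies log-index SDs of
~0.61/0.67, slightly above the published 0.50/0.62, i.e. the real data
carry mild negative dependence. A Gaussian-copula knob
(`component_rho`, common pairwise correlation of LVD, thickness and
the latent invasion propensity) is available for sensitivity analyses
and defaults to 0; it cannot move the mean log index, which is a sum
of marginal expectations.

Other generator choices:

- **Draw order is fixed** per patient (LVD, LVI, thickness, follow-up,
  hot-spot noise), so a seed identifies a cohort exactly; the same
  config + seed reproduces byte-identical CSVs.
- **Thickness ≥ 8 mm is resampled**, not clipped, to respect the
  inclusion bound without a point mass at 8 (rejected mass < 1%).
- **Control follow-up** below 60 months is reflected about 60 so every
  generated record passes the inclusion filter; this distorts the
  control follow-up distribution's lower tail, which no downstream
  statistic uses.
- **Hot-spot LVD** = 0.8 × LVD + N(0, 4.0²), floored at 0. The noise
  SD was solved from r² = a²Var(L)/(a²Var(L)+σ²) with the pooled
  two-group LVD variance (≈ 25.1), so total and hot-spot LVD share
  ≈ 50% of variance, the correlation level reported for the two
  counting methods.
- **SLNB subgroup** (10 biopsy-positive / 8 biopsy-negative): LVI
  counts are fixed at 8/10 vs 3/8 and arm LVD means pinned at 8.2 and
  4.9 vessels/mm² by a multiplicative rescale of Gamma draws —
  with n = 10 the published arm means are a design property of the
  fixture, not something to be left to sampling noise. Thickness is
  matched across arms by reusing draws.

What passing tests on these cohorts do **not** show: the generator has
independent (or exchangeably correlated) components, exact Gamma
marginals, no measurement error in LVD beyond the hot-spot noise term,
and a binary outcome fixed by group membership. Real registry data
have unknown dependence, observer variation in vessel counting, and
censoring; empirical AUCs on real cohorts need not match the
synthetic ones.

## Discrimination statistics

- **AUC** is the Mann–Whitney probability
  [#(case > control) + ½·#(ties)] / (n₁n₀), computed by midranks;
  it equals the trapezoidal area under the empirical ROC curve
  (property-tested against exhaustive pair counting). ROC thresholds
  call a patient positive iff score > t and carry ±∞ sentinels.
- **Hanley–McNeil SE**: SE² = [A(1−A) + (n₁−1)(Q₁−A²) + (n₀−1)(Q₂−A²)]
  / (n₁n₀) with Q₁ = A/(2−A) paired with the case count and
  Q₂ = 2A²/(1+A) with the control count; 95% CI = A ± 1.96·SE, clipped
  to [0, 1]. At (0.82, 45, 57) this gives (0.735, 0.905); at
  (0.70, 45, 57), (0.596, 0.804).
- **Correlated AUC comparison** (two markers on the same patients):
  z = (A_a − A_b)/√(SE_a² + SE_b² − 2r·SE_a·SE_b) with r the mean of
  the within-case and within-control Pearson correlations of the two
  score vectors, used directly — the historical table-lookup
  refinement of r is skipped. The simplification is bounded by a test:
  over 500 replicates of both a null and an unequal-AUC scenario the
  rejection rate agrees with a DeLong-covariance oracle within 5
  points. Identical or shift-equivalent scores give z = 0, p = 1 by
  convention; sentinel (±inf) scores are dropped from the r estimate
  only.
- **Cutoff selection**: sensitivity (non-increasing in t) and
  specificity (non-decreasing) are stepped over the distinct scores;
  the intersection cutoff interpolates linearly between the adjacent
  grid points where sens − spec changes sign, or sits on the grid
  point where they are equal.
- **Proportion CIs** are exact Clopper–Pearson by default (the
  design-stage interval for 90% sensitivity from 45 cases, i.e. 40/45
  successes after flooring, is 75.9%–96.3% → the quoted 76%–96%;
  Wilson, available by flag, gives 78%–96% and was therefore not the
  convention used). Confusion matrices at a cutoff use strict
  exceedance and attach Clopper–Pearson CIs.

## Association statistics

- **Odds ratio**: cross-product (ad)/(bc) with the Woolf log-scale
  Wald CI, SE = √(1/a+1/b+1/c+1/d), which reproduces the published
  invasion OR 6.47 (2.48, 16.90) exactly; zero cells raise unless the
  Haldane–Anscombe +0.5 correction is requested. Exact conditional
  CIs are out of scope.
- **Fisher exact (two-sided)**: sum of hypergeometric point
  probabilities ≤ the observed one (relative tolerance ~1e−7). This
  convention — not doubling the one-sided p — reproduces the published
  SLNB invasion p = 0.145 and matches a full enumeration oracle on
  every table with n ≤ 12.
- **Logistic regression** (univariable, IRLS/Newton): convergence at
  max|score| < 1e−8 or relative log-likelihood change < 1e−10, at most
  50 iterations. Perfect separation is flagged non-converged with NaN
  estimates rather than returning a divergent slope; near-separation
  (finite slope, enormous Wald SE) saturates the CI at infinity. On a
  binary covariate the fitted OR equals the 2×2 cross-product OR to
  1e−6. Wald CIs throughout (profile likelihood not offered): the
  published CI style is Wald-consistent.
- **t tests** default to Student's pooled-variance form (the source
  analyses say "unpaired t test" without a Welch qualifier); Welch by
  flag. Degenerate zero-variance inputs raise rather than returning
  NaN.

## Pipeline and reproducibility

`run_full_analysis` chains load/simulate → inclusion filter → scoring
→ associations → per-marker ROC/AUC with comparisons against the
Shields index → cutoff report, and writes a manifest (config, seed,
version, counts) sufficient to re-run the bundle bit-identically.
Markers without data (hot-spot LVD, AJCC stage) are skipped and named
in the manifest. Full precision is written alongside 2-dp display
fields; nothing hardware- or time-dependent enters any output.

Problem sizes used by the test suite and the acceptance script: exact
contingency/CI checks are O(1); large-sample consistency uses one
shared cohort of 10⁵ patients per group; replicate-based checks use
200 replicates (binormal AUC, logistic slope recovery) or 500
(correlated-AUC calibration at n = 102).

## Known limitations

- The generator targets first and second moments and invasion
  frequency; it does not model covariance between components, age,
  Clark level or AJCC stage (the reference config leaves those fields
  empty, so the AJCC ROC only appears for cohorts that supply them).
- The Hanley 95% CI for AUC 0.82 with 45/57 patients has upper bound
  0.9053, which rounds to 0.91; published intervals computed from
  unrounded AUCs can differ in the last printed digit.
- The correlated-AUC z test inherits the normal approximation; for
  very small groups (< ~20 per arm) the DeLong construction is the
  safer choice, and the test suite's oracle shows where they part.
- Binary five-year outcome only; no censoring or time-to-event
  modelling.
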