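# Methods

## The question and the estimator

Systematic reviews that restrict their searches or eligibility to English
may suffer *language bias*: trials published in other languages tend to be
smaller, more often "positive", and systematically different in effect
size. This package estimates the average impact of including non-English
trials on meta-analytic effect estimates, treating meta-analyses — not
trials — as the units of analysis.

The effect measure is the standardized mean difference (SMD). For an
arm-level trial with means m₁, m₂, SDs s₁, s₂ and sizes n₁, n₂:

    g = J · (m₁ − m₂) / s_p,   s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2),
    J = 1 − 3/(4(n₁+n₂−2) − 1),
    Var(g) = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)).

J is the usual small-sample (Hedges) correction; `correct=False` gives the
uncorrected Cohen's d for sensitivity. Contrast-level rows (an SMD with
its standard error, as read off a forest plot) enter verbatim with
v = se². Which SMD variant each source review used is unknowable per
review; we default to the corrected form, the convention of mainstream
meta-analysis software. The sign convention is arm 1 minus arm 2 and is
the caller's responsibility to keep consistent within a meta-analysis.

### Stage 1 — ΔSMD within each meta-analysis

Within meta-analysis j, trial effects yᵢ with variances vᵢ follow

    yᵢ ~ N(β₀ + δⱼ·Lᵢ, vᵢ + τⱼ²),

with Lᵢ = 1 for non-English trials. Weighted least squares with weights
1/(vᵢ + τ̂ⱼ²) gives δ̂ⱼ (the meta-analysis's ΔSMD) and its variance from
(XᵀWX)⁻¹. Negative ΔSMD means non-English trials yield a larger effect in
the direction the source review reported. Outcome directions are *not*
harmonized across meta-analyses — each ΔSMD lives on the scale of its own
forest plot; users who want a common direction can flip trial signs per
meta-analysis before entry.

τ² is estimated by REML (default): a bounded scalar maximization of the
restricted log-likelihood over τ² ∈ [0, 100], absolute tolerance 1e-8,
deterministic, with an explicit boundary comparison at τ² = 0. The
DerSimonian–Laird moment estimator is available as an option and, under a
moderator design, generalizes to the residual-moment form
τ̂² = max(0, (Q_E − (k − p))/tr(P)). The model is the single additive-τ²
(study-level) random-effects structure; no extra clustering levels for
multi-arm trials are modeled (one effect row per trial is assumed).

### Stage 2 — pooling ΔSMDs

The δ̂ⱼ are pooled by inverse-variance meta-analysis: random-effects with
between-meta-analysis variance κ² (REML by default, DL optional), and a
fixed-effect model (κ² ≡ 0) as a sensitivity analysis. Confidence
intervals use normal quantiles; the Knapp–Hartung adjustment is available
behind a flag but off by default, matching conventional software output.
With substantial κ², the random-effects interval is materially wider than
the fixed-effect one — the configuration in which a fixed-effect
"significance" is spurious.

Eligibility and the one-per-review rule: a review contributes its first
primary-outcome meta-analysis with ≥ 3 trials including ≥ 1 non-English;
failing that, its first such secondary-outcome meta-analysis; otherwise
nothing. A trial contributing several rows counts once toward these
thresholds (a conservative reading). Only one meta-analysis per review is
ever pooled, so stage-2 units are independent reviews.

### Subset sensitivity

For each selected meta-analysis the summary SMD and heterogeneity are
recomputed on all trials and on the English-only subset (requiring ≥ 2
English trials, else flagged unavailable). This reproduces the two
standard displays: the precision gained by including non-English trials,
and the change in between-study SD when they are removed.

## The association model (review level)

Whether a review includes any non-English study is modeled by multivariable
logistic regression on its characteristics: author-count band, continent of
first author, Cochrane status, publication year (centered on the cohort
mean), PROSPERO registration, number of included studies, search precision
(logit scale), language restriction, explicit exclusion of non-English
studies, librarian involvement, meta-analysis conduct, review type and
study type. Categories are dummy-coded against the reference levels of the
cohort table; no variable selection is performed. Search precision is
included studies over deduplicated search records; an exact 1.0 is clamped
to 1 − 1e-6 before the logit with a logged warning. Missing precision or
restriction status drops the row from the regression (complete case) while
descriptives keep all rows; unused-level (constant) dummy columns are
dropped with a logged note.

Because some characteristics separate the outcome completely (e.g. every
review that explicitly excluded non-English studies includes none),
ordinary maximum likelihood diverges. We therefore maximize the
Jeffreys-prior penalized likelihood (Firth):

    l*(β) = l(β) + ½ log det(XᵀWX),   W = diag(πᵢ(1−πᵢ)),

by modified Fisher scoring with hat-value–adjusted responses
(residual yᵢ − πᵢ + hᵢ(½ − πᵢ)), safeguarded by step-halving and a
per-iteration step cap of 5 on the log-odds scale. Convergence requires
max |score| < 1e-6 and step norm < 1e-8; the iteration cap is 300 because
the scoring recursion contracts only linearly near quasi-separation.
Inference is by the profile penalized likelihood: confidence bounds solve
2[l*(β̂) − l*_profile(βⱼ)] = χ²₁ quantile by bracketed bisection
(tolerance 1e-6), with the inner maximization re-run at each fixed βⱼ
(falling back to a derivative-free polish where the information matrix
flattens); a bound is infinite only if the profile never crosses the
threshold within ±50 log-odds. P-values come from the same penalized
likelihood-ratio statistic, so p < α exactly when the (1−α) CI excludes
zero. Plain-MLE mode (penalty off, Wald inference) backs the univariate
2×2 analysis, where the slope odds ratio equals the cross-product ratio of
the table identically.

## The synthetic-data generator

The original row-level data are not deposited, so the generator emulates
the structure the analysis assumes.

Trial tables: for meta-analysis k, a true effect θₖ ~ N(0.3, 0.3²), a
language-bias effect bₖ ~ N(δ, κ²) with defaults δ = −0.3 (the magnitude
of the reported average bias) and κ = 0.1; trial i's true effect is
θₖ + bₖLᵢ + N(0, τ²) with τ = 0.3 (substantial within-meta-analysis
heterogeneity). Each trial's two arms have sizes drawn from 15–60 and a
common outcome SD σ = 1, so the true SMD equals the mean difference; arm
summaries are drawn from their exact sampling distributions (normal means,
χ² variances). Language labels are Bernoulli(0.25), resampled wholesale
until both groups are present — the regression needs an estimable contrast
and resampling (rather than flipping a fixed trial) keeps labels
exchangeable. Trials per meta-analysis are uniform on 3–12; K defaults to
200 meta-analyses, the scale used for the recovery and calibration
studies. What the generator does *not* emulate: publication-bias and
small-study-effect mechanisms, outcome-direction heterogeneity across
meta-analyses, correlated multi-arm trials, and non-normal outcomes — so
passing recovery tests demonstrate internal consistency of the estimator
under its assumed model, not robustness to those violations.

Review tables: characteristics drawn from the cohort's marginal
frequencies; the inclusion response follows a logistic model whose default
reproduces the dominant association (a language restriction multiplies the
odds by 0.11) around a baseline of about 30%; `force_separation` makes the
explicit-exclusion level perfectly predict non-inclusion to exercise the
penalized fitter.

The deterministic 174-row fixture reproduces every categorical count of
the cohort table, overall and split by non-English inclusion, plus the
footnoted missingness (one review without precision and language count,
six without restriction status), the medians/IQRs/ranges of the metric
columns, 2568 included studies in total, and 98 non-English studies among
them. Within those margins the joint structure is arbitrary: each field is
independently permuted with fixed seeds. One printed value is numerically
unattainable (a subgroup Q3 of 16.50 from 129 integers at an exact type-7
order statistic) and is resolved to 16. The fixture is a synthetic
stand-in, not the original data.

## Numerical choices and degenerate inputs

- Quartiles: type-7 (linear interpolation), so IQR outputs are
  deterministic and match NumPy defaults.
- Identical effects: Q = 0 and I² is defined as 0 (0/0 guarded).
- τ² estimates are truncated at zero; the REML search is seedless.
- Percentages in summary tables are rounded to integers; denominators
  exclude missing values (matching footnoted tables). Full precision is
  retained internally and in CSV outputs.
- Empty result tables are an error, never an empty file; readers validate
  every domain invariant and never coerce silently.

## Simulation-study sizes

The recovery study uses 500 replicates of K = 200 meta-analyses (point
recovery of δ within ±0.05 and 95% CI coverage); the null-calibration
study uses 1000 replicates with δ = κ = 0 and checks the fixed-effect
stage-2 test's size at α = 0.05. These sizes give Monte-Carlo standard
errors of about 0.001 on the pooled mean and under 0.01 on the rejection
rate.

## Known limitations

- The stage-1 normal approximation treats each trial's sampling variance
  as known; with very small trials this understates uncertainty slightly.
- Plug-in τ² weights make stage-1 ΔSMD standard errors too small when a
  meta-analysis contains only a handful of trials (the standardized
  estimates are noticeably heavier-tailed than normal at 3–12 trials).
  The downstream fixed-effect stage-2 test consequently rejects a true
  null more often than its nominal 5% — the null-calibration test in the
  suite measures this inflation rather than hiding it. Supplying the true
  τ² restores exact calibration, which localizes the effect to τ²
  estimation, not the pooling algebra. This is a property of the
  prescribed procedure (normal-theory meta-regression inference), shared
  by the standard software it mirrors.
- ΔSMDs are pooled as extracted; without direction harmonization the sign
  of the pooled bias is interpretable only under the reviews' own
  reporting conventions.
- The association model's profile intervals assume the χ²₁ calibration of
  the penalized likelihood ratio, which is asymptotic; with 174 reviews
  and 18 parameters it is an approximation, the standard one for this
  estimator.
- The univariate 2×2 odds ratio uses Wald inference on four cells; with
  cells this small the interval is fragile, which is why the multivariable
  analysis relies on profile penalized likelihood instead.
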