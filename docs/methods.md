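# Methods

## Data model

A coded trial is a YAML document: citation, workflow status, coding items
drawn from controlled vocabularies, arms, measures, and numeric cells
(n, mean, SD per arm × measure × time point × subgroup). The item catalogue
is itself data (`src/cotmeta/data/item_catalogue.yaml`): items, allowed
codes, multi-select flags, and which items are required before a coding
counts as complete. Extending the extraction form is a config edit, not a
code change.

Statuses move along `queued → in_progress → requirements_met →
{revisions_required → in_progress, verified}`; `verified` is terminal and
`requirements_met` can only be entered on a clean validation. A standard
deviation may be *absent* (`sd: null`) — that is "not reported", which loads
fine and triggers automatic exclusion from any analysis needing it — whereas
`sd: 0` is a schema violation and rejects the file. Baseline cells may be
stored but effects are computed per post-intervention time point only;
change-from-baseline effects are out of scope.

## Effect estimates

Hedges' g with the J small-sample correction; the variance uses the
uncorrected d² in its second term under a J² prefactor (one of the textbook
variants; the oracle tests pin this choice). Sign convention: positive
favors the experimental condition, with `lower_better` scales flipped at
computation time — the `direction` field is therefore required on every
measure. Single-study CIs use the normal 1.96 multiplier; the t-based HKSJ
correction applies only at the pooled level.

**Subgroups.** A study reporting only disjoint subgroups contributes their
inverse-variance fixed-effect combination (whole-sample cells are preferred
when both are present).

**Multi-arm studies.** With several experimental arms sharing a control,
comparisons are correlated. Each comparison's variance is replaced by
v\*ₖ = 1/(Σ⁻¹1)ₖ, where Σ is the comparison covariance matrix; then a naive
inverse-variance fixed-effect pool of the adjusted comparisons reproduces
the GLS estimate and variance under Σ exactly. The covariance between two
comparisons sharing their control arm is taken as

    cov = J_k J_l [ 1/n_shared + d_k d_l / (2 (n_k + n_l + n_shared − 2)) ]

— the shared arm's sampling contribution plus the pooled-SD correction with
degrees of freedom over all participants entering either comparison. The
precise covariance convention for SMDs varies across the literature; the
binding contract here is GLS equivalence, which a direct linear-algebra
oracle checks to 1e−8 on random 3–4-arm trials. Experimental-vs-experimental
contrasts are computed and reported but never pooled against controls, which
would break the "positive favors experimental" semantics. When several
control arms carry data, comparisons are adjusted within each shared-control
block; covariance between blocks (via a shared experimental arm) is ignored
— a known limitation.

**Correlated outcomes.** Related measures on the same participants combine
as a composite: g\* is the plain mean and
var\* = (1/m²)[Σvᵢ + Σ_{i≠j} r√(vᵢvⱼ)], with r defaulting to 0.50 when the
true between-measure correlation is unknown. Variance is monotone in r:
r = 0 recovers the independent-average limit v/m, r → 1 gives no precision
gain. When both apply, the multi-arm adjustment runs first (per measure),
then the correlated-outcome combination across measures.

## Meta-analysis

Random-effects model y_i ~ N(μ + u_i, v_i), u_i ~ N(0, τ²).

- **τ² by REML**: bounded scalar maximization of the restricted
  log-likelihood on [0, 10·(max v + var(y))] with xatol 1e−10, with the
  boundary τ² = 0 compared explicitly against the interior optimum. The test
  suite checks 100 random fixtures against a two-stage grid search of the
  same restricted likelihood (10⁵ coarse points on [0, 2], then 10⁵ points
  around the coarse argmax) to 1e−6, and cross-checks τ², μ̂, the HKSJ SE
  and CI against R's `metafor` (`rma(method="REML", test="knha")`).
- **HKSJ interval**: weights wᵢ = 1/(vᵢ + τ²), μ̂ the weighted mean,
  se² = [Σwᵢ(yᵢ − μ̂)²/(k−1)]/Σwᵢ, CI via t(k−1). Plain HKSJ without a
  variance floor: with zero observed dispersion the CI degenerates to a
  point. That is documented behavior, not an error.
- **Heterogeneity**: Q against χ²(k−1), flagged significant at p < 0.10
  (metadata only — never a gate on pooling); I² = max(0, 100(Q−(k−1))/Q),
  invariant to rescaling all (y, √v) by a common factor.
- **Prediction interval**: μ̂ ± t_{k−2,0.975}·√(τ² + se²), reported for
  k ≥ 3. The k−2 degrees of freedom are the default; k−1 is available via
  `pi_df_convention`.
- **Eligibility**: studies lacking means/SDs are excluded with a logged
  reason; groups need ≥ `min_k` (default 3) studies. `n_total` counts each
  participant once per study (n_exp + n_ctl at the analyzed time point),
  with the shared control counted once in multi-arm studies.

## Quality scoring

Each PEDro/Jadad item and each RoB domain is a small predicate over the
coding (`any_of` leaves combined with `all`/`any`/`not`), shipped as YAML.
PEDro scores items 2–11 (eligibility is recorded, not counted) with the
published >85% retention cut-off; Jadad is the additive 5-point form
(randomized mentioned / method appropriate / double-blind described /
blinding appropriate / withdrawals described); RoB rates each of seven
domains low when its low-predicate fires, high when the high-predicate
fires, else unclear. Missing items evaluate false, so incomplete codings
degrade monotonically toward unsatisfied/unclear — never toward
satisfied/low — and nothing is imputed.

## Certainty grading and recommendations

Three components: mean PEDro of contributing studies (≥7 favorable, 4–6
intermediate, <4 unfavorable), I² (<30% / 30–60% / >60%), and total
participants (≥400 / 100–399 / <100). Level: high iff all favorable; low if
quality is unfavorable or ≥2 components are; else moderate. These cut-offs
are a declared rule set held in `src/cotmeta/data/grading.yaml` so a
recalibrated scheme drops in without code changes. Significance means the
HKSJ CI excludes zero (not p_Q, not a normal-theory CI). Recommendations:
high → strong, moderate → modest, low → none; direction follows the sign of
μ̂; a CI covering zero blocks any recommendation. Narrative magnitude bands
are the conventional |g| < 0.2 / 0.5 / 0.8 cuts.

## Interpretation statistics

Under two unit-variance normal distributions separated by g: U3 = 100·Φ(g);
overlap = 100·2·Φ(−|g|/2) (the overlapping coefficient — the convention that
yields 80% at g = 0.5); probability of superiority = 100·Φ(g/√2), verified
against a 10⁶-pair Monte-Carlo simulation. Narrative percentages round
half-up to integers; tables keep full precision. At g = 0.50 the triple is
(69, 80, 64).

## Synthetic repositories

The generator draws per-study true effects θᵢ ~ N(true_mu, tau2_true);
control populations are standardized (mean 0, SD 1) so θᵢ is directly the
standardized effect. Arm summaries come from their exact sampling
distributions (mean ~ N(μ, 1/n); SD ~ √(χ²(n−1)/(n−1))) rather than
simulated participants — faster and distributionally identical under
normality. Defaults define the simulated study conditions: 20–60 per arm
(typical for COT trials), 20% multi-arm studies (second experimental arm
with the same θᵢ), 15% subgroup-only reporting, 10% missing-SD studies,
two correlated measures per outcome domain at latent r = 0.50 (matching the
analysis default), and a 40/40/20 mix of ideal/moderate/poor coding
profiles. Repositories are byte-reproducible from the seed and ship a
ground-truth sidecar.

`recovery_report` runs the Monte-Carlo calibration (bias and RMSE of μ̂,
bias of τ̂², empirical HKSJ coverage). It draws per-study summaries through
the same sampling kernel as the repository generator for plain two-arm
studies, skipping file I/O so the 9-cell × 1000-replicate grid at k = 20
finishes in seconds; a separate end-to-end test pushes 300 full generated
repositories through `run_meta` and checks CI coverage there too. What
passing shows: the pipeline is calibrated *under its own generative
assumptions* (normal outcomes, reported post scores, ignorable
missingness). Real trial data violate these in ways the generator does not
emulate — non-normal scales, floor/ceiling effects, selective reporting
correlated with results, pre-post correlations — so calibration here is
necessary, not sufficient, evidence for real-world coverage.

## Numerical conventions and edge cases

- REML convergence: |Δτ²| below 1e−8 at the optimizer's tolerance; τ̂² = 0
  returned whenever the boundary likelihood dominates.
- Zero-dispersion groups: HKSJ se = 0 and a degenerate CI (see above).
- Q = 0 (or ≤ k−1): I² = 0 by definition; p_Q = 1 at Q = 0.
- Covariance matrices are validated for positive semidefiniteness (tol
  1e−10); non-positive adjusted weights abort the multi-arm adjustment with
  an error rather than returning a meaningless pool.
- Report content is deterministic given inputs and config; timestamps live
  only in the run manifest, never in section content.

## Known limitations

No network meta-analysis, meta-regression, or publication-bias diagnostics;
no change-from-baseline effects or pre-post correlations; no
cluster-randomization variance corrections; RoB is the first-version tool,
not RoB 2.0. The quality-scoring rule tables implement the published scale
definitions but have not been calibrated against human raters; treat
inter-rater agreement as an open calibration exercise.
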