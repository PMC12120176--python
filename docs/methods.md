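# Methods

## Scope and truth model

The package calibrates continuous computational scores for missense
variants into ACMG/AMP PP3/BP4 evidence using MAVE functional classes as
truth proxies. Classes are fixed by MAVE score cutoffs: FUNC above −0.748,
LoF below −1.328, INT between. The published cutoffs are strict
inequalities, leaving the boundary scores undefined; we assign boundary
values to INT, the conservative class that never contributes evidence.
Likewise RSA bin boundaries (30%, 60%) go to the partially-buried bin,
matching the closed interval in the binning definition. One source
describes buried residues as RSA < 30% in its methods but RSA ≤ 30% in its
results; we use the strict form (< 30) everywhere, configurable through
`RsaBinning`.

INT variants are excluded from calibration (`build_analysis_cohort`)
because partial functional impairment has no established disease
association; all LR estimates are therefore conditional on a variant being
either clearly functional or clearly non-functional.

## Likelihood ratios and evidence strength

For a three-zone split of a tool's score range, each evidence zone carries
LR = (x₁/n₁)/(x₂/n₂) with x₁/n₁ the LoF-class proportion and x₂/n₂ the
FUNC-class proportion in the zone. Confidence intervals use the standard
asymptotic interval for a ratio of binomial proportions on the log scale
(Simel-type): ln LR ± z·sqrt((1−p₁)/x₁ + (1−p₂)/x₂), reported in log₂. The
original analyses cite only an external web calculator for these intervals;
we adopted the asymptotic form because it reproduces the published interval
for the AlphaMissense pathogenicity zone (+2.578 to +3.042) to within 0.002
per bound from the reconstructed counts.

Zero cells receive the Haldane–Anscombe +0.5 correction on all four counts,
with a `corrected` flag; a zone empty in *both* classes is an error for
single-tool evaluation (there is nothing to estimate) but is continuity-
corrected (and flagged) in concordance and cascade settings where empty
categories are structural rather than exceptional.

log₂ LR maps to the ACMG point scale by snapping |log₂ LR| to the nearest
member of {1, 2, 4, 8} (Supporting/Moderate/Strong/Very Strong), ties to
the lower tier, signed by the LR direction; |log₂ LR| < 0.5 — below the
rounding basin of one point — yields no evidence. Intermediate point
values (3, 5–7) are intentionally not emitted: the evidence scheme names
only the four tiers. Note one published footnote labels an AM ≤ 0.34 zone
(log₂ LR = −4.603) "very strong" benignity while the nearest-point rule
gives Strong; we surface the nearest-point result and do not resolve the
inconsistency.

An optional `require_ci_excludes_null` gate demotes any evidence whose CI
spans log₂ LR = 0 to "no evidence"; it is always on inside the threshold
search and the cascade leaf calibration.

## Threshold search

The published threshold choice is described only as a trade-off iteration
maximising evidence strength while minimising the uninformative fraction.
We implement it as exhaustive grid search over all ordered threshold pairs
(t_b ≤ t_p), with constraints (minimum |log₂ LR| on each side, CI excluding
the null, maximum gray fraction) and return the Pareto front under
(max min-side |log₂ LR|, min gray fraction), ranked by achieved strength
tier then gray fraction. The CLI default grid is the empirical score
quantiles plus the configured default thresholds for the tool.

## Stratification, concordance, cascade

Stratified evaluation requires strata that partition the cohort; strata
with fewer than two variants in either class are flagged, not errored, and
sides whose CI spans 0 are flagged as non-significant. Collapsing strata
recovers the unstratified LR exactly (the counts are additive).

Tool-pair concordance treats only both-pathogenic and both-benign calls as
evidence categories; discordant pairs or any gray call are uninformative.
This follows the empirical observation that score-discordant variants show
no case-control risk signal.

The cascade is a depth-≤ 4 binary decision tree over record fields (RSA,
tool scores), fully config-driven and JSON-serialisable. The published
cascade's exact cutpoints are in supplementary material we do not have; the
default tree uses the main-text zones (RSA 30/60, AM 0.65/0.75, ΔΔG
+1.5/+2.5 kcal/mol) and reproduces the *structure*: buried/partially buried
branches can reach Strong concordant evidence on both sides, exposed
branches carry pathogenicity evidence only. Leaf LRs are estimated on the
calibration cohort being assigned; leaves whose CI spans 0 are demoted to
GRAY (idempotently), and variants missing a routed field are assigned GRAY
and counted.

## Discrimination and diagnostics

auROC is the Mann–Whitney probability computed from midranks (ties count
half); the ROC curve itself comes from scikit-learn. Tool comparison is a
paired, class-stratified bootstrap of the auROC difference with a two-sided
normal p-value on the observed difference normalised by the bootstrap SD
(10,000 replicates by default). The exact bootstrap statistic used by the
original pROC-based analysis may differ slightly; this implementation is
labelled as what it is.

The rank-sum test enumerates all label assignments exactly when both
samples have n ≤ 10 (midranks make this valid under ties) and otherwise
uses the tie-corrected normal approximation.

Diagnostic 2×2 metrics are percents with 95% CIs: Clopper–Pearson exact for
sensitivity, specificity and accuracy; for PPV/NPV the default is the
Mercaldo-style logit interval that propagates the sensitivity/specificity
variances through the predictive-value formula at the observed prevalence —
chosen because it reproduces the published PPV interval (63.0–70.1 for
284/426) where a naive logit or exact interval does not. Exact and Wilson
alternatives are selectable.

## Burden analysis

Per-stratum association uses the carrier-vs-noncarrier 2×2: OR = ad/bc,
Woolf CI (ln OR ± z·sqrt(1/a+1/b+1/c+1/d)), two-sided Fisher exact p, and
Haldane correction (flagged) on zero cells. This construction reproduces
every published OR/CI in the validation table to rounding (e.g. 4.69,
2.83–7.77 vs printed 2.83–7.76; 4.356 vs printed truncated 4.35), so it is
adopted as the default; covariate-adjusted logistic regression is out of
scope. The published carrier counts (53,572 cases / 48,048 controls) ship
as `BRIDGES_CARRIER_COUNTS` and are real published tallies, not synthetic
data. One published intermediate-zone p-value prints as 1.08, which is
impossible; we treat it as a typo and never consume p-values as inputs.

## Synthetic data generator

`generate_mave_cohort` draws, per variant: an RSA bin (fractions 879/331/428
out of 1,638), uniform RSA within the bin (exposed capped at 120% —
normalised accessibility can exceed 100%), impairment conditional on the
bin (42%/16%/7%), LoF vs INT within impaired preserving the global 337:119
ratio, a domain label (536:1102 split, independent of everything else), a
MAVE score from a class-respecting truncated normal (FUNC: N(0, 0.35)
truncated above −0.748; LoF: N(−2.2, 0.5) truncated below −1.328; INT:
uniform between the cutoffs), and one score per configured tool.

Published sources give class-conditional *means* only, not spreads. Default
score models are: ΔΔG tools as truncated normals (floor −5 kcal/mol) at the
published class means with scales 2.9 (AlphaFold templates) / 3.2 (PDB
templates); the AlphaMissense-like tool as a logit-normal with class
locations 2.2/0.4/−1.1 and scale 1.6; the meta-predictor as a truncated
normal at 0.50/0.28/0.05 with scale 0.25 on [−1.3, 1]. Scales were fixed
once so that the class overlap lands in the reported discrimination regime
(auROC ≈ 0.87–0.93) and are config-exposed; they were not adjusted after
observing test outcomes. The lower truncation shifts the realised FUNC-class
ΔΔG mean slightly above its configured location (~+0.2 kcal/mol); the
LoF-class mean, ~4σ from the floor, is unaffected.

Inter-tool dependence uses a Gaussian copula on the class-conditional
margins; the default correlates the AlphaMissense-like and meta-predictor
latents at r = 0.74 (the published overall score correlation) and leaves
other pairs independent. Because functional class itself correlates all
tools, the realised marginal correlation exceeds the within-class copula
value; the knob is exposed without asserting fidelity to the real
correlation structure.

What a green test on synthetic data does **not** establish: the generator
has no per-residue structure, no sequence context, no RSA-conditional score
distributions within class (so RSA-stratified *score* effects beyond class
composition are absent), and no INT-specific discordance structure. Tests
of RSA-dependent evidence therefore construct weakly-separated tools
explicitly rather than relying on emergent behaviour.

`generate_case_control_counts` draws control carriers Binomial(N₀, p₀) and
case carriers Binomial(N₁, p₁) with p₁ the odds-transform of p₀ by the
stratum's true OR; defaults match the published cohort sizes. Parameter
recovery (OR ∈ {1, 2, 4.69}, baseline 18/48,048) holds within 3 Monte-Carlo
SEs over 200 replicates; the residual small-sample log-OR bias at these
rare-carrier counts is ~2 SEs at OR = 4.69 and is inherent to the
estimator, not the generator.

## Numerical and degenerate-input choices

- Table parsing accepts unicode minus and treats "", "NA", "NaN" (and
  case variants) as missing; unparseable numeric cells become missing and
  are counted, never silently dropped. Rows missing the mandatory MAVE
  score are rejected and reported (rows_in = kept + rejected).
- Written tables use `%.17g`, so read→write→read round-trips within 1e-12.
- `benign_max == path_min` is allowed (empty gray zone); the boundary score
  then falls in the benign zone by the ≤ rule.
- Degenerate CI cases: proportions equal to 1 in both classes give a
  zero-width interval at log₂ LR = 0.
- All randomness flows from a single `numpy` Generator seeded from the
  config; identical config + seed gives byte-identical outputs.

## Known limitations

- The package consumes pre-computed scores; it does not run structure
  prediction, ΔΔG estimation, RSA computation, or score retrieval.
- No local/windowed LR smoothing (fixed-zone LRs only), no DeLong analytic
  auROC test, no covariate-adjusted burden regression, no automatic cascade
  tree induction.
- The published per-tool auROCs and score–MAVE correlations depend on the
  full per-variant supplementary data and are not reproduced; the
  implementation is instead pinned to exact combinatorial oracles
  (all-pairs auROC, hypergeometric Fisher enumeration, permutation
  rank-sum) on small inputs.
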