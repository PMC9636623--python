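# Methods

## The question and the model

When a trial measures the same participants' pain on two bounded
instruments at the same timepoint, any systematic difference between the
instruments' between-group effects — after both are expressed on a
common 0–100 scale — is attributable to the instruments themselves
(range, discreteness, anchoring), not to the patients or the
intervention. `painrescale` operationalises that comparison.

**Rescaling.** A mean m and standard deviation s on a scale with range
R = upper − lower are re-expressed on a target scale with range R′ as
m′ = m·R′/R, s′ = s·R′/R (endpoint scores on scales with a nonzero lower
bound are shifted to zero first; change-from-baseline scores are
differences and get the pure range ratio). The transformation is linear,
so it is exact for means and SDs, preserves the SD/mean ratio, and makes
the MD equivariant: MD′ = MD·R′/R, var′ = var·(R′/R)².

**Verbal categories.** When trial investigators did not number their
verbal categories, the least severe category is coded 0 and each
subsequent one adds a point, giving a 0..(k−1) scale for k categories.
Treating these codes as interval-scaled is an assumption, recorded per
scale via `values_assigned_by`.

**Median conversions.** Trials that report median with range or IQR are
converted to mean/SD before rescaling. The default estimators are Wan et
al. (2014):

- median/range: mean = (a + 2m + b)/4, SD = (b − a)/ξ(n),
  ξ(n) = 2·Φ⁻¹((n − 0.375)/(n + 0.25));
- median/IQR: mean = (q₁ + m + q₃)/3, SD = (q₃ − q₁)/η(n),
  η(n) = 2·Φ⁻¹((0.75n − 0.125)/(n + 0.25)) → 1.349 as n → ∞.

The Hozo et al. (2005) rules sit behind `method="hozo"`; since Hozo
gives no finite-sample IQR formula, that family uses the large-sample
normal constant (q₃ − q₁)/1.35. Wan is the default because it is the
current standard in Cochrane-adjacent practice and is consistent across
sample sizes. A constant report (min = median = max, or q₁ = q₃)
converts to SD = 0; that is not an error but a *degenerate* summary —
the exclusion decision belongs to the pair analysis, where it is logged
with its reason, and excluded pairs never enter any summary statistic.

## Effect sizes and weighting

For two arms A and B (A minus B; treatment minus placebo in
placebo-controlled comparisons), MD = m̄_A − m̄_B with sampling variance
v = s²_A/n_A + s²_B/n_B and Wald interval MD ± z₀.₉₇₅·√v
(z = 1.959964; no Knapp–Hartung adjustment, matching standard
random-effects defaults). Crossover trials that report each arm
separately are analysed exactly like parallel trials: the
within-participant correlation is ignored, which leaves the MD untouched
but widens its variance. This is justified when the correlation is
similar across the instruments being compared — the condition under
which the paired contrast remains fair — and the simulator encodes that
assumption by sharing one correlation ρ across all scales.

**Random effects.** The between-estimate variance τ² is estimated by
restricted maximum likelihood: the profiled restricted log-likelihood

ll(τ²) = −½Σ log(vᵢ+τ²) − ½ log Σ 1/(vᵢ+τ²) − ½Σ (yᵢ−μ̂)²/(vᵢ+τ²),

with μ̂ the inverse-variance-weighted mean, is maximised over
τ² ∈ [0, 10⁴] (generous for effects on a 0–100 scale) by bounded scalar
minimisation with tolerance 1e-8, truncating at the zero boundary; on
the rare non-convergence the engine falls back to a dense grid search
with a warning. Weights are wᵢ ∝ 1/(vᵢ+τ²), normalised to sum to one
and reported as percentages.

**Analysis pairs.** Within each trial/comparison/timepoint, every
two-arm combination (A–B, A–C, B–C for three-arm trials; the correlation
between overlapping comparisons sharing an arm is ignored) is crossed
with every pair of scales of different range. Each pair records
ΔMD = MD_small − MD_large (smaller-range scale minus the larger-range
reference — a negative value reads "the short scale's MD was lower") and
the short scale's percentage weight from a two-row random-effects fit of
the pair. With k = 2 the REML estimate of τ² is frequently truncated to
zero, reducing the weights to fixed-effect inverse-variance weights;
this is documented behaviour, and a pure fixed-effect weighting is
available via `weight_model="fixed_effect"`. Equal variances give
exactly 50 %/50 %, the benchmark for "no difference in CI width".

**Class summaries.** Pairs are grouped into four classes (0–10 vs 0–100;
0–10 vs 0–<10; 0–100 vs 4-point; 0–100 vs 5-point). Per class the
package reports the *signed* arithmetic mean, min and max of ΔMD
(matching the directional phrasing "x points lower/higher"), the mean of
|ΔMD| for transparency, counts of pairs with ΔMD above/below zero (exact
ties count in neither), and the weight differential
(w_small − 50)×2 — the short scale's percentage-point surplus or
shortfall relative to an even split — summarised by mean/min/max. The
sensitivity analysis removes every pair that relied on a median-based
conversion and recomputes the summaries.

## The synthetic evidence base

The generator draws each participant's latent pain from
Normal(arm mean, arm SD) on the 0–100 metric and measures it on every
instrument simultaneously: the continuous scale adds noise and censors
to [0, 100]; the 0–10 scale rounds (latent+noise)/10; k-point ordinal
scales bin latent+noise at cutpoints over [0, 100] (equal-width by
default, configurable because real verbal-category boundaries are
unknown). Censoring (clipping) rather than truncated re-drawing is used
at the bounds, since bounded pain scales censor: someone in more pain
than the top anchor still marks the maximum. Crossover designs draw each
participant's period scores from a multivariate normal with a common
within-participant correlation ρ and still emit per-arm summaries, the
way such trials report data when they do not report paired differences.

Defaults, chosen once as the simulated study conditions: latent effect
10 points and SD 20 points on 0–100 (typical analgesic-trial
magnitudes), measurement noise SD 5 (test–retest-scale noise),
ρ = 0.6 (moderate within-participant correlation), n = 100 per arm
(real arms span roughly 20–400). `study_scenarios()` instantiates a
twelve-trial set mirroring a realistic evidence base: nine two-arm and
three three-arm trials, three crossovers, one to three timepoints, all
four scale pairings, one trial reporting median (range) and one median
(IQR). One root seed spawns per-trial/timepoint child generators
(stable CRC-based keys), so single trials regenerate in isolation and
tables are byte-identical across runs.

What the simulator does *not* emulate: dropout and missingness,
longitudinal correlation across timepoints, floor/ceiling-induced skew
beyond censoring, unequal arm sizes within a trial, and
instrument-specific response styles. Passing tests therefore show the
pipeline's arithmetic and its behaviour under the latent-variable
measurement model, not that real instruments are interchangeable.

## Numerical and design choices

- All computation keeps full double precision; only the text report
  rounds to one decimal.
- Rescaling round-trips are exact to ~1e-12; ξ(n)/η(n) match an
  independent erfinv-based normal-quantile oracle to 1e-9.
- The REML engine is cross-checked against a dense grid search (step
  1e-4) and against an independent reference implementation on fixed
  instances.
- Arm pairing requires identical trial/comparison/timepoint keys and a
  shared source scale; arms present on only one scale are logged and
  skipped rather than silently dropped.
- Problem sizes in the test suite (500 replicate trials for parameter
  recovery, 2000 replicates for τ² bias and CI coverage) were chosen to
  keep Monte-Carlo error a few times smaller than the tolerances being
  asserted.

## Known limitations

- Rescaling is linear by construction; genuinely nonlinear relations
  between instruments (e.g. anchoring effects) are out of scope.
- The crossover treatment inherits the equal-correlation assumption; if
  the correlation differed by scale, the weight contrast would be
  biased in favour of the scale with the higher correlation.
- Ordinal category means are not unbiased estimators of latent means,
  so coarse scales can carry a systematic ΔMD offset that depends on
  the latent distribution and cutpoints; the pipeline measures it
  rather than correcting it.
- Missing SDs are never imputed from other trials, and individual-level
  rescaling is not attempted.
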