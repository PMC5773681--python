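# Methods

## Model and estimands

The unit of analysis is a two-arm randomized trial in which every patient
has a cost C and a clinical outcome E recorded by each of two data
sources (e.g. trial case report forms and a linked routine database).
Rows are complete cases; the pairing of the two sources is within-patient
and structural (one row per patient). The economic endpoint is the mean
incremental net monetary benefit at a willingness-to-pay threshold λ,

    β(λ) = λ·ΔE − ΔC,

estimated per source as the difference in arm means of the per-patient
net benefit nb = λ·e − c, where e is the *oriented* effect: e = 1 −
outcome when the outcome is an adverse event (so that ΔE counts events
averted), e = outcome otherwise. Orientation happens once, at net-benefit
construction, so every downstream statistic inherits the sign convention.

Because the two arms are independent samples,

    Var(β̂) = s²_nb,int / n_int + s²_nb,ctl / n_ctl ,

with n−1 denominators throughout (the standard-error formulas presume
unbiased sample variances). This per-patient route is algebraically equal
to the moment decomposition Σ_arms [λ²·var(e) + var(c) − 2λ·cov(c, e)]/n;
the implementation uses the former (simpler, numerically stable) and the
test suite verifies the identity on random data to 1e−9 relative.

## Agreement statistics

**Difference in means.** ω(λ) = β₂(λ) − β₁(λ), with variance
σ²_β1 + σ²_β2 − 2·cov(β̂₁, β̂₂). The covariance — the two INBs are
correlated because they describe the same patients — is realized exactly
by working with the per-patient paired differences d_j = nb₂ⱼ − nb₁ⱼ:
ω̂ = mean(d | intervention) − mean(d | control) and se²_ω =
s²_d,int/n_int + s²_d,ctl/n_ctl. Equivalently, the cross-source
covariance of the mean-INB estimators is the arm-wise sample covariance
of the paired net benefits divided by arm size, summed over arms; the
equality of the two routes is property-tested. Z = ω̂/σ̂_ω is referred
to the standard normal (two-sided). Failing to reject does not establish
equivalence, so a TOST procedure is provided: for margin δ > 0,
p = max[1 − Φ((ω̂+δ)/σ̂_ω), 1 − Φ((δ−ω̂)/σ̂_ω)].

**Miscoverage.** One source is designated referent, the other test.
β̂_ref is computed once from the full data. S bootstrap replicates
resample whole patient rows with replacement, stratified by arm with arm
sizes preserved (keeping both sources' values together preserves both the
randomization structure and the cross-source correlation). Each replicate
yields the test source's β̂* and its analytic standard error, hence a
Wald interval β̂* ± z_{1−α/2}·se*; the miscoverage is the fraction of
intervals excluding β̂_ref. A well-agreeing test source gives values near
α; referent = test is allowed as a calibration check and flagged.

**Concordance.** Lin's concordance correlation coefficient adapted to the
INB scale:

    ρ̂_c = 2·côv(β̂₁, β̂₂) / [ (β̂₂ − β̂₁)² + σ̂²_β1 + σ̂²_β2 ],

with σ̂²_βi the squared standard errors of the mean INB estimators and
côv the paired covariance described above (the variance/covariance of
the *estimators*, not patient-level SDs — the alternative reading is
inconsistent with the Z-test variance in the same framework).
ρ̂_c factors into Pearson precision ρ̂ = côv/(σ̂_β1·σ̂_β2) and accuracy
C_b = ρ̂_c/ρ̂ ∈ (0, 1]. Interval estimation uses the same arm-stratified
paired bootstrap: each replicate's ρ̂*_c is Fisher-transformed
(z = arctanh ρ_c, replicates at |ρ_c| = 1 clipped to 1 − 1e−12), se_z is
the sample SD of the transformed replicates, and the CI is
tanh(z(ρ̂_c) ± z_{1−α/2}·se_z). The one-sided test of ρ_c > ρ_c0 uses
p = 1 − Φ((z(ρ̂_c) − z(ρ_c0))/se_z) at significance 0.025 by default;
ρ_c0 is either fixed (0.4, 0.65 and 0.8 are conventional benchmarks) or
derived as C_b·√(ρ̂² − x) for an acceptable precision loss x (default
x = 0.05), undefined when ρ̂² < x.

**λ-grid sweep.** All three statistics are evaluated over a grid
(default £0–£500,000 in 101 steps). Per-row sub-seeds are generated from
the root seed via `numpy.random.SeedSequence`, recorded in the output
table, and guarantee each row equals the standalone operation at that λ —
rows are individually auditable. No multiplicity adjustment is applied by
default; users who sweep many thresholds can tighten the per-λ level
(e.g. to 0.01).

## Degenerate inputs and numerical choices

- Identical sources (all paired differences zero) report exact agreement:
  ω = 0, z = 0, p = 1, ρ̂_c = 1 with a point CI and a `degenerate` flag,
  rather than NaN — the identity case is the natural calibration fixture.
  Detection is exact (array equality), not a float threshold.
- ΔE = 0 leaves the ICER undefined (flagged, quadrant `boundary`), never
  an exception.
- A replicate with zero variance yields a point CI, counted by the same
  exclusion rule as any other interval.
- c_b is clamped at 1 within 1e−9 to absorb floating-point overshoot of
  the AM–GM bound.
- CEACs use the nonparametric arm-stratified bootstrap of (ΔE, ΔC)
  (matching the CE-plane cloud); a normal-approximation variant
  Φ(β̂/se) is available as an option.

## Synthetic paired-trial generator

`SimConfig`/`simulate_paired_trial` emulate a neonatal trial observed by
two linked sources. Per patient in arm t: a latent event y* ~
Bernoulli(p_t) and latent cost c* ~ Gamma(mean μ_t, CV) +
premium·y* (Gamma because neonatal cost data are right-skewed and
non-negative, and the CV parameterization keeps closed-form moments);
source i records cost_i = max(0, c* + shift_i + N(0, sd_i²)) and
outcome_i = y* flipped with probability m_i. The number of truncations at
zero is recorded per dataset; default noise levels make it negligible.

Defaults are calibrated to the motivating trial's published summaries:
638/620 patients, arm mean costs £62,284/£62,799 with SE(mean) ≈ £1,880
(hence CV 0.76), sepsis proportions 0.113/0.108, an event cost premium of
£10,000 (an episode of neonatal sepsis materially prolongs intensive
care), between-source cost noise of £12,000 SD per source — chosen so the
SE of ω̂ is of order £1,000, the order observed for between-source INB
differences in that comparison — no misclassification in source 1 and 2%
in source 2 (trial forms treated as outcome gold standard; routine
outcome coding imperfect), and no systematic shift.

The generator's truth is available in closed form: with adverse
orientation, E[observed outcome] = m_i + p_t(1 − 2m_i) and E[observed
cost] = μ_t + premium·p_t + shift, so

    ω(λ) = λ·(p_ctl − p_int)·[(1−2m₂) − (1−2m₁)] − Δshift,

where Δshift is the source-2 shift's contribution to ΔC. A key subtlety:
a shift applied to *both* arms cancels in the incremental contrast and
leaves ω unchanged; only an arm-targeted shift (`shift_arm="control"` or
`"intervention"`) produces true disagreement in ω. Power studies must
therefore target one arm.

What the generator does **not** emulate: linkage error or missingness
(complete cases are assumed upstream), heteroscedastic or cost-dependent
measurement error, correlated misclassification between sources, and
within-patient correlation of cost noise across sources beyond the shared
latent cost. Passing calibration tests on these synthetic trials
demonstrates the statistics behave correctly under the stated error
model, not that any particular real routine database agrees with trial
forms.

## Operating characteristics

`operating_characteristics` repeats simulate → analyse over n_reps
trials and reports the ω-test rejection rate, mean ρ̂_c (point estimator;
no inner CI bootstrap), the empirical bias of ω̂ against the closed-form
truth with its Monte-Carlo SE, and optionally the mean miscoverage. The
per-rep miscoverage runs a full bootstrap inside every replication, so it
is opt-in (`miscoverage_boot`, default 0 → reported as NaN); the other
summaries are cheap and always computed.

Problem sizes used in the shipped checks: 1000 replications at the
default (638/620) trial size for type-I error and parameter recovery; 300
replications at 400/arm for the three-level power monotonicity check;
S = 1000 bootstrap replicates at 500/arm for miscoverage calibration;
S = 2000 for the symmetric-null CEAC. These sizes put Monte-Carlo error
well inside the asserted bands.

## Known limitations

- Inference is large-sample (normal) for the difference test; very small
  arms rely on the bootstrap statistics instead.
- The framework assumes randomized arms; applied to non-randomized
  comparisons, confounding propagates into the agreement estimates.
- A kinked (quadrant-dependent) willingness-to-pay threshold is not
  supported; λ is a single non-negative slope.
- Binary outcomes are the exercised path; continuous effects flow through
  the same formulas but are not covered by the shipped tests.
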