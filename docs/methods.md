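# Methods

## Statistical model

Primary effect sizes are log response ratios generated from the standard
two-level hierarchical Gaussian model of random-effects meta-analysis:

    y_i = theta_i + eps_i,   theta_i ~ N(mu, sigma_theta^2),
                             eps_i   ~ N(0, sigma_eps_i^2),

so that marginally y_i ~ N(mu, sigma_theta^2 + sigma_eps_i^2). mu is the
true mean effect the synthesis methods try to recover, sigma_theta^2 the
between-study variance of true effects, and sigma_eps_i^2 a study-specific
within-study variance. (Some presentations write the sampling error with a
non-zero location; the mean-zero form used here is the standard one — the
effect's location enters once, through theta.) The generator draws y_i
directly from the marginal, which is distributionally identical to drawing
theta_i first and adds no per-study state.

All fits — first-order, pooled (REMA) and second-order (SOMA) — use the
same algebra: DerSimonian–Laird moment estimation of the heterogeneity
variance tau^2 (truncated at zero; zero for a single unit), weights
w = 1/(tau^2 + v), pooled mean sum(w y)/sum(w), SE = sum(w)^(-1/2), and
z-based 95% intervals with the constant 1.96. DL was chosen over iterative
REML because it is closed-form, deterministic, and fast enough for the
~800k fits of a full benchmark run; it is also the conventional choice in
simulation studies of this kind. The fit is cross-checked in the test
suite against two independent routes: a pure-Python brute-force evaluation
of the formulas, and R's metafor `rma(method = "DL")`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| sigma_theta | 0.15 | between-study SD of true effects (log-ratio scale); moderate heterogeneity relative to the benchmark's true means (±0.22 to ±0.69) |
| SE range, high precision | U(0.05, 0.15) | within-study SE of precise studies |
| SE range, medium precision | U(0.15, 0.35) | intermediate |
| SE range, low precision | U(0.35, 0.70) | imprecise studies |
| n_iter | 100 | Monte-Carlo iterations per scenario |

The precision ranges are a calibration choice: they span SEs typical of
log-response-ratio field studies and keep the three levels disjoint and
strictly ordered. Absolute headline percentages (e.g. how often a method's
PCC drops below 0.9) are sensitive to this calibration; signs, orderings
and the bias/coverage structure are not.

The unbiased benchmark grid is the full factorial of
mu ∈ {−0.69, −0.29, 0, 0.22, 0.41} × K ∈ {3, 5, 10} × N ∈ {10, 15, 25, 50}
× P ∈ {0, 0.10, 0.25, 0.50} × precision ∈ {low, medium, high} — 720
scenarios. The publication-bias grid fixes N = 50, P = 0, medium precision
and crosses mu ∈ {−0.69, −0.29, 0} × K ∈ {3, 5, 10} × three bias regimes —
27 scenarios (positive mu would be symmetric).

## Overlap construction

m = round(P·N) studies (halves rounded up) are drawn once into a single
shared pool inserted into *all* K datasets; each dataset is completed with
N − m independent studies. The deduplicated union therefore has
K·(N − m) + m studies. A global shared pool (rather than pairwise overlaps)
is the simplest construction consistent with "a proportion P of data in
common among the K datasets" and with the pooled-size statement; it is a
design choice, and the overlap pattern of real MA collections is generally
messier.

## Publication-bias sampling

Each regime conditions y on a significance region defined by the study's
own SE: |y| > 1.96·se (regime 1, "sig_both"), y < −1.96·se (regime 2,
"sig_negative"), y > +1.96·se (regime 3, "sig_positive"). The 1.96·se
(standard-error) form of the significance condition is used for all three
regimes. Sampling is exact: after drawing se, the tail masses of the
marginal N(mu, sigma_theta^2 + se^2) are computed with the normal CDF and
a uniform variate is mapped through the inverse CDF restricted to the
region (for the two-sided regime, the tail is chosen in proportion to its
mass). Uniforms are clipped into the open unit interval so every emitted
study satisfies its condition strictly. Regions with probability below
1e-300 raise a degenerate-region error rather than returning junk. The
truncated sampler is validated against naive rejection sampling (two-sample
KS test) in a region where rejection is feasible.

## Evaluation criteria

Per scenario and method, over the iterations: PCC is the fraction of
three-way verdicts matching sign(mu); BES is mean(estimate) − mu
(estimated minus true, so overestimation is positive); RMSE is the root
mean squared error of the estimates; CCI is the fraction of 95% CIs
containing mu. COMA yields no estimate, so only PCC is defined for it.
`summarize` additionally reports 1 − PCC (the proportion of wrong
conclusions) and the share of scenarios with PCC under configurable
thresholds (default 0.9 and 0.75).

## Numerical and design choices

- **CV of a zero mean**: se/|mean| is +inf when mean = 0, so such an MA is
  never selected by MAMA (probability-zero event under the model).
- **CI endpoint exactly 0**: classified as no effect (conservative;
  measure-zero).
- **COMA ties**: any tie for the most votes returns no_effect — a split
  verdict is not evidence for a direction, and the rule is symmetric.
- **MAMA CV ties**: lowest index wins (deterministic; measure-zero).
- **Seeding**: the master seed and the pair (scenario index, iteration)
  key an independent SeedSequence substream, so tables are bit-identical
  across reruns and across serial vs multi-process execution.
- **Scenario order**: lexicographic in (mu, K, N, P, precision, bias),
  each factor in its configured level order.

## Problem sizes and runtime

The full 720-scenario × 100-iteration unbiased grid plus the 27-scenario
bias grid complete in well under a minute on one CPU with the DL
estimator; the test suite's end-to-end checks run the same full grids.

## What the simulations do and do not show

The generator emulates ideal conditions: Gaussian effects, known
within-study SEs, equal-sized MAs, a single global overlap pool, and
publication bias acting study-wise through a sharp significance rule.
Real MA collections have skewed effect distributions, estimated and
correlated SEs, unequal and unknown overlap, and softer selection
mechanisms. Passing benchmarks here show the methods' *relative* behaviour
under the model — SOMA's anti-conservative intervals under overlap, MAMA's
selection bias toward extreme means, COMA's low power at small N, REMA's
calibrated coverage — not absolute performance guarantees on real
evidence bases. Dependence-adjusted second-order variances and shrinkage
(BLUP) re-estimation of first-order means are deliberately out of scope:
the benchmark studies the naive methods as practitioners use them.
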