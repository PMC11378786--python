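"""Fit a random-effects meta-analysis to a handful of primary studies.

Each study contributes a log-response-ratio effect and its standard error;
the fit estimates between-study heterogeneity (DerSimonian-Laird), pools
the effects with weights 1/(tau^2 + se^2) and reports a 95% CI with a
three-way verdict on the intervention.
"""

from masynth import Study, fit_random_effects

studies = [
    Study(effect=0.25, within_se=0.10, study_id="trial-A"),
    Study(effect=0.40, within_se=0.15, study_id="trial-B"),
    Study(effect=0.10, within_se=0.12, study_id="trial-C"),
    Study(effect=0.31, within_se=0.09, study_id="trial-D"),
]

fit = fit_random_effects(studies)
print(f"pooled mean effect : {fit.mean:.4f} (log ratio)")
print(f"standard error     : {fit.se:.4f}")
print(f"95% CI             : [{fit.ci_low:.4f}, {fit.ci_high:.4f}]")
print(f"heterogeneity tau^2: {fit.tau2:.4f}")
print(f"verdict            : {fit.category.value}")
# A CI entirely above zero means the intervention significantly increases
# the outcome; exp(mean) - 1 is the implied relative change.
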