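"""Synthesize the published results of several meta-analyses.

Given only each meta-analysis' mean effect size and standard error (no
primary data), the three fast-track methods give: a second-order pooled
estimate (SOMA), the single most accurate MA by coefficient of variation
(MAMA), and a vote count over significance categories (COMA).
"""

from masynth import MAResult, coma, mama, soma

summaries = [
    ("cover-crops-2018", 0.30, 0.05),
    ("cover-crops-2020", 0.10, 0.20),
    ("cover-crops-2022", 0.25, 0.08),
]
results = [MAResult.from_summary(mean, se) for _, mean, se in summaries]

s = soma(results)
print(f"SOMA: mean={s.mean:.4f}  95% CI=[{s.ci_low:.4f}, {s.ci_high:.4f}]  "
      f"verdict={s.category.value}  (tau^2 across MAs={s.detail['tau2']:.4f})")

m = mama(results)
print(f"MAMA: selects MA #{m.detail['selected']} ({summaries[m.detail['selected']][0]}), "
      f"mean={m.mean:.4f}, CV={m.detail['cv']:.3f}")

c = coma(results)
print(f"COMA: votes={c.detail['votes']}  verdict={c.category.value}")
# SOMA averages the three means with inverse-variance weights; MAMA passes
# through the estimate with the lowest se/|mean|; COMA only counts how many
# MAs are significantly positive / negative / inconclusive.
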