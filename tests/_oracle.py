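"""Brute-force reference implementation of the DerSimonian–Laird fit.

Pure-Python loops, independent of the package's numpy code path; used to
pin down the closed-form examples and for randomized equivalence checks.
"""

import math


def dl_tau2(effects, variances):
    k = len(effects)
    if k == 1:
        return 0.0
    w = [1.0 / v for v in variances]
    sw = sum(w)
    ybar = sum(wi * yi for wi, yi in zip(w, effects)) / sw
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, effects))
    c = sw - sum(wi * wi for wi in w) / sw
    return max(0.0, (q - (k - 1)) / c)


def dl_fit(effects, ses):
    """Returns (mean, se, ci_low, ci_high, tau2) of a random-effects fit."""
    variances = [s * s for s in ses]
    tau2 = dl_tau2(effects, variances)
    w = [1.0 / (tau2 + v) for v in variances]
    sw = sum(w)
    mean = sum(wi * yi for wi, yi in zip(w, effects)) / sw
    se = 1.0 / math.sqrt(sw)
    return mean, se, mean - 1.96 * se, mean + 1.96 * se, tau2
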