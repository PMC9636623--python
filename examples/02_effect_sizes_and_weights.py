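"""Between-group mean differences and random-effects weights.

Computes the MD (with Wald 95% CI) for a two-arm comparison, shows that
the same groups expressed on a 0-10 scale rescale to the identical
estimate, and fits the from-scratch REML random-effects model to a small
set of estimates to obtain tau^2 and inverse-variance weights.
"""

import numpy as np

from painrescale import (
    SCALE_0_100,
    ArmSummary,
    ScaleDefinition,
    md_estimate,
    random_effects_fit,
    reml_tau2,
)
from painrescale.meta import EffectEstimate

arm = lambda name, scale, mean, sd: ArmSummary(
    "trial-1", "c1", "week-4", name, scale, n=50, mean=mean, sd=sd
)

active = arm("active", SCALE_0_100, 40.0, 20.0)
placebo = arm("placebo", SCALE_0_100, 50.0, 20.0)
est = md_estimate(active, placebo, SCALE_0_100)
print(
    f"MD = {est.md:.1f} points (variance {est.variance:.1f}), "
    f"95% CI {est.ci_lower:.2f} to {est.ci_upper:.2f}"
)

nrs = ScaleDefinition("NRS-10", 0, 10)
est10 = md_estimate(
    arm("active", nrs, 4.0, 2.0), arm("placebo", nrs, 5.0, 2.0), SCALE_0_100
)
print(f"same groups on 0-10, rescaled: MD = {est10.md:.1f} (identical)")

# REML on a handful of heterogeneous estimates
y_v = [(2.0, 1.0), (-1.0, 2.0), (3.5, 0.5), (0.5, 1.5)]
tau2 = reml_tau2(y_v)
print(f"REML between-estimate variance tau^2 = {tau2:.3f}")

fit = random_effects_fit(
    [
        EffectEstimate(y, v, 0, 0, SCALE_0_100, "t", "c", "tp")
        for y, v in y_v
    ]
)
print(
    "pooled mu = %.3f; weights = %s%%"
    % (fit.mu, np.round(fit.weights_pct, 1).tolist())
)
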