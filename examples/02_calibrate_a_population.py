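"""Calibrate a synthetic population's discrimination to a target C.

Builds the cesarean-like population (five predictors: maternal age, height,
gestational age, infant sex, birthweight centile) and scales its outcome
coefficients so the generating logistic model attains C = 0.71, then
verifies the achieved C on an independent Monte-Carlo sample.
"""

import numpy as np

from optimcv import calibrate_scale_constant, cesarean_like_spec, population_c

spec = calibrate_scale_constant(cesarean_like_spec(), target_c=0.71,
                                rng=np.random.default_rng(7), n_mc=500_000)
print(f"calibrated scale constant: {spec.scale_constant:.4f}")

c = population_c(spec, n_mc=500_000, rng=np.random.default_rng(8))
print(f"population C on an independent 500,000-person sample: {c:.4f}")
# The achieved C should sit within Monte-Carlo error (~0.002) of 0.71:
# multiplying all covariate coefficients by one constant moves the model's
# discrimination smoothly from 0.5 (constant 0) upward.
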