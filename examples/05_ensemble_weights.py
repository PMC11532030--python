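"""Fit simplex-constrained ensemble weights and compare with theory.

Two unbiased member models with error variances 1 and 4 are combined by
minimizing the ensemble MSE over the probability simplex. The optimal
weights for independent unbiased members are inverse-variance weights,
here (0.8, 0.2); the fitted weights land within sampling error of that,
and the ensemble loss beats both members and the uniform mean.
"""

import numpy as np

from kcatpred import (
    PredictionPanelSpec,
    generate_prediction_panel,
    optimize_weights,
    weighted_average,
)

y = np.random.default_rng(0).standard_normal(10_000)
panel = generate_prediction_panel(
    y, PredictionPanelSpec(n=10_000, sigmas=(1.0, 2.0), rho=0.0, seed=0)
)

w = optimize_weights(panel)
print("member MSEs:", np.round(panel.member_losses(), 3))
print("fitted weights:", np.round(w.w, 3), "(theory: [0.8, 0.2])")
print(f"ensemble MSE {w.loss_at_optimum:.3f} "
      f"(uniform mean: {np.mean((panel.preds.mean(axis=1) - y) ** 2):.3f})")

combined = weighted_average(panel.preds, w)
print("combined prediction MSE:", round(float(np.mean((combined - y) ** 2)), 3))
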