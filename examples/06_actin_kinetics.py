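"""Pyrene-actin polymerization rates and the activation dose-response.

The polymerization rate of one reaction is its maximal sliding-window
slope.  Slopes across activator concentrations follow a one-site
saturation curve slope = vmax * c / (c + k_half); fitting it recovers the
half-maximal activating concentration (planted at 6.3 nM, substoichiometric
to the 50 nM nucleation-promoting factor in the reaction).
"""

import numpy as np

from cmequant import kinetics, pipelines

# a single logistic-shaped polymerization curve and its maximal slope
t = np.linspace(0, 900, 901)
curve = kinetics.PolymerizationCurve(t, 1000.0 / (1 + np.exp(-0.01 * (t - 400))))
print(f"max slope of the example curve: {curve.max_slope():.2f} a.u./s "
      "(logistic inflection slope L*k/4 = 2.50)")

fit = pipelines.halfmax_recovery_experiment(k_half_nM=6.3, seed=8)
lo, hi = fit.k_half_ci
print(f"fitted k_half: {fit.k_half:.2f} nM (95% CI {lo:.2f}-{hi:.2f}), "
      f"vmax: {fit.vmax:.3f}")
print("-> the fit recovers the planted 6.3 nM half-max from 8 "
      "concentrations x 3 replicates with 5% multiplicative noise.")
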