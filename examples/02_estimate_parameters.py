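"""Estimate a rate constant with the hybrid unscented Kalman filter.

Generates dense, lightly noisy observations of all five fibroblast states
from the default scenario, then asks the filter to recover the SLIT2
degradation rate h1 and the SMAD7 degradation rate h4 starting from
deliberately wrong priors (+50% and -40%).  The parameters ride along as
augmented state coordinates with zero dynamics; each measurement pulls
them through their cross-covariance with the observed states.
"""

import numpy as np

from cafswitch import ScenarioPreset, generate_truth
from cafswitch.hukf import UkfSettings, estimate_parameters, fibroblast_parameter_model
from cafswitch.model_core import FibroblastParameters
from cafswitch.synthetic import sample_observations

FIBRO = ("SLIT2", "CXCL12", "SMAD", "SMAD7", "JAKSTAT")

truth = generate_truth(ScenarioPreset())
times = np.linspace(1.0, 72.0, 50)
sigmas = [0.01 * np.ptp(truth.species(s)) for s in FIBRO]  # 1% of each range
obs = sample_observations(truth, FIBRO, times, sigmas, "additive-gaussian", seed=0)

# the fibroblast's received signals are the cancer cell's known outputs
tg, lif, tgfb = truth.times, truth.species("LIF"), truth.species("TGFB")
model = fibroblast_parameter_model(
    inputs=lambda t: (np.interp(t, tg, lif), np.interp(t, tg, tgfb))
)

fp = FibroblastParameters()
result = estimate_parameters(
    obs, model, ["h1", "h4"],
    settings=UkfSettings(ode_step=0.05),
    initial_state=np.full(5, 0.01),
    param_prior={"h1": fp.h1 * 1.5, "h4": fp.h4 * 0.6},
)

for name, true in (("h1", fp.h1), ("h4", fp.h4)):
    est = result.parameters[name]
    print(f"{name}: prior {'%.4f' % (true * (1.5 if name == 'h1' else 0.6))} -> "
          f"estimate {est:.4f} (true {true:.4f}, "
          f"relative error {abs(est - true) / true:.1%})")
print(f"total estimation error (mean per-gene RMSE of the filtered fit): "
      f"{result.total_error:.4g}")

# Relative errors of a few percent from a 50-point series show the filter
# extracting rate constants it never observes directly.
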