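"""Metric calibration and path-integration accuracy under compass noise.

Calibrates the activity-to-metres scale kappa on scripted straight legs,
then measures the positional error of the estimate over noisy foraging
trials.  The printed mean error is the time-averaged distance between the
decoded position and the true position, in metres; it grows with the
sensory noise level (the SD of the compass shift is 2*pi*zeta radians,
so 0.05 = 18 degrees).
"""

from antnav import KinematicsParams, PIParams, calibrate_metric_scale
from antnav.experiments import run_pi_accuracy

params, kin = PIParams(), KinematicsParams()
calib = calibrate_metric_scale(params, kin.step_len)
print(f"kappa = {calib.kappa:.4e} m per activity unit (N=18, zero noise)\n")

res = run_pi_accuracy(
    noise_levels=(0.0, 0.02, 0.05), n_trials=150, t_forage=500.0, seed=1
)
print(res.summary[["noise_level", "mean_error", "sd_error", "homing_rate"]]
      .to_string(index=False))
print(
    "\nmean_error: time-averaged |estimate - true position| in metres; "
    "homing_rate: fraction of trials back inside the 0.2 m nest radius."
)
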