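"""Learning walks: acquiring a global vector to a single feeder.

One agent forages from the nest with a feeder 10 m away at bearing 90
degrees.  Early trials are random search; once the feeder is found, the
reward-modulated rule copies the current path-integration state into the
global-vector weights, and subsequent trials run straight to the food at a
collapsed exploration rate.  The decoded vector (length, angle) is read
from the learned weights by the population-vector average.
"""

from antnav.experiments import run_gv_single_feeder

res = run_gv_single_feeder(
    feeder_distance=10.0, feeder_angle_deg=90.0, t_forage=2000.0,
    n_trials=5, seed=2,
)
cols = ["trial", "goal_success", "mean_eps_outward", "gv_length_m", "gv_angle_deg"]
print(res.summary[cols].round(3).to_string(index=False))
print(
    "\ngv_length_m / gv_angle_deg: the learned nest->feeder vector decoded "
    "from the plastic weights (true feeder: 10 m at 90 deg); "
    "mean_eps_outward ~ 0 means the agent exploits the memory instead of "
    "searching randomly."
)
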