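"""Water residence time around a glutamate from survival probabilities.

Plants a single bound-water site 3 Å from a glutamate with a 10-ps mean
continuous lifetime, samples ten 1-ns windows, and integrates the survival
probability of water within 3.6 Å of the glutamate to a residence time per
window.
"""

import numpy as np

from hydroshell import residence_time_over_windows, sample_windows
from hydroshell.synth import PlantedSite, auto_site_positions, generate_trajectory, toy_protein
from hydroshell.trajectory import align_window

scaffold = toy_protein(n_copies_per_type=1)
site = auto_site_positions(scaffold, 1, residue_name="GLU")[0]
traj, truth = generate_trajectory(
    None, n_frames=5000, sites=[PlantedSite(site, occupancy=0.8, tau_ps=10.0)],
    bulk_density=0.0, scaffold=scaffold, seed=42)

windows = [align_window(w) for w in sample_windows(traj, 500, 1.0)]
rt = residence_time_over_windows(windows, "GLU", cutoff=3.6)

print("per-window residence times (ps):",
      [round(v, 1) for v in rt.window_values])
se = np.std(rt.window_values, ddof=1) / np.sqrt(len(rt.window_values))
print(f"tau = {rt.tau_ps:.2f} ± {se:.2f} ps (planted 10 ps)")
print("τ is the integral of the continuous survival probability S(t): how "
      "long a water stays in the 3.6 Å shell without leaving.")
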