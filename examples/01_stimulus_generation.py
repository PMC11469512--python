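"""Generate one 90 s random-walk heading stimulus and a plant field.

The observer translates through a virtual plane; every 200 ms the heading
changes by a N(0, 20 deg) step, reflecting off a circular boundary.  Plants
provide the optic flow; SPARSE vs DENSE conditions differ in their count.
"""

import numpy as np

from headtrack import GeneratorConfig, generate_heading_path, generate_plant_field
from headtrack.angles import signed_diff_deg

traj = generate_heading_path(GeneratorConfig(seed=42))
steps = signed_diff_deg(traj.heading_deg[1:], traj.heading_deg[:-1])
steps = steps[~traj.reflected[1:]]

print(f"steps: {traj.n_steps} (90 s at 200 ms)")
print(f"start heading: {traj.heading_deg[0]:.0f} deg (180 = forwards)")
print(f"non-reflected step SD: {steps.std(ddof=1):.2f} deg (design: 20)")
print(f"reflections at the 50 m boundary: {traj.reflected.sum()}")
print(f"max distance from origin: {np.hypot(traj.x_m, traj.y_m).max():.1f} m")

field = generate_plant_field(n=5000, area_m2=10_000.0, min_dist_m=1.0, seed=1)
from scipy.spatial.distance import pdist

print(f"DENSE field: {field.n} plants, min spacing {pdist(field.points).min():.2f} m")
# The step SD and spacing match the generator's design parameters; the
# reflection count shows how often the boundary rule turned the walk around.
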