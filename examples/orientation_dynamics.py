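"""Inter-domain orientation and transient extension along a trajectory.

Generates a rigid two-domain trajectory with thermal orientation noise and
one transient partial-unbending event, then builds the orientation
probability map (probe-domain axis projected into the reference-domain
frame) and the end-to-end distance series with a running average.
"""

import numpy as np

from cadmech.geometry import distance_series, orientation_map
from cadmech.io_formats import DomainDefinition
from cadmech.synthetic_data import gen_domain_trajectory

traj, truth = gen_domain_trajectory(
    n_frames=300, dt=2.0, mean_bend=90.0, bend_sd=6.0,
    unbending_events=[(330.0, 120.0, 2.0)],   # +2 nm from 330 to 450 ns
    seed=5, n_atoms_per_domain=40,
)
doms = {k: DomainDefinition(**v) for k, v in truth.labels["base"]["domains"].items()}

omap = orientation_map(traj, doms["domain1"], doms["domain2"])
occupied = np.count_nonzero(omap.probabilities)
radii = np.hypot(omap.points[:, 0], omap.points[:, 1])
print(f"orientation map: {occupied} occupied bins, probability sum "
      f"{omap.probabilities.sum():.3f}, mean projected radius {radii.mean():.2f}")
print("(radius ~1 means the probe axis lies near the plane normal to the")
print(" reference axis, i.e. a ~90 deg bend; the spread is the thermal noise)")

ds = distance_series(
    traj, tuple(truth.labels["terminus_a"]), tuple(truth.labels["terminus_b"]),
    window_ns=10.0, name="end-to-end",
)
before = ds.values[ds.times < 320].mean() / 10.0
during = ds.values[(ds.times > 340) & (ds.times < 440)].mean() / 10.0
print(f"\nend-to-end distance: {before:.2f} nm at rest, {during:.2f} nm during the event")
print(f"transient extension: {during - before:.2f} nm — the signature of a")
print("partial unbending excursion that later re-bends.")
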