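"""Decompose 30S head motion into rotation, tilt and tilt direction.

Builds the synthetic mini-ribosome, programs a motion that visits the
highly rotated (ap/P-pe/E-like) pose and then a head-tilted pose, and
recovers the angles with the kinematics pipeline.
"""

import numpy as np

import translodyn as td

structure, group_specs = td.make_mini_ribosome()
groups = td.resolve_groups(structure, group_specs)
classical, rotated = td.make_reference_pair(structure)
axes = td.define_reference_axes(classical, rotated, groups["mrna"],
                                groups["body"], groups["head"],
                                groups["large"])

# rotation ramp to 16.5 deg, back-rotation with a 9.5 deg tilt, return
phi = np.concatenate([np.linspace(0, 16.5, 5), np.linspace(16.5, 3.5, 5),
                      np.linspace(3.5, 0, 5)])
theta = np.concatenate([np.zeros(5), np.linspace(0, 9.5, 5),
                        np.linspace(9.5, 0, 5)])
program = td.MotionProgram(phi_body=np.full(15, 1.9), phi_head=phi,
                           theta_head=theta, chi_head=np.zeros(15),
                           noise_sigma=0.3, seed=1)
traj = td.make_programmed_trajectory(structure, program)
series = td.angle_series(traj, axes, groups)

print(series.round(2).to_string(index=False))
print("\n-> phi_head traces the programmed swivel (peak ~16.5 deg), the")
print("   tilt theta_head appears during back-rotation, and chi_head ~ 0")
print("   means the tilt axis is parallel to the mRNA (head moving away")
print("   from the subunit interface). Noise of 0.3 A per atom perturbs")
print("   the recovered angles by well under half a degree.")
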