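# translodyn

Structure-based modelling and trajectory analysis of mRNA–tRNA
translocation through the bacterial ribosome, at desk scale.

During translocation the mRNA and two tRNAs advance by one binding site
while the 30S subunit undergoes large collective motions: an intersubunit
(body) rotation φ_body, a swivel of the 30S head φ_head of up to ~18–20°,
and — transiently, during back-rotation of the head — a *tilt* of the head
of ~10° about an axis roughly parallel to the mRNA. `translodyn`
implements the computational machinery used to study this process with
all-atom structure-based ("Gō-like") models:

- **forcefield** — single-basin structure-based potentials (bonds, angles,
  dihedrals at native values; native contacts as 6–12 wells; inverse-12
  excluded volume), multi-basin merging of a second endpoint's contact set
  with configurable cross-group weight rescaling (ribosome↔mRNA–tRNA
  contacts ×0.3; weakened subunit and head–body interfaces), and
  steric-perturbation variants that delete the repulsion between chosen
  group pairs (e.g. protein S13 ↔ tRNA) as an ideal mutation experiment.
- **dynamics** — Langevin dynamics in reduced units (BAOAB splitting;
  production protocol dt = 0.002 at T = 0.5) with per-term energy logging,
  basin-occupancy analysis and termination predicates.
- **kinematics** — rigid-body decomposition of the head pose: after body
  alignment, the head rotation matrix is factored as
  R = R_tilt(χ_head, θ_head) · R_swivel(φ_head), with the swivel about the
  head axis and the tilt azimuth χ_head measured from the mRNA axis
  (χ_head = 0 ⇔ tilting away from the subunit interface).
- **coordinates** — the translocation reaction coordinates: ASL
  displacements after body alignment (R_P−ASL, R_A−ASL), the A-tRNA elbow
  distance (R_A−ELB), the P/E gate opening R_gate (P atoms of 16S U1340
  and A790), the ASL compaction R_A31 and the head-site distance R_pe.
- **ensembles** — normalized 2-D probability surfaces, ensemble assignment
  (chimeric ap/P–pe/E, head-tilted HT, endpoints), per-ensemble
  mean ± s.d., ensemble-average structures, FWHM of circular angle
  distributions, and conditional mean curves ⟨θ_head⟩(φ_head).
- **synthetic_data** — a geometric mini-ribosome with every named landmark
  the coordinates need, programmed-motion trajectory generation with exact
  rigid kinematics plus Gaussian noise (the ground truth for all recovery
  tests), and two-basin toy polymers with exactly controlled energy gaps.

Everything runs on synthetic fixtures generated in seconds; no structure
downloads or cluster time are required.

## Worked example

`examples/ensemble_statistics.py` pools ten synthetic translocation
events, assigns every frame to an ensemble and prints the study's core
statistics:

```
            count  phi_head_mean  phi_head_sd  theta_head_mean  theta_head_sd  R_A31_mean  R_pe_mean
HT          241.0           3.48         1.49             9.67           1.98       25.20      13.51
P/P-E/E     249.0           0.11         0.99             0.83           0.40       25.15      11.64
ap/P-pe/E   240.0          16.65         1.23             1.90           0.79       19.13      11.54
unassigned  270.0           5.28         2.15             1.16           0.88       24.93      23.75

FWHM of P(chi_head) in the HT ensemble: 23.0 deg over 241 frames
```

Reading the table: the chimeric ap/P–pe/E ensemble combines a highly
rotated head (φ_head = 16.7 ± 1.2°) with modest body rotation and
compacted tRNA anticodon stem-loops (R_A31 ≈ 19 Å, down from 25.2 Å in
the classical state); the head-tilted (HT) ensemble appears after nearly
complete back-rotation (φ_head ≈ 3.5°) with θ_head ≈ 9.7°, and the
distribution of its tilt direction is ~24° wide and centred on the mRNA
axis. The other examples demonstrate the forcefield construction, the
Langevin engine, the angle decomposition frame by frame, and the distance
coordinates (including the R_gate = 16.7 Å classical gate distance and its
opening under head swivel).

A thin CLI mirrors the library for shell pipelines:

```sh
translodyn synth trajectory --out run/ --seed 3
translodyn angles --traj run/traj.tsv --refs run/classical.pdb run/rotated.pdb \
    --groups run/groups.yaml --out run/angles.tsv
translodyn coords --traj run/traj.tsv --post run/classical.pdb \
    --groups run/groups.yaml --out run/coords.tsv
```

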