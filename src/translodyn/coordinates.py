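"""Distance reaction coordinates of translocation.

Built-in coordinates follow the study's definitions:

* ``R_P-ASL`` / ``R_A-ASL`` — distance of the anticodon stem-loop (ASL)
  centroid of the P / A site tRNA from its post-translocation position,
  measured after 30S-body alignment to the POST reference; R_P-ASL = 0
  when the tRNA occupies the 30S E site.
* ``R_A-ELB`` — distance of the A-tRNA elbow from its P/P-state location,
  after large-subunit (23S) alignment.
* ``R_gate`` — P-atom distance between 16S U1340 (head, PE loop) and A790
  (body): the P/E-site gate-opening coordinate.
* ``R_A31`` — P-atom distance between the A31 residues of the two tRNAs
  (ASL compaction).
* ``R_pe`` — P-atom distance between A31 of the P-site tRNA and A1229 of
  the 16S rRNA (P-tRNA position relative to the head).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .kinematics import kabsch_fit
from .structure_io import AtomGroup, Structure, Trajectory


class CoordinateError(ValueError):
    pass


@dataclass
class CoordinateSpec:
    """One reaction coordinate.

    kind "aligned": superpose the frame onto ``reference`` using
    ``alignment_group``, then measure the probe-centroid distance from its
    reference position. kind "pair": plain Euclidean distance between two
    single-atom groups (no alignment needed).
    """

    name: str
    kind: str                       # "aligned" | "pair"
    probe: AtomGroup
    target: AtomGroup | None = None           # pair partner
    alignment_group: AtomGroup | None = None
    reference: Structure | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("aligned", "pair"):
            raise CoordinateError(f"unknown coordinate kind {self.kind!r}")
        if self.kind == "aligned" and (self.alignment_group is None
                                       or len(self.alignment_group) == 0
                                       or self.reference is None):
            raise CoordinateError(
                f"{self.name}: aligned coordinate needs a non-empty "
                "alignment_group and a reference structure")
        if self.kind == "pair" and (self.target is None
                                    or len(self.probe) != 1
                                    or len(self.target) != 1):
            raise CoordinateError(
                f"{self.name}: pair coordinate needs two single-atom groups")


def pair_distance(frame: np.ndarray, atom_a: int, atom_b: int) -> float:
    """Euclidean distance between two atoms (Angstrom)."""
    frame = np.asarray(frame, dtype=float)
    n = len(frame)
    for idx, label in ((atom_a, "first"), (atom_b, "second")):
        if not 0 <= idx < n:
            raise CoordinateError(f"{label} atom index {idx} outside 0..{n - 1}")
    return float(np.linalg.norm(frame[atom_a] - frame[atom_b]))


def aligned_group_distance(frame: np.ndarray, spec: CoordinateSpec) -> float:
    """Probe-centroid displacement from its reference position (Angstrom)."""
    if spec.kind != "aligned":
        raise CoordinateError(f"{spec.name} is not an aligned coordinate")
    align = spec.alignment_group.members
    fit = kabsch_fit(frame[align], spec.reference.coords[align])
    probe_now = fit.apply(frame[spec.probe.members]).mean(axis=0)
    probe_ref = spec.reference.coords[spec.probe.members].mean(axis=0)
    return float(np.linalg.norm(probe_now - probe_ref))


def evaluate(frame: np.ndarray, spec: CoordinateSpec) -> float:
    if spec.kind == "pair":
        return pair_distance(frame, int(spec.probe.members[0]),
                             int(spec.target.members[0]))
    return aligned_group_distance(frame, spec)


def contact_within(frame: np.ndarray, group_a: AtomGroup, group_b: AtomGroup,
                   cutoff: float) -> tuple[bool, float]:
    """(any cross pair within cutoff, minimal cross-pair distance)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise CoordinateError("contact_within requires non-empty groups")
    dmin = float(cdist(frame[group_a.members], frame[group_b.members]).min())
    return dmin <= cutoff, dmin


def coordinate_series(trajectory: Trajectory,
                      specs: list[CoordinateSpec]) -> pd.DataFrame:
    """Per-frame evaluation of each spec; columns in spec order."""
    rows = []
    for k in range(trajectory.n_frames):
        row = {"frame": k, "time": trajectory.times[k]}
        for spec in specs:
            try:
                row[spec.name] = evaluate(trajectory.frames[k], spec)
            except CoordinateError as exc:
                raise CoordinateError(f"frame {k}, {spec.name}: {exc}") from exc
        rows.append(row)
    return pd.DataFrame(rows)


#: group names the built-in coordinate table expects
BUILTIN_GROUPS = ("body", "large", "asl_p", "asl_a", "elbow_a",
                  "gate_head", "gate_body", "a31_p", "a31_a", "a1229")


def builtin_specs(post_reference: Structure,
                  groups: dict[str, AtomGroup],
                  names: list[str] | None = None) -> list[CoordinateSpec]:
    """Instantiate the built-in coordinates against a POST reference.

    ``groups`` must resolve the names in :data:`BUILTIN_GROUPS` (single
    P atoms for the pair coordinates).
    """
    missing = [g for g in BUILTIN_GROUPS if g not in groups]
    if missing:
        raise CoordinateError(f"missing group definitions: {missing}")
    g = groups
    table = {
        "R_P-ASL": CoordinateSpec("R_P-ASL", "aligned", g["asl_p"],
                                  alignment_group=g["body"],
                                  reference=post_reference),
        "R_A-ASL": CoordinateSpec("R_A-ASL", "aligned", g["asl_a"],
                                  alignment_group=g["body"],
                                  reference=post_reference),
        "R_A-ELB": CoordinateSpec("R_A-ELB", "aligned", g["elbow_a"],
                                  alignment_group=g["large"],
                                  reference=post_reference),
        "R_gate": CoordinateSpec("R_gate", "pair", g["gate_head"],
                                 target=g["gate_body"]),
        "R_A31": CoordinateSpec("R_A31", "pair", g["a31_p"], target=g["a31_a"]),
        "R_pe": CoordinateSpec("R_pe", "pair", g["a31_p"], target=g["a1229"]),
    }
    if names is None:
        return list(table.values())
    unknown = [n for n in names if n not in table]
    if unknown:
        raise CoordinateError(f"unknown built-in coordinates: {unknown}")
    return [table[n] for n in names]
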