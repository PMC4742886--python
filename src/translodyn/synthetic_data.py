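"""Synthetic fixtures: mini-ribosome, programmed motions, two-basin polymers.

The mini-ribosome is a geometrically (not chemically) realistic bead model:
rigid body/head/large-subunit clouds, an mRNA laid along +x, two tRNAs and
the named landmarks every built-in coordinate needs (gate P atoms 16.7 A
apart in the classical pose, A31 analogues, A1229, PE-loop and S13
analogues). Domain sizes and site spacings are scaled so that programmed
motions produce angle and distance magnitudes in the translocation study's
ranges (tRNA displacements of ~25 A, head rotations up to ~20 deg).

Programmed-motion trajectories apply exact rigid rotations (tilt o swivel,
matching the kinematics convention) to the head, a body rotation to the
whole small subunit, and rigid tRNA translations solved per frame to hit
the programmed R-coordinate targets, then add iid Gaussian coordinate
noise. They are the ground truth for the recovery tests.

Two-basin polymers are short tethered-arm chains whose arm can dock on
either of two binding patches with distinct contact sets; the basin-B
contact weights are solved linearly so the two minima differ by a
requested energy gap, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from scipy.spatial.transform import Rotation

from . import forcefield as ff
from .structure_io import AtomGroup, Structure, Trajectory, resolve_groups


class SyntheticDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mini-ribosome

#: study-range geometry of the bead model (Angstrom)
E_SITE = np.array([-25.2, 10.0, 12.0])   # P-tRNA ASL centroid in POST
P_SITE = np.array([0.0, 10.0, 12.0])     # A-tRNA ASL centroid in POST
HEAD_CENTER = np.array([0.0, 0.0, 35.0])
BODY_CENTER = np.array([0.0, 0.0, 0.0])
LARGE_CENTER = np.array([0.0, -45.0, 0.0])
A790_POS = np.array([-10.0, 6.0, 8.0])
A1229_POS = np.array([-22.4, 15.0, 20.5])
S13_CENTER = np.array([12.0, 8.0, 24.0])
HEAD_AXIS = np.array([0.0, 0.0, 1.0])    # swivel axis of the construction
BODY_AXIS = np.array([0.0, 1.0, 0.0])    # intersubunit rotation axis
MRNA_AXIS = np.array([1.0, 0.0, 0.0])

SMALL_SUBUNIT_CHAINS = ("B", "H", "S", "M", "P", "A")
HEAD_CHAINS = ("H", "S")

GROUP_SPECS: dict[str, str] = {
    "body": "chain B",
    "head": "chain H or chain S",
    "large": "chain L",
    "mrna": "chain M",
    "trna_p": "chain P",
    "trna_a": "chain A",
    "asl_p": "chain P and resid 30-40",
    "asl_a": "chain A and resid 30-40",
    "elbow_a": "chain A and resid 54-60",
    "gate_head": "chain H and resid 1340 and name P",
    "gate_body": "chain B and resid 790 and name P",
    "a31_p": "chain P and resid 31",
    "a31_a": "chain A and resid 31",
    "a1229": "chain H and resid 1229",
    "s13": "chain S",
    "s13_tail": "chain S and resid 13-15",
    "pe_loop": "chain H and resid 1338-1341",
}


@dataclass
class MiniRibosomeParams:
    n_body: int = 200
    n_head: int = 100
    n_trna: int = 40
    n_mrna: int = 20
    n_large: int = 150
    n_s13: int = 15
    gate_distance: float = 16.7   # classical U1340-A790 P-atom distance
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_body, self.n_head, self.n_large) < 10 or self.n_trna < 40:
            raise SyntheticDataError("degenerate mini-ribosome parameters")
        if self.n_mrna < 4 or self.n_s13 < 5 or self.gate_distance <= 0:
            raise SyntheticDataError("degenerate mini-ribosome parameters")


def _cloud(rng: np.random.Generator, n: int, center: np.ndarray,
           sd: float) -> np.ndarray:
    return center + rng.normal(0.0, sd, size=(n, 3))


def _trna_shape(n: int) -> np.ndarray:
    """Canonical L-shaped tRNA bead geometry; residues 25..25+n-1.

    Residues 30-40 (the ASL) sit at the bottom around the local origin;
    54-60 (the elbow) ride ~18 A higher. A loose helix keeps the shape
    non-degenerate.
    """
    res = np.arange(25, 25 + n)
    t = (res - res[0]) / (len(res) - 1)
    pts = np.column_stack([
        2.0 * np.cos(2 * np.pi * 2.2 * t),
        2.0 * np.sin(2 * np.pi * 2.2 * t),
        22.0 * t - 3.0,
    ])
    asl = (res >= 30) & (res <= 40)
    pts -= pts[asl].mean(axis=0)  # local origin = ASL centroid
    return pts


def make_mini_ribosome(params: MiniRibosomeParams | None = None
                       ) -> tuple[Structure, dict[str, str]]:
    """Build the POST-state (classical, unrotated) mini-ribosome.

    Returns the structure and the group-definition mapping (group name ->
    selection expression) that resolves every built-in coordinate on it.
    """
    params = params or MiniRibosomeParams()
    rng = np.random.default_rng(params.seed)

    chains, res_ids, res_names, names, elements, coords = [], [], [], [], [], []

    def add(chain, rid, rname, aname, elem, xyz):
        chains.append(chain)
        res_ids.append(rid)
        res_names.append(rname)
        names.append(aname)
        elements.append(elem)
        coords.append(np.asarray(xyz, dtype=float))

    # 30S body (16S body analogue) + the A790 gate bead
    for k, xyz in enumerate(_cloud(rng, params.n_body, BODY_CENTER, 10.0)):
        add("B", 400 + k, "G", "P", "P", xyz)
    add("B", 790, "A", "P", "P", A790_POS)

    # 30S head: cloud + PE loop + A1229; U1340 placed at the gate distance
    for k, xyz in enumerate(_cloud(rng, params.n_head, HEAD_CENTER, 8.0)):
        add("H", 930 + k, "G", "P", "P", xyz)
    u1340 = A790_POS + np.array([0.0, 0.0, params.gate_distance])
    pe_names = {1338: "G", 1339: "G", 1340: "U", 1341: "U"}
    pe_offsets = {1338: (-1.6, 0.3, 1.0), 1339: (-0.8, -0.3, 0.5),
                  1340: (0.0, 0.0, 0.0), 1341: (0.9, 0.4, 0.8)}
    for rid in (1338, 1339, 1340, 1341):
        add("H", rid, pe_names[rid], "P", "P", u1340 + np.asarray(pe_offsets[rid]))
    add("H", 1229, "A", "P", "P", A1229_POS)

    # protein S13 (head protein, C-terminal tail between the tRNAs)
    s13 = _cloud(rng, params.n_s13, S13_CENTER, 2.5)
    s13[-3:] = S13_CENTER + np.array([0.0, 0.0, -3.0]) \
        + np.array([[0.0, 0.0, 0.0], [1.2, 0.4, -0.8], [2.4, 0.8, -1.6]])
    for k, xyz in enumerate(s13):
        add("S", 1 + k, "ALA", "CA", "C", xyz)

    # mRNA along +x through the binding track
    for k in range(params.n_mrna):
        x = -28.0 + k * (57.0 / (params.n_mrna - 1))
        add("M", 1 + k, "U", "P", "P", (x, 10.0, 8.0))

    # tRNAs in POST: the translocating (P-site) tRNA in the E site,
    # the A-site tRNA in the P site
    shape = _trna_shape(params.n_trna)
    for chain, site in (("P", E_SITE), ("A", P_SITE)):
        for k, xyz in enumerate(site + shape):
            add(chain, 25 + k, "A", "P", "P", xyz)

    # 50S (23S analogue)
    for k, xyz in enumerate(_cloud(rng, params.n_large, LARGE_CENTER, 12.0)):
        add("L", 1 + k, "G", "P", "P", xyz)

    structure = Structure(
        atom_names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        res_ids=np.asarray(res_ids, dtype=int),
        res_names=np.asarray(res_names, dtype=object),
        chain_ids=np.asarray(chains, dtype=object),
        coords=np.asarray(coords),
    )
    return structure, dict(GROUP_SPECS)


def write_groups_yaml(group_specs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(group_specs, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Programmed motion


@dataclass
class MotionProgram:
    """Per-frame rigid-motion targets (degrees / Angstrom).

    r_targets maps coordinate names (R_P-ASL, R_A-ASL, R_A31, R_pe) to
    per-frame target arrays; NaN entries leave that constraint off for the
    frame. R_A-ELB and R_gate are dependent coordinates of the rigid
    construction and cannot be programmed directly.
    """

    phi_body: np.ndarray
    phi_head: np.ndarray
    theta_head: np.ndarray
    chi_head: np.ndarray
    r_targets: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        arrays = [self.phi_body, self.phi_head, self.theta_head, self.chi_head]
        n = len(arrays[0])
        for a in arrays:
            if len(a) != n:
                raise SyntheticDataError("program arrays have unequal lengths")
        if np.any(self.theta_head < 0):
            raise SyntheticDataError("tilt targets must be >= 0")
        allowed = {"R_P-ASL", "R_A-ASL", "R_A31", "R_pe"}
        for key, vals in self.r_targets.items():
            if key not in allowed:
                raise SyntheticDataError(
                    f"{key!r} cannot be programmed (allowed: {sorted(allowed)})")
            if len(vals) != n:
                raise SyntheticDataError(f"{key} target length != {n}")
            if np.any(np.asarray(vals)[np.isfinite(vals)] < 0):
                raise SyntheticDataError(f"{key} has negative targets")
        if self.noise_sigma < 0:
            raise SyntheticDataError("noise sigma must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.phi_head)


def head_rotation_matrix(phi_deg: float, theta_deg: float,
                         chi_deg: float) -> np.ndarray:
    """R_tilt(chi, theta) . R_swivel(phi) in the construction's body frame."""
    n = HEAD_AXIS
    e1 = MRNA_AXIS
    e2 = np.cross(n, e1)
    r_swivel = Rotation.from_rotvec(np.radians(phi_deg) * n).as_matrix()
    chi = np.radians(chi_deg)
    t_axis = np.cos(chi) * e1 + np.sin(chi) * e2
    r_tilt = Rotation.from_rotvec(np.radians(theta_deg) * t_axis).as_matrix()
    return r_tilt @ r_swivel


def _sphere_intersection(r1: float, center2: np.ndarray | None,
                         r2: float | None, preferred: np.ndarray) -> np.ndarray:
    """Point with |t| = r1 (and |t - center2| = r2 if given), near ``preferred``.

    The two-sphere intersection circle is resolved deterministically toward
    the preferred direction. Raises on geometric infeasibility.
    """
    if center2 is None:
        direction = preferred if np.linalg.norm(preferred) > 1e-9 else MRNA_AXIS
        return r1 * direction / np.linalg.norm(direction)
    d = float(np.linalg.norm(center2))
    if d < 1e-9:
        raise SyntheticDataError("coincident constraint centres")
    u = center2 / d
    a = (r1**2 - r2**2 + d**2) / (2.0 * d)
    rho_sq = r1**2 - a**2
    if rho_sq < -1e-9 * max(r1, 1.0) ** 2:
        raise SyntheticDataError(
            f"infeasible R program: spheres r1={r1:.2f}, r2={r2:.2f} "
            f"at separation {d:.2f} do not intersect")
    rho = np.sqrt(max(rho_sq, 0.0))
    w = preferred - (preferred @ u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-9:   # preferred direction parallel to u: any perpendicular
        w = np.cross(u, MRNA_AXIS)
        if np.linalg.norm(w) < 1e-9:
            w = np.cross(u, np.array([0.0, 0.0, 1.0]))
        nw = np.linalg.norm(w)
    return a * u + rho * w / nw


def _solve_trna_translations(structure: Structure, groups: dict[str, AtomGroup],
                             a1229_now: np.ndarray, targets: dict[str, float]
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Rigid tRNA translations hitting the frame's R targets exactly.

    Solved sequentially in closed form: the P-tRNA translation lies on the
    R_P-ASL sphere intersected (if requested) with the R_pe sphere; the
    A-tRNA translation on the R_A-ASL sphere intersected with the R_A31
    sphere. The intersection circles are resolved toward the mRNA track
    direction, so the construction is deterministic.
    """
    c = structure.coords
    a31_p0 = c[groups["a31_p"].members][0]
    a31_a0 = c[groups["a31_a"].members][0]

    def has(key):
        return np.isfinite(targets.get(key, np.nan))

    t_p = np.zeros(3)
    if has("R_P-ASL"):
        center2 = r2 = None
        if has("R_pe"):
            center2 = a1229_now - a31_p0
            r2 = targets["R_pe"]
        t_p = _sphere_intersection(targets["R_P-ASL"], center2, r2,
                                   preferred=MRNA_AXIS)
    elif has("R_pe"):
        d = a1229_now - a31_p0
        t_p = d - targets["R_pe"] * d / np.linalg.norm(d)

    t_a = np.zeros(3)
    if has("R_A-ASL"):
        center2 = r2 = None
        if has("R_A31"):
            center2 = a31_p0 + t_p - a31_a0
            r2 = targets["R_A31"]
        t_a = _sphere_intersection(targets["R_A-ASL"], center2, r2,
                                   preferred=MRNA_AXIS)
    elif has("R_A31"):
        d = a31_p0 + t_p - a31_a0
        t_a = d - targets["R_A31"] * d / np.linalg.norm(d)
    return t_p, t_a


def make_programmed_trajectory(structure: Structure, program: MotionProgram,
                               group_specs: dict[str, str] | None = None
                               ) -> Trajectory:
    """Frames built by exact rigid motions plus iid Gaussian noise.

    Per frame: the head (chains H, S) gets R_tilt . R_swivel about the
    head pivot; tRNAs are rigidly translated to hit the frame's R targets;
    the whole small subunit is rotated by phi_body about the intersubunit
    axis; finally, noise. Seed-deterministic.
    """
    groups = resolve_groups(structure, group_specs or GROUP_SPECS)
    rng = np.random.default_rng(program.seed)
    c0 = structure.coords
    head_idx = np.isin(structure.chain_ids, HEAD_CHAINS)
    ssu_idx = np.isin(structure.chain_ids, SMALL_SUBUNIT_CHAINS)
    trna_p_idx = groups["trna_p"].members
    trna_a_idx = groups["trna_a"].members
    pivot = c0[groups["head"].members].mean(axis=0)
    body_centroid = c0[groups["body"].members].mean(axis=0)
    a1229_idx = groups["a1229"].members[0]

    frames = []
    for k in range(program.n_frames):
        coords = c0.copy()
        if program.phi_head[k] != 0.0 or program.theta_head[k] != 0.0:
            r_head = head_rotation_matrix(program.phi_head[k],
                                          program.theta_head[k],
                                          program.chi_head[k])
            coords[head_idx] = (coords[head_idx] - pivot) @ r_head.T + pivot

        targets = {name: float(vals[k])
                   for name, vals in program.r_targets.items()}
        tp, ta = _solve_trna_translations(structure, groups,
                                          coords[a1229_idx], targets)
        coords[trna_p_idx] += tp
        coords[trna_a_idx] += ta

        if program.phi_body[k] != 0.0:
            r_body = Rotation.from_rotvec(
                np.radians(program.phi_body[k]) * BODY_AXIS).as_matrix()
            coords[ssu_idx] = ((coords[ssu_idx] - body_centroid) @ r_body.T
                               + body_centroid)
        if program.noise_sigma > 0:
            coords += rng.normal(0.0, program.noise_sigma, size=coords.shape)
        frames.append(coords)
    return Trajectory(frames=np.stack(frames),
                      times=np.arange(program.n_frames, dtype=float))


def make_reference_pair(structure: Structure,
                        phi_head: float = 18.0, phi_body: float = 1.9
                        ) -> tuple[Structure, Structure]:
    """(classical, head-rotated) endpoint pair for define_reference_axes."""
    prog = MotionProgram(
        phi_body=np.array([phi_body]), phi_head=np.array([phi_head]),
        theta_head=np.array([0.0]), chi_head=np.array([0.0]),
        noise_sigma=0.0)
    traj = make_programmed_trajectory(structure, prog)
    return structure, structure.with_coords(traj.frames[0])


# ---------------------------------------------------------------------------
# Stage-resolved translocation program (the study's reported ensemble
# means and s.d. are the stage targets)

TRANSLOCATION_STAGES: tuple[dict, ...] = (
    {"name": "A/P-P/E", "phi_head": (5.0, 1.0), "theta_head": (1.0, 0.5),
     "chi_head": (0.0, 30.0), "phi_body": (0.5, 0.5),
     "R_P-ASL": (24.0, 0.8), "R_A-ASL": (24.0, 0.8)},
    {"name": "ap/P-pe/E", "phi_head": (16.5, 1.5), "theta_head": (2.0, 0.8),
     "chi_head": (0.0, 30.0), "phi_body": (1.9, 1.2),
     "R_P-ASL": (5.0, 0.5), "R_A-ASL": (6.0, 0.8),
     "R_A31": (19.1, 1.6), "R_pe": (11.5, 1.3)},
    {"name": "HT", "phi_head": (3.5, 1.5), "theta_head": (9.5, 2.2),
     "chi_head": (0.0, 10.19), "phi_body": (0.5, 0.5),
     "R_P-ASL": (3.0, 0.5), "R_A-ASL": (3.0, 0.5)},
    {"name": "P/P-E/E", "phi_head": (0.0, 1.0), "theta_head": (0.8, 0.4),
     "chi_head": (0.0, 30.0), "phi_body": (0.0, 0.4),
     "R_P-ASL": (0.6, 0.3), "R_A-ASL": (0.6, 0.3)},
)


def translocation_program(frames_per_stage: int = 30, noise_sigma: float = 0.3,
                          seed: int = 0,
                          stages: tuple[dict, ...] = TRANSLOCATION_STAGES
                          ) -> tuple[MotionProgram, np.ndarray]:
    """A translocation-like event: per-frame targets drawn per stage.

    Each stage contributes ``frames_per_stage`` frames whose angle and
    distance targets are drawn from the stage's (mean, sd); tilt targets
    are clipped at zero. Returns the program and the per-frame stage label.
    """
    rng = np.random.default_rng(seed)
    n = frames_per_stage * len(stages)

    def draw(key, lo=None, clip_sd=None):
        cols = []
        for stage in stages:
            if key not in stage:
                cols.append(np.full(frames_per_stage, np.nan))
                continue
            mu, sd = stage[key]
            vals = rng.normal(mu, sd, size=frames_per_stage)
            if clip_sd is not None:
                # R targets are truncated so the rigid tRNA construction
                # stays geometrically consistent in every frame
                vals = np.clip(vals, mu - clip_sd * sd, mu + clip_sd * sd)
            cols.append(vals)
        vals = np.concatenate(cols)
        if lo is not None:
            vals = np.maximum(vals, lo)
        return vals

    prog = MotionProgram(
        phi_body=np.nan_to_num(draw("phi_body")),
        phi_head=np.nan_to_num(draw("phi_head")),
        theta_head=draw("theta_head", lo=0.0),
        chi_head=np.nan_to_num(draw("chi_head")),
        r_targets={k: draw(k, lo=0.0, clip_sd=1.5)
                   for k in ("R_P-ASL", "R_A-ASL", "R_A31", "R_pe")},
        noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31)),
    )
    labels = np.repeat([s["name"] for s in stages], frames_per_stage)
    assert len(labels) == n
    return prog, labels


# ---------------------------------------------------------------------------
# Two-basin polymer


def _polymer_conformations(n_atoms: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Tethered-arm chain with parity-split docking faces.

    The backbone is a high-zigzag bead chain (even beads low, odd beads
    raised); a rigid arm is bonded to the backbone's end. Docked above
    (conformation A) the arm reaches only the raised odd beads; docked
    below (conformation B) only the low even beads are within the contact
    cutoff, so the two basins have disjoint cross-contact sets. The arm's
    internal geometry and the tether bond length are identical in both
    conformations; only the hinge terms at the tether differ (and are
    zeroed by the builder), leaving the arm free to swing between faces.
    """
    if n_atoms < 8:
        raise SyntheticDataError("two-basin polymer needs at least 8 atoms")
    n_arm = max(3, n_atoms // 2 - 1)
    m = n_atoms - n_arm
    if (m - 1) % 2 == 1:       # tether bead must be a low (even) bead
        n_arm += 1
        m -= 1
    zig = 1.2
    backbone = np.column_stack([1.5 * np.arange(m), np.zeros(m),
                                zig * (np.arange(m) % 2)])
    # arm: flat in z, small y-zigzag to keep angles non-degenerate
    arm_shape = np.column_stack([-1.5 * np.arange(n_arm),
                                 0.3 * (np.arange(n_arm) % 2),
                                 np.zeros(n_arm)])
    tether = backbone[-1]
    z_above = 4.2              # within cutoff of odd beads only
    z_below = -3.0             # within cutoff of even beads only
    bond_len = z_above         # tether bead is low, so |A bond| = z_above
    conf_a = np.vstack([backbone,
                        tether + np.array([0.0, 0.0, z_above]) + arm_shape])
    dx = np.sqrt(bond_len**2 - z_below**2)   # keep the tether bond length
    conf_b = np.vstack([backbone,
                        tether + np.array([-dx, 0.0, z_below]) + arm_shape])
    return conf_a, conf_b, m


def make_two_basin_polymer(n_atoms: int = 12, gap: float = 5.0,
                           params: ff.ForcefieldParams | None = None
                           ) -> tuple[Structure, Structure, ff.Topology]:
    """Two conformations + merged topology with an exact energy gap.

    Bonded terms come from conformation A; any angle/dihedral whose native
    value differs between the conformations (the tether hinge terms) has
    its force constant zeroed, so both conformations sit at the bonded
    minimum and the arm reorients freely between the basins. Basin-B
    contact weights are solved linearly so that
    U(B) - U(A) = ``gap`` exactly; an unachievable gap (weights <= 0)
    raises.
    """
    params = params or ff.ForcefieldParams(min_seq_sep=3)
    conf_a, conf_b, _ = _polymer_conformations(n_atoms)

    def as_structure(coords):
        n = len(coords)
        return Structure(
            atom_names=np.asarray(["CA"] * n, dtype=object),
            elements=np.asarray(["C"] * n, dtype=object),
            res_ids=np.arange(1, n + 1),
            res_names=np.asarray(["GLY"] * n, dtype=object),
            chain_ids=np.asarray(["C"] * n, dtype=object),
            coords=coords)

    struct_a, struct_b = as_structure(conf_a), as_structure(conf_b)
    topo = ff.build_single_basin(struct_a, params, basin="A")

    # tether-hinge terms: zero whatever differs between the conformations
    if len(topo.bonds):
        rb = np.linalg.norm(conf_b[topo.bonds[:, 0]]
                            - conf_b[topo.bonds[:, 1]], axis=1)
        if np.max(np.abs(rb - topo.bond_r0)) > 1e-9:
            raise SyntheticDataError("bond lengths differ between conformations")
    if len(topo.angles):
        th_b = ff._angle(conf_b, topo.angles)
        topo.k_angle[np.abs(th_b - topo.angle_theta0) > 1e-9] = 0.0
    if len(topo.dihedrals):
        ph_b = ff._dihedral(conf_b, topo.dihedrals)
        dd = np.abs(np.angle(np.exp(1j * (ph_b - topo.dihedral_phi0))))
        topo.k_dihedral[dd > 1e-9] = 0.0

    cmap_b = ff.compute_contact_map(struct_b, params.cutoff,
                                    params.min_seq_sep, basin="B")
    set_a = set(zip(topo.contacts.i, topo.contacts.j))
    set_b = set(zip(cmap_b.i, cmap_b.j))
    if cmap_b.n_contacts == 0 or set_a == set_b or not (set_b - set_a):
        raise SyntheticDataError("conformations do not have distinct contact sets")

    # linear solve for the basin-B weight scale: U(X; lam) = C(X) + lam*S_B(X)
    def contact_sum(coords):
        r = np.linalg.norm(coords[cmap_b.i] - coords[cmap_b.j], axis=1)
        s6 = (cmap_b.r0 / r) ** 6
        return float(np.sum(s6 * s6 - 2.0 * s6))

    merged0 = ff.merge_basins(topo, cmap_b)
    # C(X): merged energy minus the unit-weight basin-B contact term
    c_a = ff.potential_energy(merged0, conf_a).total - contact_sum(conf_a)
    c_b = ff.potential_energy(merged0, conf_b).total - contact_sum(conf_b)
    s_a, s_b = contact_sum(conf_a), contact_sum(conf_b)
    denom = s_b - s_a
    if abs(denom) < 1e-12:
        raise SyntheticDataError("basin-B contacts do not discriminate the basins")
    lam = (gap - (c_b - c_a)) / denom
    if lam <= 0:
        raise SyntheticDataError(
            f"gap {gap} unachievable with positive basin-B weights (scale {lam:.3g})")
    cmap_b_scaled = ff.ContactMap(cmap_b.i, cmap_b.j, cmap_b.r0,
                                  cmap_b.weight * lam, cmap_b.basin)
    merged = ff.merge_basins(topo, cmap_b_scaled)
    return struct_a, struct_b, merged
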