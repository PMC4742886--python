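"""Multi-basin all-atom structure-based potential.

A single-basin structure-based model places the global potential-energy
minimum at an experimentally derived structure: bonds, angles and dihedrals
are harmonic/cosine terms at their native values, native contacts are 6-12
wells with minimum -epsilon*weight at the native separation r0, and all
remaining pairs feel a short-range inverse-12 repulsion. A multi-basin
model merges the contact set of a second endpoint conformation into the
first basin's topology, so the chain is stabilised at two adjacent binding
configurations at once; cross-group contact weights (ribosome vs mRNA-tRNA,
subunit and head-body interfaces) are rescaled by configurable rules.

Steric-perturbation variants remove the generic repulsion between chosen
group pairs (e.g. protein S13 vs the tRNAs) without touching attractive
contacts, mimicking an ideal mutation experiment.

Energies are in reduced units (epsilon = 1); lengths in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomGroup, Structure


class ForcefieldError(ValueError):
    pass


@dataclass
class ContactMap:
    """Native-contact list: pairs (i<j) with native distance and weight."""

    i: np.ndarray
    j: np.ndarray
    r0: np.ndarray
    weight: np.ndarray
    basin: np.ndarray  # str label per contact

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.r0 = np.asarray(self.r0, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        self.basin = np.asarray(self.basin, dtype=object)
        if np.any(self.i >= self.j):
            raise ForcefieldError("contact pairs must satisfy i < j")
        if np.any(self.r0 <= 0):
            raise ForcefieldError("contact r0 must be positive")
        keys = list(zip(self.i, self.j, self.basin))
        if len(set(keys)) != len(keys):
            raise ForcefieldError("duplicate (i, j, basin) contact")

    @property
    def n_contacts(self) -> int:
        return len(self.i)

    @classmethod
    def empty(cls) -> "ContactMap":
        z = np.array([], dtype=int)
        return cls(z, z, np.array([]), np.array([]), np.array([], dtype=object))


@dataclass(frozen=True)
class ScaleRule:
    """Multiply the weight of contacts crossing two groups by ``factor``."""

    group_a: str
    group_b: str
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ForcefieldError("scale factors must be positive")


@dataclass
class ForcefieldParams:
    """Tunable constants of the structure-based potential (reduced units).

    cutoff / min_seq_sep control the native contact map; sigma_ex is the
    uniform excluded-volume diameter; repulsion is force-shifted to zero at
    sigma_ex so native structures remain exact stationary points.
    """

    cutoff: float = 4.0          # contact cutoff, Angstrom
    min_seq_sep: int = 4         # minimum intra-chain residue separation
    k_bond: float = 100.0        # reduced units / A^2
    k_angle: float = 40.0        # reduced units / rad^2
    sigma_ex: float = 2.5        # excluded-volume diameter, Angstrom
    eps_ex: float = 0.01
    stabilization_per_atom: float = 1.0
    contact_dihedral_ratio: float = 2.0  # contact:dihedral energy partition


@dataclass
class Topology:
    """The assembled potential: bonded terms, contacts, exclusions, sterics."""

    n_atoms: int
    bonds: np.ndarray            # (nb, 2)
    bond_r0: np.ndarray
    k_bond: np.ndarray
    angles: np.ndarray           # (na, 3)
    angle_theta0: np.ndarray
    k_angle: np.ndarray
    dihedrals: np.ndarray        # (nd, 4)
    dihedral_phi0: np.ndarray
    k_dihedral: np.ndarray
    contacts: ContactMap
    sigma_ex: float
    eps_ex: float
    exclusions: frozenset        # {(i, j)} exempt from generic repulsion
    steric_deletions: frozenset = frozenset()   # extra deleted repulsion pairs
    steric_deletion_labels: tuple = ()          # ((group_a, group_b), ...)
    _rep_pairs: np.ndarray | None = field(default=None, repr=False, compare=False)

    def repulsion_pairs(self) -> np.ndarray:
        """All (i<j) pairs subject to generic repulsion, cached."""
        if self._rep_pairs is None:
            iu, ju = np.triu_indices(self.n_atoms, k=1)
            dead = self.exclusions | self.steric_deletions
            keep = np.fromiter(((a, b) not in dead for a, b in zip(iu, ju)),
                               dtype=bool, count=len(iu))
            object.__setattr__(self, "_rep_pairs",
                               np.column_stack([iu[keep], ju[keep]]))
        return self._rep_pairs


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    contact: float
    repulsion: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.contact + self.repulsion


# ---------------------------------------------------------------------------
# Contact map


def compute_contact_map(structure: Structure, cutoff: float = 4.0,
                        min_seq_sep: int = 4, basin: str = "native") -> ContactMap:
    """All heavy-atom pairs within ``cutoff`` satisfying the separation rule.

    Intra-chain pairs must be at least ``min_seq_sep`` residues apart;
    inter-chain pairs are always eligible. Hydrogens are ignored. Each
    contact carries its native distance and weight 1.
    """
    heavy = np.asarray([e.upper() != "H" for e in structure.elements])
    idx = np.nonzero(heavy)[0]
    if len(set(zip(structure.chain_ids, structure.res_ids))) < 2:
        warnings.warn("structure has fewer than 2 residues; contact map is empty")
        return ContactMap.empty()
    tree = cKDTree(structure.coords[idx])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return ContactMap.empty()
    ai, aj = idx[pairs[:, 0]], idx[pairs[:, 1]]
    swap = ai > aj
    ai[swap], aj[swap] = aj[swap], ai[swap]
    same_chain = structure.chain_ids[ai] == structure.chain_ids[aj]
    sep = np.abs(structure.res_ids[ai] - structure.res_ids[aj])
    keep = ~same_chain | (sep >= min_seq_sep)
    ai, aj = ai[keep], aj[keep]
    order = np.lexsort((aj, ai))
    ai, aj = ai[order], aj[order]
    r0 = np.linalg.norm(structure.coords[ai] - structure.coords[aj], axis=1)
    return ContactMap(ai, aj, r0, np.ones(len(ai)),
                      np.full(len(ai), basin, dtype=object))


# ---------------------------------------------------------------------------
# Topology construction


def _chain_connectivity(structure: Structure) -> np.ndarray:
    """Bead-chain bonds: consecutive atoms within each chain.

    The toy systems are bead models with one atom per residue; a residue
    holding several atoms has no connectivity template here and is rejected.
    """
    chains = structure.chain_ids
    res = structure.res_ids
    counts: dict[tuple, int] = {}
    for c, r in zip(chains, res):
        counts[(c, r)] = counts.get((c, r), 0) + 1
    bad = [k for k, v in counts.items() if v > 1]
    if bad:
        c, r = bad[0]
        raise ForcefieldError(
            f"no bonded connectivity template for residue {r} of chain {c} "
            f"({counts[(c, r)]} atoms); bead models require one atom per residue")
    bonds = []
    for k in range(structure.n_atoms - 1):
        if chains[k] == chains[k + 1]:
            bonds.append((k, k + 1))
    return np.asarray(bonds, dtype=int).reshape(-1, 2)


def _consecutive_tuples(bonds: np.ndarray, order: int) -> np.ndarray:
    """Angles (order=3) / dihedrals (order=4) from a bead-chain bond list."""
    bond_set = {tuple(b) for b in bonds}
    out = []
    for (i, j) in bonds:
        run = [i, j]
        while len(run) < order and (run[-1], run[-1] + 1) in bond_set:
            run.append(run[-1] + 1)
        if len(run) == order:
            out.append(tuple(run))
    return np.asarray(out, dtype=int).reshape(-1, order)


def _angle(coords: np.ndarray, triples: np.ndarray) -> np.ndarray:
    u = coords[triples[:, 0]] - coords[triples[:, 1]]
    v = coords[triples[:, 2]] - coords[triples[:, 1]]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedral(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    b1 = coords[quads[:, 1]] - coords[quads[:, 0]]
    b2 = coords[quads[:, 2]] - coords[quads[:, 1]]
    b3 = coords[quads[:, 3]] - coords[quads[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


def _bonded_exclusions(bonds: np.ndarray, angles: np.ndarray,
                       dihedrals: np.ndarray) -> set:
    excl = set()
    for b in bonds:
        excl.add((min(b), max(b)))
    for a in angles:
        excl.add((min(a[0], a[2]), max(a[0], a[2])))
    for d in dihedrals:
        excl.add((min(d[0], d[3]), max(d[0], d[3])))
    return excl


def build_single_basin(structure: Structure,
                       params: ForcefieldParams | None = None,
                       basin: str = "native") -> Topology:
    """Single-basin topology with the input structure as stationary point.

    Bonded terms take their native values; contacts come from
    :func:`compute_contact_map`. The total stabilizing (contact + dihedral)
    energy is normalized to ``stabilization_per_atom * n_atoms``, split
    contact:dihedral by ``contact_dihedral_ratio``. Any non-contact,
    non-bonded pair closer than sigma_ex at the native coordinates is added
    to the exclusion list, so the native structure carries zero net force.
    """
    params = params or ForcefieldParams()
    coords = structure.coords
    bonds = _chain_connectivity(structure)
    angles = _consecutive_tuples(bonds, 3)
    dihedrals = _consecutive_tuples(bonds, 4)
    cmap = compute_contact_map(structure, params.cutoff, params.min_seq_sep,
                               basin=basin)

    # stabilization budget
    e_total = params.stabilization_per_atom * structure.n_atoms
    ratio = params.contact_dihedral_ratio
    n_d = len(dihedrals)
    if cmap.n_contacts and n_d:
        e_contact = e_total * ratio / (1.0 + ratio)
        e_dih = e_total / (1.0 + ratio)
    elif cmap.n_contacts:
        e_contact, e_dih = e_total, 0.0
    else:
        e_contact, e_dih = 0.0, e_total if n_d else 0.0
    weight = cmap.weight * (e_contact / cmap.n_contacts if cmap.n_contacts else 1.0)
    cmap = replace(cmap, weight=weight)
    k_d = np.full(n_d, e_dih / n_d if n_d else 0.0)

    excl = _bonded_exclusions(bonds, angles, dihedrals)
    excl |= {(int(a), int(b)) for a, b in zip(cmap.i, cmap.j)}
    # pairs inside repulsion range at the native coordinates that are neither
    # bonded nor contacts are treated as part of the reference and excluded
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(params.sigma_ex):
        excl.add((min(a, b), max(a, b)))

    topo = Topology(
        n_atoms=structure.n_atoms,
        bonds=bonds, bond_r0=np.linalg.norm(
            coords[bonds[:, 0]] - coords[bonds[:, 1]], axis=1) if len(bonds)
            else np.array([]),
        k_bond=np.full(len(bonds), params.k_bond),
        angles=angles, angle_theta0=_angle(coords, angles) if len(angles)
            else np.array([]),
        k_angle=np.full(len(angles), params.k_angle),
        dihedrals=dihedrals,
        dihedral_phi0=_dihedral(coords, dihedrals) if n_d else np.array([]),
        k_dihedral=k_d,
        contacts=cmap,
        sigma_ex=params.sigma_ex, eps_ex=params.eps_ex,
        exclusions=frozenset(excl),
    )
    return topo


def merge_basins(base: Topology, extra_contacts: ContactMap,
                 rules: list[ScaleRule] | None = None,
                 groups: dict[str, AtomGroup] | None = None) -> Topology:
    """Merge a second basin's contacts into ``base`` and apply scale rules.

    Contacts present in both basins are kept as two independently labelled
    terms, each with its own r0 and (scaled) weight, preserving both minima.
    Rules rescale every contact whose endpoints fall one in group_a and one
    in group_b (searched across the merged set). Basin-A contacts keep their
    pair list and r0 values exactly.
    """
    if extra_contacts.n_contacts == 0 and not rules:
        return base
    cm = base.contacts
    merged = ContactMap(
        np.concatenate([cm.i, extra_contacts.i]),
        np.concatenate([cm.j, extra_contacts.j]),
        np.concatenate([cm.r0, extra_contacts.r0]),
        np.concatenate([cm.weight, extra_contacts.weight]),
        np.concatenate([cm.basin, extra_contacts.basin]),
    )
    if rules:
        if groups is None:
            raise ForcefieldError("scale rules given without group definitions")
        weight = merged.weight.copy()
        for rule in rules:
            for gname in (rule.group_a, rule.group_b):
                if gname not in groups:
                    raise ForcefieldError(
                        f"scale rule references undefined group {gname!r}")
            in_a = np.zeros(base.n_atoms, dtype=bool)
            in_a[groups[rule.group_a].members] = True
            in_b = np.zeros(base.n_atoms, dtype=bool)
            in_b[groups[rule.group_b].members] = True
            cross = ((in_a[merged.i] & in_b[merged.j])
                     | (in_b[merged.i] & in_a[merged.j]))
            weight[cross] *= rule.factor
        merged = replace(merged, weight=weight)
    excl = set(base.exclusions)
    excl |= {(int(a), int(b)) for a, b in zip(extra_contacts.i, extra_contacts.j)}
    return replace(base, contacts=merged, exclusions=frozenset(excl),
                   _rep_pairs=None)


def remove_steric_pairs(topology: Topology, group_a: AtomGroup,
                        group_b: AtomGroup) -> Topology:
    """Disable generic repulsion between every cross pair of two groups.

    Attractive contacts between the groups are untouched. The operation is
    idempotent and composable (set semantics on the deleted-pair list).
    Overlapping groups are rejected: removing self-sterics is never intended.
    """
    if set(group_a.members) & set(group_b.members):
        raise ForcefieldError(
            f"groups {group_a.name!r} and {group_b.name!r} overlap")
    dele = {(min(int(a), int(b)), max(int(a), int(b)))
            for a in group_a.members for b in group_b.members}
    labels = topology.steric_deletion_labels
    lab = (group_a.name, group_b.name)
    if lab not in labels:
        labels = labels + (lab,)
    return replace(topology,
                   steric_deletions=frozenset(topology.steric_deletions | dele),
                   steric_deletion_labels=labels, _rep_pairs=None)


# ---------------------------------------------------------------------------
# Energy and forces


def _repulsion_energy(topology: Topology, coords: np.ndarray) -> float:
    pairs = topology.repulsion_pairs()
    if len(pairs) == 0:
        return 0.0
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    rc = topology.sigma_ex
    mask = r < rc
    if not mask.any():
        return 0.0
    r = r[mask]
    s = topology.sigma_ex / r
    # force-shifted inverse-12: energy and force both vanish at r = sigma_ex
    e = topology.eps_ex * (s**12 - 1.0 + 12.0 * (r - rc) / rc)
    return float(e.sum())


def potential_energy(topology: Topology, coords: np.ndarray) -> EnergyBreakdown:
    """Per-term potential energy (reduced units) at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ForcefieldError(
            f"coordinate shape {coords.shape} != ({topology.n_atoms}, 3)")
    e_bond = e_angle = e_dih = e_contact = 0.0
    if len(topology.bonds):
        r = np.linalg.norm(coords[topology.bonds[:, 0]]
                           - coords[topology.bonds[:, 1]], axis=1)
        e_bond = float(np.sum(topology.k_bond * (r - topology.bond_r0) ** 2))
    if len(topology.angles):
        th = _angle(coords, topology.angles)
        e_angle = float(np.sum(topology.k_angle * (th - topology.angle_theta0) ** 2))
    if len(topology.dihedrals):
        phi = _dihedral(coords, topology.dihedrals)
        dphi = phi - topology.dihedral_phi0
        e_dih = float(np.sum(topology.k_dihedral
                             * ((1 - np.cos(dphi)) + 0.5 * (1 - np.cos(3 * dphi)))))
    cm = topology.contacts
    if cm.n_contacts:
        r = np.linalg.norm(coords[cm.i] - coords[cm.j], axis=1)
        s6 = (cm.r0 / r) ** 6
        e_contact = float(np.sum(cm.weight * (s6 * s6 - 2.0 * s6)))
    e_rep = _repulsion_energy(topology, coords)
    return EnergyBreakdown(e_bond, e_angle, e_dih, e_contact, e_rep)


def forces(topology: Topology, coords: np.ndarray) -> np.ndarray:
    """Analytic forces -dU/dx, shape (n_atoms, 3)."""
    coords = np.asarray(coords, dtype=float)
    f = np.zeros_like(coords)

    if len(topology.bonds):
        bi, bj = topology.bonds[:, 0], topology.bonds[:, 1]
        d = coords[bi] - coords[bj]
        r = np.linalg.norm(d, axis=1)
        # dE/dr = 2 k (r - r0)
        fmag = -2.0 * topology.k_bond * (r - topology.bond_r0) / r
        fv = fmag[:, None] * d
        np.add.at(f, bi, fv)
        np.add.at(f, bj, -fv)

    if len(topology.angles):
        a, b, c = (topology.angles[:, k] for k in range(3))
        u = coords[a] - coords[b]
        v = coords[c] - coords[b]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh, vh = u / nu[:, None], v / nv[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        sinang = np.sqrt(np.clip(1.0 - cosang**2, 1e-16, None))
        th = np.arccos(cosang)
        dEdth = 2.0 * topology.k_angle * (th - topology.angle_theta0)
        ga = (cosang[:, None] * uh - vh) / (nu * sinang)[:, None]
        gc = (cosang[:, None] * vh - uh) / (nv * sinang)[:, None]
        np.add.at(f, a, -dEdth[:, None] * ga)
        np.add.at(f, c, -dEdth[:, None] * gc)
        np.add.at(f, b, dEdth[:, None] * (ga + gc))

    if len(topology.dihedrals):
        qi, qj, qk, ql = (topology.dihedrals[:, k] for k in range(4))
        b1 = coords[qj] - coords[qi]
        b2 = coords[qk] - coords[qj]
        b3 = coords[ql] - coords[qk]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m = np.cross(n1, b2 / nb2[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m, n2)
        phi = np.arctan2(y, x)
        dphi = phi - topology.dihedral_phi0
        dEdphi = topology.k_dihedral * (np.sin(dphi) + 1.5 * np.sin(3 * dphi))
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        gi = (nb2 / n1sq)[:, None] * n1
        gl = -(nb2 / n2sq)[:, None] * n2
        s12 = np.einsum("ij,ij->i", b1, b2) / nb2**2
        s32 = np.einsum("ij,ij->i", b3, b2) / nb2**2
        gj = -(1.0 + s12)[:, None] * gi + s32[:, None] * gl
        gk = s12[:, None] * gi - (1.0 + s32)[:, None] * gl
        for idx, g in ((qi, gi), (qj, gj), (qk, gk), (ql, gl)):
            np.add.at(f, idx, -dEdphi[:, None] * g)

    cm = topology.contacts
    if cm.n_contacts:
        d = coords[cm.i] - coords[cm.j]
        r = np.linalg.norm(d, axis=1)
        s6 = (cm.r0 / r) ** 6
        # dE/dr = 12 w (s6 - s12)/r
        dEdr = 12.0 * cm.weight * (s6 - s6 * s6) / r
        fv = -(dEdr / r)[:, None] * d
        np.add.at(f, cm.i, fv)
        np.add.at(f, cm.j, -fv)

    pairs = topology.repulsion_pairs()
    if len(pairs):
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        rc = topology.sigma_ex
        mask = r < rc
        if mask.any():
            pi, pj = pairs[mask, 0], pairs[mask, 1]
            rm = r[mask]
            dm = d[mask]
            s12 = (topology.sigma_ex / rm) ** 12
            # dE/dr = eps * (-12 s12 / r + 12 / rc)
            dEdr = topology.eps_ex * 12.0 * (1.0 / rc - s12 / rm)
            fv = -(dEdr / rm)[:, None] * dm
            np.add.at(f, pi, fv)
            np.add.at(f, pj, -fv)
    return f


# ---------------------------------------------------------------------------
# Serialization


def topology_to_json(topology: Topology) -> dict:
    """JSON-serializable dict of a topology (documented schema, version 1)."""
    cm = topology.contacts
    return {
        "schema": "translodyn-topology-1",
        "n_atoms": topology.n_atoms,
        "bonds": topology.bonds.tolist(),
        "bond_r0": topology.bond_r0.tolist(),
        "k_bond": topology.k_bond.tolist(),
        "angles": topology.angles.tolist(),
        "angle_theta0": topology.angle_theta0.tolist(),
        "k_angle": topology.k_angle.tolist(),
        "dihedrals": topology.dihedrals.tolist(),
        "dihedral_phi0": topology.dihedral_phi0.tolist(),
        "k_dihedral": topology.k_dihedral.tolist(),
        "contacts": {
            "i": cm.i.tolist(), "j": cm.j.tolist(), "r0": cm.r0.tolist(),
            "weight": cm.weight.tolist(), "basin": cm.basin.tolist(),
        },
        "sigma_ex": topology.sigma_ex,
        "eps_ex": topology.eps_ex,
        "exclusions": sorted([int(a), int(b)] for a, b in topology.exclusions),
        "steric_deletions": sorted([int(a), int(b)]
                                   for a, b in topology.steric_deletions),
        "steric_deletion_labels": [list(p) for p in topology.steric_deletion_labels],
    }


def topology_from_json(data: dict) -> Topology:
    if data.get("schema") != "translodyn-topology-1":
        raise ForcefieldError(f"unknown topology schema {data.get('schema')!r}")
    cm = data["contacts"]
    return Topology(
        n_atoms=int(data["n_atoms"]),
        bonds=np.asarray(data["bonds"], dtype=int).reshape(-1, 2),
        bond_r0=np.asarray(data["bond_r0"], dtype=float),
        k_bond=np.asarray(data["k_bond"], dtype=float),
        angles=np.asarray(data["angles"], dtype=int).reshape(-1, 3),
        angle_theta0=np.asarray(data["angle_theta0"], dtype=float),
        k_angle=np.asarray(data["k_angle"], dtype=float),
        dihedrals=np.asarray(data["dihedrals"], dtype=int).reshape(-1, 4),
        dihedral_phi0=np.asarray(data["dihedral_phi0"], dtype=float),
        k_dihedral=np.asarray(data["k_dihedral"], dtype=float),
        contacts=ContactMap(
            np.asarray(cm["i"], dtype=int), np.asarray(cm["j"], dtype=int),
            np.asarray(cm["r0"], dtype=float),
            np.asarray(cm["weight"], dtype=float),
            np.asarray(cm["basin"], dtype=object)),
        sigma_ex=float(data["sigma_ex"]),
        eps_ex=float(data["eps_ex"]),
        exclusions=frozenset((int(a), int(b)) for a, b in data["exclusions"]),
        steric_deletions=frozenset(
            (int(a), int(b)) for a, b in data["steric_deletions"]),
        steric_deletion_labels=tuple(
            tuple(p) for p in data["steric_deletion_labels"]),
    )
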