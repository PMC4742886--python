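"""Rigid-body decomposition of 30S motions.

The small-subunit head pose in each frame, expressed in the body frame
after body alignment, is a single rotation R. It is factored as

    R = R_tilt(chi, theta) . R_swivel(phi)

with the swivel applied first: R_swivel rotates about the fixed head
(swivel) axis n by the signed angle phi_head, and R_tilt is the minimal
rotation carrying n to R.n — a rotation by theta_head >= 0 about an axis
perpendicular to n whose azimuth chi_head is measured from the projection
of the mRNA axis into the plane perpendicular to n. chi_head = 0 thus
means tilting about an axis parallel to the mRNA, displacing the head away
from the subunit interface; chi_head = +-90 deg is tilting perpendicular
to the mRNA. The factorization is exact for any R with R.n != -n.

Angles are reported in degrees; internal computation is in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomGroup, Structure, Trajectory

import pandas as pd


class KinematicsError(ValueError):
    pass


THETA_FLOOR_DEG = 0.5  # below this tilt, the azimuth is numerically meaningless


@dataclass
class RigidBodyFit:
    """Optimal proper rotation + translation mapping mobile onto reference."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidBodyFit:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Requires >= 3 non-collinear points. The returned fit maps mobile
    coordinates as x -> R x + t.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[0] < 3:
        raise KinematicsError("need matching (n>=3, 3) coordinate sets")
    cm_m = mobile.mean(axis=0)
    cm_r = reference.mean(axis=0)
    a = mobile - cm_m
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise KinematicsError("degenerate (collinear) point set; fit ill-defined")
    rot, rssd = Rotation.align_vectors(reference - cm_r, a)
    r = rot.as_matrix()
    return RigidBodyFit(rotation=r, translation=cm_r - r @ cm_m,
                        rmsd=float(rssd) / np.sqrt(len(mobile)))


@dataclass
class ReferenceAxes:
    """Fixed geometric frame against which all angles are defined.

    Built from a reference pair of endpoint structures (classical and
    head-rotated); carries the classical reference coordinates of the
    fitted groups so that per-frame decompositions are self-contained.
    """

    body_frame: np.ndarray     # rows e1 (mRNA projection), e2, e3 (= head axis)
    head_axis: np.ndarray
    mrna_axis: np.ndarray
    body_axis: np.ndarray
    origin: np.ndarray
    body_ref: np.ndarray       # classical body-group coordinates
    head_ref: np.ndarray       # classical head-group coordinates
    large_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        for ax in (self.head_axis, self.mrna_axis, self.body_axis):
            if abs(np.linalg.norm(ax) - 1.0) > 1e-8:
                raise KinematicsError("reference axes must be unit vectors")
        if abs(abs(self.head_axis @ self.mrna_axis) - 1.0) < 1e-6:
            raise KinematicsError("head axis parallel to mRNA axis")


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def define_reference_axes(classical: Structure, head_rotated: Structure,
                          mrna_group: AtomGroup, body_group: AtomGroup,
                          head_group: AtomGroup,
                          large_group: AtomGroup | None = None,
                          min_head_angle: float = 2.0) -> ReferenceAxes:
    """Derive the swivel axis, mRNA axis and body frame from a reference pair.

    The swivel axis is the rotation axis of the head-group fit between the
    two endpoint structures, expressed in the classical body frame and
    oriented so the classical -> rotated transition has positive phi_head.
    The mRNA axis is the principal axis of the mRNA group, sign-resolved
    along the first-to-last atom direction (the 5'->3' analogue). The body
    (intersubunit) axis comes from the body-group rotation after alignment
    on the large subunit, when a large-subunit group and a body-rotated
    reference are available; otherwise it falls back to the swivel axis.
    """
    if not classical.same_atoms(head_rotated):
        raise KinematicsError("reference structures must share atom indexing")
    b = body_group.members
    h = head_group.members
    fit_body = kabsch_fit(head_rotated.coords[b], classical.coords[b])
    rot_head_aligned = fit_body.apply(head_rotated.coords[h])
    r_head = kabsch_fit(classical.coords[h], rot_head_aligned).rotation
    rotvec = Rotation.from_matrix(r_head).as_rotvec()
    angle = np.linalg.norm(rotvec)
    if np.degrees(angle) < min_head_angle:
        raise KinematicsError(
            f"head rotation between references is {np.degrees(angle):.2f} deg "
            f"(< {min_head_angle}); swivel axis ill-defined")
    head_axis = rotvec / angle

    m = mrna_group.members
    mrna_axis = _principal_axis(classical.coords[m])
    span = classical.coords[m[-1]] - classical.coords[m[0]]
    if mrna_axis @ span < 0:
        mrna_axis = -mrna_axis

    e3 = head_axis
    e1 = mrna_axis - (mrna_axis @ e3) * e3
    n1 = np.linalg.norm(e1)
    if n1 < 1e-8:
        raise KinematicsError("mRNA axis parallel to head axis")
    e1 /= n1
    e2 = np.cross(e3, e1)

    body_axis = head_axis
    large_ref = None
    if large_group is not None:
        lg = large_group.members
        large_ref = classical.coords[lg].copy()
        fit_large = kabsch_fit(head_rotated.coords[lg], classical.coords[lg])
        body_aligned = fit_large.apply(head_rotated.coords[b])
        rv = Rotation.from_matrix(
            kabsch_fit(classical.coords[b], body_aligned).rotation).as_rotvec()
        if np.degrees(np.linalg.norm(rv)) >= 0.5:
            body_axis = rv / np.linalg.norm(rv)

    return ReferenceAxes(
        body_frame=np.vstack([e1, e2, e3]),
        head_axis=head_axis, mrna_axis=mrna_axis, body_axis=body_axis,
        origin=classical.coords[h].mean(axis=0),
        body_ref=classical.coords[b].copy(),
        head_ref=classical.coords[h].copy(),
        large_ref=large_ref,
    )


def factor_tilt_swivel(r: np.ndarray, head_axis: np.ndarray,
                       chi_reference: np.ndarray) -> tuple[float, float, float]:
    """Factor a rotation matrix as R = R_tilt . R_swivel; degrees out.

    Returns (phi, theta, chi); chi is NaN when theta < THETA_FLOOR_DEG.
    """
    n = head_axis
    n2 = r @ n
    cos_t = float(np.clip(n @ n2, -1.0, 1.0))
    theta = float(np.arccos(cos_t))
    if np.degrees(theta) < THETA_FLOOR_DEG:
        r_swivel = r
        chi = np.nan
    else:
        t_axis = np.cross(n, n2)
        t_axis /= np.linalg.norm(t_axis)
        r_tilt = Rotation.from_rotvec(theta * t_axis).as_matrix()
        r_swivel = r_tilt.T @ r
        e1 = chi_reference
        chi = float(np.degrees(np.arctan2(np.cross(e1, t_axis) @ n, e1 @ t_axis)))
        if chi <= -180.0:
            chi += 360.0
    rv = Rotation.from_matrix(r_swivel).as_rotvec()
    phi = float(np.degrees(rv @ n))
    return phi, float(np.degrees(theta)), chi


def decompose_head_rotation(frame: np.ndarray, refaxes: ReferenceAxes,
                            body_group: AtomGroup, head_group: AtomGroup,
                            max_fit_rmsd: float = 2.0
                            ) -> tuple[float, float, float]:
    """(phi_head, theta_head, chi_head) of one frame, in degrees.

    The frame is body-aligned internally; a head-fit RMSD above
    ``max_fit_rmsd`` signals non-rigid deformation beyond the model's
    assumptions and raises.
    """
    fit_body = kabsch_fit(frame[body_group.members], refaxes.body_ref)
    head_now = fit_body.apply(frame[head_group.members])
    head_fit = kabsch_fit(refaxes.head_ref, head_now)
    if head_fit.rmsd > max_fit_rmsd:
        raise KinematicsError(
            f"head fit RMSD {head_fit.rmsd:.2f} A exceeds {max_fit_rmsd}; "
            "head is not behaving rigidly")
    return factor_tilt_swivel(head_fit.rotation, refaxes.head_axis,
                              refaxes.body_frame[0])


def body_rotation(frame: np.ndarray, refaxes: ReferenceAxes,
                  body_group: AtomGroup, large_subunit_group: AtomGroup) -> float:
    """Signed body rotation (degrees) about the intersubunit axis."""
    if refaxes.large_ref is None:
        raise KinematicsError(
            "reference axes were built without a large-subunit group")
    fit_large = kabsch_fit(frame[large_subunit_group.members], refaxes.large_ref)
    body_now = fit_large.apply(frame[body_group.members])
    rv = Rotation.from_matrix(
        kabsch_fit(refaxes.body_ref, body_now).rotation).as_rotvec()
    return float(np.degrees(rv @ refaxes.body_axis))


def angle_series(trajectory: Trajectory, refaxes: ReferenceAxes,
                 groups: dict[str, AtomGroup]) -> pd.DataFrame:
    """Per-frame angle decomposition of a trajectory.

    ``groups`` must provide "body" and "head"; "large" enables phi_body.
    Columns: frame, time, phi_body, phi_head, theta_head, chi_head
    (chi_head is NaN below the tilt floor). Errors are re-raised with the
    offending frame index.
    """
    body = groups["body"]
    head = groups["head"]
    large = groups.get("large")
    rows = []
    for k in range(trajectory.n_frames):
        coords = trajectory.frames[k]
        try:
            phi, theta, chi = decompose_head_rotation(coords, refaxes, body, head)
            phi_b = (body_rotation(coords, refaxes, body, large)
                     if large is not None else np.nan)
        except KinematicsError as exc:
            raise KinematicsError(f"frame {k}: {exc}") from exc
        rows.append({"frame": k, "time": trajectory.times[k], "phi_body": phi_b,
                     "phi_head": phi, "theta_head": theta, "chi_head": chi})
    return pd.DataFrame(rows)
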