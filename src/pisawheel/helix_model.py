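"""Ideal α-helix backbone generation and per-residue NMR frames.

Builds a polyalanine-like backbone from (φ, ψ) by iterated standard
peptide geometry, canonicalizes it so the helical screw axis is +z through
the origin, and derives the per-residue amide N-H unit vectors and the
¹⁵N chemical-shift-anisotropy (CSA) principal-axis frames that the
oriented-sample forward model consumes.

Conventions: trans peptide bonds (ω = 180°); the amide proton lies in the
peptide plane, trans to the carbonyl oxygen; the σ33 principal axis lies
in the peptide plane at ``beta_deg`` from the N-H bond, rotated toward the
preceding carbonyl carbon, and σ22 is normal to the peptide plane — the
common convention in PISA-wheel modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BondGeometry",
    "TensorOrientation",
    "HelixGeometry",
    "build_helix",
    "nh_axis_angle",
    "csa_frames",
    "write_pdb",
]


@dataclass(frozen=True)
class BondGeometry:
    """Standard backbone bond lengths (Å) and angles (deg).

    PISA observables depend only weakly on these; they are fixed library
    constants, configurable for sensitivity checks.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    n_h: float = 1.02
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 117.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_c_n_h: float = 119.5


@dataclass(frozen=True)
class TensorOrientation:
    """Orientation of the ¹⁵N CSA tensor in the peptide-plane frame.

    ``beta_deg`` is the angle between the σ33 axis and the N-H bond,
    measured in the peptide plane toward the N→C' direction.  σ22 is
    normal to the peptide plane.  Default 17° is the common amide value.
    """

    beta_deg: float = 17.0
    sigma22_normal: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_deg < 90.0:
            raise ValueError(f"beta_deg must be in [0, 90), got {self.beta_deg}")


@dataclass
class HelixGeometry:
    """Backbone coordinates and per-residue frames of an ideal helix.

    All coordinates are in the molecule frame: the helical screw axis is
    +z through the origin, residue numbering runs N→C with rise in +z.

    ``nh_vectors`` and ``csa_frames`` are defined for residues 2..n (the
    first residue has no amide proton from a preceding carbonyl); entries
    for residue 1 are NaN.  ``csa_frames[i]`` rows are the unit axes of
    (σ11, σ22, σ33).
    """

    n_residues: int
    phi: float
    psi: float
    n_coords: np.ndarray      # (n, 3)
    ca_coords: np.ndarray     # (n, 3)
    c_coords: np.ndarray      # (n, 3)
    o_coords: np.ndarray      # (n, 3)
    h_coords: np.ndarray      # (n, 3), row 0 NaN
    nh_vectors: np.ndarray    # (n, 3) unit, row 0 NaN
    csa_frames: np.ndarray | None  # (n, 3, 3), row 0 NaN
    twist_deg: float
    rise: float
    axis: np.ndarray          # canonically +z

    def interior(self) -> np.ndarray:
        """Indices (0-based) of residues with both N-H and CSA data."""
        return np.arange(1, self.n_residues)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d.

    Given chain a-b-c, returns d with |c-d| = bond, angle(b,c,d) =
    ``angle_deg`` and dihedral(a,b,c,d) = ``dihedral_deg``.
    """
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi: float, psi: float, n_residues: int, omega: float,
                    geo: BondGeometry):
    """Iterated peptide-geometry chain in an arbitrary frame."""
    N = np.zeros((n_residues, 3))
    CA = np.zeros((n_residues, 3))
    C = np.zeros((n_residues, 3))

    # seed residue: N at origin, CA along +x, C in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (geo.n_ca, 0.0, 0.0)
    ang = np.radians(geo.ang_n_ca_c)
    C[0] = CA[0] + geo.ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_residues):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           geo.c_n, geo.ang_ca_c_n, psi)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            geo.n_ca, geo.ang_c_n_ca, omega)
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           geo.ca_c, geo.ang_n_ca_c, phi)

    # carbonyl O: in the peptide plane, anti to the next N (dihedral
    # N-CA-C-O = psi + 180); the last residue uses the same rule.
    O = np.empty_like(N)
    for i in range(n_residues):
        O[i] = _place_atom(N[i], CA[i], C[i], geo.c_o, geo.ang_ca_c_o,
                           psi + 180.0)

    # amide H on residues 1..n-1: in the peptide plane, trans to the
    # carbonyl O across the C-N bond (dihedral CA(i-1)-C(i-1)-N(i)-H = 0).
    H = np.full_like(N, np.nan)
    for i in range(1, n_residues):
        H[i] = _place_atom(CA[i - 1], C[i - 1], N[i], geo.n_h,
                           geo.ang_c_n_h, 0.0)
    return N, CA, C, O, H


def _screw_from_superposition(P: np.ndarray, Q: np.ndarray):
    """Rigid transform Q ≈ R P + t by Kabsch; returns (R, t)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    Hm = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def _axis_of_rotation(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit rotation axis and angle (deg) of a proper rotation matrix."""
    w, v = np.linalg.eig(R)
    k = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, k])
    axis /= np.linalg.norm(axis)
    cos_t = (np.trace(R) - 1.0) / 2.0
    angle = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    # fix the sign of the angle relative to the axis direction
    test = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        test = np.array([0.0, 1.0, 0.0])
    perp = test - (test @ axis) * axis
    perp /= np.linalg.norm(perp)
    rotated = R @ perp
    if np.cross(perp, rotated) @ axis < 0:
        angle = -angle
    return axis, angle


def build_helix(phi: float, psi: float, n_residues: int, omega: float = 180.0,
                geometry: BondGeometry | None = None,
                orientation: TensorOrientation | None = None) -> HelixGeometry:
    """Build an ideal helix and canonicalize its screw axis to +z.

    Parameters
    ----------
    phi, psi : float
        Backbone torsion angles in degrees (e.g. −69, −42 for the slightly
        tighter-than-canonical TM helix used here; −57.8, −47 canonical).
    n_residues : int
        Number of residues, at least 2.
    omega : float
        Peptide-bond torsion, 180° for trans.

    The backbone is generated residue by residue from standard bond
    geometry, the residue-to-residue screw transform is extracted by
    superposition, and the whole chain is rigidly moved so the screw axis
    is +z through the origin with rise in +z.  Degenerate torsions giving
    (near-)zero rise are rejected.
    """
    if n_residues < 2:
        raise ValueError(f"n_residues must be >= 2, got {n_residues}")
    geo = geometry or BondGeometry()
    N, CA, C, O, H = _build_backbone(phi, psi, n_residues, omega, geo)

    # screw transform mapping residue i onto residue i+1, averaged over the
    # whole chain by superposing the residue-shifted backbone onto itself
    P = np.concatenate([N[:-1], CA[:-1], C[:-1]])
    Q = np.concatenate([N[1:], CA[1:], C[1:]])
    R, t = _screw_from_superposition(P, Q)
    axis, twist = _axis_of_rotation(R)
    rise = float(t @ axis)
    if abs(rise) < 1e-3:
        raise ValueError(
            f"torsions (phi={phi}, psi={psi}) give a degenerate non-helical "
            f"trace (rise {rise:.2e} Å per residue)"
        )
    if rise < 0:  # orient the axis so the chain rises N→C
        axis, twist, rise = -axis, -twist, -rise

    # point on the axis: (I - R) p = t_perp
    t_perp = t - (t @ axis) * axis
    A = np.eye(3) - R
    p0, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p0 = p0 - (p0 @ axis) * axis  # any axis point will do; fix the gauge

    # rigid map: translate axis point to origin, rotate axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, cth = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        Rot = np.eye(3) if cth > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        Rot = np.eye(3) + vx + vx @ vx * ((1 - cth) / s**2)

    def xform(X):
        return (X - p0) @ Rot.T

    N, CA, C, O = xform(N), xform(CA), xform(C), xform(O)
    H = xform(H)
    # center the helix along z
    z0 = np.concatenate([N, CA, C]).mean(axis=0)[2]
    for X in (N, CA, C, O, H):
        X[:, 2] -= z0

    nh = H - N
    with np.errstate(invalid="ignore"):
        nh = nh / np.linalg.norm(nh, axis=1, keepdims=True)

    h = HelixGeometry(
        n_residues=n_residues, phi=phi, psi=psi,
        n_coords=N, ca_coords=CA, c_coords=C, o_coords=O, h_coords=H,
        nh_vectors=nh, csa_frames=None,
        twist_deg=float(twist), rise=rise, axis=z.copy(),
    )
    csa_frames(h, orientation or TensorOrientation())
    return h


def nh_axis_angle(h: HelixGeometry) -> float:
    """Angle (deg) between the N-H bond vectors and the helical axis.

    For an ideal helix this angle is identical for every interior residue;
    the mean over residues 2..n is returned.  The angle is folded to the
    acute line angle (the N→H vectors point toward the N-terminus, i.e.
    antiparallel to the rise direction); it sets the radius of the dipolar
    dimension of the PISA wheel (near 15° for canonical torsions).
    """
    cosines = np.abs(h.nh_vectors[1:] @ h.axis)
    return float(np.degrees(np.arccos(np.clip(cosines, -1, 1))).mean())


def csa_frames(h: HelixGeometry,
               orient: TensorOrientation) -> HelixGeometry:
    """Populate per-residue ¹⁵N CSA principal-axis frames in place.

    For residue i (i ≥ 2) the σ33 axis lies in the peptide plane of the
    i−1 → i amide, at ``orient.beta_deg`` from the N-H bond rotated toward
    the preceding carbonyl carbon; σ22 is the peptide-plane normal; σ11
    completes the right-handed triad.
    """
    n = h.n_residues
    beta = np.radians(orient.beta_deg)
    frames = np.full((n, 3, 3), np.nan)
    for i in range(1, n):
        u_nh = h.nh_vectors[i]
        u_nc = h.c_coords[i - 1] - h.n_coords[i]
        u_nc = u_nc / np.linalg.norm(u_nc)
        e22 = np.cross(u_nh, u_nc)
        e22 /= np.linalg.norm(e22)
        # in-plane direction perpendicular to N-H, toward C'
        w = u_nc - (u_nc @ u_nh) * u_nh
        w /= np.linalg.norm(w)
        e33 = np.cos(beta) * u_nh + np.sin(beta) * w
        e11 = np.cross(e22, e33)
        frames[i] = np.stack([e11, e22, e33])
    h.csa_frames = frames
    return h


def write_pdb(h: HelixGeometry, path: str | Path) -> None:
    """Write the backbone as a minimal PDB file for visual inspection."""
    lines = []
    serial = 1
    for i in range(h.n_residues):
        atoms = [("N", h.n_coords[i]), ("CA", h.ca_coords[i]),
                 ("C", h.c_coords[i]), ("O", h.o_coords[i])]
        if i > 0:
            atoms.append(("H", h.h_coords[i]))
        for name, xyz in atoms:
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}ALA A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
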