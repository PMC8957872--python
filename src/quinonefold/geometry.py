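"""Low-level Cartesian geometry: internal-coordinate atom placement (NeRF),
signed dihedrals, and least-squares rigid-body superposition.

All angles are in degrees at the public surface; lengths in Ångstroms.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "place_atom",
    "bond_angle",
    "dihedral_angle",
    "kabsch",
    "superpose_points",
]


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Position a new atom D given three reference positions.

    D is placed so that |D-c| = bond, angle(D, c, b) = angle_deg and the
    signed dihedral D-c-b-a equals dihedral_deg (natural extension
    reference frame, the standard Z-matrix convention).

    Implemented with scalar math: this sits in the inner loop of the
    torsion-space optimizer and is called tens of thousands of times.
    """
    ax, ay, az = a
    bx, by, bz = b
    cx, cy, cz = c

    theta = math.radians(angle_deg)
    phi = -math.radians(dihedral_deg)  # sign: measured dihedral == requested

    # local displacement in the frame where bc is -x
    d2 = bond * math.cos(math.pi - theta)
    dy = bond * math.sin(math.pi - theta) * math.cos(phi)
    dz = bond * math.sin(math.pi - theta) * math.sin(phi)

    # frame axes
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    nbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nbc, bcy / nbc, bcz / nbc

    abx, aby, abz = bx - ax, by - ay, bz - az
    # n = ab x bc (normal of the a-b-c plane)
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms: dihedral frame undefined")
    nx, ny, nz = nx / nn, ny / nn, nz / nn

    # m = n x bc
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx

    return (
        cx + d2 * bcx + dy * mx + dz * nx,
        cy + d2 * bcy + dy * my + dz * ny,
        cz + d2 * bcz + dy * mz + dz * nz,
    )


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    v = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    cosx = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosx))))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing |R P + t - Q|.

    P, Q are (n, 3) paired coordinate arrays. Returns (R, t) such that
    P @ R.T + t best matches Q in the least-squares sense.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if P.shape[0] < 3:
        raise ValueError("at least 3 points required for a unique superposition")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def superpose_points(P: np.ndarray, Q: np.ndarray) -> tuple[float, np.ndarray]:
    """Superpose P onto Q; return (RMSD over the pairing, transformed P)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    # degenerate (collinear) subsets leave a rotation freedom undetermined
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom subset")
    R, t = kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return rmsd, moved
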