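"""Parameterized lipoquinone topologies (UQ-n, MK-n) with idealized internal
coordinates.

A topology is a Z-matrix-style recipe: every atom after the first three is
placed relative to three earlier atoms by a bond length, a bond angle and a
dihedral. Dihedrals are either fixed constants (ring geometry, E-configured
double bonds) or references to named torsions, so a single torsion assignment
deterministically embeds a full Cartesian conformer.

Geometry is idealized: regular rings (1.40 Å sides), standard bond lengths
(Csp3-Csp3 1.53 Å, C=C 1.34 Å, C=O 1.22 Å, C-H 1.09 Å), tetrahedral and
trigonal angles. Sub-0.1 Å fidelity is immaterial to the 1 Å-wide NOE
distance bins this model feeds.

Proton groups follow the field's labeling for the UQ-2/MK-2 systems:
H_W ring methyl, H_MN first allylic methylene, H_B/H_A proximal/distal vinyl
protons, H_X first-isoprene methyl, H_Y/H_Z terminal methyls, H_QR mid-chain
methylenes, H_J/H_K the two methoxys (UQ only), H_Ar aromatic protons
(MK only). Equivalent protons (methyl rotors, methylene pairs, the two
methoxys' overlap partners) are treated as single named groups throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ZEntry", "Topology", "build_topology"]

# ideal internal coordinates (Å, degrees)
R_RING = 1.40
R_CC_SP3 = 1.53
R_CAR_C = 1.50
R_CSP3_CSP2 = 1.50
R_CDB = 1.34
R_CO_DB = 1.22
R_CAR_O = 1.36
R_O_CH3 = 1.43
R_CH = 1.09
A_TET = 109.5
A_TRIG = 120.0
A_COC = 117.0


@dataclass(frozen=True)
class ZEntry:
    """One internal-coordinate placement record.

    ``dihedral`` is a fixed value in degrees, or ``(torsion_name, offset)``
    meaning the named torsion's current value plus a constant offset.
    """

    element: str
    name: str
    refs: tuple[int, ...]  # (a, b, c) earlier atom indices; shorter for atoms 0-2
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float | tuple[str, float] = 0.0


@dataclass
class Topology:
    headgroup: str
    n_units: int
    zmatrix: list[ZEntry]
    extra_bonds: list[tuple[int, int]]  # ring-closure bonds not implied by parents
    torsion_defaults: dict[str, float]  # named torsions with default values
    backbone_torsions: list[str]  # rotatable side-chain torsions (optimized)
    rotor_torsions: list[str]  # methyl/methoxy rotors (sampled, not optimized)
    proton_groups: dict[str, list[int]]
    phi_atoms: tuple[int, int, int, int]  # C2, C3, Cβ, Cγ
    headgroup_atoms: list[int]  # ring + exocyclic heavy atoms, for superposition

    @property
    def n_atoms(self) -> int:
        return len(self.zmatrix)

    @property
    def elements(self) -> list[str]:
        return [z.element for z in self.zmatrix]

    @property
    def atom_names(self) -> list[str]:
        return [z.name for z in self.zmatrix]

    def bonds(self) -> list[tuple[int, int]]:
        """Bond list: each atom bonds to its placement parent, plus closures."""
        out = []
        for i, z in enumerate(self.zmatrix):
            if i == 0:
                continue
            parent = z.refs[0] if i <= 2 else z.refs[-1]
            out.append((min(parent, i), max(parent, i)))
        out.extend(self.extra_bonds)
        return sorted(set(out))

    def molecular_formula(self) -> str:
        counts: dict[str, int] = {}
        for el in self.elements:
            counts[el] = counts.get(el, 0) + 1
        parts = []
        for el in ("C", "H"):
            if el in counts:
                n = counts.pop(el)
                parts.append(el if n == 1 else f"{el}{n}")
        for el in sorted(counts):
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def heavy_atoms(self) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el != "H"]

    def steric_pairs(self) -> list[tuple[int, int]]:
        """Heavy-atom pairs ≥ 3 bonds apart (soft-sphere repulsion candidates)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds())
        heavy = self.heavy_atoms()
        dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
        pairs = []
        for ii, i in enumerate(heavy):
            near = dist.get(i, {})
            for j in heavy[ii + 1:]:
                if j not in near:
                    pairs.append((i, j))
        return pairs


class _Builder:
    def __init__(self) -> None:
        self.z: list[ZEntry] = []
        self.idx: dict[str, int] = {}

    def add(self, element: str, name: str, refs: tuple[int, ...] = (),
            bond: float = 0.0, angle: float = 0.0,
            dihedral: float | tuple[str, float] = 0.0) -> int:
        i = len(self.z)
        self.z.append(ZEntry(element, name, refs, bond, angle, dihedral))
        self.idx[name] = i
        return i

    def methyl(self, carbon: int, b: int, a: int, rotor: str,
               prefix: str) -> list[int]:
        return [
            self.add("H", f"{prefix}{k + 1}", (a, b, carbon), R_CH, A_TET,
                     (rotor, 120.0 * k))
            for k in range(3)
        ]


def _quinone_core(bld: _Builder) -> None:
    """Benzoquinone ring C1..C6 as a planar regular hexagon."""
    bld.add("C", "C1")
    bld.add("C", "C2", (0,), R_RING)
    bld.add("C", "C3", (1, 0), R_RING, A_TRIG)
    bld.add("C", "C4", (0, 1, 2), R_RING, A_TRIG, 0.0)
    bld.add("C", "C5", (1, 2, 3), R_RING, A_TRIG, 0.0)
    bld.add("C", "C6", (2, 3, 4), R_RING, A_TRIG, 0.0)


def _side_chain(bld: _Builder, n_units: int, attach: tuple[int, int, int],
                groups: dict[str, list[int]], torsions: dict[str, float],
                backbone: list[str], rotors: list[str]) -> int:
    """Append an n-unit all-E isoprenyl chain at ``attach`` = (a, b, c) where
    c is the ring carbon bearing the chain. Returns the Cβ index of unit 1."""
    a, b, c = attach
    cb1 = -1
    for i in range(1, n_units + 1):
        phi_name = "phi" if i == 1 else f"phi{i}"
        psi_name = f"psi{i}"
        if i == 1:
            cb = bld.add("C", "CB1", (a, b, c), R_CAR_C, A_TRIG, 180.0)
            cb1 = cb
            parent, grand = c, b
        else:
            # cb placed off the previous linker CH2 via tau_{i-1}
            tau_prev = f"tau{i - 1}"
            cb = bld.add("C", f"CB{i}", (prev_cg, prev_cd, prev_c4),
                         R_CC_SP3, A_TET, (tau_prev, 0.0))
            parent, grand = prev_c4, prev_cd
        cg = bld.add("C", f"CG{i}", (grand, parent, cb), R_CSP3_CSP2, A_TET,
                     (phi_name, 0.0))
        torsions[phi_name] = 180.0
        backbone.append(phi_name)
        h1 = bld.add("H", f"HB{i}a", (grand, parent, cb), R_CH, A_TET,
                     (phi_name, 120.0))
        h2 = bld.add("H", f"HB{i}b", (grand, parent, cb), R_CH, A_TET,
                     (phi_name, -120.0))
        if i == 1:
            groups["H_MN"] = [h1, h2]
        else:
            groups.setdefault("H_QR", []).extend([h1, h2])
        cd = bld.add("C", f"CD{i}", (parent, cb, cg), R_CDB, A_TRIG,
                     (psi_name, 0.0))
        torsions[psi_name] = 180.0
        backbone.append(psi_name)
        hv = bld.add("H", f"HV{i}", (parent, cb, cg), R_CH, A_TRIG,
                     (psi_name, 180.0))
        if i == 1:
            groups["H_B"] = [hv]
        if i == n_units:
            groups["H_A"] = [hv]
        # trisubstituted E double bond: methyl cis to Cβ, chain trans
        cx = bld.add("C", f"CX{i}", (cb, cg, cd), R_CSP3_CSP2, A_TRIG, 0.0)
        c4 = bld.add("C", f"C4p{i}", (cb, cg, cd), R_CSP3_CSP2, A_TRIG, 180.0)
        rot_x = f"rotx{i}"
        torsions[rot_x] = 60.0
        rotors.append(rot_x)
        hx = bld.methyl(cx, cd, cg, rot_x, f"HX{i}_")
        if i == 1:
            groups["H_X"] = hx
        if i == n_units:
            groups["H_Z"] = hx
        if i < n_units:
            tau_name = f"tau{i}"
            torsions[tau_name] = 180.0
            backbone.append(tau_name)
            hq1 = bld.add("H", f"HQ{i}a", (cg, cd, c4), R_CH, A_TET,
                          (tau_name, 120.0))
            hq2 = bld.add("H", f"HQ{i}b", (cg, cd, c4), R_CH, A_TET,
                          (tau_name, -120.0))
            groups.setdefault("H_QR", []).extend([hq1, hq2])
        else:
            rot_y = f"roty{i}"
            torsions[rot_y] = 60.0
            rotors.append(rot_y)
            groups["H_Y"] = bld.methyl(c4, cd, cg, rot_y, f"HY{i}_")
        prev_cg, prev_cd, prev_c4 = cg, cd, c4
    return cb1


def _build_uq(n_units: int) -> Topology:
    bld = _Builder()
    _quinone_core(bld)
    groups: dict[str, list[int]] = {}
    torsions: dict[str, float] = {}
    backbone: list[str] = []
    rotors: list[str] = []

    bld.add("O", "O1", (4, 5, 0), R_CO_DB, A_TRIG, 180.0)
    cw = bld.add("C", "CW", (5, 0, 1), R_CAR_C, A_TRIG, 180.0)
    o4 = bld.add("O", "O4", (1, 2, 3), R_CO_DB, A_TRIG, 180.0)
    o5 = bld.add("O", "O5", (2, 3, 4), R_CAR_O, A_TRIG, 180.0)
    cj = bld.add("C", "CJ", (3, 4, o5), R_O_CH3, A_COC, 90.0)
    o6 = bld.add("O", "O6", (3, 4, 5), R_CAR_O, A_TRIG, 180.0)
    ck = bld.add("C", "CK", (4, 5, o6), R_O_CH3, A_COC, -90.0)

    torsions["rotw"] = 60.0
    rotors.append("rotw")
    groups["H_W"] = bld.methyl(cw, 1, 0, "rotw", "HW")
    torsions["rotj"] = 180.0
    rotors.append("rotj")
    groups["H_J"] = bld.methyl(cj, o5, 4, "rotj", "HJ")
    torsions["rotk"] = 180.0
    rotors.append("rotk")
    groups["H_K"] = bld.methyl(ck, o6, 5, "rotk", "HK")

    if n_units > 0:
        cb1 = _side_chain(bld, n_units, (0, 1, 2), groups, torsions,
                          backbone, rotors)
        phi_atoms = (1, 2, cb1, bld.idx["CG1"])
    else:
        bld.add("H", "H3", (0, 1, 2), R_CH, A_TRIG, 180.0)
        phi_atoms = (1, 2, 2, 2)  # no side chain: φ undefined

    head = [bld.idx[n] for n in
            ("C1", "C2", "C3", "C4", "C5", "C6", "O1", "O4", "CW", "O5", "O6")]
    return Topology("UQ", n_units, bld.z, [(0, 5)], torsions, backbone,
                    rotors, groups, phi_atoms, head)


def _build_mk(n_units: int) -> Topology:
    bld = _Builder()
    # quinonoid ring: C1 C2 C3 C4 C4a C8a
    bld.add("C", "C1")
    bld.add("C", "C2", (0,), R_RING)
    bld.add("C", "C3", (1, 0), R_RING, A_TRIG)
    bld.add("C", "C4", (0, 1, 2), R_RING, A_TRIG, 0.0)
    c4a = bld.add("C", "C4a", (1, 2, 3), R_RING, A_TRIG, 0.0)
    c8a = bld.add("C", "C8a", (2, 3, 4), R_RING, A_TRIG, 0.0)
    # fused benzo ring, coplanar
    c5 = bld.add("C", "C5", (2, 3, c4a), R_RING, A_TRIG, 180.0)
    c6 = bld.add("C", "C6", (3, c4a, c5), R_RING, A_TRIG, 180.0)
    c7 = bld.add("C", "C7", (c4a, c5, c6), R_RING, A_TRIG, 0.0)
    c8 = bld.add("C", "C8", (c5, c6, c7), R_RING, A_TRIG, 0.0)

    groups: dict[str, list[int]] = {}
    torsions: dict[str, float] = {}
    backbone: list[str] = []
    rotors: list[str] = []

    bld.add("O", "O1", (2, 1, 0), R_CO_DB, A_TRIG, 180.0)
    cw = bld.add("C", "CW", (c8a, 0, 1), R_CAR_C, A_TRIG, 180.0)
    bld.add("O", "O4", (1, 2, 3), R_CO_DB, A_TRIG, 180.0)
    har = [
        bld.add("H", "H5", (3, c4a, c5), R_CH, A_TRIG, 0.0),
        bld.add("H", "H6", (c4a, c5, c6), R_CH, A_TRIG, 180.0),
        bld.add("H", "H7", (c5, c6, c7), R_CH, A_TRIG, 180.0),
        bld.add("H", "H8", (c6, c7, c8), R_CH, A_TRIG, 180.0),
    ]
    groups["H_Ar"] = har
    torsions["rotw"] = 60.0
    rotors.append("rotw")
    groups["H_W"] = bld.methyl(cw, 1, 0, "rotw", "HW")

    if n_units > 0:
        cb1 = _side_chain(bld, n_units, (0, 1, 2), groups, torsions,
                          backbone, rotors)
        phi_atoms = (1, 2, cb1, bld.idx["CG1"])
    else:
        bld.add("H", "H3", (0, 1, 2), R_CH, A_TRIG, 180.0)
        phi_atoms = (1, 2, 2, 2)

    head = [bld.idx[n] for n in ("C1", "C2", "C3", "C4", "C4a", "C8a",
                                 "C5", "C6", "C7", "C8", "O1", "O4", "CW")]
    return Topology("MK", n_units, bld.z, [(0, c8a), (c8, c8a)], torsions,
                    backbone, rotors, groups, phi_atoms, head)


def build_topology(headgroup: str, n_units: int) -> Topology:
    """Build a UQ-n or MK-n topology with n isoprene units.

    ``headgroup`` is ``"UQ"`` (2,3-dimethoxy-5-methyl-benzoquinone core) or
    ``"MK"`` (2-methyl-naphthoquinone core).
    """
    if n_units < 0:
        raise ValueError("n_units must be nonnegative")
    hg = headgroup.upper()
    if hg == "UQ":
        return _build_uq(n_units)
    if hg == "MK":
        return _build_mk(n_units)
    raise ValueError(f"unknown headgroup {headgroup!r}; expected 'UQ' or 'MK'")
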