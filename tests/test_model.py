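"""Topology composition, embedding round trips, group distances,
superposition, restrained fitting and the conformation taxonomy."""

import itertools

import numpy as np
import pytest

from quinonefold.geometry import dihedral_angle, superpose_points
from quinonefold.model import (ClassifyConfig, classify_conformation, embed,
                               fit_conformer, group_distance, measure_phi,
                               reference_conformer, superpose)
from quinonefold.noe import DistanceRestraint
from quinonefold.topology import build_topology


class TestTopology:
    @pytest.mark.parametrize("headgroup,n,formula", [
        ("UQ", 2, "C19H26O4"),   # matches the HRMS composition for M+H C19H27O4
        ("UQ", 0, "C9H10O4"),    # two C5H8 units removed
        ("MK", 2, "C21H24O2"),   # menadione C11H8O2 + geranyl C10H17 - H
        ("MK", 0, "C11H8O2"),
    ])
    def test_molecular_formula(self, headgroup, n, formula):
        assert build_topology(headgroup, n).molecular_formula() == formula

    def test_formula_against_rdkit(self, uq2):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula

        smiles = "COC1=C(OC)C(=O)C(C)=C(C/C=C(C)/CC/C=C(C)C)C1=O"
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        assert CalcMolFormula(mol) == uq2.molecular_formula()

    def test_unknown_headgroup_rejected(self):
        with pytest.raises(ValueError, match="headgroup"):
            build_topology("PQ", 2)

    def test_proton_groups_nonempty_and_disjoint(self, uq2, mk2):
        for topo in (uq2, mk2):
            seen = set()
            for name, members in topo.proton_groups.items():
                assert members, name
                assert not (set(members) & seen)
                seen.update(members)
                assert all(topo.elements[i] == "H" for i in members)

    def test_uq2_has_expected_groups(self, uq2):
        assert set(uq2.proton_groups) >= {
            "H_W", "H_J", "H_K", "H_MN", "H_A", "H_B", "H_X", "H_Y", "H_Z",
            "H_QR"}

    def test_bond_lengths_are_ideal(self, uq2, mk2):
        for topo in (uq2, mk2):
            conf = embed(topo)
            for a, b in topo.bonds():
                d = np.linalg.norm(conf.coords[a] - conf.coords[b])
                assert 1.0 < d < 1.6, (topo.atom_names[a], topo.atom_names[b])


class TestEmbed:
    def test_torsion_round_trip_on_grid(self, uq2):
        for name in uq2.backbone_torsions:
            for angle in np.arange(-180.0, 181.0, 15.0):
                conf = embed(uq2, {name: float(angle)})
                z = next(z for z in uq2.zmatrix
                         if isinstance(z.dihedral, tuple)
                         and z.dihedral == (name, 0.0))
                i = uq2.zmatrix.index(z)
                a, b, c = z.refs
                got = dihedral_angle(conf.coords[a], conf.coords[b],
                                     conf.coords[c], conf.coords[i])
                want = float(angle)
                if want <= -180.0:
                    want += 360.0
                assert got == pytest.approx(want, abs=1e-6)

    def test_phi_round_trip(self, uq2):
        assert measure_phi(embed(uq2, {"phi": 93.0})) == pytest.approx(93.0,
                                                                       abs=1e-6)

    def test_coplanar_phi_cases(self, uq2):
        assert measure_phi(embed(uq2, {"phi": 0.0})) == pytest.approx(0.0,
                                                                      abs=1e-6)
        assert abs(measure_phi(embed(uq2, {"phi": 180.0}))) == pytest.approx(
            180.0, abs=1e-6)

    def test_deterministic(self, uq2):
        t = {"phi": 77.0, "psi1": -30.0}
        c1, c2 = embed(uq2, t), embed(uq2, t)
        assert np.array_equal(c1.coords, c2.coords)

    def test_anti_backbone_maximizes_end_to_end(self):
        """Brute-force 10° scan: no torsion assignment beats the all-anti
        chain for end-to-end heavy-atom extension (UQ-1, 2 backbone
        torsions)."""
        topo = build_topology("UQ", 1)
        i0 = topo.atom_names.index("O1")
        i1 = topo.atom_names.index("C4p1")  # chain-terminal carbon

        def extent(tor):
            c = embed(topo, tor)
            return float(np.linalg.norm(c.coords[i0] - c.coords[i1]))

        anti = extent({n: 180.0 for n in topo.backbone_torsions})
        grid = np.arange(-180.0, 180.0, 10.0)
        best = max(extent({"phi": float(a), "psi1": float(b)})
                   for a, b in itertools.product(grid, grid))
        assert best <= anti + 1e-9


class TestGroupDistance:
    def test_euclidean_on_singletons(self, uq2):
        conf = embed(uq2)
        conf.coords[uq2.proton_groups["H_B"][0]] = (0.0, 0.0, 0.0)
        conf.coords[uq2.proton_groups["H_A"][0]] = (3.0, 4.0, 0.0)
        for mode in ("mean", "r6"):
            assert group_distance(conf, "H_A", "H_B", mode) == pytest.approx(5.0)

    def test_symmetric(self, uq2):
        conf = embed(uq2)
        assert group_distance(conf, "H_W", "H_Y") == group_distance(
            conf, "H_Y", "H_W")

    def test_r6_below_mean(self, uq2):
        conf = embed(uq2)
        for ga, gb in [("H_W", "H_MN"), ("H_W", "H_Y"), ("H_J", "H_K")]:
            assert group_distance(conf, ga, gb, "r6") <= group_distance(
                conf, ga, gb, "mean")

    def test_overlapping_groups_rejected(self, uq2):
        conf = embed(uq2)
        with pytest.raises(ValueError, match="overlap"):
            group_distance(conf, "H_W", "H_W")


class TestSuperpose:
    def test_identical_is_zero(self, uq2):
        c = embed(uq2)
        rmsd, _ = superpose(c, c)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, uq2):
        from scipy.spatial.transform import Rotation

        c = embed(uq2, {"phi": 90.0})
        rot = Rotation.from_euler("zyx", [31.0, -52.0, 117.0], degrees=True)
        moved = embed(uq2, {"phi": 90.0})
        moved.coords = c.coords @ rot.as_matrix().T + np.array([5.0, -3.0, 2.0])
        rmsd, aligned = superpose(moved, c)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(aligned.coords, c.coords, atol=1e-9)

    def test_rmsd_matches_independent_oracle(self, uq2):
        """Cross-check against scipy's closed-form optimal alignment."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(42)
        c1 = embed(uq2)
        P = c1.coords[uq2.headgroup_atoms]
        Q = P + rng.normal(0, 0.3, P.shape)
        rmsd, _ = superpose_points(P, Q)
        est, oracle_rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert rmsd == pytest.approx(oracle_rssd / np.sqrt(P.shape[0]),
                                     rel=1e-9)

    def test_degenerate_subset_rejected(self, uq2):
        c = embed(uq2)
        with pytest.raises(ValueError):
            superpose(c, c, ["C1", "C2"])


class TestClassify:
    def test_flat_extended_rule(self, uq2):
        cls = classify_conformation(reference_conformer(uq2, "flat_extended"))
        assert cls.label == "flat-extended" and abs(cls.phi) > 120.0

    def test_folded_extended_rule(self, uq2):
        # φ = 90° with the chain fully anti: folded but terminal methyls far
        conf = embed(uq2, {"phi": 90.0})
        cls = classify_conformation(conf)
        assert cls.label == "folded-extended"
        assert min(cls.terminal_distances.values()) > 6.0

    def test_u_shaped_rule(self, uq2):
        cls = classify_conformation(reference_conformer(uq2, "u_shaped"))
        assert cls.label == "U-shaped"
        assert min(cls.terminal_distances.values()) <= 6.0

    def test_depends_only_on_phi_and_terminal_distances(self, uq2):
        """Permuting rotors that move neither φ nor the terminal methyls
        never changes the label."""
        base = dict(phi=90.0)
        for rotj in (0.0, 60.0, 140.0):
            conf = embed(uq2, {**base, "rotj": rotj, "rotk": -rotj})
            assert classify_conformation(conf).label == "folded-extended"

    def test_configurable_window(self, uq2):
        conf = embed(uq2, {"phi": 130.0})
        assert classify_conformation(conf).label == "flat-extended"
        wide = ClassifyConfig(folded_window=45.0)
        assert classify_conformation(conf, wide).label == "folded-extended"


class TestFitConformer:
    def test_empty_restraints_clash_free_zero_penalty(self, uq2):
        fit = fit_conformer(uq2, [], seed=0, n_starts=1)
        assert fit.penalty == 0.0 and fit.satisfied

    def test_single_upper_bound_satisfied(self, uq2):
        r = DistanceRestraint(("H_W", "H_Y"), 1.8, 4.0)
        fit = fit_conformer(uq2, [r], seed=3, n_starts=8)
        assert fit.penalty == 0.0
        assert group_distance(fit.conformer, "H_W", "H_Y") <= 4.0 + 1e-6

    def test_invalid_bounds_rejected_before_search(self, uq2):
        with pytest.raises(ValueError, match="lower.*upper"):
            fit_conformer(uq2, [DistanceRestraint(("H_W", "H_Y"), 5.0, 3.0)])

    def test_infeasible_flagged_with_positive_penalty(self, uq2):
        # no conformer can place the terminal methyls 30 Å from the ring
        fit = fit_conformer(uq2, [DistanceRestraint(("H_W", "H_Y"), 30.0,
                                                    None)],
                            seed=0, n_starts=4, maxfev=200)
        assert fit.penalty > 0 and not fit.satisfied
        assert fit.violations[("H_W", "H_Y")] > 0

    def test_penalty_nonincreasing_in_n_starts(self, uq2):
        restraints = [DistanceRestraint(("H_W", "H_Y"), 1.8, 3.6),
                      DistanceRestraint(("H_W", "H_A"), 1.8, 3.4),
                      DistanceRestraint(("H_W", "H_X"), 4.5, None)]
        pens = [fit_conformer(uq2, restraints, seed=5, n_starts=n,
                              maxfev=150).penalty
                for n in (1, 2, 4, 8)]
        assert all(b <= a + 1e-12 for a, b in zip(pens, pens[1:]))

    def test_deterministic_given_seed(self, uq2):
        r = [DistanceRestraint(("H_W", "H_Y"), 1.8, 4.5)]
        f1 = fit_conformer(uq2, r, seed=11, n_starts=4, maxfev=200)
        f2 = fit_conformer(uq2, r, seed=11, n_starts=4, maxfev=200)
        assert np.array_equal(f1.conformer.coords, f2.conformer.coords)

    def test_u_shaped_truth_recovered_zero_noise(self, uq2):
        from quinonefold.pipeline import fit_and_classify
        from quinonefold.synth import NoiseModel, simulate_peak_table

        truth = reference_conformer(uq2, "u_shaped")
        peaks = simulate_peak_table(truth, ("H_W", "H_MN"),
                                    NoiseModel(cv=0.0, seed=11))
        res = fit_and_classify(uq2, peaks, seed=11, n_starts=8)
        assert res.conformation.label == "U-shaped"
        assert abs(res.conformation.phi) == pytest.approx(90, abs=30)
        # the bins and the exact r^-6 law disagree in two boundary slivers,
        # so a handful of restraints carry small irreducible violations;
        # everything else is satisfied essentially exactly
        assert max(res.fit.violations.values()) < 0.3
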