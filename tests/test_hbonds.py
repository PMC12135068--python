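"""Hydrogen-bond detection, census partition, bridging and contacts."""

import numpy as np
import pytest

from conftest import random_water_scene
from prosolv.md_io import Box, Frame, Topology
from prosolv.hbonds import (HBondCriterion, bridging_direct, bridging_eq1,
                            categorize, census, contacts_per_residue,
                            eq1_group_counts, find_hbonds, find_hbonds_brute)
from prosolv.synthetic import HBondSceneSpec, gen_hbond_scene


def two_waters(oo_distance: float):
    """Two waters with a linear O-H...O geometry at the given O-O distance."""
    topo = Topology(names=["OW", "HW1", "HW2"] * 2,
                    resindices=[0, 0, 0, 1, 1, 1],
                    resnames=["SOL"] * 6,
                    elements=["O", "H", "H"] * 2,
                    molecule_ids=[0, 0, 0, 1, 1, 1],
                    molecule_classes=["water"] * 6,
                    donors=[(0, 1), (0, 2), (3, 4), (3, 5)],
                    acceptors=[0, 3])
    pos = np.array([[1, 1, 1], [1.1, 1, 1], [1, 1.1, 1],
                    [1 + oo_distance, 1, 1],
                    [1 + oo_distance + 0.1, 1, 1],
                    [1 + oo_distance, 1.1, 1]])
    return topo, Frame(0.0, pos, Box(np.full(3, 5.0)))


class TestDetection:
    def test_textbook_linear_bond(self):
        topo, frame = two_waters(0.28)
        bonds = find_hbonds(frame, topo)
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor, b.acceptor) == (0, 3)
        assert b.distance == pytest.approx(0.28)
        assert b.angle == pytest.approx(0.0, abs=1e-9)

    def test_beyond_cutoff_no_bond(self):
        topo, frame = two_waters(0.40)
        assert find_hbonds(frame, topo) == []

    def test_dha_convention(self):
        topo, frame = two_waters(0.28)
        bonds = find_hbonds(frame, topo,
                            HBondCriterion(0.35, 150.0, convention="dha"))
        assert len(bonds) == 1       # linear geometry: D-H-A = 180 deg

    def test_missing_annotations_raise(self):
        topo = Topology(names=["OW"], resindices=[0], resnames=["SOL"])
        frame = Frame(0.0, [[1, 1, 1]], Box(np.ones(3) * 3))
        with pytest.raises(ValueError, match="annotations"):
            find_hbonds(frame, topo)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_scenes(self, seed):
        """Exact set equality with the O(n^2) all-triples detector on dense
        random scenes (~200 atoms in a small periodic box)."""
        topo, frame = random_water_scene(n_waters=60, box_side=3.0, seed=seed,
                                         n_residues=5)
        fast = [(b.donor, b.hydrogen, b.acceptor, round(b.distance, 12))
                for b in find_hbonds(frame, topo)]
        slow = [(b.donor, b.hydrogen, b.acceptor, round(b.distance, 12))
                for b in find_hbonds_brute(frame, topo)]
        assert fast == slow


class TestCensus:
    def test_partition_sums_to_total(self):
        for seed in range(5):
            topo, frame = random_water_scene(40, 3.0, seed, n_residues=8)
            bonds = find_hbonds(frame, topo)
            row = census([bonds], topo).counts.iloc[0]
            assert row.sum() == len(bonds)

    def test_category_counts_match_scene_ledger(self):
        spec = HBondSceneSpec(n_chains=2, n_pp_inter=2, n_pp_intra=1, n_pw=3,
                              n_ww=2, n_pd=1, n_dd=2, n_dw=1, seed=3)
        topo, frame, ledger = gen_hbond_scene(spec)
        row = census([find_hbonds(frame, topo)], topo).counts.iloc[0]
        for cat, n in ledger.category_counts.items():
            assert row[cat] == n, cat

    def test_unclassified_molecule_rejected(self):
        topo, frame = two_waters(0.28)
        topo.molecule_classes = np.array([""] * 6, dtype=object)
        bonds = find_hbonds(frame, topo)
        with pytest.raises(ValueError, match="unclassified"):
            census([bonds], topo)

    def test_group_decomposition_identity(self):
        """HB(A u B) = HB(A) + HB(B) + HB(A,B) for disjoint groups, exactly."""
        for seed in range(10):
            topo, frame = random_water_scene(50, 3.0, seed, n_residues=10)
            bonds = find_hbonds(frame, topo)
            a_mask = topo.molecule_classes == "protein"
            b_mask = topo.molecule_classes == "water"

            def n_internal(mask):
                return sum(1 for b in bonds if mask[b.donor] and mask[b.acceptor])

            cross = sum(1 for b in bonds
                        if (a_mask[b.donor] and b_mask[b.acceptor])
                        or (b_mask[b.donor] and a_mask[b.acceptor]))
            assert (n_internal(a_mask | b_mask)
                    == n_internal(a_mask) + n_internal(b_mask) + cross)


class TestBridging:
    def test_constructed_scene_count(self):
        topo, frame, ledger = gen_hbond_scene(
            HBondSceneSpec(n_chains=1, n_bridges=3, n_pw=2, seed=0))
        bonds = find_hbonds(frame, topo)
        assert bridging_direct(bonds, topo)["total"] == ledger.b_star == 3

    def test_same_residue_double_bond_is_not_a_bridge(self):
        topo, frame, _ = gen_hbond_scene(
            HBondSceneSpec(n_chains=1, n_same_residue_double=2, seed=1))
        bonds = find_hbonds(frame, topo)
        assert len(bonds) == 4       # two waters, two bonds each
        assert bridging_direct(bonds, topo)["total"] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_graph_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        spec = HBondSceneSpec(n_chains=2, n_bridges=int(rng.integers(0, 4)),
                              n_pw=int(rng.integers(0, 4)),
                              n_same_residue_double=int(rng.integers(0, 2)),
                              n_ww=1, seed=seed)
        topo, frame, ledger = gen_hbond_scene(spec)
        bonds = find_hbonds(frame, topo)
        # graph oracle: water node -> set of (chain, residue) neighbours
        neigh = {}
        for b in bonds:
            for w, p in ((b.donor, b.acceptor), (b.acceptor, b.donor)):
                if (topo.molecule_classes[w] == "water"
                        and topo.molecule_classes[p] == "protein"):
                    neigh.setdefault(int(topo.molecule_ids[w]), set()).add(
                        (int(topo.molecule_ids[p]), int(topo.resindices[p])))
        oracle = 0
        for partners in neigh.values():
            for chain in {c for c, _ in partners}:
                if len([r for c, r in partners if c == chain]) >= 2:
                    oracle += 1
        assert bridging_direct(bonds, topo)["total"] == oracle == ledger.b_star

    def test_invariant_under_rigid_motion_and_relabeling(self):
        from scipy.spatial.transform import Rotation
        topo, frame, _ = gen_hbond_scene(
            HBondSceneSpec(n_chains=1, n_bridges=2, n_pw=1, seed=5))
        base = bridging_direct(find_hbonds(frame, topo), topo)["total"]
        R = Rotation.from_euler("xyz", [0.4, -0.9, 1.3]).as_matrix()
        center = frame.box.lengths / 2
        rotated = (frame.positions - center) @ R.T + center + 0.37
        frame2 = Frame(0.0, rotated, frame.box)
        assert bridging_direct(find_hbonds(frame2, topo), topo)["total"] == base


class TestEq1:
    def test_empty_protein_graph(self):
        gc = {"union": {0: 100, 1: 100}, "protein": {0: 0, 1: 0}, "ww": 100}
        literal, variant = bridging_eq1(gc)
        assert literal == 0.0 and variant == 0.0

    def test_algebraic_reduction(self):
        """With per-chain HB(p)=a, HB(p-w)=b and HB(w-w)=c the literal form
        reduces to 2a + b and the sign variant to b, independent of c."""
        a, b, c = 10, 100, 5000
        gc = {"union": {i: a + b + c for i in range(4)},
              "protein": {i: a for i in range(4)}, "ww": c}
        literal, variant = bridging_eq1(gc)
        assert literal == 2 * a + b == 120
        assert variant == b == 100

    def test_group_counts_from_detected_bonds(self):
        topo, frame, ledger = gen_hbond_scene(
            HBondSceneSpec(n_chains=2, n_pp_intra=2, n_pw=3, n_ww=4, seed=2))
        bonds = find_hbonds(frame, topo)
        gc = eq1_group_counts(bonds, topo)
        assert gc["ww"] == 4
        assert sum(gc["protein"].values()) == 2
        # union_i = protein_i + (p_i-w bonds) + all w-w bonds
        pw_by_chain = {}
        for b in bonds:
            cats = {topo.molecule_classes[b.donor],
                    topo.molecule_classes[b.acceptor]}
            if cats == {"protein", "water"}:
                p = (b.donor if topo.molecule_classes[b.donor] == "protein"
                     else b.acceptor)
                chain = int(topo.molecule_ids[p])
                pw_by_chain[chain] = pw_by_chain.get(chain, 0) + 1
        for chain, u in gc["union"].items():
            assert u == (gc["protein"][chain]
                         + pw_by_chain.get(chain, 0) + gc["ww"])

    def test_literal_equals_two_a_plus_b_on_scenes(self):
        topo, frame, _ = gen_hbond_scene(
            HBondSceneSpec(n_chains=4, n_pp_intra=3, n_pw=6, n_ww=10, seed=7))
        bonds = find_hbonds(frame, topo)
        gc = eq1_group_counts(bonds, topo)
        literal, variant = bridging_eq1(gc)
        n = len(gc["union"])
        mean_a = sum(gc["protein"].values()) / n
        mean_b = (sum(gc["union"].values()) - sum(gc["protein"].values())
                  - n * gc["ww"]) / n
        assert literal == pytest.approx(2 * mean_a + mean_b)
        assert variant == pytest.approx(mean_b)


class TestContacts:
    @staticmethod
    def chain_of_residues(positions):
        """One chain; each residue a single heavy atom at the given position."""
        n = len(positions)
        topo = Topology(names=["CA"] * n, resindices=np.arange(n),
                        resnames=["ALA"] * n, elements=["C"] * n,
                        molecule_ids=np.zeros(n, int),
                        molecule_classes=["protein"] * n,
                        resids=np.arange(1, n + 1))
        return topo, Frame(0.0, positions, Box(np.full(3, 10.0)))

    def test_neighbour_exclusion_gives_zero(self):
        topo, frame = self.chain_of_residues([[1, 1, 1], [1.5, 1, 1], [2, 1, 1]])
        counts = contacts_per_residue(frame, topo, cutoff=0.6)
        assert (counts == 0).all()

    def test_pair_within_cutoff(self):
        topo, frame = self.chain_of_residues([[1, 1, 1], [5, 5, 5], [1.5, 1, 1]])
        counts = contacts_per_residue(frame, topo, cutoff=0.6)
        assert counts[0] == 1 and counts[2] == 1 and counts[1] == 0

    def test_invalid_cutoff(self):
        topo, frame = self.chain_of_residues([[1, 1, 1]])
        with pytest.raises(ValueError):
            contacts_per_residue(frame, topo, cutoff=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        pos = rng.uniform(0, 4.0, size=(n, 3))
        topo, frame = self.chain_of_residues(pos)
        cutoff = 0.9
        counts = contacts_per_residue(frame, topo, cutoff=cutoff)
        from prosolv.md_io import minimum_distance
        for i in range(n):
            partners = 0
            for j in range(n):
                if i == j or abs(i - j) <= 1:
                    continue
                if minimum_distance(pos[i], pos[j], frame.box) <= cutoff:
                    partners += 1
            assert counts[i] == partners
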