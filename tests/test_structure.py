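"""SASA, interface detection, peptide mapping, distances and ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from flipms import simulate
from flipms.structure import (
    Chain,
    StructureModel,
    detect_interface,
    interface_roc,
    map_peptide_to_chain,
    peptide_distance_table,
    peptide_interface_distance,
    relative_sasa,
    select_structure,
    shrake_rupley,
)


def _chain(chain_id, resnames, ca, atoms=None, radius=1.9):
    ca = np.asarray(ca, float)
    atoms = ca if atoms is None else np.asarray(atoms, float)
    per_res = len(atoms) // len(ca)
    return Chain(
        chain_id,
        resnames,
        ca,
        atoms,
        np.full(len(atoms), radius),
        np.repeat(np.arange(len(ca)), per_res),
    )


class TestShrakeRupley:
    def test_single_atom_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.9]), probe_radius=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 3.3**2, rel=1e-12)

    def test_fully_enclosed_atom_buried(self):
        # central atom surrounded by a tight shell of overlapping spheres
        from flipms.structure import _golden_spiral

        shell = 3.0 * _golden_spiral(60)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        radii = np.full(len(coords), 1.9)
        area = shrake_rupley(coords, radii)
        assert area[0] == 0.0

    def test_two_distant_atoms_independent(self):
        coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        area = shrake_rupley(coords, np.array([1.9, 1.9]))
        assert np.allclose(area, 4 * np.pi * 3.3**2, rtol=1e-12)

    def test_matches_high_resolution_oracle(self, toy_dimer):
        # same algorithm at 10x point density as the independent reference
        structure, _ = toy_dimer
        low = relative_sasa(structure, n_points=960)
        high = relative_sasa(structure, n_points=9600)
        exposed = high["sasa"] > 1.0
        rel = np.abs(low["sasa"][exposed] - high["sasa"][exposed]) / high["sasa"][exposed]
        assert rel.max() < 0.05


class TestDetectInterface:
    def test_separated_chains_no_interface(self):
        structure, _ = simulate.simulate_dimer_structure(
            30, 8, seed=1, contact_distance=100.0
        )
        iface = detect_interface(structure, reference=simulate.TOY_REFERENCE)
        assert not iface["is_interface"].any()

    def test_planted_patch_recovered(self, toy_dimer):
        structure, planted = toy_dimer
        iface = detect_interface(structure, reference=simulate.TOY_REFERENCE)
        detected = set(
            map(tuple, iface[iface["is_interface"]][["chain_id", "residue_index"]].values)
        )
        tp = len(detected & planted)
        sensitivity = tp / len(planted)
        precision = tp / max(len(detected), 1)
        assert sensitivity >= 0.9
        assert precision >= 0.9

    def test_threshold_strictly_above(self, toy_dimer):
        # a residue whose burial equals the threshold exactly is not interface
        structure, _ = toy_dimer
        iface = detect_interface(structure, reference=simulate.TOY_REFERENCE)
        delta = iface[iface["delta_rsasa"] > 0]["delta_rsasa"].max()
        at_threshold = detect_interface(
            structure, threshold=float(delta), reference=simulate.TOY_REFERENCE
        )
        sel = at_threshold["delta_rsasa"] == delta
        assert sel.any()
        assert not at_threshold.loc[sel, "is_interface"].any()

    def test_single_chain_warns_empty(self):
        structure, _ = simulate.simulate_dimer_structure(20, 5, seed=0)
        single = StructureModel("mono", structure.chains[:1])
        with pytest.warns(UserWarning, match="single chain"):
            iface = detect_interface(single, reference=simulate.TOY_REFERENCE)
        assert not iface["is_interface"].any()

    def test_rigid_motion_invariance(self, toy_dimer):
        structure, _ = toy_dimer
        rng = np.random.default_rng(7)
        # random rotation (QR of a gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.uniform(-30, 30, 3)
        moved = StructureModel(
            "moved",
            [
                Chain(
                    c.chain_id,
                    c.resnames,
                    c.ca @ q.T + shift,
                    c.atom_coords @ q.T + shift,
                    c.atom_radii,
                    c.atom_residue,
                )
                for c in structure.chains
            ],
        )
        a = detect_interface(structure, reference=simulate.TOY_REFERENCE)
        b = detect_interface(moved, reference=simulate.TOY_REFERENCE)
        assert a["is_interface"].tolist() == b["is_interface"].tolist()

    def test_chain_order_symmetric(self, toy_dimer):
        structure, _ = toy_dimer
        flipped = StructureModel("flipped", structure.chains[::-1])
        a = detect_interface(structure, reference=simulate.TOY_REFERENCE)
        b = detect_interface(flipped, reference=simulate.TOY_REFERENCE)
        key = ["chain_id", "residue_index"]
        merged = a.merge(b, on=key, suffixes=("_a", "_b"))
        assert (merged["is_interface_a"] == merged["is_interface_b"]).all()


class TestFileRoundTrip:
    def test_pdb_write_read_preserves_chains(self, toy_dimer, tmp_path):
        structure, _ = toy_dimer
        path = tmp_path / "dimer.pdb"
        structure.to_pdb(path)
        back = StructureModel.from_file(path)
        assert back.n_subunits == 2
        for orig, read in zip(structure.chains, back.chains):
            assert read.sequence == orig.sequence
            assert np.allclose(read.ca, orig.ca, atol=1e-3)


class TestMapPeptide:
    def test_unique_match(self, toy_dimer):
        structure, _ = toy_dimer
        seq = structure.chains[0].sequence
        peptide = seq[5:12]
        assert structure.chains[1].sequence.find(peptide) == -1
        chain_id, start, end = map_peptide_to_chain(peptide, structure)
        assert (chain_id, start, end) == ("A", 5, 11)

    def test_absent_peptide_unmapped(self, toy_dimer):
        structure, _ = toy_dimer
        assert map_peptide_to_chain("WWWWWWWW", structure) is None

    def test_homodimer_copy_choice_deterministic(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        structure, _ = simulate.simulate_dimer_structure(
            sequences=(seq, seq), interface_width=5, seed=0
        )
        picks = {map_peptide_to_chain(seq[3:10], structure, rng=42) for _ in range(10)}
        assert len(picks) == 1


class TestPeptideDistance:
    def _square_structure(self):
        # chain A on a line, all interface; chain B residues at known offsets
        resnames = ["ALA"] * 3
        a = _chain("A", resnames, [[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        b = _chain("B", resnames, [[0, 3, 0], [10, 5, 0], [20, 100, 0]])
        return StructureModel("sq", [a, b])

    def _iface(self, structure, residues):
        rows = []
        for chain in structure.chains:
            for i in range(chain.n_residues):
                rows.append(
                    {
                        "chain_id": chain.chain_id,
                        "residue_index": i,
                        "is_interface": (chain.chain_id, i) in residues,
                    }
                )
        return pd.DataFrame(rows)

    def test_peptide_of_interface_residues_distance_zero(self):
        st = self._square_structure()
        iface = self._iface(st, {("A", 0), ("A", 1), ("A", 2)})
        assert peptide_interface_distance(st, "A", (0, 2), iface) == 0.0

    def test_mean_of_per_residue_minima(self):
        st = self._square_structure()
        iface = self._iface(st, {("A", 0), ("A", 1), ("A", 2)})
        # B residues 0 and 1 sit 3 and 5 A from their nearest interface residue
        assert peptide_interface_distance(st, "B", (0, 1), iface) == pytest.approx(4.0)

    def test_empty_interface_undefined(self):
        st = self._square_structure()
        iface = self._iface(st, set())
        with pytest.raises(ValueError):
            peptide_interface_distance(st, "A", (0, 2), iface)

    def test_matches_exhaustive_oracle(self, toy_dimer):
        structure, _ = toy_dimer
        iface = detect_interface(structure, reference=simulate.TOY_REFERENCE)
        iface_ca = [
            structure.chain(c).ca[i]
            for c, i in iface[iface["is_interface"]][
                ["chain_id", "residue_index"]
            ].itertuples(index=False, name=None)
        ]
        chain = structure.chains[0]
        start, end = 2, 9
        got = peptide_interface_distance(structure, "A", (start, end), iface)
        per_residue = []
        for i in range(start, end + 1):
            per_residue.append(
                min(np.linalg.norm(chain.ca[i] - c) for c in iface_ca)
            )
        assert got == pytest.approx(sum(per_residue) / len(per_residue), rel=1e-12)

    def test_cutoff_monotonicity(self, toy_dimer):
        structure, _ = toy_dimer
        peptides = ["".join(p) for p in (
            structure.chains[0].sequence[i : i + 8] for i in range(0, 30, 4)
        )]
        table = peptide_distance_table(
            structure, peptides, reference=simulate.TOY_REFERENCE
        )
        strict = set(table[table["interface_lt_0.3"]]["peptide_id"])
        loose = set(table[table["interface_lt_2.6"]]["peptide_id"])
        assert strict <= loose


class TestSelectStructure:
    def test_biggest(self, toy_dimer):
        dimer, _ = toy_dimer
        mono = StructureModel("mono", dimer.chains[:1])
        chosen = select_structure({"m": mono, "d": dimer}, policy="biggest")
        assert chosen.n_subunits == 2

    def test_random_deterministic(self, toy_dimer):
        dimer, _ = toy_dimer
        mono = StructureModel("mono", dimer.chains[:1])
        picks = {
            select_structure({"m": mono, "d": dimer}, policy="random", seed=3).structure_id
            for _ in range(5)
        }
        assert len(picks) == 1

    def test_best_prefers_agreeing_structure(self):
        contact, _ = simulate.simulate_dimer_structure(30, 8, seed=2)
        apart, _ = simulate.simulate_dimer_structure(
            30, 8, seed=2, contact_distance=100.0
        )
        contact.structure_id = "contact"
        apart.structure_id = "apart"
        seq = contact.chains[0].sequence
        # markers tile the contact patch (center), non-markers the terminus
        markers = [seq[11:19]]
        nonmarkers = [seq[0:8]]
        chosen = select_structure(
            {"contact": contact, "apart": apart},
            policy="best",
            marker_peptides=markers,
            nonmarker_peptides=nonmarkers,
            reference=simulate.TOY_REFERENCE,
        )
        assert chosen.structure_id == "contact"


class TestInterfaceRoc:
    def test_perfect_separation(self):
        out = interface_roc([True, True, False, False], [0.9, 0.8, 0.2, 0.1])
        assert out["auc"] == 1.0

    def test_all_ties_half(self):
        out = interface_roc([True, False, True, False], [0.5] * 4)
        assert out["auc"] == 0.5

    def test_matches_pair_counting_oracle(self):
        labels = [True, False, True, False, False, True]
        scores = [0.9, 0.9, 0.7, 0.3, 0.6, 0.2]
        wins = ties = total = 0
        for (la, sa), (lb, sb) in itertools.product(
            [(l, s) for l, s in zip(labels, scores) if l],
            [(l, s) for l, s in zip(labels, scores) if not l],
        ):
            total += 1
            wins += sa > sb
            ties += sa == sb
        expected = (wins + 0.5 * ties) / total
        out = interface_roc(labels, scores)
        assert out["auc"] == pytest.approx(expected, rel=1e-12)

    def test_single_class_undefined(self):
        out = interface_roc([True, True], [0.1, 0.2])
        assert out["auc"] is None

    def test_confusion_counts_use_marker_mapping(self):
        out = interface_roc(
            [True, False, True, False],
            [0.9, 0.8, 0.2, 0.1],
            markers=[True, True, False, False],
        )
        assert (out["tp"], out["fp"], out["fn"], out["tn"]) == (1, 1, 1, 1)
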