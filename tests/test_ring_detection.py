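"""Plane fitting and ring perception (templates + graph heuristic)."""

import numpy as np
import pytest

from aroclust.ring_detection import (
    detect_ligand_rings,
    detect_protein_rings,
    infer_bonds,
    plane_fit,
)
from aroclust.structure_io import Atom, Residue, Structure
from conftest import hexagon, make_ligand


def eig_plane_oracle(pts):
    """Independent best-fit plane via covariance eigendecomposition."""
    pts = np.asarray(pts, dtype=float)
    c = pts.mean(axis=0)
    cov = (pts - c).T @ (pts - c)
    w, v = np.linalg.eigh(cov)
    return c, v[:, 0]


class TestPlaneFit:
    def test_regular_hexagon(self):
        pts = hexagon((0, 0, 2), (0, 0, 1))
        center, normal, rms = plane_fit(pts)
        assert np.allclose(center, (0, 0, 2), atol=1e-12)
        assert np.allclose(normal, (0, 0, 1), atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_displaced_vertex_matches_eigen_oracle(self):
        pts = hexagon((0, 0, 2), (0, 0, 1))
        pts[0, 2] += 0.1
        center, normal, _ = plane_fit(pts)
        c2, n2 = eig_plane_oracle(pts)
        assert np.allclose(center, c2, atol=1e-12)
        assert min(np.linalg.norm(normal - n2), np.linalg.norm(normal + n2)) < 1e-9

    def test_rotational_equivariance(self):
        rng = np.random.default_rng(7)
        pts = hexagon((0, 0, 2), (0, 0, 1))
        pts[0, 2] += 0.07
        c0, n0, rms0 = plane_fit(pts)
        for _ in range(10):
            from scipy.spatial.transform import Rotation
            rot = Rotation.random(random_state=rng).as_matrix()
            c, n, rms = plane_fit(pts @ rot.T)
            assert np.allclose(c, rot @ c0, atol=1e-9)
            assert min(np.linalg.norm(n - rot @ n0),
                       np.linalg.norm(n + rot @ n0)) < 1e-9
            assert rms == pytest.approx(rms0, abs=1e-9)

    def test_collinear_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            plane_fit(pts)

    def test_sign_canonicalization(self):
        pts = hexagon((0, 0, 0), (0, 0, -1))
        _, normal, _ = plane_fit(pts)
        assert normal[2] > 0


def make_residue(res_name, ring_names, center=(0, 0, 0), skip=()):
    coords = hexagon(center, (0, 0, 1)) if len(ring_names) == 6 else \
        hexagon(center, (0, 0, 1))[:5]
    if len(ring_names) == 5:
        # regular pentagon
        ang = 2 * np.pi * np.arange(5) / 5
        coords = np.array([np.asarray(center, dtype=float) +
                           1.2 * np.array([np.cos(a), np.sin(a), 0]) for a in ang])
    atoms = [Atom(i + 1, n, n[0], c) for i, (n, c) in
             enumerate(zip(ring_names, coords)) if n not in skip]
    return Residue(chain_id="A", seq_num=1, res_name=res_name, atoms=atoms)


class TestProteinRings:
    def test_trp_two_rings_share_atoms(self):
        from conftest import trp_residue
        rings = detect_protein_rings(Structure(id="t", residues=[trp_residue()]))
        assert len(rings) == 2
        types = sorted(r.ring_type for r in rings)
        assert types == ["benzene", "pyrrole"]
        shared = set(rings[0].atom_keys) & set(rings[1].atom_keys)
        assert {k[1] for k in shared} == {"CD2", "CE2"}

    def test_ala_yields_nothing(self):
        res = Residue("A", 1, "ALA", [Atom(1, "CB", "C", (0, 0, 0))])
        assert detect_protein_rings(Structure(id="t", residues=[res])) == []

    def test_incomplete_template_skipped(self, caplog):
        names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        res = make_residue("PHE", names, skip=("CZ",))
        with caplog.at_level("WARNING"):
            rings = detect_protein_rings(Structure(id="t", residues=[res]))
        assert rings == []
        assert any("missing" in r.message for r in caplog.records)

    def test_phe_tyr_his_single_ring(self, dimer_factory):
        rec = dimer_factory(5.0, 0, 0)
        rings = detect_protein_rings(rec.structure)
        assert len(rings) == 1 and rings[0].ring_type == "benzene"


class TestLigandRings:
    def test_biphenyl_two_rings(self, biphenyl):
        rings = detect_ligand_rings(biphenyl)
        assert len(rings) == 2
        assert all(r.ring_type == "benzene" for r in rings)

    def test_indole_fused_rings_counted_individually(self, indole_ligand):
        rings = detect_ligand_rings(indole_ligand)
        assert sorted(r.ring_type for r in rings) == ["benzene", "pyrrole"]

    def test_cyclohexane_chair_rejected(self):
        # ideal chair: alternating +-h puckering, rms deviation = h = 0.25 A
        r, h = 1.457, 0.25
        ang = 2 * np.pi * np.arange(6) / 6
        coords = np.array([[r * np.cos(a), r * np.sin(a), h * (-1) ** k]
                           for k, a in enumerate(ang)])
        _, _, rms = __import__("aroclust.ring_detection", fromlist=["plane_fit"]).plane_fit(coords)
        assert rms > 0.10
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        lig = make_ligand(coords, ["C"] * 6, bonds)
        assert detect_ligand_rings(lig) == []

    def test_no_bonds_raises(self):
        lig = make_ligand(np.array([[0.0, 0, 0], [80.0, 0, 0], [160.0, 0, 0]]),
                          ["C"] * 3, [])
        with pytest.raises(ValueError, match="CONECT"):
            detect_ligand_rings(lig)

    def test_override_injects_rings(self, biphenyl):
        rings = detect_ligand_rings(
            biphenyl, ring_overrides={"LIG": [[a.name for a in biphenyl.atoms[:6]]]})
        assert len(rings) == 1

    def test_exhaustive_cycle_oracle(self, biphenyl, indole_ligand):
        """Perceived rings match exhaustive chordless-cycle enumeration."""
        import networkx as nx

        for lig in (biphenyl, indole_ligand):
            g = nx.Graph(lig.bonds)
            cycles = [c for c in nx.simple_cycles(g) if 5 <= len(c) <= 6]
            chordless = [c for c in cycles
                         if g.subgraph(c).number_of_edges() == len(c)]
            expected = {frozenset(c) for c in chordless}
            got = {frozenset(i for (_, n) in r.atom_keys
                             for i, a in enumerate(lig.atoms) if a.name == n)
                   for r in detect_ligand_rings(lig)}
            assert got == expected


class TestInferBonds:
    def test_aromatic_distance_bonded(self):
        atoms = [Atom(1, "C1", "C", (0, 0, 0)), Atom(2, "C2", "C", (1.39, 0, 0))]
        assert infer_bonds(atoms) == [(0, 1)]

    def test_far_apart_not_bonded(self):
        atoms = [Atom(1, "C1", "C", (0, 0, 0)), Atom(2, "C2", "C", (2.5, 0, 0))]
        assert infer_bonds(atoms) == []

    def test_single_atom(self):
        assert infer_bonds([Atom(1, "C1", "C", (0, 0, 0))]) == []

    def test_recovers_ring_bonds(self, biphenyl):
        inferred = infer_bonds(biphenyl.atoms)
        expected = {tuple(sorted(b)) for b in biphenyl.bonds}
        assert set(inferred) == expected


class TestRdkitPanel:
    """Cross-check perception against RDKit on common aromatic fragments."""

    SMILES = {
        "benzene": "c1ccccc1", "pyridine": "c1ccncc1", "imidazole": "c1cnc[nH]1",
        "indole": "c1ccc2[nH]ccc2c1", "naphthalene": "c1ccc2ccccc2c1",
        "furan": "c1ccoc1", "thiophene": "c1ccsc1", "pyrimidine": "c1cncnc1",
        "pyrrole": "c1cc[nH]c1", "phenol": "Oc1ccccc1",
    }

    @pytest.mark.parametrize("name", sorted(SMILES))
    def test_aromatic_ring_count_matches(self, name):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.MolFromSmiles(self.SMILES[name])
        molh = Chem.AddHs(mol)
        assert AllChem.EmbedMolecule(molh, randomSeed=11) == 0
        AllChem.MMFFOptimizeMolecule(molh)
        molh = Chem.RemoveHs(molh)
        conf = molh.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i))
                           for i in range(molh.GetNumAtoms())])
        elements = [a.GetSymbol() for a in molh.GetAtoms()]
        bonds = sorted((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                        max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                       for b in molh.GetBonds())
        lig = make_ligand(coords, elements, bonds, comp_id=name.upper()[:3])
        ours = detect_ligand_rings(lig)
        ri = molh.GetRingInfo()
        rdkit_aromatic = sum(
            1 for ring in ri.AtomRings()
            if all(molh.GetAtomWithIdx(i).GetIsAromatic() for i in ring))
        assert len(ours) == rdkit_aromatic
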