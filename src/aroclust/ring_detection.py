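"""Aromatic ring identification and plane fitting.

Protein rings come from fixed templates: Phe and Tyr carry one benzene
ring, Trp an indole (benzene + pyrrole, counted as two rings sharing the
CD2-CE2 bond), His an imidazole. Ligand rings are perceived from the
bond graph: small cycles (5-6 atoms) of C/N/O/S atoms with low heavy-atom
connectivity and a nearly planar geometry are accepted as aromatic.
Every ring is reduced to its least-squares plane: centroid, unit normal
and out-of-plane rms deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import LigandInstance, Residue, Structure

logger = logging.getLogger(__name__)

#: covalent radii (A) for bond inference between heavy atoms
COVALENT_RADIUS = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "SE": 1.20,
}

#: residue ring templates: atom names per ring, with the ring chemical type
PROTEIN_RING_TEMPLATES = {
    "PHE": [("benzene", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TYR": [("benzene", ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"))],
    "TRP": [
        ("pyrrole", ("CG", "CD1", "NE1", "CE2", "CD2")),
        ("benzene", ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")),
    ],
    "HIS": [("imidazole", ("CG", "ND1", "CD2", "CE1", "NE2"))],
}

AROMATIC_RESIDUES = tuple(PROTEIN_RING_TEMPLATES)

_RING_ELEMENTS = {"C", "N", "O", "S"}


@dataclass
class AromaticRing:
    """A typed aromatic ring with its fitted plane.

    ``source_class`` is "R" for rings on protein residues and "D" for
    rings on drug-like ligands. ``atom_keys`` are globally unique
    (residue key, atom name) pairs used to detect fused/shared-atom
    ring pairs downstream.
    """

    ring_id: str
    source_class: str                 # "R" | "D"
    ring_type: str                    # benzene | pyrrole | imidazole | other-aromatic
    parent: tuple                     # (chain_id, seq_num, name)
    atom_keys: tuple
    center: np.ndarray
    normal: np.ndarray
    rms_dev: float = 0.0
    chain_id: str = ""
    parent_key: tuple = field(default=None)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("ring normal must be a unit vector")

    def shares_atoms(self, other: "AromaticRing") -> bool:
        return bool(set(self.atom_keys) & set(other.atom_keys))


def plane_fit(coords) -> tuple:
    """Least-squares plane through >= 3 points.

    Returns ``(center, normal, rms_dev)`` where center is the centroid,
    normal the unit direction minimizing the sum of squared point-plane
    distances (smallest principal component of the centered coordinates)
    and rms_dev the root-mean-square out-of-plane deviation. The normal
    sign is canonicalized: z-component >= 0; if zero, y >= 0; if both
    zero, x > 0.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("plane_fit needs at least 3 points in 3D")
    center = pts.mean(axis=0)
    centered = pts - center
    # smallest right singular vector = least-squares plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-30) or s[0] < 1e-12:
        raise ValueError("degenerate (collinear or coincident) points")
    normal = vt[2]
    normal = _canonical_sign(normal)
    rms_dev = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return center, normal, rms_dev


def _canonical_sign(normal: np.ndarray) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    for axis in (2, 1, 0):
        if n[axis] > 1e-12:
            return n
        if n[axis] < -1e-12:
            return -n
    return n


def detect_protein_rings(structure: Structure) -> list:
    """Template-based rings for Phe/Tyr/Trp/His residues.

    A residue missing any template ring atom yields no ring for that
    template (logged); Trp contributes two rings sharing two atoms.
    """
    rings = []
    for res in structure.residues:
        templates = PROTEIN_RING_TEMPLATES.get(res.res_name)
        if not templates:
            continue
        for ring_type, names in templates:
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                missing = [n for n, a in zip(names, atoms) if a is None]
                logger.warning("%s %s%d: incomplete %s ring (missing %s), skipped",
                               res.res_name, res.chain_id, res.seq_num,
                               ring_type, ",".join(missing))
                continue
            coords = np.array([a.coords for a in atoms])
            try:
                center, normal, rms = plane_fit(coords)
            except ValueError:
                logger.warning("%s %s%d: degenerate ring geometry, skipped",
                               res.res_name, res.chain_id, res.seq_num)
                continue
            rid = f"R:{res.chain_id}:{res.seq_num}{res.icode}:{res.res_name}:{ring_type}"
            rings.append(AromaticRing(
                ring_id=rid, source_class="R", ring_type=ring_type,
                parent=(res.chain_id, res.seq_num, res.res_name),
                atom_keys=tuple((res.key, n) for n in names),
                center=center, normal=normal, rms_dev=rms,
                chain_id=res.chain_id, parent_key=res.key))
    return rings


def infer_bonds(atoms, slack: float = 0.40) -> list:
    """Distance-based heavy-atom bonds.

    Two atoms are bonded iff their separation is at most the sum of
    covalent radii plus ``slack`` (default 0.40 A). Hydrogens are ignored.
    """
    heavy = [(i, a) for i, a in enumerate(atoms) if a.element.upper() != "H"]
    if len(heavy) < 2:
        return []
    coords = np.array([a.coords for _, a in heavy])
    radii = []
    for _, a in heavy:
        r = COVALENT_RADIUS.get(a.element.upper())
        if r is None:
            raise ValueError(f"no covalent radius for element {a.element!r}")
        radii.append(r)
    rmax = max(radii)
    tree = cKDTree(coords)
    bonds = []
    for ii, jj in tree.query_pairs(2 * rmax + slack):
        d = np.linalg.norm(coords[ii] - coords[jj])
        if d <= radii[ii] + radii[jj] + slack:
            i, j = heavy[ii][0], heavy[jj][0]
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def _ring_type_from_composition(elements) -> str:
    n = len(elements)
    counts = {e: sum(1 for x in elements if x == e) for e in set(elements)}
    if n == 6 and counts.get("C", 0) == 6:
        return "benzene"
    if n == 5 and counts.get("N", 0) == 1 and counts.get("C", 0) == 4:
        return "pyrrole"
    if n == 5 and counts.get("N", 0) == 2 and counts.get("C", 0) == 3:
        return "imidazole"
    return "other-aromatic"


def detect_ligand_rings(ligand: LigandInstance, planarity_rms_max: float = 0.10,
                        ring_overrides: dict | None = None) -> list:
    """Perceive aromatic rings on a ligand from its bond graph.

    Candidate rings are the minimum cycle basis of the heavy-atom bond
    graph. A cycle is accepted when it has 5 or 6 atoms, all in
    {C, N, O, S}, each with at most 3 heavy-atom neighbors, and its
    least-squares plane fit has rms deviation <= ``planarity_rms_max``
    (default 0.10 A). Fused systems emit each ring individually.

    ``ring_overrides`` maps comp_id -> list of atom-name lists and
    bypasses perception (e.g. to inject toolkit-perceived rings).
    """
    if ring_overrides and ligand.comp_id in ring_overrides:
        name_rings = [tuple(r) for r in ring_overrides[ligand.comp_id]]
        cycles = []
        name_to_idx = {a.name: i for i, a in enumerate(ligand.atoms)}
        for names in name_rings:
            try:
                cycles.append([name_to_idx[n] for n in names])
            except KeyError as exc:
                raise ValueError(
                    f"override ring for {ligand.comp_id} names missing atom {exc}")
        return _emit_rings(ligand, cycles, planarity_rms_max=np.inf,
                           check_chemistry=False)

    bonds = ligand.bonds
    if not bonds:
        bonds = infer_bonds(ligand.atoms)
        if not bonds:
            raise ValueError(
                f"ligand {ligand.comp_id} has no bonds: supply CONECT records, "
                "a ring-template override, or coordinates allowing bond inference")
    g = nx.Graph()
    g.add_nodes_from(range(len(ligand.atoms)))
    g.add_edges_from(bonds)
    cycles = nx.minimum_cycle_basis(g)
    return _emit_rings(ligand, cycles, planarity_rms_max, check_chemistry=True)


def _emit_rings(ligand, cycles, planarity_rms_max, check_chemistry) -> list:
    g = nx.Graph()
    g.add_nodes_from(range(len(ligand.atoms)))
    g.add_edges_from(ligand.bonds or [])
    rings = []
    for k, cyc in enumerate(sorted(cycles, key=lambda c: sorted(c))):
        atoms = [ligand.atoms[i] for i in cyc]
        elements = [a.element.upper() for a in atoms]
        if check_chemistry:
            if not (5 <= len(cyc) <= 6):
                continue
            if any(e not in _RING_ELEMENTS for e in elements):
                continue
            if any(g.degree(i) > 3 for i in cyc):
                continue
        coords = np.array([a.coords for a in atoms])
        try:
            center, normal, rms = plane_fit(coords)
        except ValueError:
            continue
        if rms > planarity_rms_max:
            continue
        rid = f"D:{ligand.chain_id}:{ligand.seq_num}:{ligand.comp_id}:{k}"
        rings.append(AromaticRing(
            ring_id=rid, source_class="D",
            ring_type=_ring_type_from_composition(elements),
            parent=(ligand.chain_id, ligand.seq_num, ligand.comp_id),
            atom_keys=tuple((ligand.key, ligand.atoms[i].name) for i in cyc),
            center=center, normal=normal, rms_dev=rms,
            chain_id=ligand.chain_id, parent_key=ligand.key))
    return rings


def detect_rings(structure: Structure, drug_like=None,
                 planarity_rms_max: float = 0.10,
                 ring_overrides: dict | None = None) -> list:
    """All aromatic rings of a structure (R rings + D rings).

    ``drug_like`` restricts which ligands contribute D rings (default:
    all non-water ligands present on the structure).
    """
    rings = detect_protein_rings(structure)
    ligands = structure.ligands if drug_like is None else drug_like
    for lig in ligands:
        try:
            rings.extend(detect_ligand_rings(lig, planarity_rms_max, ring_overrides))
        except ValueError as exc:
            logger.warning("%s: %s", structure.id, exc)
    return rings
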