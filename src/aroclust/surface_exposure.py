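"""Solvent-accessible surface area and side-chain exposure ratios.

SASA is computed with the Shrake-Rupley numerical method: each heavy
atom is inflated by the probe radius (1.4 A, water-sized) and covered
with a deterministic Fibonacci lattice of test points; the accessible
fraction of points scales the sphere area. The per-residue exposure
ratios follow the side-chain-in-three-contexts construction:

* iSASA - side chain alone;
* eSASA - side chain within its own protein monomer;
* nSASA - side chain within the entire complex (partner chains and
  ligands included);

    %Exposed  = 100 * eSASA / iSASA
    %inContact = 100 * (eSASA - nSASA) / eSASA

so %Exposed measures how much of the intrinsic side-chain surface the
protein leaves uncovered, and %inContact how much of that exposed
surface the binding partner buries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import Config
from .structure_io import Residue, Structure

logger = logging.getLogger(__name__)

#: van der Waals radii (A); heavy atoms only, hydrogens ignored
VDW_RADIUS = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "B": 1.92,
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ExposureRecord:
    residue_key: tuple
    iSASA: float
    eSASA: float
    nSASA: float

    @property
    def pct_exposed(self) -> float:
        return 100.0 * self.eSASA / self.iSASA if self.iSASA > 0 else 0.0

    @property
    def pct_in_contact(self) -> float | None:
        if self.eSASA <= 0:
            return None
        return 100.0 * (self.eSASA - self.nSASA) / self.eSASA


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii(atoms, table) -> np.ndarray:
    radii = []
    unknown = []
    for a in atoms:
        r = table.get(a.element.upper())
        if r is None:
            unknown.append(f"{a.name}({a.element})")
        radii.append(r if r is not None else np.nan)
    if unknown:
        raise ValueError(f"no van der Waals radius for atom(s): {', '.join(unknown)}")
    return np.array(radii)


def sasa(atoms, probe: float = 1.4, n_sphere_points: int = 960,
         radii_table: dict | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    A test point on atom i's inflated sphere is accessible when it lies
    outside every other atom's inflated sphere; SASA_i is the accessible
    point fraction times 4*pi*(r_i + probe)^2. Hydrogens are excluded.
    The point lattice is deterministic, so results are bit-reproducible.
    """
    heavy = [a for a in atoms if a.element.upper() != "H"]
    if not heavy:
        return np.zeros(0)
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    coords = np.array([a.coords for a in heavy])
    radii = _radii(heavy, radii_table or VDW_RADIUS) + probe

    if len(heavy) > 1:
        tree = cKDTree(coords)
        close = tree.query_pairs(1e-6)
        if close:
            i, j = next(iter(close))
            raise ValueError(
                f"coincident atom centers: {heavy[i].name} and {heavy[j].name}")

    sphere = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(heavy))
    rmax = radii.max()
    for i in range(len(heavy)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i]
        accessible = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def _sidechain_atoms(residue: Residue, include_cb: bool = True) -> list:
    names_excluded = set(_BACKBONE_NAMES)
    if not include_cb:
        names_excluded.add("CB")
    return [a for a in residue.atoms
            if a.name not in names_excluded and a.element.upper() != "H"]


def _monomer_atoms(structure: Structure, chain_ids, skip_key, skip_names) -> list:
    """Heavy polymer atoms of the given chains (hetero excluded)."""
    out = []
    for r in structure.residues:
        if r.chain_id not in chain_ids:
            continue
        for a in r.atoms:
            if a.element.upper() == "H":
                continue
            if r.key == skip_key and a.name in skip_names:
                continue
            out.append(a)
    return out


def _complex_atoms(structure: Structure, skip_key, skip_names) -> list:
    out = _monomer_atoms(structure, set(structure.polymer_chain_ids),
                         skip_key, skip_names)
    for lig in structure.ligands:
        out.extend(a for a in lig.atoms if a.element.upper() != "H")
    return out


def exposure_record(residue: Residue, structure: Structure,
                    monomer_chains=None,
                    config: Config | None = None) -> ExposureRecord | None:
    """iSASA/eSASA/nSASA and the exposure ratios for one residue.

    ``monomer_chains`` names the polymer chains forming the residue's own
    binding side (defaults to all polymer chains, which is the whole
    protein for a protein-drug complex). Glycine has no side chain and
    returns None. The side chain is CB and beyond (CB switchable via
    config). Hetero atoms enter only the complex-context nSASA.
    """
    cfg = config or Config()
    side = _sidechain_atoms(residue, cfg.sidechain_includes_cb)
    if not side:
        return None
    if monomer_chains is None:
        monomer_chains = structure.polymer_chain_ids
    side_names = {a.name for a in side}

    def sidechain_sasa(context_atoms):
        ordered = side + list(context_atoms)
        areas = sasa(ordered, probe=cfg.probe_radius,
                     n_sphere_points=cfg.n_sphere_points)
        return float(areas[:len(side)].sum())

    iS = sidechain_sasa([])
    eS = sidechain_sasa(_monomer_atoms(structure, set(monomer_chains),
                                       residue.key, side_names))
    nS = sidechain_sasa(_complex_atoms(structure, residue.key, side_names))
    if eS > iS + 1e-6 or nS > eS + 1e-6:
        logger.warning("%s: SASA ordering violated numerically "
                       "(iSASA=%.2f eSASA=%.2f nSASA=%.2f)", residue.key, iS, eS, nS)
    return ExposureRecord(residue_key=residue.key, iSASA=iS, eSASA=eS, nSASA=nS)


def exposure_table(records) -> "pd.DataFrame":
    import pandas as pd
    rows = []
    for r in records:
        rows.append({
            "chain": r.residue_key[0], "seq": r.residue_key[1],
            "res": r.residue_key[3], "iSASA": r.iSASA, "eSASA": r.eSASA,
            "nSASA": r.nSASA, "pct_exposed": r.pct_exposed,
            "pct_in_contact": r.pct_in_contact,
        })
    return pd.DataFrame(rows)
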