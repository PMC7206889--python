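"""Shared fixtures: all test structures are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from aroclust import synthetic_fixtures as sf
from aroclust.structure_io import Atom, LigandInstance, load_complex, read_structure


@pytest.fixture
def helix_pdb(tmp_path):
    path = tmp_path / "helix.pdb"
    sf.make_helix_fixture(12, out=path)
    return path


@pytest.fixture
def sheet_pdb(tmp_path):
    path = tmp_path / "sheet.pdb"
    sf.make_sheet_fixture(8, out=path)
    return path


@pytest.fixture
def dimer_factory(tmp_path):
    def make(d, alpha, theta, name="dimer.pdb"):
        path = tmp_path / name
        sf.make_dimer(sf.DimerRecipe(d, alpha, theta), out=path)
        return load_complex(path)
    return make


def hexagon(center, normal, radius=1.39, phase=0.0):
    """Explicit regular hexagon for hand-built ligands."""
    u, v, _ = sf._orthonormal_frame(normal)
    center = np.asarray(center, dtype=float)
    ang = np.radians(phase) + 2 * np.pi * np.arange(6) / 6
    return np.array([center + radius * (np.cos(a) * u + np.sin(a) * v)
                     for a in ang])


def make_ligand(coords, elements, bonds, comp_id="LIG", names=None):
    atoms = [Atom(serial=i + 1,
                  name=names[i] if names else f"{elements[i]}{i + 1}",
                  element=elements[i], coords=c)
             for i, c in enumerate(coords)]
    return LigandInstance(comp_id=comp_id, chain_id="A", seq_num=101,
                          atoms=atoms, bonds=bonds)


@pytest.fixture
def biphenyl():
    """Two benzene rings joined by a single C-C bond (13 bonds total)."""
    ring1 = hexagon((0, 0, 0), (0, 0, 1))
    # place ring2 so one vertex of each ring faces the other at 1.48 A
    v0 = ring1[0]
    out_dir = (v0 - np.zeros(3)) / np.linalg.norm(v0)
    c2 = v0 + out_dir * (1.48 + 1.39)
    ring2 = hexagon(c2, (0, 0, 1))
    # rotate ring2 so its nearest vertex points back toward ring1
    idx = np.argmin(np.linalg.norm(ring2 - v0, axis=1))
    ring2 = np.roll(ring2, -idx, axis=0)
    coords = np.vstack([ring1, ring2])
    bonds = [(i, (i + 1) % 6) for i in range(6)]
    bonds += [(6 + i, 6 + (i + 1) % 6) for i in range(6)]
    bonds += [(0, 6)]
    return make_ligand(coords, ["C"] * 12, sorted(bonds))


def fused_56_coords():
    """Hexagon + pentagon sharing one edge (indole-like 9-atom system)."""
    ring6 = hexagon((0, 0, 0), (0, 0, 1))
    v0, v1 = ring6[0], ring6[1]
    mid = 0.5 * (v0 + v1)
    outward = mid / np.linalg.norm(mid)
    r5 = 1.39 / (2 * np.sin(np.pi / 5))
    c5 = mid + r5 * np.cos(np.pi / 5) * outward

    def rot(p, ang):
        d = p - c5
        return c5 + np.array([np.cos(ang) * d[0] - np.sin(ang) * d[1],
                              np.sin(ang) * d[0] + np.cos(ang) * d[1], 0.0])

    step = -2 * np.pi / 5
    if np.linalg.norm(rot(v0, step) - v1) > 1e-6:
        step = -step
    extra = np.array([rot(v1, step), rot(v1, 2 * step), rot(v1, 3 * step)])
    return ring6, extra


def trp_residue():
    """A complete Trp ring system (benzene + pyrrole sharing CD2-CE2)."""
    from aroclust.structure_io import Residue

    ring6, extra = fused_56_coords()
    names6 = ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")
    atoms = [Atom(i + 1, n, n[0], c) for i, (n, c) in enumerate(zip(names6, ring6))]
    atoms += [Atom(7 + i, n, n[0], c)
              for i, (n, c) in enumerate(zip(("NE1", "CD1", "CG"), extra))]
    return Residue(chain_id="A", seq_num=1, res_name="TRP", atoms=atoms)


@pytest.fixture
def indole_ligand():
    """Fused benzene + pyrrole sharing one edge (9 heavy atoms)."""
    ring6, extra = fused_56_coords()
    coords = np.vstack([ring6, extra])
    elements = ["C"] * 6 + ["C", "N", "C"]
    bonds = [(i, (i + 1) % 6) for i in range(6)]
    bonds += [(1, 6), (6, 7), (7, 8), (8, 0)]
    return make_ligand(coords, elements, sorted(bonds))
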