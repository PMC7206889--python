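"""Toy-structure generators with exactly controlled aromatic geometry.

Every pipeline stage is testable without downloading coordinates: these
builders write standard PDB text (so the full parsing path is exercised)
containing rings whose center distance d, planar angle alpha and
orientational angle theta are realized exactly by construction.

* :func:`make_ring` - regular planar 5/6-membered ring coordinates;
* :func:`make_dimer` - one Phe residue plus one HETATM benzene ligand
  (with CONECT records) at a requested (d, alpha, theta);
* :func:`make_trimer` - three Phe residues in the Symmetric (triangle)
  or Ladder (path) motif;
* :func:`make_complex_fixture` - protein-drug or two-chain
  protein-protein toy complexes, with locally valid backbones so SASA
  and secondary-structure stages run;
* :func:`build_backbone` / :func:`make_helix_fixture` /
  :func:`make_sheet_fixture` - ideal poly-Ala backbones from (phi, psi)
  dihedrals for secondary-structure tests;
* :func:`sample_ensemble` - reproducible (d, alpha) mixture samples
  emulating the observed geometry distribution (a broad T-shape mode
  near d = 5 A, alpha = 75 deg and a narrow stacking mode near
  d = 3.75 A, alpha = 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

C_C_AROMATIC = 1.39        # A, aromatic ring circumradius (= bond length for hexagon)

# ideal backbone geometry (A / degrees)
_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5, "omega": 180.0,
}

@dataclass
class DimerRecipe:
    d: float
    alpha: float
    theta: float
    ring_type_a: str = "benzene"
    ring_type_b: str = "benzene"

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("d must be positive")
        for ang, name in ((self.alpha, "alpha"), (self.theta, "theta")):
            if not (0.0 <= ang <= 90.0):
                raise ValueError(f"{name} must lie in [0, 90] degrees")


@dataclass
class EnsembleRecipe:
    """Mixture of (d, alpha) Gaussians; defaults emulate the observed
    geometry: 60% T-shape near (5.0 A, 75 deg), 40% stacking near
    (3.75 A, 0 deg)."""
    components: tuple = (
        # (weight, mean_d, mean_alpha, sd_d, sd_alpha)
        (0.6, 5.0, 75.0, 0.3, 8.0),
        (0.4, 3.75, 0.0, 0.15, 8.0),
    )
    n: int = 50_000

    def __post_init__(self):
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _orthonormal_frame(normal) -> tuple:
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("zero normal vector")
    n = n / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


def make_ring(ring_type: str, center, normal, radius: float = C_C_AROMATIC) -> np.ndarray:
    """Regular planar ring coordinates (6 atoms for benzene, else 5).

    Atoms lie on a circle of the given circumradius in the plane through
    ``center`` perpendicular to ``normal``; for a hexagon the 1.39 A
    circumradius equals the aromatic C-C bond length.
    """
    n_atoms = 6 if ring_type == "benzene" else 5
    u, v, _ = _orthonormal_frame(normal)
    center = np.asarray(center, dtype=float)
    angles = 2.0 * np.pi * np.arange(n_atoms) / n_atoms
    return np.array([center + radius * (np.cos(a) * u + np.sin(a) * v)
                     for a in angles])


# --- PDB text writing -------------------------------------------------------

_PHE_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")   # hexagon order
_LIG_RING_NAMES = ("C1", "C2", "C3", "C4", "C5", "C6")


class PDBWriter:
    """Minimal fixed-width PDB text assembler for fixtures."""

    def __init__(self, resolution: float = 2.0, header: str = "SYNTHETIC FIXTURE"):
        self.lines = [f"HEADER    {header:<40s}"]
        if resolution is not None:
            self.lines.append(
                f"REMARK   2 RESOLUTION. {resolution:7.2f} ANGSTROMS.")
        self.serial = 0
        self.conect = []

    def atom(self, name, res_name, chain, seq, xyz, element, hetero=False,
             occupancy=1.0, alt_loc=""):
        self.serial += 1
        record = "HETATM" if hetero else "ATOM  "
        nm = name if len(name) >= 4 else f" {name:<3s}"
        x, y, z = xyz
        self.lines.append(
            f"{record}{self.serial:5d} {nm:<4s}{alt_loc or ' '}{res_name:<3s} "
            f"{chain}{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}"
            f"{0.0:6.2f}          {element:>2s}")
        return self.serial

    def bond(self, s1, s2):
        self.conect.append((s1, s2))

    def ter(self):
        self.lines.append("TER")

    def text(self) -> str:
        lines = list(self.lines)
        partners: dict[int, list] = {}
        for s1, s2 in self.conect:
            partners.setdefault(s1, []).append(s2)
            partners.setdefault(s2, []).append(s1)
        for s in sorted(partners):
            tail = "".join(f"{p:5d}" for p in sorted(partners[s]))
            lines.append(f"CONECT{s:5d}{tail}")
        lines.append("END")
        return "\n".join(lines) + "\n"

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.text())
        return path


def _write_phe(writer: PDBWriter, chain, seq, ring_coords, away=None,
               with_backbone=False):
    """A Phe residue around the given benzene ring coordinates.

    CB (and optionally a locally ideal backbone stub) is placed on the
    in-plane outward direction from CG, biased away from ``away`` (a
    point to keep clear of, e.g. the partner ring).
    """
    center = ring_coords.mean(axis=0)
    cg = ring_coords[0]
    out_dir = cg - center
    out_dir /= np.linalg.norm(out_dir)
    if away is not None:
        away_dir = center - np.asarray(away, dtype=float)
        na = np.linalg.norm(away_dir)
        if na > 1e-9 and np.dot(out_dir, away_dir) < 0:
            # flip the ring ordering so CG (and the stub) points away
            ring_coords = ring_coords[[3, 4, 5, 0, 1, 2]]
            cg = ring_coords[0]
            out_dir = -out_dir
    serials = {}
    normal = np.cross(ring_coords[1] - ring_coords[0],
                      ring_coords[2] - ring_coords[0])
    normal /= np.linalg.norm(normal)
    cb = cg + 1.53 * out_dir
    if with_backbone:
        ca = cb + 1.53 * _unit(0.5 * out_dir + 0.85 * normal)
        n = ca + 1.46 * _unit(out_dir + 0.3 * np.cross(normal, out_dir))
        c = ca + 1.52 * _unit(out_dir - 0.9 * np.cross(normal, out_dir) + 0.3 * normal)
        o = c + 1.23 * _unit(normal + 0.4 * out_dir)
        serials["N"] = writer.atom("N", "PHE", chain, seq, n, "N")
        serials["CA"] = writer.atom("CA", "PHE", chain, seq, ca, "C")
        serials["C"] = writer.atom("C", "PHE", chain, seq, c, "C")
        serials["O"] = writer.atom("O", "PHE", chain, seq, o, "O")
    serials["CB"] = writer.atom("CB", "PHE", chain, seq, cb, "C")
    for name, xyz in zip(_PHE_RING_NAMES, ring_coords):
        serials[name] = writer.atom(name, "PHE", chain, seq, xyz, "C")
    return serials


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _write_benzene_ligand(writer: PDBWriter, chain, seq, ring_coords,
                          comp_id="LIG"):
    serials = [writer.atom(name, comp_id, chain, seq, xyz, "C", hetero=True)
               for name, xyz in zip(_LIG_RING_NAMES, ring_coords)]
    for k in range(6):
        writer.bond(serials[k], serials[(k + 1) % 6])
    return serials


# --- fixture constructors ---------------------------------------------------

def dimer_geometry(recipe: DimerRecipe) -> tuple:
    """Centers and normals realizing (d, alpha, theta) exactly.

    Ring A sits at the origin with normal +z; the center-center vector is
    tilted by theta from +z in the xz-plane; ring B's normal is tilted by
    alpha from +z at an azimuth chosen so that min(theta_a, theta_b)
    after folding equals theta. Constructible for all alpha, theta in
    [0, 90].
    """
    a, t = np.radians(recipe.alpha), np.radians(recipe.theta)
    u = np.array([np.sin(t), 0.0, np.cos(t)])            # center direction
    if recipe.alpha + recipe.theta <= 90.0 or recipe.alpha < 1e-9 or recipe.theta < 1e-9:
        phi = np.pi                                       # angle(n_b, u) = alpha+theta
    else:
        # choose azimuth so n_b is perpendicular to u (folded angle 90 >= theta)
        cos_phi = np.clip(-(np.cos(a) * np.cos(t)) / (np.sin(a) * np.sin(t)),
                          -1.0, 1.0)
        phi = np.arccos(cos_phi)
    n_b = np.array([np.sin(a) * np.cos(phi), np.sin(a) * np.sin(phi), np.cos(a)])
    center_a = np.zeros(3)
    normal_a = np.array([0.0, 0.0, 1.0])
    center_b = recipe.d * u
    return center_a, normal_a, center_b, n_b


def make_dimer(recipe: DimerRecipe, out=None, resolution: float = 2.0):
    """Toy PDB: one Phe residue and one benzene ligand at the recipe
    geometry. Returns the PDB text (and writes it when ``out`` given)."""
    ca, na, cb, nb = dimer_geometry(recipe)
    shift = np.array([20.0, 20.0, 20.0])     # keep all coordinates positive
    ring_a = make_ring(recipe.ring_type_a, ca + shift, na)
    ring_b = make_ring(recipe.ring_type_b, cb + shift, nb)
    w = PDBWriter(resolution=resolution)
    _write_phe(w, "A", 1, ring_a, away=cb + shift)
    w.ter()
    _write_benzene_ligand(w, "A", 101, ring_b)
    text = w.text()
    if out is not None:
        Path(out).write_text(text)
    return text


def make_trimer(motif: str, spacing: float = 5.0, end_distance: float | None = None,
                out=None, resolution: float = 2.0):
    """Three Phe residues in the Sym (triangle) or Lad (path) motif.

    Sym: equilateral triangle of ring centers, side ``spacing`` (all
    three pairs within the 7 A cutoff -> 3 interactions). Lad: isoceles
    placement with adjacent centers at ``spacing`` and the two end
    centers at ``end_distance`` (default 2 * spacing, collinear, beyond
    the cutoff -> 2 interactions).
    """
    if motif not in ("Sym", "Lad"):
        raise ValueError("motif must be 'Sym' or 'Lad'")
    shift = np.array([20.0, 20.0, 20.0])
    if motif == "Sym":
        h = spacing * np.sqrt(3) / 2.0
        centers = [np.array([-spacing / 2, 0.0, 0.0]),
                   np.array([spacing / 2, 0.0, 0.0]),
                   np.array([0.0, h, 0.0])]
    else:
        dd = 2.0 * spacing if end_distance is None else end_distance
        if dd > 2.0 * spacing:
            raise ValueError("end_distance cannot exceed twice the spacing")
        h = np.sqrt(max(0.0, spacing ** 2 - (dd / 2.0) ** 2))
        centers = [np.array([-dd / 2, 0.0, 0.0]),
                   np.array([0.0, h, 0.0]),
                   np.array([dd / 2, 0.0, 0.0])]
    w = PDBWriter(resolution=resolution)
    centroid = np.mean(centers, axis=0)
    for i, c in enumerate(centers):
        # stagger normals slightly so rings are not coplanar stacks
        normal = _unit(np.array([0.0, 0.3 * (i - 1), 1.0]))
        ring = make_ring("benzene", c + shift, normal)
        _write_phe(w, "A", i + 1, ring, away=centroid + shift)
    w.ter()
    text = w.text()
    if out is not None:
        Path(out).write_text(text)
    return text


@dataclass
class RingSpec:
    """One ring of a complex fixture: a Phe ring on a chain, or a benzene
    ligand ring."""
    kind: str                  # "PHE" | "ligand"
    chain: str
    center: tuple
    normal: tuple = (0.0, 0.0, 1.0)
    seq: int | None = None
    with_backbone: bool = True


def make_complex_fixture(kind: str, rings, out=None, resolution: float = 2.0,
                         min_separation: float = 1.5):
    """Toy PD or PP complex from a list of :class:`RingSpec`.

    PP fixtures must use exactly two polymer chains and no ligand; PD
    fixtures at least one chain plus at least one ligand ring. Raises a
    generation error when two atoms of different residues come closer
    than ``min_separation``.
    """
    rings = list(rings)
    chains = sorted({r.chain for r in rings if r.kind != "ligand"})
    n_lig = sum(1 for r in rings if r.kind == "ligand")
    if kind == "PP" and (len(chains) != 2 or n_lig):
        raise ValueError("PP fixture needs exactly 2 polymer chains and no ligand")
    if kind == "PD" and (not chains or not n_lig):
        raise ValueError("PD fixture needs >= 1 polymer chain and >= 1 ligand ring")

    w = PDBWriter(resolution=resolution)
    centroid = np.mean([np.asarray(r.center, dtype=float) for r in rings], axis=0)
    placed: list[tuple[tuple, np.ndarray]] = []   # (residue tag, coords)

    seq_counter = {c: 0 for c in chains}
    before = 0
    for spec in (r for r in rings if r.kind != "ligand"):
        seq_counter[spec.chain] += 1
        seq = spec.seq or seq_counter[spec.chain]
        ring = make_ring("benzene", np.asarray(spec.center, dtype=float),
                         spec.normal)
        _write_phe(w, spec.chain, seq, ring, away=centroid,
                   with_backbone=spec.with_backbone)
        placed.append(((spec.chain, seq), _coords_since(w, before)))
        before = w.serial
    w.ter()
    lig_seq = 100
    for spec in (r for r in rings if r.kind == "ligand"):
        lig_seq += 1
        ring = make_ring("benzene", np.asarray(spec.center, dtype=float),
                         spec.normal)
        _write_benzene_ligand(w, spec.chain or "L", lig_seq, ring)
        placed.append((("LIG", lig_seq), _coords_since(w, before)))
        before = w.serial

    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            di = np.linalg.norm(placed[i][1][:, None, :] - placed[j][1][None, :, :],
                                axis=-1).min()
            if di < min_separation:
                raise ValueError(
                    f"unsatisfiable geometry: atoms of {placed[i][0]} and "
                    f"{placed[j][0]} clash at {di:.2f} A")
    text = w.text()
    if out is not None:
        Path(out).write_text(text)
    return text


def _coords_since(writer: PDBWriter, start_serial: int) -> np.ndarray:
    coords = []
    for line in writer.lines:
        if line.startswith(("ATOM  ", "HETATM")) and int(line[6:11]) > start_serial:
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    return np.array(coords)


# --- backbone builders ------------------------------------------------------

def _nerf(a, b, c, length, angle_deg, torsion_deg) -> np.ndarray:
    """Place the next atom from three predecessors (natural extension
    reference frame)."""
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-length * np.cos(ang),
                  length * np.sin(ang) * np.cos(tor),
                  length * np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi, start=np.zeros(3)) -> list:
    """Poly-Ala backbone (N, CA, C, O per residue) from (phi, psi) pairs.

    Bond lengths and angles are ideal; omega is trans. Returns a list of
    dicts of atom coordinates per residue.
    """
    n_res = len(phi_psi)
    start = np.asarray(start, dtype=float)
    residues = []
    # seed the first residue in the xy-plane
    n0 = start
    ca0 = n0 + np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.radians(_BB["ang_n_ca_c"])
    c0 = ca0 + _BB["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        phi_prev, psi_prev = phi_psi[i - 1]
        phi_i, _ = phi_psi[i]
        prev = residues[-1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _BB["c_n"],
                    _BB["ang_ca_c_n"], psi_prev)
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _BB["n_ca"],
                     _BB["ang_c_n_ca"], _BB["omega"])
        c_i = _nerf(prev["C"], n_i, ca_i, _BB["ca_c"],
                    _BB["ang_n_ca_c"], phi_i)
        # carbonyl O of the previous residue, anti to the new N
        prev["O"] = _nerf(n_i, prev["CA"], prev["C"], _BB["c_o"],
                          _BB["ang_ca_c_o"], 180.0)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # terminal O from psi of the last residue
    last = residues[-1]
    psi_last = phi_psi[-1][1]
    last["O"] = _nerf(last["N"], last["CA"], last["C"], _BB["c_o"],
                      _BB["ang_ca_c_o"], psi_last + 180.0)
    return residues


def _write_backbone(writer: PDBWriter, residues, chain, start_seq=1,
                    res_name="ALA"):
    for i, res in enumerate(residues):
        seq = start_seq + i
        for name in ("N", "CA", "C", "O"):
            writer.atom(name, res_name, chain, seq, res[name], name[0])


def make_helix_fixture(n_res: int = 12, out=None) -> str:
    """Ideal poly-Ala alpha helix (phi = -57, psi = -47)."""
    residues = build_backbone([(-57.0, -47.0)] * n_res)
    w = PDBWriter(resolution=2.0, header="SYNTHETIC HELIX")
    _write_backbone(w, residues, "A")
    w.ter()
    text = w.text()
    if out is not None:
        Path(out).write_text(text)
    return text


def make_strand_fixture(n_res: int = 8, out=None) -> str:
    """A single extended strand with no hydrogen-bond partner."""
    residues = build_backbone([(-139.0, 135.0)] * n_res)
    w = PDBWriter(resolution=2.0, header="SYNTHETIC STRAND")
    _write_backbone(w, residues, "A")
    w.ter()
    text = w.text()
    if out is not None:
        Path(out).write_text(text)
    return text


#: inversion-center offset from the CA centroid for the partner strand,
#: calibrated once so cross-strand amide H-bonds form along the whole ribbon
_SHEET_INV_OFFSET = np.array([-1.0, 1.0, 1.0])


def make_sheet_fixture(n_res: int = 8, out=None) -> str:
    """Two-strand antiparallel beta fixture (phi = -139, psi = 135).

    The partner strand is the point inversion of the first through a
    calibrated center near the CA centroid. Inversion reverses the chain
    direction (antiparallel) and cancels the strand twist, so backbone
    hydrogen bonds form along the entire ribbon; the partner is a mirror
    image, which is immaterial for a backbone-only poly-Ala fixture.
    """
    strand1 = build_backbone([(-139.0, 135.0)] * n_res)
    center = np.mean([r["CA"] for r in strand1], axis=0) + _SHEET_INV_OFFSET
    strand2 = [{k: 2.0 * center - v for k, v in res.items()} for res in strand1]
    w = PDBWriter(resolution=2.0, header="SYNTHETIC SHEET")
    _write_backbone(w, strand1, "A")
    w.ter()
    _write_backbone(w, strand2, "B")
    w.ter()
    text = w.text()
    if out is not None:
        Path(out).write_text(text)
    return text


# --- ensemble sampling ------------------------------------------------------

def sample_ensemble(recipe: EnsembleRecipe, seed: int) -> np.ndarray:
    """Reproducible (d, alpha) samples from the recipe's mixture.

    alpha is folded into [0, 90] by reflection; non-positive d values
    are redrawn. Same (recipe, seed) -> identical samples.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([c[0] for c in recipe.components])
    comp_idx = rng.choice(len(recipe.components), size=recipe.n, p=weights)
    d = np.empty(recipe.n)
    alpha = np.empty(recipe.n)
    for k, (_, mu_d, mu_a, sd_d, sd_a) in enumerate(recipe.components):
        mask = comp_idx == k
        m = int(mask.sum())
        dk = rng.normal(mu_d, sd_d, size=m)
        bad = dk <= 0
        while bad.any():
            dk[bad] = rng.normal(mu_d, sd_d, size=int(bad.sum()))
            bad = dk <= 0
        ak = rng.normal(mu_a, sd_a, size=m)
        ak = np.abs(ak) % 180.0
        ak = np.where(ak > 90.0, 180.0 - ak, ak)
        d[mask] = dk
        alpha[mask] = ak
    return np.column_stack([d, alpha])
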