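"""Coordinate-file I/O and dataset filters.

Structures are parsed with :mod:`gemmi` (PDB and mmCIF) and re-exposed as
small frozen-ish dataclasses that downstream stages consume: polymer
residues, hetero ligand instances with CONECT-derived bonds, and header
metadata (resolution, HELIX/SHEET records).

Dataset filters follow the study design for protein-drug (PD) and
protein-protein (PP) complexes: drug-like ligands must weigh at least
100 Da (heavy atoms only, see :func:`mol_weight`) and occur in at most
ten distinct crystals; complexes must be solved at 2.5 A resolution or
better; PP complexes are dimers with exactly two polymer chains.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .config import Config

logger = logging.getLogger(__name__)

#: standard atomic masses (Da) for elements seen in drug-like ligands
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "B": 10.81, "SE": 78.971, "SI": 28.085,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "CU": 63.546, "CO": 58.933, "NI": 58.693,
}

_WATER_NAMES = {"HOH", "DOD", "WAT"}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray           # shape (3,), angstrom
    occupancy: float = 1.0
    alt_loc: str = ""
    is_hetero: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    atoms: list = field(default_factory=list)
    icode: str = ""

    @property
    def key(self):
        return (self.chain_id, self.seq_num, self.icode, self.res_name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class LigandInstance:
    comp_id: str
    chain_id: str
    seq_num: int
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)   # pairs of atom indices

    def __post_init__(self):
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references invalid atom index")

    @property
    def key(self):
        return (self.chain_id, self.seq_num, "", self.comp_id)

    @property
    def mol_weight(self) -> float:
        """Sum of standard atomic masses over *recorded* atoms.

        Crystal structures rarely record hydrogens, so this is a
        heavy-atom weight in practice; the 100 Da drug-likeness gate is
        applied to this quantity and documented as such.
        """
        return mol_weight(self.atoms)


@dataclass
class Structure:
    id: str
    residues: list = field(default_factory=list)     # polymer Residue
    ligands: list = field(default_factory=list)      # LigandInstance
    resolution: float | None = None
    helices: list = field(default_factory=list)      # (chain, start, end)
    sheets: list = field(default_factory=list)       # (chain, start, end)

    @property
    def polymer_chain_ids(self) -> list:
        seen = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> list:
        return [r for r in self.residues if r.chain_id == chain_id]


@dataclass
class ComplexRecord:
    id: str
    structure: Structure
    resolution: float | None = None
    n_polymer_chains: int = 0
    dataset_class: str | None = None   # "PD" | "PP" | "other"


def infer_element(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Used when the element column (77-78) is blank, as in many toy and
    legacy files. Digits and primes are stripped; a leading two-letter
    match against known elements wins only when the remaining letters
    start with a recognized two-letter symbol (FE, CL, BR, ...), else the
    first letter is taken. Protein/nucleic naming (CA = alpha carbon, not
    calcium) is honored because single letters are preferred for
    ATOM-style names.
    """
    letters = "".join(c for c in name if c.isalpha()).upper()
    if not letters:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    # halogens/metals in ligands use the full symbol as the name stem;
    # ATOM-style remoteness names (CA, CB, ND1, ...) are single-element
    two = letters[:2]
    if two in ("CL", "BR", "SE", "FE", "ZN", "MG", "MN") and letters == two:
        return two
    return letters[0]


def mol_weight(atoms) -> float:
    """Standard-atomic-mass sum over the given atoms (no implicit H)."""
    total = 0.0
    for a in atoms:
        m = ATOMIC_MASS.get(a.element.upper())
        if m is None:
            raise ValueError(f"no atomic mass for element {a.element!r} (atom {a.name})")
        total += m
    return total


def _convert_atom(ga: gemmi.Atom, hetero: bool) -> Atom:
    el = ga.element.name.upper()
    if not el or el == "X":
        el = infer_element(ga.name)
    return Atom(
        serial=ga.serial,
        name=ga.name,
        element=el,
        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
        occupancy=ga.occ if ga.occ is not None else 1.0,
        alt_loc=ga.altloc.strip("\x00") if ga.altloc != "\x00" else "",
        is_hetero=hetero,
    )


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read a PDB (or mmCIF) file into a :class:`Structure`.

    Returns polymer residues, hetero ligands (waters excluded) with
    CONECT-derived bonds, and the header resolution when present. Only
    the model selected by ``model_index`` (default: first) is read; for
    multi-model NMR entries this follows the convention of analyzing the
    first model, and the selection is logged.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if not (0 <= model_index < len(st)):
        raise IndexError(
            f"model_index {model_index} out of range: {path} has {len(st)} model(s)")
    if len(st) > 1:
        logger.info("%s: %d models, using model %d", path.name, len(st), model_index)
    model = st[model_index]

    serial_to_key: dict[int, tuple] = {}
    residues: list[Residue] = []
    ligands: list[LigandInstance] = []
    for chain in model:
        for res in chain:
            hetero = res.het_flag == "H"
            atoms = []
            for ga in res:
                a = _convert_atom(ga, hetero)
                atoms.append(a)
            if hetero:
                if res.name in _WATER_NAMES:
                    continue
                lig = LigandInstance(
                    comp_id=res.name, chain_id=chain.name,
                    seq_num=res.seqid.num, atoms=atoms)
                for i, a in enumerate(atoms):
                    serial_to_key[a.serial] = (len(ligands), i)
                ligands.append(lig)
            else:
                residues.append(Residue(
                    chain_id=chain.name, seq_num=res.seqid.num,
                    res_name=res.name, atoms=atoms,
                    icode=res.seqid.icode.strip()))

    # CONECT records -> intra-ligand bonds
    conect = getattr(st, "conect_map", {}) or {}
    bond_sets: dict[int, set] = {}
    for s1, partners in conect.items():
        for s2 in partners:
            k1, k2 = serial_to_key.get(s1), serial_to_key.get(s2)
            if k1 is None or k2 is None or k1[0] != k2[0]:
                continue
            i, j = sorted((k1[1], k2[1]))
            if i != j:
                bond_sets.setdefault(k1[0], set()).add((i, j))
    for li, bonds in bond_sets.items():
        ligands[li].bonds = sorted(bonds)

    helices = [(h.start.chain_name, h.start.res_id.seqid.num,
                h.end.res_id.seqid.num) for h in st.helices]
    sheets = []
    for sheet in st.sheets:
        for strand in sheet.strands:
            sheets.append((strand.start.chain_name,
                           strand.start.res_id.seqid.num,
                           strand.end.res_id.seqid.num))

    res_ang = st.resolution if st.resolution and st.resolution > 0 else None
    return Structure(id=path.stem, residues=residues, ligands=ligands,
                     resolution=res_ang, helices=helices, sheets=sheets)


def resolve_altloc(structure: Structure) -> Structure:
    """Collapse alternate conformations to one atom per name.

    For each atom name with multiple altLocs, the highest-occupancy
    conformer is kept; ties are broken toward the lexicographically
    smallest altLoc identifier. Idempotent.
    """

    def collapse(atoms):
        by_name: dict[str, list] = {}
        order = []
        for a in atoms:
            if a.name not in by_name:
                order.append(a.name)
            by_name.setdefault(a.name, []).append(a)
        out = []
        for name in order:
            group = by_name[name]
            best = min(group, key=lambda a: (-(a.occupancy if a.occupancy is not None else 1.0),
                                             a.alt_loc))
            out.append(replace(best, alt_loc=""))
        return out

    residues = [replace(r, atoms=collapse(r.atoms)) for r in structure.residues]
    ligands = [replace(l, atoms=collapse(l.atoms)) for l in structure.ligands]
    return replace(structure, residues=residues, ligands=ligands)


def read_occurrence_table(path: str | Path) -> dict:
    """Two-column CSV (comp_id, n_crystals) -> occurrence map."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lower() in ("comp_id", "compound"):
                continue
            out[row[0].strip()] = int(row[1])
    return out


def read_cluster_membership(path: str | Path) -> dict:
    """Two-column CSV (structure id, sequence-cluster id).

    Sequence-identity clustering itself (e.g. CD-HIT at 95%) is performed
    externally; this reads its result for optional dataset deduplication.
    """
    out = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lower() in ("id", "structure"):
                continue
            out[row[0].strip()] = row[1].strip()
    return out


def filter_drug_like(ligands, occurrence: dict | None = None,
                     config: Config | None = None) -> list:
    """Keep drug-like ligands: MW >= 100 Da and occurrence <= 10 crystals.

    Both bounds are inclusive on the keep side (a compound seen in more
    than ten crystals, or lighter than 100 Da, is excluded). Ligands on
    the deny-list (waters, buffers, ions) are always excluded. If no
    occurrence map is supplied the occurrence filter is skipped with a
    warning.
    """
    cfg = config or Config()
    if not occurrence:
        logger.warning("no ligand occurrence table: occurrence filter skipped")
        occurrence = {}
    deny = set(cfg.ligand_denylist)
    kept = []
    for lig in ligands:
        if lig.comp_id in deny:
            continue
        if lig.mol_weight < cfg.min_ligand_mw:
            continue
        occ = occurrence.get(lig.comp_id)
        if occ is not None and occ > cfg.max_ligand_occurrence:
            continue
        kept.append(lig)
    return kept


def filter_resolution(records, max_res: float = 2.5) -> list:
    """Keep complexes solved at ``max_res`` (default 2.5 A) or better.

    Records with no recorded resolution are dropped and logged.
    """
    kept = []
    for rec in records:
        res = rec.resolution
        if res is None:
            logger.warning("%s: no resolution recorded, dropped", rec.id)
            continue
        if res <= max_res:
            kept.append(rec)
    return kept


def classify_dataset(record: ComplexRecord, occurrence: dict | None = None,
                     config: Config | None = None) -> tuple:
    """Emit the dataset labels a complex qualifies for.

    PD if at least one drug-like ligand survives the filters; PP if the
    structure has exactly two polymer chains. A complex may carry both
    labels (analyzed separately in each dataset); neither -> ("other",).
    """
    cfg = config or Config()
    labels = []
    drug_like = filter_drug_like(record.structure.ligands, occurrence, cfg)
    if drug_like:
        labels.append("PD")
    if record.n_polymer_chains == 2:
        labels.append("PP")
    return tuple(labels) if labels else ("other",)


def load_complex(path: str | Path, model_index: int = 0) -> ComplexRecord:
    """Read and altLoc-resolve a file into a :class:`ComplexRecord`."""
    st = resolve_altloc(read_structure(path, model_index))
    return ComplexRecord(
        id=st.id, structure=st, resolution=st.resolution,
        n_polymer_chains=len(st.polymer_chain_ids))
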