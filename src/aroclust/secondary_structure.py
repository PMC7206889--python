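"""Three-class secondary structure and interaction preference log-odds.

Residues are assigned one of {Helix, Sheet, Loop}. Three provenances are
supported:

* ``internal`` - a Kabsch-Sander-style assignment computed from backbone
  geometry: the amide hydrogen is placed from the preceding peptide
  C=O, backbone H-bonds are scored with the electrostatic energy
  E = 27.888 * (1/rON + 1/rCH - 1/rOH - 1/rCN) kcal/mol and accepted
  below -0.5 kcal/mol; runs of n -> n+4 bonds make helices and paired
  bridges make sheets. This is a documented approximation of DSSP's
  8-state algorithm collapsed to 3 classes.
* ``dssp-file`` - parse a classic DSSP output and map 8 -> 3
  (H, G, I -> Helix; E, B -> Sheet; the rest -> Loop).
* ``header`` - trust the coordinate file's HELIX/SHEET records.

The preference statistic is a log odds ratio: for a context class c and
partner class p,

    preference(c, p) = log10( P(p | c) / P(p) )

positive when partners of class p are enriched around context c relative
to the background class frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SS_CLASSES = ("Loop", "Sheet", "Helix")

#: DSSP 8-state -> 3-class mapping
DSSP_TO_3 = {"H": "Helix", "G": "Helix", "I": "Helix",
             "E": "Sheet", "B": "Sheet"}

_KS_COUPLING = 27.888      # kcal/mol * A, = 0.084 e^2 * 332
_KS_CUTOFF = -0.5          # kcal/mol
_NH_LENGTH = 1.0           # A, amide N-H


@dataclass
class SSAssignment:
    classes: dict                      # residue key -> Helix | Sheet | Loop
    provenance: str = "internal"

    def get(self, key, default="Loop"):
        return self.classes.get(key, default)

    def __getitem__(self, key):
        return self.classes[key]


def _backbone(residue):
    atoms = {}
    for name in ("N", "CA", "C", "O"):
        a = residue.atom(name)
        if a is None:
            return None
        atoms[name] = a.coords
    return atoms


def hbond_energy(donor_n, donor_h, acceptor_c, acceptor_o) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol)."""
    r_on = np.linalg.norm(acceptor_o - donor_n)
    r_ch = np.linalg.norm(acceptor_c - donor_h)
    r_oh = np.linalg.norm(acceptor_o - donor_h)
    r_cn = np.linalg.norm(acceptor_c - donor_n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 1e6    # clashing geometry, never a bond
    return _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _assign_internal(structure) -> dict:
    # global residue list; chain-internal index arithmetic for turns/bridges
    chains: dict[str, list] = {}
    for r in structure.residues:
        chains.setdefault(r.chain_id, []).append(r)

    entries = []       # (key, chain_id, pos_in_chain, backbone, h_pos or None)
    for cid, residues in chains.items():
        for pos, res in enumerate(residues):
            bb = _backbone(res)
            h = None
            if bb is not None and pos > 0 and res.res_name != "PRO":
                prev_bb = _backbone(residues[pos - 1])
                if prev_bb is not None:
                    co = prev_bb["C"] - prev_bb["O"]
                    n = np.linalg.norm(co)
                    if n > 1e-6:
                        h = bb["N"] + _NH_LENGTH * co / n
            if bb is None:
                logger.warning("%s %s%d: missing backbone atoms, assigned Loop",
                               res.res_name, res.chain_id, res.seq_num)
            entries.append((res.key, cid, pos, bb, h))

    n = len(entries)
    index_of = {(e[1], e[2]): i for i, e in enumerate(entries)}

    # hbond[i][j]: CO of i accepts the NH of j
    hbond = [[False] * n for _ in range(n)]
    for i in range(n):
        bb_i = entries[i][3]
        if bb_i is None:
            continue
        for j in range(n):
            if i == j:
                continue
            if entries[i][1] == entries[j][1] and abs(entries[i][2] - entries[j][2]) < 2:
                continue
            bb_j, h_j = entries[j][3], entries[j][4]
            if bb_j is None or h_j is None:
                continue
            if np.linalg.norm(bb_i["O"] - bb_j["N"]) > 5.5:
                continue
            e = hbond_energy(bb_j["N"], h_j, bb_i["C"], bb_i["O"])
            if e < _KS_CUTOFF:
                hbond[i][j] = True

    def hb(cid, pi, pj) -> bool:
        a = index_of.get((cid, pi))
        b = index_of.get((cid, pj))
        return a is not None and b is not None and hbond[a][b]

    classes = {e[0]: "Loop" for e in entries}

    # helices: consecutive n -> n+4 turns cover residues i+1 .. i+4
    for cid, residues in chains.items():
        m = len(residues)
        turn = [hb(cid, i, i + 4) for i in range(m)]
        for i in range(m - 1):
            if turn[i] and turn[i + 1]:
                for k in range(i + 1, min(i + 5, m)):
                    classes[residues[k].key] = "Helix"

    # bridges (parallel / antiparallel), possibly across chains
    def hb_glob(i, j) -> bool:
        return 0 <= i < n and 0 <= j < n and hbond[i][j]

    def neighbor(i, off):
        key = (entries[i][1], entries[i][2] + off)
        return index_of.get(key, -1)

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if entries[i][1] == entries[j][1] and abs(entries[i][2] - entries[j][2]) < 3:
                continue
            im, ip = neighbor(i, -1), neighbor(i, 1)
            jm, jp = neighbor(j, -1), neighbor(j, 1)
            parallel = ((hb_glob(im, j) and hb_glob(j, ip)) or
                        (hb_glob(jm, i) and hb_glob(i, jp)))
            anti = ((hb_glob(i, j) and hb_glob(j, i)) or
                    (hb_glob(im, jp) and hb_glob(jm, ip)))
            if parallel or anti:
                for k in (i, j):
                    if classes[entries[k][0]] == "Loop":
                        classes[entries[k][0]] = "Sheet"
    return classes


def _assign_from_ranges(structure) -> dict:
    classes = {r.key: "Loop" for r in structure.residues}
    for chain, start, end in structure.helices:
        for r in structure.residues:
            if r.chain_id == chain and start <= r.seq_num <= end:
                classes[r.key] = "Helix"
    for chain, start, end in structure.sheets:
        for r in structure.residues:
            if r.chain_id == chain and start <= r.seq_num <= end:
                if classes[r.key] == "Loop":
                    classes[r.key] = "Sheet"
    return classes


def parse_dssp(path) -> dict:
    """Classic DSSP output -> {(chain, seq_num, icode) -> 3-class}."""
    classes = {}
    with open(path) as fh:
        in_table = False
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":      # chain break
                continue
            try:
                seq = int(line[5:10])
            except ValueError:
                continue
            icode = line[10].strip()
            chain = line[11].strip()
            ss8 = line[16].strip()
            classes[(chain, seq, icode)] = DSSP_TO_3.get(ss8, "Loop")
    return classes


def assign_ss(structure, mode: str = "internal",
              dssp_path=None) -> SSAssignment:
    """Per-residue Loop/Sheet/Helix assignment.

    ``mode`` is one of internal | dssp-file | header; dssp-file requires
    ``dssp_path``. Residues absent from an external source default to
    Loop.
    """
    if mode == "internal":
        return SSAssignment(_assign_internal(structure), provenance="internal")
    if mode == "header":
        return SSAssignment(_assign_from_ranges(structure), provenance="header")
    if mode == "dssp-file":
        if dssp_path is None:
            raise ValueError("dssp-file mode requires dssp_path")
        by_pos = parse_dssp(dssp_path)
        classes = {}
        for r in structure.residues:
            classes[r.key] = by_pos.get((r.chain_id, r.seq_num, r.icode), "Loop")
        return SSAssignment(classes, provenance="dssp-file")
    raise ValueError(f"unknown SS mode {mode!r}")


@dataclass
class PreferenceTable:
    log_odds: pd.DataFrame             # context class x partner class
    background: dict                   # partner class -> probability
    counts: pd.DataFrame
    base: float = 10.0


def preference(counts, background: dict | None = None,
               base: float = 10.0) -> PreferenceTable:
    """Log-odds preference of context classes for partner classes.

    ``counts`` is a contingency table (context class -> partner class ->
    count; dict of dicts or DataFrame). ``background`` gives partner
    class probabilities; by default it is estimated from the column sums
    of the table itself. Cells needed at zero count receive a +0.5
    (Jeffreys) adjustment, logged; an all-zero context row is reported
    as missing (NaN).
    """
    table = pd.DataFrame(counts).T if isinstance(counts, dict) else pd.DataFrame(counts)
    table = table.astype(float).fillna(0.0)
    if (table.values < 0).any():
        raise ValueError("counts must be non-negative")

    if background is None:
        col = table.sum(axis=0)
        total = col.sum()
        if total == 0:
            raise ValueError("empty contingency table and no background given")
        background = (col / total).to_dict()
    bg = pd.Series(background, dtype=float).reindex(table.columns)
    if bg.isna().any() or (bg <= 0).any():
        raise ValueError("background probabilities must be positive for all classes")

    adjusted = table.copy()
    zero_mask = adjusted == 0
    if zero_mask.values.any():
        logger.info("preference: %d zero cells adjusted by +0.5",
                    int(zero_mask.values.sum()))
        adjusted = adjusted.where(~zero_mask, 0.5)

    out = pd.DataFrame(np.nan, index=table.index, columns=table.columns)
    log_base = math.log(base)
    for ctx in table.index:
        row_total = table.loc[ctx].sum()
        if row_total == 0:
            logger.warning("preference: context %r has no observations", ctx)
            continue
        row = adjusted.loc[ctx]
        row_p = row / row.sum()
        out.loc[ctx] = np.log(row_p / bg) / log_base
    return PreferenceTable(log_odds=out, background=dict(bg), counts=table, base=base)
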