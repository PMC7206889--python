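"""Dataset-level distributions and affinity stratification.

Covers the ensemble views of ring-interaction geometry and affinity:

* :func:`rdf` - radial distribution of ring-center distances (frequency
  or spherical-shell normalization);
* :func:`energy_map` - Boltzmann inversion of the (d, alpha) histogram,
  dG(bin) = -R T ln(N / N_max) at 298 K by default, so the most
  populated bin sits at dG = 0;
* :func:`ki_ingest` / :func:`affinity_stratify` - Ki tables (BindingDB
  style) grouped by cluster count x interaction count, by contact-residue
  exposure (the 20% split) and by contact-residue secondary structure,
  compared with a two-sided Mann-Whitney rank-sum test on log Ki.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config

logger = logging.getLogger(__name__)

R_KCAL = 1.987e-3     # gas constant, kcal / (mol K)


@dataclass
class RDF:
    bin_centers: np.ndarray
    g: np.ndarray
    bin_width: float
    normalization: str      # "shell" | "frequency"


@dataclass
class EnergyMap:
    d_edges: np.ndarray
    alpha_edges: np.ndarray
    counts: np.ndarray          # shape (n_d, n_alpha)
    dG: np.ndarray              # kcal/mol, NaN for empty bins
    temperature: float

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    @property
    def alpha_centers(self) -> np.ndarray:
        return 0.5 * (self.alpha_edges[:-1] + self.alpha_edges[1:])

    def minimum(self) -> tuple:
        """(d, alpha) bin-center location of the global dG minimum."""
        i, j = np.unravel_index(np.nanargmin(self.dG), self.dG.shape)
        return float(self.d_centers[i]), float(self.alpha_centers[j])


@dataclass
class AffinityRecord:
    complex_id: str
    ki: float                       # molar
    n_clusters: int = 0
    n_interactions: int = 0
    max_exposure: float | None = None            # % of contact residues
    ss_classes: frozenset = frozenset()          # of contact residues

    def __post_init__(self):
        if not self.ki > 0:
            raise ValueError("Ki must be positive")


def rdf(distances, bin_width: float = 0.1, r_max: float = 7.0,
        normalization: str = "frequency") -> RDF:
    """Histogram of ring-center distances on (0, r_max].

    ``frequency`` normalizes bin counts to sum to 1; ``shell`` divides
    each bin by its spherical-shell volume 4 pi r^2 dr before
    renormalizing, giving a flat profile for uniform-in-volume points.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("rdf needs at least one distance")
    if np.any(d <= 0) or np.any(d > r_max):
        raise ValueError("distances must lie in (0, r_max]")
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    counts, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if normalization == "frequency":
        g = counts / counts.sum()
    elif normalization == "shell":
        shell = 4.0 * np.pi * centers ** 2 * np.diff(edges)
        g = counts / shell
        g = g / g.sum()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return RDF(bin_centers=centers, g=g, bin_width=bin_width,
               normalization=normalization)


def energy_map(samples, temperature: float = 298.0,
               d_bin: float = 0.25, alpha_bin: float = 5.0,
               d_range: tuple = (0.0, 7.0),
               alpha_range: tuple = (0.0, 90.0)) -> EnergyMap:
    """Boltzmann-inverted free-energy surface over (d, alpha).

    dG(bin) = -R T ln(N_bin / N_max), with the most populated bin as the
    zero reference; empty bins are NaN. Invariant under duplication of
    the sample set (depends on count ratios only).
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("energy_map needs at least one (d, alpha) sample")
    d_edges = np.arange(d_range[0], d_range[1] + d_bin * 0.5, d_bin)
    a_edges = np.arange(alpha_range[0], alpha_range[1] + alpha_bin * 0.5, alpha_bin)
    counts, d_edges, a_edges = np.histogram2d(
        arr[:, 0], arr[:, 1], bins=[d_edges, a_edges])
    nmax = counts.max()
    if nmax == 0:
        raise ValueError("no samples fall inside the histogram ranges")
    with np.errstate(divide="ignore"):
        dG = -R_KCAL * temperature * np.log(counts / nmax)
    dG[counts == 0] = np.nan
    return EnergyMap(d_edges=d_edges, alpha_edges=a_edges, counts=counts,
                     dG=dG, temperature=temperature)


_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
               "pm": 1e-12, "fm": 1e-15}


def _parse_ki(value, unit=None, default_scale: float = 1.0) -> float | None:
    """Ki cell (+ optional unit column) -> molar; None when unusable.

    Unit resolution order: explicit unit column, then an in-cell unit
    ("5 nM"), then ``default_scale`` (e.g. 1e-9 when the Ki column is
    named in nM).
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip().lstrip("<>~ ")
    scale = None
    if unit is not None and not (isinstance(unit, float) and math.isnan(unit)):
        scale = _UNIT_SCALE.get(str(unit).strip().lower())
    if scale is None:
        parts = s.split()
        if len(parts) == 2 and parts[1].lower() in _UNIT_SCALE:
            s, scale = parts[0], _UNIT_SCALE[parts[1].lower()]
    if scale is None:
        scale = default_scale
    try:
        ki = float(s) * scale
    except ValueError:
        return None
    return ki if ki > 0 else None


def ki_ingest(path) -> dict:
    """CSV/TSV affinity table -> {complex id: Ki in molar}.

    The table needs an id column and a Ki column; an optional unit
    column (nM/uM/M) or in-cell units are converted to molar. Duplicate
    ids are resolved by geometric mean (logged); non-positive or
    unparseable values are skipped with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    id_col = next((cols[k] for k in ("id", "complex_id", "pdb", "pdb_id", "complex")
                   if k in cols), None)
    ki_col = next((cols[k] for k in ("ki", "ki (nm)", "ki_nm", "affinity")
                   if k in cols), None)
    if id_col is None or ki_col is None:
        raise ValueError(f"{path}: need an id column and a Ki column "
                         f"(found {list(df.columns)})")
    unit_col = next((cols[k] for k in ("unit", "units", "ki_unit") if k in cols), None)
    default_scale = 1e-9 if "(nm)" in ki_col.lower() or ki_col.lower().endswith("_nm") else 1.0

    values: dict[str, list] = {}
    for _, row in df.iterrows():
        unit = row[unit_col] if unit_col else None
        ki = _parse_ki(row[ki_col], unit, default_scale)
        if ki is None:
            logger.warning("%s: unusable Ki %r for %r, skipped",
                           path.name, row[ki_col], row[id_col])
            continue
        values.setdefault(str(row[id_col]).strip(), []).append(ki)

    out = {}
    for cid, kis in values.items():
        if len(kis) > 1:
            logger.info("%s: %d Ki values for %s, geometric mean taken",
                        path.name, len(kis), cid)
        out[cid] = float(np.exp(np.mean(np.log(kis))))
    return out


def _interaction_bin(n: int, bins) -> str | None:
    for lo, hi in bins:
        if n >= lo and (hi is None or n <= hi):
            return f"{lo}-{hi}" if hi is not None else f">={lo}"
    return None


def _group_stats(kis) -> dict:
    kis = np.asarray(kis, dtype=float)
    return {
        "n": int(kis.size),
        "median_ki": float(np.median(kis)) if kis.size else None,
        "geomean_ki": float(np.exp(np.mean(np.log(kis)))) if kis.size else None,
    }


def _rank_sum(a, b) -> float | None:
    if len(a) == 0 or len(b) == 0:
        return None
    res = stats.mannwhitneyu(np.log(a), np.log(b), alternative="two-sided")
    return float(res.pvalue)


def affinity_stratify(records, config: Config | None = None) -> dict:
    """Group affinity records and compare strata.

    Groups: (number of clusters in {1, 2}) x interaction bins {2-3, 4-5,
    >=6}; contact-residue exposure above vs at-or-below 20%; and the
    secondary-structure classes of contacted residues. Records with more
    than two clusters are reported but excluded from the 1-vs-2
    comparison. Each group reports n, median and geometric-mean Ki;
    named group pairs get a two-sided Mann-Whitney p-value on log Ki.
    """
    cfg = config or Config()
    groups: dict[tuple, list] = {}
    out_of_range = []
    for rec in records:
        b = _interaction_bin(rec.n_interactions, cfg.interaction_bins)
        if rec.n_clusters in (1, 2) and b is not None:
            groups.setdefault((rec.n_clusters, b), []).append(rec.ki)
        else:
            out_of_range.append(rec.complex_id)

    exposure_groups = {"le20": [], "gt20": []}
    for rec in records:
        if rec.max_exposure is None:
            continue
        key = "gt20" if rec.max_exposure > cfg.exposure_threshold else "le20"
        exposure_groups[key].append(rec.ki)

    ss_groups: dict[str, list] = {"Loop": [], "Sheet": [], "Helix": []}
    for rec in records:
        for ss in rec.ss_classes:
            if ss in ss_groups:
                ss_groups[ss].append(rec.ki)

    cluster_strata = {
        f"{nc}_clusters_{b}": _group_stats(kis)
        for (nc, b), kis in sorted(groups.items())
    }
    tests = {}
    for b in {key[1] for key in groups}:
        a, c = groups.get((1, b), []), groups.get((2, b), [])
        tests[f"1_vs_2_clusters_{b}"] = _rank_sum(a, c)
    tests["exposure_gt20_vs_le20"] = _rank_sum(
        exposure_groups["gt20"], exposure_groups["le20"])
    for pair in (("Sheet", "Helix"), ("Sheet", "Loop"), ("Helix", "Loop")):
        tests[f"ss_{pair[0]}_vs_{pair[1]}"] = _rank_sum(
            ss_groups[pair[0]], ss_groups[pair[1]])

    return {
        "cluster_strata": cluster_strata,
        "exposure_strata": {k: _group_stats(v) for k, v in exposure_groups.items()},
        "ss_strata": {k: _group_stats(v) for k, v in ss_groups.items()},
        "tests": tests,
        "out_of_range": out_of_range,
    }
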