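"""Run configuration for the aromatic-cluster pipeline.

All geometric thresholds and dataset filters are collected here so that a
single YAML/JSON file controls a run and its provenance can be hashed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: ligand residue names never considered drug-like (waters, common
#: crystallization additives and cryoprotectants)
DEFAULT_LIGAND_DENYLIST = (
    "HOH", "DOD", "WAT",
    "SO4", "PO4", "GOL", "EDO", "PEG", "PGE", "MPD", "DMS", "ACT", "FMT",
    "TRS", "EPE", "MES", "CIT", "TLA", "NO3", "CL", "NA", "K", "MG", "CA",
    "ZN", "MN", "FE", "NI", "CO", "CU", "CD", "BR", "IOD",
)


@dataclass
class Config:
    """Pipeline parameters with their field-standard defaults.

    Distances are in angstrom, angles in degrees, temperatures in kelvin.
    """

    # dataset filters
    max_resolution: float = 2.5          # keep structures at <= this resolution
    min_ligand_mw: float = 100.0         # Da, heavy atoms only (documented)
    max_ligand_occurrence: int = 10      # distinct crystals a compound appears in
    ligand_denylist: tuple = DEFAULT_LIGAND_DENYLIST

    # interaction geometry
    cutoff_d: float = 7.0                # ring center-center detection cutoff
    alpha_parallel_max: float = 30.0     # alpha <= this -> parallel planes
    theta_ftf_max: float = 45.0          # theta <= this (parallel) -> face-to-face
    alpha_tshape_min: float = 60.0       # alpha >= this -> edge-to-face (T-shape)

    # ring perception
    planarity_rms_max: float = 0.10      # max out-of-plane rms for ligand rings
    bond_slack: float = 0.40             # covalent-radius slack for inferred bonds

    # solvent accessibility
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    sidechain_includes_cb: bool = True

    # statistics
    temperature: float = 298.0           # K, Boltzmann inversion
    log_base: float = 10.0               # preference log-odds base
    exposure_threshold: float = 20.0     # % exposed split for affinity strata
    rdf_bin_width: float = 0.1
    energy_d_bin: float = 0.25
    energy_alpha_bin: float = 5.0
    interaction_bins: tuple = ((2, 3), (4, 5), (6, None))

    # residue-composition counting unit: residue instances (TRP once) or rings
    composition_per_ring: bool = False
    include_his: bool = True

    extras: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        extras = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extras.update(extras)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ligand_denylist"] = list(self.ligand_denylist)
        d["interaction_bins"] = [list(b) for b in self.interaction_bins]
        return d

    def hash(self) -> str:
        """Stable digest of the configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
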