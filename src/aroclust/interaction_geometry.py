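"""Pairwise ring-interaction descriptors and conformation classes.

A ring pair is described by three quantities (all computed from the
fitted ring planes):

* ``d`` - Euclidean distance between ring centers (A);
* ``alpha`` - planar angle, the angle between the two ring normals,
  folded into [0, 90] degrees (rings are two-sided);
* ``theta`` - orientational angle, the angle between a ring normal and
  the center-to-center vector, folded into [0, 90]; reported as the
  minimum over the two rings so the descriptor is symmetric, with both
  per-ring values retained.

Interactions are *detected* on distance alone (center separation at most
7.0 A by default); the angles classify the conformation: parallel close
geometries are face-to-face stacking (optimum near d = 3.75 A,
alpha = 0), perpendicular ones edge-to-face (the T-shape, optimum near
d = 5 A, alpha = 75 deg), parallel-offset ones edge-to-edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import Config
from .ring_detection import AromaticRing


@dataclass
class AromaticInteraction:
    ring_a: str
    ring_b: str
    d: float
    alpha: float
    theta: float
    theta_a: float
    theta_b: float
    conformation: str        # face-to-face | edge-to-face | edge-to-edge | oblique
    context: str             # drug-residue | inter-chain | intra-chain

    @property
    def key(self):
        return tuple(sorted((self.ring_a, self.ring_b)))


def _fold_angle_deg(cosine: float) -> float:
    """Angle between two lines (not vectors), in [0, 90] degrees."""
    c = min(1.0, abs(float(cosine)))
    return float(np.degrees(np.arccos(c)))


def pair_descriptors(ring_a: AromaticRing, ring_b: AromaticRing) -> tuple:
    """(d, alpha, theta) for a ring pair; theta = min over the two rings."""
    sep = ring_b.center - ring_a.center
    d = float(np.linalg.norm(sep))
    if d < 1e-9:
        raise ValueError("coincident ring centers")
    u = sep / d
    alpha = _fold_angle_deg(np.dot(ring_a.normal, ring_b.normal))
    theta_a = _fold_angle_deg(np.dot(ring_a.normal, u))
    theta_b = _fold_angle_deg(np.dot(ring_b.normal, u))
    return d, alpha, min(theta_a, theta_b)


def interaction_context(ring_a: AromaticRing, ring_b: AromaticRing) -> str:
    if ring_a.source_class != ring_b.source_class:
        return "drug-residue"
    if ring_a.source_class == "D":
        return "drug-drug"
    return "inter-chain" if ring_a.chain_id != ring_b.chain_id else "intra-chain"


def classify_conformation(alpha: float, theta: float,
                          config: Config | None = None) -> str:
    """Conformation class from the two angles.

    Near-parallel planes (alpha <= 30 deg) are face-to-face when the
    center vector is near a ring normal (theta <= 45) and edge-to-edge
    when offset (theta > 45); near-perpendicular planes (alpha >= 60)
    are edge-to-face (T-shape); intermediate tilts are oblique.
    Thresholds are configurable.
    """
    cfg = config or Config()
    if not (0.0 <= alpha <= 90.0 and 0.0 <= theta <= 90.0):
        raise ValueError("angles must lie in [0, 90] degrees")
    if alpha <= cfg.alpha_parallel_max:
        return "face-to-face" if theta <= cfg.theta_ftf_max else "edge-to-edge"
    if alpha >= cfg.alpha_tshape_min:
        return "edge-to-face"
    return "oblique"


def detect_interaction(ring_a: AromaticRing, ring_b: AromaticRing,
                       cutoff: float = 7.0,
                       config: Config | None = None):
    """Emit the interaction for a ring pair, or None.

    An interaction exists iff the center distance is within ``cutoff``
    (7.0 A default), the rings share no atoms (fused systems are one
    chemical entity) and they do not belong to the same residue.
    """
    if ring_a.ring_id == ring_b.ring_id:
        return None
    if ring_a.parent_key is not None and ring_a.parent_key == ring_b.parent_key:
        return None
    if ring_a.shares_atoms(ring_b):
        return None
    d, alpha, theta = pair_descriptors(ring_a, ring_b)
    if d > cutoff:
        return None
    sep = ring_b.center - ring_a.center
    u = sep / d
    theta_a = _fold_angle_deg(np.dot(ring_a.normal, u))
    theta_b = _fold_angle_deg(np.dot(ring_b.normal, u))
    return AromaticInteraction(
        ring_a=ring_a.ring_id, ring_b=ring_b.ring_id,
        d=d, alpha=alpha, theta=theta, theta_a=theta_a, theta_b=theta_b,
        conformation=classify_conformation(alpha, theta, config),
        context=interaction_context(ring_a, ring_b))


def find_interactions(rings, cutoff: float = 7.0,
                      config: Config | None = None) -> list:
    """All pairwise interactions among ``rings``.

    Candidate pairs are pruned with a KD-tree at the cutoff radius;
    results are identical to the all-pairs scan.
    """
    rings = list(rings)
    if len(rings) < 2:
        return []
    centers = np.array([r.center for r in rings])
    tree = cKDTree(centers)
    out = []
    for i, j in sorted(tree.query_pairs(cutoff + 1e-9)):
        inter = detect_interaction(rings[i], rings[j], cutoff, config)
        if inter is not None:
            out.append(inter)
    return out
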