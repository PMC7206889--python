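"""Aromatic-cluster enumeration and dataset summaries.

A cluster is a connected component of the ring-interaction graph, built
from a context-specific *detection* edge set:

* protein-drug (PD): drug-residue edges plus all residue-residue edges;
  only components containing at least one drug (D) ring are clusters.
* protein-protein (PP): inter-chain residue-residue edges only.
* intraprotein (intra): intra-chain residue-residue edges only.

The number of interactions of a cluster is counted over a wider
*counting* edge set: in PP mode, intra-chain residue-residue edges among
member rings are added to the detection edges; in PD mode all
drug-residue and residue-residue edges among members count. Clusters
have at least two rings (singletons are not clusters). Three-ring
clusters come in two motifs: Symmetric (Sym, a triangle of three
interactions) and Ladder (Lad, a path of two).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .config import Config

logger = logging.getLogger(__name__)

AROMATIC_RES_NAMES = ("PHE", "TYR", "TRP", "HIS")
SS_CLASSES = ("Loop", "Sheet", "Helix")


@dataclass
class AromaticCluster:
    rings: list                       # AromaticRing members
    detection_edges: list             # AromaticInteraction
    counting_edges: list              # superset of detection_edges
    context: str                      # PD | PP | intra
    cluster_id: str = ""

    def __post_init__(self):
        det = {e.key for e in self.detection_edges}
        cnt = {e.key for e in self.counting_edges}
        if not det <= cnt:
            raise ValueError("detection edges must be a subset of counting edges")
        if self.size < 2:
            raise ValueError("a cluster has at least two rings")

    @property
    def size(self) -> int:
        return len(self.rings)

    @property
    def ring_ids(self) -> set:
        return {r.ring_id for r in self.rings}

    @property
    def n_interactions(self) -> int:
        return len(self.counting_edges)

    @property
    def trimer_motif(self) -> str:
        return trimer_motif(self) if self.size == 3 else "n/a"

    @property
    def residue_keys(self) -> set:
        """Keys of the protein residues contributing R rings."""
        return {r.parent_key for r in self.rings if r.source_class == "R"}


def _edge_in_mode(inter, mode: str) -> bool:
    if mode == "PD":
        return inter.context in ("drug-residue", "intra-chain", "inter-chain")
    if mode == "PP":
        return inter.context == "inter-chain"
    if mode == "intra":
        return inter.context == "intra-chain"
    raise ValueError(f"unknown cluster mode {mode!r} (expected PD, PP or intra)")


def _counting_edge_in_mode(inter, mode: str) -> bool:
    if mode in ("PD", "PP"):
        return inter.context in ("drug-residue", "intra-chain", "inter-chain")
    return inter.context == "intra-chain"


def enumerate_clusters(rings, interactions, mode: str,
                       complex_id: str = "") -> list:
    """Connected-component clusters under the mode's detection rules."""
    if mode not in ("PD", "PP", "intra"):
        raise ValueError(f"unknown cluster mode {mode!r} (expected PD, PP or intra)")
    by_id = {r.ring_id: r for r in rings}
    det_edges = [i for i in interactions if _edge_in_mode(i, mode)]
    g = nx.Graph()
    g.add_nodes_from(by_id)
    for e in det_edges:
        g.add_edge(e.ring_a, e.ring_b, inter=e)

    clusters = []
    for k, comp in enumerate(sorted(nx.connected_components(g),
                                    key=lambda c: sorted(c))):
        if len(comp) < 2:
            continue
        members = [by_id[rid] for rid in sorted(comp)]
        if mode == "PD" and not any(r.source_class == "D" for r in members):
            continue
        det = [e for e in det_edges if e.ring_a in comp and e.ring_b in comp]
        cnt_extra = [
            i for i in interactions
            if _counting_edge_in_mode(i, mode)
            and i.ring_a in comp and i.ring_b in comp
            and i.key not in {e.key for e in det}
        ]
        clusters.append(AromaticCluster(
            rings=members, detection_edges=det, counting_edges=det + cnt_extra,
            context=mode, cluster_id=f"{complex_id}:{mode}:{k}"))
    return clusters


def trimer_motif(cluster: AromaticCluster) -> str:
    """Sym (triangle, 3 interactions) vs Lad (path, 2) for 3-ring clusters."""
    if cluster.size != 3:
        raise ValueError("trimer motif is defined only for clusters of size 3")
    n_edges = len({e.key for e in cluster.counting_edges})
    return "Sym" if n_edges == 3 else "Lad"


@dataclass
class DatasetSummary:
    """Dataset-level cluster statistics for one complex class.

    The derived averages are defined exactly as the ratios of the count
    fields: clusters per complex *with at least one cluster*, and
    counting-edge interactions per cluster.
    """

    dataset: str = ""
    n_complexes_total: int | None = None
    n_complexes_with_cluster: int = 0
    n_clusters: int = 0
    n_interactions: int = 0
    composition: dict = field(default_factory=dict)    # residue -> fraction
    ss_fractions: dict = field(default_factory=dict)   # Loop/Sheet/Helix -> fraction
    mean_pct_exposed: float | None = None

    @property
    def avg_clusters_per_complex(self) -> float | None:
        if self.n_complexes_with_cluster == 0:
            return None
        return self.n_clusters / self.n_complexes_with_cluster

    @property
    def avg_interactions_per_cluster(self) -> float | None:
        if self.n_clusters == 0:
            return None
        return self.n_interactions / self.n_clusters

    @property
    def pct_with_cluster(self) -> float | None:
        if not self.n_complexes_total:
            return None
        return 100.0 * self.n_complexes_with_cluster / self.n_complexes_total

    def to_row(self) -> dict:
        row = {
            "dataset": self.dataset,
            "complexes_with_cluster": self.n_complexes_with_cluster,
            "n_clusters": self.n_clusters,
            "avg_clusters": (None if self.avg_clusters_per_complex is None
                             else round(self.avg_clusters_per_complex, 2)),
            "n_interactions": self.n_interactions,
            "avg_interactions_per_cluster": (
                None if self.avg_interactions_per_cluster is None
                else round(self.avg_interactions_per_cluster, 2)),
            "pct_with_cluster": (None if self.pct_with_cluster is None
                                 else round(self.pct_with_cluster)),
            "mean_pct_exposed": self.mean_pct_exposed,
        }
        for res in AROMATIC_RES_NAMES:
            row[f"pct_{res}"] = (round(100 * self.composition[res], 1)
                                 if res in self.composition else None)
        for ss in SS_CLASSES:
            row[f"pct_{ss}"] = (round(100 * self.ss_fractions[ss], 1)
                                if ss in self.ss_fractions else None)
        return row


def summarize_dataset(clusters_by_complex: dict, exposures: dict | None = None,
                      ss_assignments: dict | None = None,
                      n_complexes_total: int | None = None,
                      dataset: str = "", config: Config | None = None) -> DatasetSummary:
    """Table-style summary over ``complex id -> list of clusters``.

    Residue composition counts each interacting aromatic residue once per
    cluster membership (a Trp's two rings count once; switchable to
    per-ring via config). ``exposures`` maps (complex id, residue key) ->
    percent exposed; ``ss_assignments`` maps the same keys to a
    Loop/Sheet/Helix class. Zero clusters produce a zero summary rather
    than a division error.
    """
    cfg = config or Config()
    n_with = sum(1 for cl in clusters_by_complex.values() if cl)
    all_clusters = [c for cl in clusters_by_complex.values() for c in cl]
    n_clusters = len(all_clusters)
    n_inter = sum(c.n_interactions for c in all_clusters)

    res_names = AROMATIC_RES_NAMES if cfg.include_his else AROMATIC_RES_NAMES[:3]
    comp_counts = dict.fromkeys(res_names, 0)
    ss_counts = dict.fromkeys(SS_CLASSES, 0)
    exp_values = []
    for cid, cl_list in clusters_by_complex.items():
        for cluster in cl_list:
            if cfg.composition_per_ring:
                units = [(r.parent_key, r.parent_key[3]) for r in cluster.rings
                         if r.source_class == "R"]
            else:
                units = sorted({(r.parent_key, r.parent_key[3])
                                for r in cluster.rings if r.source_class == "R"})
            for res_key, res_name in units:
                if res_name in comp_counts:
                    comp_counts[res_name] += 1
                if ss_assignments is not None:
                    ss = ss_assignments.get((cid, res_key))
                    if ss in ss_counts:
                        ss_counts[ss] += 1
                if exposures is not None:
                    e = exposures.get((cid, res_key))
                    if e is not None:
                        exp_values.append(e)

    total_comp = sum(comp_counts.values())
    composition = ({k: v / total_comp for k, v in comp_counts.items()}
                   if total_comp else {})
    total_ss = sum(ss_counts.values())
    ss_fractions = ({k: v / total_ss for k, v in ss_counts.items()}
                    if total_ss else {})
    if n_clusters == 0:
        logger.warning("dataset %s: no clusters found", dataset or "<unnamed>")
    return DatasetSummary(
        dataset=dataset,
        n_complexes_total=n_complexes_total,
        n_complexes_with_cluster=n_with,
        n_clusters=n_clusters,
        n_interactions=n_inter,
        composition=composition,
        ss_fractions=ss_fractions,
        mean_pct_exposed=(float(pd.Series(exp_values).mean())
                          if exp_values else None),
    )


def summary_table(summaries) -> pd.DataFrame:
    """Stack per-dataset summaries into one table (one row per dataset)."""
    return pd.DataFrame([s.to_row() for s in summaries])


def clusters_table(clusters_by_complex: dict) -> pd.DataFrame:
    """Flat per-cluster table (complex, id, size, context, edges, motif)."""
    rows = []
    for cid, cl_list in clusters_by_complex.items():
        for c in cl_list:
            rows.append({
                "complex_id": cid, "cluster_id": c.cluster_id,
                "size": c.size, "context": c.context,
                "n_detection_edges": len(c.detection_edges),
                "n_counting_edges": len(c.counting_edges),
                "motif": c.trimer_motif,
            })
    return pd.DataFrame(rows)
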