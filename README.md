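# aroclust

Aromatic clusters in protein–drug and protein–protein complexes.

Aromatic rings — the side chains of Phe, Tyr, Trp and His, and the ring
systems of most drug-like molecules — interact through π–π contacts that
matter for binding affinity and interface stability. `aroclust` is a
structural-bioinformatics pipeline for detecting these rings in
coordinate files, measuring the geometry of every ring pair, grouping
rings into *aromatic clusters*, and computing dataset-level structural
and statistical summaries.

## The model

Each aromatic ring is reduced to its least-squares plane: a centroid
**c** and a unit normal **n̂**. A ring pair is described by three
quantities:

* **d** = ‖**c**₁ − **c**₂‖, the center–center distance (Å);
* **α**, the planar angle between **n̂**₁ and **n̂**₂, folded to [0°, 90°];
* **θ**, the orientational angle between a ring normal and the
  center–center vector (the minimum over the two rings, folded likewise).

An interaction exists when d ≤ 7.0 Å. The angles classify the
conformation: near-parallel close pairs are **face-to-face** stacking
(optimum near d ≈ 3.75 Å, α ≈ 0°), near-perpendicular pairs are
**edge-to-face** T-shapes (optimum near d ≈ 5 Å, α ≈ 75°), and parallel
offset pairs are **edge-to-edge**.

An *aromatic cluster* is a connected component of the interaction graph
under context-specific edge rules: in protein–drug (PD) complexes,
drug–residue and residue–residue edges detect clusters and only
components containing a drug ring count; in protein–protein (PP)
dimers, only inter-chain residue–residue edges detect clusters, while
intra-chain edges among members still count toward the interaction
total. Three-ring clusters come in two motifs: **Sym** (a triangle,
three interactions) and **Lad** (a path, two).

On top of the clusters the package computes:

* per-residue solvent exposure from Shrake–Rupley SASA in three
  contexts — side chain alone (iSASA), within its own protein (eSASA),
  within the full complex (nSASA):
  `%Exposed = 100·eSASA/iSASA`, `%inContact = 100·(eSASA−nSASA)/eSASA`;
* three-class secondary structure (Helix/Sheet/Loop) with a
  Kabsch–Sander-style hydrogen-bond assignment, plus the interaction
  preference statistic `preference(c, p) = log₁₀(P(p|c)/P(p))`;
* Boltzmann-inverted free-energy maps over (d, α),
  `ΔG = −RT ln(N/N_max)` at 298 K, and radial distribution functions;
* binding-affinity (Ki) stratification by cluster count, interaction
  count, exposure (20% split) and secondary structure, compared with a
  two-sided Mann–Whitney test on log Ki.

## Worked example

Everything is testable without downloading structures: the
`synthetic_fixtures` module writes toy PDB files with exactly
controlled ring geometry.

```python
from aroclust import synthetic_fixtures as sf
from aroclust import (load_complex, detect_rings, find_interactions,
                      enumerate_clusters)

sf.make_dimer(sf.DimerRecipe(d=3.75, alpha=0.0, theta=0.0), out="stack.pdb")
rec = load_complex("stack.pdb")
rings = detect_rings(rec.structure)
inter = find_interactions(rings)[0]
print(f"d={inter.d:.2f} A  alpha={inter.alpha:.1f}  theta={inter.theta:.1f}"
      f"  -> {inter.conformation}")
clusters = enumerate_clusters(rings, [inter], "PD")
print(f"{len(clusters)} cluster of size {clusters[0].size}")
```

prints

```
d=3.75 A  alpha=0.0  theta=0.0  -> face-to-face
1 cluster of size 2
```

— a Phe benzene ring and a benzene ligand stacked at the π-stacking
optimum form one protein–drug cluster with a single face-to-face
interaction. The same pipeline is available from the shell:

```sh
aroclust fixtures dimer --d 5.0 --alpha 75 --theta 10 --out fix/
aroclust detect fix/*.pdb --mode pd --out run/
aroclust stats run/interactions.tsv --out run/
```

`detect` writes per-pair interaction tables and per-cluster tables
(TSV); `stats` adds the distance RDF and the (d, α) ΔG grid.

## Layout

| module | role |
|---|---|
| `structure_io` | PDB/mmCIF reading, altLoc resolution, dataset filters (resolution ≤ 2.5 Å, drug-likeness) |
| `ring_detection` | template rings for Phe/Tyr/Trp/His, graph-perceived ligand rings, plane fitting |
| `interaction_geometry` | (d, α, θ) descriptors, 7 Å detection, conformation classes |
| `cluster_analysis` | connected-component clusters, PD/PP/intra edge rules, trimer motifs, summaries |
| `surface_exposure` | Shrake–Rupley SASA, %Exposed / %inContact |
| `secondary_structure` | Helix/Sheet/Loop assignment (internal, DSSP file, header), preference log-odds |
| `ensemble_stats` | RDF, Boltzmann ΔG maps, Ki ingestion and strata |
| `synthetic_fixtures` | toy PDB generators with exact ring geometry; ideal helix/sheet backbones |
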