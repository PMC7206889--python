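# Methods

This note documents the procedures implemented in `aroclust`, their
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Ring detection and plane fitting

Protein rings are template-based: Phe and Tyr contribute one benzene
ring (CG, CD1, CD2, CE1, CE2, CZ), His one imidazole (CG, ND1, CD2,
CE1, NE2), and Trp an indole counted as two rings — a pyrrole (CG, CD1,
NE1, CE2, CD2) and a benzene (CD2, CE2, CZ2, CH2, CZ3, CE3) — sharing
the CD2–CE2 bond. A residue missing any template atom contributes no
ring for that template (logged), rather than a ring with a biased
centroid.

Ligand rings are perceived from the bond graph (CONECT records when
present, otherwise distance-based inference with covalent radii +
0.40 Å slack). Candidates are the minimum cycle basis of the heavy-atom
graph; a cycle is accepted as aromatic when it has 5–6 atoms, all in
{C, N, O, S}, each with at most three heavy-atom neighbors, and its
best-fit plane has ≤ 0.10 Å rms out-of-plane deviation. This planarity
+ connectivity proxy replaces electronic-structure aromaticity
perception: it is deterministic, testable, and agrees with a
cheminformatics toolkit on the common aromatic fragments covered in the
test suite (benzene, pyridine, imidazole, indole, naphthalene, furan,
thiophene, pyrimidine, pyrrole, phenol). Exotic heterocycles can
diverge; an override file (comp_id → ring atom names) injects
externally perceived rings bit-exactly. Sp3 rings are rejected by
planarity (an ideal cyclohexane chair deviates by 0.25 Å rms).

Plane fitting is least squares: centroid plus the smallest principal
direction of the centered coordinates. The normal sign is canonicalized
(z ≥ 0, then y, then x) so downstream angles — which are all folded to
[0°, 90°] because rings are two-sided — are deterministic. Hydrogens
are ignored throughout; crystal structures rarely record them.

## Interaction descriptors and conformation classes

For a ring pair: d is the centroid distance; α the angle between
normals folded to [0°, 90°]; θ the angle between a normal and the
center–center vector, folded likewise. Since nothing privileges one
ring, θ is reported as the minimum over the two rings (both per-ring
values are retained in the interaction record), which makes all three
descriptors symmetric under argument exchange and invariant under
rigid-body transforms (verified to 1e-9).

Detection is distance-only: d ≤ 7.0 Å (configurable `cutoff_d`), with
two exclusions — rings sharing an atom (fused systems are one chemical
entity) and rings of the same residue. Angles are descriptive, not
detection criteria.

Conformation boundaries are not canonical in the literature, so they
are configuration-exposed with defaults chosen to put the two density
optima safely inside their classes: α ≤ 30° is "parallel" (face-to-face
when θ ≤ 45°, else edge-to-edge), α ≥ 60° is edge-to-face (the T-shape;
the observed optimum sits near α ≈ 75°), the 30–60° band is oblique.

Candidate pairs are pruned with a KD-tree at the cutoff radius; the
result is identical to the all-pairs scan (tested).

## Cluster enumeration

Clusters are connected components of the interaction graph under
context-specific *detection* edges:

* **PD** — drug–residue plus all residue–residue edges; only components
  containing at least one drug ring are clusters. Residue–residue edges
  may chain residues not directly touching the drug into the cluster.
* **PP** — inter-chain residue–residue edges only.
* **intra** — intra-chain residue–residue edges only.

Interaction counts use a wider *counting* edge set: for PP, intra-chain
edges among member rings are added to the detection edges; for PD, all
drug–residue and residue–residue edges among members count. Singleton
rings are not clusters. A three-ring cluster with three counting edges
is Symmetric (Sym); with two it is a Ladder (Lad); these are the only
connected 3-node graphs, so the classification is total.

Dataset summaries define the averages as exact ratios of the count
fields, with "clusters per complex" divided by the number of complexes
*with at least one cluster* — the only reading under which the
published table's averages equal its totals' ratios (e.g. 7236 clusters
over 5908 cluster-bearing complexes → 1.22). Residue composition counts
each interacting aromatic residue once per cluster membership (a Trp's
two rings are one residue instance; a per-ring convention is available
by configuration). His is included everywhere; a flag excludes it for
comparison with three-residue intraprotein conventions.

## Solvent accessibility

SASA uses the Shrake–Rupley numerical method rather than a
Connolly-surface construction: each heavy atom's van der Waals sphere
(C 1.70, N 1.55, O 1.52, S 1.80 Å) is inflated by the probe radius
(1.4 Å, water-sized) and sampled with a deterministic Fibonacci lattice
(960 points by default; no RNG, so results are bit-reproducible). A
point is accessible when outside every neighbor's inflated sphere. The
implementation is validated against closed forms (isolated sphere
exact; two-sphere spherical-cap within 2% at 960 points), is monotone
under added neighbors, and agrees with an independent Shrake–Rupley
implementation within 5% per residue. Algorithmic divergence from
Connolly-based surface areas is expected at a few percent and is the
main caveat when comparing absolute exposure values to Connolly-derived
numbers.

The per-residue ratios use the side chain (CB and beyond; CB membership
configurable) in three contexts: alone (iSASA), with the residue's own
protein monomer (eSASA — all polymer chains of its binding side, hetero
atoms excluded), and in the full complex including partner chains and
ligands (nSASA). `%Exposed = 100·eSASA/iSASA` and
`%inContact = 100·(eSASA−nSASA)/eSASA`; the latter is undefined (and
reported missing) for a fully buried side chain. Glycine has no side
chain and is skipped. Excluding ligands and waters from eSASA isolates
partner-induced burial in the numerator of %inContact; whether the
reference analysis did the same is unknown, which is a divergence risk
for absolute %inContact values.

## Secondary structure

Three provenances: a classic DSSP output file (8→3 mapping: H, G, I →
Helix; E, B → Sheet; rest → Loop, exact by construction), coordinate
file HELIX/SHEET records, or an internal assignment. The internal mode
is a Kabsch–Sander-style approximation: the amide H is placed 1.0 Å
from N opposite the preceding carbonyl, hydrogen bonds are scored with
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol and accepted
below −0.5 kcal/mol; two consecutive n→n+4 turns make a minimal helix,
and parallel/antiparallel bridge patterns (possibly across chains) make
sheets, with helix taking precedence. It is deliberately not a full
8-state re-implementation (no π/3₁₀ distinction beyond the collapse, no
bend/chirality states); on ideal fixtures it agrees with an independent
DSSP implementation at 100%, and the test suite enforces ≥ 85%.

The preference statistic is `log(P(partner|context)/P(partner))` in
base 10 (base-e available). The background is estimated from the
interacting residues of the dataset under analysis by default (a pooled
background is a one-line switch); zero cells receive a +0.5 Jeffreys
adjustment (logged) so log-odds stay finite without distorting large
counts; an empty context row is reported missing rather than smoothed.

## Ensemble statistics

The RDF is a histogram of ring-center distances (default 0.1 Å bins to
7 Å). Frequency normalization (bins sum to 1) is the default so curves
from datasets of different size are comparable; spherical-shell
normalization (dividing by 4πr²Δr) is available and is flat for
uniform-in-volume points (tested by Monte Carlo).

The (d, α) free-energy map is a Boltzmann inversion of the 2-D
histogram (default 0.25 Å × 5° bins): ΔG = −RT·ln(N/N_max) at T = 298 K
with R = 1.987×10⁻³ kcal/(mol·K). The most populated bin is the zero
reference — the maps are relative surfaces with no absolute anchor —
and empty bins are masked rather than assigned infinite energy. The map
depends only on count ratios, hence is invariant under duplication of
the sample set.

Affinity analysis ingests BindingDB-style tables (id + Ki, units by
column or in-cell, nM/µM/M → molar; duplicates resolved by geometric
mean). Records are grouped by cluster count {1, 2} × interaction bins
{2–3, 4–5, ≥6} — the upper bin is a configurable reading of an
ambiguous "5 or more" alongside "4 or 5" — and separately by
contact-residue exposure (strictly greater than 20% vs at most 20%) and
secondary-structure class. Complexes with more than two clusters are
reported but excluded from the 1-vs-2 comparison. Group differences use
a two-sided Mann–Whitney rank-sum test on log Ki; the source analyses
report significance without naming a test, and the rank-sum choice is
robust to the heavy right tail of Ki distributions. Medians and
geometric means are reported per group; median ordering is invariant to
log-scaling.

## Synthetic fixtures

The generators exist so that every stage runs on files whose ground
truth is known exactly:

* `make_dimer(d, α, θ)` places a Phe ring at the origin and a benzene
  ligand such that the measured descriptors equal the request exactly
  (to PDB fixed-width precision, ~1e-3 Å); the construction is solvable
  for every (α, θ) in [0°, 90°]² by choosing the azimuth of the second
  normal. Defaults and test anchors use the two observed optima:
  stacking (3.75 Å, 0°) and T-shape (5 Å, 75°).
* `make_trimer` builds Sym (equilateral, 5 Å sides) and Lad (collinear,
  5 Å spacing, ends 10 Å apart — beyond the cutoff) motifs; pulling the
  ladder ends inside 7 Å flips the classification, which the tests use
  as a sensitivity check.
* `make_complex_fixture` assembles PD (chain + ligand) and PP
  (two-chain) toys from ring placements, with locally ideal Phe
  backbones and a ≥ 1.5 Å inter-residue clash guard.
* `build_backbone` constructs poly-Ala backbones from (φ, ψ) with ideal
  bond lengths/angles (natural-extension reference frame). The helix
  fixture is (−57°, −47°); the two-strand antiparallel fixture is
  (−139°, 135°) with the partner strand generated by point inversion
  through a calibrated center — inversion reverses the chain direction
  and cancels the strand twist so amide H-bonds form along the whole
  ribbon; the partner is therefore a mirror-image backbone, immaterial
  for a backbone-only fixture but not a model of L-peptide geometry.
* `sample_ensemble` draws (d, α) from a seeded Gaussian mixture. The
  default mixture — 60% T-shape at (5.0 Å, 75°) with spreads (0.3 Å,
  8°), 40% stacking at (3.75 Å, 0°) with (0.15 Å, 8°), α folded into
  [0°, 90°] — emulates the two-mode geometry distribution observed in
  complexes, with the stacking mode deliberately prominent as in
  protein–drug data.

What the fixtures do *not* emulate: real packing density, rotamer
statistics, crystallographic noise, heteroatom diversity, or realistic
protein folds. Passing tests demonstrate the correctness of the
geometry, graph and statistics code on controlled inputs, not the
field-accuracy of, say, ring perception on arbitrary PDB ligands.

## Problem sizes and numerical choices

Test and acceptance runs use 100-dimer round trips, 200 random graphs
(≤ 50 rings) against the union-find oracle, 5×10⁴-sample ensembles and
8–12-residue backbone fixtures; these sizes give stable statistics for
every check while keeping the suite fast. Degenerate inputs fail
loudly: collinear points in plane fits, coincident ring centers,
coincident atoms in SASA, unknown elements, unknown cluster modes.
Ties in altLoc occupancy resolve to the lexicographically smallest
identifier; missing occupancy is 1.0; missing resolution drops a
complex from filtered datasets (logged). Multi-model files use the
first model by default (logged), matching common practice for NMR
entries.
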