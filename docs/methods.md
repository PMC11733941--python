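# Methods

## Model

A backbone conformation is modelled as an embedding of the vertex order ρ
in 3-D space. The order begins (N¹, Hα¹, C¹, Cα¹) and continues per
residue i ≥ 2 with (Hⁱ, Nⁱ, Cαⁱ, Hαⁱ, Cⁱ), repeating Cαⁱ directly after
Cⁱ for intermediary residues; every vertex t ≥ 4 references its three
immediate predecessors (t−1, t−2, t−3). Two hypotheses make the search
space a binary tree: the first three vertices form a clique (H1), and
each later vertex has known distances to its three references (H2). Each
placement is then a three-sphere intersection: at most two points, mirror
images through the reference plane, recorded as an orientation bit (the
sign of the signed volume det[x_{t−1}−p, x_{t−2}−p, x_{t−3}−p] evaluated
with the references in order t−1, t−2, t−3; on-plane points take bit 0).

Distances come from rigid geometry: bonded and two-bond (1–3) pairs from
bond lengths and angles, peptide-plane 1–4 pairs from the ω torsion, and
two genuinely conformational pairs per residue — Hα(i−1)···H(i) spanning
ψ(i−1) and H(i)···Hα(i) spanning φ(i) — which in experiments are
NMR-detectable contacts. Pruning edges fall into three families:
Hα–Hα of consecutive residues (label `HA-7-HA`, window length 4),
Hα–H two residues apart (`HA-10-H`, length 7, containing the repeated
Cα), and C–Cα across the peptide bond (`C-5-CA`, length 2).

Vertex 4 never has a fourth neighbour, so solutions come in mirror pairs
related by total bit inversion from position 4 on; strings are normalized
to b₄ = 0. Repeated vertices and degenerate (single-intersection)
placements carry a fixed bit 0 and are exempt from all flips — on exactly
planar synthetic data the peptide N and Cα are degenerate, a case
experimental coordinates never produce; the exemption makes
encode/decode round trips exact in both regimes.

## Solver

Pruning edges are sorted (ascending j, then i) and grouped into
components connected by shared relevant bits. The first edge of a
component is searched exhaustively over its free window bits; each later
edge is searched over its not-yet-assigned free bits under the current
assignment. If that fails, the solver enumerates partial reflections:
flipping the component's assignment from any position p that no earlier
window straddles preserves every solved edge (each earlier window is
flipped in full or not at all), and XOR-compositions of such flips cover
exactly the reachable symmetry classes. A failure under every composition
is reported as infeasibility naming the edge.

Search-node accounting follows two deliberately different conventions.
The frequency-based search charges every tested root-leaf path in full:
a sequence accepted at rank k among tested candidates costs k·n nodes,
n being the full window length. Left-first DFS counts unique expanded
nodes in a tree with one shared root plus one level per free (branching)
bit; shared prefixes count once, and forced bits contribute to n but not
to branching. On the height-four worked tree (8 paths of 4 nodes,
solution the 7th leaf, ranked 3rd by frequency) these give 14 and 12
nodes respectively.

FBS candidates come from a per-edge-type table ranked by descending
count with lexicographic tie-breaks; candidates conflicting with pinned
bits are skipped uncharged, and unseen sequences are appended in
left-first order, so the search is complete even with an empty table.
The brute-force branch-and-prune enumerator (`bp_reference`, capped at
22 free bits) prunes each edge at its endpoint depth and serves as the
independent oracle for the build-up solver.

## Sequence-space accounting

For window length L the package reports k_max = 2^(L−1) possible
sequences ("one non-free bit per independent-edge sequence") alongside
the raw 2^L. Two mechanisms justify the halving and give the same number
in every analysed family: feasible sequences come in complete-flip pairs,
and the `HA-10-H` window contains one fixed repeated-Cα bit. The package
does not commit to one mechanism; both counts are exposed.

## Synthetic data

`sample_conformation` realizes ρ vertex by vertex through trilateration,
drawing a free bit wherever two intersection points exist. The sphere
radii are implied by the geometry parameters: bonds N–Cα 1.458, Cα–C
1.525, C–N 1.329, N–H 1.01, Cα–Hα 1.09 Å; angles N–Cα–C 111.0°, Cα–C–N
117.2°, C–N–Cα 121.7°, C–N–H 119.0°, H–N–Cα 119.3°, N–Cα–Hα 108.5°,
Hα–Cα–C 109.4° (standard backbone stereochemistry; all configurable).
The two conformational torsion magnitudes per residue are drawn uniform
in [20°, 160°], keeping placements away from degeneracy, and ω = 180°
with optional Gaussian jitter (default σ = 5° in instance-generation
pipelines, matching the scale of peptide non-planarity in experimental
structures; 0 for exact-plane tests).

Because every radius derives from one coherent parameter set, generation
cannot dead-end, and instances built by measuring all H1/H2 and policy
distances from the sampled conformation are solvable by construction
(planted-solution property).

Two numerical floors are part of the study conditions. The
discriminant clip of the trilateration (10⁻⁵ Å, squared 10⁻¹⁰) sits
between the squared coordinate error accumulated along an exactly planar
chain (~10⁻¹⁶) and the squared out-of-plane offsets of jittered peptides
(~10⁻²), so degenerate placements are classified identically during
generation, encoding and solving. The ω jitter is redrawn until at least
1° from planarity: the separation between the two flip classes of a
C–Cα pruning edge grows only quadratically in the peptide deviation
(≈1.2·10⁻⁴ Å per deg²), and a draw too close to 180° would make that
family undecidable at the 10⁻⁶ Å feasibility tolerance.

What the generator does not emulate: side chains and their sterics,
Ramachandran correlations between φ and ψ, chirality preferences
(both Cα mirror branches are sampled), interval (lower ≠ upper)
restraints, and coordinate noise. Passing tests therefore demonstrate
correctness of the combinatorial machinery on idealized geometry, not
performance on experimental restraint data.

## Benchmark conditions

The DFS/FBS comparison needs a regime where frequency guidance can act.
Two facts shape it. First, tables are trained on the *first solutions* a
left-first search reports — the member of each feasible flip pair whose
first free bit is 0 — so an i.i.d. per-bit bias does not survive
training; the empirical law must live at the sequence level, as backbone
regularities (helices, sheets) do in real data. Second, under the dense
default policy at desk scale every edge couples into one component whose
first-searched window is the 2-bit C–Cα family, leaving nothing for a
frequency ordering to reorder — consistent with frequency guidance
paying off on the long Hα–H windows and not on C–Cα.

The benchmark therefore plants a two-motif sequence law (weights
0.5/0.2, the rest uniform) on the free window of the Hα–H family. Motifs
are drawn per run-seed among canonical sequences outside the leftmost
quarter of the leaf order: a law concentrated exactly where DFS looks
first is the regime where both searches coincide and the comparison is
uninformative. Instances are split 80/20, the table trained on the
training share, and each test instance solved with both strategies; the
primary metric is visited nodes (hardware-independent), with wall times
recorded as a secondary column. Default scale: 3-residue instances,
200-instance runs (1,000 for a 200-instance test share); win fractions
observed across seeds fall in 0.68–0.82.

## Problem sizes and tolerances

Library defaults: solver feasibility tolerance 10⁻⁶ Å; on-plane
orientation tolerance 10⁻⁷ (signed-volume units) for synthetic data,
10⁻³ recommended for parsed PDB coordinates (the CLI `encode` default).
Tests run at n = 2–6 residues; the oracle cross-checks use 200 planted
instances at n = 3–5, round trips 1,000 sampled conformations, and
exhaustive flip-symmetry checks cover all single-family policies at
n = 3 (windows of at most 10 free bits). The branch-and-prune oracle
refuses instances with more than 22 free bits.

## Known limitations

Coupled-edge reuse enumerates reflection compositions rather than
implementing the reference build-up's internal edge-ordering heuristics;
edge processing order is fixed (ascending j, then i). Interval distances
and Pro/Gly geometry are out of scope. mmCIF input is not parsed. The
PDB-scale empirical claims (corpus-wide win rates, observed sequence
counts) require the full NMR corpus and are outside the package's
desk-scale tests.
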