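# Methods

## The topology model

A protein chain's secondary structure elements (SSEs) are observed twice:
as ordered *segments* on the sequence (`SQ_1 … SQ_M`, each helix `H` or
strand `E`) and as unordered *sticks* in a cryo-EM volume
(`D_1 … D_N`, line segments in Å, helices numbered before strands).  A
topology assigns each stick to a segment of the same type with a
traversal direction; segments may be left unassigned when `M > N`
(slack `Δ = M − N + 1`).  The assignment is modelled as a layered
directed graph over nodes `(i, j, t)` with special START/END nodes whose
edges carry weight 0.  Direction semantics: `t = 0` traverses a stick
p0→p1, so the exit endpoint of `(j, t)` is `p1` for `t = 0` and `p0` for
`t = 1`, and the entry endpoint of the next stick is the opposite label.
The graph is direction-aware throughout (the two directions are distinct
nodes, so distances, traces, geometry and energies all depend on `t`).

An edge between consecutive assignments exists only if the loop can
physically reach: `vLength ≤ sLength`, where `sLength = (L + 1) × 3.8 Å`
for `L` loop residues (3.8 Å is the Cα–Cα step; residues of skipped
segments count toward `L`, computed from sequential chain positions, not
author numbering gaps) and `vLength` is the Euclidean exit-to-entry
endpoint distance.  The base edge weight is the slack
`W_Eucl = sLength − vLength ≥ 0`.

## Solver

The search runs on the expanded state DAG `(i, j, t, used-column
bitmask)`, in which every START→END path is valid by construction.  The
single best path is a dynamic program in `O(Δ²N²2^N)`; the best-K list
keeps the K cheapest partial paths per state and merges them in
topological (bitmask-popcount) order.  This is equivalent to deviation
(Yen-style) K-shortest-path search on the same DAG but needs no
nonnegativity assumption — combined schemes produce negative edge
weights.  The bitmask caps N at 24 sticks, above any problem this method
targets.  Equal-cost topologies are ordered lexicographically by their
`(i, j, t)` triples, which makes ranks deterministic; any other
implementation of the same scores could order exact ties differently.
A brute-force DFS enumerator (`enumerate_all`) serves as the oracle in
tests and refuses inputs above a combinatorial cap (10⁶ topologies).

## Skeleton scoring

The skeleton (produced externally, read as an MRC map and binarized at
density > 0) is reduced to a graph:

1. **SSE removal** — foreground voxels within 2.5 Å of any stick axis are
   cleared, keeping loop regions only.  The radius is a package default;
   it should be of the order of the skeleton's tube radius.
2. **Clustering** — greedy: seed at a random unassigned foreground voxel,
   repeatedly absorb the nearest unassigned voxel within 2.0 Å of the
   running centroid, recompute the centroid after every addition.  The
   seed order comes from a required, logged RNG seed; the partition
   property holds for any seed, and cluster counts vary only within a
   narrow band.
3. **Linking** — clusters whose voxel sets approach within 3.0 Å become
   adjacent; edge weight = centroid–centroid distance.
4. **Clique merging** — maximal cliques of size ≥ 3 (Bron–Kerbosch via
   networkx) are processed in decreasing size; nodes already absorbed are
   excluded from later cliques, and a clique left with fewer than 3 fresh
   nodes is skipped.  A merged node sits at the geometric center of all
   member voxels.
5. **Gap bridging** — end nodes at most 10 Å apart are connected.  An
   *end node* is one with ≤ 1 neighbor, or one whose two neighbors lie on
   the same side of it (on reduced cluster chains the terminal cluster is
   often chord-linked to its next-nearest neighbor, so a literal degree-1
   rule misses real trace ends); isolated fragment remnants also count.
6. **Anchoring** — each stick endpoint is anchored to its nearest node,
   and the endpoint-to-anchor distance (*stub*) is recorded.

`W_trace` for an edge enumerates simple anchor-to-anchor paths by bounded
DFS (cost cap `sLength + 20 Å`, at most 60 nodes — both configurable;
they prevent path explosion on noisy skeletons) and returns the best
`|path length − sLength|`.  A trace conceptually runs stick endpoint →
anchor → … → anchor → stick endpoint, so both stubs count toward its
length; an endpoint with a stub above 7 Å is treated as unreached by the
skeleton and the trace is ∞.  Without the stub term and gate,
wrong-direction edges that exit through a stick's far end would inherit
the same anchors (hence the same trace) as the true direction.  The final
skeleton weight is `W_sk = min(W_Eucl + e, W_trace)` with no-trace
penalty `e = 15 Å` by default — of the order of one loop span, so a
missing trace is worse than any decent trace but not prohibitive.

## Geometry scoring

For a consecutive SSE pair, `V1` and `V3` run along the SSEs and `V2`
joins the end of the first to the start of the second.  From atomic
structures, helix ends are the backbone (N, Cα, C) centroids of the first
and last residue and strand ends are Cα atoms; pairs with missing atoms
are skipped.  On graph edges, where no backbone exists yet, the vectors
come from stick endpoints with `V2` joining the direction-aware
exit/entry points.  The dihedral `φ` is the signed angle between the
projections of `V1` and `V3` onto the plane perpendicular to `V2`,
right-handed about `V2`, canonicalised to (−180°, 180°] (−180° → +180°);
`η = ∠(V1,V2) + ∠(V2,V3) ∈ [0°, 360°]`.  Degenerate configurations (zero
loop vector, SSE parallel to the loop) carry no information and score
`f = 0` on edges.

The score is `f(φ,η) = A·exp(−½ (x−Λ)ᵀ Σ⁻¹ (x−Λ))` with
`Λ = (−4.501, 203.207)°` and `Σ = diag(5581.972, 2103.773) deg²` — the
independence of φ and η is an assumption of the fitted model, so
refitting (`fit_params`) zeroes the off-diagonal covariance.  `A`
defaults to 1, making `f` dimensionless in (0, 1]; combined schemes
subtract `f` from Å-valued skeleton weights, a deliberate unit mismatch
inherited from the scheme definitions (`A` is configurable to rebalance).
When geometry stands alone the weight is `A − f`, since minimising `f`
itself would favour implausible packings.

## Energy scoring

Each node gets an ideal-geometry model: helices as a 1.5 Å-rise,
100°-twist, 2.3 Å-radius Cα spiral; strands as a 3.3 Å-rise zigzag whose
pleat amplitude (±0.94 Å) is solved so consecutive Cα atoms sit 3.8 Å
apart.  The trace is rigidly placed on the stick axis in the node's
direction, with axial scaling clamped to ±20% (logged).  A side-chain
center sits along the local outward normal at a per-residue-type distance
(1.5 Å for Ala … 4.1 Å for Arg; 0 for Gly) — a centroid approximation
replacing rotamer packing, which changes absolute energies but not the
module's contracts.  Two residues are in contact when their side-chain
centers are within a type-dependent cutoff (default 6.5 Å for all pairs);
each contact contributes `(3.5/r)¹² − Σ_k d_k exp(−(r−r_k)²/2σ_k²)` with
one default well (r = 5.5 Å, depth 1, width 1).  `W_e` sums inter-model
contacts plus intra-model contacts of **both** models (sequence-adjacent
pairs excluded from the intra term); with no inter-model contact the edge
weight falls back to a constant `e` (default 0, neutral).  Cutoffs, wells
and radii are pluggable configuration: the energy module is a faithful
skeleton of the procedure with physically plausible defaults, not a
reproduction of any published parameter set, and no attempt is made to
tune it (the energy scheme is the weakest performer by design of the
benchmark).

## Synthetic fixtures

`make_bundle` builds the study conditions for all tests: SSE axes stand
in a row in the xz-plane (12 Å spacing, alternating up/down, the geometry
of an antiparallel bundle), helices of 14–20 residues and strands of
8–12, loop residue counts drawn from 4–10 but never below what the placed
gap requires and at most 3 residues of slack.  Loops are routed 3.5 Å
axially past the SSE tips (as real chains continue past a helix end
before turning) and bow out of the bundle plane until their arc length
equals `(L + 1) × 3.8 Å`, so a clean skeleton trace matches its loop span
almost exactly.  Loop lengths are kept pairwise ≥ 2 residues apart so no
trace can masquerade as a neighbouring pair's loop.  Stick endpoint
labels are flipped at random and recorded in the ground truth, so
direction recovery is genuinely exercised.  SSE lengths and spacing are
chosen so the 10 Å bridge rule cannot alias loops at opposite stick ends.

Skeletons are rasterized from the loop curves onto a 1 Å grid;
`corrupt_skeleton` injects reproducible gaps (clearing a ball around a
random trace voxel; the radius is `gap_len/2 − 1 Å` to compensate the
~1 Å centroid inset at each cut end, so the node-level gap matches the
nominal length) and random short spurs.  In the bridging experiment the
gap centers avoid stick endpoints: a gap that detaches a trace from its
stick tests anchor loss, not bridging.

What passing these tests shows: the graph construction, scoring and
solver are exact (oracle-checked), and the skeleton machinery recovers
planted topologies through the full I/O round trip under clean and
moderately gapped conditions.  What it does not show: performance on real
maps — the generator has straight SSE axes, single-voxel-wide noiseless
traces, no β-sheet lateral packing, no spur forests near sheets, and no
density-threshold artefacts.  A two-SSE bundle is excluded from the
end-to-end experiments because its reversed topology traces the same loop
backward and ties the truth exactly under skeleton scoring — an inherent
ambiguity of the method, not an implementation artefact.

## Problem sizes and determinism

End-to-end experiments use 100 bundles of 3–5 sticks (the regime where
exhaustive verification stays cheap); solver oracle checks use 200 random
problems with N ≤ 5; parameter recovery uses 50,000 draws.  All
randomness flows from explicit integer seeds (one per bundle/experiment),
and identical configurations produce byte-identical outputs.  Score
comparisons in tests use 10⁻⁹ absolute tolerance; ties are exact float
equality, resolved by the lexicographic rule above.

## Known limitations

* Sticks of more than 24 columns exceed the bitmask state (documented
  solver error); K-best memory grows with K·2^N and is intended for
  desk-scale N.
* The bespoke stick/segment TSVs are the only interchange formats; there
  is no community standard for detected SSE sticks.
* Mixed units across schemes (Å, probability, energy) are combined
  unnormalised; per-component scales are exposed in configuration but
  default to 1.
* `mark_endpoints` anchors to the nearest node with no tie handling
  beyond array order; exact ties are resolved by node index.
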