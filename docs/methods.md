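# Methods

This note records the exact conventions, parameter defaults and design
decisions behind `csncrit`, in enough detail to reimplement every number the
package produces.

## Molecule curation (`csncrit.mol_io`)

- SMILES are canonicalised with RDKit: keep the largest covalent fragment
  (salts and solvents dropped), strip stereochemistry, emit non-isomeric
  canonical SMILES. Canonicalisation is idempotent.
- Merging multiple sources deduplicates on the canonical SMILES. First-seen
  records win for identifier and source; a labelled record always beats an
  unlabelled duplicate. Duplicates with *opposite* labels are removed
  entirely and reported in a `ConflictReport` — a molecule with contradictory
  toxicity calls is evidence of a data problem, not a vote to average.
- Labels normalise to `toxic` / `nontoxic` (accepting `1`/`0`,
  `positive`/`negative`, `non-toxic`, case-insensitive); anything else is an
  error, not a guess.

## MCS Tanimoto similarity (`csncrit.mcs`)

- The similarity between molecules A and B is
  `T = m / (n_A + n_B − m)` where `m` is the heavy-atom count of the
  **maximum common connected induced subgraph** and `n_A`, `n_B` are the
  molecules' heavy-atom counts. Hydrogens are ignored throughout.
- Atom compatibility is element-exact (with aromaticity carried as an atom
  flag); bond compatibility is order-exact with *aromatic as its own order*,
  so a benzene edge never matches a Kekulé single or double bond. Under
  these rules benzene–cyclohexane have MCS 1, benzene–toluene have MCS 6.
- The *induced* convention means every bond of the parent graphs between two
  mapped atoms must be present and matching in the mapping. It guarantees
  the clean special case: if A is an induced, bond-compatible connected
  subgraph of B then `T = n_A / n_B`.
- The search is an exact branch-and-bound over atom mappings
  (McGregor-style): per-atom candidate bitmasks filtered incrementally,
  fail-first pivot selection, a connectivity-reachability upper bound, and
  seed canonicalisation to kill orbit symmetry. It is exact — verified
  against brute-force subgraph enumeration via isomorphism testing — and
  bounded: a node-expansion cap (default 2,000,000) raises
  `McsTimeoutError`; the engine never silently returns an approximation.
- Pairwise computation stores only pairs with similarity strictly above a
  **floor** (default 0.3) in a sparse `SimilarityStore`. The floor also
  prunes the search: a pair can be abandoned as soon as the best achievable
  common-subgraph size provably cannot exceed
  `floor · (n_A + n_B) / (1 + floor)` atoms.

## Threshold networks and null model (`csncrit.network`)

- A network at cut-off `t` has an edge for every stored pair with `s > t`
  (strictly greater). Cut-offs below the floor are rejected — the store
  does not contain the information to build them.
- Edge density is `p = E / E_max`, `E_max = N(N−1)/2`.
- The null model is **uniform `G(N, E)`** — same node count, exactly the
  same edge count as the CSN at each cut-off — so mean degree matches
  exactly by construction (asserted in tests), not just in expectation.
- Centralities: degree; betweenness (Brandes, unnormalised); eigenvector
  centrality by power iteration (tolerance 1e-10, max 10,000 iterations) on
  the **largest connected component**, zero elsewhere, L2-normalised. The
  largest-component convention is needed because the dominant eigenvector of
  a fragmented graph is not unique.
- Degree assortativity is the Pearson correlation of degrees across edge
  endpoints (both orientations). When it is undefined — no edges, or zero
  degree variance at the endpoints — the result is `None`, never a
  fabricated 0.

## Criticality sweep (`csncrit.sweep`)

- Cut-offs run from the floor to 1.0 (default step 0.01). At each cut-off
  the CSN summary statistics (edges, density, mean degree/betweenness/
  eigenvector centrality, giant-component fraction, assortativity) are
  compared against `n_er = 20` independent `G(N, E)` replicates (mean and
  standard deviation). Replicate seeding fans out from one root seed via
  `numpy.random.SeedSequence`, so sweeps are reproducible.
- Curves are min-max scaled to [0, 1] for comparison plots (constant curves
  scale to zeros; undefined values propagate as NaN).
- Critical-point criteria:
  - `betweenness_peak` — cut-off maximising mean betweenness;
  - `assortativity_peak` — cut-off maximising assortativity;
  - `giant_onset` — the largest cut-off at which the giant-component
    fraction still exceeds 0.05.
  Ties break toward the larger cut-off. A flat curve raises
  `NoTransitionError` rather than reporting an arbitrary point.
- Calibration: in uniform random graphs the percolation transition sits at
  mean degree ≈ 1, i.e. density `p ≈ 1/N`. For `N = 684`, a sweep of
  `G(N, E)` over `p ∈ [10⁻⁴, 10⁻²]` (20 replicates/point) puts both the
  giant-component onset and the betweenness peak within half a decade of
  `1/N = 10⁻³`; the giant-component fraction at mean degree 2 matches the
  fixed point of `S = 1 − e^(−2S)` (≈ 0.797). Both are asserted in the
  acceptance tests.

## Communities and descriptor screen (`csncrit.communities`)

- Louvain partitions (NetworkX implementation, resolution 1, seeded).
  Modularity is cross-checked against the direct formula
  `Q = Σ_c (e_c/E − (d_c/2E)²)` to machine precision. An edgeless graph
  yields singleton communities with `Q = 0`.
- Descriptors come from RDKit's 2D descriptor set; the screen itself accepts
  any numeric table. A variability filter drops descriptors whose modal
  value covers more than 90% of molecules (strictly: variability below 10%).
- **Mood's median test**, implemented from the contingency-table definition:
  pool the groups, take the grand median, count per group above vs not-above
  (ties count as *not above*), chi-square with `k − 1` degrees of freedom,
  no continuity correction. `scipy.stats.median_test(ties="below",
  correction=False)` is used in tests as an independent cross-check, not as
  the implementation. Degenerate tables (an empty row) are an error.
- The screen compares the top 3 communities pairwise (3 tests per
  descriptor) and Bonferroni-corrects over *all* tests performed:
  `m = n_descriptors × 3`. A descriptor is flagged only if **all** its
  pairwise p-values fall below `α/m` (default `α = 0.01`). Community
  medians and IQRs are reported alongside. With 200 null descriptors the
  screen flags ≤ 1% (asserted).

## Toxicity classifier (`csncrit.classify`)

- Score of a test molecule = similarity-weighted mean of its labelled
  training neighbours' labels (toxic = 1) in the cut-off network;
  `score ≥ 0.5` predicts toxic (ties resolve to toxic, the conservative
  choice for a toxicity screen). With equal weights this reduces exactly to
  majority vote (property-tested).
- Molecules with no labelled neighbour are *unclassifiable*; they are
  imputed with the training-majority label and counted, never silently
  dropped — dropping them would inflate accuracy on exactly the molecules
  the network cannot see.
- Evaluation: stratified hold-out (default 80% held out, mirroring a
  small-training-set regime), 100 iterations, per-iteration seeds fanned out
  from one root seed. Metrics (accuracy, sensitivity, specificity, F1) are
  averaged over iterations where they are defined; undefined values
  (zero-denominator) are skipped, not zero-filled.

## Synthetic fixtures (`csncrit.synth`)

- `generate_scaffold_families` decorates a scaffold with 1–3 substituents
  (`C`, `CC`, `O`, `N`, `F`, `Cl`, `CO`) at random open valences, keeping
  only distinct, sanitisable molecules. The `three_archetypes_preset` uses
  naphthalene (aromatic, "toxic"), decalin (fused aliphatic rings, "toxic")
  and diethylene-glycol-like ethers ("non-toxic"). Aromatic vs aliphatic
  bond orders keep cross-family MCS small, so the preset has a genuine
  similarity gap between families — which is what makes it a fixture: the
  community, criticality and classification machinery must find structure
  that is known to be there. It emulates family/gap structure only; it does
  not emulate realistic toxicity mechanisms, descriptor distributions, or
  the size of real screening sets.
- `generate_planted_store` builds abstract block similarity stores (uniform
  within-family and between-family similarity ranges, the within range
  strictly above the between range) for tests that need exact control of
  the gap without chemistry.
- A caveat found during development and honoured by the tests: on a uniform
  block store, any cut-off strictly inside the gap makes each family a
  complete disconnected clique — betweenness is exactly 0 and assortativity
  undefined there. Criticality signatures on planted fixtures are therefore
  asserted over the *transition band* (between the typical cross-family and
  within-family similarities), and the assortativity-elevation signature is
  demonstrated on a latent-geometry store (1D positions,
  `s = max(0, 1 − 2|x_i − x_j|)`), whose transitive similarity is the actual
  mechanism that distinguishes CSNs from uniform random graphs.

## Pipeline (`csncrit.pipeline`, `csn` CLI)

- `RunConfig` (YAML-serialisable) fixes all knobs: floor 0.3, grid
  0.3→1.0 step 0.01, 20 ER replicates, 80% hold-out × 100 iterations,
  `α = 0.01`, top-3 communities, one root seed.
- `run_pipeline` writes every stage artifact (curated CSV, similarity CSV,
  sweep CSV, critical point JSON, community files, CV CSV) plus a
  `manifest.json` with SHA-256 checksums of each artifact; a rerun with the
  same config and inputs reproduces the checksums. The similarity stage is
  checkpointed, keyed by the checksum of the curated input.
- The descriptor screen stage is skipped with a warning when descriptors
  cannot be computed; every other stage failure is fatal.

## Scale limitations

Exact MCS is the bottleneck: all-pairs similarity is quadratic in molecule
count with an NP-hard kernel per pair. The default expansion cap handles
drug-like molecules (tens of heavy atoms) comfortably — the 120-molecule
synthetic preset (7,140 pairs) computes in a few seconds — but an 800+
molecule screening set means ~300k MCS calls and is an overnight batch job,
not a desk-scale run. Timeouts are recorded per pair in the store's metadata
so their effect on the network is auditable.
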