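# Methods

## Models

The observed network is an undirected simple graph `G = (V, E)` with string
vertex labels.  Three hereditary target classes formalize "the true network
is a union of core–periphery structures":

* **Split cluster graphs** (disjoint model): every connected component splits
  into a clique (core) and an independent set (periphery).  Characterization:
  a graph is a split cluster graph iff it contains no induced C4, C5, P5,
  necktie (triangle plus a two-edge path at one triangle vertex) or bowtie
  (two triangles sharing a vertex).
* **Monopolar graphs** (shared-periphery model): `V` partitions into an
  independent set and a cluster graph (disjoint cliques).  Recognition is
  NP-hard; the minimal forbidden subgraph list is infinite (W4 is the unique
  one on ≤5 vertices; the census at six vertices, recomputed by the package,
  is 11).
* **Cluster graphs** (baseline): disjoint cliques; forbidden subgraph P3.
  In the core–periphery reading, size-1 clusters form a shared periphery.

Fitting means finding a minimum-cardinality set of edge insertions and
deletions whose application lands in the class.  The edit count `k` is the
objective; the implied partition (clusters with core/periphery roles) is the
scientific output.

Assumptions worth keeping in mind: cores interact completely (cliques),
peripheral proteins never interact with each other, and (disjoint model)
peripheries touch exactly one core.  Two-protein subcomplexes attached to a
core violate both models and surface as edits.

## Recognition

* **Split graphs.** The splittance of a degree sequence `d1 ≥ … ≥ dn` with
  `kmax` the largest index with `d_k ≥ k−1` is
  `(kmax(kmax−1) − Σ_{i≤kmax} d_i + Σ_{i>kmax} d_i)/2` — the minimum number
  of edits to any split graph, achieved by completing the `kmax`
  highest-degree vertices into a clique and emptying the rest.  Membership
  is splittance = 0.  Degree ties break lexicographically; when the cost is
  zero, degree-one vertices whose neighbor has degree > 1 are demoted to the
  periphery so that the reported witness matches the local-improvement
  argument used by the solvers ("no pendant vertex needs to sit in a core").
* **Split cluster graphs.** Per component: if the split check fails with a
  C4/C5, done; a 2K2 is first relocated next to a common attachment vertex
  by the shortest-path argument (cases: distance 2, 3, ≥4 between the two
  edges), and the five vertices then induce a P5, necktie, or bowtie
  according to how many of the two optional triangle edges are present
  (0/1/2).  Certificates carry an ordered vertex tuple and are verified
  positionally against the kind's edge pattern.  Certificate extraction is
  O(n·m)-ish rather than linear time; correctness, not asymptotics, is the
  contract here.
* **Monopolar graphs (exact, exponential).** Branch on an induced P3 inside
  the candidate core: one of its three vertices must join the independent
  set, and may only do so if it has no neighbor there.  Exhaustive,
  branching factor 3, guarded at 20 vertices by default.

## Exact solvers

All ILPs use binary edge variables `e_uv` per unordered pair with objective
`Σ_{uv∈E}(1−e_uv) + Σ_{uv∉E} e_uv`, solved with HiGHS (scipy `milp`).  The
backend has no callback interface, so lazy constraints are an iterative
re-solve loop: solve, inspect the integral candidate, add violated rows,
repeat.  Returned solutions are feasible by construction (the loop only
stops when the recognizer or the annotated checks accept) and optimal when
no time limit interferes.

* **SCE, forbidden-subgraph form.** Each round runs the recognizer on the
  candidate; the certificate contributes the row "at least one pair inside
  the certificate must differ", then one certificate vertex is deleted and
  the search repeats, adding up to `n` rows per round.  Strengthenings
  (optional, on by default): C5 rows get right-hand side 2 (a C5 needs two
  edits), and each P5 `u-v-w-x-y` also contributes
  `ē_uv+ē_vw+ē_wx+ē_xy + ½e_uw + e_vx + ½e_wy + ½e_xu + ½e_yv ≥ 1`
  (insertions that provably need a follow-up edit get coefficient ½; the
  end-pair insertion, which creates a C5, is omitted).  Analogous
  strengthenings for neckties/bowties exist but are not implemented.
* **SCE/ME, partition-variable form.** Core indicators `c_u` join the edge
  variables.  Independent-set rows `c_u + c_v + ē_uv ≥ 1` for *all* pairs
  are added up front (the all-pairs choice is safe and simple), along with
  the P3 rows for triples inducing a P3 in the input:
  `ē_uv + ē_vw + e_uw + c̄_u + c̄_w ≥ 1` for SCE (core endpoints must be
  adjacent) and the same row with `c̄_v` added for ME (no P3 entirely inside
  the core).  Remaining P3 rows are generated lazily from induced P3s of the
  integral candidate.  Cutting planes are separated on the LP relaxation
  before the MIP phase: violated P3 rows plus forbidden-subgraph
  inequalities (C4 and the strengthened P5 for SCE, W4 for ME), keeping at
  most the 500 most violated with violation ≥ 0.3 per round (cap and
  threshold as in the reference protocol), for at most 10 rounds.
* **CE.** Edge variables with conflict-triple rows `ē_uv + ē_vw + e_uw ≥ 1`,
  seeded from input P3s and completed lazily.
* **Variable fixing.** If `deg(u) = 1` and u's neighbor has degree > 1, some
  optimal SCE solution makes u a periphery vertex with no incident
  insertions; the partition model fixes `c_u = 0` and `e_uw = 0` for all
  `w ∉ {u, v}`.
* **Warm start.** The backend accepts no MIP start, so the "heuristic
  solution after 10 restarts" enters as a valid upper-bound row
  `objective ≤ h` instead (flag `warm_start`, default on).
* **Output canonicalization.** SCE partitions are reported as the canonical
  per-component split partition (highest-degree core, pendant demotion),
  not the solver's arbitrary optimal labeling; ME partitions report the
  solver's independent set and the components of the core subgraph.

Independent oracles, sharing no code with the ILPs: (1) iterative-deepening
enumeration of all edit sets of size 0, 1, 2, …; (2) a subset-DP solver —
every optimal edited graph is described by a partition of `V` into blocks,
so the optimum is `m + min over partitions` of per-block costs
(`splittance(block) − edges(block)` for SCE; `missing pairs − 2·edges` for
CE; ME adds an outer minimization over the shared independent set), computed
over vertex bitmasks in O(3^n); (3) the 10^k search tree, branching on the
at most ten vertex pairs inside a certificate.  The test suite demands
agreement of every route on exhaustive small-graph suites and seeded random
graphs.

## Heuristic

Simulated annealing over clusterings (ME: plus a shared periphery set).
For a fixed state the optimal edit count is computed exactly: SCE = edges
between clusters + per-cluster splittance; ME = periphery-internal edges +
inter-cluster edges + missing intra-cluster edges.  Moves take a uniform
random vertex to the cluster of one of its neighbors, to a fresh singleton
cluster, or (ME) into the periphery; cost changes are evaluated
incrementally and, under a debug flag, re-derived from scratch after every
acceptance.  Acceptance is `Δ ≤ 0` or with probability `exp(−Δ/T)`.

Defaults follow the reference protocol: 20,000 steps per restart, `T0 = 1`,
100 restarts.  The published schedule only says the temperature falls to
zero; linear decay `T(t) = T0(1 − t/steps)` is the default, geometric decay
is available behind `cooling="geometric"`.  Both problems restart from the
all-singletons state (stated for SCE; adopted for ME by symmetry).  Fixed
seeds give bit-identical trajectories.  Test suites run a reduced schedule
(2,000 steps, 10 restarts), at which the SCE heuristic still matches the
exact optimum on ≥95% of the random suite and the ME heuristic's mean gap
stays below one edit.

## Synthetic data

* `er_graph(n, p, seed)`: every pair present independently with probability
  p — the solvers' stress test; test suites use n ≤ 10 and
  p ∈ {0.1, 0.3, 0.5}, where exact optima are still available from the DP
  oracle.
* `planted_instance(core_sizes, periphery_sizes, model, attach_prob, seed)`:
  complete disjoint cores; periphery vertices gain an edge to each allowed
  core vertex (own core in the disjoint model, any core in the shared model)
  with probability `attach_prob`, redrawn until at least one attachment.
  Defaults used in the recovery suites: cores of 6 (typical curated complex
  size in yeast), peripheries of 4, `attach_prob = 0.5`.  Noise =
  `perturb(g, t, seed)`: `t` distinct pairs toggled uniformly.

What the generator does *not* emulate: overlapping complexes, degree
heterogeneity within cores, distance-2 attachments, and correlated
(non-uniform) measurement error.  Passing recovery tests therefore show
that the solvers find planted structure under the models' own assumptions,
not that real interactomes satisfy those assumptions.

**Identifiability.** The planted core labeling is not always recoverable
even in principle: a periphery vertex attached to its entire core can join
the clique at zero cost, and a noise edit deleting a core edge can make
demoting an endpoint exactly as cheap as re-inserting the edge — and
occasionally strictly cheaper, in which case the planted structure is not an
optimal explanation of the corrupted graph at all.  The recovery suite
therefore counts a trial as successful when the solver's cores match the
planted cores, or when the planted repair is certified optimal and the
solver returned a different optimum (ties between optima are resolved
arbitrarily by design throughout the package).

## Evaluation protocol

Gold-standard complexes are filtered per analyzed subnetwork: drop
complexes with under half their members present, restrict to present
members, drop those smaller than three.  A cluster is *nontrivial* with ≥3
vertices and ≥2 core vertices; in the shared-periphery modes a cluster's
effective periphery is the neighborhood `N(core)`, taken in the edited
graph by default (the input graph behind a switch).  A complex is
*detected* by a cluster when ≥50% of the core lies in the complex and ≥50%
of the complex lies in the cluster; each complex counts once, scored by its
best-scoring detecting cluster (highest core% + complex%), and the report
carries mean and median core%, complex-coverage% and periphery-extra% over
detected complexes (extra% of an empty periphery is 0).  Detection is
restricted to nontrivial clusters.  Functional-coherence columns that
require an external semantic-similarity service are out of scope and left
absent.

## Numerical and design notes

* All deterministic orders are lexicographic on vertex labels; certificate
  searches scan in sorted order, so outputs are reproducible.
* Degenerate inputs: empty graphs and single vertices short-circuit all
  solvers with empty edit sets; empty clusters are dropped from annealing
  states; `extra% = 0/0` is defined as 0.
* Subset-DP and brute-force oracles are guarded (16 and 9 vertices); the
  monopolar brute-force recognizer at 20; graph-class enumeration at 7
  (canonical form = minimal adjacency bitstring over all vertex
  permutations, vectorized with numpy and cross-checked against the
  networkx graph atlas).
* Solver time limits return the best integral solution found with
  `optimal=False`; tests always run without limits.

## Known limitations

* ILP scalability: HiGHS through scipy without callbacks re-solves from
  scratch each round; practical for the desk-scale instances exercised here
  (tens of vertices), not for thousand-protein subnetworks.
* Certificate extraction is not the linear-time algorithm from the
  literature; it is polynomial and certificate-correct.
* Monopolar recognition beyond ~20 vertices must go through the ME ILP
  (objective 0 test) rather than the exhaustive recognizer.
* Weighted, directed, or multi-edge networks are out of scope, as are
  degree-preserving random rewiring nulls and external comparison
  algorithms; their partitions can still be scored by the evaluation module
  if supplied as TSV.
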