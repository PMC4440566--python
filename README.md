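# coreperiphery

Global core–periphery decomposition of protein-interaction networks by graph
modification.

## The problem

Protein complexes are commonly modeled as a stable *core* — proteins that
interact with each other — plus an *attachment* (periphery) of proteins with
transient interactions to the core.  Instead of growing such structures
locally around seeds, this package fits the **whole network** to a formal
model in which the true interactome is a disjoint union of core–periphery
structures, and measurement noise is the only reason the observed graph
deviates from it.  Under independent errors, the most likely true network is
one reachable from the observation by a **minimum number of edge insertions
and deletions** (the edit count *k*).

Three target graph classes give three fitting problems:

| problem | target class | structure |
|---|---|---|
| split cluster editing (SCE) | every connected component is a split graph | disjoint cores (cliques), each with its own independent periphery |
| monopolar editing (ME) | monopolar graph | disjoint clique cores sharing one independent periphery |
| cluster editing (CE) | disjoint cliques | cores only; size-1 clusters interpreted as periphery |

For every graph, k(ME) ≤ k(SCE) ≤ k(CE).

Key combinatorics implemented here: split graphs are exactly the
(2K2, C4, C5)-free graphs and are recognizable from the degree sequence
alone via the Hammer–Simeone *splittance*; split cluster graphs are exactly
the (C4, C5, P5, necktie, bowtie)-free graphs, with a certificate-producing
recognizer; monopolar graphs have infinitely many minimal forbidden induced
subgraphs (the unique one on ≤5 vertices is the wheel W4, and there are
exactly 11 on six vertices — the package recomputes this census).

Both SCE and ME are NP-hard, so the package provides exact integer linear
programs (forbidden-subgraph and partition-variable formulations with row
generation and cutting planes, solved by HiGHS through scipy), a 10^k
branching search tree, brute-force and subset-DP oracles, and a simulated
annealing heuristic whose per-state cost evaluation is linear time.

## Worked example

Plant two core–periphery structures (cores of six proteins, peripheries of
four, attachment probability 0.5), corrupt the graph with two random edge
toggles, and fit the disjoint model:

```python
from coreperiphery import SplitClusterEditing, MonopolarEditing, ClusterEditing
from coreperiphery.synthetic import planted_instance, perturb

inst = planted_instance([6, 6], [4, 4], model="disjoint", seed=7)
noisy, noise = perturb(inst.graph, 2, seed=8)

res = SplitClusterEditing(noisy).fit()
print(res.summary())
```

```
SplitClusterEditing results
========================================
vertices:            20
edges:               51
method:              ilp (sce_partition)
edit count k:        1  (insert 1, delete 0)
proven optimal:      True
nontrivial clusters: 2
mean core size:      6
mean periphery size: 4
```

One noise toggle deleted a core edge (the solver re-inserts it, `k = 1`);
the other inserted a core–periphery edge, which split graphs accommodate at
no cost.  Both planted clusters are recovered with their core and periphery
sizes intact.  The model sandwich on the same input:

```python
MonopolarEditing(noisy).fit().objective   # 1
ClusterEditing(noisy).fit().objective     # 16  (peripheries are expensive for CE)
```

Partitions can be scored against gold-standard complexes with
`res.evaluate_complexes(...)` (detection = ≥50% of the core inside the
complex and ≥50% of the complex inside the cluster), and everything is also
reachable from the shell:

```sh
coreperiphery simulate --model planted-sce --seed 7 --out g.tsv --truth t.tsv
coreperiphery solve --problem sce g.tsv --out-partition part.tsv
coreperiphery recognize --class split-cluster g.tsv
coreperiphery enumerate-forbidden --class monopolar --max-n 6
```

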