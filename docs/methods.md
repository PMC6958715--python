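# Methods

## Model

A signed interaction graph *G(V, E, σ)* has directed edges labeled
activation (+) or inhibition (−); nodes are genes (`X_gen`), proteins
(`X_prot`) or complexes (`A_prot::B_prot`). Observations (S, μ) fix the
sign of a measured subset S ⊂ V (here: discretized differential gene
expression, so S contains gene nodes). A total labeling μᵗ: V → {+, −, 0}
is **consistent** when:

1. observed nodes keep their observed sign;
2. every node labeled + or − receives at least one *influence* equal to its
   label, where the influence of predecessor p over edge e is
   μᵗ(p) · σ(e) (zero absorbing, minus·minus = plus);
3. every node labeled 0 receives only zero influences, or at least one +
   and one − influence.

Rules 2–3 apply only to nodes with predecessors: in-degree-0 nodes are free
inputs (without this exemption no non-trivial labeling could exist, since
justification must start somewhere). Rule 3 is deliberately phrased over
*received influences* rather than raw predecessor labels: an inhibitory
edge from a +-labeled node contributes a −, and can therefore balance an
activation — the natural reading of the influence algebra, and the only one
under which a single node with both a + and a − edge from the same active
regulator can be held at 0.

**Prediction.** pred(x) = s iff every consistent total labeling assigns s
to x; otherwise x is undecided (∅). Observed nodes are excluded from the
reported prediction map — predictions concern unmeasured biomolecules.

**Repair.** When no consistent labeling exists, a *minimal correction set*
is a smallest set of nodes each granted one artificial incoming influence
(implemented as exemption from rules 2–3; rule 1 still binds, so a repaired
observation keeps its sign but no longer needs justification). All
cardinality-minimal repair sets are enumerated by increasing k (cap
`max_k=3` by default) and predictions are computed per repair. Across
repairs, a node is reported with sign s iff at least one repair scenario
entails s and no scenario entails a different sign; scenarios leaving the
node undecided do not block. This union rule degrades gracefully: with a
unique repair it is exactly the per-repair prediction, and disagreeing
scenarios yield ∅ rather than an arbitrary choice. Repair candidates are
restricted to nodes with in-degree > 0 — exempting a free input changes
nothing, so the restriction provably returns the same repair sets as
searching all nodes.

## Solver

The engine is a bespoke ternary-domain constraint solver. Each node holds a
domain ⊆ {+, −, 0} (3-bit mask). Propagation enforces generalized arc
consistency on every justification constraint: a value is pruned from a
node when no predecessor assignment can achieve it, and from a predecessor
when pinning it there leaves the constrained node without any achievable
value. The achievability test is exact for singleton predecessor domains
and an over-approximation otherwise, so pruning is always sound; a
backtracking search (minimum-remaining-values, deterministic node order)
restores completeness. Satisfiability, labeling sampling (randomized value
order) and enumeration all run on this search.

Entailment queries implement pred directly: after root propagation, a
singleton domain is an entailed sign; otherwise one witness labeling is
computed and at most two unsatisfiability probes (the alternative signs)
decide the node. This never materializes the labeling space.

A brute-force path — filtering all 3^|V| candidate labelings through an
independent implementation of the three rules, plus exhaustive subset
search for repairs — is kept as the test oracle (`method="exhaustive"`,
`brute_force_predict`) and is confronted with the production path on
thousands of seeded random instances (≤ 10 nodes, both arbitrary and
planted-consistent observations) in the test and acceptance suites.

## Graph construction from KGML

PPrel relations join `_prot` nodes; GErel relations run `_prot` → `_gen`;
KGML groups become complex nodes with one +-signed membership edge per
member; for every symbol present, a +-signed GPrel edge `X_gen → X_prot`
links expression to signaling (a gene node also materializes its protein
product, and vice versa). Edge signs come from relation subtype keywords
via a user-editable configuration (defaults: activation / expression /
indirect effect → +; inhibition / repression → −; everything else, e.g.
binding/association or phosphorylation, → drop). Dropping unsigned
keywords trades recall for causal precision: no edge is guessed. A relation
annotated with both roles emits both edges and logs the ambiguity.
Multi-symbol entries expand to one edge per symbol. Compound/map entries
and non-PPrel/GErel relation types are excluded; complex members of
multi-symbol components use the component's first symbol. Gene symbols are
read from the KGML graphics name (one comma-separated token per KEGG id
when counts line up, first token otherwise) — a documented convention,
since offline KGML carries no authoritative symbol table. Display-only
gene entries that participate in no relation are not materialized.

## Upstream extraction

Seeds are the gene nodes of the target symbols (a symbol matching only a
protein node does not seed). The result is the subgraph induced by
seeds ∪ {x : x has a directed path to a seed}, computed by multi-source
BFS on the reversed graph after removing excluded biomolecules (gene,
protein, and any complex containing an excluded member). Exclusion runs
first so undetectable genes cannot serve as regulators. Note that any
induced edge (u, v) has v inside the upstream set, hence lies on a directed
path to a seed — "induced subgraph" and "edges on upstream paths" coincide
under this node-set definition, so only one semantics is implemented. A
`downstream=True` flag adds the symmetric forward closure.

## Discretization

Strict thresholds, all exposed on the CLI: + when log2FC > 2, − when
log2FC < −0.5, both under p_adj < 10⁻⁵. The asymmetric pair (+2 / −0.5 on
the log2 scale) is the convention of the expression analysis this pipeline
was built around; the negative reading of the down-threshold is used
because the two classes must be disjoint on the log2 scale. Conflicting
duplicate records are an error; same-sign duplicates collapse.

## Validation study

Stratified subsampling draws round-half-up(f/100 · n_s) observations per
sign stratum s without replacement (round-half-up keeps 50 % of an odd
stratum above floor semantics; the difference is at most one observation).
Per-experiment RNG streams derive from (plan seed, fraction, replicate), so
the study is order-independent and embarrassingly parallel. Repairs are
recomputed per subset — a subset may lack the very observation that forced
a repair. Precision compares sign predictions to raw fold-change
directions after stripping `_gen`/`_prot` suffixes; complex nodes and
0-sign predictions are excluded from t (the latter counted separately —
only a fold-change of exactly 0 could match them). Stability classifies
every reference-predicted node as good / bad / missing, so
good + bad + missing equals the reference prediction count on every row.
Because the stability-curve normalization is ambiguous between "per
sub-run prediction count" and "per reference count", both are exported
(`*_frac_sub`, `*_frac_ref`); plots default to per sub-run. Plots are
static matplotlib PNGs; all raw rows are exported as tidy CSV.

## Synthetic data

The generator emulates the structural properties the pipeline assumes of
curated pathway graphs: paired `X_gen → X_prot` GPrel edges, random
PPrel/GErel edges, and complexes wired from two members. The default
inhibition fraction 0.153 reproduces the 2110 : 13771 inhibition share of
the curated human signaling network the method targets; activation-heavy
graphs are the realistic regime. Defaults (30 genes, density 0.05, 3
complexes) give ~60-node instances that solve in well under a second.

Planted labelings are drawn by running the production solver with
randomized value ordering: free inputs get uniform random signs and
downstream nodes any justifiable sign, cycles handled by the search itself.
This replaces a topological-propagation-plus-rejection scheme: since the
all-zero labeling is always consistent, the search cannot fail and no
retry bound is needed; the result is still re-checked against the
independent rule checker. Revealed observations (non-zero gene labels, a
chosen fraction) are consistent by construction, giving ground truth for
the soundness battery: repair-free inference and no prediction ever
contradicting the planted sign.

What passing these tests does **not** show: synthetic graphs do not mimic
KEGG degree distributions, motif frequencies or hub structure beyond the
sign ratio, and planted observations are noise-free, unlike discretized
patient data. Conclusions about real-cohort precision therefore come only
from running the pipeline on real graph + expression inputs.

## Problem sizes and numerics

Test and acceptance batteries use graphs of ≤ ~25 nodes for
oracle-equivalence (where 3^|V| enumeration is exact and fast) and ≤ ~60
nodes for pipeline runs, with 18 × 2–4 replicate sampling plans; these
sizes fully exercise every code path while keeping the suites fast. The
default production plan remains 18 × 100. All node iteration is in sorted
order and every random draw flows from an explicit seed, so identical
inputs give byte-identical outputs. Complex ids canonicalize member order
lexicographically (`B::A` ≡ `A::B`); unsuffixed identifiers in third-party
SIF files are accepted as proteins with a logged warning.

## Known limitations

* Repair search is exhaustive by cardinality (≤ max_k); instances needing
  many simultaneous repairs are out of reach and raise an explicit error.
* No undirected edges, edge weights, multi-sign semantics, or dynamic
  (Boolean-network) interpretation.
* Gene-symbol matching is exact and case-sensitive; no alias resolution.
* KGML ingestion covers PPrel/GErel (plus groups); ECrel compound
  chemistry and PCrel relations are dropped.
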