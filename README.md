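# signpred

Sign-consistency modeling of signed regulatory networks: predict the
expression or activity shift of biomolecules that were never measured, from
the ones that were.

## The problem

Genome-wide differential expression between two patient groups (say, low-
versus high-aggressive tumors) labels a few hundred genes as up- (+) or
down-regulated (−). Most of the signaling machinery — proteins, protein
complexes, and all the unmeasured genes — receives no label at all. Curated
pathway knowledge constrains what those hidden states can be: a protein
cannot be "up" if nothing upstream pushes it up, and a node can only sit
still if its inputs cancel or are silent. `signpred` turns that idea into a
pipeline:

1. **Graph construction** — KEGG KGML pathway files are converted into a
   signed, directed interaction graph *G(V, E, σ)*, σ: E → {+, −}. Genes and
   proteins are split into distinct nodes (`X_gen`, `X_prot`), complexes
   become `A_prot::B_prot` nodes fed by their members, and every protein is
   linked to its gene by a "gene–protein" (GPrel) edge so expression data can
   flow into signaling.
2. **Upstream extraction** — only the subnetwork regulating the measured
   gene list is kept (reverse reachability to the gene nodes), after
   removing genes whose expression is undetectable.
3. **Observations** — the expression table (gene, log2 fold-change,
   adjusted p-value) is discretized: + if log2FC > 2, − if log2FC < −0.5,
   both requiring p<sub>adj</sub> < 10⁻⁵.
4. **Inference** — a *total labeling* μ: V → {+, −, 0} is *consistent* when
   every observation keeps its sign, every +/− node receives at least one
   influence (predecessor label × edge sign) equal to its label, and every
   0 node receives only zeros or a balancing {+, −} pair. The *prediction
   function* is

   pred(x) = s  iff  μ(x) = s for **every** consistent total labeling μ,

   and ∅ (undecided) otherwise. If the observations contradict the graph,
   all *minimal correction sets* (MCoS) — smallest sets of artificial
   influences whose addition restores consistency — are found first, and
   predictions are combined across repairs.
5. **Validation** — the observation set is subsampled (10–95 % in steps of
   5, stratified by sign, 100 replicates each by default = 1800 runs) to
   measure the precision *s = m/t* of sub-predictions against raw
   fold-change directions and their stability (good / bad / missing) against
   the full-observation run.

The consistency engine is a ternary-domain constraint solver (generalized
arc consistency + backtracking) that decides per-node entailment without
enumerating the labeling space; an independent brute-force 3^|V| enumerator
is kept alongside it and the two are confronted on thousands of random
instances in the test suite.

## Worked example

`examples/` contains a five-node conflict motif: the hub regulator
`TP53_prot` activates four genes; `PMAIP1` is observed up while `CCNG1`,
`SHISA5` and `TP73` are observed down — no labeling of the hub can justify
all four.

```bash
signpred run \
  --graph examples/motif_graph.sif \
  --diffexp examples/motif_diffexp.csv \
  --excluded examples/excluded.txt \
  --steps 1,2,3 --outdir out
```

prints

```
step 1: 4 discretized observations
step 2: kept 5 nodes / 4 edges, 4 targets matched
step 3: 1 predictions, MCoS k=1
observations required 1 repair(s); exiting with status 2
```

`out/mcos.json` reports the unique minimal repair — one artificial
influence toward `PMAIP1_gen`, the observation that conflicts with its
three siblings — and `out/predictions.tsv` contains

```
TP53_prot	protein	-
```

i.e. once the outlier is explained away, every consistent labeling agrees
the hub must be down-regulated. The exit status 2 flags that repairs were
needed (0 means the observations were already consistent).

Other entry points: `signpred build-graph *.xml --out graph.sif` converts
KGML pathways (step 0), `signpred generate` creates synthetic
graph/observation pairs with a planted consistent labeling, and steps 4–5
(`--steps 4,5`) run the subsampling study and render the precision boxplots
and good/bad/missing stability curves.

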