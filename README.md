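# palmdelim

Multi-criterion species delimitation for recent radiations, built around the
Hawaiian *Pritchardia* (loulu palm) case: a library (plus a thin `delim`
command-line tool) that tests whether putative species behave as separately
evolving lineages under three independent operational criteria and
synthesizes the evidence per lineage.

Under the general lineage species concept, species are separately evolving
metapopulation lineages, and each operational criterion captures one property
that lineages acquire during divergence. The package implements the
post-inference side of such a study — tree searches, admixture MCMC and
sequencing are inputs, not computations:

1. **Diagnosability (PSC I)** — *population aggregation analysis* (PAA).
   Each unit (terminal, population, or putative species) gets a profile of
   observed character-state sets; a character is *diagnostic* between two
   profiles when their state sets are mutually exclusive (disjoint),
   evidence that gene flow has ceased. Units with no diagnostic difference
   are merged (profile union) and re-compared until a fixed point; an
   exhaustive merge-order oracle verifies the result on small instances.
   Missing data never create or block a diagnostic: terminals missing at
   characters diagnostic for their group are *sequestered* and reported
   rather than allowed to collapse otherwise diagnosable groups.
   Microsatellite genotypes are coded as multistate characters with
   heterozygotes as subset polymorphisms {a, b}.

2. **Monophyly (PSC II)** — per-species monophyly across replicate trees
   (support = % of replicates in which the species' leaves form a rooted
   cluster), with strict consensus (cluster-set intersection), Adams
   consensus (recursive product of root partitions), and a greedy *wildcard*
   scan that removes terminals whose unstable placement collapses
   strict-consensus resolution.

3. **Genotypic clustering (GSC)** — from Bayesian admixture output: the
   Evanno-style ΔK statistic, ΔK(K) = mean|L″(K)| / sd(L(K)), to choose the
   number of clusters; greedy CLUMPP-style label alignment of replicate Q
   matrices (the per-step optimum solved exactly as a K×K assignment
   problem); and membership-coefficient rules — a species is *necessary*
   when its mean membership in its modal cluster exceeds 0.8, *exclusive*
   when no outside individual exceeds 0.8 in that cluster.

A conformance table (one row per putative lineage, one column per criterion,
plus a criteria-satisfied count) assembles the evidence; a transcription of
the published 33-lineage Hawaiian *Pritchardia* table ships as
`palmdelim/data/table1_pritchardia.tsv`. A seeded synthetic-data module
generates matrices with planted fixed differences, replicate trees with
rogue terminals, and admixture replicates with label switching, so every
stage is testable with known truth.

## Worked example

```bash
python examples/02_consensus_and_wildcards.py
```

```
input trees: R sits in a different place in each
strict consensus: (A,B,C,R);  (0 resolved internal edges -- R destroys all grouping)
Adams consensus:  (A,(B,C),R);  (the (B,C) nesting common to all trees survives)
wildcard scan removed: ['R']; strict-consensus resolution went 0 -> 1
after pruning the wildcard, the remaining trees agree completely
```

One wandering terminal erases every cluster from the strict consensus, but
the Adams consensus keeps the (B,C) nesting that all trees share — which is
exactly how wildcards are spotted and removed.

```bash
python examples/05_published_table_tallies.py
```

```
lineages in the table: 33
diagnosable by a unique character-state combination: 18
membership coefficient > 0.8: 8
necessary-and-sufficient genotypic clusters: 5
monophyletic in the primary analysis: 6
```

18 of 33 putative lineages are diagnosable by unique character-state
combinations; 8 pass the necessary membership threshold but only 5 are also
exclusive genotypic clusters.

The other examples cover PAA with sequestration (`01`), ΔK / alignment / GSC
on simulated admixture output (`03`), and the full pipeline on synthetic
five-species data (`04`). The same operations are reachable from a shell:

```bash
delim simulate matrix --seed 3 --out sim/
delim paa --matrix sim/matrix.tsv --grouping sim/grouping.tsv --level species
delim trees consensus --trees trees.nwk --method adams
delim clusters deltak --lnp lnp.tsv
delim report tally
```

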