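# Methods

This note records the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and the limits of what the synthetic tests demonstrate.

## Character matrices and coding

A matrix cell is a non-empty set of state symbols or MISSING; polymorphic
and ambiguous observations are simply larger sets. Three character classes
are tagged (sequence site, microsatellite locus, morphological) because the
criteria consume them differently downstream.

- **Microsatellite coding.** A diploid genotype (a, b) at a binned locus
  becomes the multistate set {a, b} (a *subset polymorphism*); homozygotes
  are singletons; a genotype whose two alleles both carry the missing code
  is MISSING. A half-missing genotype is rejected by default — it usually
  indicates an upstream calling error — with an opt-in `keep-observed`
  policy that keeps the observed allele. Allele binning itself is upstream
  of this package: inputs are integers already binned.
- **Gaps.** The gap symbol `-` in sequence characters is treated as missing
  by default, with a fifth-state option (`gap_as_missing=False`). Gap
  treatment is a genuinely open choice; missing is the conservative default
  because a gap state can manufacture diagnosability from alignment
  artifacts.
- **Composite terminals** union member state sets per character, ignoring
  MISSING; a composite cell is MISSING only when every member is. This is
  idempotent and invariant to member order.
- **Informativeness.** Only unambiguous cells (single state, non-missing)
  enter the tallies: parsimony-informative requires ≥2 states each in ≥2
  unambiguous cells; constant means ≤1 observed state. Excluding ambiguous
  cells is conservative and avoids counting one polymorphic individual as
  two observations.
- **Formats.** NEXUS `DATA`/`CHARACTERS` blocks (brace polymorphism, `?`
  missing) are parsed through dendropy; the package's TSV layout adds
  `#class` and `#alphabet` header rows so multi-character symbols (allele
  sizes) and class tags round-trip losslessly. NEXUS cannot name characters
  or carry per-character alphabets, so its round-trip identity holds for
  canonically named columns sharing one single-character alphabet.

## Population aggregation analysis

Profiles are character-wise unions of member terminals' non-missing cells;
per-terminal missing positions are recorded on the side. A character is
diagnostic between two profiles iff both observed sets are non-empty and
disjoint. Aggregation repeatedly merges any pair of groups with zero
diagnostic characters (merged profile = union) until every remaining pair is
separated; the scan order is deterministic (input order, pairs
lexicographic), and order invariance is asserted by test rather than
assumed.

**Missing-data semantics.** Missing entries never create or block a
diagnostic. Terminals missing at characters diagnostic for their final group
are *sequestered*: listed (`set-aside`) or additionally collected under one
labelled pseudo-group (`single-group`), so that incomplete terminals are
surfaced instead of silently collapsing otherwise diagnosable groups.

**Fixed-point uniqueness — a real caveat.** When every unit has at least one
observed cell at every character, mergeability is monotone under profile
enlargement (unions can only destroy disjointness), so every merge order
reaches the same fixed point; the exhaustive merge-order oracle
(`oracle_aggregate`, feasible to 6 units) confirms a unique fixed point on
randomized instances of this kind. When a unit is *wholly* missing at a
character, however, merging it with an observed unit creates a state set
where none existed, which can create new diagnosability — and then different
merge orders can genuinely reach different fixed points. The deterministic
scan still lands on one valid fixed point (every final pair separated), and
the oracle exposes the full reachable set so the ambiguity is detectable.
Characters missing-only in every unit are dropped from any sensible input;
unit-level missing-only characters are supported but flagged as the one
regime where results are order-dependent.

Cross-dataset PAA is column-wise concatenation (`CharacterMatrix.concat`) on
the intersection of terminals followed by a single aggregation: a "unique
combination of character states" reads over all characters jointly.

## Trees, consensus, wildcards, monophyly

Trees are rooted as read (an outgroup reroot operation is available and
should precede monophyly tests when the stored rooting is arbitrary).
Internal node labels are parsed as support; scale is auto-detected (all
values ≤ 1 → proportions ×100) and overridable. Resolution is the count of
non-root internal edges, with a normalized variant against n−2.

- **Strict consensus** contains exactly the rooted clusters present in
  every input tree (computed as a set intersection, then reassembled from
  the laminar family).
- **Adams consensus** recurses on the common refinement (product) of the
  trees' root-child leaf partitions. It preserves every nesting common to
  all inputs, and relative to its own clusters it is exact: a set nests
  inside an Adams cluster iff it nests there in every input. Taken over
  *all* subset pairs the consensus can display nestings that are not common
  — the wandering-terminal trio is the textbook case — which is an inherent
  property of the method, not an implementation artifact; the test oracle
  states the two provable properties and checks them exhaustively at ≤7
  leaves.
- **Wildcard scan.** Manual wildcard deletion stops at a subjective
  trade-off; the scan replaces it with an explicit contract
  (`min_gain`, `max_rounds`, `protected`): each round scores every
  unprotected terminal by the strict-consensus resolution gained by pruning
  it everywhere, removes the best candidate if the gain reaches `min_gain`
  (ties to the lexicographically first label), and reports each round's
  Adams consensus for inspection without scoring it — the stopping rule is
  about strict-consensus resolution. Blocked (protected) best candidates
  are flagged.
- **Monophyly.** Per species with ≥2 sampled leaves: support = 100 × the
  fraction of replicate trees in which the species' sampled leaves form a
  cluster; the yes/no status is read from a designated primary tree (the
  first, by default). Singletons and unsampled species are not assessed —
  a single leaf is trivially a clade, so calling it monophyletic would be
  vacuous.

## ΔK, Q alignment, genotypic-cluster rules

- **ΔK.** ΔK(K) = mean|L″(K)| / sd(L(K)) with sample sd; undefined at the
  range endpoints and wherever sd = 0 (flagged, excluded from the argmax;
  all-undefined is an error). Default pairing is `by-replicate`
  (|L_r(K+1) − 2L_r(K) + L_r(K−1)| averaged over replicates paired by
  index, requiring equal replicate counts per K); `by-mean` (second
  difference of means) is available because harvesting tools differ.
  ΔK is invariant under positive affine transforms of L.
- **Alignment.** Replicate Q matrices suffer label switching. The greedy
  scheme incorporates replicates one at a time over many random orderings
  (seeded), permuting each incoming replicate's columns to best match the
  running mean; the per-step optimum is found exactly by
  `linear_sum_assignment` on the K×K matrix of summed absolute coefficient
  differences — identical to scanning all K! permutations but feasible at
  K in the twenties. The first ordering tried is the input order, so
  already-aligned sets are a no-op. The reported similarity is the mean
  over replicate pairs of 1 − ‖A−B‖₁/(2N), which is 1 for identical
  replicates and 0 for disjoint crisp assignments; the aligned label frame
  is defined only up to one global permutation.
- **GSC rules.** Species-level coefficient = mean over the species'
  individuals of membership in the modal cluster (the minimum is reported
  alongside; the summary statistic behind a single printed value per
  species is an open choice, and the mean is the least surprising).
  *Necessary*: mean > `high` (default 0.8, strict inequality — the
  threshold is a convention, hence configurable). *Exclusive*: no outside
  individual above `high` in the modal cluster. *Intermediates*: members
  whose maximum coefficient falls strictly inside (`low`, `high`) =
  (0.5, 0.8). Modal-cluster ties go to the lowest index and are flagged.

## Conformance synthesis

Per lineage: monophyly satisfied iff the primary-tree status is
monophyletic; GSC satisfied iff necessary *and* exclusive (a necessary-only
column is also emitted); diagnosability satisfied iff the lineage's units
occupy only groups containing no other lineage's units — with a distinct
`yes-with-substructure` verdict when they split over several pure groups
(over-splitting is evidence of diagnosability, not failure, but worth
flagging). Absent sources yield `not-assessed`, which never counts toward or
against the criteria count. The packaged transcription of the published
33-lineage table carries a `gsc_satisfied` column encoding the bold
(necessary-and-sufficient) genotypic-cluster cells of the original, because
the printed coefficient alone cannot distinguish a high-membership lineage
whose cluster is shared; without that column the reader falls back to the
0.8 coefficient rule.

## Synthetic data: what it emulates and what it does not

One master seed feeds three fixed-offset streams, so each generator is
independently reproducible and byte-identical under the same seed.

- **Matrices.** For each species pair, `diag_per_pair` (default 2) sequence
  characters carry state 0 fixed in one species, 1 in the other, and {0,1}
  elsewhere — diagnostic for exactly that pair. Noise characters
  (sequence, 5 microsatellite-style, 10 morphology-style) draw states per
  terminal, with the first terminal of every species pinned to a shared
  state so noise can never separate species by itself; at each planted
  diagnostic the first terminal of each contrasted species is exempt from
  the missing mask so planted diagnosability survives any missing rate.
  These two guarantees make species-level recovery exact by construction —
  deliberately: the recovery tests verify the analysis pipeline, not the
  sampling distribution of accidental fixation. Sampling defaults (5
  species × 2 populations × 3 terminals, polymorphism 0.1, missing 0.05)
  echo the study's few-individuals-per-population design.
- **Trees.** A fixed ladderized base tree keeps species monophyletic; per
  replicate each species is left intact with probability `p_monophyly`,
  otherwise one member is regrafted to a position chosen so the regraft
  genuinely breaks monophyly (attachment points that would recreate the
  species clade are excluded — without this the nominal rate would be
  diluted by regrafts landing back inside the clade). Rogue terminals are
  extra leaves regrafted uniformly at random in every replicate; 30-100
  replicates stand in for the thousand-replicate resampling analyses of a
  real study at test scale.
- **Admixture.** True membership rows are Dirichlet draws with weight
  `admixture_concentration` (default 50 → mean own-cluster membership
  ≈ 0.93; 1 → uniform admixture) on the species' own cluster; replicates
  perturb the true row (Dirichlet, sharpness `q_noise_concentration` = 200)
  and apply a uniform random label permutation. LnP(K) is piecewise linear
  with slopes 200/20 meeting at the true K plus Gaussian replicate noise
  (sd 10) — the minimal shape that makes ΔK peak at the knee; with these
  defaults the knee's ΔK ≈ 18 against a noise floor ≈ 2, giving ≥95%
  true-K recovery across seeds.

What passing tests do *not* show: performance on real data with correlated
missingness, isolation by distance, uneven sampling, actual MCMC label
degeneracies beyond pure permutation, or morphology scored with observer
error. The generators plant clean truth; they validate the machinery, not
the robustness of the criteria themselves.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small problems
(≤6 units for the exhaustive merge oracle, ≤7 leaves for the nesting oracle,
200 randomized aggregation instances, 100 ΔK recovery seeds, 3-8 species
end to end) — sizes at which the exhaustive oracles are computable and the
whole suite completes in seconds. Row-sum tolerance for Q matrices is 1e-6;
coefficient thresholds use strict inequality; consensus tie-breaking never
arises (cluster families are canonical sets); wildcard ties break
lexicographically; all percentages are reported on the 0-100 scale.
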