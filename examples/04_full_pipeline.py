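"""The whole pipeline: three criteria synthesized into a conformance table.

Simulates matched inputs for five crisp, monophyletic, diagnosable species
(with one rogue terminal in the trees), runs diagnosability, monophyly, and
genotypic clustering, and assembles the per-lineage conformance table.
"""

from palmdelim import (
    SimSpec,
    aggregate_profiles,
    align_q_replicates,
    assemble_conformance,
    build_profiles,
    evanno_delta_k,
    gsc_report,
    monophyly_support,
    render_conformance,
    simulate_character_matrix,
    simulate_replicate_trees,
    simulate_structure_run,
    wildcard_scan,
)

spec = SimSpec(seed=11, n_species=5, n_tree_replicates=30, n_rogues=1)

matrix, grouping, _ = simulate_character_matrix(spec)
paa = aggregate_profiles(build_profiles(matrix, grouping, level="species"))

trees, tree_truth = simulate_replicate_trees(spec)
scan = wildcard_scan(trees)
print(f"wildcard scan removed {scan.removed} "
      f"(planted rogue: {tree_truth.rogue_labels})")
mono = monophyly_support(scan.final_trees, grouping)

q_by_k, lnp, struct_truth = simulate_structure_run(spec)
best_k = evanno_delta_k(lnp).best_k
aligned = align_q_replicates(q_by_k[best_k], permutations=50, seed=2)
gsc = gsc_report(aligned.mean_q, struct_truth.individuals, grouping)

table = assemble_conformance(mono, gsc, paa, {sp: sp for sp in grouping.species})
print()
print(render_conformance(table, format="tsv"))
print("every lineage satisfies all three criteria (criteria count 3): "
      "strong evidence each is a separately evolving lineage")
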