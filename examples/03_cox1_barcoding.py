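"""cox1 barcoding: haplotypes, reference-panel matches, K2P distances, ME tree.

Simulates the study-scale cox1 dataset (166 sequences, 25 haplotypes: 22
C. canis + 3 C. orientis), dereplicates it, matches haplotypes against a
90-entry reference panel, measures within-species K2P divergence and
builds a bootstrapped minimum-evolution tree.
"""

from fleagm.molecular import (
    SequenceRecord,
    bootstrap_support,
    collapse_haplotypes,
    k2p_matrix,
    match_reference,
    max_intragroup_distance,
)
from fleagm.synthetic import SeqSimSpec, simulate_cox1_dataset, simulate_reference_panel

records, _ = simulate_cox1_dataset(SeqSimSpec(seed=3))
table = collapse_haplotypes(records)
print(f"{table.n_sequences} sequences -> {len(table)} haplotypes")
print("five most frequent:",
      [(h.haplotype_id, h.count, h.species) for h in table.haplotypes[:5]])

panel, _ = simulate_reference_panel(records, seed=5)
matched = match_reference(table, panel)
hits = [(h.haplotype_id, h.matched_reference_id)
        for h in matched.haplotypes if h.matched_reference_id]
print(f"haplotypes identical to a reference-panel haplotype: {hits}")

reps = [SequenceRecord(h.haplotype_id, h.sequence, h.species) for h in table.haplotypes]
matrix = k2p_matrix(reps)
intra = max_intragroup_distance(matrix, [r.species for r in reps])
print("maximum intraspecific K2P distance:",
      {sp: round(v, 4) for sp, v in intra.items()})

tree = bootstrap_support(reps, n_reps=100, seed=7)
supports = [int(n.label) for n in tree.preorder_node_iter() if n.label is not None]
print(f"ME tree on {len(reps)} haplotypes; "
      f"{sum(s >= 95 for s in supports)} of {len(supports)} internal edges "
      f"with bootstrap support >= 95%")
# The deep, fully supported split separates the two species' haplotype
# clouds; within-species divergence stays an order of magnitude smaller.
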