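"""Run the full contamination loop on a synthetic benchmark.

Builds a 36-taxon species tree, derives 20 gene trees with planted
contamination (single leaves grafted next to food-source/prokaryote
donors, one co-contaminated pair, and a misassigned ciliate block inside
the parabasalids), writes curator-style rules for those events, and runs
the sisters -> subsisters -> clade-grabbing schedule.
"""

from phylocurate.contamination import Phase, run_loop
from phylocurate.simulate import (
    default_event_suite,
    rules_for_events,
    simulate_gene_trees,
    simulate_species_tree,
)

species = simulate_species_tree(seed=1)
events = default_event_suite(species)
sim = simulate_gene_trees(species, n_gfs=20, events=events, seed=7)

sisters, subsisters, clades = rules_for_events(events, species)
phases = [
    Phase("sisters", sisters, n_iterations=10),
    Phase("subsisters", subsisters, n_iterations=5),
    Phase("clades", clades, n_iterations=2),
]
result = run_loop(sim.gene_trees, phases)

planted = sim.planted_ids()
removed = {(r.gf, r.seq_id) for r in result.ledger.rows}
print(f"gene families:        {len(sim.gene_trees)}")
print(f"planted contaminants: {len(planted)}")
print(f"removed sequences:    {len(removed)}")
print(f"recall:               {len(removed & planted) / len(planted):.3f}")
print(f"false removals:       {len(removed - planted)}")
print("\nledger head (one row per removed sequence):")
print(result.ledger.to_dataframe().head(5).to_string(index=False))
# recall 1.000 with 0 false removals means every planted leaf was caught
# by the rule written for its contamination pattern, and no genuine
# sequence was touched.
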