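"""The descriptive reports a curator uses to write removal rules.

Before writing sister or clade-grabbing rules you need to know where a
taxon's sequences tend to fall (sister-group tallies), how big its pure
clades get (clade sizes), and which gene families are well shared with
low paralogy (worth concatenating).
"""

from phylocurate.reports import (
    clade_size_summary,
    clade_sizes,
    contamination_by_sisters,
    flag_egt,
    presence_from_trees,
    shared_gfs,
)
from phylocurate.simulate import (
    default_event_suite,
    simulate_gene_trees,
    simulate_species_tree,
)
from phylocurate.tree_engine import root_tree

species = simulate_species_tree(seed=1)
sim = simulate_gene_trees(species, n_gfs=12, events=default_event_suite(species),
                          seed=3)
trees = [root_tree(t) for t in sim.gene_trees.values()]

print("== sister-group tallies for the contaminated ciliate Sr_ci_S025 ==")
df = contamination_by_sisters(trees, ["Sr_ci_S025"])
print(df[df.level == "minor"].to_string(index=False))
# repeated EE_ha (haptophyte) sisters on short branches are the signature
# that motivates a food-source sister rule for this taxon.

print("\n== ciliate clade sizes across gene trees ==")
print(clade_size_summary(clade_sizes(trees, ["Sr_ci"])).to_string(index=False))
# the typical maximal pure-clade size tells you what min_target a
# clade-grabbing rule can demand.

print("\n== gene families ranked for concatenation ==")
focal = sorted({lab[:10] for t in trees for lab in t.leaf_labels()
                if not lab.startswith(("Ba", "Za"))})
print(shared_gfs(presence_from_trees(sim.gene_trees), focal).head(5)
      .to_string(index=False))

print("\n== endosymbiotic-gene-transfer candidates ==")
flags = flag_egt(sim.gene_trees, photosynthetic_prefixes=["Pl_gr", "Sr_di", "EE_ha"],
                 min_photo_minors=2)
print(f"{len(flags)} flags (candidates for manual review)")
for f in flags[:3]:
    print(f"  {f.gf}  {f.kind}: {f.reason}")
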