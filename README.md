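# phylocurate

Phylogeny-informed curation of taxon-rich gene-family datasets: rule-driven
contamination removal on single-gene trees, ortholog selection and supermatrix
concatenation, and composition-based sequence filtering.

## The problem

Taxon-rich phylogenomics of microbial eukaryotes leans heavily on single-cell
and culture transcriptomes, which routinely carry sequences from food
organisms, hosts, symbionts, and bacteria. Left in place, these contaminants
pull whole lineages to the wrong part of the species tree. `phylocurate`
implements a transparent, repeatable alternative to hand curation: the user
writes explicit removal rules, the toolkit applies them iteratively to
single-gene trees, and **every removed sequence is recorded in a ledger**
(gene family, rule, iteration, observed sister context, branch length) that
can be published alongside the study.

All components key on a controlled naming scheme. Each taxon is a
10-character code `MM_mm_Ssss` — major clade (one of `Ba`, `Za`, `Op`, `Am`,
`Ex`, `Sr`, `Pl`, `EE`), minor clade, species/sample — e.g. humans are
`Op_me_Hsap`, *Arabidopsis thaliana* is `Pl_gr_Atha`. Sequence identifiers
start with the taxon code and end with a gene-family token (`OG6_` + six
digits; `OGG_`/`OGA_` variants mark GC-rich / AT-rich composition classes).

## The methods

**Contamination loop.** Two rule families operate on rooted gene trees, with
tree rebuilding between iterations (removing one contaminant can expose the
next):

* *Sister rules* remove a single sequence of a target taxon when its entire
  sister group matches a forbidden lineage — e.g. "remove the ciliate
  *Favella* when sister to a haptophyte, its food source" — optionally only
  when the sequence sits on a short terminal branch, below
  `multiplier × avg_node_to_tip(tree)` (default multiplier 0.5, with the
  average taken over terminal branch lengths). *Subsister rules* remove a
  known co-contaminated pair forming a cherry whose joint sister matches (or,
  in `non-X` form, fails to match) a lineage.
* *Clade grabbing* keeps, for a well-sampled lineage, only sequences inside
  monophyletic clades holding at least `min_target` distinct taxon codes
  (with a bounded non-target allowance, absolute or fractional); stray
  sequences of that lineage are removed unless they match an exception
  ("orphan") prefix. All clade statistics count distinct taxon codes, not
  sequences.

**Ortholog selection & concatenation.** For each gene family, a taxon with
several copies keeps the copy in the clade densest in the taxon's own minor
clade; within that clade the highest score wins, where
`score = length × k-mer coverage` when the assembler left a `cov_` field in
the contig ID and plain length otherwise. Rows are concatenated per taxon
with gap fill for absent gene families, and columns with at least 95% (or
50%) gaps can be masked.

**Composition curation.** Silent-site GC content (GC3S, over synonymously
variable codon families) and Wright's effective number of codons,

```
Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6 ,   F = (n·Σp² − 1)/(n − 1)
```

ranging 20 (one codon per amino acid) to 61 (uniform usage, standard code).
Sequences are labeled `OG6`/`OGG`/`OGA` against per-taxon GC3S ranges, and two
sequence filters remove within-taxon near-duplicates (global identity ≥ 0.99)
and length outliers (outside [mean/3, 1.5 × mean] of the gene family's
reference mean).

**Reports & fixtures.** Sister-pair tallies, clade-size distributions, taxon
occurrence, shared-gene-family ranking, endosymbiotic-gene-transfer (EGT)
candidate flagging, and monophyly tables across curation stages; plus a
seeded generator that builds species trees over valid codes and plants
contamination with a complete truth table, so removal recall is exactly
measurable.

## Worked example

`examples/01_contamination_loop.py` simulates 20 gene trees over 36 taxa with
54 planted contaminants (single-leaf, co-contaminant pair, and misassigned
block events), writes the matching rules, and runs the
sisters → subsisters → clade-grabbing schedule:

```
gene families:        20
planted contaminants: 54
removed sequences:    54
recall:               1.000
false removals:       0
```

A ledger row explains each removal, e.g. `Sr_ci_S025_xev1_OG6_000001` removed
at iteration 1 by rule `s_ev1` with observed context
`sisters=EE_ha_S007_c1_OG6_000001`, terminal branch 0.027 against threshold
0.049 — a ciliate sequence on a short branch sister to a haptophyte. The
other examples cover supermatrix assembly (`02`), GC3S/ENc profiling and
OG6/OGG/OGA labeling (`03`), and the rule-design reports (`04`).

A thin CLI wraps the same functions (`phylocurate contam|concat|composition|
simfilter|lenfilter|report|simulate`); every run writes a manifest JSON with
the config snapshot, input digests, seed, and output inventory.

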