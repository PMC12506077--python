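# Methods

This note documents the models, conventions, and numerical choices behind
`phylocurate`, and what the synthetic benchmark does and does not show.

## Naming scheme and counting unit

Taxon codes are 10 characters, `MM_mm_Ssss`, with the major clade drawn from
a closed set of eight tokens. Sequence identifiers are parsed positionally:
the taxon code is always the first 10 characters, the gene-family token is
the final `OG[6GA]_\d{6}` match, and the contig token is everything between —
assembler headers may embed underscores, lengths (`length_900`) and k-mer
coverage (`cov_12.5`), which the parser exposes but does not require.

Two samples of one species (`Am_tu_Hp01`, `Am_tu_Hp02`) are distinct codes.
Every clade statistic — clade sizes, allowances, `min_target`, ortholog-clade
density — counts **distinct taxon codes**, never sequences; biological
collapse of conspecific samples is left to the user because it is
data-dependent.

## Rooting and branch statistics

Sister relationships need a stable rooted frame, so trees are rooted
deterministically before rules are applied: the root goes on the edge
subtending the largest group of leaves all matching an outgroup prefix
(default `Ba`/`Za`, prokaryotes), considering both orientations of every
edge; size is in distinct codes and ties break on the lexicographically
smallest contained leaf label. Trees without a pure prokaryote group fall
back to midpoint rooting. Both strategies are deterministic.

The short-branch gate compares a leaf's terminal branch against
`multiplier × avg_node_to_tip(tree)`. "Average node-to-tip distance" is
implemented as the **mean terminal branch length over all leaves**: the gate
decides the fate of an individual leaf, so the comparable population is the
leaves' own terminal branches. The alternative reading (mean root-to-tip
depth) is available via `avg_node_to_tip(t, mode="root_to_tip")`; it yields
systematically larger thresholds and is not the default. Missing branch
lengths are treated as zero and flagged.

## Rule semantics

* A **sister rule** fires for a leaf when: the leaf matches the rule's
  target; it is the *only* target-matching leaf among its parent's leaf
  children (a same-target cherry is the subsister case, not "a single
  sequence"); every sister-group member (siblings pooled at multifurcations)
  matches a forbidden prefix *of that same rule* — a sister group mixing a
  forbidden and a non-forbidden lineage never fires, the conservative
  choice; and the branch condition holds.
* A **subsister rule** fires for a cherry whose two leaves match the pair
  (one each) when every joint-sister leaf satisfies at least one forbidden
  entry; `non-X` entries match leaves that do **not** match `X`. Complement
  prefixes are supported only here, mirroring their one natural use
  ("sister to non-Opisthokonta").
* **Clade grabbing** removes target-lineage leaves outside every qualifying
  clade. A node qualifies when it has ≥ `min_target` distinct target codes
  and its distinct non-target codes satisfy the allowance (absolute count,
  or fraction of the clade's distinct codes, closed bound). Exception
  prefixes are exempt; non-target leaves are never touched. Single leaves
  count as singleton clades, so `min_target=1` never removes anything.
* **Monophyly** is evaluated over both sides of every bipartition, making
  the answer independent of where the input tree happens to be rooted; an
  interloper allowance tolerates that many distinct non-target codes inside
  the clade.

Within one iteration, all rule firings are evaluated against the frozen
input topology and applied simultaneously, so the result does not depend on
rule order. Each phase (mode + rules + iteration budget) repeats
build-apply-remove until an iteration removes nothing; iterating matters
because pruning one contaminant can expose the next as a rule-matching
sister. Tree rebuilding between iterations is pluggable: the default prunes
the current tree to the kept leaves (deterministic); a neighbor-joining
rebuild from pairwise identity distances and an external-command template
are provided for full re-inference. With a stochastic rebuild, which
sequences are removed can vary between runs; the ledger records the exact
context of every removal either way.

## Ortholog selection and the supermatrix

The winning clade for a taxon maximizes the count of distinct codes sharing
the taxon's minor-clade prefix (a flag switches to major-level counting);
ties prefer the smallest clade (fewest leaves), then the smallest leaf-label
tuple — without the smallest-clade tie-break the tree's root would always
win, since density is monotone toward the root. Scores use the contig-ID
length × coverage when present, ungapped sequence length otherwise, and
rank-last when neither is available.

Column masking removes a column when its gap fraction is **≥** the threshold
(the "at least p% gaps" reading), with `-` and `?` as gap characters; the
partition map is re-indexed. Defaults 0.95 (strict) and 0.50 (lenient).

## Composition statistics

GC3S is the G/C fraction at third positions of codons from synonymously
variable families (family = codons of one amino acid under the given genetic
code; single-codon families and stops are excluded; ambiguous codons are
skipped; a terminal stop is trimmed). Undefined (reported as missing, never
imputed) when no codon is eligible.

ENc follows Wright: per-family homozygosity `F = (n·Σp² − 1)/(n − 1)`
averaged within degeneracy classes, `Nc = N1 + Σk Nk/F̄k` with class counts
taken from the code table, so non-standard codes re-derive their classes
automatically. Families observed fewer than twice are excluded from their
class average; a missing 3-fold class average is estimated as
`(F̄2 + F̄4)/2` (the standard convention); any other missing class leaves ENc
undefined. The value is capped at the code's sense-codon count (61), which is
also why exactly uniform finite samples report exactly 61: the unbiased
estimator fluctuates above the maximum and the cap clamps it.

GC-class labels use closed ranges on both ends: `OG6` when
`lower ≤ GC3S ≤ upper`, `OGG` above, `OGA` below; the emitted ID's
gene-family token is rewritten to carry the class.

The similarity filter is greedy in descending length (ties by ID): a
sequence is dropped iff its identity to an already-kept sequence reaches the
cutoff (default 0.99). Identity comes from a global alignment with free end
gaps; the denominator counts internal gap columns but not terminal
overhangs, so a fragment nested in a longer sequence still registers as a
near-duplicate. The relative-length filter keeps sequences within
`[mean/3, 1.5 × mean]` of the gene family's reference mean, closed bounds;
gene families missing from the reference table keep their sequences with a
logged warning.

The per-sequence homology-score cutoff (default 0.3) used by external
MSA-confidence filtering is carried as a config constant and a pluggable
hook only; no such score is computed here.

## Reports

Sister tallies classify each focal leaf's sister group at major and minor
level, pure groups under their prefix and mixed groups under `mixed`.
Shared-gene-family ranking defines sharedness as the fraction of focal taxa
present (≥ 1 sequence) and paralogy as the mean sequence count over present
taxa — the statistic is deliberately simple and documented rather than
inferred. EGT flagging is a *candidate generator for manual review*:
"primary" needs a clade of ≥ K leaves (default 4) containing only
photosynthetic eukaryotes and prokaryotes with at least one of each;
"secondary" needs ≥ M distinct photosynthetic minor clades (default 3) and
no non-photosynthetic eukaryote in the clade. The photosynthetic-lineage
list is user configuration, never hard-coded biology.

## The synthetic benchmark

The generator emulates the contamination situations the rules target, at
topology level: a species tree over valid codes (random joins with
exponential branch lengths, mean 0.1 substitutions/site; every minor and
major clade monophyletic by construction; default 36 taxa across 10 minor
clades including prokaryote outgroups), and per gene family multiplicative
log-normal branch noise (σ = 0.25), Bernoulli taxon dropout (rate 0.2),
paralog duplication (rate 0.1), and planted events: a lone recipient-labeled
leaf grafted as sole sister to a donor-lineage leaf with terminal branch
0.25 × the tree's mean terminal branch; a recipient cherry; or a block of
recipient-labeled leaves inside the donor clade. The default event suite
plants 5 single-leaf, 2 pair, and 1 block event across 20 gene families.

Two construction guarantees keep the benchmark a *clean-separation* test:
event recipients' minor clades and the rooting outgroup (`Za`) are exempt
from dropout (so genuine sequences always have same-lineage sisters, home
clades stay at full size, and rooting never lands on a donor leaf), and
donors are always genuine donor-lineage leaves, never previously planted
contaminants. Perfect recall with zero false removals on this benchmark
therefore demonstrates the *machinery* — rule evaluation, iteration,
ledgering — not performance on real data, where rule quality, tree error,
and genuine lateral transfers (which sister rules cannot distinguish from
contamination) dominate.

Coding sequences are drawn from all synonymously variable families of the
standard code in balanced counts; the silent-site GC target is met by quota
(realized GC3S differs from the target only by rounding), and a skew
parameter concentrates usage within each family's GC class without moving
GC3S, driving ENc down. No substitution-model evolution or read-level
artifacts are simulated.

All randomness flows from one integer seed, fanned out per gene family by
CRC32 hashing, so outputs are byte-identical across runs and any subset of
gene families is independently reproducible.

## Problem sizes and verification

The test suite and `scripts/acceptance.py` use sizes a laptop handles in
seconds, chosen to make the checks exhaustive rather than large: oracle
equivalence on 200 random trees of ≤ 12 leaves (where every node can be
enumerated), the 20-gene-family planted benchmark, 50 simulated genes of
150–200 codons for the ENc cross-check, and 20 random supermatrix fixtures.
The closed-form pins (ENc 61/20, GC3S boundary cases, the default
parameters) are size-independent.

## Known limitations

Rules are applied to one rooting per iteration; pathological trees whose
outgroup structure collapses to singletons can root near a contaminant and
change its sister group (the generator avoids this by construction; real
pipelines should supply trees with an adequate outgroup or use midpoint
rooting deliberately). The similarity filter is O(n²) alignments per
taxon-gene-family group. EGT flags and sister reports are descriptive; no
automatic adjudication is attempted.
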