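"""Seeded synthetic fixtures: species trees over valid taxon codes, gene
trees with planted contaminants and paralogs, and coding sequences with
controlled silent-site GC and codon-usage bias.

The generator emulates the situations the curation rules are written
for: a single-cell transcriptome picking up food-source or host
sequences (a lone short-branch leaf grafted inside the donor lineage), a
pair of co-contaminated libraries (a cherry of two recipient-labeled
leaves inside the donor lineage), and a wholesale misassignment (a block
of recipient-labeled leaves nested in the donor clade, as when rumen
ciliate libraries carry parabasalid transcripts). Each planted leaf is
recorded in a truth table, so removal recall and false-removal rates are
exactly measurable.

Gene trees are the species tree with per-branch multiplicative
log-normal noise, Bernoulli taxon dropout and optional paralog
duplications — a topology-level model, not a coalescent: the curation
logic responds to topological patterns, not to population-genetic
branch-length distributions. Leaves that a planted event depends on
(the recipient's minor clade, so genuine sequences always have
same-lineage sisters and full-size home clades) are exempt from dropout.

All randomness flows from one integer seed, fanned out to per-gene
streams by stable hashing, so any subset of gene families is
reproducible independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phylocurate.contamination import CladeRule, SisterRule, SubsisterRule
from phylocurate.taxon_codes import matches_prefix, parse_taxon_code
from phylocurate.tree_engine import GeneTree

DEFAULT_TAXON_COUNTS = {
    "Ba_pr": 3, "Za_eu": 3,
    "Op_me": 5, "Op_fu": 3,
    "Sr_ci": 6, "Sr_di": 3,
    "Ex_pa": 3, "Am_tu": 3,
    "Pl_gr": 4, "EE_ha": 3,
}


class SimulationError(ValueError):
    pass


def _subseed(seed: int, token: str) -> int:
    return zlib.crc32(f"{seed}:{token}".encode()) & 0x7FFFFFFF


def _join_random(subtrees: list[str], rng: np.random.Generator, mean_branch: float) -> str:
    """Random sequential joins with exponential branch lengths; parts are
    subtree strings without an outer edge length."""
    parts = list(subtrees)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b1 = rng.exponential(mean_branch)
        b2 = rng.exponential(mean_branch)
        merged = f"({parts[i]}:{b1:.6f},{parts[j]}:{b2:.6f})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0]


def simulate_species_tree(
    taxon_counts: Mapping[str, int] | None = None,
    seed: int = 0,
    mean_branch: float = 0.1,
) -> GeneTree:
    """A random species tree whose leaves are valid 10-character taxon
    codes, with every minor clade (and major clade) monophyletic by
    construction. ``taxon_counts`` maps minor-clade prefixes (``Op_me``)
    to taxon counts."""
    counts = dict(taxon_counts or DEFAULT_TAXON_COUNTS)
    if sum(counts.values()) < 3:
        raise SimulationError("need at least 3 taxa")
    for minor, n in counts.items():
        if n < 1:
            raise SimulationError(f"minor clade {minor}: count must be positive")
        parse_taxon_code(minor + "_S000")  # validates the prefix
    rng = np.random.default_rng(seed)
    idx = 0
    majors: dict[str, list[str]] = {}
    for minor in sorted(counts):
        leaves = []
        for _ in range(counts[minor]):
            leaves.append(f"{minor}_S{idx:03d}")
            idx += 1
        sub = _join_random(leaves, rng, mean_branch)
        majors.setdefault(minor[:2], []).append(sub)
    major_subtrees = [
        _join_random(subs, rng, mean_branch) for _, subs in sorted(majors.items())
    ]
    newick = _join_random(major_subtrees, rng, mean_branch) + ";"
    return GeneTree.from_newick_string(newick, validate=False)


@dataclass(frozen=True)
class ContaminationEvent:
    """One planted contamination pattern.

    ``sister_single``: one recipient-labeled leaf grafted as sole sister
    to a donor-lineage leaf, terminal branch = ``terminal_branch_scale``
    × the tree's mean terminal branch. ``cherry_pair``: a cherry of
    recipient + partner leaves grafted likewise. ``misassigned_clade``:
    ``block_size`` recipient-labeled leaves grafted as a block.
    """

    event_id: str
    recipient_taxon: str
    donor_prefix: str
    mode: str  # sister_single | cherry_pair | misassigned_clade
    terminal_branch_scale: float = 0.25
    n_gfs_affected: int = 1
    block_size: int = 6
    partner_taxon: str | None = None

    def __post_init__(self):
        if self.mode not in ("sister_single", "cherry_pair", "misassigned_clade"):
            raise SimulationError(f"unknown event mode {self.mode!r}")
        if matches_prefix(self.recipient_taxon, self.donor_prefix):
            raise SimulationError(
                f"event {self.event_id}: recipient inside donor lineage"
            )
        if self.terminal_branch_scale <= 0:
            raise SimulationError(f"event {self.event_id}: scale must be positive")
        if self.mode == "cherry_pair" and (
            self.partner_taxon is None or self.partner_taxon == self.recipient_taxon
        ):
            raise SimulationError(
                f"event {self.event_id}: cherry_pair needs a distinct partner_taxon"
            )


@dataclass
class SimulatedSet:
    species_tree: GeneTree
    gene_trees: dict[str, GeneTree]
    truth: pd.DataFrame  # columns: gf, seq_id, is_contaminant, event_id
    events: list[ContaminationEvent] = field(default_factory=list)

    def planted_ids(self) -> set[tuple[str, str]]:
        mask = self.truth["is_contaminant"]
        return set(zip(self.truth.loc[mask, "gf"], self.truth.loc[mask, "seq_id"]))


def _mean_terminal(tree) -> float:
    tips = [lf.edge.length or 0.0 for lf in tree.leaf_node_iter()]
    return sum(tips) / len(tips) if tips else 0.0


def _graft(tree, donor_leaf, new_labels: Sequence[str], branch_len: float):
    """Insert ``new_labels`` as the sister subtree of ``donor_leaf``: one
    label becomes a lone leaf, two a cherry, more a caterpillar block."""
    parent = donor_leaf.parent_node
    orig = donor_leaf.edge.length or 0.0
    parent.remove_child(donor_leaf)
    joint = parent.new_child(edge_length=orig / 2.0)
    joint.add_child(donor_leaf)
    donor_leaf.edge.length = orig / 2.0
    ns = tree.taxon_namespace
    if len(new_labels) == 1:
        joint.new_child(taxon=ns.new_taxon(new_labels[0]), edge_length=branch_len)
        return
    node = joint.new_child(edge_length=branch_len)
    remaining = list(new_labels)
    while len(remaining) > 2:
        lab = remaining.pop()
        node.new_child(taxon=ns.new_taxon(lab), edge_length=branch_len)
        node = node.new_child(edge_length=branch_len / 2.0)
    for lab in remaining:
        node.new_child(taxon=ns.new_taxon(lab), edge_length=branch_len)


def simulate_gene_trees(
    species_tree: GeneTree,
    n_gfs: int,
    events: Sequence[ContaminationEvent] = (),
    paralog_rate: float = 0.1,
    dropout_rate: float = 0.2,
    branch_noise_sigma: float = 0.25,
    seed: int = 0,
    gf_start: int = 1,
    outgroup_protect: tuple[str, ...] = ("Za",),
) -> SimulatedSet:
    """Gene trees derived from a species tree, with planted contaminants
    recorded in a truth table.

    Per gene family: branch lengths get multiplicative log-normal noise;
    unprotected taxa drop out independently (always keeping ≥4 leaves);
    paralogs duplicate a leaf as a cherry; then each event assigned to
    this gene family grafts its contaminant leaves inside the donor
    lineage. Leaves matching ``outgroup_protect`` are exempt from
    dropout so every gene tree keeps an uncontaminated outgroup clade
    and rooting stays stable (plant no events with donors there).
    """
    codes = [lab for lab in species_tree.leaf_labels()]
    protected: set[str] = {
        c for c in codes if any(matches_prefix(c, p) for p in outgroup_protect)
    }
    for ev in events:
        recips = [ev.recipient_taxon] + ([ev.partner_taxon] if ev.partner_taxon else [])
        for r in recips:
            if r not in codes:
                raise SimulationError(f"event {ev.event_id}: {r} not in species tree")
            minor = r[:5]
            protected.update(c for c in codes if c.startswith(minor))
        if not any(matches_prefix(c, ev.donor_prefix) for c in codes):
            raise SimulationError(f"event {ev.event_id}: no donor {ev.donor_prefix} leaves")

    gf_ids = [f"OG6_{gf_start + i:06d}" for i in range(n_gfs)]
    assign_rng = np.random.default_rng(_subseed(seed, "assign"))
    assignment: dict[str, list[ContaminationEvent]] = {gf: [] for gf in gf_ids}
    for ev in events:
        n_aff = min(ev.n_gfs_affected, n_gfs)
        chosen = assign_rng.choice(n_gfs, size=n_aff, replace=False)
        for i in sorted(chosen):
            assignment[gf_ids[i]].append(ev)

    base_newick = species_tree.as_newick()
    gene_trees: dict[str, GeneTree] = {}
    truth_rows: list[dict] = []
    for gf in gf_ids:
        rng = np.random.default_rng(_subseed(seed, gf))
        gt = GeneTree.from_newick_string(base_newick, validate=False)
        tree = gt.tree
        for edge in tree.preorder_edge_iter():
            if edge.head_node.parent_node is None:
                continue
            length = edge.length or 0.0
            edge.length = length * float(rng.lognormal(0.0, branch_noise_sigma))
        # dropout (never below 4 leaves, never a protected taxon)
        droppable = [c for c in codes if c not in protected]
        drops = [c for c in droppable if rng.random() < dropout_rate]
        max_drops = max(0, len(codes) - 4)
        drops = drops[:max_drops]
        if drops and len(drops) < len(codes):
            gt = gt.without_leaves(drops)
            tree = gt.tree
        # relabel to full sequence IDs
        counter = 1
        relabel: dict[str, str] = {}
        for lf in tree.leaf_node_iter():
            code = lf.taxon.label
            new = f"{code}_c{counter}_{gf}"
            relabel[code] = new
            lf.taxon = tree.taxon_namespace.new_taxon(new)
            counter += 1
        # paralogs: duplicate a leaf as a cherry of the same taxon code
        for lf in list(tree.leaf_node_iter()):
            if rng.random() < paralog_rate:
                lab = lf.taxon.label
                code = lab[:10]
                dup = f"{code}_c{counter}_{gf}"
                counter += 1
                _graft(tree, lf, [dup], max(lf.edge.length or 0.0, 1e-6))
        for row_label in [lf.taxon.label for lf in tree.leaf_node_iter()]:
            truth_rows.append(
                {"gf": gf, "seq_id": row_label, "is_contaminant": False, "event_id": ""}
            )
        # plant contamination; donors are genuine donor-lineage leaves,
        # never contaminants planted by an earlier event
        planted_here: set[str] = set()
        for ev in assignment[gf]:
            donor_leaves = sorted(
                lf.taxon.label for lf in tree.leaf_node_iter()
                if matches_prefix(lf.taxon.label[:10], ev.donor_prefix)
                and lf.taxon.label[:10] != ev.recipient_taxon
                and lf.taxon.label not in planted_here
            )
            if not donor_leaves:
                continue
            pick = donor_leaves[int(rng.integers(len(donor_leaves)))]
            donor_node = next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label == pick
            )
            blen = ev.terminal_branch_scale * _mean_terminal(tree)
            if ev.mode == "sister_single":
                labels = [f"{ev.recipient_taxon}_x{ev.event_id}_{gf}"]
            elif ev.mode == "cherry_pair":
                labels = [
                    f"{ev.recipient_taxon}_x{ev.event_id}_{gf}",
                    f"{ev.partner_taxon}_x{ev.event_id}_{gf}",
                ]
            else:  # misassigned_clade
                labels = [
                    f"{ev.recipient_taxon}_x{ev.event_id}b{k}_{gf}"
                    for k in range(ev.block_size)
                ]
            _graft(tree, donor_node, labels, max(blen, 1e-9))
            planted_here.update(labels)
            for lab in labels:
                truth_rows.append(
                    {"gf": gf, "seq_id": lab, "is_contaminant": True,
                     "event_id": ev.event_id}
                )
        gene_trees[gf] = GeneTree.from_newick_string(
            tree.as_string(schema="newick", unquoted_underscores=True,
                           suppress_rooting=True),
            validate=True,
        )
    truth = pd.DataFrame(truth_rows, columns=["gf", "seq_id", "is_contaminant", "event_id"])
    return SimulatedSet(
        species_tree=species_tree, gene_trees=gene_trees, truth=truth,
        events=list(events),
    )


def rules_for_events(
    events: Sequence[ContaminationEvent],
    species_tree: GeneTree,
    sister_branch_mode: str = "short",
    sister_multiplier: float = 0.5,
    clade_allowance: float | int = 0,
) -> tuple[list[SisterRule], list[SubsisterRule], list[CladeRule]]:
    """The rule set a curator would write knowing the planted events:
    one sister rule per single-leaf event, one subsister rule per
    co-contaminant pair, and one clade rule per misassignment (minimum
    clade size = the recipient minor clade's true taxon count)."""
    codes = species_tree.leaf_labels()
    sisters, subsisters, clades = [], [], []
    for ev in events:
        if ev.mode == "sister_single":
            sisters.append(
                SisterRule(
                    rule_id=f"s_{ev.event_id}", target=ev.recipient_taxon,
                    forbidden_sisters=(ev.donor_prefix,),
                    branch_mode=sister_branch_mode, multiplier=sister_multiplier,
                )
            )
        elif ev.mode == "cherry_pair":
            major = ev.recipient_taxon[:2]
            subsisters.append(
                SubsisterRule(
                    rule_id=f"ss_{ev.event_id}",
                    pair=(ev.recipient_taxon, ev.partner_taxon),
                    forbidden_joint_sisters=(f"non-{major}",),
                )
            )
        else:
            minor = ev.recipient_taxon[:5]
            n_true = len({c for c in codes if c.startswith(minor)})
            clades.append(
                CladeRule(
                    rule_id=f"c_{ev.event_id}", target=minor,
                    min_target=n_true, nontarget_allowance=clade_allowance,
                )
            )
    return sisters, subsisters, clades


def load_sim_spec(path) -> dict:
    """Load a YAML simulation spec: optional ``taxon_counts`` (minor
    prefix -> count), an ``events`` list (ContaminationEvent fields), and
    optional ``paralog_rate`` / ``dropout_rate`` / ``n_gfs``. See
    ``examples/simulation_spec.yaml`` for a commented template."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    spec = {
        "taxon_counts": raw.get("taxon_counts"),
        "n_gfs": int(raw.get("n_gfs", 20)),
        "paralog_rate": float(raw.get("paralog_rate", 0.1)),
        "dropout_rate": float(raw.get("dropout_rate", 0.2)),
        "events": [ContaminationEvent(**ev) for ev in raw.get("events", [])],
    }
    return spec


def default_event_suite(species_tree: GeneTree) -> list[ContaminationEvent]:
    """The standard planted-contamination benchmark: five single-leaf
    events (food-source and prokaryote contamination), two co-contaminant
    pairs, and one wholesale misassignment of a well-sampled lineage into
    an unrelated clade."""
    codes = species_tree.leaf_labels()

    def pick(minor: str, i: int) -> str:
        members = sorted(c for c in codes if c.startswith(minor))
        return members[i]

    return [
        ContaminationEvent("ev1", pick("Sr_ci", 1), "EE_ha", "sister_single",
                           n_gfs_affected=4),
        ContaminationEvent("ev2", pick("Sr_ci", 2), "Ba_pr", "sister_single",
                           n_gfs_affected=4),
        ContaminationEvent("ev3", pick("Op_me", 2), "Ba_pr", "sister_single",
                           n_gfs_affected=4),
        ContaminationEvent("ev4", pick("Pl_gr", 0), "Ba_pr", "sister_single",
                           n_gfs_affected=4),
        ContaminationEvent("ev5", pick("Sr_di", 0), "Ba_pr", "sister_single",
                           n_gfs_affected=4),
        ContaminationEvent("ev6", pick("Op_fu", 0), "Am_tu", "cherry_pair",
                           partner_taxon=pick("Op_fu", 1), n_gfs_affected=4),
        ContaminationEvent("ev7", pick("Op_me", 0), "Sr_di", "cherry_pair",
                           partner_taxon=pick("Op_me", 1), n_gfs_affected=4),
        ContaminationEvent("ev8", pick("Sr_ci", 0), "Ex_pa", "misassigned_clade",
                           block_size=6, n_gfs_affected=3),
    ]


# ---------------------------------------------------------------------------
# Coding sequences with controlled composition


@dataclass(frozen=True)
class CdsProfile:
    """Composition target for one taxon's genes.

    ``target_gc3s`` fixes the silent-site GC fraction by quota (the
    realized value differs from the target only by third-position
    rounding); ``None`` means uniform usage within every synonymous
    family, the no-bias limit where ENc approaches its maximum.
    ``skew`` in [0, 1) concentrates usage on one codon per within-family
    GC class (0 = uniform in class, near 1 = maximal bias, low ENc)
    without moving GC3S.
    """

    taxon: str
    target_gc3s: float | None
    skew: float = 0.0
    n_genes: int = 5
    length_codons: int = 300

    def __post_init__(self):
        if self.target_gc3s is not None and not (0.0 <= self.target_gc3s <= 1.0):
            raise SimulationError(f"target_gc3s {self.target_gc3s} outside [0,1]")
        if not (0.0 <= self.skew < 1.0):
            raise SimulationError(f"skew {self.skew} outside [0,1)")


def _variable_families(table_id: int = 1):
    """(aa, GC-ending codons, AT-ending codons) for every synonymously
    variable family of the genetic code; every such family under the
    standard code has codons in both classes."""
    from phylocurate.composition import _code_families

    fams, _ = _code_families(table_id)
    out = []
    for aa in sorted(fams):
        codons = fams[aa]
        if len(codons) < 2:
            continue
        gc = tuple(c for c in codons if c[2] in "GC")
        at = tuple(c for c in codons if c[2] in "AT")
        out.append((aa, gc, at))
    return out


def simulate_cds(
    profiles: Sequence[CdsProfile],
    seed: int = 0,
    gf_start: int = 9000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Stop-free coding sequences covering every degeneracy class of the
    standard code, with silent-site GC set by quota per gene. Returns
    (sequences keyed by seq ID, truth table with the generating
    profile)."""
    rng = np.random.default_rng(seed)
    families = _variable_families()
    nf = len(families)
    seqs: dict[str, str] = {}
    rows = []
    gf_i = gf_start
    for prof in profiles:
        length = prof.length_codons
        s = prof.skew
        for j in range(prof.n_genes):
            # balanced family counts keep every class observed
            fam_idx = np.tile(np.arange(nf), length // nf + 1)[:length].copy()
            rng.shuffle(fam_idx)
            if prof.target_gc3s is None:
                is_gc = None
            else:
                n_gc = int(round(prof.target_gc3s * length))
                is_gc = np.zeros(length, dtype=bool)
                is_gc[:n_gc] = True
                rng.shuffle(is_gc)
            codons = []
            for pos in range(length):
                aa, gc_pool, at_pool = families[fam_idx[pos]]
                if is_gc is None:
                    pool = gc_pool + at_pool
                else:
                    pool = gc_pool if is_gc[pos] else at_pool
                if s > 0 and len(pool) > 1:
                    w = np.full(len(pool), (1 - s) / len(pool))
                    w[0] += s
                    codons.append(pool[int(rng.choice(len(pool), p=w))])
                else:
                    codons.append(pool[int(rng.integers(len(pool)))])
            seq = "ATG" + "".join(codons)
            sid = f"{prof.taxon}_g{j + 1}_OG6_{gf_i:06d}"
            gf_i += 1
            seqs[sid] = seq
            rows.append(
                {"seq_id": sid, "taxon": prof.taxon,
                 "target_gc3s": prof.target_gc3s, "skew": s}
            )
    truth = pd.DataFrame(rows, columns=["seq_id", "taxon", "target_gc3s", "skew"])
    return seqs, truth


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid in sequences:
            fh.write(f">{sid}\n{sequences[sid]}\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
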