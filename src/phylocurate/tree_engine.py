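"""Gene-tree IO and the topological primitives the curation rules consume.

Trees are Newick gene trees whose leaf labels are full sequence
identifiers (see :mod:`phylocurate.taxon_codes`). All clade statistics
count *distinct taxon codes*, not sequences: a clade with three sequences
from two samples has size two.

Built on dendropy; a :class:`GeneTree` owns a rooted dendropy tree plus a
cache of parsed leaf identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import dendropy

from phylocurate.taxon_codes import (
    CladePrefix,
    SeqID,
    matches_any,
    matches_prefix,
    parse_seq_id,
)

DEFAULT_OUTGROUP_PREFIXES = ("Ba", "Za")


class TreeError(ValueError):
    pass


@dataclass
class GeneTree:
    """A single-gene tree over sequence identifiers.

    Branch lengths may be absent in the source Newick; they are then
    treated as zero and ``lengths_present`` is False.
    """

    tree: dendropy.Tree
    gf: str | None = None
    lengths_present: bool = True
    _seq_ids: dict[str, SeqID] = field(default_factory=dict, repr=False)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, validate: bool = True) -> "GeneTree":
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        seen: set[str] = set()
        seq_ids: dict[str, SeqID] = {}
        for lab in labels:
            if lab in seen:
                raise TreeError(f"duplicate leaf label {lab!r}")
            seen.add(lab)
            if validate:
                try:
                    seq_ids[lab] = parse_seq_id(lab)
                except Exception as exc:
                    raise TreeError(f"leaf label {lab!r} is not a valid sequence id: {exc}")
        lengths_present = any(
            e.length is not None for e in tree.preorder_edge_iter() if e.head_node.parent_node
        )
        gfs = {sid.gf for sid in seq_ids.values()}
        gf = gfs.pop() if len(gfs) == 1 else None
        return cls(tree=tree, gf=gf, lengths_present=lengths_present, _seq_ids=seq_ids)

    @classmethod
    def from_newick_string(cls, s: str, validate: bool = True) -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=s, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise TreeError(f"failed to parse Newick: {exc}") from exc
        return cls.from_dendropy(tree, validate=validate)

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def seq_id(self, label: str) -> SeqID:
        if label not in self._seq_ids:
            self._seq_ids[label] = parse_seq_id(label)
        return self._seq_ids[label]

    def taxon_code(self, label: str) -> str:
        return label[:10]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def find_leaf(self, label: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise TreeError(f"leaf {label!r} not found in tree")

    def copy(self) -> "GeneTree":
        return GeneTree.from_newick_string(self.as_newick(), validate=False)

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", unquoted_underscores=True,
            suppress_rooting=True,
        ).strip()

    def without_leaves(self, labels: Iterable[str]) -> "GeneTree":
        """A new tree with the given leaves pruned (lengths preserved,
        unifurcations suppressed)."""
        drop = set(labels)
        keep = [lab for lab in self.leaf_labels() if lab not in drop]
        if len(keep) == 0:
            raise TreeError("cannot prune all leaves from a tree")
        sub = self.tree.extract_tree_with_taxa_labels(labels=keep)
        return GeneTree.from_dendropy(sub, validate=False)


@dataclass
class CladeHit:
    """A maximal monophyletic clade satisfying a non-target allowance."""

    gf: str | None
    node: dendropy.Node
    target_count: int
    nontarget_count: int
    leaf_labels: tuple[str, ...]


def read_newick(path, validate: bool = True) -> list[GeneTree]:
    """Read one or more Newick trees (one per line or concatenated).

    Leaf labels are preserved verbatim and must parse as sequence
    identifiers; duplicates within a tree are an error.
    """
    try:
        tlist = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError flavours
        raise TreeError(f"failed to parse Newick file {path}: {exc}") from exc
    return [GeneTree.from_dendropy(t, validate=validate) for t in tlist]


def write_newick(trees: Iterable[GeneTree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_newick() + "\n")


def _edge_len(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def root_tree(
    t: GeneTree,
    strategy: Literal["outgroup_prefixes", "midpoint"] = "outgroup_prefixes",
    outgroup_prefixes: Iterable[str] = DEFAULT_OUTGROUP_PREFIXES,
) -> GeneTree:
    """Root a gene tree deterministically.

    With ``outgroup_prefixes`` (default Ba/Za, i.e. prokaryotes), the root
    is placed on the edge subtending the largest group of leaves that all
    match one of the prefixes — considering both orientations of every
    edge, so a "clade" of outgroup leaves wrapping around the input rooting
    is found too. Size is counted in distinct taxon codes; ties break on
    the lexicographically smallest contained leaf label. Falls back to
    midpoint rooting when no pure outgroup group exists.
    """
    if t.n_leaves() < 3:
        raise TreeError("rooting requires at least 3 leaves")
    work = t.copy()
    tree = work.tree
    if strategy == "outgroup_prefixes":
        prefixes = list(outgroup_prefixes)
        all_leaves = set(work.leaf_labels())
        best = None  # (size, min_label, node, side)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            above = all_leaves - below
            for side_labels, side in ((below, "below"), (above, "above")):
                if not side_labels:
                    continue
                if all(matches_any(lab[:10], prefixes) for lab in side_labels):
                    size = len({lab[:10] for lab in side_labels})
                    key = (-size, min(side_labels))
                    if best is None or key < best[0]:
                        best = (key, node, side)
        if best is not None:
            _, node, _ = best
            length = _edge_len(node)
            tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
            tree.is_rooted = True
            return GeneTree.from_dendropy(tree, validate=False)
        strategy = "midpoint"
    if strategy == "midpoint":
        if work.lengths_present:
            for e in tree.preorder_edge_iter():
                if e.head_node.parent_node is not None and e.length is None:
                    e.length = 0.0
            tree.reroot_at_midpoint(update_bipartitions=False)
        tree.is_rooted = True
        return GeneTree.from_dendropy(tree, validate=False)
    raise TreeError(f"unknown rooting strategy {strategy!r}")


def avg_node_to_tip(t: GeneTree, mode: Literal["terminal", "root_to_tip"] = "terminal") -> float:
    """Average node-to-tip distance used to gate short-branch removal.

    Default mode averages each leaf's own terminal branch length (the
    statistic the short-branch rule compares a leaf against); the
    alternative averages full root-to-tip path lengths.
    """
    leaves = [lf for lf in t.tree.leaf_node_iter()]
    if not leaves:
        return 0.0
    if mode == "terminal":
        return sum(_edge_len(lf) for lf in leaves) / len(leaves)
    if mode == "root_to_tip":
        total = 0.0
        for lf in leaves:
            d = 0.0
            node = lf
            while node.parent_node is not None:
                d += _edge_len(node)
                node = node.parent_node
            total += d
        return total / len(leaves)
    raise TreeError(f"unknown mode {mode!r}")


def sister_group(t: GeneTree, leaf_label: str) -> set[str]:
    """Leaf labels of the sibling subtree(s) of a query leaf; siblings are
    pooled at multifurcations."""
    leaf = t.find_leaf(leaf_label)
    parent = leaf.parent_node
    if parent is None:
        return set()
    out: set[str] = set()
    for child in parent.child_nodes():
        if child is leaf:
            continue
        out.update(lf.taxon.label for lf in child.leaf_iter())
    return out


def cherry_partner(t: GeneTree, leaf_label: str) -> str | None:
    """The other member of the query's two-leaf cherry, or None."""
    leaf = t.find_leaf(leaf_label)
    parent = leaf.parent_node
    if parent is None:
        return None
    children = parent.child_nodes()
    if len(children) != 2 or not all(c.is_leaf() for c in children):
        return None
    other = children[0] if children[1] is leaf else children[1]
    return other.taxon.label


def _clade_code_counts(labels: Iterable[str], target: CladePrefix | str):
    tcodes: set[str] = set()
    ncodes: set[str] = set()
    for lab in labels:
        code = lab[:10]
        (tcodes if matches_prefix(code, target) else ncodes).add(code)
    return tcodes, ncodes


def check_allowance(n_target: int, n_nontarget: int, allowance: float | int) -> bool:
    """Non-target allowance: an int is an absolute cap on distinct
    non-target codes; a float in [0,1] is a fraction of the clade's
    distinct codes."""
    if isinstance(allowance, bool) or allowance is None:
        raise TreeError(f"malformed allowance {allowance!r}")
    if isinstance(allowance, float):
        if not (0.0 <= allowance <= 1.0):
            raise TreeError(f"fractional allowance {allowance} outside [0, 1]")
        return n_nontarget <= allowance * (n_target + n_nontarget)
    if allowance < 0:
        raise TreeError(f"negative allowance {allowance}")
    return n_nontarget <= allowance


def enumerate_clades(
    t: GeneTree,
    target: CladePrefix | str,
    max_nontarget: float | int = 0,
) -> list[CladeHit]:
    """All *maximal* clades containing the target lineage within the
    non-target allowance.

    A node qualifies when ≥1 descendant leaf matches the target prefix and
    its distinct non-target codes satisfy the allowance; maximal means not
    nested inside another qualifying node. Single leaves count as
    singleton clades. Counts are distinct taxon codes.
    """
    check_allowance(1, 0, max_nontarget)  # validates the allowance itself
    hits: list[CladeHit] = []

    def visit(node: dendropy.Node) -> None:
        labels = tuple(lf.taxon.label for lf in node.leaf_iter())
        tcodes, ncodes = _clade_code_counts(labels, target)
        if tcodes and check_allowance(len(tcodes), len(ncodes), max_nontarget):
            hits.append(
                CladeHit(
                    gf=t.gf, node=node, target_count=len(tcodes),
                    nontarget_count=len(ncodes), leaf_labels=labels,
                )
            )
            return  # maximal: do not descend
        for child in node.child_nodes():
            visit(child)

    visit(t.tree.seed_node)
    return hits


def is_monophyletic(
    t: GeneTree,
    target: CladePrefix | str,
    allowed_interlopers: int = 0,
) -> bool:
    """Whether all target-prefix leaves form one clade, tolerating up to
    ``allowed_interlopers`` distinct non-target codes inside it.

    Evaluated over both sides of every bipartition, so the answer does not
    depend on where the input tree happens to be rooted.
    """
    all_labels = t.leaf_labels()
    target_leaves = {lab for lab in all_labels if matches_prefix(lab[:10], target)}
    if not target_leaves:
        raise TreeError(f"no leaves match target prefix {target}")
    all_set = set(all_labels)
    for node in t.tree.preorder_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        for side in (below, all_set - below):
            if not target_leaves <= side:
                continue
            interloper_codes = {lab[:10] for lab in side - target_leaves}
            if len(interloper_codes) <= allowed_interlopers:
                return True
    return False
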