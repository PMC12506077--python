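"""Iterative, rule-driven removal of contaminant sequences from gene trees.

Two removal philosophies operate on rooted single-gene trees:

* **sisters / subsisters** — remove a single sequence (or a known
  co-contaminant pair forming a cherry) whose entire sister group matches
  a forbidden lineage, optionally only when the sequence sits on a short
  terminal branch (below ``multiplier`` × the tree's average node-to-tip
  distance). This targets, e.g., food-source contamination in single-cell
  transcriptomes of predatory ciliates.

* **clade grabbing** — for a well-sampled lineage, retain only sequences
  that fall inside monophyletic clades holding at least ``min_target``
  distinct taxon codes of that lineage (with a bounded non-target
  allowance); everything else from the lineage is treated as contamination
  unless it matches an exception ("orphan") prefix.

Rules are applied iteratively with a pluggable tree-rebuild callback,
because removing one contaminant can expose the next. Every removal is
recorded in a :class:`RemovalLedger` so curation is fully publishable.

Within one iteration all rule firings are evaluated against the frozen
input topology and applied simultaneously, making the outcome independent
of rule order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd

from phylocurate.taxon_codes import matches_any, matches_prefix
from phylocurate.tree_engine import (
    GeneTree,
    TreeError,
    avg_node_to_tip,
    check_allowance,
    enumerate_clades,
    root_tree,
)

logger = logging.getLogger(__name__)


class RuleError(ValueError):
    pass


@dataclass(frozen=True)
class SisterRule:
    """Remove a single target sequence whose whole sister group is
    forbidden; ``branch_mode='short'`` additionally requires a terminal
    branch below ``multiplier`` × average node-to-tip distance."""

    rule_id: str
    target: str
    forbidden_sisters: tuple[str, ...]
    branch_mode: Literal["any", "short"] = "any"
    multiplier: float = 0.5

    def __post_init__(self):
        if not self.forbidden_sisters:
            raise RuleError(f"rule {self.rule_id}: empty forbidden-sister list")
        if self.multiplier <= 0:
            raise RuleError(f"rule {self.rule_id}: multiplier must be positive")
        if self.branch_mode not in ("any", "short"):
            raise RuleError(f"rule {self.rule_id}: bad branch_mode {self.branch_mode!r}")


@dataclass(frozen=True)
class SubsisterRule:
    """Remove a co-contaminant pair forming a cherry whose joint sister
    group matches every forbidden prefix; entries of the form ``non-X``
    match any leaf that does *not* match X."""

    rule_id: str
    pair: tuple[str, str]
    forbidden_joint_sisters: tuple[str, ...]

    def __post_init__(self):
        if self.pair[0] == self.pair[1]:
            raise RuleError(f"rule {self.rule_id}: pair members must differ")
        if not self.forbidden_joint_sisters:
            raise RuleError(f"rule {self.rule_id}: empty forbidden list")


@dataclass(frozen=True)
class CladeRule:
    """Keep target-lineage sequences only inside clades with at least
    ``min_target`` distinct target codes (allowance caps non-target
    codes); exception prefixes are never removed."""

    rule_id: str
    target: str
    min_target: int
    nontarget_allowance: float | int = 0
    exceptions: tuple[str, ...] = ()

    def __post_init__(self):
        if self.min_target < 1:
            raise RuleError(f"rule {self.rule_id}: min_target must be >= 1")
        check_allowance(1, 0, self.nontarget_allowance)


@dataclass(frozen=True)
class LedgerRow:
    gf: str
    seq_id: str
    iteration: int
    mode: Literal["sister", "subsister", "clade"]
    rule_id: str
    observed_context: str
    terminal_branch_length: float
    threshold_applied: float | None


LEDGER_COLUMNS = (
    "gf", "seq_id", "iteration", "mode", "rule_id",
    "observed_context", "terminal_branch_length", "threshold_applied",
)


class RemovalLedger:
    """The transparency record: exactly one row per removed sequence."""

    def __init__(self) -> None:
        self.rows: list[LedgerRow] = []
        self._seen: set[tuple[str, str]] = set()

    def add(self, row: LedgerRow) -> None:
        key = (row.gf, row.seq_id)
        if key in self._seen:
            raise RuleError(f"duplicate ledger entry for {key}")
        self._seen.add(key)
        self.rows.append(row)

    def extend(self, rows: Iterable[LedgerRow]) -> None:
        for r in rows:
            self.add(r)

    def __len__(self) -> int:
        return len(self.rows)

    def removed_ids(self, gf: str | None = None) -> set[str]:
        return {r.seq_id for r in self.rows if gf is None or r.gf == gf}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows], columns=list(LEDGER_COLUMNS))

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _matches_forbidden_entry(code: str, entry: str) -> bool:
    if entry.startswith("non-"):
        return not matches_prefix(code, entry[4:])
    return matches_prefix(code, entry)


def apply_sister_rules(
    t: GeneTree,
    rules: Sequence[SisterRule],
    branch_stat: str = "terminal",
) -> list[LedgerRow]:
    """Evaluate all sister rules on the frozen topology; removals are
    returned, not applied.

    A rule fires for a leaf when (i) the leaf matches the rule's target
    and is the only target-matching leaf among its parent's leaf children
    ("single sequences" — a same-target cherry is subsister territory),
    (ii) every sister-group member matches a forbidden prefix *of that
    rule*, and (iii) the branch condition holds.
    """
    removals: list[LedgerRow] = []
    mean_tip = avg_node_to_tip(t, mode=branch_stat)
    gf = t.gf or ""
    taken: set[str] = set()
    for leaf in t.tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in taken:
            continue
        parent = leaf.parent_node
        if parent is None:
            continue
        sisters = [
            lf.taxon.label
            for child in parent.child_nodes() if child is not leaf
            for lf in child.leaf_iter()
        ]
        if not sisters:
            continue
        leaf_children = [c.taxon.label for c in parent.child_nodes() if c.is_leaf()]
        for rule in rules:
            if not matches_prefix(label[:10], rule.target):
                continue
            n_target_leafchildren = sum(
                1 for lab in leaf_children if matches_prefix(lab[:10], rule.target)
            )
            if n_target_leafchildren != 1:
                continue
            if not all(matches_any(lab[:10], rule.forbidden_sisters) for lab in sisters):
                continue
            blen = leaf.edge.length or 0.0
            threshold = None
            if rule.branch_mode == "short":
                threshold = rule.multiplier * mean_tip
                if not blen < threshold:
                    continue
            removals.append(
                LedgerRow(
                    gf=gf, seq_id=label, iteration=0, mode="sister",
                    rule_id=rule.rule_id,
                    observed_context="sisters=" + ",".join(sorted(sisters)),
                    terminal_branch_length=blen, threshold_applied=threshold,
                )
            )
            taken.add(label)
            break
    return removals


def apply_subsister_rules(
    t: GeneTree,
    rules: Sequence[SubsisterRule],
) -> list[LedgerRow]:
    """Evaluate subsister (co-contaminant cherry) rules on the frozen
    topology."""
    removals: list[LedgerRow] = []
    gf = t.gf or ""
    taken: set[str] = set()
    for node in t.tree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) != 2 or not all(c.is_leaf() for c in children):
            continue
        a, b = (c.taxon.label for c in children)
        if a in taken or b in taken:
            continue
        parent = node.parent_node
        if parent is None:
            continue
        joint_sisters = [
            lf.taxon.label
            for sib in parent.child_nodes() if sib is not node
            for lf in sib.leaf_iter()
        ]
        if not joint_sisters:
            continue
        for rule in rules:
            p, q = rule.pair
            pairing = (
                (matches_prefix(a[:10], p) and matches_prefix(b[:10], q))
                or (matches_prefix(a[:10], q) and matches_prefix(b[:10], p))
            )
            if not pairing:
                continue
            ok = all(
                any(_matches_forbidden_entry(lab[:10], e) for e in rule.forbidden_joint_sisters)
                for lab in joint_sisters
            )
            if not ok:
                continue
            context = "joint_sisters=" + ",".join(sorted(joint_sisters))
            for lab, nd in ((a, children[0]), (b, children[1])):
                removals.append(
                    LedgerRow(
                        gf=gf, seq_id=lab, iteration=0, mode="subsister",
                        rule_id=rule.rule_id, observed_context=context,
                        terminal_branch_length=nd.edge.length or 0.0,
                        threshold_applied=None,
                    )
                )
            taken.update((a, b))
            break
    return removals


def clade_grab(
    t: GeneTree,
    rules: Sequence[CladeRule],
) -> tuple[set[str], list[LedgerRow]]:
    """Retain target sequences only inside qualifying clades.

    Returns (kept leaf labels, removal rows). Non-target leaves are never
    removed; exception prefixes are exempt regardless of clade size.
    """
    all_labels = t.leaf_labels()
    removed: dict[str, LedgerRow] = {}
    gf = t.gf or ""
    for rule in rules:
        hits = enumerate_clades(t, rule.target, rule.nontarget_allowance)
        qualifying = [h for h in hits if h.target_count >= rule.min_target]
        safe: set[str] = set()
        for h in qualifying:
            safe.update(h.leaf_labels)
        sizes = sorted((h.target_count for h in qualifying), reverse=True)
        context = f"qualifying_clade_target_sizes={sizes}"
        for lab in all_labels:
            if lab in removed or lab in safe:
                continue
            code = lab[:10]
            if not matches_prefix(code, rule.target):
                continue
            if matches_any(code, rule.exceptions):
                continue
            leaf = t.find_leaf(lab)
            removed[lab] = LedgerRow(
                gf=gf, seq_id=lab, iteration=0, mode="clade",
                rule_id=rule.rule_id, observed_context=context,
                terminal_branch_length=leaf.edge.length or 0.0,
                threshold_applied=float(rule.min_target),
            )
    kept = {lab for lab in all_labels if lab not in removed}
    return kept, list(removed.values())


@dataclass
class Phase:
    """One stage of the loop: a mode, its rules, and an iteration budget."""

    mode: Literal["sisters", "subsisters", "clades"]
    rules: Sequence[SisterRule] | Sequence[SubsisterRule] | Sequence[CladeRule]
    n_iterations: int = 1


@dataclass
class LoopResult:
    kept: dict[str, list[str]]
    ledger: RemovalLedger
    trees: dict[str, GeneTree]
    skipped: list[str] = field(default_factory=list)


RebuildFn = Callable[[str, list[str], GeneTree], GeneTree]


def prune_rebuild(gf: str, kept_labels: list[str], prev: GeneTree) -> GeneTree:
    """Default rebuild: restrict the previous tree to the kept leaves."""
    drop = set(prev.leaf_labels()) - set(kept_labels)
    return prev.without_leaves(drop) if drop else prev


def nj_rebuild_from_sequences(sequences: dict[str, dict[str, str]]) -> RebuildFn:
    """A rebuild callback that re-infers each gene tree by neighbor
    joining on pairwise identity distances of the kept sequences.

    Intended for tests and small runs; real pipelines plug in an external
    inference command via :func:`command_rebuild`.
    """
    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor
    from io import StringIO
    from Bio import Phylo

    def p_distance(s1: str, s2: str) -> float:
        n = min(len(s1), len(s2))
        pairs = [(a, b) for a, b in zip(s1[:n], s2[:n]) if a != "-" and b != "-"]
        if not pairs:
            return 1.0
        return sum(1 for a, b in pairs if a != b) / len(pairs)

    def rebuild(gf: str, kept_labels: list[str], prev: GeneTree) -> GeneTree:
        seqs = sequences[gf]
        labels = sorted(kept_labels)
        matrix = [
            [p_distance(seqs[labels[i]], seqs[labels[j]]) for j in range(i)] + [0.0]
            for i in range(len(labels))
        ]
        dm = DistanceMatrix(names=labels, matrix=matrix)
        nj = DistanceTreeConstructor().nj(dm)
        for clade in nj.find_clades():
            if clade.branch_length is not None and clade.branch_length < 0:
                clade.branch_length = 0.0
            if not clade.is_terminal():
                clade.name = None  # drop Inner1.. labels
        buf = StringIO()
        Phylo.write(nj, buf, "newick")
        return GeneTree.from_newick_string(buf.getvalue(), validate=False)

    return rebuild


def command_rebuild(template: str) -> RebuildFn:
    """Rebuild via an external command template with ``{fasta}`` and
    ``{tree}`` placeholders, e.g. ``"fasttree {fasta} > {tree}"``. The
    command must read the kept sequences and write a Newick tree."""
    import subprocess
    import tempfile
    from pathlib import Path

    def rebuild(gf: str, kept_labels: list[str], prev: GeneTree) -> GeneTree:
        raise NotImplementedError(
            "command_rebuild requires per-GF sequences; use run_loop(..., "
            "sequences=...) so the kept FASTA can be written"
        )

    def rebuild_with_seqs(gf, kept_labels, prev, sequences):
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / f"{gf}.fasta"
            treef = Path(tmp) / f"{gf}.nwk"
            with open(fasta, "w") as fh:
                for lab in kept_labels:
                    fh.write(f">{lab}\n{sequences[gf][lab]}\n")
            subprocess.run(
                template.format(fasta=fasta, tree=treef),
                shell=True, check=True, capture_output=True,
            )
            return GeneTree.from_newick_string(treef.read_text(), validate=False)

    rebuild.with_sequences = rebuild_with_seqs  # type: ignore[attr-defined]
    return rebuild


def _apply_phase_rules(tree: GeneTree, phase: Phase, branch_stat: str):
    if phase.mode == "sisters":
        return apply_sister_rules(tree, phase.rules, branch_stat=branch_stat)
    if phase.mode == "subsisters":
        return apply_subsister_rules(tree, phase.rules)
    if phase.mode == "clades":
        _, removals = clade_grab(tree, phase.rules)
        return removals
    raise RuleError(f"unknown phase mode {phase.mode!r}")


def run_loop(
    trees: dict[str, GeneTree],
    phases: Sequence[Phase],
    rebuild: RebuildFn | None = None,
    root_strategy: str = "outgroup_prefixes",
    branch_stat: str = "terminal",
    min_leaves: int = 3,
) -> LoopResult:
    """Run the full contamination loop over a set of gene trees.

    Per gene family and per phase, the cycle is: root the tree, evaluate
    the phase's rules on the frozen topology, remove all firings at once,
    rebuild, and repeat up to the phase's iteration budget — stopping
    early at the first iteration that removes nothing. The ledger
    accumulates across phases; a rebuild failure skips that gene family
    (logged) and the run continues.
    """
    if rebuild is None:
        rebuild = prune_rebuild
    ledger = RemovalLedger()
    kept: dict[str, list[str]] = {}
    final_trees: dict[str, GeneTree] = {}
    skipped: list[str] = []
    for gf, tree0 in trees.items():
        tree = tree0
        current = list(tree.leaf_labels())
        iteration = 0
        failed = False
        for phase in phases:
            if failed:
                break
            for _ in range(phase.n_iterations):
                if len(current) < min_leaves:
                    break
                iteration += 1
                try:
                    rooted = root_tree(tree, strategy=root_strategy)
                except TreeError as exc:
                    logger.warning("gene family %s: rooting failed (%s); skipped", gf, exc)
                    skipped.append(gf)
                    failed = True
                    break
                removals = _apply_phase_rules(rooted, phase, branch_stat)
                if not removals:
                    break
                for row in removals:
                    ledger.add(
                        LedgerRow(
                            gf=gf, seq_id=row.seq_id, iteration=iteration,
                            mode=row.mode, rule_id=row.rule_id,
                            observed_context=row.observed_context,
                            terminal_branch_length=row.terminal_branch_length,
                            threshold_applied=row.threshold_applied,
                        )
                    )
                removed_now = {row.seq_id for row in removals}
                current = [lab for lab in current if lab not in removed_now]
                if len(current) < min_leaves:
                    break
                try:
                    tree = rebuild(gf, current, rooted)
                except Exception as exc:
                    logger.warning("gene family %s: rebuild failed (%s); skipped", gf, exc)
                    skipped.append(gf)
                    failed = True
                    break
        kept[gf] = current
        final_trees[gf] = tree
    return LoopResult(kept=kept, ledger=ledger, trees=final_trees, skipped=skipped)


# ---------------------------------------------------------------------------
# Rules files


def _parse_allowance(text: str) -> float | int:
    text = text.strip()
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    if "." in text:
        return float(text)
    return int(text)


def read_sister_rules(path) -> tuple[list[SisterRule], list[SubsisterRule]]:
    """Read the sisters/subsisters rules TSV.

    Columns: rule_id, mode, target (``A;B`` pair for subsister),
    forbidden (comma-joined prefixes; ``non-X`` allowed in subsister),
    branch_mode, multiplier. ``#`` comment lines are ignored.
    """
    sisters: list[SisterRule] = []
    subsisters: list[SubsisterRule] = []
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        required = {"rule_id", "mode", "target", "forbidden"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise RuleError(f"rules file {path}: header must include {sorted(required)}")
        for rec in reader:
            mode = rec["mode"].strip().lower()
            forbidden = tuple(x.strip() for x in rec["forbidden"].split(",") if x.strip())
            if mode == "sister":
                sisters.append(
                    SisterRule(
                        rule_id=rec["rule_id"].strip(),
                        target=rec["target"].strip(),
                        forbidden_sisters=forbidden,
                        branch_mode=(rec.get("branch_mode") or "any").strip() or "any",
                        multiplier=float(rec.get("multiplier") or 0.5),
                    )
                )
            elif mode == "subsister":
                pair = tuple(x.strip() for x in rec["target"].split(";"))
                if len(pair) != 2:
                    raise RuleError(f"rule {rec['rule_id']}: subsister target must be 'A;B'")
                subsisters.append(
                    SubsisterRule(
                        rule_id=rec["rule_id"].strip(),
                        pair=pair,  # type: ignore[arg-type]
                        forbidden_joint_sisters=forbidden,
                    )
                )
            else:
                raise RuleError(f"rule {rec['rule_id']}: unknown mode {mode!r}")
    return sisters, subsisters


def read_clade_rules(path, exceptions_dir=None) -> list[CladeRule]:
    """Read the clade-grabbing rules TSV: rule_id, target, min_target,
    allowance (int or ``p%``), exceptions_file (optional; one prefix per
    line, ``-`` for none)."""
    from pathlib import Path

    rules: list[CladeRule] = []
    base = Path(exceptions_dir) if exceptions_dir else Path(path).parent
    with open(path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            exc_file = (rec.get("exceptions_file") or "-").strip()
            exceptions: tuple[str, ...] = ()
            if exc_file and exc_file != "-":
                p = Path(exc_file)
                if not p.is_absolute():
                    p = base / p
                exceptions = tuple(
                    line.strip() for line in p.read_text().splitlines()
                    if line.strip() and not line.startswith("#")
                )
            rules.append(
                CladeRule(
                    rule_id=rec["rule_id"].strip(),
                    target=rec["target"].strip(),
                    min_target=int(rec["min_target"]),
                    nontarget_allowance=_parse_allowance(rec.get("allowance") or "0"),
                    exceptions=exceptions,
                )
            )
    return rules
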