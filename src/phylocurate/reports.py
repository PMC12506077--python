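"""Descriptive reports used to design curation rules and assess outcomes.

These are the read-only companions to the contamination loop: where a
sequence's sisters tend to come from (to draft sister rules), how large
the pure clades of a lineage get (to pick clade-grabbing minima), which
taxa and gene families are well covered, which gene families look touched
by endosymbiotic gene transfer, and whether named clades are
monophyletic at each curation stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from phylocurate.taxon_codes import PROKARYOTE_MAJORS, matches_any, matches_prefix
from phylocurate.tree_engine import GeneTree, TreeError, is_monophyletic, sister_group


def contamination_by_sisters(
    trees: Sequence[GeneTree],
    focal: Sequence[str],
) -> pd.DataFrame:
    """Tally the sister-group composition of every focal-taxon leaf.

    For each focal prefix, each tree contributes one tally per focal
    leaf: the sister group's prefix at major and minor level when the
    group is pure, or ``mixed`` otherwise. Columns: focal, level,
    sister_prefix, n_trees, n_sequences, mean_terminal_branch.
    """
    acc: dict[tuple[str, str, str], dict] = {}
    for tree in trees:
        seen_in_tree: set[tuple[str, str, str]] = set()
        for label in tree.leaf_labels():
            code = label[:10]
            for f in focal:
                if not matches_prefix(code, f):
                    continue
                sisters = sister_group(tree, label)
                blen = tree.find_leaf(label).edge.length or 0.0
                for level, width in (("major", 2), ("minor", 5)):
                    prefixes = {lab[:width] for lab in sisters}
                    prefix = prefixes.pop() if len(prefixes) == 1 else "mixed"
                    key = (f, level, prefix)
                    rec = acc.setdefault(
                        key, {"n_trees": 0, "n_sequences": 0, "branch_sum": 0.0}
                    )
                    rec["n_sequences"] += 1
                    rec["branch_sum"] += blen
                    if key not in seen_in_tree:
                        rec["n_trees"] += 1
                        seen_in_tree.add(key)
    rows = []
    for f in focal:
        keys = [k for k in acc if k[0] == f]
        if not keys:
            rows.append(
                {"focal": f, "level": "major", "sister_prefix": "none",
                 "n_trees": 0, "n_sequences": 0, "mean_terminal_branch": 0.0}
            )
            continue
        for key in sorted(keys):
            rec = acc[key]
            rows.append(
                {"focal": key[0], "level": key[1], "sister_prefix": key[2],
                 "n_trees": rec["n_trees"], "n_sequences": rec["n_sequences"],
                 "mean_terminal_branch": rec["branch_sum"] / rec["n_sequences"]}
            )
    return pd.DataFrame(
        rows, columns=["focal", "level", "sister_prefix", "n_trees",
                       "n_sequences", "mean_terminal_branch"]
    )


def clade_sizes(
    trees: Sequence[GeneTree],
    prefixes: Sequence[str],
) -> dict[str, list[list[int]]]:
    """Per prefix, the distinct-code sizes of every maximal *pure* clade
    (allowance 0) in each tree. Returns prefix -> per-tree size lists
    (descending)."""
    from phylocurate.tree_engine import enumerate_clades

    out: dict[str, list[list[int]]] = {p: [] for p in prefixes}
    for tree in trees:
        for p in prefixes:
            hits = enumerate_clades(tree, p, 0)
            out[p].append(sorted((h.target_count for h in hits), reverse=True))
    return out


def clade_size_summary(sizes: Mapping[str, list[list[int]]]) -> pd.DataFrame:
    """Distribution summaries (max, median of per-tree maxima) across
    trees, for picking clade-grabbing minima."""
    import statistics

    rows = []
    for prefix, per_tree in sizes.items():
        maxima = [s[0] for s in per_tree if s]
        rows.append(
            {"prefix": prefix,
             "n_trees_present": len(maxima),
             "max_clade": max(maxima) if maxima else 0,
             "median_max_clade": statistics.median(maxima) if maxima else 0}
        )
    return pd.DataFrame(rows, columns=["prefix", "n_trees_present", "max_clade",
                                       "median_max_clade"])


def count_taxon_occurrence(trees: Sequence[GeneTree]) -> pd.DataFrame:
    """Per taxon code: number of gene trees it appears in and total
    sequence count."""
    gfs: dict[str, set[int]] = {}
    nseqs: dict[str, int] = {}
    for i, tree in enumerate(trees):
        for label in tree.leaf_labels():
            code = label[:10]
            gfs.setdefault(code, set()).add(i)
            nseqs[code] = nseqs.get(code, 0) + 1
    rows = [
        {"taxon": code, "n_gfs_present": len(gfs[code]), "n_sequences": nseqs[code]}
        for code in sorted(gfs)
    ]
    return pd.DataFrame(rows, columns=["taxon", "n_gfs_present", "n_sequences"])


def shared_gfs(
    presence: Mapping[str, Mapping[str, int]],
    focal_taxa: Sequence[str],
    top_n: int | None = None,
) -> pd.DataFrame:
    """Rank gene families for concatenation by coverage and paralogy.

    ``presence`` maps gf -> {taxon code -> sequence count}. Sharedness is
    the fraction of focal taxa with ≥1 sequence; paralogy is the mean
    sequence count over present focal taxa. Ranking: sharedness
    descending, paralogy ascending, then gf for stability.
    """
    if not focal_taxa:
        raise ValueError("empty focal taxon set")
    rows = []
    for gf in sorted(presence):
        counts = [presence[gf].get(t, 0) for t in focal_taxa]
        present = [c for c in counts if c > 0]
        sharedness = len(present) / len(focal_taxa)
        paralogy = sum(present) / len(present) if present else 0.0
        rows.append({"gf": gf, "sharedness": sharedness, "paralogy": paralogy})
    df = pd.DataFrame(rows, columns=["gf", "sharedness", "paralogy"])
    df = df.sort_values(
        by=["sharedness", "paralogy", "gf"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df.head(top_n) if top_n is not None else df


def presence_from_trees(trees: Mapping[str, GeneTree]) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for gf, tree in trees.items():
        counts: dict[str, int] = {}
        for label in tree.leaf_labels():
            counts[label[:10]] = counts.get(label[:10], 0) + 1
        out[gf] = counts
    return out


@dataclass(frozen=True)
class EgtFlag:
    gf: str
    kind: str  # "primary" | "secondary"
    clade_leaves: tuple[str, ...]
    reason: str


def flag_egt(
    trees: Mapping[str, GeneTree],
    photosynthetic_prefixes: Sequence[str],
    prokaryote_prefixes: Sequence[str] = PROKARYOTE_MAJORS,
    min_clade_leaves: int = 4,
    min_photo_minors: int = 3,
) -> list[EgtFlag]:
    """Flag gene families showing endosymbiotic-gene-transfer patterns,
    as candidates for manual review.

    *primary*: a clade of ≥ ``min_clade_leaves`` leaves containing only
    photosynthetic eukaryotes and prokaryotes, at least one of each —
    plastid-derived genes nesting among bacteria.
    *secondary*: a clade of ≥ ``min_clade_leaves`` leaves with ≥
    ``min_photo_minors`` distinct photosynthetic minor clades and no
    non-photosynthetic eukaryote — interdigitated photosynthetic
    lineages.
    """
    if not photosynthetic_prefixes or not prokaryote_prefixes:
        raise ValueError("photosynthetic and prokaryote prefix lists must be non-empty")
    flags: list[EgtFlag] = []
    for gf, tree in trees.items():
        found: dict[str, EgtFlag] = {}
        for node in tree.tree.preorder_internal_node_iter():
            labels = tuple(lf.taxon.label for lf in node.leaf_iter())
            if len(labels) < min_clade_leaves:
                continue
            photo = [l for l in labels if matches_any(l[:10], photosynthetic_prefixes)]
            prok = [l for l in labels if matches_any(l[:10], prokaryote_prefixes)]
            other_euk = [l for l in labels if l not in photo and l not in prok]
            if "primary" not in found and photo and prok and not other_euk:
                found["primary"] = EgtFlag(
                    gf, "primary", labels,
                    f"clade of {len(labels)} leaves: only photosynthetic "
                    f"eukaryotes ({len(photo)}) and prokaryotes ({len(prok)})",
                )
            photo_minors = {l[:5] for l in photo}
            if (
                "secondary" not in found
                and len(photo_minors) >= min_photo_minors
                and not other_euk
                and photo
            ):
                found["secondary"] = EgtFlag(
                    gf, "secondary", labels,
                    f"clade of {len(labels)} leaves: {len(photo_minors)} "
                    f"photosynthetic minor clades interdigitated",
                )
        flags.extend(found[k] for k in ("primary", "secondary") if k in found)
    return flags


def monophyly_table(
    stage_trees: Mapping[str, GeneTree],
    clades: Sequence[str],
    allowed_interlopers: int = 0,
) -> pd.DataFrame:
    """Monophyly status of each named clade prefix in each stage's
    species tree: monophyletic / non-monophyletic / absent."""
    rows = []
    for stage, tree in stage_trees.items():
        for clade in clades:
            try:
                mono = is_monophyletic(tree, clade, allowed_interlopers)
                status = "monophyletic" if mono else "non-monophyletic"
            except TreeError:
                status = "absent"
            rows.append(
                {"stage": stage, "clade": clade, "status": status,
                 "allowed_interlopers": allowed_interlopers}
            )
    return pd.DataFrame(rows, columns=["stage", "clade", "status", "allowed_interlopers"])
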