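"""Independent brute-force oracles for the tree operations.

Everything here enumerates every node / every (node, sequence) pair
directly on the dendropy topology, sharing no logic with the
implementations it checks.
"""

from phylocurate.taxon_codes import matches_prefix
from phylocurate.tree_engine import GeneTree, check_allowance


def all_below_sets(t: GeneTree) -> list[frozenset]:
    return [
        frozenset(lf.taxon.label for lf in node.leaf_iter())
        for node in t.tree.preorder_node_iter()
    ]


def _counts(labels, target):
    tc = {l[:10] for l in labels if matches_prefix(l[:10], target)}
    nc = {l[:10] for l in labels if not matches_prefix(l[:10], target)}
    return len(tc), len(nc)


def brute_enumerate_clades(t: GeneTree, target, allowance) -> set[frozenset]:
    """Qualifying = >=1 target code and allowance satisfied; maximal =
    not a strict subset of another qualifying set."""
    qualifying = []
    for s in all_below_sets(t):
        nt, nn = _counts(s, target)
        if nt >= 1 and check_allowance(nt, nn, allowance):
            qualifying.append(s)
    return {
        s for s in qualifying
        if not any(s < other for other in qualifying)
    }


def brute_clade_grab_removed(t: GeneTree, rule) -> set[str]:
    """A target leaf survives iff SOME node containing it satisfies both
    the allowance and the minimum target count."""
    removed = set()
    below = all_below_sets(t)
    for lab in t.leaf_labels():
        code = lab[:10]
        if not matches_prefix(code, rule.target):
            continue
        if any(matches_prefix(code, e) for e in rule.exceptions):
            continue
        ok = False
        for s in below:
            if lab not in s:
                continue
            nt, nn = _counts(s, rule.target)
            if nt >= rule.min_target and check_allowance(nt, nn, rule.nontarget_allowance):
                ok = True
                break
        if not ok:
            removed.add(lab)
    return removed


def brute_is_monophyletic(t: GeneTree, target, allowed=0) -> bool:
    all_set = set(t.leaf_labels())
    targets = {l for l in all_set if matches_prefix(l[:10], target)}
    assert targets
    for s in all_below_sets(t):
        for side in (set(s), all_set - set(s)):
            if targets <= side:
                extra = {l[:10] for l in side - targets}
                if len(extra) <= allowed:
                    return True
    return False


def brute_select_ortholog(t: GeneTree, taxon: str) -> str | None:
    """Exhaustive search over (node, candidate sequence) pairs with the
    documented tie-breaks."""
    from phylocurate.concat import seq_score

    taxon = taxon[:10]
    prefix = taxon[:5]
    own = [l for l in t.leaf_labels() if l[:10] == taxon]
    if not own:
        return None
    candidates = []
    for node in t.tree.preorder_node_iter():
        labels = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        if not any(l[:10] == taxon for l in labels):
            continue
        density = len({l[:10] for l in labels if matches_prefix(l[:10], prefix)})
        candidates.append((-density, len(labels), labels))
    candidates.sort()
    win = candidates[0][2]
    inside = [l for l in win if l[:10] == taxon]
    return sorted(inside, key=lambda l: (-seq_score(l).score, l))[0]


def brute_pure_clade_sizes(t: GeneTree, prefix) -> list[int]:
    """Sizes (distinct codes) of maximal pure clades of a prefix."""
    sets = brute_enumerate_clades(t, prefix, 0)
    return sorted((len({l[:10] for l in s}) for s in sets), reverse=True)
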