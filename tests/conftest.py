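import numpy as np
import pytest

from phylocurate.tree_engine import GeneTree

MINOR_POOL = ["Op_me", "Op_fu", "Sr_ci", "Ex_pa", "Ba_pr", "EE_ha", "Pl_gr"]


def random_gene_tree(rng: np.random.Generator, max_leaves: int = 12,
                     gf: str = "OG6_000777") -> GeneTree:
    """A random small gene tree with realistic labels; taxon codes are
    reused between leaves now and then, so distinct-code counting is
    exercised."""
    n = int(rng.integers(4, max_leaves + 1))
    labels = []
    for i in range(n):
        minor = MINOR_POOL[int(rng.integers(len(MINOR_POOL)))]
        sp = int(rng.integers(0, max(2, n // 2)))
        labels.append(f"{minor}_S{sp:03d}_c{i}_{gf}")
    parts = [f"{lab}:{rng.exponential(0.1):.6f}" for lab in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = f"({parts[i]},{parts[j]}):{rng.exponential(0.1):.6f}"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    newick = parts[0].rsplit(":", 1)[0] + ";"
    return GeneTree.from_newick_string(newick)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def favella_tree():
    """A ciliate sequence on a short branch sister to a haptophyte (its
    food source), with a second ciliate further away."""
    return GeneTree.from_newick_string(
        "((Sr_ci_Fehr_c1_OG6_000001:0.01,EE_ha_Ehux_c1_OG6_000001:0.01):0.1,"
        "Sr_ci_Tthe_c1_OG6_000001:0.1);"
    )
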