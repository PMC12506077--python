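"""Ortholog selection and supermatrix concatenation.

For each gene family and taxon with several candidate sequences, the
representative ortholog is the sequence falling in the clade that packs
the greatest number of distinct taxon codes from the taxon's own minor
clade (ties prefer the smallest such clade, then the lexicographically
smallest label set); within the winning clade, candidates are ranked by a
score — contig length × k-mer coverage when an assembler-style coverage
field is present in the ID, otherwise sequence length. Selected rows are
concatenated per taxon, absent gene families are gap-filled, and
high-gap columns can be masked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from phylocurate.taxon_codes import matches_prefix, parse_seq_id
from phylocurate.tree_engine import GeneTree

GAP_CHARS = frozenset("-?")


class ConcatError(ValueError):
    pass


@dataclass(frozen=True)
class SeqScore:
    """Ranking score for ortholog candidates: length × k-mer coverage
    when coverage is in the contig token, otherwise plain length."""

    seq_id: str
    length: int
    kmer_cov: float | None

    @property
    def score(self) -> float:
        return self.length * self.kmer_cov if self.kmer_cov is not None else float(self.length)


def seq_score(seq_id: str, sequence: str | None = None) -> SeqScore:
    sid = parse_seq_id(seq_id)
    if sid.contig_length is not None:
        length = sid.contig_length
    elif sequence is not None:
        length = sum(1 for c in sequence if c not in GAP_CHARS)
    else:
        length = 0  # unscoreable: ranks last, ties break lexicographically
    return SeqScore(seq_id=seq_id, length=length, kmer_cov=sid.kmer_coverage)


def select_ortholog(
    t: GeneTree,
    taxon: str,
    alignment: Mapping[str, str] | None = None,
    clade_level: str = "minor",
) -> str | None:
    """Pick the representative sequence of ``taxon`` (a 10-character
    code) from a gene tree, or None if the taxon is absent.

    Candidate clades are all nodes containing ≥1 sequence of the taxon;
    the winner maximizes distinct codes sharing the taxon's minor-clade
    prefix (``clade_level='major'`` counts at the major level instead),
    with ties going to the clade with fewest leaves, then the smallest
    leaf-label tuple. Within it, the highest-scoring sequence of the
    taxon wins; score ties break on the lexicographically smallest ID.
    """
    taxon = taxon[:10]
    if clade_level == "minor":
        prefix = taxon[:5]
    elif clade_level == "major":
        prefix = taxon[:2]
    else:
        raise ConcatError(f"unknown clade_level {clade_level!r}")
    own = [lab for lab in t.leaf_labels() if lab[:10] == taxon]
    if not own:
        return None
    best = None  # (-clade_count, n_leaves, labels, node_labels)
    for node in t.tree.preorder_node_iter():
        labels = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        if not any(lab[:10] == taxon for lab in labels):
            continue
        clade_codes = {lab[:10] for lab in labels if matches_prefix(lab[:10], prefix)}
        key = (-len(clade_codes), len(labels), labels)
        if best is None or key < best[0]:
            best = (key, labels)
    assert best is not None
    winning_labels = best[1]
    candidates = [lab for lab in winning_labels if lab[:10] == taxon]
    scored = []
    for lab in candidates:
        seq = alignment.get(lab) if alignment is not None else None
        scored.append(seq_score(lab, seq))
    scored.sort(key=lambda s: (-s.score, s.seq_id))
    return scored[0].seq_id


@dataclass
class Supermatrix:
    """Concatenated per-taxon alignment with a partition map."""

    taxa: list[str]
    partitions: list[tuple[str, int, int]]  # (gf, start, end) half-open
    rows: dict[str, str]

    @property
    def width(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                fh.write(f">{taxon}\n{self.rows[taxon]}\n")

    def write_partitions_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gf\tstart\tend\n")
            for gf, start, end in self.partitions:
                fh.write(f"{gf}\t{start}\t{end}\n")

    def write_raxml_partitions(self, path, model: str = "LG") -> None:
        with open(path, "w") as fh:
            for gf, start, end in self.partitions:
                fh.write(f"{model}, {gf} = {start + 1}-{end}\n")


def build_supermatrix(
    per_gf_alignments: Mapping[str, Mapping[str, str]],
    taxa: Iterable[str],
    selected: Mapping[tuple[str, str], str],
) -> Supermatrix:
    """Concatenate selected orthologs into one row per taxon.

    ``selected`` maps (gf, taxon) to the chosen sequence ID within that
    GF's alignment; a missing entry gap-fills the taxon across that
    partition.
    """
    taxa = list(taxa)
    gfs = list(per_gf_alignments)
    if not gfs:
        raise ConcatError("no gene-family alignments supplied")
    widths: dict[str, int] = {}
    for gf, aln in per_gf_alignments.items():
        if not aln:
            raise ConcatError(f"gene family {gf}: empty alignment")
        lens = {len(s) for s in aln.values()}
        if len(lens) != 1:
            raise ConcatError(f"gene family {gf}: ragged alignment widths {sorted(lens)}")
        widths[gf] = lens.pop()
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for gf in gfs:
        partitions.append((gf, pos, pos + widths[gf]))
        pos += widths[gf]
    rows: dict[str, str] = {}
    for taxon in taxa:
        chunks: list[str] = []
        for gf in gfs:
            sid = selected.get((gf, taxon))
            if sid is None:
                chunks.append("-" * widths[gf])
            else:
                aln = per_gf_alignments[gf]
                if sid not in aln:
                    raise ConcatError(f"selected {sid!r} missing from alignment of {gf}")
                chunks.append(aln[sid])
        rows[taxon] = "".join(chunks)
    return Supermatrix(taxa=taxa, partitions=partitions, rows=rows)


def mask_gap_columns(
    sm: Supermatrix,
    max_gap_fraction: float,
) -> Supermatrix:
    """Remove alignment columns whose gap fraction reaches the threshold
    (a column is dropped when its gap fraction is ≥ ``max_gap_fraction``,
    i.e. "at least p% gaps"); the partition map is re-indexed."""
    if not (0.0 < max_gap_fraction <= 1.0):
        raise ConcatError(f"max_gap_fraction {max_gap_fraction} outside (0, 1]")
    if not sm.rows:
        raise ConcatError("empty supermatrix")
    n = len(sm.taxa)
    width = sm.width
    keep = []
    for col in range(width):
        gaps = sum(1 for taxon in sm.taxa if sm.rows[taxon][col] in GAP_CHARS)
        if gaps / n < max_gap_fraction:
            keep.append(col)
    keep_set = set(keep)
    new_rows = {taxon: "".join(sm.rows[taxon][c] for c in keep) for taxon in sm.taxa}
    new_partitions: list[tuple[str, int, int]] = []
    pos = 0
    for gf, start, end in sm.partitions:
        w = sum(1 for c in range(start, end) if c in keep_set)
        new_partitions.append((gf, pos, pos + w))
        pos += w
    return Supermatrix(taxa=list(sm.taxa), partitions=new_partitions, rows=new_rows)


def select_all_orthologs(
    trees: Mapping[str, GeneTree],
    alignments: Mapping[str, Mapping[str, str]],
    taxa: Iterable[str],
    clade_level: str = "minor",
) -> dict[tuple[str, str], str]:
    """Run :func:`select_ortholog` over every (gf, taxon) pair."""
    selected: dict[tuple[str, str], str] = {}
    for gf, tree in trees.items():
        aln = alignments.get(gf)
        for taxon in taxa:
            sid = select_ortholog(tree, taxon, alignment=aln, clade_level=clade_level)
            if sid is not None:
                selected[(gf, taxon)] = sid
    return selected
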