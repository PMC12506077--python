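"""Composition-based sequence curation.

Most genomes use G+C at silent (synonymous third codon) positions within
a fairly narrow range, so a wide spread of silent-site GC among the
coding sequences of one sample usually means more than one organism is
present. Two statistics drive this curation:

* **GC3S** — the G+C fraction at third positions of codons from
  synonymously variable amino-acid families (single-codon families such
  as Met/Trp under the standard code carry no silent signal and are
  excluded, as are stop codons).

* **ENc** — Wright's effective number of codons,
  ``Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6`` under the standard code,
  where ``F̄k`` averages the bias-corrected codon homozygosity
  ``F = (n·Σp² − 1)/(n − 1)`` over the k-fold degenerate families.
  Nc runs from 20 (one codon per amino acid) to 61 (uniform usage).

Sequences are then labeled per taxon-specific GC3S ranges (``OG6`` in
range, ``OGG`` GC-rich, ``OGA`` AT-rich), and two sequence-level filters
remove near-duplicates (≥99% amino-acid identity within a taxon and gene
family) and length outliers (< 1/3 or > 1.5× the gene family's reference
mean length).

Degeneracy classes are derived from the genetic-code table, so
non-standard codes are handled by passing their NCBI table id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

from Bio.Data import CodonTable

from phylocurate.taxon_codes import parse_seq_id

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class CompositionError(ValueError):
    pass


@lru_cache(maxsize=None)
def _code_families(table_id: int) -> tuple[dict[str, tuple[str, ...]], frozenset[str]]:
    """Map amino acid -> its sense codons, plus the stop-codon set, for an
    NCBI genetic-code table."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return (
        {aa: tuple(sorted(codons)) for aa, codons in fams.items()},
        frozenset(table.stop_codons),
    )


def _codons(cds: str, table_id: int) -> list[str]:
    """Clean codon list: upper-cased, terminal stop trimmed, ambiguous
    and internal stop codons skipped."""
    s = re.sub(r"\s", "", cds).upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise CompositionError(f"CDS length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    _, stops = _code_families(table_id)
    if codons and codons[-1] in stops:
        codons = codons[:-1]
    return [c for c in codons if set(c) <= _VALID_BASES and c not in stops]


def gc3s(cds: str, table_id: int = 1) -> float | None:
    """Silent-site GC: fraction of G/C third positions among codons of
    synonymously variable families. None when no codon is eligible."""
    fams, _ = _code_families(table_id)
    table = CodonTable.unambiguous_dna_by_id[table_id].forward_table
    variable = {aa for aa, codons in fams.items() if len(codons) >= 2}
    eligible = [c for c in _codons(cds, table_id) if table[c] in variable]
    if not eligible:
        return None
    return sum(1 for c in eligible if c[2] in "GC") / len(eligible)


def enc(cds: str, table_id: int = 1) -> float | None:
    """Wright's effective number of codons, or None when the sequence
    lacks the degeneracy-class coverage the estimator needs.

    Families observed fewer than twice are excluded from their class
    average; a missing 3-fold class average is estimated as
    (F̄2 + F̄4)/2 (Wright's convention); any other missing class leaves
    ENc undefined. The value is capped at the code's sense-codon count
    (61 for the standard code).
    """
    fams, _ = _code_families(table_id)
    table = CodonTable.unambiguous_dna_by_id[table_id].forward_table
    counts: dict[str, dict[str, int]] = {}
    for codon in _codons(cds, table_id):
        aa = table[codon]
        counts.setdefault(aa, {}).setdefault(codon, 0)
        counts[aa][codon] += 1

    # class sizes in the code itself
    class_families: dict[int, list[str]] = {}
    for aa, codons in fams.items():
        class_families.setdefault(len(codons), []).append(aa)

    f_bar: dict[int, float] = {}
    for k, aas in class_families.items():
        if k == 1:
            continue
        fs = []
        for aa in aas:
            obs = counts.get(aa, {})
            n = sum(obs.values())
            if n < 2:
                continue
            s = sum((c / n) ** 2 for c in obs.values())
            f = (n * s - 1) / (n - 1)
            fs.append(f)
        if fs:
            f_bar[k] = sum(fs) / len(fs)

    if 3 in class_families and 3 not in f_bar:
        if 2 in f_bar and 4 in f_bar:
            f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    nc = float(len(class_families.get(1, [])))
    for k, aas in class_families.items():
        if k == 1:
            continue
        fk = f_bar.get(k)
        if fk is None or fk <= 0:
            return None
        nc += len(aas) / fk
    n_sense = sum(len(c) for c in fams.values())
    return min(nc, float(n_sense))


@dataclass(frozen=True)
class GcRange:
    """Per-taxon acceptable GC3S interval, closed on both ends."""

    taxon: str
    lower: float
    upper: float

    def __post_init__(self):
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise CompositionError(f"bad GC range [{self.lower}, {self.upper}]")


@dataclass
class CompositionRecord:
    seq_id: str
    gc3s: float | None
    enc: float | None
    gc_class: str | None = None

    @property
    def relabeled_id(self) -> str:
        """The sequence ID with its GF token rewritten to carry the
        composition class (OG6/OGG/OGA)."""
        if self.gc_class is None:
            return self.seq_id
        prefix = {"OG6": "OG6", "OGG": "OGG", "OGA": "OGA"}[self.gc_class]
        return re.sub(r"OG[6GA](_[0-9]{6})$", prefix + r"\1", self.seq_id)


def compute_composition(
    sequences: Mapping[str, str], table_id: int = 1
) -> list[CompositionRecord]:
    return [
        CompositionRecord(seq_id=sid, gc3s=gc3s(seq, table_id), enc=enc(seq, table_id))
        for sid, seq in sequences.items()
    ]


def classify_gc(
    records: Iterable[CompositionRecord],
    ranges: Mapping[str, GcRange],
    default: GcRange | None = None,
) -> list[CompositionRecord]:
    """Label each record OG6 (in its taxon's GC3S range, closed
    interval), OGG (above) or OGA (below). Records with undefined GC3S
    are left unlabeled."""
    out = []
    for rec in records:
        taxon = parse_seq_id(rec.seq_id).taxon.full
        rng = ranges.get(taxon, default)
        if rng is None:
            raise CompositionError(f"no GC range for taxon {taxon} and no default")
        if rec.gc3s is None:
            label = None
        elif rec.gc3s > rng.upper:
            label = "OGG"
        elif rec.gc3s < rng.lower:
            label = "OGA"
        else:
            label = "OG6"
        out.append(CompositionRecord(rec.seq_id, rec.gc3s, rec.enc, label))
    return out


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment amino-acid identity: matches over alignment
    columns, counting internal gaps in the denominator but not terminal
    overhangs (end gaps are unpenalised in the alignment)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    start, end = 0, len(ga)
    while start < end and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    core = range(start, end)
    if not core:
        return 0.0
    matches = sum(1 for i in core if ga[i] == gb[i] and ga[i] != "-")
    return matches / len(core)


def similarity_filter(
    sequences: Mapping[str, str],
    identity_cutoff: float = 0.99,
) -> set[str]:
    """Greedy near-duplicate removal within one taxon and gene family.

    Sequences are visited in descending length (ties: lexicographic ID);
    each is dropped iff its identity to an already-kept sequence reaches
    the cutoff. Returns the kept IDs.
    """
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    kept: list[str] = []
    for sid in order:
        if any(pairwise_identity(sequences[sid], sequences[k]) >= identity_cutoff for k in kept):
            continue
        kept.append(sid)
    return set(kept)


def relative_length_filter(
    sequences: Mapping[str, str],
    gf_mean_lengths: Mapping[str, float],
) -> set[str]:
    """Keep sequences within [mean/3, 1.5×mean] of their gene family's
    reference mean length (closed bounds); a GF missing from the table
    keeps its sequences with a warning."""
    kept: set[str] = set()
    for sid, seq in sequences.items():
        gf = parse_seq_id(sid).gf
        mean = gf_mean_lengths.get(gf)
        if mean is None:
            logger.warning("gene family %s absent from mean-length table; keeping %s", gf, sid)
            kept.add(sid)
            continue
        if mean / 3.0 <= len(seq) <= 1.5 * mean:
            kept.add(sid)
    return kept


def read_gc_ranges(path) -> dict[str, GcRange]:
    """Ranges TSV: taxon, lower, upper (header optional)."""
    out: dict[str, GcRange] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("taxon"):
                continue
            taxon, lo, hi = line.split("\t")[:3]
            out[taxon] = GcRange(taxon, float(lo), float(hi))
    return out


def read_mean_lengths(path) -> dict[str, float]:
    """Mean-length TSV: gf, mean_len (header optional)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gf"):
                continue
            gf, mean = line.split("\t")[:2]
            out[gf] = float(mean)
    return out
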