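"""Controlled taxon codes and sequence identifiers.

Every sequence in the toolkit is named by a 10-character taxon code —
``MM_mm_Ssss``, where the first two characters pick one of eight major
clades (Ba bacteria, Za archaea, Op Opisthokonta, Am Amoebozoa, Ex
excavate lineages, Sr SAR, Pl Archaeplastida, EE orphan lineages), the
next two a minor clade within it, and the last four the species/sample —
followed by a free-form contig token and a terminal gene-family token
(``OG6_`` + six digits; ``OGG``/``OGA`` variants mark GC-rich / AT-rich
composition classes).

Distinct 10-character codes are the counting unit everywhere: two samples
of one species (``Am_tu_Hp01`` / ``Am_tu_Hp02``) count as two taxa unless
the caller collapses them explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

MAJOR_CLADES = frozenset({"Ba", "Za", "Op", "Am", "Ex", "Sr", "Pl", "EE"})
PROKARYOTE_MAJORS = ("Ba", "Za")

_GF_RE = re.compile(r"OG[6GA]_[0-9]{6}$")
_GF_TOKEN_RE = re.compile(r"^OG[6GA]_[0-9]{6}$")


class TaxonCodeError(ValueError):
    """A taxon code or sequence identifier failed validation."""


@dataclass(frozen=True)
class TaxonCode:
    """A validated 10-character taxon code ``MM_mm_Ssss``."""

    major: str
    minor: str
    species: str

    @property
    def full(self) -> str:
        return f"{self.major}_{self.minor}_{self.species}"

    @property
    def major_minor(self) -> str:
        """The 5-character minor-clade prefix, e.g. ``Op_me``."""
        return f"{self.major}_{self.minor}"

    def __str__(self) -> str:
        return self.full


@dataclass(frozen=True)
class SeqID:
    """A full sequence identifier: taxon code + contig token + GF token."""

    taxon: TaxonCode
    contig: str
    gf: str

    @property
    def full(self) -> str:
        if self.contig:
            return f"{self.taxon.full}_{self.contig}_{self.gf}"
        return f"{self.taxon.full}_{self.gf}"

    def __str__(self) -> str:
        return self.full

    @property
    def kmer_coverage(self) -> float | None:
        """k-mer coverage parsed from an assembler-style contig token
        (``..._cov_<float>...``), or None when absent."""
        m = re.search(r"(?:^|_)cov_([0-9]+(?:\.[0-9]+)?)", self.contig)
        return float(m.group(1)) if m else None

    @property
    def contig_length(self) -> int | None:
        """Contig length parsed from ``..._length_<int>...``, or None."""
        m = re.search(r"(?:^|_)length_([0-9]+)", self.contig)
        return int(m.group(1)) if m else None


@dataclass(frozen=True)
class CladePrefix:
    """A rule target at one of three levels: major (``Op``), minor
    (``Op_me``), or a full taxon code (``Op_me_Hsap``)."""

    text: str

    def __post_init__(self) -> None:
        n = len(self.text)
        if n == 2:
            if self.text not in MAJOR_CLADES:
                raise TaxonCodeError(
                    f"unknown major clade prefix {self.text!r}; "
                    f"expected one of {sorted(MAJOR_CLADES)}"
                )
        elif n == 5:
            if self.text[2] != "_" or self.text[:2] not in MAJOR_CLADES:
                raise TaxonCodeError(f"malformed minor-clade prefix {self.text!r}")
        elif n == 10:
            parse_taxon_code(self.text)
        else:
            raise TaxonCodeError(
                f"clade prefix {self.text!r} must be 2 (major), 5 (minor) "
                f"or 10 (full code) characters"
            )

    @property
    def level(self) -> str:
        return {2: "major", 5: "minor", 10: "taxon"}[len(self.text)]

    def __str__(self) -> str:
        return self.text


def parse_taxon_code(s: str) -> TaxonCode:
    """Parse and validate a 10-character taxon code.

    >>> parse_taxon_code("Op_me_Hsap")
    TaxonCode(major='Op', minor='me', species='Hsap')
    """
    if not s:
        raise TaxonCodeError("empty taxon code")
    if len(s) != 10:
        raise TaxonCodeError(f"taxon code {s!r} must be 10 characters, got {len(s)}")
    if s[2] != "_" or s[5] != "_":
        raise TaxonCodeError(f"taxon code {s!r} must have underscores at positions 3 and 6")
    major, minor, species = s[:2], s[3:5], s[6:]
    if major not in MAJOR_CLADES:
        raise TaxonCodeError(
            f"unknown major clade {major!r} in {s!r}; expected one of {sorted(MAJOR_CLADES)}"
        )
    if "_" in minor or "_" in species:
        raise TaxonCodeError(f"taxon code {s!r} has stray underscores in minor/species fields")
    return TaxonCode(major, minor, species)


def parse_seq_id(s: str) -> SeqID:
    """Parse a full sequence identifier.

    The taxon code is always the first 10 characters, the GF token is the
    final ``OG[6GA]_\\d{6}`` match, and the contig is everything between
    (assembler headers may embed underscores, so parsing is positional).

    >>> parse_seq_id("Op_me_Hsap_c1_OG6_000001").gf
    'OG6_000001'
    """
    if not s:
        raise TaxonCodeError("empty sequence identifier")
    taxon = parse_taxon_code(s[:10])
    m = _GF_RE.search(s)
    if m is None:
        raise TaxonCodeError(f"sequence id {s!r} lacks a terminal gene-family token (OG6_nnnnnn)")
    gf = m.group(0)
    middle = s[10 : m.start()]
    contig = middle.strip("_")
    if len(s) > 10 and s[10] != "_":
        raise TaxonCodeError(f"sequence id {s!r}: taxon code not underscore-delimited")
    return SeqID(taxon=taxon, contig=contig, gf=gf)


def is_gf_token(s: str) -> bool:
    return bool(_GF_TOKEN_RE.match(s))


def matches_prefix(code: TaxonCode | SeqID | str, prefix: CladePrefix | str) -> bool:
    """True iff the taxon code begins with the prefix at a token boundary.

    Accepts a TaxonCode, a SeqID (its taxon is used), or a raw string
    (first 10 characters used).
    """
    if isinstance(code, SeqID):
        full = code.taxon.full
    elif isinstance(code, TaxonCode):
        full = code.full
    else:
        full = str(code)[:10]
    text = prefix.text if isinstance(prefix, CladePrefix) else str(prefix)
    if len(text) not in (2, 5, 10):
        raise TaxonCodeError(f"invalid clade prefix {text!r}")
    if len(text) == 10:
        return full == text
    return full.startswith(text) and full[len(text)] == "_"


def matches_any(code: TaxonCode | SeqID | str, prefixes) -> bool:
    """True iff the code matches at least one of the given prefixes."""
    return any(matches_prefix(code, p) for p in prefixes)


def load_minor_major_table(path) -> dict[str, str]:
    """Optional TSV (minor_prefix -> major) used to sanity-check rules;
    no built-in taxonomy is assumed."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            minor, major = line.split("\t")[:2]
            table[minor] = major
    return table
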