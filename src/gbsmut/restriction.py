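"""In-silico restriction digestion for reduced-representation (GBS) library design.

A genome is cut with one enzyme (nGBS style, e.g. MslI) or two enzymes
(ddGBS style, e.g. PstI + MspI), optionally respecting a cytosine-methylation
mask: a recognition site containing a methylated cytosine in one of the
enzyme's blocking contexts is not cut.  Fragments are the intervals between
consecutive cuts; library size selection keeps fragments within a length
window and, for double digests, optionally only fragments carrying one end
from each enzyme (the usual rare-cutter/common-cutter adapter design).

Coordinates are 0-based half-open throughout; cut positions are top-strand
coordinates (overhangs are ignored for interval arithmetic, since size
selection operates on approximate lengths).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RestrictionEnzyme",
    "Fragment",
    "SelectionParams",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "find_sites",
    "digest",
    "select_fragments",
    "iupac_to_regex",
    "reverse_complement",
    "TERMINUS",
]

# End label for a fragment boundary created by the contig edge, not an enzyme.
TERMINUS = "terminus"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a regex over {A,C,G,T}.

    N in the *subject* never matches: every symbol expands to a concrete
    character class that excludes N.
    """
    parts = []
    for sym in pattern.upper():
        try:
            bases = _IUPAC[sym]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme: IUPAC recognition pattern, top-strand cut offset
    and the methylation contexts that block cutting.

    ``cut_offset`` is measured in bases from the pattern start on the top
    strand; ``blocking_contexts`` is a subset of {"CpG", "CHG", "CHH"} — a
    methylated cytosine in such a context anywhere inside the matched site
    abolishes the cut.
    """

    name: str
    recognition: str
    cut_offset: int
    blocking_contexts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside pattern "
                f"of length {len(self.recognition)}"
            )
        iupac_to_regex(self.recognition)  # validates the alphabet
        bad = set(self.blocking_contexts) - {"CpG", "CHG", "CHH"}
        if bad:
            raise ValueError(f"{self.name}: unknown methylation contexts {bad}")

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    def residual_site(self) -> str:
        """IUPAC sequence left at the 5' end of a downstream fragment's reads.

        After cutting and end repair, the sequenced top strand of the
        downstream fragment starts at the nearer of the two strand cuts, so
        the remaining part of the site is ``recognition[min(c, L-c):]``
        (e.g. "TGCAG" for PstI, "CGG" for MspI).
        """
        c = self.cut_offset
        return self.recognition[min(c, len(self.recognition) - c):]


# Enzymes used in the nGBS (MslI) and ddGBS (PstI/MspI) designs.  PstI is
# blocked by CHG (CpNpG) methylation; MspI cuts CCGG regardless of internal
# CpG methylation by default (pass a modified enzyme to model blocking).
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "MslI": RestrictionEnzyme("MslI", "CAYNNNNRTG", 5),
    "PstI": RestrictionEnzyme("PstI", "CTGCAG", 5, frozenset({"CHG"})),
    "MspI": RestrictionEnzyme("MspI", "CCGG", 1),
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins: {sorted(BUILTIN_ENZYMES)}"
        )


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment: half-open interval with labelled ends.

    ``left_end``/``right_end`` name the enzyme whose cut created that
    boundary, or ``TERMINUS`` for a contig edge.
    """

    contig: str
    start: int
    end: int
    left_end: str = TERMINUS
    right_end: str = TERMINUS

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SelectionParams:
    """Size-selection window (inclusive endpoints) and end-composition rule.

    ``end_rule``: "both-any" keeps any enzyme-ended fragment composition;
    "rare-common" additionally requires one end from each of the two
    digestion enzymes (terminus ends never qualify).
    """

    min_len: int = 200
    max_len: int = 500
    end_rule: str = "both-any"

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.end_rule not in ("both-any", "rare-common"):
            raise ValueError(f"unknown end_rule {self.end_rule!r}")


MethylationMask = Mapping[str, Mapping[int, str]]
"""Per-contig map of 0-based methylated-cytosine position -> context label."""


def _site_blocked(
    contig_mask: Mapping[int, str] | None,
    start: int,
    length: int,
    blocking: frozenset[str],
) -> bool:
    if not contig_mask or not blocking:
        return False
    return any(
        contig_mask.get(p) in blocking for p in range(start, start + length)
    )


def find_sites(
    sequence: str,
    enzyme: RestrictionEnzyme,
    mask: Mapping[int, str] | None = None,
) -> list[int]:
    """Top-strand cut coordinates of every unblocked recognition site.

    Both strands are scanned (for the built-in enzymes the patterns are their
    own reverse complements, so the forward scan already covers both).  A cut
    coordinate is ``site_start + cut_offset`` for a top-strand match and
    ``site_start + (L - cut_offset)`` for a bottom-strand match.  Cuts at the
    very ends of the sequence (coordinate 0 or len) create no new boundary
    and are dropped.
    """
    seq = sequence.upper()
    L = enzyme.site_length
    cuts: set[int] = set()

    def scan(pattern: str, offset: int) -> None:
        rx = re.compile(f"(?=({iupac_to_regex(pattern)}))")
        for m in rx.finditer(seq):
            s = m.start()
            if _site_blocked(mask, s, L, enzyme.blocking_contexts):
                continue
            cut = s + offset
            if 0 < cut < len(seq):
                cuts.add(cut)

    scan(enzyme.recognition, enzyme.cut_offset)
    rc = reverse_complement(enzyme.recognition)
    if rc != enzyme.recognition:
        scan(rc, L - enzyme.cut_offset)
    return sorted(cuts)


def digest(
    genome: Mapping[str, str],
    enzymes: RestrictionEnzyme | Sequence[RestrictionEnzyme],
    mask: MethylationMask | None = None,
) -> list[Fragment]:
    """Digest every contig with one or two enzymes; fragments tile each contig.

    Cut positions of all enzymes are merged and sorted; when two enzymes cut
    at the same coordinate the first enzyme in ``enzymes`` labels the ends.
    """
    if isinstance(enzymes, RestrictionEnzyme):
        enzymes = [enzymes]
    names = [e.name for e in enzymes]
    if len(set(names)) != len(names):
        raise ValueError("enzymes must be distinct")

    fragments: list[Fragment] = []
    for contig, seq in genome.items():
        contig_mask = mask.get(contig) if mask else None
        cut_label: dict[int, str] = {}
        for enz in enzymes:
            for cut in find_sites(seq, enz, contig_mask):
                cut_label.setdefault(cut, enz.name)
        boundaries = [0, *sorted(cut_label), len(seq)]
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            fragments.append(
                Fragment(
                    contig,
                    a,
                    b,
                    left_end=cut_label.get(a, TERMINUS),
                    right_end=cut_label.get(b, TERMINUS),
                )
            )
    return fragments


@dataclass
class SelectionSummary:
    """Count, total bases and length histogram of a selected fragment set."""

    count: int
    total_bases: int
    length_histogram: Counter = field(default_factory=Counter)

    @classmethod
    def from_fragments(cls, fragments: Iterable[Fragment], bin_size: int = 50):
        frags = list(fragments)
        hist = Counter((f.length // bin_size) * bin_size for f in frags)
        return cls(len(frags), sum(f.length for f in frags), hist)


def select_fragments(
    fragments: Iterable[Fragment],
    params: SelectionParams = SelectionParams(),
) -> tuple[list[Fragment], SelectionSummary]:
    """Library size selection: keep fragments with min_len <= length <= max_len.

    Under ``end_rule="rare-common"`` a fragment must additionally have ends
    from two *different* enzymes (one from each of the double-digest pair).
    """
    frags = list(fragments)
    enzyme_ends = {
        e for f in frags for e in (f.left_end, f.right_end) if e != TERMINUS
    }
    if params.end_rule == "rare-common" and len(enzyme_ends) < 2:
        raise ValueError(
            "rare-common end rule requires a double digest (two enzymes); "
            f"observed enzyme ends: {sorted(enzyme_ends) or 'none'}"
        )
    kept = []
    for f in frags:
        if not (params.min_len <= f.length <= params.max_len):
            continue
        if params.end_rule == "rare-common":
            if TERMINUS in (f.left_end, f.right_end):
                continue
            if f.left_end == f.right_end:
                continue
        kept.append(f)
    return kept, SelectionSummary.from_fragments(kept)
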