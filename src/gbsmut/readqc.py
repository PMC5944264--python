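"""FASTQ read preprocessing for GBS libraries.

Reads are kept or discarded by four rules applied in a fixed order:

1. discard any read containing an unspecified nucleotide (N);
2. discard reads shorter than ``min_raw_length`` (default 20) before trimming;
3. if prefix checking is on, discard reads whose 5' end does not match the
   residual restriction site of the digestion enzyme (IUPAC semantics);
4. trim low-quality bases from the 3' end, then discard reads whose trimmed
   length falls below ``min_trimmed_length`` (default 64).

The reported discard reason is the first failing rule.  Quality trimming
strips the maximal 3' suffix of bases below the Phred threshold (simple
cutoff, no sliding window).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .restriction import RestrictionEnzyme, iupac_to_regex

__all__ = [
    "ReadQCParams",
    "ReadQCReport",
    "ReadDecision",
    "filter_read",
    "run_readqc",
    "DISCARD_REASONS",
]

DISCARD_REASONS = (
    "contains_N",
    "too_short_raw",
    "prefix_mismatch",
    "too_short_after_trim",
)


@dataclass(frozen=True)
class ReadQCParams:
    """Thresholds of the read filter.

    ``expected_prefix`` is an IUPAC pattern, normally the residual enzyme
    site (:meth:`gbsmut.restriction.RestrictionEnzyme.residual_site`), e.g.
    "TGCAG" for PstI fragments.  Phred scores are offset-33 encoded.
    """

    min_raw_length: int = 20
    min_trimmed_length: int = 64
    expected_prefix: str | None = None
    quality_threshold: int = 20
    check_prefix: bool = True

    def __post_init__(self) -> None:
        if self.min_trimmed_length < self.min_raw_length:
            raise ValueError("min_trimmed_length must be >= min_raw_length")
        if self.expected_prefix is not None:
            iupac_to_regex(self.expected_prefix)  # validate alphabet

    @classmethod
    def for_enzyme(cls, enzyme: RestrictionEnzyme, **kw) -> "ReadQCParams":
        return cls(expected_prefix=enzyme.residual_site(), **kw)


@dataclass(frozen=True)
class ReadDecision:
    """Outcome for a single read: kept (with trimmed sequence) or a reason."""

    kept: bool
    reason: str | None = None
    sequence: str | None = None
    qualities: list[int] | None = None


@dataclass
class ReadQCReport:
    """Per-reason discard tallies; ``kept + sum(discarded) == total``."""

    total: int = 0
    kept: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in DISCARD_REASONS}
    )

    def add(self, decision: ReadDecision) -> None:
        self.total += 1
        if decision.kept:
            self.kept += 1
        else:
            self.discarded[decision.reason] += 1

    def to_tsv(self) -> str:
        lines = ["metric\tcount", f"total\t{self.total}", f"kept\t{self.kept}"]
        lines += [f"{r}\t{n}" for r, n in self.discarded.items()]
        return "\n".join(lines) + "\n"


def filter_read(
    sequence: str,
    qualities: list[int],
    params: ReadQCParams,
) -> ReadDecision:
    """Apply the QC rules to one read; see the module docstring for the order."""
    if len(sequence) != len(qualities):
        raise ValueError(
            f"sequence length {len(sequence)} != quality length {len(qualities)}"
        )
    seq = sequence.upper()
    if not set(seq) <= set("ACGTN"):
        raise ValueError(f"sequence contains non-ACGTN characters: {seq!r}")

    if "N" in seq:
        return ReadDecision(False, "contains_N")
    if len(seq) < params.min_raw_length:
        return ReadDecision(False, "too_short_raw")
    if params.check_prefix and params.expected_prefix:
        rx = re.compile(iupac_to_regex(params.expected_prefix))
        if rx.match(seq) is None:
            return ReadDecision(False, "prefix_mismatch")
    # 3' quality trim: drop the maximal suffix of bases below threshold.
    end = len(seq)
    while end > 0 and qualities[end - 1] < params.quality_threshold:
        end -= 1
    if end < params.min_trimmed_length:
        return ReadDecision(False, "too_short_after_trim")
    return ReadDecision(True, None, seq[:end], qualities[:end])


def _open_maybe_gzip(path: str | Path, mode: str) -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _iter_fastq(handle: IO) -> Iterator[SeqRecord]:
    yield from SeqIO.parse(handle, "fastq")


def run_readqc(
    fastq_in: str | Path,
    fastq_out: str | Path | None,
    params: ReadQCParams,
) -> ReadQCReport:
    """Stream a FASTQ file (optionally gzipped) through :func:`filter_read`.

    Writes the kept, trimmed reads to ``fastq_out`` (pass None to only
    tally) and returns the :class:`ReadQCReport`.
    """
    report = ReadQCReport()
    out_handle = _open_maybe_gzip(fastq_out, "w") if fastq_out else None
    try:
        with _open_maybe_gzip(fastq_in, "r") as fh:
            for rec in _iter_fastq(fh):
                quals = rec.letter_annotations["phred_quality"]
                decision = filter_read(str(rec.seq), quals, params)
                report.add(decision)
                if decision.kept and out_handle is not None:
                    kept = SeqRecord(
                        rec.seq[: len(decision.sequence)],
                        id=rec.id,
                        description="",
                    )
                    kept.letter_annotations["phred_quality"] = decision.qualities
                    SeqIO.write(kept, out_handle, "fastq")
    finally:
        if out_handle is not None:
            out_handle.close()
    return report


def filter_pairs(
    pairs: Iterable[tuple[tuple[str, list[int]], tuple[str, list[int]]]],
    params: ReadQCParams,
    require_both: bool = True,
) -> Iterator[tuple[ReadDecision, ReadDecision, bool]]:
    """Filter read pairs; mates are judged independently.

    Yields the two decisions plus whether the pair is kept: with
    ``require_both`` (default) both mates must pass, otherwise one suffices.
    """
    for (seq1, q1), (seq2, q2) in pairs:
        d1 = filter_read(seq1, q1, params)
        d2 = filter_read(seq2, q2, params)
        keep = (d1.kept and d2.kept) if require_both else (d1.kept or d2.kept)
        yield d1, d2, keep
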