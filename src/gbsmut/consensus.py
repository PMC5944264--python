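"""Wild-type consensus construction and induced-mutation calling.

The wild-type accessions of a mutagenized cohort carry a heterogeneous
natural background, so induced mutations are called against a *consensus*:
the set of positions at which every wild-type sample has the same non-missing
homozygous genotype (hom-ref or hom-alt).  At each consensus position every
mutant genotype is classified as

* ``induced``          — non-missing, adequately covered, different from the
                         consensus genotype (an EMS-induced change);
* ``consensus_equal``  — identical to the consensus genotype;
* ``removed``          — missing, or backed by fewer reads than the
                         per-sample depth cutoff (reason ``missing`` or
                         ``low_depth``).

The bookkeeping identity induced + equal + removed = positions x mutants
holds for every run.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Iterable, Sequence

import pandas as pd

from .variants import VariantTable

__all__ = [
    "ConsensusSite",
    "MutationCallRecord",
    "EmsSummary",
    "build_consensus",
    "call_ems",
    "summarize_by_sample",
    "consensus_to_frame",
]


@dataclass(frozen=True)
class ConsensusSite:
    """A position where all wild-type samples share one homozygous genotype."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: tuple[int, int]  # (0, 0) hom-ref or (1, 1) hom-alt

    def __post_init__(self) -> None:
        if self.genotype not in ((0, 0), (1, 1)):
            raise ValueError("consensus genotype must be homozygous")

    @property
    def klass(self) -> str:
        return "hom_ref" if self.genotype == (0, 0) else "hom_alt"


@dataclass(frozen=True)
class MutationCallRecord:
    """Classification of one mutant sample at one consensus position."""

    sample: str
    contig: str
    pos: int
    category: str  # induced | consensus_equal | removed
    observed: tuple[int, int] | None
    removal_reason: str | None = None  # low_depth | missing


@dataclass
class EmsSummary:
    n_consensus: int
    n_mutants: int
    induced: int
    consensus_equal: int
    removed: int

    @property
    def total(self) -> int:
        return self.induced + self.consensus_equal + self.removed


def build_consensus(
    table: VariantTable,
    wildtype_samples: Sequence[str],
) -> list[ConsensusSite]:
    """Consensus from the variants all wild-type accessions have in common.

    A filtered site enters the consensus iff every wild-type sample has a
    non-missing call, all those calls are identical, and the shared genotype
    is homozygous.  Sites shared as heterozygotes are excluded (consistent
    with the upstream het-only exclusion).
    """
    wt = list(wildtype_samples)
    if not wt:
        raise ValueError("no wild-type samples given")
    missing = [s for s in wt if s not in table.samples]
    if missing:
        raise ValueError(f"wild-type samples absent from call set: {missing}")

    consensus = []
    for site in table.sites:
        if not site.is_biallelic:
            raise ValueError("build_consensus expects a filtered, biallelic call set")
        genotypes = {site.calls[s].alleles for s in wt}
        if None in genotypes or len(genotypes) != 1:
            continue
        gt = genotypes.pop()
        if gt[0] != gt[1]:
            continue
        consensus.append(
            ConsensusSite(site.contig, site.pos, site.ref, site.alts[0], gt)
        )
    return consensus


def call_ems(
    table: VariantTable,
    consensus: Sequence[ConsensusSite],
    mutant_samples: Sequence[str],
    min_sample_depth: int = 8,
) -> tuple[list[MutationCallRecord], EmsSummary]:
    """Classify every (mutant, consensus position) pair.

    The ``min_sample_depth`` cutoff mirrors the per-sample filter rule (8
    reads): genotypes below it are ``removed`` rather than trusted.
    """
    mutants = list(mutant_samples)
    absent = [s for s in mutants if s not in table.samples]
    if absent:
        raise ValueError(f"mutant samples absent from call set: {absent}")

    site_index = {(s.contig, s.pos): s for s in table.sites}
    records: list[MutationCallRecord] = []
    for cons in consensus:
        site = site_index.get((cons.contig, cons.pos))
        if site is None:
            raise ValueError(
                f"consensus position {cons.contig}:{cons.pos} not in call set; "
                "consensus must be built from the same filtered sites"
            )
        for sample in mutants:
            call = site.calls[sample]
            if call.is_missing:
                cat, reason = "removed", (
                    "low_depth" if call.depth < min_sample_depth else "missing"
                )
            elif call.depth < min_sample_depth:
                cat, reason = "removed", "low_depth"
            elif call.alleles == cons.genotype:
                cat, reason = "consensus_equal", None
            else:
                cat, reason = "induced", None
            records.append(
                MutationCallRecord(
                    sample, cons.contig, cons.pos, cat, call.alleles, reason
                )
            )
    summary = EmsSummary(
        n_consensus=len(consensus),
        n_mutants=len(mutants),
        induced=sum(r.category == "induced" for r in records),
        consensus_equal=sum(r.category == "consensus_equal" for r in records),
        removed=sum(r.category == "removed" for r in records),
    )
    return records, summary


def summarize_by_sample(
    records: Iterable[MutationCallRecord],
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample induced/equal/removed counts, joined with treatment labels.

    Column sums reproduce the :class:`EmsSummary` totals.
    """
    df = pd.DataFrame(
        [(r.sample, r.category) for r in records], columns=["sample", "category"]
    )
    if df.empty:
        counts = pd.DataFrame(
            columns=["induced", "consensus_equal", "removed"], dtype=int
        )
        counts.index.name = "sample"
    else:
        counts = (
            df.groupby(["sample", "category"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["induced", "consensus_equal", "removed"], fill_value=0)
        )
        counts.columns.name = None
    counts = counts.reset_index()
    if manifest is not None and "treatment" in manifest.columns:
        counts = counts.merge(
            manifest[["sample_id", "treatment"]],
            left_on="sample",
            right_on="sample_id",
            how="left",
        ).drop(columns="sample_id")
    return counts


def consensus_to_frame(consensus: Sequence[ConsensusSite]) -> pd.DataFrame:
    """Tabular view (also BED-writable: start = pos - 1)."""
    return pd.DataFrame(
        [
            {
                "contig": c.contig,
                "start": c.pos - 1,
                "end": c.pos - 1 + len(c.ref),
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "consensus_class": c.klass,
            }
            for c in consensus
        ]
    )


def records_to_frame(records: Sequence[MutationCallRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "contig": r.contig,
                "pos": r.pos,
                "category": r.category,
                "observed_gt": "./." if r.observed is None else f"{r.observed[0]}/{r.observed[1]}",
                "removal_reason": r.removal_reason or "",
            }
            for r in records
        ]
    )
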