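"""End-to-end orchestration: simulated cohort -> filter -> consensus -> EMS calls.

Ties the stages together and scores the result against the simulator's
ground truth.  Recall and precision are evaluated at consensus positions
only: the consensus defines the universe of positions at which induced
mutations can be called at all, mirroring how the analysis restricts the
mutant/wild-type comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import compute_spectrum, SpectrumSummary
from .consensus import (
    ConsensusSite,
    EmsSummary,
    MutationCallRecord,
    build_consensus,
    call_ems,
)
from .gfilter import FilterParams, FilterTally, filter_table
from .simulate import Genome, SimulationConfig, simulate_cohort
from .variants import VariantTable

__all__ = ["PipelineResult", "run_pipeline", "score_against_truth", "RecoveryScore"]


@dataclass
class RecoveryScore:
    """Truth-table scoring of induced-mutation calls at consensus positions."""

    true_positives: int
    false_negatives: int
    false_positives: int

    @property
    def recall(self) -> float | None:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else None


@dataclass
class PipelineResult:
    config: SimulationConfig
    genome: Genome
    truth: pd.DataFrame
    manifest: pd.DataFrame
    raw_table: VariantTable
    filtered: VariantTable
    tally: FilterTally
    consensus: list[ConsensusSite]
    records: list[MutationCallRecord]
    summary: EmsSummary
    score: RecoveryScore

    def induced_spectrum(self) -> SpectrumSummary:
        """Substitution spectrum of the called induced SNP changes.

        Classified from the site ref/alt alleles of each induced record.
        """
        site_alleles = {(s.contig, s.pos): (s.ref, s.alts[0]) for s in self.filtered}
        pairs = [
            site_alleles[(r.contig, r.pos)]
            for r in self.records
            if r.category == "induced"
        ]
        pairs = [(ref, alt) for ref, alt in pairs if len(ref) == 1 and len(alt) == 1]
        return compute_spectrum(pairs)

    def induced_ems_class_fraction(self) -> float | None:
        """Fraction of induced SNP calls in the canonical EMS class (G>A or C>T).

        This is the directed counterpart of the simulator's
        ``transition_fraction`` parameter.
        """
        site_alleles = {(s.contig, s.pos): (s.ref, s.alts[0]) for s in self.filtered}
        pairs = [
            site_alleles[(r.contig, r.pos)]
            for r in self.records
            if r.category == "induced"
        ]
        pairs = [(r, a) for r, a in pairs if len(r) == 1 and len(a) == 1]
        if not pairs:
            return None
        hits = sum((r, a) in (("G", "A"), ("C", "T")) for r, a in pairs)
        return hits / len(pairs)

    def filtered_spectrum(self) -> SpectrumSummary:
        """Spectrum over every SNP surviving the genotype filter."""
        return compute_spectrum(
            (s.ref, s.alts[0]) for s in self.filtered if s.is_snp
        )


def score_against_truth(
    truth: pd.DataFrame,
    consensus: list[ConsensusSite],
    records: list[MutationCallRecord],
) -> RecoveryScore:
    """Compare induced calls with truth EMS records at consensus positions."""
    cons_pos = {(c.contig, c.pos) for c in consensus}
    ems = truth[truth["origin"] == "ems"]
    truth_keys = {
        (row.sample, row.contig, row.pos)
        for row in ems.itertuples()
        if (row.contig, row.pos) in cons_pos
    }
    called = {
        (r.sample, r.contig, r.pos) for r in records if r.category == "induced"
    }
    tp = len(truth_keys & called)
    return RecoveryScore(
        true_positives=tp,
        false_negatives=len(truth_keys - called),
        false_positives=len(called - truth_keys),
    )


def run_pipeline(
    config: SimulationConfig,
    filter_params: FilterParams = FilterParams(),
    min_sample_depth: int | None = None,
) -> PipelineResult:
    """Simulate a cohort and run filtering, consensus and EMS calling on it."""
    if min_sample_depth is None:
        min_sample_depth = filter_params.min_sample_depth
    genome, truth, raw_table, manifest = simulate_cohort(config)
    filtered, tally = filter_table(raw_table, filter_params)
    consensus = build_consensus(filtered, config.wildtype_samples)
    records, summary = call_ems(
        filtered, consensus, config.mutant_samples, min_sample_depth
    )
    score = score_against_truth(truth, consensus, records)
    return PipelineResult(
        config, genome, truth, manifest, raw_table, filtered, tally,
        consensus, records, summary, score,
    )
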