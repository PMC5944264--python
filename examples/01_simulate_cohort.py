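"""Simulate a GBS cohort of 14 wild-type and 82 EMS-mutant accessions.

Generates a random reference with gene models and a methylation mask, digests
it in silico, and emits a multi-sample call set restricted to the size-selected
fragments, together with a ground-truth table of every planted variant.
"""

from gbsmut import SimulationConfig, simulate_cohort

config = SimulationConfig(seed=1)
genome, truth, table, manifest = simulate_cohort(config)

print(f"reference: {len(genome.contigs)} contigs, {genome.total_length:,} bp, "
      f"{len(genome.genes)} genes")
print(f"cohort: {len(table.samples)} samples "
      f"({config.n_wildtype} wild type + {config.n_mutant} mutants)")
print(f"variant sites in the reduced representation: {len(table)}")
print("planted variants by origin:")
print(truth.groupby("origin").size().to_string())
# 'ems' rows are the heterozygous induced mutations the pipeline must find;
# 'background' rows are shared by all samples; 'private_wt' rows are the
# natural heterogeneity of the wild-type panel.
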