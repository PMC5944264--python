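"""Apply the GBS-specific genotype filter to a simulated multi-sample call set.

Per-sample rules first (depth < 8 reads -> missing; heterozygote with allele
balance outside 20-80% -> reverted to the majority homozygote), then site
rules (both alleles called, >= 66% call rate, summed depth >= 20, summed
per-allele depth >= 10, not heterozygous-only).
"""

from gbsmut import FilterParams, SimulationConfig, filter_table, simulate_cohort

config = SimulationConfig(seed=4)
_, _, table, _ = simulate_cohort(config)

filtered, tally = filter_table(table, FilterParams())
print(tally.to_tsv())
print(f"{tally.kept} of {tally.input_sites} sites pass the filter")
# Shared heterozygous background sites fall to the het-only rule and sites
# whose only carrier dropped out fall to the both-alleles rule — the main
# reductions a GBS call set undergoes before consensus building.
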