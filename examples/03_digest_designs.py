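"""Compare the nGBS (MslI) and ddGBS (PstI+MspI) library designs in silico.

Shows how CHG (CpNpG) methylation, which blocks PstI, shrinks the sequencable
fraction of a plant genome under the double-digest design.
"""

from gbsmut import SelectionParams, SimulationConfig, digest, get_enzyme, select_fragments
from gbsmut.simulate import generate_genome

for chg_rate in (0.0, 0.3, 0.6):
    config = SimulationConfig(
        seed=3, n_contigs=1, contig_length=200_000, n_genes=0,
        methylation_rate_chg=chg_rate, methylation_rate_cpg=0.6,
    )
    genome = generate_genome(config)

    ngbs = digest(genome.contigs, get_enzyme("MslI"), genome.methylation)
    ngbs_sel, ngbs_sum = select_fragments(ngbs, SelectionParams(200, 500))

    ddgbs = digest(
        genome.contigs, [get_enzyme("PstI"), get_enzyme("MspI")], genome.methylation
    )
    ddgbs_sel, ddgbs_sum = select_fragments(
        ddgbs, SelectionParams(200, 500, end_rule="rare-common")
    )
    print(
        f"CHG methylation {chg_rate:.0%}: "
        f"nGBS {ngbs_sum.count} fragments ({ngbs_sum.total_bases:,} bp), "
        f"ddGBS {ddgbs_sum.count} fragments ({ddgbs_sum.total_bases:,} bp)"
    )
# The nGBS numbers are untouched by methylation (MslI is insensitive) while
# the ddGBS representation collapses as CHG methylation rises — the behaviour
# that makes enzyme choice critical in heavily methylated genomes.
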