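"""Statistical and structural properties of the synthetic cohort generator."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from gbsmut.simulate import (
    ReadSimParams,
    SimulationConfig,
    callable_fragments,
    generate_genome,
    simulate_cohort,
    simulate_population,
    simulate_reads,
    write_genome_fasta,
)


class TestGenome:
    def test_length_bookkeeping(self):
        config = SimulationConfig(seed=1, n_contigs=2, contig_length=50_000, n_genes=0)
        genome = generate_genome(config)
        assert len(genome.contigs) == 2
        assert genome.total_length == 100_000

    def test_seeded_determinism_byte_identical(self, tmp_path):
        config = SimulationConfig(seed=4, n_contigs=1, contig_length=50_000, n_genes=4)
        paths = []
        for run in range(2):
            genome = generate_genome(config)
            p = tmp_path / f"ref{run}.fasta"
            write_genome_fasta(genome, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_gc_fraction_within_binomial_bound(self):
        n = 100_000
        config = SimulationConfig(
            seed=2, n_contigs=1, contig_length=n, gc_fraction=0.5, n_genes=0
        )
        genome = generate_genome(config)
        seq = genome.contigs["contig1"]
        gc = seq.count("G") + seq.count("C")
        assert abs(gc - 0.5 * n) <= 3 * np.sqrt(n * 0.25)

    def test_gene_models_are_valid_orfs(self):
        config = SimulationConfig(seed=3, n_contigs=1, contig_length=80_000, n_genes=8)
        genome = generate_genome(config)
        assert len(genome.genes) == 8
        for gene in genome.genes:
            cds = gene.cds_sequence(genome.contigs[gene.contig])
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = str(Seq(cds).translate())
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_genes_non_overlapping(self):
        config = SimulationConfig(seed=3, n_contigs=1, contig_length=80_000, n_genes=8)
        genome = generate_genome(config)
        spans = sorted((g.start, g.end) for g in genome.genes)
        for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
            assert b1 <= a2

    def test_intron_splice_motifs(self):
        config = SimulationConfig(seed=6, n_contigs=1, contig_length=80_000, n_genes=8)
        genome = generate_genome(config)
        checked = 0
        for gene in genome.genes:
            seq = genome.contigs[gene.contig]
            for a, b in gene.introns():
                intron = seq[a:b]
                if gene.strand == "-":
                    intron = str(Seq(intron).reverse_complement())
                assert intron.startswith("GT") and intron.endswith("AG")
                checked += 1
        assert checked > 0

    def test_gene_too_large_for_contig_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            generate_genome(
                SimulationConfig(seed=1, n_contigs=1, contig_length=3000, n_genes=2)
            )

    def test_methylation_contexts_correct(self):
        config = SimulationConfig(seed=8, n_contigs=1, contig_length=30_000, n_genes=0)
        genome = generate_genome(config)
        seq = genome.contigs["contig1"]
        mask = genome.methylation["contig1"]
        assert mask, "expected some methylated cytosines"
        for pos, ctx in mask.items():
            assert seq[pos] == "C"
            if ctx == "CpG":
                assert seq[pos + 1] == "G"
            else:
                assert ctx == "CHG"
                assert seq[pos + 1] in "ACT" and seq[pos + 2] == "G"


class TestPopulation:
    def test_config_validation(self):
        with pytest.raises(ValueError, match="transition_fraction"):
            SimulationConfig(transition_fraction=1.5)
        with pytest.raises(ValueError, match="depth_dispersion"):
            SimulationConfig(depth_dispersion=0)
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig(seed=2**31)

    def test_sample_panel_size(self, small_config, small_cohort):
        _, _, table, manifest = small_cohort
        assert len(table.samples) == small_config.n_samples
        assert (manifest["group"] == "wildtype").sum() == small_config.n_wildtype
        assert (manifest["group"] == "mutant").sum() == small_config.n_mutant

    def test_zero_ems_rate_no_ems_records(self):
        config = SimulationConfig(
            seed=5, n_contigs=1, contig_length=60_000, n_genes=4,
            n_wildtype=3, n_mutant=4, ems_mutations_per_sample=0.0,
        )
        _, truth, _, _ = simulate_cohort(config)
        assert (truth["origin"] == "ems").sum() == 0

    def test_forced_transition_fraction_one(self):
        config = SimulationConfig(
            seed=5, n_contigs=1, contig_length=60_000, n_genes=4,
            n_wildtype=3, n_mutant=6, transition_fraction=1.0,
        )
        _, truth, _, _ = simulate_cohort(config)
        ems = truth[truth["origin"] == "ems"]
        assert len(ems) > 0
        assert all(
            (r, a) in (("G", "A"), ("C", "T"))
            for r, a in zip(ems["ref"], ems["alt"])
        )

    def test_ems_only_in_mutants_and_zygosity(self, small_cohort):
        _, truth, _, manifest = small_cohort
        mutants = set(manifest.loc[manifest["group"] == "mutant", "sample_id"])
        ems = truth[truth["origin"] == "ems"]
        assert set(ems["sample"]) <= mutants
        assert (ems["zygosity"] == "het").all()

    def test_background_shared_by_all_samples(self, small_config, small_cohort):
        _, truth, _, _ = small_cohort
        bg = truth[truth["origin"] == "background"]
        per_variant = bg.groupby(["contig", "pos", "ref", "alt", "zygosity"])[
            "sample"
        ].nunique()
        assert (per_variant == small_config.n_samples).all()

    def test_transition_share_within_binomial_bound(self):
        # pool EMS draws across seeds until the bound is tight
        records = []
        for seed in (101, 102, 103):
            config = SimulationConfig(
                seed=seed, n_contigs=1, contig_length=120_000, n_genes=0,
                n_wildtype=2, n_mutant=82, ems_mutations_per_sample=25.0,
            )
            _, truth, _, _ = simulate_cohort(config)
            ems = truth[truth["origin"] == "ems"]
            records += [
                (r, a) in (("G", "A"), ("C", "T"))
                for r, a in zip(ems["ref"], ems["alt"])
            ]
        n = len(records)
        assert n >= 5000
        p = 0.678
        assert abs(np.mean(records) - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_ems_counts_poisson_distributed(self):
        """Chi-square goodness of fit of per-mutant EMS counts, alpha=0.01."""
        config = SimulationConfig(
            seed=77, n_contigs=1, contig_length=120_000, n_genes=0,
            n_wildtype=2, n_mutant=82,
        )
        _, truth, _, _ = simulate_cohort(config)
        counts = (
            truth[truth["origin"] == "ems"].groupby("sample").size()
            .reindex(config.mutant_samples, fill_value=0)
        )
        mu = config.ems_mutations_per_sample
        # bin the Poisson support so expected counts stay >= 5
        edges = [0, 14, 17, 20, 23, 26, np.inf]
        observed, expected = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            observed.append(((counts >= lo) & (counts < hi)).sum())
            p_lo = stats.poisson.cdf(lo - 1, mu)
            p_hi = stats.poisson.cdf(hi - 1, mu) if np.isfinite(hi) else 1.0
            expected.append((p_hi - p_lo) * len(counts))
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        crit = stats.chi2.ppf(0.99, df=len(observed) - 1)
        assert chi2 < crit

    def test_variants_restricted_to_selected_fragments(self, small_config, small_cohort):
        genome, _, table, _ = small_cohort
        frags = callable_fragments(small_config, genome)
        intervals = {(f.contig, f.start, f.end) for f in frags}
        for site in table.sites:
            pos0 = site.pos - 1
            assert any(
                c == site.contig and a <= pos0 < b for c, a, b in intervals
            )

    def test_identical_seed_identical_vcf(self, tmp_path):
        from gbsmut.variants import write_vcf

        config = SimulationConfig(
            seed=12, n_contigs=1, contig_length=60_000, n_genes=4,
            n_wildtype=3, n_mutant=4,
        )
        blobs = []
        for run in range(2):
            _, _, table, _ = simulate_cohort(config)
            p = tmp_path / f"v{run}.vcf"
            write_vcf(table, p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]


@pytest.fixture(scope="module")
def ctx():
    config = SimulationConfig(
        seed=5, n_contigs=1, contig_length=80_000, n_genes=0,
        n_wildtype=2, n_mutant=2,
    )
    genome = generate_genome(config)
    frags = callable_fragments(config, genome)
    return config, genome, frags


class TestReads:
    def test_reads_start_with_residual_site(self, ctx):
        import re

        from gbsmut.restriction import get_enzyme, iupac_to_regex

        config, genome, frags = ctx
        reads = simulate_reads(frags, genome, config.enzyme_objects(), seed=1)
        assert reads
        rx = re.compile(iupac_to_regex(get_enzyme("MslI").residual_site()))
        for _, s1, _, s2, _ in reads:
            assert rx.match(s1), s1[:10]
            assert rx.match(s2), s2[:10]

    def test_empty_fragment_set_warns(self, ctx):
        config, genome, _ = ctx
        with pytest.warns(UserWarning, match="empty fragment set"):
            assert simulate_reads([], genome, config.enzyme_objects()) == []

    def test_seeded_reads_identical(self, ctx):
        config, genome, frags = ctx
        a = simulate_reads(frags, genome, config.enzyme_objects(), seed=9)
        b = simulate_reads(frags, genome, config.enzyme_objects(), seed=9)
        assert a == b

    def test_quality_strings_valid_phred33(self, ctx):
        config, genome, frags = ctx
        reads = simulate_reads(
            frags, genome, config.enzyme_objects(),
            ReadSimParams(corrupt_fraction=0.5), seed=2,
        )
        for _, s1, q1, s2, q2 in reads:
            assert len(s1) == len(q1) and len(s2) == len(q2)
            for q in (q1, q2):
                assert all(33 <= ord(ch) <= 74 for ch in q)
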