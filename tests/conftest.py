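"""Shared fixtures: a small simulated cohort and helper builders."""

import pytest

from gbsmut import SimulationConfig, simulate_cohort
from gbsmut.variants import GenotypeCall, VariantSite, VariantTable


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort (1 contig, 17 samples) for fast unit tests."""
    return SimulationConfig(
        seed=11,
        n_contigs=1,
        contig_length=80_000,
        n_genes=8,
        n_wildtype=5,
        n_mutant=12,
        ems_mutations_per_sample=10.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_site(calls, ref="A", alt="G", contig="c1", pos=100, samples=None):
    """Build a biallelic VariantSite from (gt, dp, ad_ref, ad_alt) tuples.

    ``gt`` is None (missing), "rr", "ra" or "aa".
    """
    code = {"rr": (0, 0), "ra": (0, 1), "aa": (1, 1), None: None}
    if samples is None:
        samples = [f"s{i}" for i in range(len(calls))]
    call_map = {
        s: GenotypeCall(code[gt], dp, (adr, ada))
        for s, (gt, dp, adr, ada) in zip(samples, calls)
    }
    return VariantSite(contig, pos, ref, (alt,), call_map)


def make_table(sites, samples):
    return VariantTable(list(samples), list(sites))
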