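"""GBS genotype-filter rules, oracle equivalence and monotonicity."""

import numpy as np
import pytest

from gbsmut.gfilter import (
    FilterParams,
    apply_sample_rules,
    apply_site_rules,
    filter_table,
)
from gbsmut.variants import GenotypeCall, VariantSite, VariantTable

from conftest import make_site, make_table

P = FilterParams()


# ---------------------------------------------------------------------------
# Independent brute-force reference, written directly from the rule text.
# Sites are plain tuples: (gt, dp, ad_ref, ad_alt) with gt in
# {None, "rr", "ra", "aa"}.


def oracle_sample(call, p):
    gt, dp, adr, ada = call
    if gt is not None and dp < p.min_sample_depth:
        gt = None
    if gt == "ra":
        tot = adr + ada
        if tot > 0:
            ab = ada / tot
            if ab < p.allele_balance_low:
                gt = "rr"
            elif ab > p.allele_balance_high:
                gt = "aa"
    return (gt, dp, adr, ada)


def oracle_site(calls, p, n_samples):
    adj = [oracle_sample(c, p) for c in calls]
    present = [c for c in adj if c[0] is not None]
    alleles = set()
    for gt, *_ in present:
        alleles |= {"rr": {0}, "ra": {0, 1}, "aa": {1}}[gt]
    if len(alleles) < 2:
        return adj, False
    if len(present) / n_samples < p.min_call_fraction:
        return adj, False
    if sum(c[1] for c in present) < p.min_total_depth:
        return adj, False
    if sum(c[2] for c in present) < p.min_allele_depth:
        return adj, False
    if sum(c[3] for c in present) < p.min_allele_depth:
        return adj, False
    if all(gt == "ra" for gt, *_ in present):
        return adj, False
    return adj, True


def random_matrix(rng, n_sites=50, n_samples=10):
    """A random genotype matrix exercising all rules."""
    sites = []
    for _ in range(n_sites):
        calls = []
        for _ in range(n_samples):
            gt = rng.choice([None, "rr", "ra", "aa"], p=[0.1, 0.45, 0.3, 0.15])
            dp = int(rng.integers(0, 31))
            if gt == "ra":
                ada = int(rng.binomial(dp, rng.choice([0.5, 0.1, 0.9])))
            elif gt == "aa":
                ada = int(rng.binomial(dp, 0.97))
            else:
                ada = int(rng.binomial(dp, 0.03))
            calls.append((gt, dp, dp - ada, ada))
        sites.append(calls)
    return sites


GT_CODE = {(0, 0): "rr", (0, 1): "ra", (1, 1): "aa", None: None}


class TestSampleRules:
    def test_low_depth_set_missing(self):
        call = GenotypeCall((0, 1), 7, (3, 4))
        adj, _ = apply_sample_rules(call, P)
        assert adj.is_missing

    def test_depth_eight_retained(self):
        call = GenotypeCall((0, 1), 8, (4, 4))
        adj, _ = apply_sample_rules(call, P)
        assert adj.alleles == (0, 1)

    def test_high_ab_reverts_to_hom_alt(self):
        call = GenotypeCall((0, 1), 20, (3, 17))  # AB = 0.85
        adj, _ = apply_sample_rules(call, P)
        assert adj.alleles == (1, 1)

    def test_low_ab_reverts_to_hom_ref(self):
        call = GenotypeCall((0, 1), 20, (17, 3))  # AB = 0.15
        adj, _ = apply_sample_rules(call, P)
        assert adj.alleles == (0, 0)

    def test_band_edges_inclusive(self):
        # AB exactly 0.20 and 0.80 stay heterozygous (strictly-outside rule)
        assert apply_sample_rules(GenotypeCall((0, 1), 20, (16, 4)), P)[0].alleles == (0, 1)
        assert apply_sample_rules(GenotypeCall((0, 1), 20, (4, 16)), P)[0].alleles == (0, 1)

    def test_balanced_het_unchanged(self):
        call = GenotypeCall((0, 1), 20, (10, 10))
        adj, _ = apply_sample_rules(call, P)
        assert adj == call

    def test_het_without_ad_flagged(self):
        call = GenotypeCall((0, 1), 20, ())
        adj, skipped = apply_sample_rules(call, P)
        assert skipped and adj.alleles == (0, 1)

    def test_homozygote_ab_not_touched(self):
        call = GenotypeCall((1, 1), 20, (10, 10))
        adj, _ = apply_sample_rules(call, P)
        assert adj.alleles == (1, 1)


class TestSiteRules:
    def test_call_fraction_boundary(self):
        # 63/96 = 0.656 < 0.66 fails; 64/96 = 0.667 passes
        calls = [("rr", 20, 20, 0)] * 62 + [("ra", 20, 10, 10)] + [(None, 0, 0, 0)] * 33
        site = make_site(calls)
        keep, reason = apply_site_rules(site, P, 96)
        assert (keep, reason) == (False, "call_fraction")
        calls[63] = ("rr", 20, 20, 0)
        keep, _ = apply_site_rules(make_site(calls), P, 96)
        assert keep

    def test_het_only_excluded(self):
        calls = [("ra", 20, 10, 10)] * 8 + [(None, 0, 0, 0)] * 2
        keep, reason = apply_site_rules(make_site(calls), P, 10)
        assert (keep, reason) == (False, "het_only")

    def test_monomorphic_excluded(self):
        calls = [("rr", 20, 20, 0)] * 10
        keep, reason = apply_site_rules(make_site(calls), P, 10)
        assert (keep, reason) == (False, "monomorphic")

    def test_summed_alt_depth_boundary(self):
        # summed alt AD 9 < 10 drops; 10 keeps
        calls = [("rr", 20, 20, 0)] * 8 + [("ra", 18, 9, 9), ("rr", 20, 20, 0)]
        keep, reason = apply_site_rules(make_site(calls), P, 10)
        assert (keep, reason) == (False, "allele_depth")
        calls[8] = ("ra", 20, 10, 10)
        keep, _ = apply_site_rules(make_site(calls), P, 10)
        assert keep

    def test_total_depth_boundary(self):
        calls = [("rr", 5, 5, 0), ("aa", 9, 0, 9), ("ra", 5, 2, 3)]
        # rule (e) removes the dp<8 calls first in filter_table; here we call
        # site rules directly so every call counts: DP sum 19 < 20
        keep, reason = apply_site_rules(make_site(calls), FilterParams(min_call_fraction=0, min_allele_depth=0), 3)
        assert (keep, reason) == (False, "total_depth")

    def test_zero_samples_is_error(self):
        with pytest.raises(ValueError, match="n_samples"):
            apply_site_rules(make_site([("rr", 20, 20, 0)]), P, 0)


class TestFilterTable:
    def _table_from_matrix(self, matrix):
        inv = {"rr": (0, 0), "ra": (0, 1), "aa": (1, 1), None: None}
        samples = [f"s{i}" for i in range(len(matrix[0]))]
        sites = []
        for k, calls in enumerate(matrix):
            call_map = {
                s: GenotypeCall(inv[gt], dp, (adr, ada))
                for s, (gt, dp, adr, ada) in zip(samples, calls)
            }
            sites.append(VariantSite("c1", k + 1, "A", ("G",), call_map))
        return VariantTable(samples, sites)

    def test_hand_built_sites_one_drop_per_rule(self):
        """Six hand-built sites: one clean keeper plus one violation per rule.

        The summed-depth rule is only reachable when individual calls are
        allowed to be shallow, so the per-sample cutoff is lowered to 2.
        """
        deep_mixed = [("rr", 20, 20, 0)] * 5 + [("aa", 20, 0, 20)] * 5
        sites = {
            "monomorphic": [("rr", 20, 20, 0)] * 10,
            "call_fraction": [("rr", 20, 20, 0)] * 3
            + [("aa", 20, 0, 20)] * 3
            + [(None, 0, 0, 0)] * 4,  # 6/10 = 0.60 < 0.66
            "total_depth": [("rr", 2, 2, 0)] * 4
            + [("aa", 2, 0, 2)] * 3
            + [(None, 0, 0, 0)] * 3,  # DP sum 14 < 20
            "allele_depth": [("rr", 20, 20, 0)] * 9
            + [("aa", 9, 0, 9)],  # alt AD 9 < 10
            "het_only": [("ra", 20, 10, 10)] * 10,
        }
        params = FilterParams(min_sample_depth=2)
        table = self._table_from_matrix([deep_mixed] + list(sites.values()))
        _, tally = filter_table(table, params)
        assert tally.kept == 1
        assert tally.dropped == {
            "monomorphic": 1, "call_fraction": 1, "total_depth": 1,
            "allele_depth": 1, "het_only": 1,
        }

    def test_oracle_equivalence_quick(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            matrix = random_matrix(rng)
            table = self._table_from_matrix(matrix)
            filtered, tally = filter_table(table, P)
            kept_expected = []
            for k, calls in enumerate(matrix):
                adj, keep = oracle_site(calls, P, len(calls))
                if keep:
                    kept_expected.append((k + 1, adj))
            assert [s.pos for s in filtered.sites] == [p for p, _ in kept_expected]
            for site, (_, adj) in zip(filtered.sites, kept_expected):
                got = [GT_CODE[site.calls[s].alleles] for s in filtered.samples]
                assert got == [gt for gt, *_ in adj]

    def test_idempotence(self):
        rng = np.random.default_rng(77)
        table = self._table_from_matrix(random_matrix(rng))
        once, _ = filter_table(table, P)
        twice, tally = filter_table(once, P)
        assert len(twice) == len(once)
        assert all(
            a.calls == b.calls for a, b in zip(once.sites, twice.sites)
        )

    def test_tally_conservation(self):
        rng = np.random.default_rng(5)
        table = self._table_from_matrix(random_matrix(rng))
        _, tally = filter_table(table, P)
        assert tally.kept + sum(tally.dropped.values()) == tally.input_sites
        assert tally.input_sites == len(table)

    @pytest.mark.parametrize(
        "tighter",
        [
            {"min_call_fraction": 0.9},
            {"min_total_depth": 60},
            {"min_allele_depth": 25},
            {"min_sample_depth": 15},
            {"allele_balance_low": 0.35, "allele_balance_high": 0.65},
        ],
    )
    def test_tightening_thresholds_monotone(self, tighter):
        rng = np.random.default_rng(99)
        table = self._table_from_matrix(random_matrix(rng, n_sites=80))
        base, _ = filter_table(table, P)
        strict, _ = filter_table(table, FilterParams(**tighter))
        assert len(strict) <= len(base)

    def test_reversion_preserves_sample_count(self):
        rng = np.random.default_rng(31)
        table = self._table_from_matrix(random_matrix(rng))
        filtered, _ = filter_table(table, P)
        for site in filtered.sites:
            assert set(site.calls) == set(table.samples)
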