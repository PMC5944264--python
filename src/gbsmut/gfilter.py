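"""GBS-specific genotype filtering of a multi-sample variant call set.

Reduced-representation genotyping produces uneven depth and a high rate of
miscalled heterozygotes, so calls are cleaned with a two-level rule set.

Per-sample rules (applied first):
  (e) a genotype backed by fewer than ``min_sample_depth`` reads (default 8)
      is set missing;
  (f) a heterozygous call whose allele balance AB = alt depth / (ref + alt
      depth) falls strictly outside [``allele_balance_low``,
      ``allele_balance_high``] (default [0.20, 0.80]) is reverted to the
      homozygote of the majority allele.

Per-site rules (on the adjusted calls; the first failing rule is reported):
  (a) both alleles must be observed among non-missing calls;
  (b) non-missing calls in at least ``min_call_fraction`` (default 0.66) of
      the manifest samples;
  (c) total depth summed over non-missing calls >= ``min_total_depth`` (20);
  (d) each allele's depth summed over non-missing calls >=
      ``min_allele_depth`` (10);
  (g) sites where every non-missing call is heterozygous are excluded.

Multiallelic records are decomposed to biallelic records before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .variants import (
    GenotypeCall,
    VariantSite,
    VariantTable,
    decompose_site,
    read_vcf,
    write_vcf,
)

__all__ = [
    "FilterParams",
    "FilterTally",
    "apply_sample_rules",
    "apply_site_rules",
    "filter_table",
    "run_filter",
    "DROP_REASONS",
]

DROP_REASONS = (
    "monomorphic",      # (a) fewer than two alleles observed
    "call_fraction",    # (b) too few genotyped samples
    "total_depth",      # (c) summed DP below threshold
    "allele_depth",     # (d) an allele's summed AD below threshold
    "het_only",         # (g) only heterozygous calls
)


@dataclass(frozen=True)
class FilterParams:
    min_call_fraction: float = 0.66
    min_total_depth: int = 20
    min_allele_depth: int = 10
    min_sample_depth: int = 8
    allele_balance_low: float = 0.20
    allele_balance_high: float = 0.80

    def __post_init__(self) -> None:
        if not (0 <= self.allele_balance_low < self.allele_balance_high <= 1):
            raise ValueError("require 0 <= AB low < AB high <= 1")
        if not (0 <= self.min_call_fraction <= 1):
            raise ValueError("min_call_fraction must be in [0, 1]")
        for name in ("min_total_depth", "min_allele_depth", "min_sample_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterTally:
    """Kept/dropped bookkeeping; kept + sum(dropped) = input sites."""

    input_sites: int = 0
    kept: int = 0
    dropped: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in DROP_REASONS}
    )
    ab_skipped_no_ad: int = 0  # het calls where AD was absent, rule (f) skipped

    def to_tsv(self) -> str:
        lines = [
            "metric\tcount",
            f"input_sites\t{self.input_sites}",
            f"kept\t{self.kept}",
        ]
        lines += [f"dropped_{r}\t{n}" for r, n in self.dropped.items()]
        lines.append(f"ab_skipped_no_ad\t{self.ab_skipped_no_ad}")
        return "\n".join(lines) + "\n"


def apply_sample_rules(
    call: GenotypeCall, params: FilterParams = FilterParams()
) -> tuple[GenotypeCall, bool]:
    """Rules (e) and (f) for one biallelic call.

    Returns the adjusted call and a flag set when an AD-less heterozygote
    had to skip the allele-balance rule.
    """
    if call.is_missing:
        return call, False
    if call.depth < params.min_sample_depth:
        return call.as_missing(), False
    if not call.is_het:
        return call, False
    if len(call.allele_depths) < 2:
        return call, True  # cannot evaluate AB; leave the het untouched
    ref_d, alt_d = call.allele_depths[0], call.allele_depths[1]
    if ref_d + alt_d == 0:
        return call, True
    ab = alt_d / (ref_d + alt_d)
    if ab < params.allele_balance_low:
        return GenotypeCall((0, 0), call.depth, call.allele_depths), False
    if ab > params.allele_balance_high:
        return GenotypeCall((1, 1), call.depth, call.allele_depths), False
    return call, False


def apply_site_rules(
    site: VariantSite,
    params: FilterParams = FilterParams(),
    n_samples: int | None = None,
) -> tuple[bool, str | None]:
    """Site rules (a)-(d) and the het-only exclusion (g) on adjusted calls.

    ``n_samples`` is the manifest panel size used as the call-fraction
    denominator (defaults to the number of calls at the site).
    """
    if n_samples is None:
        n_samples = len(site.calls)
    if n_samples == 0:
        raise ValueError("n_samples must be positive")

    present = [c for c in site.calls.values() if not c.is_missing]

    observed_alleles = {a for c in present for a in c.alleles}
    if len(observed_alleles) < 2:
        return False, "monomorphic"
    if len(present) / n_samples < params.min_call_fraction:
        return False, "call_fraction"
    if sum(c.depth for c in present) < params.min_total_depth:
        return False, "total_depth"
    ad_sum = [0, 0]
    for c in present:
        for i in range(min(2, len(c.allele_depths))):
            ad_sum[i] += c.allele_depths[i]
    if min(ad_sum) < params.min_allele_depth:
        return False, "allele_depth"
    if all(c.is_het for c in present):
        return False, "het_only"
    return True, None


def filter_table(
    table: VariantTable, params: FilterParams = FilterParams()
) -> tuple[VariantTable, FilterTally]:
    """Decompose, apply sample rules then site rules to every record."""
    tally = FilterTally()
    out = VariantTable(list(table.samples), contig_lengths=dict(table.contig_lengths))
    n_samples = len(table.samples)
    for raw_site in table.sites:
        for site in decompose_site(raw_site):
            tally.input_sites += 1
            adjusted: dict[str, GenotypeCall] = {}
            for sample, call in site.calls.items():
                new_call, skipped = apply_sample_rules(call, params)
                adjusted[sample] = new_call
                tally.ab_skipped_no_ad += skipped
            adj_site = VariantSite(
                site.contig, site.pos, site.ref, site.alts, adjusted
            )
            keep, reason = apply_site_rules(adj_site, params, n_samples)
            if keep:
                tally.kept += 1
                out.sites.append(adj_site)
            else:
                tally.dropped[reason] += 1
    return out, tally


def run_filter(
    vcf_in: str | Path,
    vcf_out: str | Path | None,
    params: FilterParams = FilterParams(),
    tally_out: str | Path | None = None,
) -> tuple[VariantTable, FilterTally]:
    """File-level wrapper: VCF in, filtered VCF + per-rule tally out."""
    table = read_vcf(vcf_in)
    filtered, tally = filter_table(table, params)
    if vcf_out is not None:
        write_vcf(filtered, vcf_out)
    if tally_out is not None:
        Path(tally_out).write_text(tally.to_tsv())
    return filtered, tally
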