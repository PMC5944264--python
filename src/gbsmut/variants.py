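"""In-memory model of a multi-sample variant call set and its VCF round trip.

The unit of analysis is a :class:`VariantSite` (one VCF record, biallelic
after decomposition) holding one :class:`GenotypeCall` per sample with
genotype (GT), total depth (DP) and per-allele depths (AD) — the substrate of
the GBS genotype filter and of the consensus/EMS comparison.  VCF reading and
writing goes through pysam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path


import pandas as pd
import pysam

__all__ = [
    "GenotypeCall",
    "VariantSite",
    "VariantTable",
    "read_vcf",
    "write_vcf",
    "decompose_site",
    "read_manifest",
    "write_manifest",
]

MISSING = None


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``alleles`` is a pair of allele indices (0 = ref) or ``None`` for a
    missing genotype; ``allele_depths`` is ordered (ref, alt, ...).
    """

    alleles: tuple[int, int] | None
    depth: int = 0
    allele_depths: tuple[int, ...] = ()

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def as_missing(self) -> "GenotypeCall":
        return replace(self, alleles=None)


@dataclass
class VariantSite:
    """One VCF record: position, alleles and the per-sample call map."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF positions are 1-based; got {self.pos}")
        if self.ref in self.alts:
            raise ValueError(f"ref allele {self.ref!r} repeated in alts")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def indel_length(self) -> int:
        """Signed length difference of the (biallelic) alt vs ref allele."""
        return len(self.alts[0]) - len(self.ref)


@dataclass
class VariantTable:
    """An ordered collection of sites sharing one sample panel."""

    samples: list[str]
    sites: list[VariantSite] = field(default_factory=list)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


def decompose_site(site: VariantSite) -> list[VariantSite]:
    """Split a multiallelic site into biallelic records, one per alt allele.

    In each decomposed record a genotype referring to a *different* alt
    allele is set missing, and AD is reduced to (ref, this-alt).  Biallelic
    sites pass through unchanged.
    """
    if site.is_biallelic:
        return [site]
    out = []
    for k, alt in enumerate(site.alts, start=1):
        calls = {}
        for sample, call in site.calls.items():
            if call.is_missing:
                calls[sample] = replace(call, allele_depths=_ad_pair(call, k))
                continue
            if any(a not in (0, k) for a in call.alleles):
                calls[sample] = GenotypeCall(None, call.depth, _ad_pair(call, k))
                continue
            remapped = tuple(0 if a == 0 else 1 for a in call.alleles)
            calls[sample] = GenotypeCall(remapped, call.depth, _ad_pair(call, k))
        out.append(VariantSite(site.contig, site.pos, site.ref, (alt,), calls))
    return out


def _ad_pair(call: GenotypeCall, alt_index: int) -> tuple[int, ...]:
    ad = call.allele_depths
    if len(ad) > alt_index:
        return (ad[0], ad[alt_index])
    return ad[:1] if ad else ()


def _vcf_header(table: VariantTable) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs = dict(table.contig_lengths)
    for site in table.sites:
        contigs.setdefault(site.contig, max(
            (s.pos + len(s.ref) for s in table.sites if s.contig == site.contig),
            default=site.pos,
        ))
    for contig, length in contigs.items():
        header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for sample in table.samples:
        header.add_sample(sample)
    return header


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a VariantTable as VCF (plain or bgzipped by extension)."""
    path = str(path)
    mode = "wz" if path.endswith(".gz") else "w"
    header = _vcf_header(table)
    with pysam.VariantFile(path, mode, header=header) as vcf:
        for site in table.sites:
            rec = vcf.new_record(
                contig=site.contig,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *site.alts),
            )
            for sample in table.samples:
                call = site.calls[sample]
                rec.samples[sample]["GT"] = call.alleles or (None, None)
                rec.samples[sample]["DP"] = call.depth
                if call.allele_depths:
                    rec.samples[sample]["AD"] = call.allele_depths
            vcf.write(rec)


def read_vcf(path: str | Path, require_depths: bool = True) -> VariantTable:
    """Read a VCF with GT/DP/AD into a :class:`VariantTable`.

    Raises a hard error naming the field when DP or AD is absent from the
    FORMAT declarations and ``require_depths`` is set.
    """
    with pysam.VariantFile(str(path)) as vcf:
        if require_depths:
            for fmt in ("DP", "AD"):
                if fmt not in vcf.header.formats:
                    raise ValueError(
                        f"VCF {path} lacks required FORMAT field {fmt}"
                    )
        samples = list(vcf.header.samples)
        lengths = {
            name: ctg.length
            for name, ctg in vcf.header.contigs.items()
            if ctg.length
        }
        table = VariantTable(samples, contig_lengths=lengths)
        for rec in vcf.fetch() if vcf.index else vcf:
            calls = {}
            for sample in samples:
                fmt = rec.samples[sample]
                gt = fmt.get("GT")
                alleles = None
                if gt is not None and None not in gt and len(gt) == 2:
                    alleles = (gt[0], gt[1])
                dp = fmt.get("DP") or 0
                ad = fmt.get("AD")
                ad = tuple(x or 0 for x in ad) if ad is not None else ()
                calls[sample] = GenotypeCall(alleles, dp, ad)
            table.sites.append(
                VariantSite(rec.contig, rec.pos, rec.ref, tuple(rec.alts or ()), calls)
            )
    return table


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV (sample_id, group, treatment)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    bad = set(df["group"]) - {"wildtype", "mutant"}
    if bad:
        raise ValueError(f"manifest group values must be wildtype/mutant; got {bad}")
    return df
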