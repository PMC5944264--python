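"""Variant-effect classification against gene models and substitution spectra.

Effects follow the conventional categories of codon-level annotators:
coding SNPs are translated reference-vs-alternate (strand- and phase-aware)
into synonymous / non_synonymous / stop_gained / stop_lost / start_lost;
coding InDels become frame_shift (length not a multiple of 3) or
codon_insertion / codon_deletion; intronic positions within ``splice_region``
bases of an exon boundary are splice_site_donor (intron 5' end) or
splice_site_acceptor (intron 3' end); positions within the strand-aware
upstream/downstream windows get those labels; everything else is intergenic.

Substitutions are summarized as the six unordered base pairs with the
transition ({A,G}, {C,T}) / transversion split and the Ts/Tv ratio, the
standard summary of an EMS mutation spectrum (EMS alkylates guanine and
drives G/C -> A/T transitions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .restriction import reverse_complement
from .variants import VariantSite

__all__ = [
    "GeneModel",
    "AnnotationParams",
    "EffectAnnotation",
    "SpectrumSummary",
    "classify_substitution",
    "compute_spectrum",
    "annotate_variant",
    "annotate_table",
    "summarize_effects",
    "most_severe",
    "write_gff3",
    "read_gff3",
    "SEVERITY_ORDER",
]

TRANSITION_CLASSES = (frozenset("AG"), frozenset("CT"))

# Printed labels of the six unordered substitution classes.
CLASS_LABELS: dict[frozenset, str] = {
    frozenset("CT"): "C/T",
    frozenset("AG"): "A/G",
    frozenset("CG"): "C/G",
    frozenset("AT"): "A/T",
    frozenset("AC"): "A/C",
    frozenset("GT"): "G/T",
}

SEVERITY_ORDER = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frame_shift",
    "splice_site_acceptor",
    "splice_site_donor",
    "codon_insertion",
    "codon_deletion",
    "non_synonymous",
    "synonymous",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

# Categories for which the per-category report counts distinct genes
# (intron/intergenic rows conventionally report 0).
_GENIC_COUNTED = {
    "synonymous", "non_synonymous", "stop_gained", "stop_lost", "start_lost",
    "frame_shift", "codon_insertion", "codon_deletion",
    "splice_site_acceptor", "splice_site_donor", "upstream", "downstream",
}


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Unordered substitution class label and transition flag for a SNP."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"invalid bases for substitution: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    klass = frozenset((ref, alt))
    return CLASS_LABELS[klass], klass in TRANSITION_CLASSES


@dataclass
class SpectrumSummary:
    """Counts of the six substitution classes with the Ts/Tv split."""

    class_counts: dict[str, int]

    @property
    def transitions(self) -> int:
        return self.class_counts.get("C/T", 0) + self.class_counts.get("A/G", 0)

    @property
    def transversions(self) -> int:
        return sum(
            self.class_counts.get(k, 0) for k in ("C/G", "A/T", "A/C", "G/T")
        )

    @property
    def total(self) -> int:
        return self.transitions + self.transversions

    @property
    def ts_tv_ratio(self) -> float | None:
        """Ts/Tv quotient; None when no transversions were observed."""
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions

    @property
    def transition_fraction(self) -> float | None:
        return self.transitions / self.total if self.total else None

    def to_frame(self) -> pd.DataFrame:
        ratio = self.ts_tv_ratio
        rows = [("Transitions", self.transitions)]
        rows += [(k, self.class_counts.get(k, 0)) for k in ("C/T", "A/G")]
        rows.append(("Transversions", self.transversions))
        rows += [(k, self.class_counts.get(k, 0)) for k in ("C/G", "A/T", "A/C", "G/T")]
        rows.append(("Ts/Tv ratio", "undefined" if ratio is None else f"{ratio:.1f}"))
        return pd.DataFrame(rows, columns=["Substitution", "Number of SNPs"])


def compute_spectrum(
    variants: Iterable[tuple[str, str]] | Mapping[str, int],
) -> SpectrumSummary:
    """Spectrum from (ref, alt) SNP pairs or from pre-tabulated class counts."""
    if isinstance(variants, Mapping):
        unknown = set(variants) - set(CLASS_LABELS.values())
        if unknown:
            raise ValueError(f"unknown substitution classes: {sorted(unknown)}")
        return SpectrumSummary(dict(variants))
    counts: Counter = Counter()
    for ref, alt in variants:
        label, _ = classify_substitution(ref, alt)
        counts[label] += 1
    return SpectrumSummary(dict(counts))


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript protein-coding gene.

    ``cds`` are 0-based half-open genomic intervals in ascending genomic
    order; they double as the exons (untranslated regions are not modelled).
    ``phase`` is the number of bases to skip before the first complete codon
    of the first CDS segment in transcription order (0 for complete models).
    """

    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    cds: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.cds:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        for (a, b) in self.cds:
            if a >= b:
                raise ValueError(f"gene {self.gene_id}: empty CDS interval")
        if list(self.cds) != sorted(self.cds):
            raise ValueError(f"gene {self.gene_id}: CDS intervals not sorted")

    @property
    def start(self) -> int:
        return self.cds[0][0]

    @property
    def end(self) -> int:
        return self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    def cds_sequence(self, contig_seq: str) -> str:
        """Spliced coding sequence in translation orientation."""
        s = "".join(contig_seq[a:b] for a, b in self.cds)
        if self.strand == "-":
            s = reverse_complement(s)
        return s[self.phase:]

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a 0-based genomic position to a coding-sequence offset."""
        offset = 0
        parts = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        for a, b in parts:
            if a <= pos0 < b:
                within = (pos0 - a) if self.strand == "+" else (b - 1 - pos0)
                cds_pos = offset + within - self.phase
                return cds_pos if cds_pos >= 0 else None
            offset += b - a
        return None

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.cds[i][1], self.cds[i + 1][0])
            for i in range(len(self.cds) - 1)
        ]


@dataclass(frozen=True)
class AnnotationParams:
    upstream_window: int = 5000
    downstream_window: int = 5000
    splice_region: int = 2

    def __post_init__(self) -> None:
        for name in ("upstream_window", "downstream_window", "splice_region"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EffectAnnotation:
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    category: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.category not in SEVERITY_ORDER:
            raise ValueError(f"unknown effect category {self.category!r}")
        if self.category == "intergenic" and self.gene_id is not None:
            raise ValueError("intergenic annotations carry no gene id")

    @property
    def impact_rank(self) -> int:
        return SEVERITY_ORDER.index(self.category)


def _classify_cds_snp(
    gene: GeneModel, contig_seq: str, pos0: int, ref: str, alt: str
) -> str:
    cds_pos = gene.genomic_to_cds(pos0)
    cds_seq = gene.cds_sequence(contig_seq)
    if len(cds_seq) % 3 != 0:
        raise ValueError(
            f"gene {gene.gene_id}: CDS length {len(cds_seq)} not divisible by 3"
        )
    if gene.strand == "-":
        ref, alt = reverse_complement(ref), reverse_complement(alt)
    if cds_seq[cds_pos] != ref:
        raise ValueError(
            f"gene {gene.gene_id}: reference allele {ref!r} does not match "
            f"CDS base {cds_seq[cds_pos]!r} at coding offset {cds_pos}"
        )
    codon_i = cds_pos // 3
    within = cds_pos % 3
    ref_codon = cds_seq[3 * codon_i: 3 * codon_i + 3]
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    return "synonymous" if ref_aa == alt_aa else "non_synonymous"


def _classify_intron(
    gene: GeneModel, pos0: int, splice_region: int
) -> str | None:
    for (a, b) in gene.introns():
        if not (a <= pos0 < b):
            continue
        # Donor = intron 5' end, acceptor = 3' end, in transcription order.
        if gene.strand == "+":
            donor_side = pos0 - a < splice_region
            acceptor_side = b - 1 - pos0 < splice_region
        else:
            donor_side = b - 1 - pos0 < splice_region
            acceptor_side = pos0 - a < splice_region
        if donor_side:
            return "splice_site_donor"
        if acceptor_side:
            return "splice_site_acceptor"
        return "intron"
    return None


def annotate_variant(
    site: VariantSite,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    params: AnnotationParams = AnnotationParams(),
) -> list[EffectAnnotation]:
    """Annotate one biallelic variant against every overlapping gene.

    Returns one annotation per gene whose span or flanking window contains
    the position, or a single intergenic annotation when none does.
    """
    if site.contig not in genome:
        raise ValueError(f"contig {site.contig!r} absent from the reference")
    ref, alt = site.ref, site.alts[0]
    pos0 = site.pos - 1
    contig_seq = genome[site.contig]
    out: list[EffectAnnotation] = []

    def add(category: str, gene_id: str | None) -> None:
        out.append(EffectAnnotation(site.contig, site.pos, ref, alt, category, gene_id))

    for gene in genes:
        if gene.contig != site.contig:
            continue
        if gene.start <= pos0 < gene.end:
            in_cds = any(a <= pos0 < b for a, b in gene.cds)
            if in_cds:
                if site.is_snp:
                    add(_classify_cds_snp(gene, contig_seq, pos0, ref, alt), gene.gene_id)
                else:
                    delta = site.indel_length()
                    if delta % 3 != 0:
                        add("frame_shift", gene.gene_id)
                    elif delta > 0:
                        add("codon_insertion", gene.gene_id)
                    else:
                        add("codon_deletion", gene.gene_id)
            else:
                cat = _classify_intron(gene, pos0, params.splice_region)
                if cat is not None:
                    add(cat, gene.gene_id)
            continue
        # Flanking windows, strand-aware: upstream lies before the gene in
        # transcription orientation.
        if gene.strand == "+":
            if gene.start - params.upstream_window <= pos0 < gene.start:
                add("upstream", gene.gene_id)
            elif gene.end <= pos0 < gene.end + params.downstream_window:
                add("downstream", gene.gene_id)
        else:
            if gene.end <= pos0 < gene.end + params.upstream_window:
                add("upstream", gene.gene_id)
            elif gene.start - params.downstream_window <= pos0 < gene.start:
                add("downstream", gene.gene_id)

    if not out:
        add("intergenic", None)
    return out


def annotate_table(
    sites: Iterable[VariantSite],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    params: AnnotationParams = AnnotationParams(),
) -> list[EffectAnnotation]:
    anns: list[EffectAnnotation] = []
    for site in sites:
        anns.extend(annotate_variant(site, genes, genome, params))
    return anns


def most_severe(annotations: Iterable[EffectAnnotation]) -> list[EffectAnnotation]:
    """One annotation per variant: the highest-impact category."""
    best: dict[tuple, EffectAnnotation] = {}
    for ann in annotations:
        key = (ann.contig, ann.pos, ann.ref, ann.alt)
        if key not in best or ann.impact_rank < best[key].impact_rank:
            best[key] = ann
    return [best[k] for k in sorted(best, key=lambda k: (k[0], k[1]))]


def summarize_effects(annotations: Iterable[EffectAnnotation]) -> pd.DataFrame:
    """Per-category occurrence and distinct-gene counts.

    Intron and intergenic rows report 0 distinct genes, following the usual
    presentation of such tables.
    """
    occ: Counter = Counter()
    genes_per_cat: dict[str, set] = {}
    for ann in annotations:
        occ[ann.category] += 1
        if ann.category in _GENIC_COUNTED and ann.gene_id is not None:
            genes_per_cat.setdefault(ann.category, set()).add(ann.gene_id)
    rows = [
        {
            "category": cat,
            "occurrences": occ.get(cat, 0),
            "distinct_genes": len(genes_per_cat.get(cat, ())),
        }
        for cat in SEVERITY_ORDER
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GFF3 round trip for the simple gene/mRNA/CDS models used here.

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid, mid = g.gene_id, f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\tgbsmut\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.contig}\tgbsmut\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mid};Parent={gid}\n"
            )
            parts = g.cds if g.strand == "+" else tuple(reversed(g.cds))
            phase, consumed = g.phase, 0
            phases = []
            for a, b in parts:
                phases.append((a, b, (3 - ((consumed - g.phase) % 3)) % 3 if consumed else g.phase))
                consumed += b - a
            for a, b, ph in phases:
                fh.write(
                    f"{g.contig}\tgbsmut\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t"
                    f"{ph}\tID={mid}.cds;Parent={mid}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read the simple gene/mRNA/CDS GFF3 layout written by :func:`write_gff3`."""
    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    phase_by_gene: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, _, ftype, start, end, _, strand, phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                meta[fields["ID"]] = (contig, strand)
            elif ftype == "CDS":
                gene_id = fields["Parent"].rsplit(".t1", 1)[0]
                iv = (int(start) - 1, int(end))
                cds_by_gene.setdefault(gene_id, []).append(iv)
                ph = 0 if phase == "." else int(phase)
                phase_by_gene.setdefault(gene_id, []).append((iv[0], iv[1], ph))
    genes = []
    for gene_id, (contig, strand) in meta.items():
        cds = tuple(sorted(cds_by_gene.get(gene_id, [])))
        parts = phase_by_gene[gene_id]
        first = min(parts)[2] if strand == "+" else max(parts)[2]
        genes.append(GeneModel(gene_id, contig, strand, cds, phase=first))
    return genes
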