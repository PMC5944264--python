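"""Synthetic GBS cohort generator with ground truth.

Emulates the study design the analysis assumes: a 96-sample panel of 14
wild-type accessions plus 82 EMS-mutagenized accessions, genotyped on the
reduced genome representation produced by restriction digestion and 200-500
bp size selection.  All samples share a set of background variants; each
wild-type accession may additionally carry private variants (the natural
heterogeneity the consensus step must eliminate); each mutant carries a
Poisson number of heterozygous EMS mutations, biased toward G>A / C>T
transitions (EMS alkylates guanine).  Per-sample per-site depth is
negative-binomial (GBS libraries are strongly overdispersed), per-allele
depths are binomial around the expected allele balance, and genotypes drop
out at a configurable missing rate.

A single global seed governs every stage; per-stage generators are derived
deterministically, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .restriction import (
    Fragment,
    RestrictionEnzyme,
    SelectionParams,
    TERMINUS,
    digest,
    get_enzyme,
    reverse_complement,
    select_fragments,
)
from .variants import GenotypeCall, VariantSite, VariantTable

__all__ = [
    "SimulationConfig",
    "ReadSimParams",
    "Genome",
    "generate_genome",
    "simulate_population",
    "simulate_reads",
    "simulate_cohort",
    "label_effects",
    "write_genome_fasta",
    "write_methylation_bed",
    "write_truth_table",
    "write_fastq_pair",
]

_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)
# G>A / C>T: the canonical EMS transition products.
_EMS_TRANSITION_ALT = {"G": "A", "C": "T"}

_TREATMENTS = tuple(
    f"{conc}% {dur} h" for conc in ("0.4", "0.8", "1.6") for dur in ("0.5", "1.5", "3")
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the study conditions the pipeline is designed for:
    a 96-sample panel (14 wild type + 82 mutants), ~30x mean GBS depth with
    strong overdispersion and 5% dropout, 20 EMS mutations per mutant of
    which 67.8% are G>A / C>T transitions.  Rates without an external
    anchor (background and private wild-type variant densities) are modest
    plausible choices, documented in the methods note.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 200_000
    gc_fraction: float = 0.36
    n_genes: int = 40
    n_wildtype: int = 14
    n_mutant: int = 82
    background_variant_rate: float = 1e-3
    private_wt_variant_rate: float = 2e-4
    ems_mutations_per_sample: float = 20.0
    transition_fraction: float = 0.678
    ems_zygosity: str = "het"  # "het" (M1 material) or "hom" for sensitivity tests
    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    missing_rate: float = 0.05
    base_error_rate: float = 0.005
    methylation_rate_cpg: float = 0.6
    methylation_rate_chg: float = 0.3
    enzymes: tuple[str, ...] = ("MslI",)
    min_fragment: int = 200
    max_fragment: int = 500
    end_rule: str = "both-any"

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction", "transition_fraction", "missing_rate",
            "base_error_rate", "methylation_rate_cpg", "methylation_rate_chg",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        for name in (
            "n_contigs", "contig_length", "n_genes", "n_wildtype", "n_mutant",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "background_variant_rate", "private_wt_variant_rate",
            "ems_mutations_per_sample", "mean_depth",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.ems_zygosity not in ("het", "hom"):
            raise ValueError("ems_zygosity must be 'het' or 'hom'")
        if not (0 <= self.seed < 2**31):
            raise ValueError("seed must fit in a signed 32-bit integer")

    @property
    def n_samples(self) -> int:
        return self.n_wildtype + self.n_mutant

    @property
    def wildtype_samples(self) -> list[str]:
        return [f"wt{i:02d}" for i in range(1, self.n_wildtype + 1)]

    @property
    def mutant_samples(self) -> list[str]:
        return [f"mut{i:02d}" for i in range(1, self.n_mutant + 1)]

    @property
    def samples(self) -> list[str]:
        return self.wildtype_samples + self.mutant_samples

    def enzyme_objects(self) -> list[RestrictionEnzyme]:
        return [get_enzyme(n) for n in self.enzymes]

    def selection_params(self) -> SelectionParams:
        return SelectionParams(self.min_fragment, self.max_fragment, self.end_rule)

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        return np.random.default_rng([self.seed, stage])


@dataclass
class Genome:
    """Reference contigs with gene models and a cytosine-methylation mask."""

    contigs: dict[str, str]
    genes: list[GeneModel]
    methylation: dict[str, dict[int, str]]  # contig -> {0-based pos: context}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _build_gene(
    rng: np.random.Generator, gene_id: str, contig: str, strand: str, offset: int
) -> tuple[GeneModel, str]:
    """A random gene: ATG .. sense codons .. stop, 1-3 exons, GT..AG introns.

    Returns the model (genomic coordinates) and the genomic-strand sequence
    to splice into the contig.
    """
    n_codons = int(rng.integers(100, 300))
    cds = "ATG" + "".join(
        rng.choice(np.array(_SENSE_CODONS), size=n_codons - 2)
    ) + str(rng.choice(np.array(_STOP_CODONS)))
    n_exons = int(rng.integers(1, 4))
    if n_exons == 1:
        pieces = [cds]
    else:
        cut_points = sorted(
            rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1, replace=False)
        )
        pieces, prev = [], 0
        for cp in cut_points:
            pieces.append(cds[prev:cp])
            prev = cp
        pieces.append(cds[prev:])
    introns = [
        "GT" + _random_sequence(rng, int(rng.integers(76, 296)), 0.4) + "AG"
        for _ in range(n_exons - 1)
    ]
    coding_seq = pieces[0]
    local_cds = [(0, len(pieces[0]))]
    for intron, piece in zip(introns, pieces[1:]):
        coding_seq += intron
        a = len(coding_seq)
        coding_seq += piece
        local_cds.append((a, a + len(piece)))
    L = len(coding_seq)
    if strand == "+":
        genomic_cds = tuple((offset + a, offset + b) for a, b in local_cds)
        genomic_seq = coding_seq
    else:
        genomic_cds = tuple(
            sorted((offset + L - b, offset + L - a) for a, b in local_cds)
        )
        genomic_seq = reverse_complement(coding_seq)
    return GeneModel(gene_id, contig, strand, genomic_cds), genomic_seq


def generate_genome(config: SimulationConfig) -> Genome:
    """Random reference contigs carrying valid gene models and a methylation mask."""
    rng = config.rng(stage=1)
    contigs: dict[str, bytearray] = {}
    names = [f"contig{i + 1}" for i in range(config.n_contigs)]
    for name in names:
        contigs[name] = bytearray(
            _random_sequence(rng, config.contig_length, config.gc_fraction), "ascii"
        )

    genes: list[GeneModel] = []
    if config.n_genes and config.n_contigs:
        per_contig = [
            config.n_genes // config.n_contigs
            + (1 if i < config.n_genes % config.n_contigs else 0)
            for i in range(config.n_contigs)
        ]
        # Worst-case gene span: 300-codon CDS plus two 300 bp introns.
        max_span = 300 * 3 + 2 * 300
        for name, n_here in zip(names, per_contig):
            if n_here == 0:
                continue
            slot = config.contig_length // n_here
            if slot < max_span + 200:
                raise ValueError(
                    f"contig_length {config.contig_length} too short for "
                    f"{n_here} genes on {name} (need >= {n_here * (max_span + 200)})"
                )
            for k in range(n_here):
                gene_id = f"gene_{name}_{k + 1:03d}"
                strand = str(rng.choice(np.array(["+", "-"])))
                offset = slot * k + 100 + int(rng.integers(0, slot - max_span - 200))
                model, gseq = _build_gene(rng, gene_id, name, strand, offset)
                contigs[name][offset: offset + len(gseq)] = gseq.encode("ascii")
                genes.append(model)

    final = {name: seq.decode("ascii") for name, seq in contigs.items()}

    methylation: dict[str, dict[int, str]] = {}
    for name, seq in final.items():
        mask: dict[int, str] = {}
        for i in range(len(seq) - 1):
            if seq[i] != "C":
                continue
            if seq[i + 1] == "G":
                if rng.random() < config.methylation_rate_cpg:
                    mask[i] = "CpG"
            elif i + 2 < len(seq) and seq[i + 2] == "G":
                if rng.random() < config.methylation_rate_chg:
                    mask[i] = "CHG"
        methylation[name] = mask
    return Genome(final, genes, methylation)


def callable_fragments(config: SimulationConfig, genome: Genome) -> list[Fragment]:
    """Size-selected digestion fragments: the sequenced genome representation."""
    frags = digest(genome.contigs, config.enzyme_objects(), genome.methylation)
    selected, _ = select_fragments(frags, config.selection_params())
    return selected


def simulate_population(
    config: SimulationConfig, genome: Genome
) -> tuple[pd.DataFrame, VariantTable, pd.DataFrame]:
    """Plant the variants, draw depths and emit the cohort call set.

    Returns (truth table, variant table, sample manifest).  The truth table
    has one row per (sample, carried variant) with origin background /
    private_wt / ems.  The variant table is restricted to positions inside
    the size-selected fragments — the reduced representation the library
    actually sequences.
    """
    rng = config.rng(stage=2)
    selected = callable_fragments(config, genome)
    if not selected:
        raise ValueError("no fragments pass size selection; enlarge the genome")

    pool: list[tuple[str, int, str]] = []  # (contig, pos0, ref base)
    for f in selected:
        seq = genome.contigs[f.contig]
        pool.extend((f.contig, p, seq[p]) for p in range(f.start, f.end))
    gc_indices = [i for i, entry in enumerate(pool) if entry[2] in "GC"]
    n_callable = len(pool)

    used: set[int] = set()

    def _draw(candidates_len: int, lookup) -> tuple[str, int, str] | None:
        """Uniform draw without replacement; rejection sampling keeps every
        draw uniform over the *unused* candidates (a sequential cursor would
        bias later draws toward whatever the earlier draws skipped)."""
        if candidates_len == 0:
            return None
        for _ in range(200):
            i = lookup(int(rng.integers(candidates_len)))
            if i not in used:
                used.add(i)
                return pool[i]
        remaining = [
            lookup(k) for k in range(candidates_len) if lookup(k) not in used
        ]
        if not remaining:
            return None
        i = remaining[int(rng.integers(len(remaining)))]
        used.add(i)
        return pool[i]

    def take_any() -> tuple[str, int, str] | None:
        return _draw(n_callable, lambda k: k)

    def take_gc() -> tuple[str, int, str] | None:
        return _draw(len(gc_indices), gc_indices.__getitem__)

    samples = config.samples
    # site key -> (ref, alt, origin, {sample: genotype code 1=het 2=hom-alt})
    sites: dict[tuple[str, int], tuple[str, str, str, dict[str, int]]] = {}
    truth_rows: list[tuple] = []

    def plant(origin: str, carriers: dict[str, int]) -> None:
        if origin == "ems":
            if rng.random() < config.transition_fraction:
                spot = take_gc()
                if spot is None:
                    return
                contig, pos, ref = spot
                alt = _EMS_TRANSITION_ALT[ref]
            else:
                spot = take_any()
                if spot is None:
                    return
                contig, pos, ref = spot
                choices = [
                    b for b in "ACGT"
                    if b != ref and _EMS_TRANSITION_ALT.get(ref) != b
                ]
                alt = choices[int(rng.integers(len(choices)))]
        else:
            spot = take_any()
            if spot is None:
                return
            contig, pos, ref = spot
            choices = [b for b in "ACGT" if b != ref]
            alt = choices[int(rng.integers(len(choices)))]
        sites[(contig, pos)] = (ref, alt, origin, carriers)
        for sample, code in carriers.items():
            truth_rows.append(
                (sample, contig, pos + 1, ref, alt,
                 "het" if code == 1 else "hom", origin)
            )

    n_bg = rng.poisson(config.background_variant_rate * n_callable)
    for _ in range(n_bg):
        code = 1 if rng.random() < 0.5 else 2
        plant("background", {s: code for s in samples})

    for wt in config.wildtype_samples:
        n_priv = rng.poisson(config.private_wt_variant_rate * n_callable)
        for _ in range(n_priv):
            plant("private_wt", {wt: 1 if rng.random() < 0.5 else 2})

    ems_code = 1 if config.ems_zygosity == "het" else 2
    for mut in config.mutant_samples:
        n_ems = rng.poisson(config.ems_mutations_per_sample)
        for _ in range(n_ems):
            plant("ems", {mut: ems_code})

    ordered = sorted(sites)
    n_sites = len(ordered)
    n_samp = len(samples)

    # Depth: negative binomial with mean mean_depth and size depth_dispersion.
    r = config.depth_dispersion
    p = r / (r + config.mean_depth) if config.mean_depth > 0 else 1.0
    dp = rng.negative_binomial(r, p, size=(n_sites, n_samp))
    missing = rng.random((n_sites, n_samp)) < config.missing_rate

    table = VariantTable(list(samples))
    table.contig_lengths = {c: len(s) for c, s in genome.contigs.items()}
    for si, key in enumerate(ordered):
        contig, pos = key
        ref, alt, _origin, carriers = sites[key]
        calls: dict[str, GenotypeCall] = {}
        for sj, sample in enumerate(samples):
            if missing[si, sj]:
                calls[sample] = GenotypeCall(None, 0, (0, 0))
                continue
            depth = int(dp[si, sj])
            code = carriers.get(sample, 0)
            if code == 1:
                alt_d = int(rng.binomial(depth, 0.5))
                gt = (0, 1)
            elif code == 2:
                ref_d = int(rng.binomial(depth, config.base_error_rate))
                alt_d = depth - ref_d
                gt = (1, 1)
            else:
                alt_d = int(rng.binomial(depth, config.base_error_rate))
                gt = (0, 0)
            calls[sample] = GenotypeCall(gt, depth, (depth - alt_d, alt_d))
        table.sites.append(VariantSite(contig, pos + 1, ref, (alt,), calls))

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "contig", "pos", "ref", "alt", "zygosity", "origin"],
    ).sort_values(["contig", "pos", "sample"], ignore_index=True)

    manifest = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["wildtype"] * config.n_wildtype + ["mutant"] * config.n_mutant,
            "treatment": ["none"] * config.n_wildtype
            + [_TREATMENTS[i % len(_TREATMENTS)] for i in range(config.n_mutant)],
        }
    )
    return truth, table, manifest


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[Genome, pd.DataFrame, VariantTable, pd.DataFrame]:
    """Genome + population in one call."""
    genome = generate_genome(config)
    truth, table, manifest = simulate_population(config, genome)
    return genome, truth, table, manifest


def label_effects(
    genome: Genome,
    variants: pd.DataFrame,
    upstream_window: int = 5000,
    downstream_window: int = 5000,
    splice_region: int = 2,
) -> pd.DataFrame:
    """Ground-truth effect labels for simulated SNVs, one row per variant-gene pair.

    Coding changes are labelled by mutating the contig, re-extracting the
    whole spliced coding sequence and diffing the two translated proteins,
    so the labels do not depend on per-codon index arithmetic.  Non-coding
    positions are labelled from the gene intervals.  Variants overlapping no
    gene or flanking window are ``intergenic`` with an empty gene id.
    """
    from Bio.Seq import Seq

    def protein(gene: GeneModel, seq: str) -> str:
        s = "".join(seq[a:b] for a, b in gene.cds)
        if gene.strand == "-":
            s = str(Seq(s).reverse_complement())
        return str(Seq(s).translate())

    rows = []
    uniq = variants.drop_duplicates(subset=["contig", "pos", "ref", "alt"])
    for row in uniq.itertuples():
        pos0 = row.pos - 1
        seq = genome.contigs[row.contig]
        hit = False
        for gene in genome.genes:
            if gene.contig != row.contig:
                continue
            if gene.start <= pos0 < gene.end:
                if any(a <= pos0 < b for a, b in gene.cds):
                    mutated = seq[:pos0] + row.alt + seq[pos0 + 1:]
                    p_ref, p_alt = protein(gene, seq), protein(gene, mutated)
                    if p_ref[0] == "M" and p_alt[0] != "M":
                        cat = "start_lost"
                    elif p_ref == p_alt:
                        cat = "synonymous"
                    elif "*" in p_alt[:-1] and "*" not in p_ref[:-1]:
                        cat = "stop_gained"
                    elif p_ref.endswith("*") and not p_alt.endswith("*"):
                        cat = "stop_lost"
                    else:
                        cat = "non_synonymous"
                else:
                    cat = "intron"
                    for a, b in zip(
                        [iv[1] for iv in gene.cds[:-1]],
                        [iv[0] for iv in gene.cds[1:]],
                    ):
                        if not (a <= pos0 < b):
                            continue
                        five_prime = pos0 - a < splice_region
                        three_prime = b - 1 - pos0 < splice_region
                        if gene.strand == "-":
                            five_prime, three_prime = three_prime, five_prime
                        if five_prime:
                            cat = "splice_site_donor"
                        elif three_prime:
                            cat = "splice_site_acceptor"
            elif gene.strand == "+" and gene.start - upstream_window <= pos0 < gene.start:
                cat = "upstream"
            elif gene.strand == "+" and gene.end <= pos0 < gene.end + downstream_window:
                cat = "downstream"
            elif gene.strand == "-" and gene.end <= pos0 < gene.end + upstream_window:
                cat = "upstream"
            elif gene.strand == "-" and gene.start - downstream_window <= pos0 < gene.start:
                cat = "downstream"
            else:
                continue
            rows.append(
                (row.contig, row.pos, row.ref, row.alt, gene.gene_id, cat)
            )
            hit = True
        if not hit:
            rows.append((row.contig, row.pos, row.ref, row.alt, "", "intergenic"))
    return pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "gene_id", "category"]
    )


# ---------------------------------------------------------------------------
# Read simulation (feeds the read-QC stage).


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end read emission from size-selected fragments.

    ``corrupt_fraction`` of reads are damaged, split evenly across the four
    QC failure modes (injected N, raw truncation, 5' mismatch, low-quality
    3' tail) so every preprocessing rule is exercised.
    """

    read_length: int = 100
    quality: int = 38
    corrupt_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.corrupt_fraction <= 1.0):
            raise ValueError("corrupt_fraction must be in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


_CORRUPTIONS = ("inject_n", "truncate", "prefix_mismatch", "low_quality_tail")

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def _end_shifts(enzyme: RestrictionEnzyme) -> tuple[int, int]:
    """Back-shifts that make reads start with the residual site.

    The sequenced strand of a fragment end begins at the nearer strand cut,
    ``min(c, L - c)`` into the site; left/right shifts move the read start
    back from the top-strand cut coordinate accordingly.
    """
    c, L = enzyme.cut_offset, enzyme.site_length
    near = min(c, L - c)
    return c - near, (L - c) - near


def _corrupt(
    rng: np.random.Generator,
    mode: str,
    seq: str,
    quals: list[int],
    residual: str,
) -> tuple[str, list[int]]:
    if mode == "inject_n":
        i = int(rng.integers(len(seq)))
        return seq[:i] + "N" + seq[i + 1:], quals
    if mode == "truncate":
        n = int(rng.integers(5, 20))
        return seq[:n], quals[:n]
    if mode == "prefix_mismatch":
        # Damage a concretely-constrained residual position (skip N symbols).
        for i, sym in enumerate(residual):
            allowed = _IUPAC_SETS[sym]
            if len(allowed) < 4:
                bad = next(b for b in "ACGT" if b not in allowed)
                return seq[:i] + bad + seq[i + 1:], quals
        return seq, quals  # fully degenerate residual: cannot force a mismatch
    if mode == "low_quality_tail":
        keep = int(rng.integers(20, 64))
        return seq, quals[:keep] + [2] * (len(quals) - keep)
    raise ValueError(mode)


def simulate_reads(
    fragments: Sequence[Fragment],
    genome: Genome,
    enzymes: Sequence[RestrictionEnzyme],
    params: ReadSimParams = ReadSimParams(),
    seed: int = 0,
) -> list[tuple[str, str, str, str, str]]:
    """Paired reads from enzyme-cut fragment ends.

    Returns (name, seq1, qual1, seq2, qual2) tuples; quality strings are
    Phred+33.  Fragment ends at a contig terminus yield no read.  An empty
    fragment set produces an empty list with a warning.
    """
    if not fragments:
        warnings.warn("empty fragment set: no reads simulated")
        return []
    rng = np.random.default_rng([seed, 3])
    by_name = {e.name: e for e in enzymes}
    reads = []
    for idx, frag in enumerate(fragments):
        seq = genome.contigs[frag.contig]
        rl = params.read_length

        def window(side: str) -> tuple[str, str] | None:
            if side == "left":
                if frag.left_end == TERMINUS:
                    return None
                shift_l, _ = _end_shifts(by_name[frag.left_end])
                a = frag.start - shift_l
                if a < 0 or a + rl > len(seq):
                    return None
                s = seq[a: a + rl]
                return s, by_name[frag.left_end].residual_site()
            if frag.right_end == TERMINUS:
                return None
            _, shift_r = _end_shifts(by_name[frag.right_end])
            b = frag.end + shift_r
            if b - rl < 0 or b > len(seq):
                return None
            s = reverse_complement(seq[b - rl: b])
            return s, by_name[frag.right_end].residual_site()

        w1, w2 = window("left"), window("right")
        if w1 is None or w2 is None:
            continue
        (s1, res1), (s2, res2) = w1, w2
        q1 = [params.quality] * len(s1)
        q2 = [params.quality] * len(s2)
        if params.corrupt_fraction and rng.random() < params.corrupt_fraction:
            mode = _CORRUPTIONS[int(rng.integers(len(_CORRUPTIONS)))]
            s1, q1 = _corrupt(rng, mode, s1, q1, res1)
        name = f"frag{idx:06d}_{frag.contig}_{frag.start}_{frag.end}"
        reads.append(
            (
                name,
                s1, "".join(chr(q + 33) for q in q1),
                s2, "".join(chr(q + 33) for q in q2),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Writers for the on-disk cohort layout.


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_methylation_bed(genome: Genome, path: str | Path) -> None:
    """BED (0-based half-open) of methylated cytosines with context labels."""
    with open(path, "w") as fh:
        for contig in sorted(genome.methylation):
            for pos in sorted(genome.methylation[contig]):
                ctx = genome.methylation[contig][pos]
                fh.write(f"{contig}\t{pos}\t{pos + 1}\t{ctx}\n")


def read_methylation_bed(path: str | Path) -> dict[str, dict[int, str]]:
    mask: dict[str, dict[int, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, _end, ctx = line.split("\t")[:4]
            mask.setdefault(contig, {})[int(start)] = ctx.strip()
    return mask


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_fastq_pair(
    reads: Sequence[tuple[str, str, str, str, str]],
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Write the simulated pairs as gzip FASTQ (suffix .gz) or plain FASTQ."""
    import gzip

    def opener(p):
        p = str(p)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    with opener(r1_path) as f1, opener(r2_path) as f2:
        for name, s1, q1, s2, q2 in reads:
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")
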