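"""Synthetic genomes, gene models and planted true variants.

Everything here is a pure function of (spec, seed) so the downstream
pipeline is testable without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gbsforge.enzymes import revcomp
from gbsforge.genome import CHROM_CLASSES, Genome

BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "origin", "alt_freq"]


@dataclass(frozen=True)
class GenomeSpec:
    """Specification for a simulated genome.

    ``motif`` + ``motif_spacing`` request planted restriction sites at a
    fixed spacing (starting at position 0 of each chromosome) with all
    accidental occurrences of the motif destroyed.
    """

    lengths: Sequence[int]
    classes: Sequence[str]
    gc: float = 0.42
    motif: str | None = None
    motif_spacing: int | None = None
    names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.classes):
            raise ValueError("lengths and classes must have equal length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if any(c not in CHROM_CLASSES for c in self.classes):
            raise ValueError(f"class labels must be in {CHROM_CLASSES}")
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must lie in [0, 1]")
        if self.motif_spacing is not None:
            if self.motif is None:
                raise ValueError("motif_spacing requires a motif")
            if self.motif_spacing < len(self.motif):
                raise ValueError("motif spacing shorter than the motif itself")

    def chrom_names(self) -> list[str]:
        if self.names is not None:
            return list(self.names)
        return [f"chr{i + 1}" for i in range(len(self.lengths))]


def default_spec(motif: str | None = None, motif_spacing: int | None = None) -> GenomeSpec:
    """Desk-scale default: 10 chromosomes, ~10 Mb, 2 large / 3 medium / 5 micro."""
    lengths = [2_500_000, 2_000_000, 1_200_000, 1_000_000, 800_000,
               600_000, 500_000, 500_000, 500_000, 400_000]
    classes = ["large", "large", "medium", "medium", "medium",
               "micro", "micro", "micro", "micro", "micro"]
    return GenomeSpec(lengths, classes, motif=motif, motif_spacing=motif_spacing)


def _destroy_motifs(seq: np.ndarray, motif: str, keep: set[int], rng: np.random.Generator) -> None:
    """Mutate the middle base of every non-planted motif occurrence in place."""
    text = "".join(seq)
    for _ in range(50):  # guard: destruction can create new occurrences
        dirty = False
        i = text.find(motif)
        while i != -1:
            if i not in keep:
                mid = i + len(motif) // 2
                cur = seq[mid]
                choices = [b for b in "ACGT" if b != cur]
                seq[mid] = choices[rng.integers(len(choices))]
                dirty = True
            i = text.find(motif, i + 1)
        if not dirty:
            return
        text = "".join(seq)
    raise RuntimeError("failed to remove accidental motif occurrences")


def simulate_genome(spec: GenomeSpec, seed: int) -> Genome:
    """Generate a random genome according to ``spec``; deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    p_gc = spec.gc / 2
    p_at = (1 - spec.gc) / 2
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    seqs: dict[str, str] = {}
    classes: dict[str, str] = {}
    for name, length, cls in zip(spec.chrom_names(), spec.lengths, spec.classes):
        arr = BASES[rng.choice(4, size=length, p=probs)]
        if spec.motif_spacing is not None:
            motif = spec.motif
            planted = set(range(0, length - len(motif) + 1, spec.motif_spacing))
            motif_arr = np.array(list(motif))
            for pos in planted:
                arr[pos : pos + len(motif)] = motif_arr
            _destroy_motifs(arr, motif, planted, rng)
        seqs[name] = "".join(arr)
        classes[name] = cls
    return Genome(seqs, classes)


@dataclass
class GeneModel:
    """One transcript model in genomic (0-based half-open) coordinates.

    Interval lists are sorted by genomic start; ``utr5`` / ``utr3`` are
    named in transcript orientation (5' UTR precedes the CDS on the
    transcript's strand).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "coding"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_positions(self) -> list[int]:
        """Genomic CDS positions in transcript (translation) order."""
        pos = [p for s, e in self.cds for p in range(s, e)]
        return pos[::-1] if self.strand == "-" else pos

    def cds_sequence(self, genome: Genome) -> str:
        seq = genome[self.chrom]
        bases = [seq[p] for p in self.cds_positions()]
        if self.strand == "-":
            bases = [revcomp(b) for b in bases]
        return "".join(bases)


def _intervals_from_run(positions: list[int]) -> list[tuple[int, int]]:
    """Collapse a sorted list of genomic positions into half-open intervals."""
    if not positions:
        return []
    positions = sorted(positions)
    out = []
    s = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        out.append((s, prev + 1))
        s = prev = p
    out.append((s, prev + 1))
    return out


def simulate_gene_models(
    genome: Genome,
    n_genes: int,
    seed: int,
    nc_fraction: float = 0.1,
    min_gap: int = 2500,
) -> tuple[list[GeneModel], Genome]:
    """Pack non-overlapping gene models onto the genome.

    The genome sequence is edited so that every coding model carries a
    valid ORF: CDS starts with ATG, ends with a stop codon, and has no
    internal stop on its own strand. Returns the models and the edited
    genome (same object, sequences replaced).

    Raises
    ------
    ValueError
        If ``n_genes`` models do not fit.
    """
    rng = np.random.default_rng(seed)
    arrays = {name: np.array(list(seq)) for name, seq in genome.sequences.items()}
    models: list[GeneModel] = []
    names = genome.names
    cursors = {name: min_gap for name in names}
    chrom_idx = 0
    placed = 0
    exhausted: set[str] = set()
    while placed < n_genes:
        if len(exhausted) == len(names):
            raise ValueError(
                f"cannot pack {n_genes} gene models; placed {placed} before running out of space"
            )
        chrom = names[chrom_idx % len(names)]
        chrom_idx += 1
        if chrom in exhausted:
            continue
        n_ex = int(rng.integers(1, 5))
        exon_lens = rng.integers(150, 400, size=n_ex)
        intron_lens = rng.integers(60, 300, size=max(n_ex - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom]
        if start + span + min_gap > genome.length(chrom):
            exhausted.add(chrom)
            continue
        cursors[chrom] = start + span + int(rng.integers(min_gap, 2 * min_gap))
        strand = "+" if rng.integers(2) == 0 else "-"
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(intron_lens):
                pos += int(intron_lens[i])
        placed += 1
        gene_id = f"gene{placed}"
        if rng.random() < nc_fraction:
            models.append(GeneModel(gene_id, chrom, strand, exons, biotype="ncRNA"))
            continue

        exonic = [p for s, e in exons for p in range(s, e)]
        tx_order = exonic[::-1] if strand == "-" else exonic
        total = len(tx_order)
        u5 = int(rng.integers(30, 101))
        u3 = int(rng.integers(30, 151))
        cds_len = total - u5 - u3
        cds_len -= cds_len % 3
        while cds_len < 6:  # need at least start + stop codon
            u3 -= 3
            cds_len = total - u5 - u3
            cds_len -= cds_len % 3
        u3 = total - u5 - cds_len
        utr5_pos = tx_order[:u5]
        cds_pos = tx_order[u5 : u5 + cds_len]
        utr3_pos = tx_order[u5 + cds_len :]

        # write a clean ORF into the genome (strand-aware)
        n_codons = cds_len // 3
        codons = ["ATG"]
        codons += [
            _NONSTOP_CODONS[i]
            for i in rng.integers(len(_NONSTOP_CODONS), size=n_codons - 2)
        ]
        codons.append(_STOPS[rng.integers(3)])
        orf = "".join(codons)
        arr = arrays[chrom]
        for p, base in zip(cds_pos, orf):
            arr[p] = base if strand == "+" else revcomp(base)

        models.append(
            GeneModel(
                gene_id,
                chrom,
                strand,
                exons,
                cds=_intervals_from_run(cds_pos),
                utr5=_intervals_from_run(utr5_pos),
                utr3=_intervals_from_run(utr3_pos),
            )
        )
    genome.sequences = {name: "".join(arr) for name, arr in arrays.items()}
    return models, genome


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    feature_type = {"coding": "mRNA", "ncRNA": "ncRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            tid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\tgbsforge\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};biotype={m.biotype}\n"
            )
            fh.write(
                f"{m.chrom}\tgbsforge\t{feature_type[m.biotype]}\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={tid};Parent={m.gene_id}\n"
            )
            for kind, ivals in (
                ("exon", m.exons),
                ("CDS", m.cds),
                ("five_prime_UTR", m.utr5),
                ("three_prime_UTR", m.utr3),
            ):
                for s, e in ivals:
                    fh.write(
                        f"{m.chrom}\tgbsforge\t{kind}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"Parent={tid}\n"
                    )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gff3`."""
    genes: dict[str, GeneModel] = {}
    tx2gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, kind, s, e, _, strand, _, attrs = line.rstrip("\n").split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            iv = (int(s) - 1, int(e))
            if kind == "gene":
                genes[attr["ID"]] = GeneModel(
                    attr["ID"], chrom, strand, [], biotype=attr.get("biotype", "coding")
                )
            elif kind in ("mRNA", "ncRNA"):
                tx2gene[attr["ID"]] = attr["Parent"]
            else:
                gene = genes[tx2gene[attr["Parent"]]]
                target = {
                    "exon": gene.exons,
                    "CDS": gene.cds,
                    "five_prime_UTR": gene.utr5,
                    "three_prime_UTR": gene.utr3,
                }[kind]
                target.append(iv)
    for g in genes.values():
        for ivals in (g.exons, g.cds, g.utr5, g.utr3):
            ivals.sort()
    return list(genes.values())


def plant_variants(
    genome: Genome,
    density: float,
    line_divergence_fraction: float,
    seed: int,
    exclude_motif: str | None = None,
) -> pd.DataFrame:
    """Plant biallelic SNPs at random positions.

    Per chromosome the variant count is Poisson(density * length). A
    fraction ``line_divergence_fraction`` of variants is fixed-divergent
    between the TT and CC founder pools (origin ``tt_fixed`` /
    ``cc_fixed`` records which line carries the alt allele); the rest are
    shared-polymorphic with a uniform population alt frequency. Positions
    inside occurrences of ``exclude_motif`` (if given) are avoided so the
    planted alleles never destroy a planted restriction site.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for name, seq in genome.sequences.items():
        length = len(seq)
        n = rng.poisson(density * length)
        banned = np.zeros(length, dtype=bool)
        if exclude_motif:
            from gbsforge.digest import find_sites

            for s in find_sites(seq, exclude_motif):
                banned[s : s + len(exclude_motif)] = True
        chosen: set[int] = set()
        attempts = 0
        while len(chosen) < n and attempts < 50 * max(n, 1):
            pos = int(rng.integers(length))
            attempts += 1
            if pos in chosen or banned[pos] or seq[pos] not in "ACGT":
                continue
            chosen.add(pos)
        for pos in sorted(chosen):
            ref = seq[pos]
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
            if rng.random() < line_divergence_fraction:
                origin = "tt_fixed" if rng.integers(2) == 0 else "cc_fixed"
                freq = 0.5
            else:
                origin = "shared"
                freq = float(rng.uniform(0.05, 0.95))
            rows.append((name, pos, ref, alt, origin, freq))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_truth_variants_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Sites-only VCF with founder-origin INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Founder origin">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Population alt frequency">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"ORIGIN={row.origin};AF={row.alt_freq:.4f}\n"
            )
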