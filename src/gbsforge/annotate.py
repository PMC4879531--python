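"""Functional-context SNP classification, inter-SNP distances, densities.

Categories mirror the usual annotation breakdown: intergenic, intronic,
splicing (2 intronic bases at each intron edge), ncRNA, UTRs, 1 kb
flanks, and exonic codon classes (synonymous / non-synonymous /
start-lost / stop-gained / stop-lost). One variant may collect several
categories across overlapping transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from gbsforge.enzymes import revcomp
from gbsforge.genome import Genome
from gbsforge.genome_sim import GeneModel

CATEGORIES = (
    "intergenic",
    "intronic",
    "exonic:synonymous",
    "exonic:non-synonymous",
    "exonic:start-lost",
    "exonic:stop-gained",
    "exonic:stop-lost",
    "splicing",
    "ncRNA",
    "5'UTR",
    "3'UTR",
    "upstream1kb",
    "downstream1kb",
)

SPLICE_WIDTH = 2
FLANK = 1000


def _in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _classify_cds(
    pos: int, ref: str, alt: str, model: GeneModel, genome: Genome
) -> str:
    """Codon-level classification of a CDS SNP (strand-aware)."""
    cds_pos = model.cds_positions()
    t = cds_pos.index(pos)
    codon_i = t // 3
    codon_positions = cds_pos[3 * codon_i : 3 * codon_i + 3]
    seq = genome[model.chrom]

    def base(p: int, substitute: str | None) -> str:
        b = substitute if substitute is not None and p == pos else seq[p]
        return b if model.strand == "+" else revcomp(b)

    ref_codon = "".join(base(p, None) for p in codon_positions)
    alt_codon = "".join(base(p, alt) for p in codon_positions)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "exonic:start-lost"
    if ref_aa == "*" and alt_aa != "*":
        return "exonic:stop-lost"
    if alt_aa == "*" and ref_aa != "*":
        return "exonic:stop-gained"
    return "exonic:synonymous" if ref_aa == alt_aa else "exonic:non-synonymous"


def annotate_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: list[GeneModel],
    genome: Genome,
    flank: int = FLANK,
    splice_width: int = SPLICE_WIDTH,
) -> list[tuple[str, str]]:
    """Categories for one variant: list of (category, transcript id).

    A variant touching no transcript and no 1 kb flank is intergenic.
    Raises ValueError when ``ref`` disagrees with the genome.
    """
    if genome[chrom][pos] != ref:
        raise ValueError(
            f"ref allele {ref} does not match genome base "
            f"{genome[chrom][pos]} at {chrom}:{pos}"
        )
    out: list[tuple[str, str]] = []
    for m in models:
        if m.chrom != chrom:
            continue
        tid = f"{m.gene_id}.t1"
        if m.start <= pos < m.end:
            if _in_intervals(pos, m.exons):
                if m.biotype == "ncRNA":
                    out.append(("ncRNA", tid))
                elif _in_intervals(pos, m.cds):
                    out.append((_classify_cds(pos, ref, alt, m, genome), tid))
                elif _in_intervals(pos, m.utr5):
                    out.append(("5'UTR", tid))
                elif _in_intervals(pos, m.utr3):
                    out.append(("3'UTR", tid))
                else:  # exon base outside annotated subfeatures
                    out.append(("ncRNA" if m.biotype == "ncRNA" else "intronic", tid))
            else:
                splice = False
                for (s1, e1), (s2, _) in zip(m.exons, m.exons[1:]):
                    if e1 <= pos < e1 + splice_width or s2 - splice_width <= pos < s2:
                        splice = True
                        break
                out.append(("splicing" if splice else "intronic", tid))
        elif m.start - flank <= pos < m.start:
            out.append(("upstream1kb" if m.strand == "+" else "downstream1kb", tid))
        elif m.end <= pos < m.end + flank:
            out.append(("downstream1kb" if m.strand == "+" else "upstream1kb", tid))
    if not out:
        out.append(("intergenic", "."))
    return out


def annotate_variants(
    variants: pd.DataFrame, models: list[GeneModel], genome: Genome, **kw
) -> pd.DataFrame:
    """Annotate a variant table; one output row per (variant, category)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    rows = []
    for v in variants.itertuples(index=False):
        cats = annotate_variant(
            v.chrom, int(v.pos), v.ref, v.alt, by_chrom.get(v.chrom, []), genome, **kw
        )
        for cat, tid in cats:
            rows.append((v.chrom, int(v.pos), v.ref, v.alt, cat, tid))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "category", "transcript"]
    )


def category_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Annotation counts and percentages by category."""
    counts = annotations["category"].value_counts()
    table = pd.DataFrame({"category": counts.index, "count": counts.values})
    table["pct"] = 100.0 * table["count"] / table["count"].sum()
    return table


@dataclass
class DistanceSummary:
    per_chrom: pd.DataFrame  # chrom, n_distances, mean, median, min, max
    mean: float
    median: float
    min: int
    max: int
    n_distances: int
    bin_fractions: pd.DataFrame  # bin label, fraction

    def __post_init__(self) -> None:
        if self.n_distances:
            assert self.min <= self.median <= self.max


def distance_summary(
    sites: pd.DataFrame, bin_edges: list[float] | None = None
) -> DistanceSummary:
    """Adjacent-SNP distance statistics, within chromosomes only.

    ``sites`` needs ``chrom`` and ``pos`` columns; positions are sorted
    and de-duplicated per chromosome. Bin fractions are computed over the
    pooled distance list with ``bin_edges`` (last edge may be inf).
    """
    if bin_edges is None:
        bin_edges = [0, 1_000, 10_000, 100_000, 1_000_000, float("inf")]
    pooled = []
    rows = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        pos = np.unique(sub["pos"].to_numpy())
        if pos.size < 2:
            continue
        d = np.diff(pos)
        pooled.append(d)
        rows.append(
            {
                "chrom": chrom,
                "n_distances": d.size,
                "mean": float(d.mean()),
                "median": float(np.median(d)),
                "min": int(d.min()),
                "max": int(d.max()),
            }
        )
    per_chrom = pd.DataFrame(rows)
    if not pooled:
        empty = pd.DataFrame(columns=["bin", "fraction"])
        return DistanceSummary(per_chrom, float("nan"), float("nan"), 0, 0, 0, empty)
    d = np.concatenate(pooled)
    counts, _ = np.histogram(d, bins=bin_edges)
    labels = [
        f"[{bin_edges[i]:g},{bin_edges[i + 1]:g})" for i in range(len(bin_edges) - 1)
    ]
    fractions = pd.DataFrame({"bin": labels, "fraction": counts / d.size})
    return DistanceSummary(
        per_chrom,
        float(d.mean()),
        float(np.median(d)),
        int(d.min()),
        int(d.max()),
        int(d.size),
        fractions,
    )


def density_by_class(
    sites: pd.DataFrame,
    chrom_classes: dict[str, str],
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """SNP count, % of SNPs and SNP/Mbp per chromosome size class."""
    for chrom in sites["chrom"].unique():
        if chrom not in chrom_classes:
            raise ValueError(f"chromosome {chrom!r} has no class label")
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} has no size")
    classes = sorted(set(chrom_classes.values()))
    total = len(sites)
    rows = []
    for cls in classes:
        chroms = [c for c, k in chrom_classes.items() if k == cls]
        n = int(sites["chrom"].isin(chroms).sum())
        mbp = sum(chrom_sizes[c] for c in chroms) / 1e6
        rows.append(
            {
                "class": cls,
                "n_snps": n,
                "pct_of_snps": 100.0 * n / total if total else 0.0,
                "mbp": mbp,
                "snp_per_mbp": n / mbp if mbp else float("nan"),
            }
        )
    return pd.DataFrame(rows)
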