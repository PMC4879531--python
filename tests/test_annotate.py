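import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from gbsforge.annotate import (
    annotate_variant,
    annotate_variants,
    category_summary,
    density_by_class,
    distance_summary,
)
from gbsforge.enzymes import revcomp
from gbsforge.genome import Genome
from gbsforge.genome_sim import GeneModel, GenomeSpec, plant_variants, simulate_gene_models, simulate_genome


def brute_force_categories(chrom, pos, ref, alt, models, genome,
                           flank=1000, splice=2):
    """Independent per-base classifier used as the annotation oracle.

    Walks every transcript base-by-base, never reusing the interval
    logic of the implementation.
    """
    cats = []
    for m in models:
        if m.chrom != chrom:
            continue
        tid = f"{m.gene_id}.t1"
        gene_positions = set(range(m.start, m.end))
        exon_positions = set(p for s, e in m.exons for p in range(s, e))
        if pos in gene_positions:
            if pos in exon_positions:
                if m.biotype == "ncRNA":
                    cats.append(("ncRNA", tid))
                else:
                    cds_positions = [p for s, e in m.cds for p in range(s, e)]
                    if pos in set(cds_positions):
                        ordered = (
                            cds_positions[::-1] if m.strand == "-" else cds_positions
                        )
                        idx = ordered.index(pos)
                        ci = idx // 3
                        codon_pos = ordered[3 * ci : 3 * ci + 3]
                        seq = genome[chrom]
                        rb = [seq[p] for p in codon_pos]
                        ab = [alt if p == pos else seq[p] for p in codon_pos]
                        if m.strand == "-":
                            rb = [revcomp(b) for b in rb]
                            ab = [revcomp(b) for b in ab]
                        rc, ac = "".join(rb), "".join(ab)
                        raa = str(Seq(rc).translate())
                        aaa = str(Seq(ac).translate())
                        if ci == 0 and rc == "ATG" and ac != "ATG":
                            cats.append(("exonic:start-lost", tid))
                        elif raa == "*" and aaa != "*":
                            cats.append(("exonic:stop-lost", tid))
                        elif aaa == "*" and raa != "*":
                            cats.append(("exonic:stop-gained", tid))
                        elif raa == aaa:
                            cats.append(("exonic:synonymous", tid))
                        else:
                            cats.append(("exonic:non-synonymous", tid))
                    elif pos in set(p for s, e in m.utr5 for p in range(s, e)):
                        cats.append(("5'UTR", tid))
                    elif pos in set(p for s, e in m.utr3 for p in range(s, e)):
                        cats.append(("3'UTR", tid))
            else:
                splice_positions = set()
                sorted_exons = sorted(m.exons)
                for (s1, e1), (s2, _) in zip(sorted_exons, sorted_exons[1:]):
                    splice_positions.update(range(e1, e1 + splice))
                    splice_positions.update(range(s2 - splice, s2))
                if pos in splice_positions:
                    cats.append(("splicing", tid))
                else:
                    cats.append(("intronic", tid))
        elif m.start - flank <= pos < m.start:
            cats.append(("upstream1kb" if m.strand == "+" else "downstream1kb", tid))
        elif m.end <= pos < m.end + flank:
            cats.append(("downstream1kb" if m.strand == "+" else "upstream1kb", tid))
    if not cats:
        cats.append(("intergenic", "."))
    return cats


def plus_strand_gene():
    """Hand-laid single-exon gene: 5'UTR [100,110), CDS [110,131), 3'UTR [131,140).

    CDS codons: ATG GCT TGG TAC CCA TAA (M A W Y P *)
    """
    cds = "ATGGCTTGGTACCCATAA"
    seq = "T" * 100 + "CACACACACA" + cds + "GTT" + "T" * 200
    genome = Genome({"c1": seq})
    model = GeneModel(
        "g1", "c1", "+",
        exons=[(100, 131 + 9)],
        cds=[(110, 128)],
        utr5=[(100, 110)],
        utr3=[(128, 140)],
    )
    return genome, [model]


class TestCodonClassification:
    def test_synonymous(self):
        genome, models = plus_strand_gene()
        # GCT -> GCC : Ala -> Ala (position 115 is the T of GCT)
        cats = annotate_variant("c1", 115, "T", "C", models, genome)
        assert ("exonic:synonymous", "g1.t1") in cats

    def test_non_synonymous(self):
        genome, models = plus_strand_gene()
        # GCT -> GAT : Ala -> Asp
        cats = annotate_variant("c1", 114, "C", "A", models, genome)
        assert ("exonic:non-synonymous", "g1.t1") in cats

    def test_start_lost(self):
        genome, models = plus_strand_gene()
        cats = annotate_variant("c1", 110, "A", "G", models, genome)  # ATG -> GTG
        assert ("exonic:start-lost", "g1.t1") in cats

    def test_stop_gained(self):
        genome, models = plus_strand_gene()
        # TGG (Trp, codon 3 at 116..119) -> TGA
        cats = annotate_variant("c1", 118, "G", "A", models, genome)
        assert ("exonic:stop-gained", "g1.t1") in cats

    def test_stop_lost(self):
        genome, models = plus_strand_gene()
        # terminal TAA at 125..128 -> CAA
        cats = annotate_variant("c1", 125, "T", "C", models, genome)
        assert ("exonic:stop-lost", "g1.t1") in cats

    def test_utrs(self):
        genome, models = plus_strand_gene()
        assert ("5'UTR", "g1.t1") in annotate_variant("c1", 104, "C", "T", models, genome)
        assert ("3'UTR", "g1.t1") in annotate_variant("c1", 135, "T", "A", models, genome)

    def test_upstream_500bp(self):
        genome, models = plus_strand_gene()
        # model starts at 100; cannot go 500 upstream, use downstream side
        cats = annotate_variant("c1", 240, "T", "A", models, genome)
        assert ("downstream1kb", "g1.t1") in cats

    def test_upstream_minus_strand(self):
        genome, models = plus_strand_gene()
        models[0].strand = "-"
        cats = annotate_variant("c1", 240, "T", "A", models, genome)
        assert ("upstream1kb", "g1.t1") in cats
        models[0].strand = "+"

    def test_ref_mismatch_raises(self):
        genome, models = plus_strand_gene()
        with pytest.raises(ValueError, match="ref allele"):
            annotate_variant("c1", 110, "C", "G", models, genome)


@pytest.fixture(scope="module")
def annotated_genome():
    genome = simulate_genome(GenomeSpec([1_000_000], ["large"]), seed=31)
    models, genome = simulate_gene_models(genome, 60, seed=32, nc_fraction=0.2)
    variants = plant_variants(genome, 5e-4, 0.5, seed=33)
    return genome, models, variants


class TestOracleEquivalence:

    def test_category_multiset_matches_bruteforce(self, annotated_genome):
        genome, models, variants = annotated_genome
        impl = annotate_variants(variants, models, genome)
        impl_multiset = sorted(
            zip(impl["pos"], impl["category"], impl["transcript"])
        )
        oracle = []
        for v in variants.itertuples(index=False):
            for cat, tid in brute_force_categories(
                v.chrom, v.pos, v.ref, v.alt, models, genome
            ):
                oracle.append((v.pos, cat, tid))
        assert impl_multiset == sorted(oracle)

    def test_every_variant_annotated(self, annotated_genome):
        genome, models, variants = annotated_genome
        impl = annotate_variants(variants, models, genome)
        assert set(impl["pos"]) == set(variants["pos"])
        summary = category_summary(impl)
        assert summary["count"].sum() == len(impl)


class TestDistanceSummary:
    def test_hand_case(self):
        sites = pd.DataFrame({"chrom": ["c1"] * 4, "pos": [100, 155, 210, 1_000_000]})
        out = distance_summary(sites)
        assert out.median == 55
        assert out.mean == pytest.approx(333_300)
        assert out.min == 55 and out.max == 999_790

    def test_single_variant_no_distances(self):
        out = distance_summary(pd.DataFrame({"chrom": ["c1"], "pos": [5]}))
        assert out.n_distances == 0

    def test_evenly_spaced(self):
        sites = pd.DataFrame({"chrom": ["c1"] * 50, "pos": list(range(0, 50_000, 1000))})
        out = distance_summary(sites)
        assert out.mean == out.median == 1000

    def test_cross_chromosome_not_counted(self):
        sites = pd.DataFrame({"chrom": ["c1", "c2"], "pos": [100, 200]})
        assert distance_summary(sites).n_distances == 0

    def test_bin_fractions_sum_to_one(self):
        sites = pd.DataFrame({"chrom": ["c1"] * 20, "pos": sorted(np.random.default_rng(5).choice(10**6, 20, replace=False))})
        out = distance_summary(sites)
        assert out.bin_fractions["fraction"].sum() == pytest.approx(1.0)


class TestDensityByClass:
    def test_all_on_micro(self):
        sites = pd.DataFrame({"chrom": ["m1"] * 7, "pos": range(7)})
        out = density_by_class(sites, {"m1": "micro", "l1": "large"},
                               {"m1": 1_000_000, "l1": 10_000_000})
        micro = out[out["class"] == "micro"].iloc[0]
        assert micro["pct_of_snps"] == 100.0
        assert micro["snp_per_mbp"] == 7.0

    def test_uniform_density_proportional(self, rng):
        sizes = {"a": 68_000_000, "b": 15_000_000, "c": 17_000_000}
        classes = {"a": "large", "b": "medium", "c": "micro"}
        rows = []
        for chrom, size in sizes.items():
            for p in rng.choice(size, size // 100_000, replace=False):
                rows.append((chrom, p))
        sites = pd.DataFrame(rows, columns=["chrom", "pos"])
        out = density_by_class(sites, classes, sizes).set_index("class")
        assert out.loc["large", "pct_of_snps"] == pytest.approx(68, abs=1)
        assert out.loc["medium", "pct_of_snps"] == pytest.approx(15, abs=1)

    def test_empty_and_unlabeled(self):
        empty = pd.DataFrame(columns=["chrom", "pos"])
        out = density_by_class(empty, {"a": "large"}, {"a": 1_000_000})
        assert (out["n_snps"] == 0).all()
        with pytest.raises(ValueError):
            density_by_class(
                pd.DataFrame({"chrom": ["zz"], "pos": [1]}), {"a": "large"}, {"a": 1}
            )
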