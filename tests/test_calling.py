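import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbsforge.calling import (
    CallerParams,
    FilterParams,
    GenotypeMatrix,
    align_tags,
    apply_filters,
    call_genotypes,
    discover_and_call,
    read_callset,
    write_callset,
)
from gbsforge.enzymes import revcomp
from gbsforge.genome import Genome
from gbsforge.tags import TagCatalog


class TestCallGenotypes:
    def test_hom_ref(self):
        # closed form: 0.99^5 ~ 0.951 vs 0.5^5 = 0.03125 vs 0.01^5 = 1e-10
        assert call_genotypes([5], [0], CallerParams())[0] == 0

    def test_het(self):
        assert call_genotypes([3], [4], CallerParams())[0] == 1

    def test_missing_on_zero_depth(self):
        assert call_genotypes([0], [0], CallerParams())[0] == -1

    def test_hom_alt(self):
        assert call_genotypes([0], [7], CallerParams())[0] == 2

    def test_min_depth(self):
        assert call_genotypes([2], [0], CallerParams(min_depth=3))[0] == -1


@pytest.fixture(scope="module")
def tag_genome(pstI):
    rng = np.random.default_rng(99)
    seq = "".join("ACGT"[i] for i in rng.integers(4, size=20_000))
    # destroy accidental motifs, then plant one site and one duplicated region
    while pstI.recognition in seq:
        seq = seq.replace(pstI.recognition, "CTACAG", 1)
    seq = seq[:5000] + pstI.recognition + seq[5006:]
    seq = seq[:12_000] + seq[2000:2200] + seq[12_200:]  # exact 200 bp duplication
    return Genome({"c1": seq})


class TestAlignTags:
    def test_exact_tag_aligns(self, tag_genome):
        tag = tag_genome["c1"][3000:3064]
        cat = TagCatalog({tag: {"s1": 4}})
        aln = align_tags(cat, tag_genome)
        row = aln.iloc[0]
        assert row["aligned"] and row["chrom"] == "c1"
        assert row["start"] == 3000 and row["strand"] == "+" and row["mismatches"] == 0

    def test_reverse_strand_tag(self, tag_genome):
        tag = revcomp(tag_genome["c1"][4000:4064])
        aln = align_tags(TagCatalog({tag: {"s1": 1}}), tag_genome)
        row = aln.iloc[0]
        assert row["aligned"] and row["start"] == 4000 and row["strand"] == "-"

    def test_mismatched_tag_aligns_with_count(self, tag_genome):
        ref = tag_genome["c1"][3000:3064]
        tag = ref[:10] + ("A" if ref[10] != "A" else "C") + ref[11:]
        aln = align_tags(TagCatalog({tag: {"s1": 1}}), tag_genome)
        row = aln.iloc[0]
        assert row["aligned"] and row["mismatches"] == 1 and row["start"] == 3000

    def test_repeated_region_tag_unaligned(self, tag_genome):
        tag = tag_genome["c1"][2050:2114]  # inside the duplicated block
        assert tag == tag_genome["c1"][12_050:12_114]
        aln = align_tags(TagCatalog({tag: {"s1": 1}}), tag_genome)
        assert not aln.iloc[0]["aligned"]

    def test_too_many_mismatches_unaligned(self, tag_genome, rng):
        tag = "".join("ACGT"[i] for i in rng.integers(4, size=64))
        aln = align_tags(TagCatalog({tag: {"s1": 1}}), tag_genome, max_mismatches=3)
        assert not aln.iloc[0]["aligned"]


class TestDiscoverAndCall:
    def test_snp_discovery_and_genotypes(self, tag_genome, pstI):
        ref = tag_genome["c1"][3000:3064]
        alt_base = "A" if ref[30] != "A" else "G"
        alt = ref[:30] + alt_base + ref[31:]
        cat = TagCatalog({ref: {"s1": 8, "s2": 4}, alt: {"s2": 4, "s3": 9}})
        aln = align_tags(cat, tag_genome)
        matrix, n_multi = discover_and_call(cat, aln, tag_genome, ["s1", "s2", "s3"])
        assert n_multi == 0
        assert matrix.n_sites == 1
        site = matrix.sites.iloc[0]
        assert (site["chrom"], site["pos"], site["ref"], site["alt"]) == (
            "c1", 3030, ref[30], alt_base,
        )
        assert matrix.geno[:, 0].tolist() == [0, 1, 2]
        assert matrix.depths[1, 0].tolist() == [4, 4]

    def test_third_allele_noise_kept_biallelic(self, tag_genome):
        ref = tag_genome["c1"][3000:3064]
        b1, b2 = [b for b in "ACGT" if b != ref[30]][:2]
        a1 = ref[:30] + b1 + ref[31:]
        a2 = ref[:30] + b2 + ref[31:]
        cat = TagCatalog({ref: {"s1": 50}, a1: {"s2": 40}, a2: {"s2": 1}})
        aln = align_tags(cat, tag_genome)
        matrix, n_multi = discover_and_call(cat, aln, tag_genome, ["s1", "s2"])
        assert matrix.n_sites == 1
        assert matrix.sites.iloc[0]["alt"] == b1

    def test_reference_minor_excluded_as_multiallelic(self, tag_genome):
        ref = tag_genome["c1"][3000:3064]
        b1, b2 = [b for b in "ACGT" if b != ref[30]][:2]
        a1 = ref[:30] + b1 + ref[31:]
        a2 = ref[:30] + b2 + ref[31:]
        cat = TagCatalog({a1: {"s1": 50}, a2: {"s2": 40}, ref: {"s3": 1}})
        aln = align_tags(cat, tag_genome)
        matrix, n_multi = discover_and_call(cat, aln, tag_genome, ["s1", "s2", "s3"])
        assert n_multi == 1
        assert matrix.n_sites == 0


def toy_matrix():
    """5 taxa x 4 sites, hand-built so that with (mnTCov .2, mnScov .9,
    mnMAF .01) taxon t5 and sites s2, s3 are removed:

      t5 call rate 0        -> removed first (< 0.2)
      s1: call 4/4, MAF .25 -> keep
      s2: call 3/4          -> drop (< 0.9)
      s3: call 4/4, MAF 0   -> drop (< 0.01)
      s4: call 4/4, MAF .375-> keep
    """
    geno = np.array(
        [
            [0, 0, 0, 1],
            [1, 0, 0, 0],
            [0, -1, 0, 1],
            [1, 0, 0, 1],
            [-1, -1, -1, -1],
        ],
        dtype=np.int8,
    )
    sites = pd.DataFrame(
        {
            "chrom": ["c1"] * 4,
            "pos": [10, 20, 30, 40],
            "ref": ["A"] * 4,
            "alt": ["C"] * 4,
        }
    )
    return GenotypeMatrix(["t1", "t2", "t3", "t4", "t5"], sites, geno)


class TestApplyFilters:
    def test_toy_fixture(self):
        out, log = apply_filters(toy_matrix(), FilterParams(0.2, 0.9, 0.01, 0.05))
        assert out.samples == ["t1", "t2", "t3", "t4"]
        assert out.sites["pos"].tolist() == [10, 40]
        assert log["taxa_removed"] == 1

    def test_all_hom_ref_drops_everything(self):
        m = toy_matrix()
        m.geno[:] = 0
        with pytest.warns(UserWarning):
            out, _ = apply_filters(m, FilterParams(0.2, 0.9, 0.01, 0.05))
        assert out.n_sites == 0

    def test_zero_thresholds_identity(self):
        m = toy_matrix()
        out, _ = apply_filters(m, FilterParams(0, 0, 0, 1))
        assert out.samples == m.samples
        assert out.n_sites == m.n_sites
        assert np.array_equal(out.geno, m.geno)

    def test_surviving_maf_at_least_threshold(self):
        out, _ = apply_filters(toy_matrix(), FilterParams(0.2, 0.9, 0.01, 0.05))
        assert (out.site_maf() >= 0.01).all()

    @given(st.floats(0, 1), st.floats(0, 0.5), st.floats(0, 1), st.floats(0, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_site_threshold_monotonicity(self, s1, m1, s2, m2):
        # site thresholds are monotone at a fixed taxon filter (raising
        # mnTCov can change site statistics through the removed taxa, so
        # joint monotonicity is not a theorem)
        import warnings

        lo = FilterParams(0.2, min(s1, s2), min(m1, m2), 0.05)
        hi = FilterParams(0.2, max(s1, s2), max(m1, m2), 0.05)
        m = toy_matrix()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out_lo, _ = apply_filters(m, lo)
            out_hi, _ = apply_filters(m, hi)
        assert out_hi.n_sites <= out_lo.n_sites

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=20, deadline=None)
    def test_taxon_threshold_monotonicity(self, t1, t2):
        import warnings

        m = toy_matrix()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out_lo, _ = apply_filters(m, FilterParams(min(t1, t2), 0.9, 0.01, 0.05))
            out_hi, _ = apply_filters(m, FilterParams(max(t1, t2), 0.9, 0.01, 0.05))
        assert out_hi.n_samples <= out_lo.n_samples

    def test_duplicate_sites_merged_when_consistent(self):
        geno = np.array([[0, 0], [1, 1], [2, -1]], dtype=np.int8)
        sites = pd.DataFrame(
            {"chrom": ["c1", "c1"], "pos": [5, 5], "ref": ["A", "A"], "alt": ["C", "C"]}
        )
        m = GenotypeMatrix(["a", "b", "c"], sites, geno)
        out, log = apply_filters(m, FilterParams(0, 0, 0, 0.05))
        assert out.n_sites == 1
        assert out.geno[:, 0].tolist() == [0, 1, 2]

    def test_duplicate_sites_dropped_when_discordant(self):
        geno = np.array([[0, 2], [1, 1], [2, 0], [0, 2]], dtype=np.int8)
        sites = pd.DataFrame(
            {"chrom": ["c1", "c1"], "pos": [5, 5], "ref": ["A", "A"], "alt": ["C", "C"]}
        )
        m = GenotypeMatrix(["a", "b", "c", "d"], sites, geno)
        out, log = apply_filters(m, FilterParams(0, 0, 0, 0.05))
        assert out.n_sites == 0
        assert log["sites_dropped_duplicate"] == 2


class TestVcfRoundTrip:
    def test_write_read_equal(self, tmp_path):
        m = toy_matrix()
        m.depths = np.zeros((5, 4, 2), dtype=np.int32)
        m.depths[:, :, 0] = 3
        m.depths[1, 0] = [3, 4]
        path = tmp_path / "calls.vcf"
        write_callset(m, path)
        back = read_callset(path)
        assert back.samples == m.samples
        assert np.array_equal(back.geno, m.geno)
        assert np.array_equal(back.depths, m.depths)
        pd.testing.assert_frame_equal(back.sites, m.sites)

    def test_missing_written_as_dots(self, tmp_path):
        m = toy_matrix()
        path = tmp_path / "calls.vcf"
        write_callset(m, path)
        text = path.read_text()
        assert "./." in text

    def test_het_with_depths(self, tmp_path):
        sites = pd.DataFrame(
            {"chrom": ["c1"], "pos": [7], "ref": ["A"], "alt": ["T"]}
        )
        m = GenotypeMatrix(
            ["x"], sites, np.array([[1]], dtype=np.int8),
            np.array([[[3, 4]]], dtype=np.int32),
        )
        path = tmp_path / "one.vcf"
        write_callset(m, path)
        assert "0/1:3,4" in path.read_text()
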