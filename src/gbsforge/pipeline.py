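"""End-to-end orchestration on synthetic data.

``run_end_to_end`` executes digestion -> pedigree/read simulation -> tag
processing -> calling/filtering -> evaluation, annotation and linkage,
writing every artifact plus a machine-readable manifest. All randomness
derives from the single config seed, so a rerun is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gbsforge import __version__
from gbsforge.annotate import annotate_variants, category_summary, distance_summary
from gbsforge.calling import (
    CallerParams,
    FilterParams,
    align_tags,
    apply_filters,
    discover_and_call,
    write_callset,
)
from gbsforge.digest import SizeWindow, digest, size_select, write_fragments_bed
from gbsforge.enzymes import get_enzyme
from gbsforge.evaluate import (
    genotype_concordance,
    heterozygosity_summary,
    mendelian_report,
    position_concordance,
    taxon_call_rate_distribution,
)
from gbsforge.genome_sim import (
    GenomeSpec,
    default_spec,
    plant_variants,
    simulate_gene_models,
    simulate_genome,
    write_gff3,
    write_truth_variants_vcf,
)
from gbsforge.library_sim import (
    ReadSimParams,
    design_barcodes,
    make_key_file,
    simulate_reads,
    write_key_file,
)
from gbsforge.linkage import classify_segregation, group_markers, pairwise_twopoint
from gbsforge.calling import GenotypeMatrix
from gbsforge.pedigree_sim import (
    build_f2_design,
    simulate_founders,
    write_pedigree,
    write_truth_vcf,
)
from gbsforge.tags import QCParams, build_master_catalog, demultiplex, parse_fastq, quality_filter

log = logging.getLogger("gbsforge")


@dataclass
class RunConfig:
    """Desk-scale default: ~10 Mb genome, 10 F0 + 8 F1 + 30 F2, depth 8."""

    seed: int = 1
    out_dir: str = "gbsforge_run"
    enzyme: str = "PstI"
    window_lo: int = 200
    window_hi: int = 500
    genome_spec: GenomeSpec | None = None
    fasta: str | None = None
    n_genes: int = 40
    variant_density: float = 1e-3
    divergence_fraction: float = 0.8
    residual_het: float = 0.02
    n_tt: int = 5
    n_cc: int = 5
    n_f1: int = 8
    family_sizes: tuple[int, ...] = (6, 6, 6, 6, 6)
    recomb_rate_per_bp: float = 3e-8
    plex: int = 48
    read_length: int = 100
    mean_depth: float = 8.0
    dispersion: float = 5.0
    error_rate: float = 0.002
    qc: QCParams = field(default_factory=QCParams)
    caller: CallerParams = field(default_factory=CallerParams)
    filters: FilterParams = field(default_factory=FilterParams)
    min_lod: float = 8.0
    max_rf: float = 0.35
    linkage_max_markers: int = 250


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Run the whole synthetic study; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enzyme = get_enzyme(config.enzyme)
    window = SizeWindow(config.window_lo, config.window_hi)
    seeds = np.random.SeedSequence(config.seed).generate_state(8)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}, "artifacts": {}}

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    # --- genome & gene models ---------------------------------------------
    s = stage("genome")
    if config.fasta:
        from gbsforge.genome import Genome

        genome = Genome.from_fasta(config.fasta)
        models = []
    else:
        spec = config.genome_spec or default_spec()
        genome = simulate_genome(spec, int(seeds[0]))
        models, genome = simulate_gene_models(genome, config.n_genes, int(seeds[1]))
    s["n_chromosomes"] = len(genome.names)
    s["total_bp"] = genome.total_length
    genome.to_fasta(out / "genome.fa")
    write_gff3(models, out / "genes.gff3")
    manifest["artifacts"]["genome"] = "genome.fa"
    manifest["artifacts"]["genes"] = "genes.gff3"

    # --- digestion --------------------------------------------------------
    s = stage("digest")
    fragments = digest(genome, enzyme)
    selected = size_select(fragments, window)
    s["total_fragments"] = len(fragments)
    s["in_window_fragments"] = len(selected)
    write_fragments_bed(selected, out / "fragments.bed")
    manifest["artifacts"]["fragments"] = "fragments.bed"

    # --- pedigree & truth -------------------------------------------------
    s = stage("pedigree")
    variants = plant_variants(
        genome, config.variant_density, config.divergence_fraction,
        int(seeds[2]), exclude_motif=enzyme.recognition,
    )
    founders = simulate_founders(
        variants, config.n_tt, config.n_cc, config.residual_het, int(seeds[3])
    )
    if config.family_sizes:
        pedigree, truth = build_f2_design(
            founders, list(config.family_sizes), config.recomb_rate_per_bp,
            config.n_f1, int(seeds[4]),
        )
    else:
        log.info("no F2 families configured; simulating founders only")
        truth = founders
        pedigree = pd.DataFrame(
            [
                (s, ".", ".", "M" if i % 2 == 0 else "F", "F0", s.split("_")[0], ".")
                for i, s in enumerate(founders.samples)
            ],
            columns=["sample", "sire", "dam", "sex", "generation", "line", "family"],
        )
    s["n_variants"] = len(variants)
    s["n_samples"] = len(truth.samples)
    write_truth_variants_vcf(variants, out / "truth_variants.vcf")
    write_pedigree(pedigree, out / "pedigree.tsv")
    write_truth_vcf(truth, out / "truth_genotypes.vcf")
    manifest["artifacts"]["pedigree"] = "pedigree.tsv"
    manifest["artifacts"]["truth"] = "truth_genotypes.vcf"

    # --- library & reads --------------------------------------------------
    s = stage("reads")
    plex = min(config.plex, len(truth.samples))
    barcodes = design_barcodes(plex, enzyme, seed=int(seeds[5]))
    key = make_key_file(truth.samples, barcodes, plex)
    write_key_file(key, out / "key.tsv")
    params = ReadSimParams(
        read_length=config.read_length, mean_depth=config.mean_depth,
        dispersion=config.dispersion, error_rate=config.error_rate,
    )
    fastqs = simulate_reads(
        genome, truth, selected, key, enzyme, params, int(seeds[6]), out / "reads"
    )
    s["n_lanes"] = len(fastqs)
    manifest["artifacts"]["key"] = "key.tsv"

    # --- tag processing ---------------------------------------------------
    s = stage("tags")
    per_sample: dict[str, list[str]] = {}
    qc_totals = {"total": 0, "retained": 0}
    demux_totals = {"assigned": 0, "unassigned": 0}
    for lane_name, path in fastqs.items():
        lane = int(str(lane_name).rsplit("_", 1)[1])
        retained, tally = quality_filter(parse_fastq(path), config.qc)
        qc_totals["total"] += tally["total"]
        qc_totals["retained"] += tally["retained"]
        assigned, dtally = demultiplex(retained, key, lane, enzyme)
        demux_totals["assigned"] += dtally["assigned"]
        demux_totals["unassigned"] += dtally["unassigned"]
        for sample, reads in assigned.items():
            per_sample.setdefault(sample, []).extend(reads)
    catalog = build_master_catalog(per_sample, enzyme)
    s.update(qc=qc_totals, demux=demux_totals, n_tags=len(catalog),
             reads_in_catalog=catalog.totals.get("retained", 0))
    catalog.write_tsv(out / "catalog.tsv")
    manifest["artifacts"]["catalog"] = "catalog.tsv"

    # --- calling ----------------------------------------------------------
    s = stage("calling")
    alignments = align_tags(catalog, genome, config.caller.max_mismatches)
    s["n_tags_aligned"] = int(alignments["aligned"].sum()) if len(alignments) else 0
    matrix, n_multi = discover_and_call(
        catalog, alignments, genome, truth.samples, config.caller
    )
    s["n_sites_discovered"] = matrix.n_sites
    s["n_multiallelic_excluded"] = n_multi
    filtered, flog = apply_filters(matrix, config.filters)
    s["filter_log"] = flog
    write_callset(filtered, out / "callset.vcf")
    manifest["artifacts"]["callset"] = "callset.vcf"

    # --- evaluation -------------------------------------------------------
    s = stage("evaluation")
    truth_matrix = GenotypeMatrix(
        truth.samples, variants.rename(columns={})[["chrom", "pos", "ref", "alt"]],
        truth.genotypes,
    )
    if filtered.n_sites and len(config.family_sizes):
        pos_conc = position_concordance(filtered.sites, truth_matrix.sites)
        conc = genotype_concordance(filtered, truth_matrix)
        s["position_concordance"] = pos_conc
        s["pct_genotype_concordant"] = conc.pct_concordant
        s["pct_both_het_agree"] = conc.pct_both_het_agree
        mendel = mendelian_report(filtered, pedigree)
        mendel.to_csv(out / "mendel.tsv", sep="\t", index=False)
        groups = dict(zip(pedigree["sample"], pedigree["generation"]))
        per_ind, per_group, missing = heterozygosity_summary(filtered, groups)
        per_group.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
        s["missing_fraction"] = missing
        _, mean_rate = taxon_call_rate_distribution(filtered)
        s["mean_taxon_call_rate"] = mean_rate
    else:
        s["skipped"] = "no surviving sites or no F2 families configured"
        log.info("evaluation skipped: %s", s["skipped"])

    # --- annotation -------------------------------------------------------
    s = stage("annotation")
    if filtered.n_sites and models:
        ann = annotate_variants(filtered.sites, models, genome)
        ann.to_csv(out / "annotations.tsv", sep="\t", index=False)
        summary = category_summary(ann)
        s["n_annotations"] = int(summary["count"].sum())
        dist = distance_summary(filtered.sites)
        s["snp_distance_mean"] = dist.mean
        s["snp_distance_median"] = dist.median
        manifest["artifacts"]["annotations"] = "annotations.tsv"
    else:
        s["skipped"] = "no sites or no gene models"

    # --- linkage ----------------------------------------------------------
    s = stage("linkage")
    fam = pedigree[pedigree["generation"] == "F2"]["family"].unique()
    if filtered.n_sites and len(fam):
        fam0 = fam[0]
        fam_rows = pedigree[pedigree["family"] == fam0]
        sire_id, dam_id = fam_rows.iloc[0][["sire", "dam"]]
        offspring = [x for x in fam_rows["sample"] if x in filtered.samples]
        if sire_id in filtered.samples and dam_id in filtered.samples and offspring:
            si = filtered.samples.index(sire_id)
            di = filtered.samples.index(dam_id)
            oi = [filtered.samples.index(x) for x in offspring]
            seg = np.array(
                [
                    classify_segregation(int(filtered.geno[si, j]), int(filtered.geno[di, j]))
                    for j in range(filtered.n_sites)
                ]
            )
            informative = np.flatnonzero(seg != "uninformative")[: config.linkage_max_markers]
            ids = [
                f"{filtered.sites['chrom'].iat[j]}:{filtered.sites['pos'].iat[j]}"
                for j in informative
            ]
            geno = filtered.geno[np.ix_(oi, informative)].T
            pw = pairwise_twopoint(
                geno, filtered.geno[si, informative], filtered.geno[di, informative],
                marker_ids=ids, min_offspring=min(20, len(oi)),
            )
            pw.to_csv(out / "twopoint.tsv", sep="\t", index=False)
            chrom_of = {i: i.split(":")[0] for i in ids}
            lgroups, unlinked = group_markers(pw, config.min_lod, config.max_rf, chrom_of)
            s["n_informative_markers"] = len(ids)
            s["n_groups"] = len(lgroups)
            s["n_unlinked"] = len(unlinked)
            manifest["artifacts"]["twopoint"] = "twopoint.tsv"
        else:
            s["skipped"] = "family parents not genotyped"
    else:
        s["skipped"] = "no sites or no F2 families configured"

    manifest["hashes"] = {
        name: _md5(out / rel) for name, rel in manifest["artifacts"].items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
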