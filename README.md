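# gbsforge

Genotyping-by-sequencing (GBS) design, simulation, SNP calling and
validation in one package. It covers the computational arc of a
reduced-representation genotyping study on an F2 cross:

- **digest** — in silico restriction digestion (PstI/SbfI built in),
  inclusive fragment size selection, per-class length histograms,
  enzyme comparison, and multiplex/coverage planning.
- **genome_sim** — synthetic genomes with chromosome size classes
  (large/medium/micro), optional planted restriction sites, gene models
  with valid ORFs (GFF3), and planted biallelic truth variants (VCF).
- **pedigree_sim** — divergent TT/CC founder lines, F1, and F2 families
  with Haldane recombination; phased truth genotypes carry zero
  Mendelian errors by construction.
- **library_sim** — barcode design (length 4–8, pairwise edit distance,
  base balance, no enzyme motif, prefix-free against the cut-site
  remnant), Tassel-style key files, and multiplexed FASTQ simulation
  with negative-binomial depth and i.i.d. base errors.
- **tags** — quality trimming (Q≥24, length≥50 defaults),
  barcode+remnant demultiplexing, and the pooled 64 bp "master" tag
  catalog with per-sample counts.
- **calling** — mismatch-tolerant unique-best tag alignment, SNP
  discovery at tag columns, per-read likelihood genotype calling, and
  the mnTCov / mnScov / mnMAF / misMat matrix filters; VCF output.
- **evaluate** — position/genotype concordance with a het-call
  decomposition, Mendelian-error testing (trio + duo rules),
  heterozygosity summaries, taxon call-rate distributions.
- **annotate** — functional SNP classification (intergenic, intronic,
  splicing, ncRNA, UTRs, 1 kb flanks, synonymous / non-synonymous /
  start-lost / stop-gained / stop-lost), inter-SNP distance statistics,
  SNP density by chromosome class.
- **linkage** — segregation classes, χ² distortion filtering (P<0.001),
  two-point recombination fractions (direct counts for pseudo-testcross
  pairs, EM for intercross pairs), LOD/rf linkage grouping, and the
  Kosambi mapping function.
- **pipeline** — a deterministic end-to-end orchestrator with a
  machine-readable manifest.

## CLI

```bash
gbsforge digest --fasta genome.fa --enzyme PstI --window 200:500 \
    --compare-with SbfI --out-prefix digest
gbsforge simulate-genome --seed 1 --out-dir sim/
gbsforge run --seed 1 --out-dir run/          # end-to-end synthetic study
gbsforge evaluate --query run/callset.vcf --truth run/truth_genotypes.vcf \
    --pedigree run/pedigree.tsv
gbsforge annotate --vcf run/callset.vcf --gff3 run/genes.gff3 \
    --fasta run/genome.fa --out annotations.tsv
gbsforge linkage --vcf run/callset.vcf --pedigree run/pedigree.tsv
```

`gbsforge run` writes every stage artifact (FASTA, GFF3, BED, key TSV,
FASTQ, tag catalog TSV, VCF, report TSVs) plus `manifest.json` with
stage counts and artifact hashes; reruns with the same seed are
bit-identical.

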