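"""Pedigree simulation: divergent founder lines, F1, and F2 families.

Truth genotypes are phased haplotype arrays; transmission follows a
Haldane (no-interference) crossover model, so truth data carries zero
Mendelian errors by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PEDIGREE_COLUMNS = ["sample", "sire", "dam", "sex", "generation", "line", "family"]


@dataclass
class TruthGenotypes:
    """Phased truth genotypes: haplotypes[sample, variant, 0/1] in {0 ref, 1 alt}."""

    samples: list[str]
    variants: pd.DataFrame
    haplotypes: np.ndarray  # (n_samples, n_variants, 2) int8

    def __post_init__(self) -> None:
        assert self.haplotypes.shape == (len(self.samples), len(self.variants), 2)

    @property
    def genotypes(self) -> np.ndarray:
        """Unphased dosage codes (n_samples, n_variants): 0 homRef, 1 het, 2 homAlt."""
        return self.haplotypes.sum(axis=2, dtype=np.int8)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def subset(self, samples: list[str]) -> "TruthGenotypes":
        idx = [self.sample_index(s) for s in samples]
        return TruthGenotypes(list(samples), self.variants, self.haplotypes[idx])

    def concat(self, other: "TruthGenotypes") -> "TruthGenotypes":
        return TruthGenotypes(
            self.samples + other.samples,
            self.variants,
            np.concatenate([self.haplotypes, other.haplotypes]),
        )


def simulate_founders(
    variants: pd.DataFrame,
    n_tt: int,
    n_cc: int,
    residual_het: float,
    seed: int,
) -> TruthGenotypes:
    """Draw founder genotypes for the TT and CC lines.

    At fixed-divergent sites one line is homozygous for the alt allele
    and the other for the ref allele, except that with probability
    ``residual_het`` an individual is heterozygous (residual within-line
    variation). At shared-polymorphic sites haplotypes are Bernoulli
    draws at the site's population alt frequency.
    """
    if n_tt < 1 or n_cc < 1:
        raise ValueError("need at least one founder per line")
    rng = np.random.default_rng(seed)
    n_var = len(variants)
    samples = [f"TT_{i + 1}" for i in range(n_tt)] + [f"CC_{i + 1}" for i in range(n_cc)]
    lines = ["TT"] * n_tt + ["CC"] * n_cc
    haps = np.zeros((len(samples), n_var, 2), dtype=np.int8)

    origin = variants["origin"].to_numpy()
    freq = variants["alt_freq"].to_numpy()
    for i, line in enumerate(lines):
        fixed_alt = (origin == ("tt_fixed" if line == "TT" else "cc_fixed"))
        fixed_ref = (origin == ("cc_fixed" if line == "TT" else "tt_fixed"))
        shared = origin == "shared"
        for h in range(2):
            haps[i, fixed_alt, h] = 1
            haps[i, shared, h] = rng.random(shared.sum()) < freq[shared]
        # residual heterozygosity at fixed sites: flip one haplotype
        fixed = fixed_alt | fixed_ref
        flip = fixed & (rng.random(n_var) < residual_het)
        haps[i, flip, 1] = 1 - haps[i, flip, 1]
    return TruthGenotypes(samples, variants, haps)


def _gamete(
    haps: np.ndarray,
    chrom_slices: list[tuple[slice, np.ndarray]],
    recomb_rate_per_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombined gamete from a parent's (n_variants, 2) haplotypes."""
    out = np.empty(haps.shape[0], dtype=np.int8)
    for sl, positions in chrom_slices:
        n = positions.size
        start = rng.integers(2)
        if n == 1:
            idx = np.full(1, start)
        else:
            d = np.diff(positions)
            p_switch = 0.5 * (1.0 - np.exp(-2.0 * recomb_rate_per_bp * d))
            switches = rng.random(n - 1) < p_switch
            idx = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
        out[sl] = haps[sl][np.arange(n), idx]
    return out


def _chrom_slices(variants: pd.DataFrame) -> list[tuple[slice, np.ndarray]]:
    out = []
    pos = variants["pos"].to_numpy()
    chroms = variants["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append((slice(start, i), pos[start:i]))
            start = i
    return out


def simulate_cross(
    sire: np.ndarray,
    dam: np.ndarray,
    n_offspring: int,
    variants: pd.DataFrame,
    recomb_rate_per_bp: float,
    seed: int,
) -> np.ndarray:
    """Offspring haplotypes (n_offspring, n_variants, 2) from two parents.

    Haplotype 0 is paternal, haplotype 1 maternal; each gamete is a
    Markov walk along every chromosome with inter-site crossover
    probability ``0.5 * (1 - exp(-2 * rate * distance))``.
    """
    rng = np.random.default_rng(seed)
    slices = _chrom_slices(variants)
    out = np.empty((n_offspring, len(variants), 2), dtype=np.int8)
    for k in range(n_offspring):
        out[k, :, 0] = _gamete(sire, slices, recomb_rate_per_bp, rng)
        out[k, :, 1] = _gamete(dam, slices, recomb_rate_per_bp, rng)
    return out


def build_f2_design(
    founders: TruthGenotypes,
    family_sizes: list[int],
    recomb_rate_per_bp: float = 3e-8,
    n_f1: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthGenotypes]:
    """TT×CC -> F1 -> F2 families.

    F1 individuals come from distinct TT sire × CC dam pairs (alternating
    sex); each F2 family descends from one F1 sire × F1 dam mating. The
    returned pedigree and genotypes cover founders + F1 + all F2.
    """
    if not family_sizes:
        raise ValueError("family_sizes must be non-empty")
    tt = [s for s in founders.samples if s.startswith("TT_")]
    cc = [s for s in founders.samples if s.startswith("CC_")]
    if not tt or not cc:
        raise ValueError("founders must include both TT and CC lines")
    rng = np.random.default_rng(seed)
    variants = founders.variants
    ped_rows = [
        (s, ".", ".", "M" if i % 2 == 0 else "F", "F0", s.split("_")[0], ".")
        for i, s in enumerate(founders.samples)
    ]

    # F1: cycle TT sires x CC dams
    f1_samples, f1_haps = [], []
    for i in range(n_f1):
        sire, dam = tt[i % len(tt)], cc[i % len(cc)]
        name = f"F1_{i + 1}"
        hap = simulate_cross(
            founders.haplotypes[founders.sample_index(sire)],
            founders.haplotypes[founders.sample_index(dam)],
            1, variants, recomb_rate_per_bp, int(rng.integers(2**31)),
        )[0]
        f1_samples.append(name)
        f1_haps.append(hap)
        ped_rows.append((name, sire, dam, "M" if i % 2 == 0 else "F", "F1", "TC", "."))
    f1 = TruthGenotypes(f1_samples, variants, np.stack(f1_haps))

    f1_males = [s for s, r in zip(f1_samples, ped_rows[-n_f1:]) if r[3] == "M"]
    f1_females = [s for s in f1_samples if s not in f1_males]
    if not f1_males or not f1_females:
        raise ValueError("need F1 of both sexes; increase n_f1")

    all_geno = founders.concat(f1)
    f2_samples, f2_haps = [], []
    for fam_idx, size in enumerate(family_sizes):
        sire = f1_males[fam_idx % len(f1_males)]
        dam = f1_females[fam_idx % len(f1_females)]
        fam = f"F2-{fam_idx + 1}"
        haps = simulate_cross(
            all_geno.haplotypes[all_geno.sample_index(sire)],
            all_geno.haplotypes[all_geno.sample_index(dam)],
            size, variants, recomb_rate_per_bp, int(rng.integers(2**31)),
        )
        for j in range(size):
            name = f"{fam}_{j + 1}"
            f2_samples.append(name)
            ped_rows.append((name, sire, dam, "M" if j % 2 == 0 else "F", "F2", "TCTC", fam))
        f2_haps.append(haps)
    f2 = TruthGenotypes(f2_samples, variants, np.concatenate(f2_haps))

    pedigree = pd.DataFrame(ped_rows, columns=PEDIGREE_COLUMNS)
    return pedigree, all_geno.concat(f2)


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).astype({"sample": str})


def write_truth_vcf(truth: TruthGenotypes, path: str | Path) -> None:
    """Phased truth genotypes as VCF 4.2."""
    gt = truth.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(truth.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(truth.samples) + "\n")
        for j, row in enumerate(truth.variants.itertuples(index=False)):
            calls = "\t".join(f"{gt[i, j, 0]}|{gt[i, j, 1]}" for i in range(len(truth.samples)))
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )
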