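"""Tag alignment, SNP discovery, likelihood genotype calling and filtering.

Tags are placed at the unique position (either strand) minimizing
mismatches, using a pigeonhole chunk index: with at most ``k`` mismatches
over a 64 bp tag, at least one of ``k + 1`` equal chunks matches the
reference exactly. Genotypes are called per sample from ref/alt allele
depths with a fixed per-read error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gbsforge.enzymes import revcomp
from gbsforge.genome import Genome
from gbsforge.tags import TAG_LENGTH, TagCatalog

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class CallerParams:
    error_rate: float = 0.01
    max_mismatches: int = 3
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def align_tags(
    catalog: TagCatalog,
    genome: Genome,
    max_mismatches: int = 3,
    tag_length: int = TAG_LENGTH,
) -> pd.DataFrame:
    """Align every catalog tag to the genome.

    Returns a table with one row per tag: ``tag``, ``aligned``, ``chrom``,
    ``start`` (0-based, forward strand), ``strand``, ``mismatches``. A tag
    whose best placement is not unique (a tie across positions/strands)
    is reported unaligned.
    """
    tag_list = list(catalog.tags)
    n_tags = len(tag_list)
    chunk = tag_length // (max_mismatches + 1)

    # chunk index: base-4 key -> [(tag_idx, offset, strand)]
    index: dict[int, list[tuple[int, int, str]]] = {}
    oriented: dict[tuple[int, str], np.ndarray] = {}
    for t_idx, tag in enumerate(tag_list):
        for strand, seq in (("+", tag), ("-", revcomp(tag))):
            codes = _encode(seq)
            oriented[(t_idx, strand)] = codes
            for c in range(max_mismatches + 1):
                off = c * chunk
                sub = codes[off : off + chunk]
                if np.any(sub >= 4):
                    continue
                key = 0
                for v in sub:
                    key = key * 4 + int(v)
                index.setdefault(key, []).append((t_idx, off, strand))
    if not index:
        return pd.DataFrame(
            columns=["tag", "aligned", "chrom", "start", "strand", "mismatches"]
        )
    sorted_keys = np.array(sorted(index), dtype=np.int64)

    best_mm = np.full(n_tags, tag_length + 1, dtype=np.int32)
    best_hit: list[tuple[str, int, str] | None] = [None] * n_tags
    tied = np.zeros(n_tags, dtype=bool)
    seen: set[tuple[int, str, int, str]] = set()

    for chrom, seq in genome.sequences.items():
        codes = _encode(seq)
        L = codes.size
        if L < chunk:
            continue
        n_win = L - chunk + 1
        keys = codes[:n_win].astype(np.int64)
        for j in range(1, chunk):
            keys = keys * 4 + codes[j : j + n_win]
        bad = np.convolve((codes >= 4).astype(np.int8), np.ones(chunk, dtype=np.int8), "valid") > 0
        idx = np.searchsorted(sorted_keys, keys)
        idx[idx == sorted_keys.size] = 0
        hit = (sorted_keys[idx] == keys) & ~bad
        for i in np.flatnonzero(hit):
            for t_idx, off, strand in index[int(keys[i])]:
                start = int(i) - off
                if start < 0 or start + tag_length > L:
                    continue
                memo = (t_idx, chrom, start, strand)
                if memo in seen:
                    continue
                seen.add(memo)
                mm = int(np.count_nonzero(codes[start : start + tag_length] != oriented[(t_idx, strand)]))
                if mm < best_mm[t_idx]:
                    best_mm[t_idx] = mm
                    best_hit[t_idx] = (chrom, start, strand)
                    tied[t_idx] = False
                elif mm == best_mm[t_idx]:
                    tied[t_idx] = True

    rows = []
    for t_idx, tag in enumerate(tag_list):
        ok = best_mm[t_idx] <= max_mismatches and not tied[t_idx]
        chrom, start, strand = best_hit[t_idx] if ok else (".", -1, ".")
        rows.append((tag, ok, chrom, start, strand, int(best_mm[t_idx]) if ok else -1))
    return pd.DataFrame(
        rows, columns=["tag", "aligned", "chrom", "start", "strand", "mismatches"]
    )


@dataclass
class GenotypeMatrix:
    """Taxa x biallelic sites with calls and allele depths.

    Genotype codes: -1 missing, 0 homRef, 1 het, 2 homAlt. ``depths`` has
    shape (n_samples, n_sites, 2) = (ref depth, alt depth), or None when
    the source carries no depth information.
    """

    samples: list[str]
    sites: pd.DataFrame  # chrom, pos, ref, alt
    geno: np.ndarray  # (n_samples, n_sites) int8
    depths: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def taxon_call_rate(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.ones(self.n_samples)
        return (self.geno != -1).mean(axis=1)

    def site_call_rate(self) -> np.ndarray:
        return (self.geno != -1).mean(axis=0)

    def site_maf(self) -> np.ndarray:
        """Minor allele frequency per site over called genotypes (NaN if none)."""
        called = self.geno != -1
        n_called = called.sum(axis=0)
        alt = np.where(called, self.geno, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * n_called)
        return np.where(n_called > 0, np.minimum(p, 1 - p), np.nan)

    def subset(self, sample_idx=None, site_idx=None) -> "GenotypeMatrix":
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None
            else np.asarray(sample_idx, dtype=np.intp)
        )
        site_idx = (
            np.arange(self.n_sites) if site_idx is None
            else np.asarray(site_idx, dtype=np.intp)
        )
        return GenotypeMatrix(
            [self.samples[i] for i in sample_idx],
            self.sites.iloc[site_idx].reset_index(drop=True),
            self.geno[np.ix_(sample_idx, site_idx)],
            None if self.depths is None else self.depths[np.ix_(sample_idx, site_idx)],
        )

    def sort_sites(self) -> "GenotypeMatrix":
        order = self.sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        return self.subset(site_idx=order)


def call_genotypes(
    ref_depth: np.ndarray, alt_depth: np.ndarray, params: CallerParams
) -> np.ndarray:
    """Vectorized likelihood genotype calls from allele depths.

    L(homRef) = (1-e)^dr * e^da, L(homAlt) symmetric, L(het) = 0.5^(dr+da);
    zero/insufficient depth or a likelihood tie yields missing (-1).
    """
    dr = np.asarray(ref_depth, dtype=np.float64)
    da = np.asarray(alt_depth, dtype=np.float64)
    e = params.error_rate
    ll = np.stack(
        [
            dr * np.log1p(-e) + da * np.log(e),
            (dr + da) * np.log(0.5),
            dr * np.log(e) + da * np.log1p(-e),
        ]
    )
    best = ll.max(axis=0)
    n_best = (ll == best).sum(axis=0)
    out = ll.argmax(axis=0).astype(np.int8)
    out[(dr + da < params.min_depth) | (n_best > 1)] = -1
    return out


def discover_and_call(
    catalog: TagCatalog,
    alignments: pd.DataFrame,
    genome: Genome,
    samples: list[str] | None = None,
    params: CallerParams = CallerParams(),
    tag_length: int = TAG_LENGTH,
) -> tuple[GenotypeMatrix, int]:
    """Discover biallelic SNPs at aligned tag columns and call genotypes.

    At every column where some tag differs from the reference, the two
    most frequent alleles define (ref, alt) and per-sample ref/alt depths
    accumulate from the per-sample tag counts; reads carrying rarer
    third alleles count toward neither. Columns where the reference base
    is not among the two most frequent alleles are excluded as
    multi-allelic (their count is returned). Duplicate sites may appear at the same
    (chrom, pos) when tag loci overlap; :func:`apply_filters` merges or
    drops them via the mismatch-rate rule.
    """
    samples = samples if samples is not None else catalog.samples
    s_index = {s: i for i, s in enumerate(samples)}
    n_samples = len(samples)

    groups: dict[tuple[str, int], list[int]] = {}
    aligned = alignments[alignments["aligned"]]
    for row in aligned.itertuples():
        groups.setdefault((row.chrom, row.start), []).append(row.Index)

    site_rows = []
    geno_cols = []
    depth_cols = []
    n_multiallelic = 0
    for (chrom, start), tag_rows in groups.items():
        cube = np.zeros((tag_length, 4, n_samples), dtype=np.int32)
        arange = np.arange(tag_length)
        for r in tag_rows:
            tag = alignments["tag"].iat[r]
            strand = alignments["strand"].iat[r]
            codes = _encode(tag if strand == "+" else revcomp(tag))
            for sample, count in catalog.tags[tag].items():
                si = s_index.get(sample)
                if si is None:
                    continue
                cube[arange, codes, si] += count
        ref_codes = _encode(genome[chrom][start : start + tag_length])
        totals = cube.sum(axis=2)  # (tag_length, 4)
        for off in range(tag_length):
            rc = int(ref_codes[off])
            if rc >= 4:
                continue
            observed = np.flatnonzero(totals[off] > 0)
            non_ref = [b for b in observed if b != rc]
            if not non_ref:
                continue
            # the two most frequent alleles define (ref, alt); deeper
            # third alleles than the reference mean a multi-allelic column
            ranked = sorted(observed, key=lambda b: (-totals[off, b], b))
            if len(ranked) > 2 and rc not in ranked[:2]:
                n_multiallelic += 1
                continue
            ac = next(b for b in ranked if b != rc)
            dr = cube[off, rc]
            da = cube[off, ac]
            site_rows.append((chrom, start + off, "ACGT"[rc], "ACGT"[ac]))
            geno_cols.append(call_genotypes(dr, da, params))
            depth_cols.append(np.stack([dr, da], axis=1))

    if not site_rows:
        empty = pd.DataFrame(columns=SITE_COLUMNS)
        return GenotypeMatrix(samples, empty, np.zeros((n_samples, 0), np.int8),
                              np.zeros((n_samples, 0, 2), np.int32)), n_multiallelic
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    geno = np.stack(geno_cols, axis=1).astype(np.int8)
    depths = np.stack(depth_cols, axis=1)
    return GenotypeMatrix(samples, sites, geno, depths).sort_sites(), n_multiallelic


@dataclass(frozen=True)
class FilterParams:
    """Genotype-matrix filters: taxon call rate, site call rate, MAF, and
    the duplicate-site mismatch rule."""

    mnTCov: float = 0.20
    mnScov: float = 0.90
    mnMAF: float = 0.01
    misMat: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mnTCov", "mnScov", "mnMAF", "misMat"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _merge_duplicates(matrix: GenotypeMatrix, mis_mat: float) -> tuple[GenotypeMatrix, int]:
    """Merge or drop co-located duplicate sites.

    For each pair at identical (chrom, pos): the mismatch rate over taxa
    called in both decides — above ``mis_mat`` both sites are removed,
    otherwise they merge (agreeing calls kept, conflicts set missing,
    depths summed). Pairs with different alleles are removed.
    """
    sites = matrix.sites
    dup_groups = sites.groupby(["chrom", "pos"]).indices
    keep_cols: list[int] = []
    merged_geno: dict[int, np.ndarray] = {}
    merged_depth: dict[int, np.ndarray] = {}
    n_dropped = 0
    for _, idxs in dup_groups.items():
        idxs = list(idxs)
        if len(idxs) == 1:
            keep_cols.append(idxs[0])
            continue
        g = matrix.geno[:, idxs[0]].copy()
        d = None if matrix.depths is None else matrix.depths[:, idxs[0], :].copy()
        alleles = (sites["ref"].iat[idxs[0]], sites["alt"].iat[idxs[0]])
        ok = True
        for j in idxs[1:]:
            if (sites["ref"].iat[j], sites["alt"].iat[j]) != alleles:
                ok = False
                break
            gj = matrix.geno[:, j]
            both = (g != -1) & (gj != -1)
            mismatch = float((g[both] != gj[both]).mean()) if both.any() else 0.0
            if mismatch > mis_mat:
                ok = False
                break
            conflict = both & (g != gj)
            g = np.where(g == -1, gj, g)
            g[conflict] = -1
            if d is not None:
                d = d + matrix.depths[:, j, :]
        if ok:
            keep_cols.append(idxs[0])
            merged_geno[idxs[0]] = g
            if d is not None:
                merged_depth[idxs[0]] = d
        else:
            n_dropped += len(idxs)
    keep_cols.sort()
    out = matrix.subset(site_idx=keep_cols)
    for col, j in zip(keep_cols, range(len(keep_cols))):
        if col in merged_geno:
            out.geno[:, j] = merged_geno[col]
            if out.depths is not None and col in merged_depth:
                out.depths[:, j, :] = merged_depth[col]
    return out, n_dropped


def apply_filters(
    matrix: GenotypeMatrix, params: FilterParams = FilterParams()
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Taxa filter first, then duplicate-site handling and site filters.

    Taxa with call rate below ``mnTCov`` are removed before any site
    statistic is computed; sites then survive iff (after duplicate
    merging) call rate >= ``mnScov`` and MAF >= ``mnMAF``.
    """
    log: dict[str, int] = {
        "taxa_in": matrix.n_samples,
        "sites_in": matrix.n_sites,
    }
    taxa_keep = np.flatnonzero(matrix.taxon_call_rate() >= params.mnTCov)
    log["taxa_removed"] = matrix.n_samples - taxa_keep.size
    m = matrix.subset(sample_idx=taxa_keep)

    m, n_dup_dropped = _merge_duplicates(m, params.misMat)
    log["sites_dropped_duplicate"] = n_dup_dropped

    call_ok = m.site_call_rate() >= params.mnScov
    maf = m.site_maf()
    maf_ok = np.nan_to_num(maf, nan=-1.0) >= params.mnMAF
    keep = np.flatnonzero(call_ok & maf_ok)
    log["sites_dropped_call_rate"] = int((~call_ok).sum())
    log["sites_dropped_maf"] = int((call_ok & ~maf_ok).sum())
    out = m.subset(site_idx=keep)
    log["taxa_out"] = out.n_samples
    log["sites_out"] = out.n_sites
    if out.n_sites == 0:
        import warnings

        warnings.warn("no sites survive filtering", stacklevel=2)
    return out, log


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_callset(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as VCF 4.2 with GT and AD fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for chrom in pd.unique(matrix.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        has_depth = matrix.depths is not None
        fmt = "GT:AD" if has_depth else "GT"
        for j, site in enumerate(matrix.sites.itertuples(index=False)):
            cells = []
            for i in range(matrix.n_samples):
                gt = _GT_STR[int(matrix.geno[i, j])]
                if has_depth:
                    dr, da = matrix.depths[i, j]
                    cells.append(f"{gt}:{dr},{da}")
                else:
                    cells.append(gt)
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\t"
                f"{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_callset(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (multi-allelic records are kept
    with alt = comma-joined alleles and all genotypes missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_rows, geno_cols, depth_cols = [], [], []
    any_depth = False
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else "."
        site_rows.append((v.CHROM, v.POS - 1, v.REF, alt))
        if len(v.ALT) != 1:
            geno_cols.append(np.full(len(samples), -1, dtype=np.int8))
            depth_cols.append(np.zeros((len(samples), 2), dtype=np.int32))
            continue
        col = np.full(len(samples), -1, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a = [x for x in g[:-1] if x is not None and x >= 0]
            if len(a) == 2:
                col[i] = a[0] + a[1]
        geno_cols.append(col)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            any_depth = True
            depth_cols.append(np.maximum(ad[:, :2], 0).astype(np.int32))
        else:
            depth_cols.append(np.zeros((len(samples), 2), dtype=np.int32))
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    if not site_rows:
        return GenotypeMatrix(samples, sites, np.zeros((len(samples), 0), np.int8))
    geno = np.stack(geno_cols, axis=1).astype(np.int8)
    depths = np.stack(depth_cols, axis=1) if any_depth else None
    return GenotypeMatrix(samples, sites, geno, depths)
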