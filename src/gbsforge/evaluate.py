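"""Validation statistics: concordance, Mendelian errors, heterozygosity.

All operations act on :class:`gbsforge.calling.GenotypeMatrix` objects;
query/reference pairs are matched by sample id and (chrom, pos).
Missing calls are excluded pairwise, never listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gbsforge.calling import GenotypeMatrix


def _multiallelic_mask(sites: pd.DataFrame) -> np.ndarray:
    return sites["alt"].astype(str).str.contains(",").to_numpy()


def position_concordance(
    query_sites: pd.DataFrame, reference_sites: pd.DataFrame
) -> dict[str, float]:
    """Fraction of query positions present in the reference set.

    Multi-allelic reference records (comma-joined alt) are excluded
    before the intersection is taken.
    """
    ref = reference_sites[~_multiallelic_mask(reference_sites)]
    q = set(zip(query_sites["chrom"], query_sites["pos"]))
    r = set(zip(ref["chrom"], ref["pos"]))
    shared = q & r
    return {
        "n_query": len(q),
        "n_reference": len(r),
        "n_shared": len(shared),
        "fraction": len(shared) / len(q) if q else float("nan"),
    }


@dataclass
class ConcordanceReport:
    """Genotype-level concordance with a het-call decomposition.

    The het section exposes three denominators (either-het, reference-het,
    both-het) because published summaries differ in which one they use.
    """

    n_shared_sites: int
    n_comparisons: int
    n_concordant: int
    pct_concordant: float
    n_either_het: int
    pct_either_het_validated: float
    n_ref_het: int
    pct_ref_het_validated: float
    n_both_het: int
    pct_both_het_agree: float
    pct_discordant_query_hom_ref_het: float
    n_query_het_calls: int
    n_ref_het_calls: int
    pct_query_het_calls: float
    pct_ref_het_calls: float


def genotype_concordance(
    query: GenotypeMatrix, reference: GenotypeMatrix
) -> ConcordanceReport:
    """Compare genotypes over shared samples and shared biallelic sites."""
    shared_samples = [s for s in query.samples if s in set(reference.samples)]
    if not shared_samples:
        raise ValueError("no overlapping samples between query and reference")

    q_sites = {(c, p): i for i, (c, p) in enumerate(zip(query.sites["chrom"], query.sites["pos"]))}
    ref_ok = ~_multiallelic_mask(reference.sites)
    pairs = []
    for j, (c, p) in enumerate(zip(reference.sites["chrom"], reference.sites["pos"])):
        if ref_ok[j] and (c, p) in q_sites:
            pairs.append((q_sites[(c, p)], j))
    if not pairs:
        return ConcordanceReport(0, 0, 0, float("nan"), 0, float("nan"), 0,
                                 float("nan"), 0, float("nan"), float("nan"),
                                 0, 0, float("nan"), float("nan"))
    q_idx, r_idx = map(np.array, zip(*pairs))
    qi = [query.samples.index(s) for s in shared_samples]
    ri = [reference.samples.index(s) for s in shared_samples]
    G_q = query.geno[np.ix_(qi, q_idx)]
    G_r = reference.geno[np.ix_(ri, r_idx)]

    both = (G_q != -1) & (G_r != -1)
    n_comp = int(both.sum())
    agree = both & (G_q == G_r)
    n_agree = int(agree.sum())

    q_het = both & (G_q == 1)
    r_het = both & (G_r == 1)
    either = q_het | r_het
    n_either = int(either.sum())
    n_ref_het = int(r_het.sum())
    n_both_het = int((q_het & r_het).sum())
    discordant = both & ~agree
    n_disc = int(discordant.sum())
    hom_vs_ref_het = discordant & (G_q != 1) & (G_r == 1)

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    return ConcordanceReport(
        n_shared_sites=len(pairs),
        n_comparisons=n_comp,
        n_concordant=n_agree,
        pct_concordant=pct(n_agree, n_comp),
        n_either_het=n_either,
        pct_either_het_validated=pct(int((either & agree).sum()), n_either),
        n_ref_het=n_ref_het,
        pct_ref_het_validated=pct(int((r_het & agree).sum()), n_ref_het),
        n_both_het=n_both_het,
        pct_both_het_agree=pct(int((q_het & r_het & agree).sum()), n_both_het),
        pct_discordant_query_hom_ref_het=pct(int(hom_vs_ref_het.sum()), n_disc),
        n_query_het_calls=int(q_het.sum()),
        n_ref_het_calls=n_ref_het,
        pct_query_het_calls=pct(int(q_het.sum()), n_comp),
        pct_ref_het_calls=pct(n_ref_het, n_comp),
    )


# trio rule: _TRIO_OK[p1, p2, o] == 1 when offspring o is compatible
_TRIO_OK = np.zeros((3, 3, 3), dtype=np.int8)
for _p1 in range(3):
    for _p2 in range(3):
        a1 = {0: (0,), 1: (0, 1), 2: (1,)}[_p1]
        a2 = {0: (0,), 1: (0, 1), 2: (1,)}[_p2]
        for _x in a1:
            for _y in a2:
                _TRIO_OK[_p1, _p2, _x + _y] = 1

# duo rule: offspring must share at least one allele with the parent
_DUO_OK = np.ones((3, 3), dtype=np.int8)
_DUO_OK[0, 2] = _DUO_OK[2, 0] = 0


def mendelian_error_counts(matrix: GenotypeMatrix, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Per-individual Mendelian error counts.

    Individuals with both parents genotyped use the trio compatibility
    table; with one genotyped parent, the allele-sharing duo rule. Sites
    with a missing call anywhere in the trio/duo are not evaluated.
    """
    sample_idx = {s: i for i, s in enumerate(matrix.samples)}
    rows = []
    for rec in pedigree.itertuples(index=False):
        if rec.sample not in sample_idx:
            continue
        o = matrix.geno[sample_idx[rec.sample]]
        sire = sample_idx.get(rec.sire) if rec.sire not in (".", None) else None
        dam = sample_idx.get(rec.dam) if rec.dam not in (".", None) else None
        if sire is None and dam is None:
            continue
        o_ok = o != -1
        if sire is not None and dam is not None:
            s, d = matrix.geno[sire], matrix.geno[dam]
            mask = o_ok & (s != -1) & (d != -1)
            errors = int((1 - _TRIO_OK[s[mask], d[mask], o[mask]]).sum())
        else:
            p = matrix.geno[sire if sire is not None else dam]
            mask = o_ok & (p != -1)
            errors = int((1 - _DUO_OK[p[mask], o[mask]]).sum())
        rows.append((rec.sample, rec.family, rec.generation, int(mask.sum()), errors))
    return pd.DataFrame(
        rows, columns=["sample", "family", "generation", "n_evaluated", "n_errors"]
    )


def mendelian_report(matrix: GenotypeMatrix, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Per-family mean +/- SD error counts and % of markers (plus totals)."""
    counts = mendelian_error_counts(matrix, pedigree)
    n_markers = matrix.n_sites
    groups: list[tuple[str, pd.DataFrame]] = []
    f1 = counts[counts["generation"] == "F1"]
    if len(f1):
        groups.append(("F1", f1))
    f2 = counts[counts["generation"] == "F2"]
    if len(f2):
        groups.append(("F2", f2))
        for fam, sub in f2.groupby("family"):
            groups.append((str(fam), sub))
    groups.append(("Total", counts))
    rows = []
    for name, sub in groups:
        mean = float(sub["n_errors"].mean())
        sd = float(sub["n_errors"].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(
            {
                "group": name,
                "n_individuals": len(sub),
                "mean_errors": mean,
                "sd_errors": sd,
                "pct_of_markers": 100.0 * mean / n_markers if n_markers else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def heterozygosity_summary(
    matrix: GenotypeMatrix, groups: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-individual het proportion and per-group mean/SD/CV.

    Returns (per-individual table, per-group table, overall missing
    fraction). ``groups`` maps sample -> group label; ungrouped samples
    fall into ``"all"``.
    """
    called = matrix.geno != -1
    n_called = called.sum(axis=1)
    n_het = (matrix.geno == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    per_ind = pd.DataFrame(
        {
            "sample": matrix.samples,
            "group": [(groups or {}).get(s, "all") for s in matrix.samples],
            "het_proportion": het,
            "call_rate": n_called / max(matrix.n_sites, 1),
        }
    )
    rows = []
    for name, sub in per_ind.groupby("group"):
        mean = float(sub["het_proportion"].mean())
        sd = float(sub["het_proportion"].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(
            {
                "group": name,
                "n": len(sub),
                "mean_het": mean,
                "sd_het": sd,
                "cv": sd / mean if mean else float("nan"),
            }
        )
    missing_fraction = 1.0 - called.mean() if matrix.n_sites else 0.0
    return per_ind, pd.DataFrame(rows), float(missing_fraction)


def taxon_call_rate_distribution(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, float]:
    """Per-taxon call rates and their mean."""
    rates = matrix.taxon_call_rate()
    table = pd.DataFrame({"sample": matrix.samples, "call_rate": rates})
    return table, float(rates.mean()) if len(rates) else float("nan")
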