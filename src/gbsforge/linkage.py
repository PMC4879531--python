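"""Two-point linkage analysis on an F2 design.

Markers are classed by the F1 parents' genotypes (pseudo-testcross
classes plus the fully informative both-het class). Recombination
fractions come from direct counting (testcross pairs sharing one het
parent) or from an EM maximum-likelihood fit of the 3x3 intercross
genotype table; phase is resolved by likelihood. Grouping is connected
components of the (LOD >= min, r <= max) graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

LN10 = np.log(10.0)

FEMALE_HET = "femaleHet"  # AA x AB (sire hom, dam het)
MALE_HET = "maleHet"  # AB x AA
BOTH_HET = "bothHet"  # AB x AB
UNINFORMATIVE = "uninformative"


def classify_segregation(sire_gt: int, dam_gt: int) -> str:
    """Segregation class from the two F1 parents' genotype codes (0/1/2/-1)."""
    if sire_gt == 1 and dam_gt == 1:
        return BOTH_HET
    if dam_gt == 1 and sire_gt in (0, 2):
        return FEMALE_HET
    if sire_gt == 1 and dam_gt in (0, 2):
        return MALE_HET
    return UNINFORMATIVE


@dataclass(frozen=True)
class SegTestResult:
    chi2: float
    df: int
    p: float
    keep: bool


def segregation_chi2(
    counts: list[int], seg_class: str, alpha: float = 0.001
) -> SegTestResult:
    """Pearson chi-square against the expected segregation ratio.

    Both-het markers test (homRef, het, homAlt) against 1:2:1 (df 2);
    single-parent-het markers test the two observable classes against
    1:1 (df 1). Markers with p < alpha are flagged for removal.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValueError("zero offspring")
    if seg_class == BOTH_HET:
        if counts.size != 3:
            raise ValueError("both-het test needs 3 genotype counts")
        expected = n * np.array([0.25, 0.5, 0.25])
    elif seg_class in (FEMALE_HET, MALE_HET):
        if counts.size != 2:
            raise ValueError("single-parent-het test needs 2 class counts")
        expected = n * np.array([0.5, 0.5])
    else:
        raise ValueError(f"cannot test class {seg_class!r}")
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = counts.size - 1
    p = float(chi2_dist.sf(stat, df))
    return SegTestResult(stat, df, p, p >= alpha)


@dataclass(frozen=True)
class TwoPointResult:
    rhat: float
    lod: float
    n_informative: int  # informative meioses used
    n_offspring: int


def _parent_gametes(g1: int, g2: int, phase: int):
    """Gamete options for one parent at two loci.

    Returns a list of (allele1, allele2, kind) with kind in
    {"one", "half", "nonrec", "rec"}; "nonrec"/"rec" only occur for
    parents heterozygous at both loci ('phase' 0 = coupling,
    1 = repulsion selects the haplotype configuration).
    """
    if g1 == 1 and g2 == 1:
        h1, h2 = ((0, 0), (1, 1)) if phase == 0 else ((0, 1), (1, 0))
        return [
            (h1[0], h1[1], "nonrec"),
            (h2[0], h2[1], "nonrec"),
            (h1[0], h2[1], "rec"),
            (h2[0], h1[1], "rec"),
        ]
    a_opts = [0, 1] if g1 == 1 else [g1 // 2]
    b_opts = [0, 1] if g2 == 1 else [g2 // 2]
    opts = [(a, b) for a in a_opts for b in b_opts]
    kind = "one" if len(opts) == 1 else "half"
    return [(a, b, kind) for a, b in opts]


def _combo_tables(sire: tuple[int, int], dam: tuple[int, int], phases: tuple[int, int]):
    """Class map, recombination counts and probability builder for all
    sire x dam gamete combinations."""
    gs = _parent_gametes(sire[0], sire[1], phases[0])
    gd = _parent_gametes(dam[0], dam[1], phases[1])
    classes, recs, kinds = [], [], []
    for (a1, b1, k1), (a2, b2, k2) in product(gs, gd):
        classes.append(3 * (a1 + a2) + (b1 + b2))
        recs.append((k1 == "rec") + (k2 == "rec"))
        kinds.append((k1, k2))
    classes = np.array(classes)
    recs = np.array(recs, dtype=float)

    def probs(r: float) -> np.ndarray:
        val = {"one": 1.0, "half": 0.5, "nonrec": (1 - r) / 2, "rec": r / 2}
        return np.array([val[k1] * val[k2] for k1, k2 in kinds])

    return classes, recs, probs


def _em_fit(counts9: np.ndarray, classes, recs, probs, k_dual: int):
    """EM for the recombination fraction; returns (rhat, loglik(rhat))."""
    n = counts9.sum()
    member = classes[None, :] == np.arange(9)[:, None]  # (9, 16)

    def class_probs(r):
        return member @ probs(r)

    # offspring in classes unreachable under this parental configuration
    reachable = class_probs(0.25) > 0
    used = counts9 * reachable
    n_used = used.sum()
    if n_used == 0:
        return 0.5, 0.0, 0
    r = 0.25
    ll_prev = -np.inf
    for _ in range(500):
        p = probs(r)
        cp = member @ p
        rec_p = member @ (p * recs)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_rec = np.where(cp > 0, rec_p / np.where(cp > 0, cp, 1), 0.0)
        total_rec = float((used * e_rec).sum())
        r = min(max(total_rec / (n_used * k_dual), 1e-9), 0.5)
        ll = float((used * np.log(np.where(cp > 0, cp, 1))).sum())
        if abs(ll - ll_prev) < 1e-8:
            break
        ll_prev = ll
    return r, ll, int(n_used)


def twopoint_rf(
    off1: np.ndarray,
    off2: np.ndarray,
    sire_gt: tuple[int, int],
    dam_gt: tuple[int, int],
    min_offspring: int = 20,
) -> TwoPointResult | None:
    """Two-point recombination fraction and LOD for one marker pair.

    ``off1``/``off2`` are offspring genotype codes at the two markers;
    ``sire_gt``/``dam_gt`` the F1 parents' genotypes at (marker1,
    marker2). Returns None when no parent is heterozygous at both
    markers (no observable meioses) or too few offspring are jointly
    genotyped.
    """
    mask = (off1 != -1) & (off2 != -1)
    if int(mask.sum()) < min_offspring:
        return None
    g1 = off1[mask]
    g2 = off2[mask]
    k_dual = sum(1 for p in (sire_gt, dam_gt) if p[0] == 1 and p[1] == 1)
    if k_dual == 0:
        return None
    counts9 = np.bincount(3 * g1 + g2, minlength=9).astype(float)

    phase_opts = [
        (ps, pd_)
        for ps in ([0, 1] if sire_gt == (1, 1) else [0])
        for pd_ in ([0, 1] if dam_gt == (1, 1) else [0])
    ]
    best = None
    ll_half = None
    for phases in phase_opts:
        classes, recs, probs = _combo_tables(sire_gt, dam_gt, phases)
        r, ll, n_used = _em_fit(counts9, classes, recs, probs, k_dual)
        member = classes[None, :] == np.arange(9)[:, None]
        cp_half = member @ probs(0.5)
        reachable = (member @ probs(0.25)) > 0
        used = counts9 * reachable
        lh = float((used * np.log(np.where(cp_half > 0, cp_half, 1))).sum())
        cand = (ll, -r, r, lh, n_used)
        if best is None or cand > best:
            best = cand
            ll_half = lh
    _, _, rhat, ll_half, n_used = best
    lod = max((best[0] - ll_half) / LN10, 0.0)
    return TwoPointResult(float(rhat), float(lod), n_used * k_dual, n_used)


def _em_f2_batch(counts9: np.ndarray, n_iter: int = 200):
    """Vectorized EM over many both-het x both-het pairs at once.

    ``counts9`` is (P, 9) of 3x3 genotype-class counts under coupling
    labelling; phase is resolved by also fitting the allele-relabelled
    table. Returns (rhat, lod, n) arrays. Semantics match
    :func:`twopoint_rf` for the both-het case.
    """
    classes, recs, _ = _combo_tables((1, 1), (1, 1), (0, 0))
    member = (classes[None, :] == np.arange(9)[:, None]).astype(float)  # (9,16)
    n = counts9.sum(axis=1)
    cp_half = member.sum(axis=1) / 16.0  # every combo has prob 1/16 at r=0.5
    ll_half = counts9 @ np.log(cp_half)

    def fit(c):
        r = np.full(c.shape[0], 0.25)
        for _ in range(n_iter):
            pnr = (1 - r) / 2
            pr = np.maximum(r, 1e-12) / 2
            combo = pnr[:, None] ** (2 - recs) * pr[:, None] ** recs  # (P,16)
            cp = combo @ member.T  # (P,9)
            rec_p = (combo * recs) @ member.T
            with np.errstate(invalid="ignore", divide="ignore"):
                e_rec = np.where(cp > 0, rec_p / np.where(cp > 0, cp, 1), 0.0)
            r = np.clip((c * e_rec).sum(axis=1) / (2 * np.maximum(n, 1)), 1e-9, 0.5)
        pnr = (1 - r) / 2
        pr = np.maximum(r, 1e-12) / 2
        combo = pnr[:, None] ** (2 - recs) * pr[:, None] ** recs
        cp = combo @ member.T
        ll = (c * np.log(np.where(cp > 0, cp, 1))).sum(axis=1)
        return r, ll

    r_c, ll_c = fit(counts9)
    swap = counts9[:, [2, 1, 0, 5, 4, 3, 8, 7, 6]]  # relabel marker-2 alleles
    r_r, ll_r = fit(swap)
    use_c = ll_c >= ll_r
    rhat = np.where(use_c, r_c, r_r)
    ll = np.where(use_c, ll_c, ll_r)
    lod = np.maximum((ll - ll_half) / LN10, 0.0)
    return rhat, lod, n.astype(int)


def testcross_rf(t1: np.ndarray, t2: np.ndarray) -> TwoPointResult:
    """Direct-count estimate from transmitted-allele vectors (0/1) of one
    shared heterozygous parent; phase is taken as the majority class."""
    n = t1.size
    x = int((t1 != t2).sum())
    n_rec = min(x, n - x)
    r = n_rec / n
    with np.errstate(divide="ignore"):
        lod = (n - n_rec) * np.log10(2 * (1 - r)) + (
            n_rec * np.log10(2 * r) if n_rec else 0.0
        )
    return TwoPointResult(float(r), max(float(lod), 0.0), n, n)


def transmitted_alleles(
    off: np.ndarray, het_parent_gt: int, other_parent_gt: int
) -> np.ndarray:
    """Alleles transmitted by the het parent at a testcross marker.

    The other parent is homozygous, so its contribution is fixed;
    impossible offspring genotypes yield -1.
    """
    other = other_parent_gt // 2
    t = off - other
    t = np.where((off == -1) | (t < 0) | (t > 1), -1, t)
    return t.astype(np.int8)


def pairwise_twopoint(
    geno: np.ndarray,
    sire: np.ndarray,
    dam: np.ndarray,
    marker_ids: list[str] | None = None,
    min_offspring: int = 20,
) -> pd.DataFrame:
    """All-pairs two-point analysis.

    ``geno`` is (n_markers, n_offspring) with codes {-1,0,1,2}; ``sire``
    and ``dam`` hold the F1 parents' genotypes per marker. Same-parent
    testcross pairs are counted directly; pairs involving a both-het
    marker use the EM fit; incompatible pairs are skipped.
    """
    n_markers = geno.shape[0]
    ids = marker_ids or [f"m{i}" for i in range(n_markers)]
    seg = [classify_segregation(int(s), int(d)) for s, d in zip(sire, dam)]
    rows = []

    # both-het x both-het pairs: one vectorized EM over the whole batch
    bh = [i for i in range(n_markers) if seg[i] == BOTH_HET]
    if len(bh) >= 2:
        G = geno[bh]  # (M, n_off)
        A = np.stack([(G == k).astype(float) for k in range(3)])  # (3, M, n)
        C = np.einsum("akn,bln->klab", A, A).reshape(len(bh), len(bh), 9)
        iu, ju = np.triu_indices(len(bh), k=1)
        counts9 = C[iu, ju]
        enough = counts9.sum(axis=1) >= min_offspring
        rhat, lod, n_used = _em_f2_batch(counts9[enough])
        for (i_loc, j_loc), r, l, nn in zip(
            zip(iu[enough], ju[enough]), rhat, lod, n_used
        ):
            rows.append((ids[bh[i_loc]], ids[bh[j_loc]], float(r), float(l), 2 * int(nn)))

    for i in range(n_markers):
        if seg[i] == UNINFORMATIVE:
            continue
        for j in range(i + 1, n_markers):
            if seg[j] == UNINFORMATIVE:
                continue
            if seg[i] == BOTH_HET and seg[j] == BOTH_HET:
                continue  # handled by the batch above
            res = None
            pair = {seg[i], seg[j]}
            if pair in ({FEMALE_HET}, {MALE_HET}):
                het_is_dam = seg[i] == FEMALE_HET
                p_i = (dam[i], sire[i]) if het_is_dam else (sire[i], dam[i])
                p_j = (dam[j], sire[j]) if het_is_dam else (sire[j], dam[j])
                t1 = transmitted_alleles(geno[i], p_i[0], p_i[1])
                t2 = transmitted_alleles(geno[j], p_j[0], p_j[1])
                ok = (t1 != -1) & (t2 != -1)
                if int(ok.sum()) >= min_offspring:
                    res = testcross_rf(t1[ok], t2[ok])
            elif pair == {FEMALE_HET, MALE_HET}:
                res = None  # no shared informative parent
            else:
                res = twopoint_rf(
                    geno[i], geno[j],
                    (int(sire[i]), int(sire[j])),
                    (int(dam[i]), int(dam[j])),
                    min_offspring,
                )
            if res is not None:
                rows.append((ids[i], ids[j], res.rhat, res.lod, res.n_informative))
    return pd.DataFrame(rows, columns=["marker1", "marker2", "r", "lod", "n"])


@dataclass
class LinkageGroup:
    group_id: int
    members: list[str]
    fragmented: bool = False


def group_markers(
    results: pd.DataFrame,
    min_lod: float = 8.0,
    max_rf: float = 0.35,
    marker_chroms: dict[str, str] | None = None,
) -> tuple[list[LinkageGroup], list[str]]:
    """Connected components of the (LOD >= min_lod, r <= max_rf) graph.

    Returns (groups, unlinked markers). A group is flagged fragmented
    when its members map to more than one reference chromosome
    (``marker_chroms``: marker -> chromosome, optional).
    """
    import networkx as nx

    g = nx.Graph()
    markers = pd.unique(results[["marker1", "marker2"]].to_numpy().ravel())
    g.add_nodes_from(markers)
    linked = results[(results["lod"] >= min_lod) & (results["r"] <= max_rf)]
    g.add_edges_from(zip(linked["marker1"], linked["marker2"]))
    groups: list[LinkageGroup] = []
    unlinked: list[str] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)[0])):
        if len(comp) == 1:
            unlinked.extend(comp)
            continue
        members = sorted(comp)
        fragmented = False
        if marker_chroms:
            chroms = {marker_chroms.get(m) for m in members} - {None}
            fragmented = len(chroms) > 1
        groups.append(LinkageGroup(len(groups) + 1, members, fragmented))
    return groups, sorted(unlinked)


def kosambi(r: float) -> float:
    """Kosambi map distance d = 25 * ln((1 + 2r) / (1 - 2r)) cM."""
    if not 0 <= r < 0.5:
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d: float) -> float:
    """Recombination fraction for a Kosambi distance in cM."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 0.5 * np.tanh(d / 50.0)
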