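"""Barcode design, key files, and multiplexed GBS read simulation.

Simulated reads are single-end: one read per sequenced fragment end,
``barcode + remnant + genomic continuation`` padded to the read length,
which carries the same tag-level information as the paired-end protocol.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from gbsforge.enzymes import Enzyme, revcomp
from gbsforge.genome import Genome
from gbsforge.pedigree_sim import TruthGenotypes

KEY_COLUMNS = ["Flowcell", "Lane", "Barcode", "Sample"]


class BarcodeDesignError(ValueError):
    """Raised when a barcode set satisfying all constraints cannot be built."""


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def balance_deviation(barcodes: list[str]) -> float:
    """Per-position deviation of base counts from a uniform composition.

    For each position, over the barcodes long enough to reach it, sums
    ``|count(base) - n/4|``; positions and barcodes are weighted equally.
    A set using each base equally often at every position scores 0.
    """
    if not barcodes:
        return 0.0
    total = 0.0
    for p in range(max(len(b) for b in barcodes)):
        col = [b[p] for b in barcodes if len(b) > p]
        n = len(col)
        total += sum(abs(col.count(base) - n / 4) for base in "ACGT")
    return total


@dataclass(frozen=True)
class BarcodeSet:
    barcodes: tuple[str, ...]
    balance: float
    min_pairwise_distance: int

    def __len__(self) -> int:
        return len(self.barcodes)


def _violates(candidate: str, chosen: list[str], enzyme: Enzyme, min_dist: int) -> bool:
    if enzyme.recognition in candidate:
        return True
    cr = candidate + enzyme.remnant
    for b in chosen:
        if edit_distance(candidate, b) < min_dist:
            return True
        br = b + enzyme.remnant
        if cr.startswith(br) or br.startswith(cr):
            return True
    return False


def design_barcodes(
    n: int,
    enzyme: Enzyme,
    length_range: tuple[int, int] = (4, 8),
    min_edit_distance: int = 3,
    seed: int = 0,
    n_candidates: int = 64,
) -> BarcodeSet:
    """Greedy barcode design under distance / prefix / motif constraints.

    Lengths cycle through ``length_range`` so the set mixes barcode
    lengths; at each step the candidate (among ``n_candidates`` random
    valid proposals) minimizing the running balance deviation is kept.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not 4 <= lo <= hi <= 8:
        raise ValueError("barcode lengths must lie in 4..8")
    rng = np.random.default_rng(seed)
    lengths = [lo + (i % (hi - lo + 1)) for i in range(n)]

    def propose(length: int) -> list[str]:
        """Valid candidates of one length: random draws, then an
        exhaustive shuffled scan if the length class is nearly saturated."""
        valid = []
        for _ in range(8 * n_candidates):
            cand = "".join("ACGT"[i] for i in rng.integers(4, size=length))
            if cand not in chosen and not _violates(cand, chosen, enzyme, min_edit_distance):
                valid.append(cand)
                if len(valid) >= n_candidates:
                    return valid
        if not valid and length <= 6:
            space = ["".join(p) for p in product("ACGT", repeat=length)]
            rng.shuffle(space)
            for cand in space:
                if cand not in chosen and not _violates(cand, chosen, enzyme, min_edit_distance):
                    valid.append(cand)
                    if len(valid) >= n_candidates:
                        break
        return valid

    chosen: list[str] = []
    for length in lengths:
        candidates: list[str] = []
        # spill over to other lengths (longer first) when one class saturates
        for trial_len in [length] + sorted(range(lo, hi + 1), key=lambda x: -x):
            candidates = propose(trial_len)
            if candidates:
                break
        if not candidates:
            raise BarcodeDesignError(
                f"could not find barcode #{len(chosen) + 1}: edit-distance >= "
                f"{min_edit_distance} plus prefix/motif constraints are infeasible "
                f"for {n} barcodes in lengths {lo}..{hi}"
            )
        chosen.append(min(candidates, key=lambda c: balance_deviation(chosen + [c])))
    min_d = min(
        (edit_distance(a, b) for i, a in enumerate(chosen) for b in chosen[i + 1 :]),
        default=0,
    )
    return BarcodeSet(tuple(chosen), balance_deviation(chosen), min_d)


def make_key_file(
    samples: list[str],
    barcode_set: BarcodeSet,
    plex: int,
    flowcell: str = "FC001",
    lanes: list[int] | None = None,
) -> pd.DataFrame:
    """Assign samples round-robin to lanes, ≤ plex per lane, unique barcodes per lane."""
    if plex > len(barcode_set):
        raise ValueError("plex exceeds the number of available barcodes")
    n_lanes = -(-len(samples) // plex)
    lanes = lanes or list(range(1, n_lanes + 1))
    if len(lanes) < n_lanes:
        raise ValueError(
            f"{len(samples)} samples need {n_lanes} lanes at plex {plex}, got {len(lanes)}"
        )
    per_lane_count = {lane: 0 for lane in lanes}
    rows = []
    for i, sample in enumerate(samples):
        lane = lanes[i % len(lanes)]
        slot = per_lane_count[lane]
        if slot >= plex:
            raise ValueError("lane capacity exceeded")
        rows.append((flowcell, lane, barcode_set.barcodes[slot], sample))
        per_lane_count[lane] += 1
    return pd.DataFrame(rows, columns=KEY_COLUMNS)


def write_key_file(key: pd.DataFrame, path: str | Path) -> None:
    key.to_csv(path, sep="\t", index=False)


def read_key_file(path: str | Path) -> pd.DataFrame:
    key = pd.read_csv(path, sep="\t", dtype={"Flowcell": str, "Barcode": str, "Sample": str})
    key["Lane"] = key["Lane"].astype(int)
    return key


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 100
    mean_depth: float = 8.0
    dispersion: float = 5.0  # negative-binomial size parameter
    error_rate: float = 0.002
    qual_hi: int = 35
    qual_lo: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error rate must lie in [0, 1)")


def tag_spans(
    fragments: pd.DataFrame, genome: Genome, enzyme: Enzyme, span: int
) -> list[tuple[str, int, int, str]]:
    """Genomic spans read from fragment ends: (chrom, start, end, strand).

    Only ends created by an actual cut are sequenced (chromosome-end
    termini have no ligatable overhang). A forward-end read covers
    ``[cut - len(remnant), ...)``; a reverse-end read is the reverse
    complement of ``(..., cut + len(recognition) - cut_offset]`` — both
    start with the remnant and are contiguous in the reference.
    """
    r = len(enzyme.remnant)
    tail = len(enzyme.recognition) - enzyme.cut_offset
    spans = []
    for row in fragments.itertuples(index=False):
        chrom_len = genome.length(row.chrom)
        if row.start > 0:
            a = row.start - r
            spans.append((row.chrom, a, min(a + span, chrom_len), "+"))
        if row.end < chrom_len:
            b = row.end + tail
            spans.append((row.chrom, max(b - span, 0), b, "-"))
    return spans


def simulate_reads(
    genome: Genome,
    truth: TruthGenotypes,
    fragments: pd.DataFrame,
    key: pd.DataFrame,
    enzyme: Enzyme,
    params: ReadSimParams,
    seed: int,
    out_dir: str | Path,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Simulate one FASTQ per (flowcell, lane) for the samples in ``key``.

    Per (sample, fragment end) the read count is negative-binomial around
    ``params.mean_depth``; each read samples one of the individual's two
    haplotypes, substitutes its alt alleles into the reference span, and
    receives i.i.d. base errors at ``params.error_rate`` (errored bases
    get ``qual_lo``, everything else ``qual_hi``).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    max_bc = max(len(b) for b in key["Barcode"])
    if params.read_length < 64 + max_bc:
        raise ValueError(
            f"read length {params.read_length} cannot hold a {max_bc} bp barcode "
            "plus a 64 bp tag"
        )
    genomic_len = {bl: params.read_length - bl for bl in set(len(b) for b in key["Barcode"])}
    spans = tag_spans(fragments, genome, enzyme, max(genomic_len.values()))

    var_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, str]] = {}
    pos_all = truth.variants["pos"].to_numpy()
    for chrom in truth.variants["chrom"].unique():
        mask = (truth.variants["chrom"] == chrom).to_numpy()
        var_by_chrom[chrom] = (np.flatnonzero(mask), pos_all[mask])

    p_nb = params.dispersion / (params.dispersion + params.mean_depth)
    qual_hi = chr(params.qual_hi + 33)
    qual_lo = chr(params.qual_lo + 33)

    handles: dict[tuple[str, int], object] = {}
    paths: dict[str, Path] = {}
    for fc, lane in key[["Flowcell", "Lane"]].drop_duplicates().itertuples(index=False):
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        path = out_dir / f"{fc}_{lane}{suffix}"
        handles[(fc, lane)] = gzip.open(path, "wt") if gzip_output else open(path, "w")
        paths[f"{fc}_{lane}"] = path

    n_reads = 0
    try:
        for rec in key.itertuples(index=False):
            fh = handles[(rec.Flowcell, rec.Lane)]
            barcode = rec.Barcode
            glen = genomic_len[len(barcode)]
            hi_tail = qual_hi * glen
            si = truth.sample_index(rec.Sample)
            counts = rng.negative_binomial(params.dispersion, p_nb, size=len(spans))
            for span_idx in np.flatnonzero(counts):
                chrom, a, b, strand = spans[span_idx]
                vidx, vpos = var_by_chrom.get(chrom, (np.empty(0, int), np.empty(0, int)))
                lo = np.searchsorted(vpos, a)
                hi = np.searchsorted(vpos, b)
                base_seq = genome[chrom][a:b]
                hap_seqs: dict[int, str] = {}
                for h in range(2):
                    carried = [
                        (int(vpos[k] - a), truth.variants["alt"].iat[int(vidx[k])])
                        for k in range(lo, hi)
                        if truth.haplotypes[si, vidx[k], h] == 1
                    ]
                    if carried:
                        s = list(base_seq)
                        for off, alt in carried:
                            s[off] = alt
                        hap_seqs[h] = "".join(s)
                    else:
                        hap_seqs[h] = base_seq
                c = int(counts[span_idx])
                hap_choice = rng.integers(2, size=c)
                err = rng.random((c, glen)) < params.error_rate
                for j in range(c):
                    seq = hap_seqs[int(hap_choice[j])]
                    if strand == "-":
                        seq = revcomp(seq)
                    seq = seq[:glen]
                    if len(seq) < glen:
                        seq = seq + "A" * (glen - len(seq))
                    errs = np.flatnonzero(err[j])
                    if errs.size:
                        s = list(seq)
                        q = list(hi_tail)
                        for e in errs:
                            s[e] = "ACGT"[(("ACGT".index(s[e]) if s[e] in "ACGT" else 0) + 1 + int(rng.integers(3))) % 4]
                            q[e] = qual_lo
                        seq, qual = "".join(s), "".join(q)
                    else:
                        qual = hi_tail
                    n_reads += 1
                    fh.write(
                        f"@r{n_reads}_{rec.Sample}_s{span_idx}\n{barcode}{seq}\n+\n"
                        f"{qual_hi * len(barcode)}{qual}\n"
                    )
    finally:
        for fh in handles.values():
            fh.close()
    return paths
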