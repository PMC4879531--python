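"""In silico restriction digestion, size selection and multiplex planning.

Coordinates are 0-based half-open throughout. A cut is placed at
``motif_start + enzyme.cut_offset`` for every exact forward-strand
occurrence of the recognition motif; palindromy makes a reverse scan
redundant. Fragments tile each sequence exactly, terminal fragments
included, so per sequence ``n_fragments == n_sites + 1``.

Fragment sets are plain :class:`pandas.DataFrame` objects with columns
``chrom``, ``start``, ``end``, ``length``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gbsforge.enzymes import Enzyme
from gbsforge.genome import CHROM_CLASSES, Genome

FRAGMENT_COLUMNS = ["chrom", "start", "end", "length"]


def find_sites(seq: str, motif: str) -> list[int]:
    """Start positions of every exact occurrence of ``motif`` in ``seq``.

    Overlapping occurrences are reported. Matching is exact, so motif
    occurrences interrupted by N (or any non-ACGT base) never match.
    """
    sites = []
    i = seq.find(motif)
    while i != -1:
        sites.append(i)
        i = seq.find(motif, i + 1)
    return sites


def digest(genome: Genome | Mapping[str, str], enzyme: Enzyme) -> pd.DataFrame:
    """Digest every sequence of ``genome`` with ``enzyme``.

    Returns the fragment table; fragments of one sequence partition it
    (no gaps, no overlaps), and the terminal fragments are included.

    Raises
    ------
    UnsupportedEnzymeError
        If the enzyme recognition site is not palindromic.
    ValueError
        If the genome holds no sequences.
    """
    enzyme.require_palindromic()
    seqs = genome.sequences if isinstance(genome, Genome) else dict(genome)
    if not seqs:
        raise ValueError("empty genome")

    chroms: list[str] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    for name, seq in seqs.items():
        seq = seq.upper()
        cuts = [s + enzyme.cut_offset for s in find_sites(seq, enzyme.recognition)]
        bounds = np.array([0] + cuts + [len(seq)], dtype=np.int64)
        chroms.extend([name] * (len(bounds) - 1))
        starts.append(bounds[:-1])
        ends.append(bounds[1:])
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    return pd.DataFrame(
        {"chrom": chroms, "start": start, "end": end, "length": end - start}
    )


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length selection window in bp."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.hi:
            raise ValueError(f"invalid size window [{self.lo}, {self.hi}]")

    @classmethod
    def parse(cls, text: str) -> "SizeWindow":
        """Parse ``"200:500"`` (or ``"200-500"``)."""
        lo, hi = text.replace("-", ":").split(":")
        return cls(int(lo), int(hi))


def size_select(fragments: pd.DataFrame, window: SizeWindow) -> pd.DataFrame:
    """Fragments with ``window.lo <= length <= window.hi`` (both inclusive).

    Coordinates and row order are preserved.
    """
    mask = (fragments["length"] >= window.lo) & (fragments["length"] <= window.hi)
    return fragments[mask].reset_index(drop=True)


def fragment_histogram(
    fragments: pd.DataFrame,
    bin_edges: Sequence[int],
    chrom_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Fragment-length histogram split by chromosome size class.

    Returns a table with one row per bin ``[edge_i, edge_{i+1})``, one
    column per class present in ``chrom_classes`` plus a ``total`` column.
    """
    edges = np.asarray(bin_edges)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    for chrom, cls in chrom_classes.items():
        if cls not in CHROM_CLASSES:
            raise ValueError(f"unknown chromosome class {cls!r} for {chrom}")
    for chrom in fragments["chrom"].unique():
        if chrom not in chrom_classes:
            raise ValueError(f"chromosome {chrom!r} has no class label")

    labels = [f"[{edges[i]},{edges[i+1]})" for i in range(len(edges) - 1)]
    out = pd.DataFrame(0, index=labels, columns=sorted(set(chrom_classes.values())))
    for cls in out.columns:
        chroms = [c for c, k in chrom_classes.items() if k == cls]
        lengths = fragments.loc[fragments["chrom"].isin(chroms), "length"]
        counts, _ = np.histogram(lengths, bins=edges)
        out[cls] = counts
    out["total"] = out.sum(axis=1)
    return out


def compare_enzymes(
    genome: Genome | Mapping[str, str],
    enzymes: Iterable[Enzyme],
    window: SizeWindow,
) -> pd.DataFrame:
    """Digest with each enzyme and compare in-window yields.

    ``ratio_vs_first`` is the first enzyme's in-window count divided by
    this enzyme's (so the first row is 1.0 and rarer cutters score >1).
    """
    enzymes = list(enzymes)
    if len(enzymes) < 2:
        raise ValueError("need at least two enzymes to compare")
    rows = []
    for enz in enzymes:
        frags = digest(genome, enz)
        selected = size_select(frags, window)
        rows.append(
            {
                "enzyme": enz.name,
                "recognition": enz.recognition,
                "total_fragments": len(frags),
                "in_window": len(selected),
            }
        )
    table = pd.DataFrame(rows)
    first = table.loc[0, "in_window"]
    with np.errstate(divide="ignore"):
        table["ratio_vs_first"] = np.where(
            table["in_window"] > 0, first / table["in_window"], np.inf
        )
    return table


@dataclass(frozen=True)
class MultiplexPlan:
    """Expected per-sample coverage for a multiplexed GBS lane."""

    n_fragments_in_window: int
    tag_sites: int
    plex: int
    reads_per_lane: int
    expected_depth: float


def plan_multiplex(
    n_fragments_in_window: int,
    ends_per_fragment: int,
    plex: int,
    reads_per_lane: int,
) -> MultiplexPlan:
    """Expected depth = reads_per_lane / (plex * tag_sites).

    ``tag_sites`` counts sequenced fragment ends:
    ``ends_per_fragment * n_fragments_in_window``.
    """
    if ends_per_fragment not in (1, 2):
        raise ValueError("ends_per_fragment must be 1 or 2")
    if min(n_fragments_in_window, plex, reads_per_lane) <= 0:
        raise ValueError("all multiplex inputs must be positive")
    tag_sites = ends_per_fragment * n_fragments_in_window
    depth = reads_per_lane / (plex * tag_sites)
    return MultiplexPlan(n_fragments_in_window, tag_sites, plex, reads_per_lane, depth)


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    """Write fragments as BED3 + length TSV (no header)."""
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=FRAGMENT_COLUMNS)
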