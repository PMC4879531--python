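"""Read QC, barcode demultiplexing, and the pooled 64 bp tag catalog.

The catalog ("master" list) merges identical 64-mers across all samples
with per-sample read counts. Reads that end up shorter than 64 bases
after barcode removal and read-through truncation are discarded (not
padded) and tallied.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from gbsforge.enzymes import Enzyme

TAG_LENGTH = 64
PHRED_OFFSET = 33


@dataclass(frozen=True)
class QCParams:
    min_quality: int = 24
    min_length: int = 50

    def __post_init__(self) -> None:
        if self.min_quality < 0 or self.min_length < 1:
            raise ValueError("invalid QC parameters")


def parse_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from FASTQ, plain or gzip.

    Raises ValueError (with the record index) on malformed input.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ near record {i}: {exc}") from exc
            i += 1
            yield rec


def quality_filter(
    reads: Iterable[tuple[str, str, str]], qc: QCParams = QCParams()
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Trim trailing low-quality bases, then drop too-short reads.

    3' bases with quality below ``qc.min_quality`` are removed (from the
    read end inward); reads shorter than ``qc.min_length`` after
    trimming are discarded. Returns (retained, tally); the tally keys are
    ``total``, ``retained``, ``trimmed``, ``discarded_short``.
    """
    cutoff = qc.min_quality + PHRED_OFFSET
    retained = []
    tally = {"total": 0, "retained": 0, "trimmed": 0, "discarded_short": 0}
    for title, seq, qual in reads:
        tally["total"] += 1
        end = len(qual)
        while end > 0 and ord(qual[end - 1]) < cutoff:
            end -= 1
        if end < len(qual):
            tally["trimmed"] += 1
            seq, qual = seq[:end], qual[:end]
        if len(seq) < qc.min_length:
            tally["discarded_short"] += 1
            continue
        tally["retained"] += 1
        retained.append((title, seq, qual))
    return retained, tally


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    key: pd.DataFrame,
    lane: int,
    enzyme: Enzyme,
    flowcell: str | None = None,
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Assign reads to samples by exact barcode + remnant prefix match.

    The barcode is removed; the remnant is retained at the read start.
    Returns ({sample: [sequence, ...]}, tally).
    """
    sub = key[key["Lane"] == lane]
    if flowcell is not None:
        sub = sub[sub["Flowcell"] == flowcell]
    if sub.empty:
        raise ValueError(f"key file has no records for lane {lane}")
    if sub["Barcode"].duplicated().any():
        raise ValueError(f"duplicate barcode within lane {lane}")
    bc2sample = dict(zip(sub["Barcode"], sub["Sample"]))
    lengths = sorted({len(b) for b in bc2sample}, reverse=True)
    remnant = enzyme.remnant
    rl = len(remnant)

    out: dict[str, list[str]] = {s: [] for s in bc2sample.values()}
    tally = {"total": 0, "assigned": 0, "unassigned": 0}
    for _, seq, _ in reads:
        tally["total"] += 1
        for bl in lengths:
            sample = bc2sample.get(seq[:bl])
            if sample is not None and seq[bl : bl + rl] == remnant:
                out[sample].append(seq[bl:])
                tally["assigned"] += 1
                break
        else:
            tally["unassigned"] += 1
    return out, tally


@dataclass
class TagCatalog:
    """Unique 64 bp tags with per-sample read counts."""

    tags: dict[str, dict[str, int]]
    totals: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tags)

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for counts in self.tags.values():
            for s in counts:
                seen.setdefault(s)
        return list(seen)

    def total_count(self, tag: str) -> int:
        return sum(self.tags[tag].values())

    def to_frame(self) -> pd.DataFrame:
        samples = self.samples
        rows = [
            [tag, sum(counts.values())] + [counts.get(s, 0) for s in samples]
            for tag, counts in self.tags.items()
        ]
        return pd.DataFrame(rows, columns=["tag", "total"] + samples)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TagCatalog":
        df = pd.read_csv(path, sep="\t")
        samples = [c for c in df.columns if c not in ("tag", "total")]
        tags = {}
        for row in df.itertuples(index=False):
            counts = {s: int(v) for s, v in zip(samples, row[2:]) if v > 0}
            tags[row.tag] = counts
        return cls(tags)


def build_master_catalog(
    per_sample_reads: dict[str, list[str]],
    enzyme: Enzyme,
    tag_length: int = TAG_LENGTH,
) -> TagCatalog:
    """Pool per-sample remnant-anchored reads into the master tag catalog.

    Each read is truncated at the first internal occurrence of the full
    recognition site (read-through into the next fragment; the search
    starts at offset 1 because a remnant-anchored read may itself begin
    with the reconstituted site), then cut to ``tag_length`` bases.
    Shorter reads are discarded and tallied.
    """
    motif = enzyme.recognition
    tags: dict[str, dict[str, int]] = {}
    totals = {"reads_in": 0, "retained": 0, "discarded_short": 0}
    for sample, reads in per_sample_reads.items():
        for read in reads:
            totals["reads_in"] += 1
            cut = read.find(motif, 1)
            if cut != -1:
                read = read[:cut]
            if len(read) < tag_length:
                totals["discarded_short"] += 1
                continue
            tag = read[:tag_length]
            totals["retained"] += 1
            counts = tags.setdefault(tag, {})
            counts[sample] = counts.get(sample, 0) + 1
    return TagCatalog(tags, totals)
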