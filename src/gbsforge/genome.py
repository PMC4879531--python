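"""Genome container and FASTA I/O.

Sequences are held in memory as plain uppercase strings; chromosome size
classes (large / medium / micro) are carried alongside for the density
reports.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

CHROM_CLASSES = ("large", "medium", "micro")


@dataclass
class Genome:
    """Named DNA sequences plus optional chromosome class labels."""

    sequences: dict[str, str]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cls in self.classes.items():
            if cls not in CHROM_CLASSES:
                raise ValueError(f"unknown chromosome class {cls!r} for {name}")

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def gc_fraction(self, name: str) -> float:
        seq = self.sequences[name]
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (seq.count("G") + seq.count("C")) / acgt

    @classmethod
    def from_fasta(cls, path: str | Path, classes: dict[str, str] | None = None) -> "Genome":
        """Load a FASTA file (plain or gzip)."""
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        seqs: dict[str, str] = {}
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                seqs[rec.id] = str(rec.seq).upper()
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs, classes or {})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
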