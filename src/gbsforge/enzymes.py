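"""Restriction enzyme definitions used for in silico digestion.

Only palindromic recognition sites are supported: a single forward-strand
scan then finds every cut site, with no strand bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class UnsupportedEnzymeError(ValueError):
    """Raised for enzymes whose recognition site cannot be handled."""


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme.

    Parameters
    ----------
    name :
        Display name, e.g. ``"PstI"``.
    recognition :
        Uppercase ACGT recognition motif (must be palindromic).
    cut_offset :
        Bases from the motif start to the top-strand cut point.
    remnant :
        Sequence expected at the start of a barcoded read, immediately
        after the sample barcode. Defaults to ``recognition[:cut_offset]``,
        i.e. the reference bases left of the top-strand cut.
    """

    name: str
    recognition: str
    cut_offset: int
    remnant: str = field(default="")

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise UnsupportedEnzymeError(
                f"{self.name}: recognition must be non-empty uppercase ACGT, "
                f"got {self.recognition!r}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise UnsupportedEnzymeError(
                f"{self.name}: cut_offset {self.cut_offset} outside motif"
            )
        if not self.remnant:
            object.__setattr__(self, "remnant", self.recognition[: self.cut_offset])

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition

    def require_palindromic(self) -> None:
        if not self.is_palindromic:
            raise UnsupportedEnzymeError(
                f"{self.name}: non-palindromic site {self.recognition} is not supported"
            )


#: Built-in enzymes. PstI cuts CTGCA^G, SbfI cuts CCTGCA^GG (top strand).
ENZYMES: dict[str, Enzyme] = {
    "PstI": Enzyme("PstI", "CTGCAG", 5),
    "SbfI": Enzyme("SbfI", "CCTGCAGG", 6),
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),
    "HindIII": Enzyme("HindIII", "AAGCTT", 1),
}


def get_enzyme(name: str) -> Enzyme:
    """Look up a built-in enzyme by (case-insensitive) name."""
    for key, enz in ENZYMES.items():
        if key.lower() == name.lower():
            return enz
    raise KeyError(f"unknown enzyme {name!r}; known: {sorted(ENZYMES)}")
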