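"""Detection and orientation classification of poly(dA:dT) tracts.

A poly(dA:dT) tract is a maximal homopolymeric run of A (or of T) on the
reference/sense strand. A run of A on one strand is a run of T on the other,
so a single scan of the given strand with both base identities captures both
orientations of the double-stranded tract. Orientation relative to a
nucleosome core is expressed the way the field does: "core 5' of polyA" or
"core 3' of polyA", where polyA refers to the A-bearing strand read 5'->3'.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

__all__ = [
    "Tract",
    "Orientation",
    "OverlapError",
    "scan_tracts",
    "classify_tract_orientation",
    "tracts_in_window",
]

_VALID_BASES = frozenset("ACGTN")


class Orientation(enum.Enum):
    """Position of the nucleosome core relative to the polyA strand's 5'->3' axis."""

    CORE_5PRIME_OF_POLYA = "core_5prime_of_polyA"
    CORE_3PRIME_OF_POLYA = "core_3prime_of_polyA"


class OverlapError(ValueError):
    """Raised when a tract overlaps the core, so orientation is undefined."""


@dataclass(frozen=True, order=True)
class Tract:
    """A maximal A or T homopolymer run, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    base: str  # base of the run on the reference/sense strand, "A" or "T"

    def __post_init__(self) -> None:
        if self.base not in ("A", "T"):
            raise ValueError(f"tract base must be A or T, got {self.base!r}")
        if self.end <= self.start:
            raise ValueError("tract end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_tracts(sequence: str, min_len: int = 6, chrom: str = "") -> list[Tract]:
    """Find all maximal runs of A and of T with length >= ``min_len``.

    The scan is a single linear pass; N (or any non-matching base) terminates
    a run, so N never extends or bridges a tract. Tracts are returned sorted
    by start coordinate.

    Raises
    ------
    ValueError
        If the sequence contains characters outside {A, C, G, T, N} or
        ``min_len`` < 1.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = sequence.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")

    out: list[Tract] = []
    n = len(seq)
    i = 0
    while i < n:
        b = seq[i]
        if b in ("A", "T"):
            j = i + 1
            while j < n and seq[j] == b:
                j += 1
            if j - i >= min_len:
                out.append(Tract(chrom=chrom, start=i, end=j, base=b))
            i = j
        else:
            i += 1
    return out


def classify_tract_orientation(
    tract: Tract, core: Tuple[int, int]
) -> Orientation:
    """Classify tract orientation from the core's position on the same axis.

    For a polyA run on the reference strand, a core lying entirely left of
    the tract sits at the 5' end of the polyA sequence; a core entirely to
    the right sits at its 3' end. For a polyT run the polyA sequence is on
    the complementary strand, whose 5'->3' direction is reversed, so the
    mapping inverts — this is the nucleosome's two-fold symmetry at work.

    Raises
    ------
    OverlapError
        If the tract and core intervals overlap (orientation undefined).
    """
    core_start, core_end = core
    if core_end <= core_start:
        raise ValueError("core interval must be non-empty")
    if tract.start < core_end and core_start < tract.end:
        raise OverlapError(
            f"tract [{tract.start},{tract.end}) overlaps core [{core_start},{core_end})"
        )
    core_is_left = core_end <= tract.start
    if tract.base == "A":
        return (
            Orientation.CORE_5PRIME_OF_POLYA
            if core_is_left
            else Orientation.CORE_3PRIME_OF_POLYA
        )
    return (
        Orientation.CORE_3PRIME_OF_POLYA
        if core_is_left
        else Orientation.CORE_5PRIME_OF_POLYA
    )


def tracts_in_window(
    tracts: Iterable[Tract], window: Tuple[int, int]
) -> list[Tract]:
    """Return tracts overlapping the half-open ``window`` by at least 1 bp."""
    w_start, w_end = window
    if w_end < w_start:
        raise ValueError("window end before start")
    return [t for t in tracts if t.start < w_end and w_start < t.end]
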