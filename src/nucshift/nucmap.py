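"""Dyad-peak handling and +1/-1 nucleosome assignment per gene.

The +1 nucleosome of a gene is the dyad peak closest to the TSS inside a
strand-oriented window of -80 bp (upstream) to +140 bp (downstream); the
-1 nucleosome is the dyad peak strictly upstream of the +1 that lies closest
to it. A simple fragment-midpoint dyad caller is provided for paired-fragment
input: midpoints are accumulated per base pair, smoothed with a Gaussian
kernel, and local maxima at least 100 bp apart become peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "DyadPeak",
    "GeneAnno",
    "AssignmentConfig",
    "NucAssignment",
    "call_dyads_from_fragments",
    "assign_plus_one",
    "assign_minus_one",
    "assign_gene",
    "filter_genes",
]

logger = logging.getLogger(__name__)

MIN_PEAK_SEPARATION = 100  # bp between called dyad peaks


@dataclass(frozen=True)
class DyadPeak:
    chrom: str
    pos: int  # 0-based dyad coordinate
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("dyad score must be non-negative")


@dataclass(frozen=True)
class GeneAnno:
    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str  # "+" or "-"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class AssignmentConfig:
    """TSS window and footprint geometry for nucleosome assignment.

    ``window_upstream``/``window_downstream`` bound the strand-oriented
    offset of the +1 dyad from the TSS (closed interval [-80, +140] by
    default). ``footprint_half`` converts a dyad position into the 147 bp
    core interval pos +/- 73 when needed.
    """

    window_upstream: int = 80
    window_downstream: int = 140
    footprint_half: int = 73

    def __post_init__(self) -> None:
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise ValueError("window bounds must be >= 0")


@dataclass(frozen=True)
class NucAssignment:
    gene_id: str
    plus1: Optional[DyadPeak] = None
    minus1: Optional[DyadPeak] = None


def _oriented_offset(pos: int, tss: int, strand: str) -> int:
    """Signed TSS offset, positive pointing downstream in gene orientation."""
    return pos - tss if strand == "+" else tss - pos


def call_dyads_from_fragments(
    fragments: pd.DataFrame,
    smoothing_bandwidth: float = 10.0,
    min_score: float = 0.0,
) -> list[DyadPeak]:
    """Call dyad peaks from paired-fragment intervals.

    ``fragments`` needs columns chrom, start, end (0-based half-open).
    Fragment midpoints are binned per base pair, smoothed with a Gaussian of
    the given bandwidth (bp), and peaks are local maxima separated by at
    least 100 bp with smoothed density > ``min_score``.
    """
    if fragments.empty:
        logger.warning("no fragments supplied; returning no dyad peaks")
        return []
    peaks: list[DyadPeak] = []
    for chrom, grp in fragments.groupby("chrom", sort=True):
        mids = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(int)
        lo, hi = int(mids.min()), int(mids.max())
        counts = np.bincount(mids - lo, minlength=hi - lo + 1).astype(float)
        density = gaussian_filter1d(counts, sigma=smoothing_bandwidth, mode="constant")
        idx, _ = find_peaks(density, distance=MIN_PEAK_SEPARATION, height=min_score)
        if idx.size == 0 and density.size:
            # a single monotone bump has its maximum at an edge; keep it
            j = int(np.argmax(density))
            if density[j] > min_score:
                idx = np.array([j])
        peaks.extend(
            DyadPeak(chrom=str(chrom), pos=lo + int(j), score=float(density[j]))
            for j in idx
        )
    return peaks


def assign_plus_one(
    dyads: Sequence[DyadPeak], gene: GeneAnno, cfg: AssignmentConfig = AssignmentConfig()
) -> Optional[DyadPeak]:
    """Pick the dyad closest to the TSS inside the [-up, +down] oriented window.

    Ties between an upstream and a downstream dyad at equal |offset| go to
    the downstream dyad, the canonical side for a +1 nucleosome.
    """
    best: Optional[DyadPeak] = None
    best_key: Optional[tuple] = None
    for d in dyads:
        if d.chrom != gene.chrom:
            continue
        off = _oriented_offset(d.pos, gene.tss, gene.strand)
        if -cfg.window_upstream <= off <= cfg.window_downstream:
            key = (abs(off), 0 if off > 0 else 1)  # downstream wins ties
            if best_key is None or key < best_key:
                best, best_key = d, key
    return best


def assign_minus_one(
    dyads: Sequence[DyadPeak], gene: GeneAnno, plus1: Optional[DyadPeak]
) -> Optional[DyadPeak]:
    """Pick the dyad strictly upstream of the +1 that is nearest to it."""
    if plus1 is None:
        raise ValueError("assign_minus_one requires an assigned +1 nucleosome")
    best: Optional[DyadPeak] = None
    best_dist: Optional[int] = None
    for d in dyads:
        if d.chrom != gene.chrom:
            continue
        rel = _oriented_offset(d.pos, plus1.pos, gene.strand)
        if rel < 0:  # strictly upstream of +1 in gene orientation
            dist = -rel
            if best_dist is None or dist < best_dist:
                best, best_dist = d, dist
    return best


def assign_gene(
    dyads: Sequence[DyadPeak], gene: GeneAnno, cfg: AssignmentConfig = AssignmentConfig()
) -> NucAssignment:
    """Assign both the +1 and (if the +1 exists) the -1 nucleosome."""
    plus1 = assign_plus_one(dyads, gene, cfg)
    minus1 = assign_minus_one(dyads, gene, plus1) if plus1 is not None else None
    return NucAssignment(gene_id=gene.gene_id, plus1=plus1, minus1=minus1)


def filter_genes(
    genes: Iterable[GeneAnno],
    excluded_chroms: Iterable[str] = (),
    excluded_gene_ids: Iterable[str] = (),
) -> list[GeneAnno]:
    """Drop genes on excluded chromosomes (e.g. chrM) or in excluded ID sets."""
    chroms = set(excluded_chroms)
    ids = set(excluded_gene_ids)
    kept = [g for g in genes if g.chrom not in chroms and g.gene_id not in ids]
    if not kept:
        logger.warning("all genes removed by exclusion filters")
    return kept


def assignments_to_frame(
    assignments: Iterable[NucAssignment], genes: Mapping[str, GeneAnno]
) -> pd.DataFrame:
    """Tabulate assignments as gene_id, chrom, strand, tss, plus1_pos, minus1_pos."""
    rows = []
    for a in assignments:
        g = genes[a.gene_id]
        rows.append(
            {
                "gene_id": a.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "plus1_pos": a.plus1.pos if a.plus1 else pd.NA,
                "minus1_pos": a.minus1.pos if a.minus1 else pd.NA,
            }
        )
    return pd.DataFrame(rows)
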