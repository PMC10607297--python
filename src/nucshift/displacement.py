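"""Per-gene nucleosome displacement, mobilization clusters, and binned
poly(dA:dT) tract frequency profiles around baseline (SGD) dyads.

Displacement is the strand-oriented difference between the dyad position in
the baseline condition (salt-gradient-dialysis reconstitution, "SGD") and
after remodeler treatment; positive means the nucleosome moved downstream in
gene orientation. Genes are clustered into "upstream", "downstream" (moves
of strictly more than the threshold, 20 bp by default) and "unchanged". For
each cluster, the fraction of genes with a sense-strand polyA (or polyT)
tract overlapping each 25 bp bin of a 500 bp window centered on the SGD dyad
is reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Literal, Mapping, Optional, Sequence
import logging

import pandas as pd

from .tracts import Tract, scan_tracts

__all__ = [
    "DisplacementRecord",
    "ProfileConfig",
    "compute_displacement",
    "classify_displacement",
    "build_clusters",
    "tract_frequency_profile",
]

logger = logging.getLogger(__name__)

ClusterLabel = Literal["upstream", "downstream", "unchanged"]


@dataclass(frozen=True)
class DisplacementRecord:
    gene_id: str
    nuc_role: str  # "minus1" or "plus1"
    delta: int  # signed bp, positive = downstream in gene orientation
    cluster: ClusterLabel


@dataclass(frozen=True)
class ProfileConfig:
    """Geometry of the tract-frequency profile.

    500 bp window (``window_half`` = 250 on each side of the SGD dyad),
    25 bp bins, tracts of at least 6 nt, and a 20 bp displacement threshold.
    ``overlap_rule`` decides whether a tract counts for a bin when it merely
    overlaps it ("overlap", default) or only when it starts in it ("start").
    """

    window_half: int = 250
    bin_width: int = 25
    min_tract_len: int = 6
    displacement_threshold: int = 20
    overlap_rule: str = "overlap"

    def __post_init__(self) -> None:
        if (2 * self.window_half) % self.bin_width != 0:
            raise ValueError("2*window_half must be divisible by bin_width")
        if self.overlap_rule not in ("overlap", "start"):
            raise ValueError("overlap_rule must be 'overlap' or 'start'")

    @property
    def n_bins(self) -> int:
        return (2 * self.window_half) // self.bin_width


def compute_displacement(
    pos_sgd: int, pos_treated: int, strand: str, chrom_sgd: str = "", chrom_treated: str = ""
) -> int:
    """Strand-oriented dyad shift between conditions (positive = downstream)."""
    if chrom_sgd != chrom_treated:
        raise ValueError(
            f"dyads on different chromosomes: {chrom_sgd!r} vs {chrom_treated!r}"
        )
    if strand == "+":
        return pos_treated - pos_sgd
    if strand == "-":
        return pos_sgd - pos_treated
    raise ValueError(f"strand must be + or -, got {strand!r}")


def classify_displacement(delta: int, threshold: int = 20) -> ClusterLabel:
    """Label a shift: strictly more than ``threshold`` bp in either direction."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if delta < -threshold:
        return "upstream"
    if delta > threshold:
        return "downstream"
    return "unchanged"


def build_clusters(
    records: Iterable[DisplacementRecord],
) -> Dict[str, Dict[str, list[DisplacementRecord]]]:
    """Partition records per nucleosome role into the three mobilization
    clusters plus the "all" cluster holding every classified gene."""
    out: Dict[str, Dict[str, list[DisplacementRecord]]] = {}
    for rec in records:
        role = out.setdefault(
            rec.nuc_role,
            {"upstream": [], "downstream": [], "unchanged": [], "all": []},
        )
        role[rec.cluster].append(rec)
        role["all"].append(rec)
    for role, clusters in out.items():
        total = sum(len(clusters[c]) for c in ("upstream", "downstream", "unchanged"))
        assert total == len(clusters["all"]), "cluster partition broken"
    return out


def _bin_interval_genomic(
    dyad: int, strand: str, off_start: int, off_end: int
) -> tuple[int, int]:
    """Genomic half-open interval of a strand-oriented offset bin."""
    if strand == "+":
        return dyad + off_start, dyad + off_end
    return dyad - off_end + 1, dyad - off_start + 1


def tract_frequency_profile(
    gene_ids: Sequence[str],
    genes: Mapping[str, "GeneLike"],
    sgd_dyads: Mapping[str, int],
    genome: Mapping[str, str],
    cfg: ProfileConfig = ProfileConfig(),
    cluster_id: str = "",
    nuc_role: str = "",
) -> pd.DataFrame:
    """Binned sense-strand polyA / polyT tract frequency around SGD dyads.

    For each 25 bp bin of the 500 bp window centered on the gene's SGD dyad
    (offsets strand-oriented, positive = downstream), the polyA frequency is
    100 x (number of genes with at least one sense-strand A-tract hitting
    the bin) / (number of genes); likewise for polyT. For minus-strand genes
    the sense strand is the reverse complement, so a sense polyA corresponds
    to a reference T-run and vice versa.

    ``genes`` maps gene_id to an object with ``chrom`` and ``strand``;
    ``sgd_dyads`` maps gene_id to the SGD dyad coordinate; ``genome`` maps
    chrom to sequence. Genes lacking a dyad are excluded and logged.

    Returns a DataFrame with columns cluster, nuc_role, bin_start_offset,
    bin_end_offset, polyA_freq, polyT_freq, n_genes.
    """
    usable = []
    for gid in gene_ids:
        if gid not in sgd_dyads:
            logger.warning("gene %s has no SGD dyad for %s; excluded", gid, nuc_role)
            continue
        usable.append(gid)
    n_genes = len(usable)

    offsets = [
        (-cfg.window_half + i * cfg.bin_width, -cfg.window_half + (i + 1) * cfg.bin_width)
        for i in range(cfg.n_bins)
    ]
    hitsA = [0] * cfg.n_bins
    hitsT = [0] * cfg.n_bins

    # cache tract scans per chromosome
    tract_cache: Dict[str, list[Tract]] = {}
    for gid in usable:
        g = genes[gid]
        dyad = sgd_dyads[gid]
        if g.chrom not in tract_cache:
            tract_cache[g.chrom] = scan_tracts(
                str(genome[g.chrom]), cfg.min_tract_len, chrom=g.chrom
            )
        tracts = tract_cache[g.chrom]
        for i, (o0, o1) in enumerate(offsets):
            b0, b1 = _bin_interval_genomic(dyad, g.strand, o0, o1)
            hitA = hitT = False
            for t in tracts:
                if cfg.overlap_rule == "overlap":
                    hit = t.start < b1 and b0 < t.end
                else:
                    hit = b0 <= t.start < b1
                if not hit:
                    continue
                # reference A-run = sense polyA on + genes, sense polyT on - genes
                sense_base = t.base if g.strand == "+" else ("T" if t.base == "A" else "A")
                if sense_base == "A":
                    hitA = True
                else:
                    hitT = True
                if hitA and hitT:
                    break
            hitsA[i] += hitA
            hitsT[i] += hitT

    rows = []
    for (o0, o1), a, t in zip(offsets, hitsA, hitsT):
        rows.append(
            {
                "cluster": cluster_id,
                "nuc_role": nuc_role,
                "bin_start_offset": o0,
                "bin_end_offset": o1,
                "polyA_freq": 100.0 * a / n_genes if n_genes else 0.0,
                "polyT_freq": 100.0 * t / n_genes if n_genes else 0.0,
                "n_genes": n_genes,
            }
        )
    return pd.DataFrame(rows)
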