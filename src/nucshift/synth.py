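"""Ground-truth synthetic data for the displacement and densitometry analyses.

The generator emulates the genome-scale study design: per-gene promoter
regions (one gene per synthetic contig) with a baseline (SGD) -1/+1
nucleosome pair around the TSS, a remodeler-treated condition in which each
gene's nucleosomes are shifted by a programmed, cluster-specific amount, and
poly(dA:dT) tracts embedded at programmed positions relative to the -1/+1
cores. Background sequence is built so that no unprogrammed A or T run
reaches the tract-detection threshold, making tract counts exactly
controllable. All randomness flows from one seeded generator, so identical
configurations yield byte-identical outputs.

Default cluster weights follow the proportions reported for ISW1a-mediated
-1 nucleosome mobilization (about 44% upstream, 21% downstream, the rest
unchanged), with 40 bp programmed shifts and a 15 bp sense-strand polyT
tract just downstream of the -1 core in upstream-mobilized genes — the
configuration whose recovered profile should show the tract enrichment
asymmetry between mobilization clusters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nucmap import GeneAnno

__all__ = [
    "TractRule",
    "ClusterSpec",
    "SyntheticConfig",
    "TruthRecord",
    "generate_promoter_genome",
    "generate_dyad_tracks",
    "generate_fragments",
    "generate_gel_tables",
    "DEFAULT_CLUSTERS",
]

FOOTPRINT_HALF = 73  # dyad +/- 73 covers the 147 bp core
PLUS1_TSS_OFFSET = 50  # SGD +1 dyad sits 50 bp downstream of the TSS
MINUS1_TSS_OFFSET = -130  # SGD -1 dyad sits 130 bp upstream of the TSS
ARRAY_SPACING = 165  # decoy -2/+2 dyads, one repeat length away


@dataclass(frozen=True)
class TractRule:
    """Programmed tract placement relative to a nucleosome core.

    ``anchor``: which SGD dyad the placement is measured from ("minus1" or
    "plus1"); ``side``: upstream/downstream of that core in gene
    orientation; ``sense_base``: base of the tract on the gene's sense
    strand; ``gap_from_core``: bp between the core edge (dyad -/+ 73) and
    the tract.
    """

    anchor: str = "minus1"
    side: str = "downstream"
    sense_base: str = "T"
    length: int = 15
    gap_from_core: int = 5

    def __post_init__(self) -> None:
        if self.anchor not in ("minus1", "plus1"):
            raise ValueError("anchor must be minus1 or plus1")
        if self.side not in ("upstream", "downstream"):
            raise ValueError("side must be upstream or downstream")
        if self.sense_base not in ("A", "T"):
            raise ValueError("sense_base must be A or T")
        if self.length < 1 or self.gap_from_core < 0:
            raise ValueError("invalid tract geometry")


@dataclass(frozen=True)
class ClusterSpec:
    """A programmed mobilization cluster: its share of genes, its signed
    gene-oriented dyad shifts (bp, positive = downstream), and the tracts
    its genes carry."""

    name: str
    weight: float
    minus1_shift: int = 0
    plus1_shift: int = 0
    tract_rules: Tuple[TractRule, ...] = ()


DEFAULT_CLUSTERS: Tuple[ClusterSpec, ...] = (
    ClusterSpec(
        name="upstream",
        weight=0.441,
        minus1_shift=-40,
        tract_rules=(TractRule(anchor="minus1", side="downstream", sense_base="T"),),
    ),
    ClusterSpec(name="downstream", weight=0.210, minus1_shift=40),
    ClusterSpec(name="unchanged", weight=0.349),
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 200
    promoter_span: int = 2000  # contig length per gene
    tss_offset: int = 1000  # TSS position within the contig (+ strand sense)
    clusters: Tuple[ClusterSpec, ...] = DEFAULT_CLUSTERS
    min_tract_len: int = 6
    dyad_jitter_sd: float = 0.0
    fragment_count_per_dyad: int = 100
    fragment_len_mean: float = 147.0
    fragment_len_sd: float = 0.0
    intensity_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.promoter_span < 500:
            raise ValueError("promoter_span must hold the 500 bp profiling window")
        total = sum(c.weight for c in self.clusters)
        if not np.isclose(total, 1.0):
            raise ValueError(f"cluster weights must sum to 1, got {total}")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    minus1_dyad_sgd: int
    plus1_dyad_sgd: int
    minus1_dyad_treated: int
    plus1_dyad_treated: int
    programmed_class_minus1: str
    programmed_class_plus1: str
    tract_placements: Tuple[Tuple[int, str, int], ...]  # (genomic start, ref base, length)


def _classify(shift: int, threshold: int = 20) -> str:
    if shift < -threshold:
        return "upstream"
    if shift > threshold:
        return "downstream"
    return "unchanged"


def _gene_to_genomic_point(tss: int, strand: str, r: int) -> int:
    """Map a gene-relative offset (positive = downstream) to genomic."""
    return tss + r if strand == "+" else tss - r


def _gene_to_genomic_interval(tss: int, strand: str, r0: int, r1: int) -> Tuple[int, int]:
    if strand == "+":
        return tss + r0, tss + r1
    return tss - r1 + 1, tss - r0 + 1


def _background(rng: np.random.Generator, length: int, min_tract_len: int) -> list[str]:
    """Random sequence with every A/T homopolymer shorter than min_tract_len."""
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.integers(0, 4, size=length)]))
    text = "".join(seq)
    pat = re.compile("A{%d,}|T{%d,}" % (min_tract_len, min_tract_len))
    for m in pat.finditer(text):
        # break the run by interrupting it every (min_tract_len - 1) bases
        for pos in range(m.start() + min_tract_len - 1, m.end(), min_tract_len - 1):
            seq[pos] = "G" if seq[pos] == "A" else "C"
    return seq


def generate_promoter_genome(
    cfg: SyntheticConfig,
) -> Tuple[Dict[str, str], List[GeneAnno], List[TruthRecord]]:
    """Emit the synthetic genome, gene annotation and per-gene truth.

    One contig per gene; strands alternate so both orientations are
    exercised. Raises if programmed tracts collide.
    """
    rng = np.random.default_rng(cfg.seed)
    # deterministic cluster assignment by weight, then shuffled
    counts = [int(round(c.weight * cfg.n_genes)) for c in cfg.clusters]
    while sum(counts) > cfg.n_genes:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < cfg.n_genes:
        counts[int(np.argmax([c.weight for c in cfg.clusters]))] += 1
    membership = np.repeat(np.arange(len(cfg.clusters)), counts)
    rng.shuffle(membership)

    genome: Dict[str, str] = {}
    genes: List[GeneAnno] = []
    truths: List[TruthRecord] = []

    for i in range(cfg.n_genes):
        cluster = cfg.clusters[membership[i]]
        gene_id = f"gene_{i:05d}"
        chrom = f"contig_{i:05d}"
        strand = "+" if i % 2 == 0 else "-"
        tss = cfg.tss_offset
        seq = _background(rng, cfg.promoter_span, cfg.min_tract_len)

        minus1_r, plus1_r = MINUS1_TSS_OFFSET, PLUS1_TSS_OFFSET
        minus1_sgd = _gene_to_genomic_point(tss, strand, minus1_r)
        plus1_sgd = _gene_to_genomic_point(tss, strand, plus1_r)
        minus1_tr = _gene_to_genomic_point(tss, strand, minus1_r + cluster.minus1_shift)
        plus1_tr = _gene_to_genomic_point(tss, strand, plus1_r + cluster.plus1_shift)

        placements: List[Tuple[int, str, int]] = []
        occupied: List[Tuple[int, int]] = []
        for rule in cluster.tract_rules:
            anchor_r = minus1_r if rule.anchor == "minus1" else plus1_r
            if rule.side == "downstream":
                r0 = anchor_r + FOOTPRINT_HALF + 1 + rule.gap_from_core
                r1 = r0 + rule.length
            else:
                r1 = anchor_r - FOOTPRINT_HALF - rule.gap_from_core
                r0 = r1 - rule.length
            g0, g1 = _gene_to_genomic_interval(tss, strand, r0, r1)
            if g0 < 1 or g1 > cfg.promoter_span - 1:
                raise ValueError("programmed tract outside the contig")
            for s, e in occupied:
                if g0 < e and s < g1:
                    raise ValueError("programmed tracts collide; reject config")
            occupied.append((g0, g1))
            ref_base = (
                rule.sense_base
                if strand == "+"
                else ("A" if rule.sense_base == "T" else "T")
            )
            seq[g0:g1] = [ref_base] * (g1 - g0)
            # pin the run to exactly the programmed length
            for flank in (g0 - 1, g1):
                if seq[flank] == ref_base:
                    seq[flank] = "G" if ref_base == "A" else "C"
            placements.append((g0, ref_base, rule.length))

        genome[chrom] = "".join(seq)
        genes.append(GeneAnno(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
        truths.append(
            TruthRecord(
                gene_id=gene_id,
                chrom=chrom,
                tss=tss,
                strand=strand,
                minus1_dyad_sgd=minus1_sgd,
                plus1_dyad_sgd=plus1_sgd,
                minus1_dyad_treated=minus1_tr,
                plus1_dyad_treated=plus1_tr,
                programmed_class_minus1=_classify(cluster.minus1_shift),
                programmed_class_plus1=_classify(cluster.plus1_shift),
                tract_placements=tuple(placements),
            )
        )
    return genome, genes, truths


def generate_dyad_tracks(
    truths: Sequence[TruthRecord], cfg: SyntheticConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Dyad tables for the baseline (SGD) and treated conditions.

    Each gene contributes its -1 and +1 dyads plus flanking -2/+2 decoy
    dyads one repeat length away (unshifted between conditions). Gaussian
    jitter of ``dyad_jitter_sd`` bp is applied independently per dyad and
    condition; with zero jitter the treated dyad equals the SGD dyad plus
    the programmed strand-oriented shift exactly.
    """
    if not truths:
        raise ValueError("truth set is empty")
    rng = np.random.default_rng(cfg.seed + 1)

    def jitter() -> int:
        if cfg.dyad_jitter_sd == 0:
            return 0
        return int(round(rng.normal(0.0, cfg.dyad_jitter_sd)))

    rows_a, rows_b = [], []
    for t in truths:
        sign = 1 if t.strand == "+" else -1
        minus2 = t.minus1_dyad_sgd - sign * ARRAY_SPACING
        plus2 = t.plus1_dyad_sgd + sign * ARRAY_SPACING
        for pos in (minus2, t.minus1_dyad_sgd, t.plus1_dyad_sgd, plus2):
            rows_a.append((t.chrom, pos + jitter(), 1.0))
        for pos in (minus2, t.minus1_dyad_treated, t.plus1_dyad_treated, plus2):
            rows_b.append((t.chrom, pos + jitter(), 1.0))

    def frame(rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "score"])
        df.insert(2, "end", df["pos"] + 1)
        return df.rename(columns={"pos": "start"})

    return frame(rows_a), frame(rows_b)


def generate_fragments(dyads: pd.DataFrame, cfg: SyntheticConfig) -> pd.DataFrame:
    """MNase-like paired-fragment intervals around each dyad.

    Midpoints are normal around the dyad (sd = ``dyad_jitter_sd``), lengths
    normal around ``fragment_len_mean``. An empty dyad table yields an
    empty fragment table.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if dyads.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    rows = []
    n = cfg.fragment_count_per_dyad
    for chrom, pos in zip(dyads["chrom"], dyads["start"]):
        mids = pos + (
            np.zeros(n)
            if cfg.dyad_jitter_sd == 0
            else rng.normal(0.0, cfg.dyad_jitter_sd, size=n)
        )
        lens = (
            np.full(n, cfg.fragment_len_mean)
            if cfg.fragment_len_sd == 0
            else rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd, size=n)
        )
        mids = np.rint(mids).astype(int)
        lens = np.maximum(np.rint(lens).astype(int), 1)
        starts = mids - lens // 2
        for s, ln in zip(starts, lens):
            rows.append((chrom, int(s), int(s + ln)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_gel_tables(
    true_extents: Mapping[str, Mapping[str, float]],
    cfg: SyntheticConfig,
) -> pd.DataFrame:
    """Emulated densitometry tables for the gel-quantification formulas.

    ``true_extents`` maps assay kinds to {lane_id: true value}:

    - ``"sliding"``: fractional sliding extent in [0, 1] -> bands
      slid/unslid;
    - ``"eviction"``: eviction extent -> a minus/plus lane pair with
      free_dna and nucleosomal bands;
    - ``"binding"``: binding extent -> bound/unbound bands;
    - ``"keq_rel"``: relative Keq -> nucleosomal/free_dna bands, with the
      reference lane ("ref") at 30% reconstitution.

    Multiplicative Gaussian noise with CV ``intensity_noise_cv`` is applied
    per band; at zero noise the gel_quant formulas recover the true values
    exactly. Returns a long table (assay_id, lane_id, band, intensity).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    cv = cfg.intensity_noise_cv

    def noisy(x: float) -> float:
        if cv == 0:
            return x
        return max(x * (1.0 + cv * rng.standard_normal()), 0.0)

    total = 100.0
    rows: List[Tuple[str, str, str, float]] = []
    for kind, lanes in true_extents.items():
        for lane_id, value in lanes.items():
            if kind == "sliding":
                if not 0 <= value <= 1:
                    raise ValueError("sliding extent must be in [0,1]")
                rows.append(("sliding", lane_id, "slid", noisy(value * total)))
                rows.append(("sliding", lane_id, "unslid", noisy((1 - value) * total)))
            elif kind == "eviction":
                if not 0 <= value <= 1:
                    raise ValueError("eviction extent must be in [0,1]")
                free0, nuc0 = 10.0, 90.0
                rows.append(("eviction", f"{lane_id}_minus", "free_dna", noisy(free0)))
                rows.append(("eviction", f"{lane_id}_minus", "nucleosomal", noisy(nuc0)))
                rows.append(
                    ("eviction", f"{lane_id}_plus", "free_dna", noisy(free0 + value * nuc0))
                )
                rows.append(
                    ("eviction", f"{lane_id}_plus", "nucleosomal", noisy((1 - value) * nuc0))
                )
            elif kind == "binding":
                if not 0 <= value <= 1:
                    raise ValueError("binding extent must be in [0,1]")
                rows.append(("binding", lane_id, "bound", noisy(value * total)))
                rows.append(("binding", lane_id, "unbound", noisy((1 - value) * total)))
            elif kind == "keq_rel":
                if value <= 0:
                    raise ValueError("relative Keq must be positive")
                # reference: 30% reconstitution (nuc 30 / free 70)
                rows.append(("keq", lane_id, "nucleosomal", noisy(value * 30.0)))
                rows.append(("keq", lane_id, "free_dna", noisy(70.0)))
            else:
                raise ValueError(f"unknown assay kind {kind!r}")
        if kind == "keq_rel":
            rows.append(("keq", "ref", "nucleosomal", noisy(30.0)))
            rows.append(("keq", "ref", "free_dna", noisy(70.0)))
    return pd.DataFrame(rows, columns=["assay_id", "lane_id", "band", "intensity"])
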