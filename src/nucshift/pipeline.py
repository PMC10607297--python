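"""End-to-end displacement pipeline: dyads in two conditions -> per-gene
-1/+1 assignments -> displacement clusters -> binned tract-frequency
profiles around the baseline (SGD) dyads."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .displacement import (
    DisplacementRecord,
    ProfileConfig,
    build_clusters,
    classify_displacement,
    compute_displacement,
    tract_frequency_profile,
)
from .nucmap import (
    AssignmentConfig,
    DyadPeak,
    GeneAnno,
    NucAssignment,
    assign_gene,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    assignments_sgd: Dict[str, NucAssignment]
    assignments_treated: Dict[str, NucAssignment]
    records: List[DisplacementRecord]
    clusters: Dict[str, Dict[str, List[DisplacementRecord]]]
    profiles: pd.DataFrame


def _by_chrom(dyads: Sequence[DyadPeak]) -> Dict[str, List[DyadPeak]]:
    idx: Dict[str, List[DyadPeak]] = defaultdict(list)
    for d in dyads:
        idx[d.chrom].append(d)
    for lst in idx.values():
        lst.sort(key=lambda d: d.pos)
    return idx


def run_pipeline(
    genome: Mapping[str, str],
    genes: Sequence[GeneAnno],
    dyads_sgd: Sequence[DyadPeak],
    dyads_treated: Sequence[DyadPeak],
    assign_cfg: AssignmentConfig = AssignmentConfig(),
    profile_cfg: ProfileConfig = ProfileConfig(),
    profile_roles: Sequence[str] = ("minus1", "plus1"),
) -> PipelineResult:
    """Assign nucleosomes in both conditions, classify displacements,
    build mobilization clusters and compute per-cluster tract profiles."""
    idx_sgd = _by_chrom(dyads_sgd)
    idx_tr = _by_chrom(dyads_treated)
    gene_map = {g.gene_id: g for g in genes}

    asg_sgd: Dict[str, NucAssignment] = {}
    asg_tr: Dict[str, NucAssignment] = {}
    records: List[DisplacementRecord] = []
    for g in genes:
        a = assign_gene(idx_sgd.get(g.chrom, ()), g, assign_cfg)
        b = assign_gene(idx_tr.get(g.chrom, ()), g, assign_cfg)
        asg_sgd[g.gene_id] = a
        asg_tr[g.gene_id] = b
        for role in ("minus1", "plus1"):
            pa: Optional[DyadPeak] = getattr(a, role)
            pb: Optional[DyadPeak] = getattr(b, role)
            if pa is None or pb is None:
                continue
            delta = compute_displacement(
                pa.pos, pb.pos, g.strand, chrom_sgd=pa.chrom, chrom_treated=pb.chrom
            )
            records.append(
                DisplacementRecord(
                    gene_id=g.gene_id,
                    nuc_role=role,
                    delta=delta,
                    cluster=classify_displacement(
                        delta, profile_cfg.displacement_threshold
                    ),
                )
            )

    clusters = build_clusters(records)

    frames = []
    for role in profile_roles:
        if role not in clusters:
            continue
        sgd_dyads = {
            gid: a.minus1.pos if role == "minus1" else a.plus1.pos
            for gid, a in asg_sgd.items()
            if getattr(a, role) is not None
        }
        for cname in ("all", "upstream", "downstream", "unchanged"):
            gids = [r.gene_id for r in clusters[role][cname]]
            frames.append(
                tract_frequency_profile(
                    gids,
                    gene_map,
                    sgd_dyads,
                    genome,
                    profile_cfg,
                    cluster_id=cname,
                    nuc_role=role,
                )
            )
    profiles = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return PipelineResult(asg_sgd, asg_tr, records, clusters, profiles)
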