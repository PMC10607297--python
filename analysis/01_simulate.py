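#!/usr/bin/env python
"""Generate the synthetic study dataset with programmed ground truth.

Emits, under results/synthetic/: the per-gene promoter genome (FASTA), the
gene annotation (BED6), dyad tracks for the baseline (SGD) and
remodeler-treated conditions (TSV), a paired-fragment table for the dyad
caller (BED) and the truth table (TSV). Cluster weights follow the reported
proportions of ISW1a-mediated -1 mobilization (44% upstream / 21%
downstream / 35% unchanged) with 40 bp programmed shifts, and
upstream-mobilized genes carry a 15 bp sense-strand polyT tract just
downstream of the -1 core.
"""

from pathlib import Path

import pandas as pd

import nucshift as ns
from nucshift import io as nio

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
N_GENES = 400
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ns.SyntheticConfig(n_genes=N_GENES, seed=SEED)
    genome, genes, truths = ns.generate_promoter_genome(cfg)
    dy_a, dy_b = ns.generate_dyad_tracks(truths, cfg)
    frags = ns.generate_fragments(dy_a, cfg)

    nio.write_fasta(genome, OUT / "genome.fa")
    nio.write_genes_bed(genes, OUT / "genes.bed")
    nio.write_dyads(dy_a, OUT / "dyads_sgd.tsv")
    nio.write_dyads(dy_b, OUT / "dyads_isw1a.tsv")
    nio.write_fragments_bed(frags, OUT / "fragments_sgd.bed")
    pd.DataFrame([t.__dict__ for t in truths]).to_csv(
        OUT / "truth.tsv", sep="\t", index=False
    )

    counts = pd.Series(
        [t.programmed_class_minus1 for t in truths]
    ).value_counts()
    print(f"wrote {N_GENES} genes to {OUT}")
    print("programmed -1 classes:", counts.to_dict())


if __name__ == "__main__":
    main()
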