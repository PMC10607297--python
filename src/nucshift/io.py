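"""Readers and writers for the on-disk formats used by the analyses.

Coordinates are 0-based half-open throughout, matching BED. Gene BED rows
carry the TSS as the strand-appropriate interval edge (start for + genes,
end - 1 for - genes); the emitted 1 bp intervals satisfy both conventions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .nucmap import DyadPeak, GeneAnno
from .tracts import Tract

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_genes_bed",
    "read_genes_bed",
    "write_dyads",
    "read_dyads",
    "write_fragments_bed",
    "read_fragments_bed",
    "write_tracts_bed",
    "write_gel_table",
    "read_gel_table",
]


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Dict[str, str]:
    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_genes_bed(genes: Iterable[GeneAnno], path: str | Path) -> None:
    rows = []
    for g in genes:
        rows.append((g.chrom, g.tss, g.tss + 1, g.gene_id, 0, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str | Path) -> List[GeneAnno]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        genes.append(
            GeneAnno(gene_id=str(row.name), chrom=str(row.chrom), tss=tss, strand=row.strand)
        )
    return genes


def write_dyads(dyads: pd.DataFrame, path: str | Path) -> None:
    dyads[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_dyads(path: str | Path) -> List[DyadPeak]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"]
    )
    return [
        DyadPeak(chrom=str(r.chrom), pos=int(r.start), score=float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])


def write_tracts_bed(tracts: Sequence[Tract], path: str | Path) -> None:
    """BED with name polyA|polyT and score = tract length."""
    rows = [
        (t.chrom, t.start, t.end, "polyA" if t.base == "A" else "polyT", t.length)
        for t in tracts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_gel_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gel_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
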