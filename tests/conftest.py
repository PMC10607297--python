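import pytest

import nucshift as ns

# the full probe panel used across the in-vitro analyses
PANEL_NAMES = [
    "0-NC-70", "0-NC-70A15", "0-NC-70T15",
    "70-NC-0", "70A15-NC-0", "70T15-NC-0",
    "0-NC-30", "0-NC-30A15", "0-NC-30T15",
    "35-NC-35", "35A15-NC-35", "35T15-NC-35",
    "35-NC-35A15", "35-NC-35T15",
    "35A15-NC-35T15", "35T15-NC-35A15",
    "70A15-NC-70T15", "70T15-NC-70A15",
]


@pytest.fixture(scope="session")
def small_synth():
    """A small zero-noise synthetic dataset with programmed ground truth."""
    cfg = ns.SyntheticConfig(n_genes=60, seed=42)
    genome, genes, truths = ns.generate_promoter_genome(cfg)
    dy_a, dy_b = ns.generate_dyad_tracks(truths, cfg)
    return cfg, genome, genes, truths, dy_a, dy_b


def dyads_from_frame(df):
    return [
        ns.DyadPeak(chrom=str(r.chrom), pos=int(r.start), score=float(r.score))
        for r in df.itertuples(index=False)
    ]
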