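# Methods

This document records the model assumptions, parameter choices and
numerical conventions behind `nucshift`. Coordinates are 0-based,
half-open unless stated otherwise; "upstream/downstream" are always in the
transcriptional (strand-oriented) sense.

## 1. Tract detection and orientation (`nucshift.tracts`)

A poly(dA:dT) tract is a **maximal run of identical A or T bases** on the
given (upper) strand, with minimum length `min_len = 6` by default —
shorter runs are treated as inert throughout the package. `N` bases break
runs; other characters raise an error. `scan_tracts` is a single linear
pass; a regex implementation is used as an independent oracle in the test
suite.

Tract orientation relative to a nucleosome core `[core_start, core_end)`
is expressed on the **polyA strand**: for an upper-strand polyA tract, a
core entirely to the tract's left is *core 5′ of polyA*; for an
upper-strand polyT tract the same geometry is *core 3′ of polyA*, because
the polyA strand is the lower strand. Tracts overlapping the core are
rejected (`OverlapError`) since the orientation is then undefined.

## 2. Nucleosome maps (`nucshift.nucmap`)

**Dyad calling.** Paired-end fragment midpoints are accumulated per base
(`numpy.bincount`), smoothed with a Gaussian kernel
(`scipy.ndimage.gaussian_filter1d`, σ = 20 bp), and peaks are called with
`scipy.signal.find_peaks` with a minimum separation of 100 bp (just under
one footprint, so adjacent nucleosomes remain resolvable while sub-
nucleosomal shoulders are suppressed). A degenerate profile with no
interior peak falls back to the argmax.

**+1/−1 assignment.** The +1 nucleosome of a gene is the dyad with the
smallest absolute oriented TSS offset within the **closed window
[−80, +140]**; ties are broken toward the downstream candidate, reflecting
the expectation that the +1 sits over the TSS/into the gene body. The −1
is the nearest dyad **strictly upstream** of the +1 (not merely upstream
of the TSS), so a dyad at the +1 position is never double-assigned.
Requesting a −1 without an assigned +1 is an error. The dyad footprint is
`pos ± 73` (147 bp).

## 3. Displacement and tract-frequency profiles (`nucshift.displacement`)

**Displacement** between the SGD baseline and a treated condition is
`Δ = pos_treated − pos_SGD` for + strand genes and the negation for −
strand genes, so Δ > 0 always means movement downstream of transcription.
Genes are partitioned into clusters with a **strict** threshold:
Δ > 20 bp → `downstream`, Δ < −20 bp → `upstream`, otherwise `unchanged`.
The partition is asserted to be exhaustive and disjoint.

**Profiles.** For a gene set and a nucleosome role, tract frequency is
computed in 25 bp bins across a 500 bp window centered on the **SGD** dyad
(`window_half = 250`). A bin counts a gene if any sense-strand tract of
the given base overlaps the bin by ≥ 1 bp (half-open interval overlap);
frequency is `100 × count / n_genes`. For − strand genes, genomic
coordinates are mirrored into oriented bin offsets and the reported base is
flipped (an upper-strand polyA is a sense-strand polyT), so `polyA_freq` /
`polyT_freq` are always sense-strand quantities. Per-chromosome tract
scans are cached.

## 4. Probe models (`nucshift.probes`)

**Geometry.** A probe named `<up>[A|T<len>]-NC-<down>[A|T<len>]` is
`up + 147 + down` bp: the linker numbers are **extranucleosomal DNA**, so
`0-NC-70` and `0-NC-70A15` are both 217 bp (the tract replaces linker
sequence rather than extending it). Adjacent (gap-0) tracts follow the
design convention that 2 bp of the tract lie inside the 147 bp footprint;
the labeled (upstream) end carries the 5′ label.

**Sequence.** The 147 bp core sequence is a **synthetic stand-in**, not a
natural positioning sequence: it is designed to contain exactly one PmlI
site (CACGTG, cut offset 3) at core offset 19 and one MfeI site (CAATTG,
cut offset 1) at core offset 116, and no A/T runs ≥ 4 nt. Linkers are
built from a fixed G/C-rich unit with flank pinning so tract insertions
never create spurious runs, and site uniqueness is re-verified for every
constructed probe.

**Digestion** is a binary footprint-protection model: a recognition site
overlapping the core interval is uncut on the nucleosome; naked DNA is
always cut; partial protection, kinetics and breathing are out of scope.
The labeled fragment length equals the upper-strand cut coordinate, and
the fragment is classed `nucleosomal` if it fully contains the core, else
`naked_dna`. On the centered 35-NC-35 probe this yields the diagnostic
fragments 152 bp (MfeI, core slid flush-upstream) and 57 bp (PmlI,
accessible).

**Sliding.** `slide_core` supports flush-to-end, absolute positioning and
beyond-end sliding limited to 51 bp of core DNA off the fragment end.

**Remodeling outcome rules** (`predict_remodeling`) encode the
orientation logic as a deterministic rule set:

- *RSC* exits through a tract-bearing linker regardless of tract
  orientation; a core 5′-of-polyA configuration additionally marks the
  probe `slide_plus_eviction_prone`; a double-tract probe with both cores
  3′-of-polyA is `blocked_at_tract`. A gap ≥ 40 bp from the core or a
  7 nt tract demotes the stimulation rank; tracts ≤ 5 nt are inert.
- *ISW1a* enters through the longer linker and slides the core toward the
  entry side (exit = shorter linker). Only a tract in the **entry**
  linker with gap < 19 bp and length ≥ 7 inhibits (rank −1 for 7 nt,
  −3/−2 for ≥ 10 nt core-3′/core-5′); distal or gapped tracts give slight
  stimulation (+1). Equal linkers default to the downstream entry.

The rule set is invariant under the nucleosome's two-fold symmetry
(complementing the tract base while mirroring the geometry), which is
enforced by construction and tested across the full probe panel.

## 5. Gel quantification (`nucshift.gelquant`)

From band-intensity tables (arbitrary units):

- **sliding extent** = Σ slid / (Σ slid + unslid), optionally counting
  smear and well bands in the denominator;
- **eviction extent** = (free⁺ − free⁻) / nucleosomal⁻ across a
  remodeler ±ATP lane pair; negative values are reported as-is rather
  than clipped, so background fluctuation remains visible;
- **binding extent** = bound / (bound + unbound);
- **within-assay normalization** divides each lane by the assay mean, so
  replicates from different exposures can be pooled;
- **relative K_eq** = (nuc/free)_probe / (nuc/free)_reference from
  reconstitution lanes, and **ΔΔG° = −RT ln K_eq,rel** with
  R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K. An 8–10-fold K_eq
  reduction corresponds to ΔΔG° ≈ 1.23–1.36 kcal/mol.

## 6. Synthetic data generator (`nucshift.synth`)

The generator is the package's study condition: it emulates a promoter
collection with programmed ground truth, **not** a realistic yeast genome.
Each gene gets its own 2000 bp contig with the TSS at offset 1000,
alternating strands. Defaults: +1 dyad at TSS + 50, −1 at TSS − 130,
flanking −2/+2 decoys at ±165 bp spacing; background sequence is generated
with A/T runs regex-interrupted below the tract threshold, and tract
insertions are collision-checked.

Genes are assigned to mobilization clusters by weight — `upstream` 0.441
(−40 bp programmed −1 shift, plus a 15 bp sense-strand polyT tract 5 bp
downstream of the −1 core, i.e. dyad-relative [+79, +94), landing in the
[+75, +100) profile bin), `downstream` 0.210 (+40 bp), `unchanged` 0.349 —
matching the reported cluster proportions. Dyad jitter, fragment sampling
and gel-band noise use child seeds (`seed+1..3`) so each layer is
independently reproducible. Gel tables are generated from programmed true
extents with configurable multiplicative band noise.

Problem sizes in the analysis scripts (400 genes; 2000 genes in the
profile-asymmetry test) are package choices balancing runtime against
statistical stability, not empirical sample sizes.

## 7. Numerical and engineering choices

- Established libraries are used for all standard primitives: NumPy/SciPy
  for histograms, smoothing and peak calling; pandas for tables;
  Biopython/pyfaidx for FASTA I/O; click for the CLI; hypothesis
  (derandomized) for property tests.
- All intervals half-open except the +1 assignment window, which is closed
  per the assignment convention above.
- Randomness flows exclusively through `numpy.random.default_rng(seed)`;
  no global seeding.

## 8. Limitations

- The digestion model is binary; real accessibility is a rate.
- Remodeling outcomes are categorical ranks, not kinetic or thermodynamic
  predictions; ranks are ordinal within a remodeler only.
- The synthetic genome has one gene per contig and no overlapping or
  divergent promoters, so −1 sharing between gene pairs is not modeled.
- The 147 bp core sequence is synthetic; fragment lengths transfer to
  natural positioning sequences only insofar as site offsets match.
- Tract effects are modeled from upper-strand sequence only; methylation,
  flexibility variation within tracts and interrupted (impure) tracts are
  out of scope.
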