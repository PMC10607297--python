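"""Mononucleosome probe construction, sliding, restriction digestion and
remodeler-directionality prediction.

Probes follow the naming convention used for 601-based mononucleosome
constructs: ``<up>[A|T<len>]-NC-<down>[A|T<len>]`` where ``up``/``down`` are
the extranucleosomal (linker) DNA lengths in bp flanking the 147 bp
nucleosome core (NC), and an ``A15``/``T15`` token records a poly(dA:dT)
tract adjacent to the core with the given base on the upper strand. When a
tract abuts the core, the positioning sequence is trimmed to its first (or
last) 145 bp and the tract contributes its terminal 2 bp to the 147 bp
footprint, keeping total probe length equal to up + 147 + down.

The 147 bp positioning core shipped here is a synthetic stand-in for the
Widom 601 region (the real sequence can be supplied instead): it embeds a
PmlI site (CACGTG, blunt cut after position 3) at core offset 19 and an
MfeI site (CAATTG, cut after position 1) at core offset 116, so that on a
217 bp probe with 35 bp linkers the upper-strand cut coordinates are 57 and
152 bp from the labeled 5' end of the upper strand.

Digestion uses binary footprint protection: a recognition site overlapping
the core interval is not cut on the nucleosomal species; naked DNA is
always cut. The labeled fragment length equals the upper-strand cut
coordinate, and the fragment is classed nucleosomal when it fully contains
the core.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence, Tuple

from .tracts import Orientation, Tract, classify_tract_orientation

__all__ = [
    "CORE_LEN",
    "MAX_BEYOND_END",
    "TractInsertion",
    "ProbeSpec",
    "ProbeLayout",
    "Enzyme",
    "PMLI",
    "MFEI",
    "DigestionResult",
    "RemodelingPrediction",
    "build_probe",
    "probe_name",
    "parse_probe_name",
    "slide_core",
    "digest",
    "predict_remodeling",
    "mirror_spec",
]

CORE_LEN = 147
MAX_BEYOND_END = 51  # bp a histone octamer can slide past a DNA end

# --- synthetic stand-in for the 601 positioning core -----------------------
# 147 bp, no A/T homopolymer of length >= 4, PmlI site at [19,25),
# MfeI site at [116,122). Not the published 601 sequence.
_CORE_147 = (
    "GCTCGAGCTACGGATCAGTCACGTGACTGGCACGACTAGCGATCCTGACGCATGCAGTCG"
    "GACTCGATCGGACTGCAGCTAGGATCGACGGTACGACTGGCATCGATCGGACGCAGCAAT"
    "TGCGATCGAGCTGACGGATCGCGACTG"
)
assert len(_CORE_147) == CORE_LEN

# deterministic linker background; free of PmlI/MfeI sites and of A/T runs
_LINKER_UNIT = "GCTAGCGACTGGCATCGACGGATCGCTGACGCATGCGGACTCAG"


class Enzyme:
    """A blunt/sticky cutter described by its recognition 6-mer and the
    upper-strand cut offset within the site."""

    def __init__(self, name: str, recognition: str, cut_offset_upper: int):
        if not (0 <= cut_offset_upper <= len(recognition)):
            raise ValueError("cut offset outside recognition site")
        self.name = name
        self.recognition = recognition.upper()
        self.cut_offset_upper = cut_offset_upper

    def __repr__(self) -> str:  # pragma: no cover
        return f"Enzyme({self.name}, {self.recognition}, cut@{self.cut_offset_upper})"


PMLI = Enzyme("PmlI", "CACGTG", 3)
MFEI = Enzyme("MfeI", "CAATTG", 1)


@dataclass(frozen=True)
class TractInsertion:
    """A poly(dA:dT) tract placed in a linker.

    ``side``: which linker ("up" or "down"); ``upper_strand_base``: A or T on
    the upper strand; ``gap_from_core``: bp of linker between the core edge
    and the tract (0 = adjacent, in which case 2 bp of the tract sit inside
    the 147 bp footprint).
    """

    side: str  # "up" | "down"
    upper_strand_base: str  # "A" | "T"
    length: int
    gap_from_core: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("up", "down"):
            raise ValueError("side must be 'up' or 'down'")
        if self.upper_strand_base not in ("A", "T"):
            raise ValueError("tract base must be A or T")
        if self.length < 1 or self.gap_from_core < 0:
            raise ValueError("invalid tract geometry")


@dataclass(frozen=True)
class ProbeSpec:
    upstream_linker: int
    downstream_linker: int
    tract_insertions: Tuple[TractInsertion, ...] = ()
    label_end: str = "upper_5prime"

    def __post_init__(self) -> None:
        if self.upstream_linker < 0 or self.downstream_linker < 0:
            raise ValueError("linker lengths must be >= 0")
        for ins in self.tract_insertions:
            linker = self.upstream_linker if ins.side == "up" else self.downstream_linker
            inside = 2 if ins.gap_from_core == 0 else 0
            if ins.gap_from_core + ins.length - inside > linker:
                raise ValueError(
                    f"tract ({ins.side}, len {ins.length}, gap {ins.gap_from_core}) "
                    f"does not fit in {linker} bp linker"
                )

    @property
    def core_variant(self) -> str:
        """'trimmed_145' when a core-adjacent tract donates 2 bp to the footprint."""
        return (
            "trimmed_145"
            if any(i.gap_from_core == 0 for i in self.tract_insertions)
            else "full_147"
        )


@dataclass(frozen=True)
class ProbeLayout:
    """A concrete probe: sequence, core footprint interval and enzyme sites."""

    sequence: str
    core: Tuple[int, int]  # 0-based half-open, always 147 bp wide
    sites: Tuple[Tuple[str, Tuple[int, int], int], ...]  # (enzyme, recognition, cut)
    overhang: int = 0  # bp of core hanging beyond a DNA end after sliding
    name: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def dyad(self) -> int:
        return (self.core[0] + self.core[1]) // 2


@dataclass(frozen=True)
class DigestionResult:
    enzyme: str
    cut: bool
    labeled_fragment_len: Optional[int]
    fragment_class: Optional[str]  # "nucleosomal" | "naked_dna"


@dataclass(frozen=True)
class RemodelingPrediction:
    remodeler: str  # "RSC" | "ISW1a"
    exit_side: str  # "up" | "down" | "blocked" | "none"
    outcome: str  # "slide" | "slide_plus_eviction_prone" | "inhibited" | "blocked_at_tract"
    stimulation_rank: int  # signed ordinal vs the tract-free control (0 = no change)


# --------------------------------------------------------------------------
# construction


def _linker_seq(length: int, reverse: bool = False) -> str:
    if length == 0:
        return ""
    unit = _LINKER_UNIT
    reps = (length // len(unit)) + 2
    seq = (unit * reps)
    # take from the end for the upstream linker so the core-adjacent context
    # is stable regardless of linker length
    return seq[-length:] if reverse else seq[:length]


def build_probe(spec: ProbeSpec, core_sequence: str = _CORE_147) -> ProbeLayout:
    """Assemble the probe sequence and layout from a spec.

    Total length is upstream_linker + 147 + downstream_linker. Tracts with
    gap 0 replace the outermost 2 bp of the core region (trimmed positioning
    sequence) plus the adjacent linker bases; tracts with a positive gap sit
    wholly in the linker.
    """
    if len(core_sequence) != CORE_LEN:
        raise ValueError(f"core sequence must be {CORE_LEN} bp")
    up, down = spec.upstream_linker, spec.downstream_linker
    length = up + CORE_LEN + down
    seq = list(_linker_seq(up, reverse=True) + core_sequence + _linker_seq(down))
    core = (up, up + CORE_LEN)

    occupied: List[Tuple[int, int]] = []
    for ins in spec.tract_insertions:
        inside = 2 if ins.gap_from_core == 0 else 0
        if ins.side == "up":
            t_end = up + inside - ins.gap_from_core
            t_start = t_end - ins.length
        else:
            t_start = up + CORE_LEN - inside + ins.gap_from_core
            t_end = t_start + ins.length
        if t_start < 0 or t_end > length:
            raise ValueError("tract insertion falls outside the probe")
        for s, e in occupied:
            if t_start < e and s < t_end:
                raise ValueError("overlapping tract insertions")
        occupied.append((t_start, t_end))
        seq[t_start:t_end] = ins.upper_strand_base * ins.length
        # keep the run maximal at exactly its programmed length
        for flank in (t_start - 1, t_end):
            if 0 <= flank < length and seq[flank] == ins.upper_strand_base:
                seq[flank] = "G"

    sequence = "".join(seq)
    sites = []
    for enz in (PMLI, MFEI):
        for m in re.finditer(enz.recognition, sequence):
            sites.append(
                (enz.name, (m.start(), m.end()), m.start() + enz.cut_offset_upper)
            )
    try:
        name = probe_name(spec)
    except ValueError:  # gapped-tract designs are described, not named
        name = ""
    return ProbeLayout(
        sequence=sequence, core=core, sites=tuple(sorted(sites, key=lambda s: s[2])),
        name=name,
    )


# --------------------------------------------------------------------------
# nomenclature

_TOKEN_RE = re.compile(r"^(\d+)(?:([AT])(\d+))?$")


def probe_name(spec: ProbeSpec) -> str:
    """Emit the ``<up>[A|T<len>]-NC-<down>[A|T<len>]`` name of a spec.

    Only core-adjacent tracts (gap 0) are part of the nomenclature; specs
    with gapped tracts raise, as those designs are described rather than
    named.
    """

    def token(linker: int, side: str) -> str:
        ins = [i for i in spec.tract_insertions if i.side == side]
        if not ins:
            return str(linker)
        if len(ins) > 1 or ins[0].gap_from_core != 0:
            raise ValueError("nomenclature covers a single core-adjacent tract per linker")
        return f"{linker}{ins[0].upper_strand_base}{ins[0].length}"

    return f"{token(spec.upstream_linker, 'up')}-NC-{token(spec.downstream_linker, 'down')}"


def parse_probe_name(name: str) -> ProbeSpec:
    """Parse a probe name back into its spec (inverse of :func:`probe_name`)."""
    parts = name.split("-NC-")
    if len(parts) != 2:
        raise ValueError(f"malformed probe name {name!r}: expected one '-NC-'")
    insertions: List[TractInsertion] = []
    linkers = []
    for part, side in zip(parts, ("up", "down")):
        m = _TOKEN_RE.match(part)
        if not m:
            raise ValueError(
                f"malformed probe name {name!r}: cannot parse token {part!r}"
            )
        linkers.append(int(m.group(1)))
        if m.group(2):
            insertions.append(
                TractInsertion(
                    side=side,
                    upper_strand_base=m.group(2),
                    length=int(m.group(3)),
                    gap_from_core=0,
                )
            )
    return ProbeSpec(
        upstream_linker=linkers[0],
        downstream_linker=linkers[1],
        tract_insertions=tuple(insertions),
    )


# --------------------------------------------------------------------------
# sliding and digestion


def slide_core(
    layout: ProbeLayout,
    mode: str,
    position: Optional[int] = None,
    beyond: int = 0,
) -> ProbeLayout:
    """Translate the 147 bp core footprint along the fixed DNA.

    Modes: ``flush_up`` / ``flush_down`` clamp the footprint to the DNA
    ends; ``to_position`` places the core start at ``position``;
    ``beyond_end`` slides the core ``beyond`` bp past the upstream end
    (at most 51 bp, the limit observed for remodeler-generated end-slid
    nucleosomes).
    """
    L = layout.length
    if mode == "flush_up":
        core = (0, CORE_LEN)
        over = 0
    elif mode == "flush_down":
        core = (L - CORE_LEN, L)
        over = 0
    elif mode == "to_position":
        if position is None:
            raise ValueError("to_position requires position")
        if position < 0 or position + CORE_LEN > L:
            raise ValueError("core would leave the DNA; use beyond_end")
        core = (position, position + CORE_LEN)
        over = 0
    elif mode == "beyond_end":
        if not (0 < beyond <= MAX_BEYOND_END):
            raise ValueError(f"beyond-end slide limited to 1..{MAX_BEYOND_END} bp")
        core = (-beyond, CORE_LEN - beyond)
        over = beyond
    else:
        raise ValueError(f"unknown slide mode {mode!r}")
    return replace(layout, core=core, overhang=over)


def digest(layout: ProbeLayout, enzyme: Enzyme, species: str = "nucleosome") -> DigestionResult:
    """Simulate single-enzyme digestion of the probe.

    On naked DNA every site is cut. On the nucleosome a site is cut iff its
    recognition interval does not overlap the core footprint. The labeled
    fragment length is the upper-strand cut coordinate (the label sits on
    the upper strand's 5' end at coordinate 0); it is classed "nucleosomal"
    when it fully contains the core footprint, otherwise "naked_dna".
    """
    if species not in ("nucleosome", "naked"):
        raise ValueError("species must be 'nucleosome' or 'naked'")
    hits = [s for s in layout.sites if s[0] == enzyme.name]
    if not hits:
        raise ValueError(f"no {enzyme.name} site present in probe {layout.name or '?'}")
    name, (r0, r1), cut_coord = hits[0]
    if species == "nucleosome":
        protected = r0 < layout.core[1] and layout.core[0] < r1
        if protected:
            return DigestionResult(enzyme.name, False, None, None)
        contains_core = layout.core[0] >= 0 and layout.core[1] <= cut_coord
        frag_class = "nucleosomal" if contains_core else "naked_dna"
    else:
        frag_class = "naked_dna"
    return DigestionResult(enzyme.name, True, cut_coord, frag_class)


# --------------------------------------------------------------------------
# remodeling-outcome rules


def _effective_tracts(spec: ProbeSpec, min_len: int = 6) -> list[TractInsertion]:
    """Tracts long enough to matter (5 bp tracts are inert for both remodelers)."""
    return [i for i in spec.tract_insertions if i.length >= min_len]


def _orientation_of(ins: TractInsertion) -> Orientation:
    """Orientation of a linker tract relative to the core, from geometry.

    Classified on the tract's linker-resident portion (relevant for gap-0
    tracts whose last 2 bp enter the footprint). Upstream tract: core to the
    right; downstream tract: core to the left.
    """
    # abstract axis: core at [100, 247); tract placed on the proper side
    if ins.side == "down":
        start = 247 + max(ins.gap_from_core, 1)
    else:
        start = 100 - max(ins.gap_from_core, 1) - ins.length
    t = Tract(chrom="", start=start, end=start + ins.length, base=ins.upper_strand_base)
    return classify_tract_orientation(t, (100, 247))


def predict_remodeling(spec: ProbeSpec, remodeler: str) -> RemodelingPrediction:
    """Rule-based prediction of the remodeling outcome on a probe.

    RSC: the tract-bearing linker is taken as exit DNA, so the core slides
    away from the tract, for either tract orientation; the orientation
    "core 5' of polyA" additionally promotes eviction; tracts adjacent to
    both linkers in the orientation "core 3' of polyA" block sliding to the
    DNA ends (the motor cannot track a polyA strand through the dyad);
    a core-tract gap of 40 bp or more weakens, and tract length <= 5
    abolishes, the stimulation.

    ISW1a: the longer linker is the entry DNA and the core slides toward
    it; a tract in the entry linker adjacent to the core (gap < 19 bp) with
    length >= 7 inhibits sliding, more strongly for "core 3' of polyA";
    tracts in the exit/distal linker, gapped tracts (19 or 40 bp) and 5 bp
    tracts do not inhibit (distal tracts even slightly stimulate).

    ``stimulation_rank`` is a signed ordinal relative to the tract-free
    control: positive = stimulated, negative = inhibited, 0 = no change.
    """
    if remodeler not in ("RSC", "ISW1a"):
        raise ValueError("remodeler must be 'RSC' or 'ISW1a'")
    tracts = _effective_tracts(spec)

    if remodeler == "RSC":
        if not tracts:
            return RemodelingPrediction("RSC", "none", "slide", 0)
        sides = {t.side for t in tracts}
        if len(sides) == 2:
            oris = {_orientation_of(t) for t in tracts}
            if oris == {Orientation.CORE_3PRIME_OF_POLYA}:
                return RemodelingPrediction("RSC", "blocked", "blocked_at_tract", 0)
            # both linkers carry tracts but at least one permissive
            # orientation: sliding reaches DNA ends, direction undetermined
            return RemodelingPrediction("RSC", "none", "slide", 2)
        (tract,) = (max(tracts, key=lambda t: t.length),) if len(tracts) > 1 else (tracts[0],)
        ori = _orientation_of(tract)
        outcome = (
            "slide_plus_eviction_prone"
            if ori is Orientation.CORE_5PRIME_OF_POLYA
            else "slide"
        )
        rank = 2
        if ori is Orientation.CORE_3PRIME_OF_POLYA:
            rank += 1  # strongest sliding stimulation
        if tract.gap_from_core >= 40 or tract.length == 7:
            rank -= 1  # weaker stimulation for distant or short tracts
        return RemodelingPrediction("RSC", tract.side, outcome, rank)

    # ISW1a
    up, down = spec.upstream_linker, spec.downstream_linker
    if up == down:
        entry = None
        exit_side = "none"
    else:
        entry = "up" if up > down else "down"
        exit_side = "down" if entry == "up" else "up"

    inhibitory = [
        t
        for t in tracts
        if t.gap_from_core < 19
        and t.length >= 7
        and (entry is None or t.side == entry)
    ]
    if inhibitory:
        worst = max(
            inhibitory,
            key=lambda t: (
                _orientation_of(t) is Orientation.CORE_3PRIME_OF_POLYA,
                t.length,
            ),
        )
        if worst.length >= 10:
            rank = -3 if _orientation_of(worst) is Orientation.CORE_3PRIME_OF_POLYA else -2
        else:
            rank = -1  # 7 bp tract: weak inhibition
        return RemodelingPrediction("ISW1a", exit_side, "inhibited", rank)
    # distal-linker or far-gapped tracts: no inhibition, slight stimulation
    stim = 1 if tracts else 0
    return RemodelingPrediction("ISW1a", exit_side, "slide", stim)


def mirror_spec(spec: ProbeSpec) -> ProbeSpec:
    """Mirror a probe through the nucleosome two-fold axis.

    Equivalent to reverse-complementing the probe: linkers swap sides and
    tract upper-strand bases complement (A <-> T).
    """
    return ProbeSpec(
        upstream_linker=spec.downstream_linker,
        downstream_linker=spec.upstream_linker,
        tract_insertions=tuple(
            TractInsertion(
                side="up" if i.side == "down" else "down",
                upper_strand_base="T" if i.upper_strand_base == "A" else "A",
                length=i.length,
                gap_from_core=i.gap_from_core,
            )
            for i in spec.tract_insertions
        ),
        label_end=spec.label_end,
    )
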