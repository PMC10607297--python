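"""Probe construction, nomenclature, sliding, digestion and the
remodeler-directionality rules."""

import pytest

from nucshift.probes import (
    CORE_LEN,
    MFEI,
    PMLI,
    ProbeSpec,
    TractInsertion,
    build_probe,
    digest,
    mirror_spec,
    parse_probe_name,
    predict_remodeling,
    probe_name,
    slide_core,
)
from nucshift.tracts import scan_tracts

from conftest import PANEL_NAMES


class TestConstruction:
    def test_control_probe_is_217_bp(self):
        layout = build_probe(parse_probe_name("0-NC-70"))
        assert layout.length == 217

    def test_centered_probe_core_interval(self):
        layout = build_probe(parse_probe_name("35-NC-35"))
        assert layout.length == 217
        assert layout.core == (35, 182)
        assert layout.dyad == 108

    def test_adjacent_tract_reaches_2bp_into_core(self):
        layout = build_probe(parse_probe_name("0-NC-70A15"))
        assert layout.length == 217
        assert layout.name == "0-NC-70A15"
        tracts = scan_tracts(layout.sequence, 6)
        assert [(t.start, t.end, t.base) for t in tracts] == [(145, 160, "A")]
        # 2 bp of the tract inside the 147 bp footprint
        assert tracts[0].start == layout.core[1] - 2

    def test_tract_exceeding_linker_rejected(self):
        with pytest.raises(ValueError):
            ProbeSpec(
                upstream_linker=0,
                downstream_linker=10,
                tract_insertions=(TractInsertion("down", "A", 15, 0),),
            )

    def test_overlapping_insertions_rejected(self):
        spec = ProbeSpec(
            upstream_linker=0,
            downstream_linker=70,
            tract_insertions=(
                TractInsertion("down", "A", 15, 0),
                TractInsertion("down", "T", 15, 5),
            ),
        )
        with pytest.raises(ValueError):
            build_probe(spec)

    def test_every_panel_probe_has_unique_enzyme_sites(self):
        for name in PANEL_NAMES:
            layout = build_probe(parse_probe_name(name))
            enzymes = [s[0] for s in layout.sites]
            assert sorted(enzymes) == ["MfeI", "PmlI"], name
            up, down = parse_probe_name(name).upstream_linker, parse_probe_name(name).downstream_linker
            assert layout.length == up + CORE_LEN + down

    def test_programmed_tracts_are_the_only_tracts(self):
        for name in PANEL_NAMES:
            spec = parse_probe_name(name)
            layout = build_probe(spec)
            found = scan_tracts(layout.sequence, 6)
            assert len(found) == len(spec.tract_insertions), name
            assert all(t.length == 15 for t in found), name


class TestNomenclature:
    @pytest.mark.parametrize("name", PANEL_NAMES)
    def test_round_trip(self, name):
        assert probe_name(parse_probe_name(name)) == name

    def test_token_fields(self):
        spec = parse_probe_name("35-NC-35T15")
        assert spec.upstream_linker == 35 and spec.downstream_linker == 35
        (ins,) = spec.tract_insertions
        assert (ins.side, ins.upper_strand_base, ins.length, ins.gap_from_core) == (
            "down", "T", 15, 0,
        )

    def test_upstream_tract_token(self):
        spec = ProbeSpec(35, 35, (TractInsertion("up", "A", 15, 0),))
        assert probe_name(spec) == "35A15-NC-35"

    @pytest.mark.parametrize("bad", ["35-35", "NC-35", "35-NC-35X15", "35A-NC-35"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_probe_name(bad)

    def test_core_variant_reflects_adjacent_tracts(self):
        assert parse_probe_name("0-NC-70").core_variant == "full_147"
        assert parse_probe_name("0-NC-70A15").core_variant == "trimmed_145"


class TestSliding:
    def test_flush_clamps(self):
        layout = build_probe(parse_probe_name("35-NC-35"))
        assert slide_core(layout, "flush_up").core == (0, 147)
        assert slide_core(layout, "flush_down").core == (70, 217)

    def test_beyond_end_limit(self):
        layout = build_probe(parse_probe_name("35-NC-35"))
        slid = slide_core(layout, "beyond_end", beyond=51)
        assert slid.core == (-51, 96) and slid.overhang == 51
        with pytest.raises(ValueError):
            slide_core(layout, "beyond_end", beyond=52)

    def test_to_position_bounds(self):
        layout = build_probe(parse_probe_name("35-NC-35"))
        assert slide_core(layout, "to_position", position=10).core == (10, 157)
        with pytest.raises(ValueError):
            slide_core(layout, "to_position", position=80)


class TestDigestion:
    def test_centered_core_protects_pmli(self):
        layout = build_probe(parse_probe_name("35-NC-35"))
        res = digest(layout, PMLI)
        assert not res.cut

    def test_flush_up_mfei_cuts_152bp_nucleosomal_fragment(self):
        layout = slide_core(build_probe(parse_probe_name("35-NC-35")), "flush_up")
        res = digest(layout, MFEI)
        assert res.cut and res.labeled_fragment_len == 152
        assert res.fragment_class == "nucleosomal"

    def test_naked_pmli_cuts_57bp_fragment(self):
        layout = build_probe(parse_probe_name("35-NC-35"))
        res = digest(layout, PMLI, species="naked")
        assert res.cut and res.labeled_fragment_len == 57
        assert res.fragment_class == "naked_dna"

    def test_flush_down_pmli_cuts_57bp_naked_class(self):
        layout = slide_core(build_probe(parse_probe_name("35-NC-35")), "flush_down")
        res = digest(layout, PMLI)
        assert res.cut and res.labeled_fragment_len == 57
        assert res.fragment_class == "naked_dna"

    def test_missing_site_is_an_error(self):
        layout = build_probe(parse_probe_name("35-NC-35"))
        from nucshift.probes import Enzyme

        with pytest.raises(ValueError, match="EcoRI"):
            digest(layout, Enzyme("EcoRI", "GAATTC", 1))


class TestDirectionalityConsistency:
    """Sliding predicted from the tract must reproduce the restriction
    accessibility matrix: upstream mobilization leaves PmlI protected and
    MfeI cut; downstream mobilization the reverse."""

    @pytest.mark.parametrize(
        "name",
        ["35-NC-35T15", "35-NC-35A15", "35A15-NC-35", "35T15-NC-35"],
    )
    def test_rsc_slide_matches_accessibility(self, name):
        spec = parse_probe_name(name)
        pred = predict_remodeling(spec, "RSC")
        assert pred.outcome in ("slide", "slide_plus_eviction_prone")
        (ins,) = spec.tract_insertions
        assert pred.exit_side == ins.side  # exit via the tract-bearing linker
        layout = build_probe(spec)
        slid = slide_core(layout, "flush_up" if pred.exit_side == "down" else "flush_down")
        pmli = digest(slid, PMLI)
        mfei = digest(slid, MFEI)
        if pred.exit_side == "down":  # core moved upstream
            assert not pmli.cut and mfei.cut
        else:  # core moved downstream
            assert pmli.cut and not mfei.cut


class TestRemodelingRules:
    def test_rsc_exits_via_tract_linker_both_orientations(self):
        for name, side in [
            ("35-NC-35T15", "down"), ("35-NC-35A15", "down"),
            ("35A15-NC-35", "up"), ("35T15-NC-35", "up"),
            ("0-NC-70A15", "down"), ("70T15-NC-0", "up"),
        ]:
            pred = predict_remodeling(parse_probe_name(name), "RSC")
            assert pred.exit_side == side, name

    def test_rsc_eviction_prone_for_core_5prime_of_polyA(self):
        assert (
            predict_remodeling(parse_probe_name("0-NC-70A15"), "RSC").outcome
            == "slide_plus_eviction_prone"
        )
        assert predict_remodeling(parse_probe_name("0-NC-70T15"), "RSC").outcome == "slide"

    def test_rsc_blocked_by_double_core3prime_tracts(self):
        pred = predict_remodeling(parse_probe_name("70A15-NC-70T15"), "RSC")
        assert pred.outcome == "blocked_at_tract" and pred.exit_side == "blocked"
        # opposite orientation slides out to the DNA ends
        pred2 = predict_remodeling(parse_probe_name("70T15-NC-70A15"), "RSC")
        assert pred2.outcome == "slide"

    def test_rsc_short_tract_inert_and_distance_demotes(self):
        short = ProbeSpec(0, 70, (TractInsertion("down", "A", 5, 0),))
        assert predict_remodeling(short, "RSC").stimulation_rank == 0
        near = parse_probe_name("0-NC-70T15")
        far = ProbeSpec(0, 70, (TractInsertion("down", "T", 15, 40),))
        assert (
            predict_remodeling(far, "RSC").stimulation_rank
            < predict_remodeling(near, "RSC").stimulation_rank
        )

    def test_isw1a_inhibited_only_by_entry_linker_tract(self):
        # tract in the (longer) entry linker, adjacent to the core
        entry = predict_remodeling(parse_probe_name("0-NC-70T15"), "ISW1a")
        assert entry.outcome == "inhibited"
        # strongest inhibition for core 3' of polyA
        weaker = predict_remodeling(parse_probe_name("0-NC-70A15"), "ISW1a")
        assert weaker.outcome == "inhibited"
        assert entry.stimulation_rank < weaker.stimulation_rank < 0
        # tract in the short exit linker: no inhibition, slight stimulation
        distal_spec = ProbeSpec(70, 30, (TractInsertion("down", "T", 15, 0),))
        distal = predict_remodeling(distal_spec, "ISW1a")
        assert distal.outcome == "slide" and distal.stimulation_rank > 0
        assert distal.exit_side == "down"  # entry is the long upstream linker

    def test_isw1a_gap_and_length_dependence(self):
        base = lambda gap, ln: ProbeSpec(
            0, 70, (TractInsertion("down", "T", ln, gap),)
        )
        assert predict_remodeling(base(0, 15), "ISW1a").outcome == "inhibited"
        assert predict_remodeling(base(19, 15), "ISW1a").outcome == "slide"
        assert predict_remodeling(base(40, 15), "ISW1a").outcome == "slide"
        assert predict_remodeling(base(0, 5), "ISW1a").stimulation_rank == 0
        assert predict_remodeling(base(0, 7), "ISW1a").stimulation_rank == -1
        assert predict_remodeling(base(0, 10), "ISW1a").outcome == "inhibited"

    def test_isw1a_equal_linkers_no_tract_exit_undetermined(self):
        pred = predict_remodeling(parse_probe_name("35-NC-35"), "ISW1a")
        assert pred.exit_side == "none" and pred.outcome == "slide"

    @pytest.mark.parametrize("name", PANEL_NAMES)
    @pytest.mark.parametrize("remodeler", ["RSC", "ISW1a"])
    def test_two_fold_symmetry(self, name, remodeler):
        """Mirroring the probe through the nucleosome dyad (reverse
        complement: linkers swap, A<->T) mirrors the prediction."""
        spec = parse_probe_name(name)
        pred = predict_remodeling(spec, remodeler)
        mirrored = predict_remodeling(mirror_spec(spec), remodeler)
        flip = {"up": "down", "down": "up", "none": "none", "blocked": "blocked"}
        assert mirrored.exit_side == flip[pred.exit_side]
        assert mirrored.outcome == pred.outcome
        assert mirrored.stimulation_rank == pred.stimulation_rank
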