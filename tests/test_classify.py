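import pytest

from brexmap.classify import catalog_effectors, classify_locus, summarize_cohort
from brexmap.model import Architecture, DomainHitRow
from conftest import make_locus


def _arch_for(locus, domains_by_index):
    """Architectures for make_locus gene ids g0..gn."""
    archs = {}
    for i, domains in domains_by_index.items():
        pos, hits = 0, []
        for d in domains:
            hits.append(DomainHitRow(f"g{i}", d, pos, pos + 60, 60.0))
            pos += 75
        archs[f"g{i}"] = Architecture(f"g{i}", hits)
    return archs


class TestDecisionList:
    def test_type1_complete_six_core(self):
        call = classify_locus(make_locus(["BrxC", "BrxX", "PglZ", "BrxA", "iSTAND", "BrxL"]))
        assert (call.system, call.subtype, call.completeness) == ("BREX", "Type-1", "complete")
        assert call.family_group == "Type-1-family"
        assert "BrxB" in call.components_present and "iSTAND" not in call.components_present

    def test_type3_br_by_pglz_presence(self):
        call = classify_locus(
            make_locus(["DUF499_ATPase", "BR_MTase", "BrxHII", "PglZ", "iSTAND"])
        )
        assert (call.system, call.subtype) == ("BR", "Type-3 BR")
        assert call.completeness == "complete"

    def test_lone_anchor_discarded(self):
        call = classify_locus(make_locus(["BrxC"]))
        assert call.system == "unassigned" and call.subtype == "NA"
        assert call.completeness == "discarded"

    def test_type4_paps_reductase_replaces_mtase(self):
        call = classify_locus(
            make_locus(["BrxC", "PglZ", "BrxP", "DUF4007", "BrxL", "CysDesulf"])
        )
        assert call.subtype == "Type-4" and call.completeness == "complete"

    def test_brc_seven_components(self):
        call = classify_locus(
            make_locus(
                ["PglZ", "BrxC", "STAND_active", "DUF4007", "HerA_FtsK", "GNAT", "TGT"],
                flags_by_index={0: ("PglZ:minimal",)},
            )
        )
        assert (call.system, call.subtype) == ("BRC", "BRC")
        assert call.completeness == "complete"

    def test_type2_by_pglw_or_brxd_brxhi(self):
        by_pglw = classify_locus(make_locus(["PglW", "BrxC", "BrxX", "PglZ", "BrxD", "BrxHI"]))
        assert by_pglw.subtype == "Type-2"
        by_pair = classify_locus(make_locus(["BrxC", "BrxX", "PglZ", "BrxD", "BrxHI"]))
        assert by_pair.subtype == "Type-2"

    def test_type2_br_by_duf3780_or_hkd_flag(self):
        by_duf = classify_locus(make_locus(["DUF499_ATPase", "BR_MTase", "BrxHII", "DUF3780"]))
        assert by_duf.subtype == "Type-2 BR"
        by_flag = classify_locus(
            make_locus(["DUF499_ATPase", "BR_MTase", "BrxHII"],
                       flags_by_index={2: ("helicase:HKD_fused",)})
        )
        assert by_flag.subtype == "Type-2 BR"
        assert by_flag.completeness == "partial"  # DUF3780 itself absent

    def test_type1_br_is_br_fallback(self):
        call = classify_locus(make_locus(["DUF499_ATPase", "BR_MTase", "BrxHII"],
                                         flags_by_index={2: ("helicase:REase_fused",)}))
        assert call.subtype == "Type-1 BR" and call.completeness == "complete"

    def test_type5_extra_helicase_and_family_collapse(self):
        call = classify_locus(
            make_locus(["BrxC", "BrxX", "PglZ", "BrxA", "iSTAND", "BrxL", "BrxHII"])
        )
        assert call.subtype == "Type-5"
        assert call.family_group == "Type-1-family"

    def test_type6_wins_over_type5_with_review_flag(self):
        call = classify_locus(
            make_locus(["BrxC", "BrxX", "PglZ", "BrxA", "iSTAND", "BrxL", "BrxE", "BrxHII"])
        )
        assert call.subtype == "Type-6"
        assert call.family_group == "Type-1-family"
        assert "type6_with_extra_helicase" in call.review_flags

    def test_type3_brxf_alias(self):
        call = classify_locus(
            make_locus(["BrxC", "BrxXI", "PglZ", "iSTAND", "BrxHII"])
        )
        assert call.subtype == "Type-3"
        assert "BrxF" in call.components_present

    def test_partial_needs_anchor_and_three_components(self):
        call = classify_locus(
            make_locus(["BrxC", "BrxX", "PglZ", "BrxA"], anchor_index=0)
        )
        assert call.subtype == "Type-1" and call.completeness == "partial"
        assert call.missing_core == frozenset({"BrxB", "BrxL"})

    def test_every_locus_gets_exactly_one_call(self):
        for comps in (["unknown"], ["HNH"], ["BrxC", "PglZ"], []):
            call = classify_locus(make_locus(comps or ["unknown"]))
            assert call.system in {"BREX", "BR", "BRC", "unassigned"}


class TestEffectorCatalog:
    def test_type1_with_hkd_brxl(self):
        locus = make_locus(["BrxC", "BrxX", "PglZ", "BrxA", "iSTAND", "BrxL"],
                           flags_by_index={5: ("BrxL:HKD",)})
        call = classify_locus(locus)
        archs = _arch_for(locus, {
            2: ["iSwi2Snf2", "helical_linker", "PglZ_core"],
            5: ["SIGMA_HTH", "OB_fold", "MCM_ATPase", "HKD"],
        })
        effectors = catalog_effectors(locus, call, archs)
        roles = {(e.effector_domain, e.role, e.provenance) for e in effectors}
        assert ("PglZ_core", "primary", "core_component_fusion") in roles
        assert ("HKD", "auxiliary", "core_component_fusion") in roles
        assert sum(1 for e in effectors if e.role == "primary") == 1

    def test_type1_br_hepn_backup_and_rease_primary(self):
        locus = make_locus(["DUF499_ATPase", "BR_MTase", "BrxHII"],
                           flags_by_index={0: ("DUF499:HEPN_fused",),
                                           2: ("helicase:REase_fused",)})
        call = classify_locus(locus)
        archs = _arch_for(locus, {
            0: ["HEPN", "AAA_ATPase", "wHTH", "alphabeta_core", "wHTH", "RRM"],
            2: ["TUDOR", "Swi2Snf2_helicase", "REase"],
        })
        effectors = catalog_effectors(locus, call, archs)
        roles = {(e.effector_domain, e.role) for e in effectors}
        assert ("REase", "primary") in roles
        assert ("HEPN", "backup") in roles
        # the primary REase instance is not recounted as auxiliary
        assert ("REase", "auxiliary") not in roles

    def test_adjacent_old_abc_toprim_is_backup_dyad(self):
        locus = make_locus(["BrxC", "BrxX", "PglZ", "OLD_ABC", "TOPRIM"])
        call = classify_locus(locus)
        archs = _arch_for(locus, {3: ["OLD_ABC"], 4: ["TOPRIM"]})
        effectors = catalog_effectors(locus, call, archs)
        by_domain = {e.effector_domain: e.role for e in effectors}
        assert by_domain["OLD_ABC"] == "backup"
        assert by_domain["TOPRIM"] == "backup"

    def test_toprim_without_old_abc_is_auxiliary(self):
        locus = make_locus(["BrxC", "BrxX", "PglZ", "TOPRIM"])
        call = classify_locus(locus)
        archs = _arch_for(locus, {3: ["TOPRIM"]})
        effectors = catalog_effectors(locus, call, archs)
        by_domain = {e.effector_domain: e.role for e in effectors}
        assert by_domain["TOPRIM"] == "auxiliary"

    def test_pglz_is_primary_whenever_present_in_brex(self):
        for comps in (["BrxC", "BrxX", "PglZ"], ["BrxC", "PglZ", "BrxP", "DUF4007"]):
            locus = make_locus(comps)
            call = classify_locus(locus)
            effectors = catalog_effectors(locus, call, {})
            primaries = [e for e in effectors if e.role == "primary"]
            assert len(primaries) == 1 and primaries[0].effector_domain == "PglZ_core"

    def test_brc_has_no_primary(self):
        locus = make_locus(
            ["PglZ", "BrxC", "STAND_active", "DUF4007", "HerA_FtsK", "GNAT", "TGT"]
        )
        call = classify_locus(locus)
        assert not [e for e in catalog_effectors(locus, call, {}) if e.role == "primary"]


class TestSummarize:
    def test_counts_match_truth_on_noiseless_cohort(self, small_cohort, small_bundle):
        report = small_bundle["report"]
        truth_counts = {}
        for lt in small_cohort["truth"]["loci"]:
            truth_counts[lt["subtype"]] = truth_counts.get(lt["subtype"], 0) + 1
        assert report["subtype_counts"] == dict(sorted(truth_counts.items()))

    def test_empty_input_gives_zeroed_report(self):
        report = summarize_cohort([], [])
        assert report["n_loci"] == 0
        assert report["subtype_counts"] == {}
        assert report["discarded"] == []
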