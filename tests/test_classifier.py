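import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secloc.categories import LocationCategory as C
from secloc.categories import SecretionTier
from secloc.classifier import (
    IncompleteBundleError,
    classify,
    count_secretion_votes,
    is_membrane_by_tmhmm,
    wolf_top_component,
)
from secloc.predictor_io import GpiClass, PredictionBundle, Tool, ToolVerdict
from secloc.records import ProteinRecord
from secloc.sequence_io import parse_curated_comment


def make_bundle(
    pid="P1",
    sp3=False,
    sp4=False,
    phobius=False,
    targetp="OTHER",
    wolf="cyto",
    helices=(),
    gpi=GpiClass.NONE,
):
    verdicts = {
        Tool.SIGNALP3: ToolVerdict(Tool.SIGNALP3, pid, signal_peptide=sp3),
        Tool.SIGNALP4: ToolVerdict(Tool.SIGNALP4, pid, signal_peptide=sp4),
        Tool.PHOBIUS: ToolVerdict(Tool.PHOBIUS, pid, signal_peptide=phobius),
        Tool.TARGETP: ToolVerdict(Tool.TARGETP, pid, targetp_loc=targetp),
        Tool.WOLFPSORT: ToolVerdict(
            Tool.WOLFPSORT, pid, wolf_top_label=wolf, wolf_scores=((wolf, 25.0),)
        ),
        Tool.TMHMM: ToolVerdict(Tool.TMHMM, pid, tm_helices=tuple(helices)),
        Tool.FRAGANCHOR: ToolVerdict(Tool.FRAGANCHOR, pid, gpi_class=gpi),
    }
    return PredictionBundle(pid, verdicts)


def make_record(pid="P1", curated=None, reviewed=None, length=200):
    locations = parse_curated_comment(curated) if curated else []
    return ProteinRecord(
        accession=pid,
        sequence="M" + "A" * (length - 1),
        reviewed=bool(curated) if reviewed is None else reviewed,
        curated_locations=locations,
    )


# ---------------------------------------------------------------------------
# an independently written truth table for the full cascade
# ---------------------------------------------------------------------------

_ORACLE_WOLF5 = {
    "cyto": C.CYTOPLASM,
    "cysk": C.CYTOSKELETON,
    "golg": C.GOLGI_LUMEN,
    "lyso": C.LYSOSOME,
    "nucl": C.NUCLEAR_NONMEMBRANE,
    "pero": C.PEROXISOME,
    "plas": C.PLASMA_MEMBRANE,
    "vacu": C.VACUOLE_NONMEMBRANE,
}
_ORACLE_SPLIT = {
    C.GOLGI_LUMEN: C.GOLGI_MEMBRANE,
    C.NUCLEAR_NONMEMBRANE: C.NUCLEAR_MEMBRANE,
    C.VACUOLE_NONMEMBRANE: C.VACUOLE_MEMBRANE,
}


def oracle(curated, sp4, phobius, targetp, wolf, helices, kdel, sp3, frag_hp):
    """Brute-force expectation for category and tier."""
    if curated is not None:
        tier = SecretionTier.CURATED_SECRETED if curated is C.SECRETED else None
        return curated, tier
    comp = "E.R." if wolf.startswith("E.R.") else wolf.split("_")[0]
    tm = any(start > 70 for start, _ in helices)
    votes = sum([sp4, phobius, targetp == "S", comp == "extr"])
    if votes >= 1 and not tm and not kdel:
        if sp3 and frag_hp:
            return C.GPI_ANCHORED, None
        tier = (
            SecretionTier.HIGHLY_LIKELY
            if votes >= 3
            else SecretionTier.LIKELY
            if votes == 2
            else SecretionTier.WEAKLY_LIKELY
        )
        return C.SECRETED, tier
    if targetp == "M" and comp == "mito":
        return (C.MITO_MEMBRANE if tm else C.MITO_NONMEMBRANE), None
    if comp == "E.R." or (sp4 and kdel):
        return (C.ER_MEMBRANE if tm else C.ER_LUMEN), None
    if comp in _ORACLE_WOLF5:
        cat = _ORACLE_WOLF5[comp]
        if tm and cat in _ORACLE_SPLIT:
            cat = _ORACLE_SPLIT[cat]
        return cat, None
    if tm:
        return C.OTHER_MEMBRANE, None
    return C.UNKNOWN, None


class TestVotesAndMembrane:
    def test_four_positive_votes(self):
        b = make_bundle(sp4=True, phobius=True, targetp="S", wolf="extr")
        assert count_secretion_votes(b) == 4

    def test_wolf_label_must_be_extr_component(self):
        b = make_bundle(sp4=True, phobius=True, targetp="S", wolf="nucl")
        assert count_secretion_votes(b) == 3
        b = make_bundle(wolf="extr_plas")
        assert count_secretion_votes(b) == 1  # dual label, first component wins

    def test_all_negative(self):
        assert count_secretion_votes(make_bundle()) == 0

    def test_missing_voting_tool_strict_vs_lenient(self):
        b = make_bundle(sp4=True, phobius=True, targetp="S", wolf="extr")
        b.verdicts.pop(Tool.PHOBIUS)
        with pytest.raises(IncompleteBundleError, match="phobius"):
            count_secretion_votes(b, "strict")
        with pytest.warns(UserWarning, match="phobius"):
            assert count_secretion_votes(b, "lenient") == 3

    @pytest.mark.parametrize(
        "helices,expected",
        [((), False), (((10, 30),), False), (((10, 30), (100, 122)), True)],
    )
    def test_nterm_helices_do_not_make_a_membrane_protein(self, helices, expected):
        assert is_membrane_by_tmhmm(make_bundle(helices=helices)) is expected

    def test_helix_beyond_sequence_length_is_an_error(self):
        with pytest.raises(ValueError, match="beyond"):
            is_membrane_by_tmhmm(make_bundle(helices=((100, 122),)), length=110)

    def test_er_label_not_split_on_dots(self):
        assert wolf_top_component("E.R.") == "E.R."
        assert wolf_top_component("extr_plas") == "extr"


class TestCascadeExamples:
    def test_three_votes_no_exclusions_is_highly_likely_secreted(self):
        a = classify(
            make_record(),
            make_bundle(sp4=True, phobius=True, targetp="S", wolf="nucl"),
            False,
        )
        assert a.category is C.SECRETED
        assert a.tier is SecretionTier.HIGHLY_LIKELY
        assert a.evidence == "predicted"

    def test_transmembrane_helix_blocks_secretion(self):
        a = classify(
            make_record(),
            make_bundle(
                sp4=True, phobius=True, targetp="S", wolf="extr",
                helices=((100, 122),),
            ),
            False,
        )
        assert a.category is C.OTHER_MEMBRANE
        assert a.tier is None

    def test_er_retention_signal_blocks_secretion(self):
        a = classify(
            make_record(),
            make_bundle(sp4=True, phobius=True, targetp="S", wolf="extr"),
            True,
        )
        assert a.category is C.ER_LUMEN

    def test_mito_requires_both_tools(self):
        a = classify(make_record(), make_bundle(targetp="M", wolf="mito"), False)
        assert a.category is C.MITO_NONMEMBRANE
        a = classify(make_record(), make_bundle(targetp="M", wolf="cyto"), False)
        assert a.category is C.CYTOPLASM
        a = classify(
            make_record(),
            make_bundle(targetp="M", wolf="mito", helices=((100, 122),)),
            False,
        )
        assert a.category is C.MITO_MEMBRANE

    def test_gpi_anchor_route(self):
        a = classify(
            make_record(),
            make_bundle(
                sp3=True, sp4=True, phobius=True, targetp="S", wolf="extr",
                gpi=GpiClass.HIGHLY_PROBABLE,
            ),
            False,
        )
        assert a.category is C.GPI_ANCHORED
        assert a.gpi_anchored

    def test_gpi_threshold_is_configurable(self):
        bundle = make_bundle(
            sp3=True, sp4=True, phobius=True, targetp="S", wolf="extr",
            gpi=GpiClass.PROBABLE,
        )
        a = classify(make_record(), bundle, False)
        assert a.category is C.SECRETED  # PROBABLE below the default threshold
        a = classify(
            make_record(), bundle, False, gpi_threshold=GpiClass.PROBABLE
        )
        assert a.category is C.GPI_ANCHORED

    def test_curated_annotation_overrides_predictions(self):
        a = classify(
            make_record(curated="Secreted."), make_bundle(), False
        )
        assert a.category is C.SECRETED
        assert a.tier is SecretionTier.CURATED_SECRETED
        assert a.evidence == "curated"

    def test_unreviewed_curation_ignored_unless_relaxed(self):
        rec = make_record(curated="Nucleus.", reviewed=False)
        assert classify(rec, make_bundle(), False).category is C.CYTOPLASM
        a = classify(rec, make_bundle(), False, honor_unreviewed=True)
        assert a.category is C.NUCLEAR_NONMEMBRANE

    def test_multi_location_uses_precedence_and_keeps_trace(self):
        rec = make_record(curated="Nucleus. Secreted.")
        a = classify(rec, make_bundle(), False)
        assert a.category is C.SECRETED
        assert any(t.startswith("curated_multi:") for t in a.rule_trace)

    def test_strict_mode_names_missing_tools(self):
        bundle = make_bundle()
        bundle.verdicts.pop(Tool.TMHMM)
        with pytest.raises(IncompleteBundleError, match="tmhmm"):
            classify(make_record(), bundle, False)

    def test_membrane_flag_matches_category(self):
        a = classify(make_record(), make_bundle(wolf="plas"), False)
        assert a.category is C.PLASMA_MEMBRANE and a.is_membrane
        a = classify(make_record(), make_bundle(wolf="cyto"), False)
        assert not a.is_membrane


class TestDecisionTableOracle:
    def test_cascade_equals_brute_force_truth_table(self):
        """Exhaustive cross-product of verdict states matches the oracle."""
        wolf_labels = [
            "extr", "mito", "E.R.", "cyto", "cysk", "golg", "lyso", "nucl",
            "pero", "plas", "vacu", "extr_plas",
        ]
        helix_states = [(), ((10, 30),), ((100, 122),)]
        curated_states = [None, C.SECRETED, C.CYTOPLASM]
        curated_text = {C.SECRETED: "Secreted.", C.CYTOPLASM: "Cytoplasm."}
        n = 0
        for sp4, phobius, targetp, wolf, helices, kdel, curated, sp3, frag in (
            itertools.product(
                [False, True],
                [False, True],
                ["S", "M", "OTHER"],
                wolf_labels,
                helix_states,
                [False, True],
                curated_states,
                [False, True],
                [GpiClass.NONE, GpiClass.HIGHLY_PROBABLE],
            )
        ):
            record = make_record(
                curated=curated_text.get(curated), length=200
            )
            bundle = make_bundle(
                sp3=sp3, sp4=sp4, phobius=phobius, targetp=targetp,
                wolf=wolf, helices=helices, gpi=frag,
            )
            got = classify(record, bundle, kdel)
            want_cat, want_tier = oracle(
                curated, sp4, phobius, targetp, wolf, helices, kdel,
                sp3, frag is GpiClass.HIGHLY_PROBABLE,
            )
            assert (got.category, got.tier) == (want_cat, want_tier), (
                sp4, phobius, targetp, wolf, helices, kdel, curated, sp3, frag
            )
            n += 1
        assert n == 2 * 2 * 3 * 12 * 3 * 2 * 3 * 2 * 2


class TestInvariants:
    def test_determinism_of_category_and_trace(self):
        rec = make_record()
        bundle = make_bundle(sp4=True, phobius=True, targetp="S", wolf="extr")
        first = classify(rec, bundle, False)
        second = classify(rec, bundle, False)
        assert first.category is second.category
        assert first.rule_trace == second.rule_trace
        assert first.rule_trace  # never empty

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        base=st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
        extra=st.integers(0, 3),
    )
    def test_more_votes_never_lower_the_tier(self, base, extra):
        order = [
            SecretionTier.NOT_SECRETED,
            SecretionTier.WEAKLY_LIKELY,
            SecretionTier.LIKELY,
            SecretionTier.HIGHLY_LIKELY,
        ]

        def tier_of(flags):
            sp4, phob, tps, wext = flags
            a = classify(
                make_record(),
                make_bundle(
                    sp4=sp4, phobius=phob,
                    targetp="S" if tps else "OTHER",
                    wolf="extr" if wext else "pero",
                ),
                False,
            )
            return a.tier if a.category is C.SECRETED else SecretionTier.NOT_SECRETED

        flags = list(base)
        lower = tier_of(flags)
        upgraded = list(flags)
        for i in range(4):
            if extra and not upgraded[i]:
                upgraded[i] = True
                extra -= 1
        assert order.index(tier_of(upgraded)) >= order.index(lower)

    def test_no_secretion_tier_on_membrane_categories(self, noiseless_dataset):
        from secloc.classifier import classify_all

        assignments = classify_all(
            noiseless_dataset.records, noiseless_dataset.bundles()
        )
        for a in assignments:
            if a.is_membrane:
                assert a.tier is None
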