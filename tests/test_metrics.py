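import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secloc.categories import LocationCategory as C
from secloc.metrics import (
    ConfusionMatrix,
    UndefinedMetricError,
    build_benchmark,
    compile_rule,
    confusion,
    evaluate_rule,
    load_reference_counts,
    mcc,
    metric_set,
    sensitivity,
    specificity,
)
from secloc.records import ProteinRecord
from secloc.sequence_io import parse_curated_comment
from secloc.simulate import SimulationConfig, generate, truth_benchmark


def make_record(acc, curated, *, reviewed=True, length=100, fragment=False,
                start="M"):
    return ProteinRecord(
        accession=acc,
        sequence=start + "A" * (length - 1),
        reviewed=reviewed,
        is_fragment=fragment,
        curated_locations=parse_curated_comment(curated) if curated else [],
    )


class TestConfusionAndMetrics:
    def test_enumerated_counts(self):
        universe = {f"P{i}" for i in range(10)}
        actual = {"P0", "P1", "P2", "P3"}
        predicted = {"P0", "P1", "P2", "P9"}
        cm = confusion(predicted, actual, universe)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (3, 1, 1, 5)

    def test_perfect_and_empty_predictions(self):
        universe = {"A", "B"}
        cm = confusion(universe, universe, universe)
        assert cm.fp == cm.fn == 0
        cm = confusion(set(), {"A"}, universe)
        assert cm.tp == cm.fp == 0

    def test_predicted_outside_universe_is_an_error(self):
        with pytest.raises(ValueError, match="predicted"):
            confusion({"X"}, {"A"}, {"A", "B"})

    @pytest.mark.parametrize(
        "tp,fn,expected", [(930, 940, 49.7), (5024, 700, 87.8), (5350, 374, 93.5)]
    )
    def test_sensitivity_printed_precision(self, tp, fn, expected):
        assert sensitivity(ConfusionMatrix(tp, 0, 1, fn)) == expected

    @pytest.mark.parametrize(
        "tn,fp,expected", [(16032, 972, 94.3), (12628, 522, 96.0), (18675, 8, 100.0)]
    )
    def test_specificity_printed_precision(self, tn, fp, expected):
        assert specificity(ConfusionMatrix(1, fp, tn, 0)) == expected

    def test_mcc_known_values(self):
        assert mcc(ConfusionMatrix(794, 262, 16742, 1076)) == 0.53
        assert mcc(ConfusionMatrix(5350, 522, 12628, 374)) == 0.89

    def test_mcc_perfect_classifier(self):
        assert mcc(ConfusionMatrix(10, 0, 10, 0)) == 1.00

    def test_zero_marginal_is_flagged_undefined(self):
        with pytest.raises(UndefinedMetricError):
            mcc(ConfusionMatrix(0, 0, 18855, 19))
        ms = metric_set(ConfusionMatrix(0, 0, 18855, 19))
        assert ms.mcc is None and ms.sensitivity == 0.0

    def test_zero_denominator_errors(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionMatrix(0, 1, 1, 0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionMatrix(1, 0, 0, 1))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 5000)] * 4))
    def test_mcc_invariant_under_class_swap(self, counts):
        tp, fp, tn, fn = counts
        assert mcc(ConfusionMatrix(tp, fp, tn, fn)) == mcc(
            ConfusionMatrix(tn, fn, tp, fp)
        )


class TestReferenceCountsFixture:
    """The frozen published evaluation rows must reproduce exactly."""

    def test_every_row_reproduces_printed_metrics(self):
        df = load_reference_counts()
        assert len(df) == 17
        for _, row in df.iterrows():
            cm = ConfusionMatrix(int(row.tp), int(row.fp), int(row.tn), int(row.fn))
            ms = metric_set(cm)
            assert ms.sensitivity == float(row.sn), row.rule
            assert ms.specificity == float(row.sp), row.rule
            if row.mcc == "-":
                assert ms.mcc is None
            else:
                assert ms.mcc == float(row.mcc), row.rule

    def test_marginals_are_internally_consistent(self):
        df = load_reference_counts()
        mito = df[df.group == "mitochondrial"]
        assert ((mito.tp + mito.fn) == 1870).all()
        assert ((mito.fp + mito.tn) == 17004).all()
        secreted = df[df.group == "secreted"]
        assert ((secreted.tp + secreted.fn) == 5724).all()
        assert ((secreted.fp + secreted.tn) == 13150).all()
        locations = df[df.group == "locations"]
        assert ((locations.tp + locations.fn + locations.fp + locations.tn)
                == 18874).all()


class TestBuildBenchmark:
    def test_filters_and_tally(self):
        records = [
            make_record("KEEP1", "Secreted."),
            make_record("KEEP2", "Cell membrane."),
            make_record("SHORT", "Nucleus.", length=65),
            make_record("MULTI", "Cytoplasm. Nucleus."),
            make_record("QUAL", "Secreted {Probable}."),
            make_record("FRAG", "Secreted.", fragment=True),
            make_record("NOMET", "Secreted.", start="A"),
            make_record("TREMBL", "Secreted.", reviewed=False),
            make_record("NOLOC", None),
            make_record("CYSK", "Cytoplasm. Cytoskeleton."),
        ]
        benchmark, tally = build_benchmark(records)
        assert benchmark[C.SECRETED] == {"KEEP1"}
        assert benchmark[C.PLASMA_MEMBRANE] == {"KEEP2"}
        # cytoskeleton entries stay out of cytoplasm and count as one location
        assert benchmark[C.CYTOSKELETON] == {"CYSK"}
        assert C.CYTOPLASM not in benchmark
        assert tally == {
            "kept": 3, "unreviewed": 1, "no_mapped_location": 1,
            "multiple_locations": 1, "qualifier": 1, "fragment": 1,
            "non_met_start": 1, "short": 1,
        }

    def test_boundary_length_is_inclusive(self):
        benchmark, _ = build_benchmark([make_record("P1", "Nucleus.", length=70)])
        assert benchmark[C.NUCLEAR_NONMEMBRANE] == {"P1"}


class TestRuleEvaluation:
    @pytest.fixture(scope="class")
    def noisy(self):
        return generate(
            SimulationConfig(
                n_proteins=4000,
                seed=5,
                curated_fraction=0.0,
                category_mix={
                    C.SECRETED: 0.3,
                    C.MITO_NONMEMBRANE: 0.2,
                    C.CYTOPLASM: 0.3,
                    C.NUCLEAR_NONMEMBRANE: 0.2,
                },
                per_tool_error={
                    "signalp4.fn": 0.1, "phobius.fn": 0.1, "targetp.fn": 0.1,
                    "wolf.err": 0.1, "targetp.fp_m": 0.05, "wolf.fp_mito": 0.05,
                },
            )
        )

    def test_and_rule_is_at_least_as_specific_as_or_rule(self, noisy):
        benchmark = truth_benchmark(noisy.truth)
        bundles = noisy.bundles()
        kwargs = dict(categories=[C.MITO_NONMEMBRANE])
        sp_and = evaluate_rule(
            "targetp=M AND wolf=mito", benchmark, bundles, **kwargs
        ).sp.iloc[0]
        sp_or = evaluate_rule(
            "targetp=M OR wolf=mito", benchmark, bundles, **kwargs
        ).sp.iloc[0]
        assert sp_and >= sp_or

    def test_vote_threshold_rules_are_nested(self, noisy):
        benchmark = truth_benchmark(noisy.truth)
        bundles = noisy.bundles()
        sn = [
            evaluate_rule(
                f"votes>={k} AND NOT tm AND NOT kdel", benchmark, bundles,
                categories=[C.SECRETED],
            ).sn.iloc[0]
            for k in (4, 3, 2, 1)
        ]
        assert sn == sorted(sn)

    def test_measured_sensitivity_matches_planted_error_rate(self, noisy):
        """k-of-4 voting sensitivity tracks the analytic binomial tail."""
        benchmark = truth_benchmark(noisy.truth)
        row = evaluate_rule(
            "votes>=3 AND NOT tm AND NOT kdel", benchmark, noisy.bundles(),
            categories=[C.SECRETED],
        ).iloc[0]
        p_hit = 0.9
        expected = (
            4 * p_hit**3 * (1 - p_hit) + p_hit**4
        )
        n_pos = row.tp + row.fn
        sd = math.sqrt(expected * (1 - expected) / n_pos)
        assert abs(row.sn / 100 - expected) < 3 * sd

    def test_unknown_atoms_and_categories_error(self, noisy):
        benchmark = truth_benchmark(noisy.truth)
        with pytest.raises(ValueError, match="unknown atom"):
            compile_rule("frobnicator=Y")
        with pytest.raises(ValueError, match="not present"):
            evaluate_rule(
                "votes>=1", benchmark, noisy.bundles(), categories=[C.LYSOSOME]
            )

    def test_empty_category_flagged_undefined(self):
        ds = generate(
            SimulationConfig(
                n_proteins=1, seed=0, curated_fraction=0.0,
                category_mix={C.SECRETED: 1.0},
            )
        )
        df = evaluate_rule(
            "votes>=3", {C.SECRETED: {"SYN000001"}}, ds.bundles()
        )
        assert math.isnan(df.mcc.iloc[0])  # no negatives -> MCC undefined
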