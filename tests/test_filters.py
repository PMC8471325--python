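"""The three filtering stages and their funnel bookkeeping."""

from itertools import permutations

import numpy as np
import pytest

from recvar import (
    ConfigurationError,
    FilterConfig,
    SampleInfo,
    ValidationError,
    filter_by_consequence,
    filter_by_controls,
    filter_by_maf,
    run_funnel,
)
from recvar.filters import assert_controls_clean

from helpers import gt, make_variant, random_cohort

CFG = FilterConfig(maf_threshold=0.01)


def _v(**kwargs):
    return make_variant(**kwargs)


class TestMafFilter:
    def test_novel_rare_variant_survives(self):
        v = _v(pop_af={"gnomAD": 0.000022})
        assert filter_by_maf([v], CFG) == [v]

    def test_boundary_is_strict_greater_than(self):
        v = _v(pop_af={"gnomAD": 0.01})
        assert filter_by_maf([v], CFG) == [v]

    def test_max_over_databases_rules(self):
        # one database below, another above threshold -> removed
        v = _v(pop_af={"dbSNP": 0.005, "1000G": 0.02})
        assert filter_by_maf([v], CFG) == []

    def test_missing_af_passes_by_default_and_is_configurable(self):
        v = _v(pop_af={})
        assert filter_by_maf([v], CFG) == [v]
        strict = FilterConfig(maf_threshold=0.01, missing_af_passes=False)
        assert filter_by_maf([v], strict) == []

    def test_only_consulted_databases_count(self):
        cfg = FilterConfig(maf_threshold=0.01, db_names=("dbSNP",))
        v = _v(pop_af={"gnomAD": 0.4})  # common, but not in a consulted db
        assert filter_by_maf([v], cfg) == [v]


class TestControlFilter:
    samples = [
        SampleInfo("CASE", "female", "case"),
        SampleInfo("CTRL_F", "female", "control"),
        SampleInfo("CTRL_M", "male", "control"),
    ]

    def test_het_controls_never_cause_removal(self):
        v = _v(genotypes={"CASE": gt(1), "CTRL_F": gt(1), "CTRL_M": gt(1)})
        assert filter_by_controls([v], self.samples) == [v]

    def test_hom_alt_control_removes(self):
        v = _v(genotypes={"CASE": gt(1), "CTRL_F": gt(2)})
        assert filter_by_controls([v], self.samples) == []

    def test_male_x_het_control_is_hemizygous_alt(self):
        v = _v(chrom="X", genotypes={"CASE": gt(1), "CTRL_M": gt(1)})
        assert filter_by_controls([v], self.samples) == []

    def test_female_x_het_control_is_just_a_carrier(self):
        v = _v(chrom="X", genotypes={"CASE": gt(1), "CTRL_F": gt(1)})
        assert filter_by_controls([v], self.samples) == [v]

    def test_par_interval_exempts_male_x(self):
        v = _v(chrom="X", pos=100, genotypes={"CTRL_M": gt(1)})
        assert filter_by_controls([v], self.samples, par_intervals=((1, 1000),)) == [v]

    def test_no_controls_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            filter_by_controls([_v()], [SampleInfo("CASE", "male", "case")])


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence,kept",
        [
            ("missense", True),
            ("frameshift", True),
            ("splice_site", True),
            ("synonymous", False),
            ("other", False),
        ],
    )
    def test_default_class_selection(self, consequence, kept):
        v = _v(consequence=consequence)
        assert (filter_by_consequence([v], CFG) == [v]) is kept


def _toy_cohort():
    """Six variants: one common, one control-hom, one synonymous, three good."""
    samples = [
        SampleInfo("CASE", "female", "case"),
        SampleInfo("CTRL", "female", "control"),
    ]
    calls = {"CASE": gt(1), "CTRL": gt(0)}
    variants = [
        _v(pos=1, pop_af={"gnomAD": 0.2}, genotypes=dict(calls)),          # common
        _v(pos=2, genotypes={"CASE": gt(1), "CTRL": gt(2)}),               # control hom
        _v(pos=3, consequence="synonymous", genotypes=dict(calls)),        # synonymous
        _v(pos=4, genotypes=dict(calls)),
        _v(pos=5, pop_af={"dbSNP": 0.001}, genotypes=dict(calls)),
        _v(pos=6, consequence="frameshift", genotypes=dict(calls)),
    ]
    return variants, samples


def test_funnel_on_hand_traced_toy_cohort():
    variants, samples = _toy_cohort()
    survivors, funnel = run_funnel(variants, samples, CFG)
    assert funnel.counts == [6, 5, 4, 3]
    assert [s.name for s in funnel.stages] == ["maf", "controls", "consequence"]
    assert {v.pos for v in survivors} == {4, 5, 6}


def test_empty_input_yields_zero_funnel():
    samples = [SampleInfo("C", "male", "case"), SampleInfo("K", "male", "control")]
    survivors, funnel = run_funnel([], samples, CFG)
    assert survivors == []
    assert funnel.counts == [0, 0, 0, 0]


def test_funnel_monotone_and_chained():
    variants, samples = _toy_cohort()
    _, funnel = run_funnel(variants, samples, CFG)
    for prev, stage in zip(funnel.stages, funnel.stages[1:]):
        assert stage.variants_in == prev.variants_out
        assert stage.variants_out <= stage.variants_in


def test_stage_order_independence_on_random_cohorts():
    """The three stages are independent per-variant predicates: any
    application order leaves the final surviving set unchanged."""
    rng = np.random.default_rng(2024)
    stages = {
        "maf": lambda vs, ss: filter_by_maf(vs, CFG),
        "controls": lambda vs, ss: filter_by_controls(vs, ss),
        "consequence": lambda vs, ss: filter_by_consequence(vs, CFG),
    }
    for _ in range(30):
        variants, samples = random_cohort(rng)
        finals = []
        for order in permutations(stages):
            current = variants
            for name in order:
                current = stages[name](current, samples)
            finals.append({v.key for v in current})
        assert all(f == finals[0] for f in finals)


def test_no_survivor_is_hom_or_hemizygous_in_any_control():
    rng = np.random.default_rng(77)
    for _ in range(20):
        variants, samples = random_cohort(rng)
        survivors, _ = run_funnel(variants, samples, CFG)
        assert_controls_clean(survivors, samples)  # raises on violation


def test_filter_config_validation():
    with pytest.raises(ValidationError):
        FilterConfig(maf_threshold=1.5)
    with pytest.raises(ValidationError):
        FilterConfig(maf_threshold=0.01, db_names=())
    with pytest.raises(ValidationError):
        FilterConfig(maf_threshold=0.01, allowed_consequences=frozenset())
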