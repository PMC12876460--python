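"""Significance classification: rule application, partition and recovery."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertescreen.significance import (
    ParameterFilterConfig,
    SexCategory,
    StatResultRow,
    classify_life_stage,
    classify_sex,
    flag_dimorphism,
    screen_main_effect,
    select_parameters,
    summarize,
)
from vertescreen.synthetic import SimConfig, simulate_annotation, simulate_stat_results


def row(gene="G1", pid="IMPC_XRY_019_001", zyg="homozygote", **p):
    return StatResultRow(
        gene_symbol=gene, parameter_id=pid, parameter_name=pid,
        procedure_code=pid.split("_")[1], zygosity=zyg,
        significant_flag=p.pop("flag", True), **p,
    )


class TestClassifySex:
    @pytest.mark.parametrize(
        "male,female,expected",
        [
            (1e-6, 0.3, SexCategory.MALE_ONLY),
            (0.3, 1e-6, SexCategory.FEMALE_ONLY),
            (5e-5, 9e-5, SexCategory.BOTH),
            (0.5, 0.5, SexCategory.NOT_SIGNIFICANT),
            (None, None, SexCategory.NOT_CONSIDERED),
        ],
    )
    def test_rule_application(self, male, female, expected):
        assert classify_sex([row(male_ko_p=male, female_ko_p=female)]) is expected

    def test_boundary_p_equal_alpha_is_not_significant(self):
        # strict '<': p exactly at the threshold does not count
        rows = [row(male_ko_p=1e-4, female_ko_p=0.9)]
        assert classify_sex(rows, alpha=1e-4) is SexCategory.NOT_SIGNIFICANT

    def test_any_row_triggers(self):
        rows = [row(male_ko_p=0.9, female_ko_p=0.9),
                row(male_ko_p=1e-7, female_ko_p=0.9)]
        assert classify_sex(rows) is SexCategory.MALE_ONLY

    def test_no_rows_is_an_error(self):
        with pytest.raises(ValueError):
            classify_sex([])


class TestDimorphismAndMainEffect:
    def test_interaction_below_alpha_flags(self):
        assert flag_dimorphism([row(interaction_p=2e-5)]) is True

    def test_interaction_at_or_above_alpha_does_not(self):
        assert flag_dimorphism([row(interaction_p=1e-4)]) is False
        assert flag_dimorphism([row()]) is False  # missing => not significant

    def test_main_effect_with_interaction_veto(self):
        assert screen_main_effect([row(genotype_main_p=1e-5, interaction_p=0.5)]) is True
        assert screen_main_effect([row(genotype_main_p=1e-5, interaction_p=1e-5)]) is False
        assert screen_main_effect([row(genotype_main_p=0.2)]) is False


class TestLifeStage:
    @pytest.mark.parametrize("code,stage", [
        ("GEL", "embryo"), ("GEM", "embryo"), ("GEO", "embryo"), ("GEP", "embryo"),
        ("XRY", "adult"), ("CSD", "adult"), ("DXA", "adult"),
    ])
    def test_mapping(self, code, stage):
        assert classify_life_stage(code) == stage

    def test_unknown_code_names_the_code(self):
        with pytest.raises(ValueError, match="ABC"):
            classify_life_stage("ABC")


class TestSelectParameters:
    def test_exclusion_list_filters_rows(self):
        rows = [row(gene=f"G{i}", pid=p) for i, p in enumerate(
            ["IMPC_XRY_019_001", "IMPC_XRY_018_001", "IMPC_XRY_060_001",
             "IMPC_XRY_100_001", "IMPC_XRY_101_001"])]
        cfg = ParameterFilterConfig(
            exclude_parameter_ids=frozenset({"IMPC_XRY_100_001", "IMPC_XRY_101_001"}),
            exclusion_reasons={"IMPC_XRY_100_001": "appendicular",
                               "IMPC_XRY_101_001": "appendicular"},
        )
        kept, summary = select_parameters(rows, cfg)
        assert {r.parameter_id for r in kept} == {
            "IMPC_XRY_019_001", "IMPC_XRY_018_001", "IMPC_XRY_060_001"}
        assert len(summary) == 3

    def test_parameter_with_no_significant_genes_dropped(self):
        rows = [row(gene="G1", pid="IMPC_XRY_019_001"),
                row(gene="G2", pid="IMPC_XRY_018_001", flag=False)]
        kept, summary = select_parameters(rows, ParameterFilterConfig())
        assert {r.parameter_id for r in kept} == {"IMPC_XRY_019_001"}
        assert "IMPC_XRY_018_001" not in set(summary["parameter_id"])

    def test_overlapping_include_exclude_rejected(self):
        with pytest.raises(ValueError):
            ParameterFilterConfig(
                include_parameter_ids=frozenset({"a"}),
                exclude_parameter_ids=frozenset({"a"}),
            )


# independent oracle: literal per-row re-evaluation of the published rules
def _oracle_category(rows, alpha):
    male = female = considered = False
    for r in rows:
        if r.male_ko_p is not None:
            considered = True
            if r.male_ko_p < alpha:
                male = True
        if r.female_ko_p is not None:
            considered = True
            if r.female_ko_p < alpha:
                female = True
    if male and female:
        return SexCategory.BOTH
    if male:
        return SexCategory.MALE_ONLY
    if female:
        return SexCategory.FEMALE_ONLY
    return SexCategory.NOT_SIGNIFICANT if considered else SexCategory.NOT_CONSIDERED


@st.composite
def gene_rows(draw):
    n = draw(st.integers(1, 20))
    ps = st.one_of(st.none(), st.floats(0, 1, allow_nan=False))
    return [
        row(male_ko_p=draw(ps), female_ko_p=draw(ps), interaction_p=draw(ps))
        for _ in range(n)
    ]


@settings(max_examples=200, derandomize=True)
@given(gene_rows(), st.sampled_from([1e-4, 1e-2]))
def test_classification_matches_exhaustive_oracle(rows, alpha):
    assert classify_sex(rows, alpha) is _oracle_category(rows, alpha)


@settings(max_examples=100, derandomize=True)
@given(gene_rows())
def test_monotone_in_alpha(rows):
    """Raising alpha never demotes a gene out of a significant category."""
    sig = {SexCategory.MALE_ONLY, SexCategory.FEMALE_ONLY, SexCategory.BOTH}
    lo, hi = classify_sex(rows, 1e-4), classify_sex(rows, 1e-2)
    if lo in sig:
        assert hi in sig


class TestRecovery:
    def test_planted_categories_recovered_exactly(self):
        cfg = SimConfig(seed=17, n_genes=500, n_target_genes=204,
                        n_planted_spatial_clusters=0)
        loci = simulate_annotation(cfg)
        rows, truth = simulate_stat_results(loci, cfg)
        records, _ = summarize(rows)
        by_gene = {g.gene_symbol: g for g in records}
        for gene, cat in truth.sex_category.items():
            assert by_gene[gene].sex_category.value == cat
        for gene, stage in truth.life_stage.items():
            expect = {"embryo", "adult"} if stage == "both" else {stage}
            assert by_gene[gene].life_stages == expect
        for gene, zygs in truth.zygosities.items():
            assert sorted(by_gene[gene].zygosities) == zygs

    def test_gene_significant_in_both_zygosities_counts_in_both(self):
        rows = [row(zyg="homozygote", male_ko_p=1e-6),
                row(zyg="heterozygote", male_ko_p=1e-6)]
        records, summary = summarize(rows)
        assert records[0].zygosities == {"homozygote", "heterozygote"}
        counts = dict(zip(summary["statistic"], summary["count"]))
        assert counts["zygosity:homozygote"] == 1
        assert counts["zygosity:heterozygote"] == 1

    def test_empty_input_yields_empty_summary(self):
        records, summary = summarize([])
        assert records == []
        assert dict(zip(summary["statistic"], summary["count"]))["n_genes"] == 0
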