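"""Three-criterion classification and screen tallies."""
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from mttrna.annotation import MtVariant, annotate
from mttrna.classify import (
    FREQ_ABSENT, FREQ_COMMON, FREQ_RARE, TIER_POLYMORPHISM, TIER_PUTATIVE,
    TIER_RARE, classify_variant, frequency_class, screen,
)


@pytest.mark.parametrize("carriers, expected", [
    (0, FREQ_ABSENT),
    (4, FREQ_RARE),       # 4/485 = 0.825% < 1%
    (7, FREQ_COMMON),     # 7/485 = 1.443% >= 1%
    (5, FREQ_COMMON),     # 5/485 = 1.031%: smallest common count at n=485
])
def test_frequency_class_boundaries_at_485_controls(carriers, expected):
    fc = frequency_class(carriers, 485)
    assert fc.label == expected
    assert fc.control_fraction == Fraction(carriers, 485)


def test_frequency_class_exact_one_percent_is_common():
    assert frequency_class(1, 100).label == FREQ_COMMON


def test_frequency_class_errors():
    with pytest.raises(ValueError):
        frequency_class(0, 0)
    with pytest.raises(ValueError):
        frequency_class(10, 5)


def _annotated(genes, position, ref, alt, ci, controls):
    v = MtVariant(position=position, ref_allele=ref, alt_allele=alt,
                  case_carriers=1, control_carriers=controls, supplied_ci=ci)
    return annotate(v, genes)


def test_classify_examples(genes):
    # conserved, absent, anticodon-stem disruption -> putative
    cv = classify_variant(_annotated(genes, 4373, "T", "C", 100, 0), 485)
    assert cv.tier == TIER_PUTATIVE
    assert len(cv.reasons) == 3 and all("pass" in r for r in cv.reasons)
    # conserved but common in controls -> polymorphism
    cv = classify_variant(_annotated(genes, 14693, "A", "G", 98, 7), 485)
    assert cv.tier == TIER_POLYMORPHISM
    # conserved, rare (2/485), not absent -> rare conserved under default
    cv = classify_variant(_annotated(genes, 5836, "A", "G", 83, 2), 485)
    assert cv.tier == TIER_RARE


def test_rare_allowed_policy_promotes_impactful_rare_variants(genes):
    av = _annotated(genes, 5836, "A", "G", 83, 2)   # T-stem, creates pair
    assert classify_variant(av, 485, policy="absent_only").tier == TIER_RARE
    assert classify_variant(av, 485, policy="rare_allowed").tier == TIER_PUTATIVE


def test_policy_putative_sets_are_nested(genes, variants):
    strict = screen(variants, genes, 494, 485, policy="absent_only")
    loose = screen(variants, genes, 494, 485, policy="rare_allowed")
    strict_set = {cv.variant.position for cv in strict.putative()}
    loose_set = {cv.variant.position for cv in loose.putative()}
    assert strict_set <= loose_set


@settings(max_examples=150, deadline=None)
@given(ci=st.integers(0, 100), controls=st.integers(0, 100),
       d_ci=st.integers(0, 40), d_controls=st.integers(0, 40))
def test_monotonicity_under_ci_and_control_perturbation(genes, ci, controls,
                                                        d_ci, d_controls):
    """Lowering CI or raising control carriers can never promote a variant
    toward the putative tier."""
    rank = {TIER_POLYMORPHISM: 0, TIER_RARE: 1, TIER_PUTATIVE: 2}
    base = _annotated(genes, 15950, "G", "A", ci, controls)
    worse = _annotated(genes, 15950, "G", "A", max(0, ci - d_ci),
                       min(485, controls + d_controls))
    t_base = classify_variant(base, 485).tier
    t_worse = classify_variant(worse, 485).tier
    assert rank[t_worse] <= rank[t_base]


def test_screen_partition_is_exhaustive_and_exclusive(report):
    tiers = report.tier_counts()
    assert sum(tiers.values()) == report.n_variants == 73
    assert sum(report.per_gene_counts().values()) == 73


def test_screen_singleton_and_degenerate_cases(genes):
    v = MtVariant(position=15950, ref_allele="G", alt_allele="A",
                  case_carriers=2, control_carriers=0, supplied_ci=100)
    rep = screen([v], genes, n_cases=100, n_controls=485)
    assert rep.tier_counts()[TIER_PUTATIVE] == 1
    assert rep.prevalence_fraction() == Fraction(2, 100)

    common = MtVariant(position=15950, ref_allele="G", alt_allele="A",
                       case_carriers=2, control_carriers=50, supplied_ci=100)
    rep = screen([common], genes, n_cases=100, n_controls=485)
    assert rep.tier_counts()[TIER_PUTATIVE] == 0

    with pytest.raises(ValueError, match="empty"):
        screen([], genes, n_cases=100, n_controls=485)


def test_screen_names_offending_variant_on_error(genes):
    bad = MtVariant(position=5000, ref_allele="A", alt_allele="G",
                    supplied_ci=50)
    with pytest.raises(ValueError, match="m.5000A>G"):
        screen([bad], genes, n_cases=10, n_controls=10)


def test_per_variant_frame_is_sorted_and_complete(report):
    frame = report.per_variant_frame()
    assert list(frame.columns[:5]) == ["gene", "position", "variant",
                                       "trna_position", "element"]
    assert frame["position"].is_unique
    keys = list(zip(frame["gene"], frame["position"]))
    assert keys == sorted(keys)
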