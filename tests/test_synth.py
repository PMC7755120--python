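"""Synthetic-data generator: determinism, feasibility, exact tier recovery."""
import dataclasses

import pytest

from mttrna.classify import screen
from mttrna.conservation import conservation_index
from mttrna.synth import (
    CohortSpec, SynthSpec, SynthSpecError, generate_alignment,
    generate_cohort, generate_variants,
)

TIER_NAME = {"putative": "putative_mutation",
             "rare_conserved": "rare_conserved_variant",
             "polymorphism": "polymorphism"}


def test_default_spec_mirrors_study_conditions():
    spec = SynthSpec()
    assert (spec.n_cases, spec.n_controls, spec.n_variants) == (494, 485, 73)
    assert spec.species_count == 16


def test_generate_variants_is_deterministic(genes):
    spec = SynthSpec(seed=11)
    v1, t1 = generate_variants(spec, genes)
    v2, t2 = generate_variants(spec, genes)
    assert v1 == v2
    assert t1.equals(t2)
    v3, _ = generate_variants(SynthSpec(seed=12), genes)
    assert v1 != v3


def test_truth_table_counts_match_tier_mix(genes):
    variants, truth = generate_variants(SynthSpec(seed=2), genes)
    assert len(variants) == 73
    counts = truth.true_tier.value_counts()
    assert counts["putative"] == 18
    assert counts["rare_conserved"] == 12
    assert counts["polymorphism"] == 43


@pytest.mark.parametrize("seed", [0, 1, 7, 123, 9999])
def test_screen_recovers_truth_tiers_exactly(genes, seed):
    spec = SynthSpec(seed=seed)
    variants, truth = generate_variants(spec, genes)
    report = screen(variants, genes, n_cases=spec.n_cases,
                    n_controls=spec.n_controls)
    observed = {cv.variant.position: cv.tier for cv in report.classified}
    for row in truth.itertuples(index=False):
        assert observed[row.position] == TIER_NAME[row.true_tier], row


def test_all_polymorphism_mix_yields_no_putative(genes):
    spec = SynthSpec(seed=4, n_variants=20, tier_mix={
        "putative": 0.0, "rare_conserved": 0.0, "polymorphism": 1.0})
    variants, truth = generate_variants(spec, genes)
    report = screen(variants, genes, 494, 485)
    assert report.tier_counts()["putative_mutation"] == 0
    assert set(truth.true_tier) == {"polymorphism"}


def test_disjoint_mode_avoids_bundled_positions(genes, variant_table):
    bundled = {int(p) for p in variant_table.position}
    variants, _ = generate_variants(SynthSpec(seed=6, disjoint=True), genes)
    assert not bundled & {v.position for v in variants}


def test_infeasible_specs_rejected(genes):
    with pytest.raises(SynthSpecError, match="control count 0"):
        SynthSpec(control_count_range={"putative": (1, 2),
                                       "rare_conserved": (1, 4),
                                       "polymorphism": (0, 20)}).validate()
    with pytest.raises(SynthSpecError, match="sum to 1"):
        SynthSpec(tier_mix={"putative": 0.5, "rare_conserved": 0.5,
                            "polymorphism": 0.5}).validate()
    with pytest.raises(SynthSpecError, match="CI > 75"):
        SynthSpec(ci_range={"putative": (50, 100),
                            "rare_conserved": (76, 100),
                            "polymorphism": (10, 75)}).validate()


def test_generate_alignment_hits_targets_exactly(genes):
    gene = genes["MT-TW"]
    targets = {"49": 100.0, "55": 75.0, "61": 81.25, "14": 0.0}
    aln = generate_alignment(gene, targets, species_count=16, seed=3)
    for label, want in targets.items():
        res = conservation_index(aln, label, mode="all_species")
        assert float(res.ci_exact) == want
        # identical result under gap-excluding mode (no gaps emitted)
        assert conservation_index(aln, label).ci_exact == res.ci_exact
    # untargeted columns are fully conserved
    assert conservation_index(aln, "34").ci_percent == 100


def test_generate_alignment_rejects_unattainable_target(genes):
    with pytest.raises(SynthSpecError, match="not attainable"):
        generate_alignment(genes["MT-TW"], {"49": 90.0}, species_count=16)
    with pytest.raises(SynthSpecError, match="no position"):
        generate_alignment(genes["MT-TW"], {"999": 100.0})


def test_generate_cohort_exact_and_stochastic_modes():
    exact = generate_cohort(CohortSpec(n_subjects=200), seed=8)
    assert len(exact) == 200
    assert generate_cohort(CohortSpec(n_subjects=200), seed=8) == exact

    loose = generate_cohort(CohortSpec(n_subjects=400), seed=8,
                            exact_counts=False)
    male = sum(1 for s in loose if s.sex == "male")
    # binomial tolerance around 81.6% of 400
    assert abs(male - 326) < 60


def test_cohort_spec_validation():
    with pytest.raises(SynthSpecError):
        dataclasses.replace(CohortSpec(), male=1.5).validate()
    with pytest.raises(SynthSpecError):
        dataclasses.replace(
            CohortSpec(), diagnoses={"TS": 0.9, "CTD": 0.9, "PTD": 0.1}
        ).validate()
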