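"""Three-criterion pathogenicity screen and headline tallies.

A variant is a *putative mutation* when it is (1) evolutionarily conserved
(CI strictly above the threshold), (2) absent from controls (default
policy) or rare below the control-frequency cutoff (``rare_allowed``
policy), and (3) predicted to alter tRNA structure or function.  Conserved
variants that miss only the frequency criterion are *rare conserved
variants*; everything non-conserved or common is a *polymorphism*.
All frequency comparisons are exact-rational.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import AnnotatedVariant, MtVariant, annotate, structural_impact
from .conservation import DEFAULT_CI_THRESHOLD, SpeciesAlignment
from .model import GeneSet, LOOP_ELEMENTS, STEM_ELEMENTS

DEFAULT_CONTROL_CUTOFF = Fraction(1, 100)

TIER_PUTATIVE = "putative_mutation"
TIER_RARE = "rare_conserved_variant"
TIER_POLYMORPHISM = "polymorphism"

FREQ_ABSENT = "absent"
FREQ_RARE = "rare_below_1pct"
FREQ_COMMON = "common_1pct_or_more"

POLICIES = ("absent_only", "rare_allowed")


@dataclass(frozen=True)
class FrequencyClass:
    label: str
    control_fraction: Fraction

    @property
    def percent(self) -> float:
        return round(float(100 * self.control_fraction), 2)


def frequency_class(control_carriers: int, n_controls: int,
                    cutoff: Fraction = DEFAULT_CONTROL_CUTOFF
                    ) -> FrequencyClass:
    """Partition by exact control carrier fraction: absent (0), rare
    (below the cutoff) or common (at or above it)."""
    if n_controls <= 0:
        raise ValueError("n_controls must be positive")
    if not 0 <= control_carriers <= n_controls:
        raise ValueError(
            f"control carriers {control_carriers} outside 0..{n_controls}")
    frac = Fraction(control_carriers, n_controls)
    if control_carriers == 0:
        label = FREQ_ABSENT
    elif frac < cutoff:
        label = FREQ_RARE
    else:
        label = FREQ_COMMON
    return FrequencyClass(label=label, control_fraction=frac)


@dataclass(frozen=True)
class ClassifiedVariant:
    annotated: AnnotatedVariant
    freq: FrequencyClass
    tier: str
    reasons: tuple[str, ...]

    @property
    def variant(self) -> MtVariant:
        return self.annotated.variant


def classify_variant(av: AnnotatedVariant, n_controls: int,
                     policy: str = "absent_only",
                     cutoff: Fraction = DEFAULT_CONTROL_CUTOFF
                     ) -> ClassifiedVariant:
    """Apply the three criteria to one annotated variant."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    freq = frequency_class(av.variant.control_carriers, n_controls, cutoff)
    conserved = av.is_conserved
    impact = structural_impact(av)
    freq_ok = (freq.label == FREQ_ABSENT if policy == "absent_only"
               else freq.label != FREQ_COMMON)
    reasons = (
        f"conservation: CI={av.ci.ci_percent} > {av.ci.threshold}: "
        f"{'pass' if conserved else 'fail'}",
        f"control frequency: {av.variant.control_carriers}/{n_controls} "
        f"-> {freq.label}: {'pass' if freq_ok else 'fail'} (policy {policy})",
        f"structural/functional impact ({av.element.canonical_name}, "
        f"wc={av.wc.status}): {'pass' if impact else 'fail'}",
    )
    if conserved and freq_ok and impact:
        tier = TIER_PUTATIVE
    elif not conserved or freq.label == FREQ_COMMON:
        tier = TIER_POLYMORPHISM
    else:
        tier = TIER_RARE
    return ClassifiedVariant(annotated=av, freq=freq, tier=tier, reasons=reasons)


def _element_class(cv: ClassifiedVariant) -> str:
    name = cv.annotated.element.canonical_name
    if name in STEM_ELEMENTS:
        return "stem"
    if name in LOOP_ELEMENTS:
        return "loop"
    return "terminal_junction"


@dataclass
class ScreenReport:
    """Per-variant tiers plus the headline counts of the screen."""

    classified: Sequence[ClassifiedVariant]
    n_cases: int
    n_controls: int
    policy: str
    ci_threshold: float
    control_cutoff: Fraction

    # -- derived tallies --------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.classified)

    def tier_counts(self) -> dict[str, int]:
        counts = {TIER_PUTATIVE: 0, TIER_RARE: 0, TIER_POLYMORPHISM: 0}
        for cv in self.classified:
            counts[cv.tier] += 1
        return counts

    def putative(self) -> list[ClassifiedVariant]:
        return [cv for cv in self.classified if cv.tier == TIER_PUTATIVE]

    def conserved(self) -> list[ClassifiedVariant]:
        return [cv for cv in self.classified if cv.annotated.is_conserved]

    def conserved_frequency_partition(self) -> dict[str, int]:
        part = {FREQ_ABSENT: 0, FREQ_RARE: 0, FREQ_COMMON: 0}
        for cv in self.conserved():
            part[cv.freq.label] += 1
        return part

    def putative_element_partition(self) -> dict[str, int]:
        part = {"loop": 0, "stem": 0, "terminal_junction": 0}
        for cv in self.putative():
            part[_element_class(cv)] += 1
        return part

    def putative_stem_wc_disrupting(self) -> int:
        return sum(1 for cv in self.putative()
                   if _element_class(cv) == "stem"
                   and cv.annotated.wc.status == "disrupts_pair")

    def per_gene_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cv in self.classified:
            counts[cv.annotated.gene_id] = counts.get(cv.annotated.gene_id, 0) + 1
        return dict(sorted(counts.items()))

    def novelty_counts(self) -> dict[str, int]:
        """A variant is novel unless its catalog flag marks it reported."""
        novel = sum(1 for cv in self.classified
                    if not cv.variant.known_flag)
        return {"novel": novel, "known": self.n_variants - novel}

    def putative_case_carriers(self) -> int:
        """Summed case carrier counts over the putative tier (assumes no
        subject carries two putative variants)."""
        return sum(cv.variant.case_carriers for cv in self.putative())

    def prevalence_fraction(self) -> Fraction:
        return Fraction(self.putative_case_carriers(), self.n_cases)

    @property
    def prevalence_percent(self) -> float:
        return round(float(100 * self.prevalence_fraction()), 2)

    def summary(self) -> dict[str, object]:
        tiers = self.tier_counts()
        part = self.conserved_frequency_partition()
        elems = self.putative_element_partition()
        nov = self.novelty_counts()
        return {
            "n_variants": self.n_variants,
            "n_conserved": len(self.conserved()),
            "conserved_absent": part[FREQ_ABSENT],
            "conserved_rare": part[FREQ_RARE],
            "conserved_common": part[FREQ_COMMON],
            "n_putative": tiers[TIER_PUTATIVE],
            "n_rare_conserved": tiers[TIER_RARE],
            "n_polymorphism": tiers[TIER_POLYMORPHISM],
            "putative_loop": elems["loop"],
            "putative_stem": elems["stem"],
            "putative_terminal_junction": elems["terminal_junction"],
            "putative_stem_wc_disrupting": self.putative_stem_wc_disrupting(),
            "novel": nov["novel"],
            "known": nov["known"],
            "putative_case_carriers": self.putative_case_carriers(),
            "prevalence_percent": self.prevalence_percent,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "policy": self.policy,
            "ci_threshold": self.ci_threshold,
            "control_cutoff_percent": round(float(100 * self.control_cutoff), 2),
        }

    def per_variant_frame(self) -> pd.DataFrame:
        rows = []
        for cv in self.classified:
            av = cv.annotated
            rows.append({
                "gene": av.gene_id,
                "position": av.variant.position,
                "variant": av.variant.notation,
                "trna_position": av.conventional_position,
                "element": av.element.canonical_name,
                "trna_ref": av.trna_ref,
                "trna_alt": av.trna_alt if av.trna_alt is not None else "-",
                "wc_status": av.wc.status,
                "wc_pair": av.wc.pair_text(),
                "ci_percent": av.ci.ci_percent,
                "conserved": av.is_conserved,
                "case_carriers": av.variant.case_carriers,
                "control_carriers": av.variant.control_carriers,
                "control_percent": cv.freq.percent,
                "frequency_class": cv.freq.label,
                "known": bool(av.variant.known_flag),
                "tier": cv.tier,
            })
        frame = pd.DataFrame(rows)
        return frame.sort_values(["gene", "position"]).reset_index(drop=True)


def screen(variants: Iterable[MtVariant], genes: GeneSet,
           n_cases: int, n_controls: int,
           alignments: Optional[Mapping[str, SpeciesAlignment]] = None,
           policy: str = "absent_only",
           ci_threshold: float = DEFAULT_CI_THRESHOLD,
           control_cutoff: Fraction = DEFAULT_CONTROL_CUTOFF,
           ci_mode: str = "non_gap",
           catalog: Optional[Mapping[int, bool]] = None,
           ) -> ScreenReport:
    """End-to-end screen: annotate, classify, and tally a variant set."""
    variants = list(variants)
    if not variants:
        raise ValueError("empty variant set")
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    classified = []
    for v in variants:
        if catalog is not None and v.position in catalog:
            v = MtVariant(**{**v.__dict__, "known_flag": catalog[v.position]})
        av = annotate(v, genes, alignments=alignments,
                      ci_threshold=ci_threshold, ci_mode=ci_mode)
        classified.append(classify_variant(av, n_controls, policy=policy,
                                           cutoff=control_cutoff))
    return ScreenReport(classified=classified, n_cases=n_cases,
                        n_controls=n_controls, policy=policy,
                        ci_threshold=ci_threshold, control_cutoff=control_cutoff)
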