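"""Seeded synthetic data: variant tables, alignments, and cohorts.

Everything the pipeline consumes can be generated here without any
download, with known ground truth:

* :func:`generate_variants` places variants at real cloverleaf positions so
  that each one's screening tier is determined by construction (the truth
  table is returned alongside);
* :func:`generate_alignment` builds a per-gene multi-species alignment whose
  conservation index at chosen positions is exactly a requested target;
* :func:`generate_cohort` emits subject records with configurable (optionally
  exact) clinical rates.

Default sizes mirror the study conditions the pipeline is meant for:
494 cases, 485 controls, 73 variants in an 18/12/43 tier mix, 16 aligned
non-human species.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import MtVariant
from .conservation import SpeciesAlignment
from .cohort import (
    DIAGNOSES, DRUG_LEVELS, ONSET_BANDS, SYMPTOMS, SubjectRecord,
)
from .model import (
    GeneSet, LOOP_ELEMENTS, STEM_ELEMENTS, TrnaGeneDef, is_watson_crick,
)

_RNA_TO_DNA = {"A": "A", "U": "T", "G": "G", "C": "C"}
_RNA_COMPLEMENT_DNA = {"A": "T", "U": "A", "G": "C", "C": "G"}
_BASES = "ACGU"


class SynthSpecError(ValueError):
    pass


def _apportion(total: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Integer apportionment by largest remainder; keys in given order."""
    keys = list(weights)
    exact = {k: total * weights[k] for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    short = total - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (counts[k] - exact[k], k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic case/control variant table."""

    seed: int = 0
    n_cases: int = 494
    n_controls: int = 485
    n_variants: int = 73
    tier_mix: Mapping[str, float] = field(default_factory=lambda: {
        "putative": 18 / 73, "rare_conserved": 12 / 73, "polymorphism": 43 / 73})
    #: CI range (inclusive, integer percent) drawn per tier
    ci_range: Mapping[str, tuple[int, int]] = field(default_factory=lambda: {
        "putative": (76, 100), "rare_conserved": (76, 100),
        "polymorphism": (10, 75)})
    #: control carrier count range (inclusive) per tier
    control_count_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "putative": (0, 0), "rare_conserved": (1, 4),
            "polymorphism": (0, 20)})
    #: element-class mix for putative placement (loop/stem/terminal_junction)
    element_mix: Mapping[str, float] = field(default_factory=lambda: {
        "loop": 7 / 18, "stem": 9 / 18, "terminal_junction": 2 / 18})
    species_count: int = 16
    ci_threshold: float = 75.0
    policy: str = "absent_only"
    #: avoid positions present in the bundled cohort variant table
    disjoint: bool = False

    def validate(self) -> None:
        if abs(sum(self.tier_mix.values()) - 1) > 1e-9:
            raise SynthSpecError("tier_mix fractions must sum to 1")
        if abs(sum(self.element_mix.values()) - 1) > 1e-9:
            raise SynthSpecError("element_mix fractions must sum to 1")
        if self.control_count_range["putative"] != (0, 0):
            raise SynthSpecError(
                "putative tier requires control count 0 (variant absent "
                "from controls)")
        for tier in ("putative", "rare_conserved"):
            lo, _ = self.ci_range[tier]
            if lo <= self.ci_threshold:
                raise SynthSpecError(
                    f"{tier} tier requires CI > {self.ci_threshold}")
        _, hi = self.ci_range["polymorphism"]
        if hi > self.ci_threshold:
            raise SynthSpecError(
                "polymorphism tier in this generator must stay at or below "
                "the CI threshold so the tier is count-independent")
        lo, hi = self.control_count_range["rare_conserved"]
        if lo < 1 or hi >= 0.01 * self.n_controls:
            raise SynthSpecError(
                "rare_conserved control counts must lie strictly between "
                "0 and 1% of controls")


def _bundled_positions() -> frozenset[int]:
    src = resources.files("mttrna").joinpath("data/cohort_variants.tsv")
    frame = pd.read_csv(src.open(), sep="\t", comment="#")
    return frozenset(int(p) for p in frame["position"])


def _heavy_allele(gene: TrnaGeneDef, trna_base: str) -> str:
    table = _RNA_COMPLEMENT_DNA if gene.is_light else _RNA_TO_DNA
    return table[trna_base]


def generate_variants(spec: SynthSpec, genes: GeneSet
                      ) -> tuple[list[MtVariant], pd.DataFrame]:
    """Synthesize a variant table with known tiers.

    Returns the variants (with supplied CI values attached, ready for
    :func:`mttrna.classify.screen`) and a truth table recording each
    variant's intended tier.  Deterministic for a fixed spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    avoid = _bundled_positions() if spec.disjoint else frozenset()

    pools: dict[str, list] = {"loop": [], "stem": [], "terminal_junction": [],
                              "stem_inert": []}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        for p in gene.positions:
            genomic = gene.genomic_at(p.label)
            if genomic in avoid:
                continue
            entry = (gene.gene_id, p.label, genomic)
            name = p.element.canonical_name
            if name in STEM_ELEMENTS:
                partner = gene.base_at(p.partner)
                if is_watson_crick(p.base, partner):
                    pools["stem"].append(entry)
                elif any(b != p.base and not is_watson_crick(b, partner)
                         for b in _BASES):
                    pools["stem_inert"].append(entry)
            elif name in LOOP_ELEMENTS:
                pools["loop"].append(entry)
            else:
                pools["terminal_junction"].append(entry)

    tier_counts = _apportion(spec.n_variants, dict(spec.tier_mix))
    put_elements = _apportion(tier_counts["putative"], dict(spec.element_mix))

    plan: list[tuple[str, str]] = []          # (tier, pool name)
    for cls, k in put_elements.items():
        plan += [("putative", cls)] * k
    rare_pool = ("stem_inert" if spec.policy == "rare_allowed" else "any")
    plan += [("rare_conserved", rare_pool)] * tier_counts["rare_conserved"]
    plan += [("polymorphism", "any")] * tier_counts["polymorphism"]

    anywhere = pools["loop"] + pools["stem"] + pools["terminal_junction"]
    used: set[int] = set()
    variants, truth = [], []
    for tier, pool_name in plan:
        pool = anywhere if pool_name == "any" else pools[pool_name]
        candidates = [e for e in pool if e[2] not in used]
        if not candidates:
            raise SynthSpecError(
                f"no eligible positions left for tier {tier!r} "
                f"(pool {pool_name!r})")
        gid, label, genomic = candidates[rng.integers(len(candidates))]
        used.add(genomic)
        gene = genes[gid]
        pos = gene.position(label)
        if pool_name in ("stem", "stem_inert"):
            partner = gene.base_at(pos.partner)
            alts = [b for b in _BASES
                    if b != pos.base and not is_watson_crick(b, partner)]
        else:
            alts = [b for b in _BASES if b != pos.base]
        trna_alt = alts[rng.integers(len(alts))]
        ci_lo, ci_hi = spec.ci_range[tier]
        ci = int(rng.integers(ci_lo, ci_hi + 1))
        c_lo, c_hi = spec.control_count_range[tier]
        controls = int(rng.integers(c_lo, c_hi + 1))
        cases = int(rng.integers(1, 4))
        variant = MtVariant(
            position=genomic,
            ref_allele=_heavy_allele(gene, pos.base),
            alt_allele=_heavy_allele(gene, trna_alt),
            case_carriers=cases, control_carriers=controls, supplied_ci=ci)
        variants.append(variant)
        truth.append({"position": genomic, "gene": gid, "trna_position": label,
                      "element": pos.element.canonical_name,
                      "true_tier": tier, "ci": ci,
                      "case_carriers": cases, "control_carriers": controls})
    order = np.argsort([v.position for v in variants])
    variants = [variants[i] for i in order]
    truth_frame = (pd.DataFrame([truth[i] for i in order])
                   .reset_index(drop=True))
    return variants, truth_frame


def generate_alignment(gene: TrnaGeneDef,
                       target_ci_per_position: Mapping[str, float],
                       species_count: int = 16, seed: int = 0,
                       human: str = "Homo_sapiens") -> SpeciesAlignment:
    """Alignment whose CI at each requested position is exactly the target.

    Targets must be multiples of ``100/species_count``; other columns are
    fully conserved.  No gaps are emitted, so the ``non_gap`` and
    ``all_species`` counting modes agree on the result.
    """
    rng = np.random.default_rng(seed)
    labels = gene.labels()
    human_seq = gene.sequence()
    matches: dict[str, int] = {}
    for label, target in target_ci_per_position.items():
        label = str(label)
        if label not in gene.labels():
            raise SynthSpecError(f"{gene.gene_id}: no position {label}")
        m = target * species_count / 100
        if abs(m - round(m)) > 1e-9 or not 0 <= round(m) <= species_count:
            raise SynthSpecError(
                f"position {label}: CI {target} not attainable with "
                f"{species_count} species (needs a multiple of "
                f"{100 / species_count:g})")
        matches[label] = int(round(m))

    species = [human] + [f"species_{i:02d}" for i in range(1, species_count + 1)]
    rows = {sp: list(human_seq) for sp in species}
    col_of = {label: i for i, label in enumerate(labels)}
    for label, m in matches.items():
        col = col_of[label]
        mismatching = rng.permutation(species_count)[: species_count - m]
        for idx in mismatching:
            sp = species[1 + int(idx)]
            current = rows[sp][col]
            rows[sp][col] = _BASES[(_BASES.index(current) + 1) % 4]
    return SpeciesAlignment(
        gene_id=gene.gene_id, species=tuple(species),
        rows={sp: "".join(chars) for sp, chars in rows.items()},
        human=human, column_map=col_of)


@dataclass(frozen=True)
class CohortSpec:
    """Target clinical rates (defaults mirror a 494-patient tic-disorder
    cohort: 81.6% male, onset mostly at 6-11 years, TS/CTD/PTD mix)."""

    n_subjects: int = 494
    male: float = 403 / 494
    onset_bands: Mapping[str, float] = field(default_factory=lambda: {
        "0-5": 129 / 494, "6-11": 334 / 494, "12-18": 31 / 494})
    diagnoses: Mapping[str, float] = field(default_factory=lambda: {
        "TS": 146 / 494, "CTD": 134 / 494, "PTD": 214 / 494})
    symptoms: Mapping[str, float] = field(default_factory=lambda: {
        "blinking": 415 / 494, "grimacing": 246 / 494,
        "throat_clearing": 234 / 494, "shrug": 131 / 494,
        "head_shake": 140 / 494, "spit": 26 / 494})
    prior_drugs: Mapping[str, float] = field(default_factory=lambda: {
        "0": 248 / 494, "1": 112 / 494, "2": 101 / 494,
        "3": 24 / 494, "4+": 9 / 494})

    def validate(self) -> None:
        for name, rates in (("onset_bands", self.onset_bands),
                            ("diagnoses", self.diagnoses),
                            ("prior_drugs", self.prior_drugs)):
            if abs(sum(rates.values()) - 1) > 1e-9:
                raise SynthSpecError(f"{name} rates must sum to 1")
        all_rates = ([self.male] + list(self.onset_bands.values())
                     + list(self.diagnoses.values())
                     + list(self.symptoms.values())
                     + list(self.prior_drugs.values()))
        if any(not 0 <= r <= 1 for r in all_rates):
            raise SynthSpecError("rates must lie in [0, 1]")


def _assign_exclusive(rng, n: int, rates: Mapping[str, float],
                      exact: bool) -> list[str]:
    levels = list(rates)
    if exact:
        counts = _apportion(n, dict(rates))
        values = sum(([lvl] * counts[lvl] for lvl in levels), [])
        return [values[i] for i in rng.permutation(n)]
    return [levels[i] for i in rng.choice(
        len(levels), size=n, p=np.asarray(list(rates.values())))]


def _assign_binary(rng, n: int, rate: float, exact: bool) -> np.ndarray:
    if exact:
        k = int(round(rate * n))
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        return flags[rng.permutation(n)]
    return rng.random(n) < rate


def generate_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0,
                    exact_counts: bool = True) -> list[SubjectRecord]:
    """Subject records with the requested clinical rates.

    ``exact_counts`` realizes each target count exactly (rounded to the
    nearest integer, exclusive variables apportioned by largest remainder);
    otherwise each attribute is drawn independently.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    sexes = _assign_binary(rng, n, spec.male, exact_counts)
    bands = _assign_exclusive(rng, n, spec.onset_bands, exact_counts)
    dxs = _assign_exclusive(rng, n, spec.diagnoses, exact_counts)
    drugs = _assign_exclusive(rng, n, spec.prior_drugs, exact_counts)
    symptom_flags = {sym: _assign_binary(rng, n, rate, exact_counts)
                     for sym, rate in spec.symptoms.items()}
    band_ages = {"0-5": 4.0, "6-11": 8.0, "12-18": 13.0}
    subjects = []
    for i in range(n):
        subjects.append(SubjectRecord(
            subject_id=f"S{i + 1:04d}",
            sex="male" if sexes[i] else "female",
            age_years=band_ages[bands[i]],
            onset_band=bands[i],
            diagnosis=dxs[i],
            symptoms=frozenset(s for s in SYMPTOMS if symptom_flags[s][i]),
            prior_drugs=drugs[i],
        ))
    return subjects
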