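"""Structural annotation of mtDNA variants falling in tRNA genes.

A raw variant (rCRS coordinate, heavy-strand alleles, cohort carrier
counts) is mapped to its gene, conventional tRNA position and structural
element; alleles are converted to tRNA-strand bases; stem variants get a
Watson-Crick pairing-effect call; and a conservation index is attached
either from a multi-species alignment or from a value supplied with the
variant table.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .conservation import (
    DEFAULT_CI_THRESHOLD, ConservationResult, SpeciesAlignment,
    conservation_index,
)
from .model import (
    GeneSet, StructuralElement, TrnaGeneDef, is_watson_crick, trna_strand_base,
)

#: Conventional positions treated as functional/tertiary-core sites for the
#: loop-impact rule: the 8-14 tertiary contact, the 18-55 D/T-loop contact,
#: the wobble position 34 and anticodon-adjacent 37/38, the T-loop 55/58
#: pair, and the discriminator 73.  Overridable per call.
DEFAULT_FUNCTIONAL_SITES = frozenset(
    {"8", "14", "18", "34", "37", "38", "55", "58", "73"})

DELETION = "-"


class AnnotationError(ValueError):
    pass


class NotInTrnaError(AnnotationError):
    """The variant position does not fall inside any tRNA gene."""


@dataclass(frozen=True)
class MtVariant:
    """A single mtDNA substitution or 1-bp deletion in rCRS coordinates,
    with heavy-strand alleles and per-cohort carrier counts."""

    position: int
    ref_allele: str
    alt_allele: str                  # "-" for a deletion
    case_carriers: int = 0
    control_carriers: int = 0
    supplied_ci: Optional[float] = None
    known_flag: Optional[bool] = None

    def __post_init__(self):
        if self.ref_allele not in "ACGT":
            raise ValueError(f"bad ref allele {self.ref_allele!r}")
        if self.alt_allele not in ("A", "C", "G", "T", DELETION):
            raise ValueError(f"bad alt allele {self.alt_allele!r}")
        if not self.is_deletion and self.ref_allele == self.alt_allele:
            raise ValueError(f"m.{self.position}: ref equals alt")
        if self.case_carriers < 0 or self.control_carriers < 0:
            raise ValueError("carrier counts must be >= 0")

    @property
    def is_deletion(self) -> bool:
        return self.alt_allele == DELETION

    @property
    def notation(self) -> str:
        if self.is_deletion:
            return f"m.{self.position}del{self.ref_allele}"
        return f"m.{self.position}{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class WcEffect:
    """Predicted Watson-Crick pairing consequence at a stem position.

    ``before_pair``/``after_pair`` are (variant-position base, partner base)
    on the tRNA strand; they are ``None`` off-stem and for deletions.
    """

    status: str   # disrupts_pair | creates_pair | no_pair_change | not_applicable
    before_pair: Optional[tuple[str, str]] = None
    after_pair: Optional[tuple[str, str]] = None

    def pair_text(self) -> str:
        """Report form: the informative pair with a direction arrow, e.g.
        ``A-U↓`` (a WC pair lost) or ``C-G↑`` (a WC pair gained)."""
        if self.status == "disrupts_pair":
            return "-".join(self.before_pair) + "↓"
        if self.status == "creates_pair":
            return "-".join(self.after_pair) + "↑"
        return ""


def wc_effect(gene: TrnaGeneDef, label: str, trna_ref: str,
              trna_alt: Optional[str]) -> WcEffect:
    """Pairing effect of a tRNA-strand base change at a conventional
    position.  ``trna_alt=None`` denotes a deletion.  Positions without a
    pairing partner return ``not_applicable``."""
    pos = gene.position(label)
    if pos.partner is None:
        return WcEffect(status="not_applicable")
    if trna_ref not in "ACGU" or (trna_alt is not None and trna_alt not in "ACGU"):
        raise ValueError("tRNA bases must be A/C/G/U")
    partner_base = gene.base_at(pos.partner)
    before = (trna_ref, partner_base)
    if trna_alt is None:   # deletion removes the pair outright
        return WcEffect(status="disrupts_pair" if is_watson_crick(*before)
                        else "no_pair_change",
                        before_pair=before, after_pair=None)
    after = (trna_alt, partner_base)
    wc_before, wc_after = is_watson_crick(*before), is_watson_crick(*after)
    if wc_before and not wc_after:
        status = "disrupts_pair"
    elif wc_after and not wc_before:
        status = "creates_pair"
    else:
        status = "no_pair_change"
    return WcEffect(status=status, before_pair=before, after_pair=after)


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: MtVariant
    gene_id: str
    conventional_position: str
    element: StructuralElement
    trna_ref: str
    trna_alt: Optional[str]          # None for deletions
    wc: WcEffect
    ci: ConservationResult
    tertiary_site: bool

    @property
    def is_conserved(self) -> bool:
        return self.ci.is_conserved


def annotate(variant: MtVariant, genes: GeneSet,
             alignments: Optional[Mapping[str, SpeciesAlignment]] = None,
             supplied_ci: Optional[float] = None,
             ci_threshold: float = DEFAULT_CI_THRESHOLD,
             ci_mode: str = "non_gap",
             functional_sites: frozenset[str] = DEFAULT_FUNCTIONAL_SITES,
             ) -> AnnotatedVariant:
    """Fully annotate one variant.

    CI is taken from the per-gene alignment when one is available,
    otherwise from ``supplied_ci`` / the value carried by the variant
    record; having neither is a configuration error.
    """
    located = genes.locate(variant.position)
    if located is None:
        raise NotInTrnaError(
            f"{variant.notation}: position is not inside any mt-tRNA gene")
    gene, label = located.gene, located.label
    trna_ref = trna_strand_base(gene, variant.ref_allele)
    trna_alt = (None if variant.is_deletion
                else trna_strand_base(gene, variant.alt_allele))
    wc = wc_effect(gene, label, trna_ref, trna_alt)

    aln = (alignments or {}).get(gene.gene_id)
    if aln is not None:
        ci = conservation_index(aln, label, mode=ci_mode, threshold=ci_threshold)
    else:
        value = supplied_ci if supplied_ci is not None else variant.supplied_ci
        if value is None:
            raise AnnotationError(
                f"{variant.notation}: no conservation source (no alignment "
                f"for {gene.gene_id} and no supplied CI)")
        ci = ConservationResult.from_percent(label, value, threshold=ci_threshold)

    tertiary = label in functional_sites or label in gene.tertiary_labels()
    return AnnotatedVariant(
        variant=variant, gene_id=gene.gene_id, conventional_position=label,
        element=located.element, trna_ref=trna_ref, trna_alt=trna_alt,
        wc=wc, ci=ci, tertiary_site=tertiary)


def structural_impact(av: AnnotatedVariant) -> bool:
    """Criterion 3 of the screen: is the variant predicted to alter tRNA
    structure or function?

    Stem positions: yes iff the Watson-Crick pairing status changes
    (a pair lost or gained).  Non-stem positions: yes iff the position is a
    listed tertiary/functional site or is evolutionarily conserved.
    """
    if av.element.is_stem:
        return av.wc.status in ("disrupts_pair", "creates_pair")
    return av.tertiary_site or av.is_conserved


def with_ci(av: AnnotatedVariant, percent: float) -> AnnotatedVariant:
    """Copy of an annotated variant with a different CI value (same
    threshold); used by perturbation/property tests."""
    return replace(av, ci=ConservationResult.from_percent(
        av.conventional_position, percent, threshold=av.ci.threshold))
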