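"""Interspecies conservation index (CI) for mt-tRNA positions.

The CI of a position is the percentage of aligned non-human species whose
nucleotide matches the human nucleotide at that alignment column.  The
screening criterion used downstream is strict: a position counts as
evolutionarily conserved only when CI exceeds the threshold (default 75%).

Two counting modes are supported because published CI values rarely state
how alignment gaps were handled:

``non_gap`` (default)
    species with a gap at the column are dropped from the denominator;
``all_species``
    every non-human species counts, gaps scoring as mismatches.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Optional, Sequence

from Bio import SeqIO

from .model import TrnaGeneDef

GAP_CHARS = frozenset("-.")
DEFAULT_CI_THRESHOLD = 75.0
DEFAULT_HUMAN = "Homo_sapiens"


class AlignmentError(ValueError):
    pass


def _canon(ch: str) -> str:
    return ch.upper().replace("T", "U")


@dataclass
class SpeciesAlignment:
    """A per-gene multi-species alignment with the human row identified and
    a map from conventional tRNA positions to alignment columns."""

    gene_id: str
    species: Sequence[str]            # ordered, human included
    rows: Mapping[str, str]           # species -> aligned sequence
    human: str
    column_map: Mapping[str, int]     # conventional label -> 0-based column

    def __post_init__(self):
        if self.human not in self.rows:
            raise AlignmentError(
                f"{self.gene_id}: human row {self.human!r} missing")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"{self.gene_id}: ragged alignment rows")
        (self._ncol,) = lengths
        if len(set(self.column_map.values())) != len(self.column_map):
            raise AlignmentError(f"{self.gene_id}: column_map not injective")
        hrow = self.rows[self.human]
        for label, col in self.column_map.items():
            if not 0 <= col < self._ncol:
                raise AlignmentError(f"{self.gene_id}: column {col} out of range")
            if hrow[col] in GAP_CHARS:
                raise AlignmentError(
                    f"{self.gene_id}: human row gapped at mapped position {label}")

    @property
    def n_species(self) -> int:
        """Number of non-human species."""
        return len(self.rows) - 1

    @classmethod
    def from_fasta(cls, path: str | Path, gene: TrnaGeneDef,
                   human: str = DEFAULT_HUMAN) -> "SpeciesAlignment":
        """Read a per-gene multi-FASTA alignment.  Record ids are
        ``species`` or ``species|gene_id``; the human row's ungapped length
        must equal the gene length so columns can be mapped onto the gene's
        conventional numbering."""
        species, rows = [], {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id.split("|")[0]
            if name in rows:
                raise AlignmentError(f"duplicate species {name!r} in {path}")
            species.append(name)
            rows[name] = str(rec.seq)
        if human not in rows:
            raise AlignmentError(f"no {human!r} record in {path}")
        hrow = rows[human]
        ungapped = [i for i, ch in enumerate(hrow) if ch not in GAP_CHARS]
        labels = gene.labels()
        if len(ungapped) != len(labels):
            raise AlignmentError(
                f"{gene.gene_id}: human row has {len(ungapped)} bases, "
                f"gene model has {len(labels)} positions")
        column_map = dict(zip(labels, ungapped))
        return cls(gene_id=gene.gene_id, species=tuple(species), rows=rows,
                   human=human, column_map=column_map)


@dataclass(frozen=True)
class ConservationResult:
    position: str
    ci_percent: float
    ci_exact: Fraction
    n_species_counted: int
    is_conserved: bool
    threshold: float = DEFAULT_CI_THRESHOLD

    @classmethod
    def from_percent(cls, position: str, percent: float | Fraction,
                     n_species: int = 0,
                     threshold: float = DEFAULT_CI_THRESHOLD
                     ) -> "ConservationResult":
        """Wrap a precomputed CI value (e.g. one supplied in a variant
        table) in a result object, applying the strict threshold."""
        exact = Fraction(percent).limit_denominator(10**6)
        if not 0 <= exact <= 100:
            raise ValueError(f"CI must be in [0, 100], got {percent}")
        return cls(position=str(position), ci_percent=round(float(exact), 2),
                   ci_exact=exact, n_species_counted=n_species,
                   is_conserved=is_conserved(exact, threshold),
                   threshold=threshold)


def is_conserved(ci_percent: float | Fraction,
                 threshold: float = DEFAULT_CI_THRESHOLD) -> bool:
    """Strict inequality: a position at exactly the threshold is *not*
    conserved."""
    if not 0 <= ci_percent <= 100:
        raise ValueError(f"CI must be in [0, 100], got {ci_percent}")
    return ci_percent > Fraction(threshold).limit_denominator(10**6)


def conservation_index(aln: SpeciesAlignment, position: str,
                       mode: str = "non_gap",
                       threshold: float = DEFAULT_CI_THRESHOLD
                       ) -> ConservationResult:
    """CI of one conventional tRNA position from a multi-species alignment.

    The human character defines the consensus; the exact rational
    matches/denominator is kept alongside the 2-decimal percentage, and the
    threshold comparison uses the exact value.
    """
    if mode not in ("non_gap", "all_species"):
        raise ValueError(f"unknown counting mode {mode!r}")
    position = str(position)
    try:
        col = aln.column_map[position]
    except KeyError:
        raise KeyError(
            f"{aln.gene_id}: position {position} not mapped to a column") from None
    if aln.n_species == 0:
        raise ValueError(f"{aln.gene_id}: alignment has no non-human species")
    human_char = _canon(aln.rows[aln.human][col])
    matches = counted = 0
    for sp in aln.species:
        if sp == aln.human:
            continue
        ch = aln.rows[sp][col]
        if ch in GAP_CHARS:
            if mode == "non_gap":
                continue
            counted += 1
        else:
            counted += 1
            if _canon(ch) == human_char:
                matches += 1
    if counted == 0:
        raise ValueError(
            f"{aln.gene_id}: no species counted at position {position}")
    exact = Fraction(100 * matches, counted)
    return ConservationResult(
        position=position, ci_percent=round(float(exact), 2), ci_exact=exact,
        n_species_counted=counted, is_conserved=is_conserved(exact, threshold),
        threshold=threshold)
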