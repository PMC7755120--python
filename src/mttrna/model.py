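"""Structural model of the 22 human mitochondrial tRNA genes.

Each gene is described by its rCRS (NC_012920.1) coordinate span, the strand
it is encoded on, and a cloverleaf layout: an ordered list of conventional
tRNA position labels (integers with occasional insertion labels such as
``27a``), each carrying a tRNA-strand reference base, a structural element
assignment, and -- for stem positions -- a secondary-structure pairing
partner.  Eight of the 22 genes are encoded on the light strand, so their
tRNA-level bases are the Watson-Crick complements of the heavy-strand
(rCRS) alleles in which mtDNA variants are conventionally reported.

The definitions ship as a human-editable text fixture
(``data/structure.txt``) and are validated exhaustively at load time.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

MTDNA_LENGTH = 16569

GENE_IDS = (
    "MT-TA", "MT-TC", "MT-TD", "MT-TE", "MT-TF", "MT-TG", "MT-TH", "MT-TI",
    "MT-TK", "MT-TL1", "MT-TL2", "MT-TM", "MT-TN", "MT-TP", "MT-TQ", "MT-TR",
    "MT-TS1", "MT-TS2", "MT-TT", "MT-TV", "MT-TW", "MT-TY",
)

STEM_ELEMENTS = frozenset({"acceptor_stem", "d_stem", "anticodon_stem", "t_stem"})
LOOP_ELEMENTS = frozenset({"d_loop", "anticodon_loop", "variable_loop", "t_loop"})
ALL_ELEMENTS = STEM_ELEMENTS | LOOP_ELEMENTS | {"junction", "acceptor_terminus"}

#: Synonyms as they appear in published variant tables.
_ELEMENT_SYNONYMS = {
    "acc-stem": "acceptor_stem",
    "acc stem": "acceptor_stem",
    "acceptor stem": "acceptor_stem",
    "acc terminus": "acceptor_terminus",
    "acceptor terminus": "acceptor_terminus",
    "dhu-stem": "d_stem",
    "d-stem": "d_stem",
    "d stem": "d_stem",
    "dhu-loop": "d_loop",
    "d-loop": "d_loop",
    "d loop": "d_loop",
    "ac stem": "anticodon_stem",
    "anticodon stem": "anticodon_stem",
    "ac loop": "anticodon_loop",
    "anticodon loop": "anticodon_loop",
    "t-stem": "t_stem",
    "t stem": "t_stem",
    "t-loop": "t_loop",
    "t loop": "t_loop",
    "variable loop": "variable_loop",
    "d-a junction": "junction",
    "junction": "junction",
}

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
_WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})


class StructureError(ValueError):
    """Raised when a structure-definition file violates a model invariant."""


def normalize_element(text: str) -> str:
    """Map a free-text structural location (e.g. ``"DHU-stem"``) to its
    canonical element name.  Raises :class:`StructureError` for vocabulary
    outside the supported synonym set."""
    key = text.strip().lower()
    if key in ALL_ELEMENTS:
        return key
    try:
        return _ELEMENT_SYNONYMS[key]
    except KeyError:
        raise StructureError(f"unknown structural location {text!r}") from None


def is_watson_crick(base5: str, base3: str) -> bool:
    """True for the canonical A-U / G-C pairs only; G·U wobble is not WC."""
    return (base5, base3) in _WC_PAIRS


def label_sort_key(label: str) -> tuple[int, str]:
    m = re.fullmatch(r"(\d+)([a-z]?)", str(label))
    if not m:
        raise StructureError(f"bad conventional position label {label!r}")
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class StructuralElement:
    canonical_name: str
    junction_label: Optional[str] = None

    def __post_init__(self):
        if self.canonical_name not in ALL_ELEMENTS:
            raise StructureError(f"unknown element {self.canonical_name!r}")

    @property
    def is_stem(self) -> bool:
        return self.canonical_name in STEM_ELEMENTS

    @property
    def is_loop(self) -> bool:
        return self.canonical_name in LOOP_ELEMENTS

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.junction_label:
            return f"{self.canonical_name}({self.junction_label})"
        return self.canonical_name


@dataclass(frozen=True)
class TrnaPosition:
    """One encoded cloverleaf position of a single gene."""

    label: str                      # conventional tRNA number, e.g. "28", "27a"
    base: str                       # tRNA-strand reference base, RNA alphabet
    element: StructuralElement
    partner: Optional[str] = None   # pairing partner label for stem positions


@dataclass
class TrnaGeneDef:
    gene_id: str
    amino_acid: str
    rcrs_start: int
    rcrs_end: int
    strand: str                     # "heavy" | "light"
    positions: Sequence[TrnaPosition]          # ordered 5'->3' along the tRNA
    tertiary_pairs: Sequence[tuple[str, str]] = field(default_factory=tuple)

    def __post_init__(self):
        self._by_label = {p.label: p for p in self.positions}
        if len(self._by_label) != len(self.positions):
            raise StructureError(f"{self.gene_id}: duplicate position labels")
        self.validate()

    # -- invariant checks -------------------------------------------------
    def validate(self) -> None:
        gid = self.gene_id
        if self.rcrs_start > self.rcrs_end:
            raise StructureError(f"{gid}: rcrs_start > rcrs_end")
        if not 1 <= self.rcrs_start <= self.rcrs_end <= MTDNA_LENGTH:
            raise StructureError(f"{gid}: span outside the rCRS")
        if self.strand not in ("heavy", "light"):
            raise StructureError(f"{gid}: strand must be heavy or light")
        if len(self.positions) != self.length:
            raise StructureError(
                f"{gid}: {len(self.positions)} positions for a "
                f"{self.length} bp span")
        for p in self.positions:
            label_sort_key(p.label)
            if p.base not in "ACGU":
                raise StructureError(f"{gid} pos {p.label}: bad base {p.base!r}")
            if p.partner is not None:
                if not p.element.is_stem:
                    raise StructureError(
                        f"{gid} pos {p.label}: paired but element is "
                        f"{p.element.canonical_name}, not a stem")
                q = self._by_label.get(p.partner)
                if q is None or q.partner != p.label:
                    raise StructureError(
                        f"{gid} pos {p.label}: pairing_map not symmetric "
                        f"(partner {p.partner})")
            elif p.element.is_stem:
                raise StructureError(
                    f"{gid} pos {p.label}: stem position without a partner")
        for a, b in self.tertiary_pairs:
            if a not in self._by_label or b not in self._by_label:
                raise StructureError(f"{gid}: tertiary pair {a}-{b} off-model")

    # -- basic accessors --------------------------------------------------
    @property
    def length(self) -> int:
        return self.rcrs_end - self.rcrs_start + 1

    @property
    def is_light(self) -> bool:
        return self.strand == "light"

    def contains(self, position: int) -> bool:
        return self.rcrs_start <= position <= self.rcrs_end

    def label_at(self, position: int) -> str:
        """Conventional label for a genomic rCRS coordinate inside the gene."""
        if not self.contains(position):
            raise KeyError(f"{position} not in {self.gene_id}")
        i = (self.rcrs_end - position if self.is_light
             else position - self.rcrs_start)
        return self.positions[i].label

    def genomic_at(self, label: str) -> int:
        i = self.positions.index(self._by_label[label])
        return (self.rcrs_end - i) if self.is_light else (self.rcrs_start + i)

    def position(self, label: str) -> TrnaPosition:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(
                f"{self.gene_id} has no conventional position {label!r}") from None

    def element_at(self, label: str) -> StructuralElement:
        return self.position(label).element

    def base_at(self, label: str) -> str:
        return self.position(label).base

    def sequence(self) -> str:
        """tRNA-strand reference sequence, 5'->3'."""
        return "".join(p.base for p in self.positions)

    def labels(self) -> list[str]:
        return [p.label for p in self.positions]

    def tertiary_labels(self) -> frozenset[str]:
        return frozenset(l for pair in self.tertiary_pairs for l in pair)


def trna_strand_base(gene: TrnaGeneDef, genomic_base: str) -> str:
    """tRNA-level base for a heavy-strand (rCRS) allele: identity for
    heavy-strand genes, Watson-Crick complement for light-strand genes;
    T is rendered as U either way."""
    b = genomic_base.upper()
    if b not in _DNA_COMPLEMENT:
        raise ValueError(f"not a nucleotide: {genomic_base!r}")
    if gene.is_light:
        b = _DNA_COMPLEMENT[b]
    return b.replace("T", "U")


def pairing_partner(gene: TrnaGeneDef, label: str) -> Optional[str]:
    """Secondary-structure partner of a conventional position, or ``None``
    for loop / junction / terminus positions."""
    return gene.position(label).partner


@dataclass(frozen=True)
class LocatedPosition:
    gene: TrnaGeneDef
    label: str
    element: StructuralElement


class GeneSet:
    """The 22 tRNA gene definitions with coordinate-based lookup."""

    def __init__(self, genes: Iterable[TrnaGeneDef], require_complete: bool = True):
        self.genes: dict[str, TrnaGeneDef] = {g.gene_id: g for g in genes}
        if require_complete:
            missing = set(GENE_IDS) - set(self.genes)
            if missing:
                raise StructureError(f"missing gene definitions: {sorted(missing)}")
        spans = sorted((g.rcrs_start, g.rcrs_end, g.gene_id)
                       for g in self.genes.values())
        for (s1, e1, g1), (s2, e2, g2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise StructureError(f"overlapping spans: {g1} and {g2}")
        self._spans = spans

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> TrnaGeneDef:
        return self.genes[gene_id]

    def locate(self, position: int) -> Optional[LocatedPosition]:
        """Map an rCRS coordinate to (gene, conventional position, element),
        or ``None`` when the coordinate is not inside any tRNA gene."""
        if not 1 <= position <= MTDNA_LENGTH:
            raise ValueError(
                f"position {position} outside the rCRS (1..{MTDNA_LENGTH})")
        for start, end, gid in self._spans:
            if start <= position <= end:
                gene = self.genes[gid]
                label = gene.label_at(position)
                return LocatedPosition(gene, label, gene.element_at(label))
            if position < start:
                break
        return None


# ---------------------------------------------------------------------------
# structure-definition file
# ---------------------------------------------------------------------------

def _parse_gene_block(header: Mapping[str, str], gene_id: str,
                      pos_lines, tert_lines) -> TrnaGeneDef:
    try:
        start, end = (int(x) for x in header["span"].split("-"))
    except (KeyError, ValueError):
        raise StructureError(f"{gene_id}: bad or missing span") from None
    strand = {"H": "heavy", "L": "light"}.get(header.get("strand", ""))
    if strand is None:
        raise StructureError(f"{gene_id}: strand must be H or L")
    positions = []
    for label, base, element, opts in pos_lines:
        jl = opts.get("junction", "").replace("_", " ") or None
        positions.append(TrnaPosition(
            label=label, base=base,
            element=StructuralElement(normalize_element(element), jl),
            partner=opts.get("pair")))
    return TrnaGeneDef(
        gene_id=gene_id, amino_acid=header.get("aa", "?"),
        rcrs_start=start, rcrs_end=end, strand=strand,
        positions=tuple(positions), tertiary_pairs=tuple(tert_lines))


def load_gene_definitions(path: Optional[str | Path] = None,
                          require_complete: bool = True) -> GeneSet:
    """Load (and validate) tRNA gene definitions.

    With no ``path``, the packaged default file covering all 22 human
    mt-tRNA genes is used.
    """
    if path is None:
        src = resources.files("mttrna").joinpath("data/structure.txt")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")

    genes: list[TrnaGeneDef] = []
    gene_id = None
    header: dict[str, str] = {}
    pos_lines: list = []
    tert_lines: list = []

    def flush():
        if gene_id is not None:
            genes.append(_parse_gene_block(header, gene_id, pos_lines, tert_lines))

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        kind = fields[0]
        if kind == "gene":
            flush()
            gene_id = fields[1]
            header = dict(f.split("=", 1) for f in fields[2:] if "=" in f)
            pos_lines, tert_lines = [], []
        elif kind == "pos":
            if gene_id is None:
                raise StructureError(f"line {lineno}: pos before any gene")
            if len(fields) < 4:
                raise StructureError(f"line {lineno}: malformed pos line")
            opts = dict(f.split("=", 1) for f in fields[4:] if "=" in f)
            pos_lines.append((fields[1], fields[2], fields[3], opts))
        elif kind == "tertiary":
            a, _, b = fields[1].partition("-")
            tert_lines.append((a, b))
        else:
            raise StructureError(f"line {lineno}: unknown directive {kind!r}")
    flush()
    return GeneSet(genes, require_complete=require_complete)


# ---------------------------------------------------------------------------
# text rendering
# ---------------------------------------------------------------------------

_RENDER_ORDER = [
    "acceptor_stem", "junction", "d_stem", "d_loop", "anticodon_stem",
    "anticodon_loop", "variable_loop", "t_stem", "t_loop", "acceptor_terminus",
]


def render_cloverleaf(gene: TrnaGeneDef, highlight: Iterable[str] = ()) -> str:
    """Deterministic ASCII rendering of a gene's cloverleaf: one line per
    structural element, listing ``label:base`` tokens 5'->3', with
    highlighted positions wrapped in ``[...]``."""
    marks = {str(h) for h in highlight}
    unknown = marks - set(gene.labels())
    if unknown:
        raise KeyError(
            f"{gene.gene_id} has no position(s) {sorted(unknown)} to highlight")
    strand = "light" if gene.is_light else "heavy"
    lines = [f"{gene.gene_id}  tRNA-{gene.amino_acid}  ({strand} strand, "
             f"m.{gene.rcrs_start}-{gene.rcrs_end})"]
    groups: dict[str, list[str]] = {}
    for p in gene.positions:
        token = f"{p.label}:{p.base}"
        if p.label in marks:
            token = f"[{token}]"
        groups.setdefault(p.element.canonical_name, []).append(token)
    for name in _RENDER_ORDER:
        if name in groups:
            lines.append(f"  {name:<17} {' '.join(groups[name])}")
    if gene.tertiary_pairs:
        pairs = " ".join(f"{a}-{b}" for a, b in gene.tertiary_pairs)
        lines.append(f"  {'tertiary':<17} {pairs}")
    return "\n".join(lines)
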