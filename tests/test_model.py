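"""Structural model: gene definitions, coordinate mapping, pairing."""
import random

import pytest

from mttrna.model import (
    GENE_IDS, MTDNA_LENGTH, STEM_ELEMENTS, StructureError, load_gene_definitions,
    normalize_element, pairing_partner, render_cloverleaf, trna_strand_base,
)

LIGHT_GENES = {"MT-TQ", "MT-TA", "MT-TN", "MT-TC", "MT-TY", "MT-TS1",
               "MT-TE", "MT-TP"}


def test_default_file_covers_all_22_genes(genes):
    assert len(genes) == 22
    assert set(g.gene_id for g in genes) == set(GENE_IDS)
    assert {g.gene_id for g in genes if g.is_light} == LIGHT_GENES


@pytest.mark.parametrize("position, gene_id, label, element", [
    (4452, "MT-TM", "55", "t_loop"),
    (15910, "MT-TT", "25", "d_stem"),
    (7502, "MT-TS1", "14", "d_loop"),
    (4373, "MT-TQ", "28", "anticodon_stem"),
    (7492, "MT-TS1", "27a", "junction"),
])
def test_locate_known_positions(genes, position, gene_id, label, element):
    loc = genes.locate(position)
    assert (loc.gene.gene_id, loc.label, loc.element.canonical_name) == \
        (gene_id, label, element)


def test_locate_outside_trna_and_out_of_range(genes):
    assert genes.locate(5000) is None          # inside MT-ND2
    assert genes.locate(1) is None             # control region
    with pytest.raises(ValueError):
        genes.locate(0)
    with pytest.raises(ValueError):
        genes.locate(MTDNA_LENGTH + 1)


def test_locate_agrees_with_brute_force_scan(genes):
    spans = [(g.rcrs_start, g.rcrs_end, g.gene_id) for g in genes]
    rng = random.Random(20_240_101)
    for _ in range(10_000):
        pos = rng.randint(1, MTDNA_LENGTH)
        hits = [gid for s, e, gid in spans if s <= pos <= e]
        loc = genes.locate(pos)
        if hits:
            assert loc is not None and loc.gene.gene_id == hits[0]
        else:
            assert loc is None


def test_element_blocks_partition_and_stems_pair_evenly(genes):
    for gene in genes:
        labels = gene.labels()
        assert len(set(labels)) == len(labels)          # injective numbering
        paired = {p.label for p in gene.positions if p.partner is not None}
        for p in gene.positions:
            if p.element.canonical_name in STEM_ELEMENTS:
                assert p.label in paired
                q = gene.position(p.partner)
                assert q.partner == p.label             # symmetric, involutive
                assert q.element.canonical_name in STEM_ELEMENTS
            else:
                assert p.partner is None
        assert len(paired) % 2 == 0


def test_trna_strand_base_heavy_identity_light_complement(genes):
    assert trna_strand_base(genes["MT-TT"], "C") == "C"
    assert trna_strand_base(genes["MT-TT"], "T") == "U"
    assert trna_strand_base(genes["MT-TP"], "A") == "U"
    assert trna_strand_base(genes["MT-TQ"], "G") == "C"
    with pytest.raises(ValueError):
        trna_strand_base(genes["MT-TT"], "N")


def test_pairing_partner_stem_loop_and_terminus(genes):
    assert pairing_partner(genes["MT-TW"], "49") == "65"   # T-stem pair
    assert pairing_partner(genes["MT-TM"], "55") is None   # T-loop
    assert pairing_partner(genes["MT-TA"], "73") is None   # discriminator
    with pytest.raises(KeyError):
        pairing_partner(genes["MT-TM"], "999")


def test_normalize_element_covers_published_vocabulary():
    cases = {
        "ACC-stem": "acceptor_stem", "ACC stem": "acceptor_stem",
        "ACC terminus": "acceptor_terminus", "DHU-stem": "d_stem",
        "D-stem": "d_stem", "DHU-loop": "d_loop", "D-loop": "d_loop",
        "AC stem": "anticodon_stem", "Anticodon stem": "anticodon_stem",
        "AC loop": "anticodon_loop", "Anticodon loop": "anticodon_loop",
        "T-stem": "t_stem", "T-loop": "t_loop",
        "Variable loop": "variable_loop", "D-A junction": "junction",
    }
    for text, want in cases.items():
        assert normalize_element(text) == want
    with pytest.raises(StructureError):
        normalize_element("intron")


def test_render_cloverleaf_highlights_and_roundtrips(genes):
    gene = genes["MT-TT"]
    text = render_cloverleaf(gene, {"25"})
    d_stem_line = next(l for l in text.splitlines() if "d_stem" in l)
    assert "[25:C]" in d_stem_line
    # rendering lists every position exactly once, under its element
    rendered = {}
    for line in text.splitlines()[1:]:
        parts = line.split()
        if parts[0] in ("tertiary",):
            continue
        for token in parts[1:]:
            label = token.strip("[]").split(":")[0]
            rendered[label] = parts[0]
    assert rendered == {p.label: p.element.canonical_name
                        for p in gene.positions}
    assert render_cloverleaf(gene, set()).count("[") == 0
    with pytest.raises(KeyError):
        render_cloverleaf(gene, {"999"})


def test_render_marks_anticodon_loop_position(genes):
    text = render_cloverleaf(genes["MT-TP"], {"34"})
    line = next(l for l in text.splitlines() if "anticodon_loop" in l)
    assert "[34:" in line


def _write_structure(tmp_path, text):
    path = tmp_path / "structure.txt"
    path.write_text(text)
    return path


MINIMAL_GENE = """\
gene MT-TX aa=Xxx span={span} strand=H
  pos 1 G acceptor_stem pair=4
  pos 2 U t_loop
  pos 3 A t_loop
  pos 4 C acceptor_stem pair={back}
"""


def test_loader_rejects_asymmetric_pairing(tmp_path):
    path = _write_structure(tmp_path, MINIMAL_GENE.format(span="100-103", back="2"))
    with pytest.raises(StructureError, match="MT-TX.*symmetric"):
        load_gene_definitions(path, require_complete=False)


def test_loader_rejects_overlapping_spans(tmp_path):
    block = MINIMAL_GENE.format(span="100-103", back="1")
    other = block.replace("MT-TX", "MT-TZ").replace("100-103", "103-106")
    with pytest.raises(StructureError, match="overlapping"):
        load_gene_definitions(_write_structure(tmp_path, block + other),
                              require_complete=False)


def test_loader_requires_all_genes_by_default(tmp_path):
    path = _write_structure(tmp_path, MINIMAL_GENE.format(span="100-103", back="1"))
    with pytest.raises(StructureError, match="missing gene"):
        load_gene_definitions(path)


def test_loader_rejects_span_length_mismatch(tmp_path):
    path = _write_structure(tmp_path, MINIMAL_GENE.format(span="100-110", back="1"))
    with pytest.raises(StructureError, match="MT-TX"):
        load_gene_definitions(path, require_complete=False)
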