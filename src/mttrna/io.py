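"""Readers and writers for variant tables, catalogs and screen reports.

Variant tables are TSV with a header; the position may be given either as
separate ``position``/``ref``/``alt`` columns or as a single ``variant``
column in ``m.<pos><ref>><alt>`` / ``m.<pos>del<ref>`` notation.  A minimal
VCF reader (chrM/MT/NC_012920.1; SNVs and 1-bp deletions) is provided for
interoperability.  All outputs are deterministic: fixed column order, rows
sorted by gene then position, percentages to 2 decimals.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from . import __version__
from .annotation import DELETION, MtVariant
from .classify import ScreenReport
from .model import MTDNA_LENGTH

CHROM_SYNONYMS = frozenset({"chrM", "MT", "NC_012920.1"})

_SUB_RE = re.compile(r"m\.(\d+)([ACGT])>([ACGT])")
_DEL_RE = re.compile(r"m\.(\d+)del([ACGT])")


class VariantParseError(ValueError):
    pass


def parse_variant_notation(text: str) -> tuple[int, str, str]:
    """Parse ``m.4373T>C`` / ``m.5878delT`` into (position, ref, alt);
    alt is ``"-"`` for deletions."""
    text = text.strip()
    m = _SUB_RE.fullmatch(text)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    else:
        m = _DEL_RE.fullmatch(text)
        if not m:
            raise VariantParseError(f"cannot parse variant notation {text!r}")
        pos, ref, alt = int(m.group(1)), m.group(2), DELETION
    if not 1 <= pos <= MTDNA_LENGTH:
        raise VariantParseError(
            f"{text!r}: position outside the rCRS (1..{MTDNA_LENGTH})")
    return pos, ref, alt


def _row_variant(row: dict, lineno: int) -> MtVariant:
    try:
        if row.get("variant"):
            pos, ref, alt = parse_variant_notation(str(row["variant"]))
        else:
            pos = int(row["position"])
            ref = str(row["ref"]).strip().upper()
            alt = str(row["alt"]).strip().upper()
            if row.get("kind", "").strip() == "deletion" or alt in ("", "-", "DEL"):
                alt = DELETION
        if not 1 <= pos <= MTDNA_LENGTH:
            raise ValueError(f"position {pos} outside the rCRS")
        ci = row.get("ci")
        known = row.get("known")
        return MtVariant(
            position=pos, ref_allele=ref, alt_allele=alt,
            case_carriers=int(row.get("case_carriers", 0) or 0),
            control_carriers=int(row.get("control_carriers", 0) or 0),
            supplied_ci=float(ci) if ci not in (None, "") else None,
            known_flag=(None if known in (None, "")
                        else str(known).strip().upper() in ("Y", "YES", "1", "TRUE")),
        )
    except VariantParseError:
        raise
    except (KeyError, ValueError) as exc:
        raise VariantParseError(f"line {lineno}: {exc}") from exc


def read_variants(path: str | Path) -> list[MtVariant]:
    """Read a variant TSV.  Duplicate (position, ref, alt) records are
    rejected; ``#`` lines are treated as comments."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                        keep_default_na=False)
    needed = {"variant"} if "variant" in frame.columns else {"position", "ref", "alt"}
    missing = needed - set(frame.columns)
    if missing:
        raise VariantParseError(f"{path}: missing columns {sorted(missing)}")
    variants, seen = [], set()
    for i, row in enumerate(frame.to_dict("records"), start=2):
        v = _row_variant(row, i)
        key = (v.position, v.ref_allele, v.alt_allele)
        if key in seen:
            raise VariantParseError(
                f"{path} line {i}: duplicate variant {v.notation}")
        seen.add(key)
        variants.append(v)
    return variants


def bundled_variants() -> list[MtVariant]:
    """The packaged example dataset: 73 mt-tRNA variants ascertained in a
    494-case / 485-control tic-disorder cohort, with published conservation
    values, carrier counts and novelty flags."""
    src = resources.files("mttrna").joinpath("data/cohort_variants.tsv")
    with resources.as_file(src) as path:
        return read_variants(path)


def bundled_variant_table() -> pd.DataFrame:
    """Same dataset as :func:`bundled_variants`, as a raw frame including
    the published tRNA position / structural location / pairing columns."""
    src = resources.files("mttrna").joinpath("data/cohort_variants.tsv")
    return pd.read_csv(src.open(), sep="\t", comment="#", dtype=str,
                       keep_default_na=False)


def read_catalog(path: Optional[str | Path] = None) -> dict[int, bool]:
    """Previously-reported catalog: position -> reported flag.  The
    packaged default covers the bundled cohort dataset."""
    if path is None:
        src = resources.files("mttrna").joinpath("data/reported_catalog.tsv")
        frame = pd.read_csv(src.open(), sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"position", "reported"} <= set(frame.columns):
        raise VariantParseError("catalog needs 'position' and 'reported' columns")
    return {int(r.position): str(r.reported).strip().upper() in ("Y", "YES", "1", "TRUE")
            for r in frame.itertuples(index=False)}


def read_vcf(path: str | Path) -> list[MtVariant]:
    """Minimal VCF ingestion: mitochondrial SNVs and 1-bp deletions.
    Carrier counts are taken from INFO fields ``CASES``/``CONTROLS`` when
    present, else 0."""
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.chrom not in CHROM_SYNONYMS:
                raise VariantParseError(
                    f"{path}: chromosome {rec.chrom!r} is not mitochondrial "
                    f"(expected one of {sorted(CHROM_SYNONYMS)})")
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1:
                    pos, ref, a = rec.pos, rec.ref, alt
                elif len(rec.ref) == 2 and len(alt) == 1 and rec.ref[0] == alt:
                    pos, ref, a = rec.pos + 1, rec.ref[1], DELETION
                else:
                    continue   # not an SNV or 1-bp deletion
                variants.append(MtVariant(
                    position=pos, ref_allele=ref, alt_allele=a,
                    case_carriers=int(rec.info.get("CASES", 0)),
                    control_carriers=int(rec.info.get("CONTROLS", 0))))
    return variants


def write_variants(variants: Iterable[MtVariant], path: str | Path,
                   seed: Optional[int] = None) -> None:
    """Write a variant TSV in the same format :func:`read_variants`
    consumes; a provenance comment records the generator seed."""
    rows = [{
        "position": v.position, "ref": v.ref_allele,
        "alt": v.alt_allele if not v.is_deletion else "-",
        "kind": "deletion" if v.is_deletion else "substitution",
        "ci": "" if v.supplied_ci is None else v.supplied_ci,
        "case_carriers": v.case_carriers,
        "control_carriers": v.control_carriers,
        "known": {True: "Y", False: "N", None: ""}[v.known_flag],
    } for v in sorted(variants, key=lambda v: (v.position, v.alt_allele))]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# mttrna {__version__} variant table"
                 + (f" (seed={seed})" if seed is not None else "") + "\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_report(report: ScreenReport, outdir: str | Path,
                 seed: Optional[int] = None) -> dict[str, Path]:
    """Write the screen outputs: per-variant classifications, per-gene
    tallies, summary counts, and the per-variant criterion decision log.
    Byte-identical across reruns on the same input."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv"
             for name in ("per_variant", "per_gene", "summary")}
    paths["decisions"] = outdir / "decisions.log"

    report.per_variant_frame().to_csv(paths["per_variant"], sep="\t", index=False)

    gene_counts = report.per_gene_counts()
    pd.DataFrame({"gene": list(gene_counts), "n_variants": list(gene_counts.values())}
                 ).to_csv(paths["per_gene"], sep="\t", index=False)

    summary = report.summary()
    summary["tool_version"] = __version__
    if seed is not None:
        summary["seed"] = seed
    pd.DataFrame({"key": list(summary), "value": [str(v) for v in summary.values()]}
                 ).to_csv(paths["summary"], sep="\t", index=False)

    with open(paths["decisions"], "w", encoding="utf-8") as fh:
        for cv in sorted(report.classified,
                         key=lambda c: (c.annotated.gene_id, c.variant.position)):
            fh.write(f"{cv.variant.notation} [{cv.annotated.gene_id}] "
                     f"-> {cv.tier}\n")
            for reason in cv.reasons:
                fh.write(f"    {reason}\n")
    return paths
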