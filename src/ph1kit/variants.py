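"""Variant nomenclature parsing and the tri-allelic AGXT haplotype vocabulary.

Variants are described in HGVS-like protein ("p.M49L", "p.Arg333*") and
cDNA ("c.145A>C", "c.33dupC") notation, singly or paired as
"p.M49L (c.145A > C)".  cDNA positions are 1-based from the A of the
initiator ATG; protein positions are 1-based from the initiator Met, so a
substitution at protein position ``p`` must fall in cDNA positions
``3p-2 .. 3p``.

The AGXT gene circulates as two polymorphic haplotypes: the common "major"
allele and a "minor" allele tagged by a 74-bp duplication in intron 1
(IVS1+74bp).  The minor-allele tag is modelled as a boolean haplotype
marker, not a sequence edit.  Mutation-bearing haplotypes are labelled
AGT-Ma (mutated major) and AGT-Mi (mutated minor); AGT-MA is the normal
major allele.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio.Data.IUPACData import protein_letters, protein_letters_3to1

__all__ = [
    "VariantKind",
    "Variant",
    "HaplotypeLabel",
    "VariantParseError",
    "SynonymousVariantError",
    "parse_variant",
    "format_variant",
    "read_variants_tsv",
]

AA1 = set(protein_letters)  # the 20 standard one-letter codes
STOP = "*"
_AA3 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_AA3["TER"] = STOP


class VariantParseError(ValueError):
    """Raised when a variant label cannot be parsed; names the bad token."""


class SynonymousVariantError(VariantParseError):
    """Raised for protein changes with identical reference and alternate
    residues, which the pathogenicity rubric cannot score."""


class VariantKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    DUPLICATION = "duplication"
    OTHER = "other"


@dataclass(frozen=True)
class Variant:
    """A parsed protein and/or cDNA change.

    Positions are 1-based (HGVS convention).  ``prot_alt`` uses "*" for a
    stop codon.  ``label`` preserves the input string.
    """

    kind: VariantKind
    label: str = field(compare=False)
    cdna_pos: int | None = None
    cdna_ref: str | None = None
    cdna_alt: str | None = None
    prot_pos: int | None = None
    prot_ref: str | None = None
    prot_alt: str | None = None

    def __post_init__(self) -> None:
        if self.cdna_pos is not None and self.cdna_pos < 1:
            raise VariantParseError(f"cDNA position must be >= 1, got {self.cdna_pos}")
        if self.prot_pos is not None and self.prot_pos < 1:
            raise VariantParseError(f"protein position must be >= 1, got {self.prot_pos}")
        if self.kind is VariantKind.MISSENSE:
            if self.prot_ref == self.prot_alt:
                raise SynonymousVariantError(
                    f"{self.label!r}: synonymous change {self.prot_ref}->{self.prot_alt}"
                )
            for res in (self.prot_ref, self.prot_alt):
                if res not in AA1:
                    raise VariantParseError(
                        f"{self.label!r}: {res!r} is not a standard amino acid"
                    )
        if self.kind is VariantKind.NONSENSE and self.prot_alt != STOP:
            raise VariantParseError(
                f"{self.label!r}: nonsense variant must end in a stop codon"
            )

    @property
    def is_missense(self) -> bool:
        return self.kind is VariantKind.MISSENSE


_PROT_RE = re.compile(r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3}|\*|X)$")
_CDNA_SUB_RE = re.compile(r"^c\.(\d+)\s*([ACGTacgt])\s*>\s*([ACGTacgt])$")
_CDNA_DUP_RE = re.compile(r"^c\.(\d+)dup([ACGTacgt]*)$")
_PAIRED_RE = re.compile(r"^(?P<first>[^()]+?)\s*\(\s*(?P<second>[^()]+?)\s*\)$")


def _residue(token: str, label: str) -> str:
    """One- or three-letter residue token -> canonical one-letter code."""
    t = token.upper()
    if t in ("*", "X"):
        return STOP
    if len(t) == 1:
        if t not in AA1:
            raise VariantParseError(f"{label!r}: unknown residue code {token!r}")
        return t
    if t in _AA3:
        return _AA3[t]
    raise VariantParseError(f"{label!r}: unknown residue code {token!r}")


def _parse_protein_part(text: str, label: str) -> dict:
    m = _PROT_RE.match(text.strip())
    if not m:
        raise VariantParseError(f"{label!r}: cannot parse protein change {text!r}")
    ref = _residue(m.group(1), label)
    alt = _residue(m.group(3), label)
    pos = int(m.group(2))
    if ref == STOP:
        raise VariantParseError(f"{label!r}: reference residue cannot be a stop codon")
    if ref == alt:
        raise SynonymousVariantError(f"{label!r}: synonymous change {ref}{pos}{alt}")
    kind = VariantKind.NONSENSE if alt == STOP else VariantKind.MISSENSE
    return {"prot_ref": ref, "prot_pos": pos, "prot_alt": alt, "kind": kind}


def _parse_cdna_part(text: str, label: str) -> dict:
    text = text.strip()
    m = _CDNA_SUB_RE.match(text)
    if m:
        return {
            "cdna_pos": int(m.group(1)),
            "cdna_ref": m.group(2).upper(),
            "cdna_alt": m.group(3).upper(),
        }
    m = _CDNA_DUP_RE.match(text)
    if m:
        return {
            "cdna_pos": int(m.group(1)),
            "cdna_alt": m.group(2).upper() or None,
            "kind": VariantKind.DUPLICATION,
        }
    raise VariantParseError(f"{label!r}: cannot parse cDNA change {text!r}")


def parse_variant(label: str) -> Variant:
    """Parse an HGVS-like variant label into a :class:`Variant`.

    Accepts protein-only ("p.M49L", bare "P11L" shorthand, three-letter
    codes, "*" or "X" stops), cDNA-only ("c.145A>C" with or without spaces
    around ">", "c.33dupC"), and paired "p.M49L (c.145A > C)" forms.  For
    paired notation the cDNA position is checked to lie within the codon of
    the protein position.

    Raises :class:`VariantParseError` on malformed input and the stricter
    :class:`SynonymousVariantError` on a same-residue protein change.
    """
    if not label or not label.strip():
        raise VariantParseError("empty variant label")
    text = label.strip()

    fields: dict = {}
    m = _PAIRED_RE.match(text)
    parts = [m.group("first"), m.group("second")] if m else [text]
    for part in parts:
        part = part.strip()
        if part.lower().startswith("c."):
            fields.update(_parse_cdna_part(part, label))
        else:
            fields.update(_parse_protein_part(part, label))

    kind = fields.pop("kind", VariantKind.OTHER)
    v = Variant(kind=kind, label=text, **fields)
    if v.prot_pos is not None and v.cdna_pos is not None and v.cdna_ref is not None:
        lo, hi = 3 * v.prot_pos - 2, 3 * v.prot_pos
        if not lo <= v.cdna_pos <= hi:
            raise VariantParseError(
                f"{label!r}: cDNA position {v.cdna_pos} is outside codon "
                f"{v.prot_pos} (c.{lo}-c.{hi})"
            )
    return v


def format_variant(v: Variant) -> str:
    """Canonical label for a variant; re-parsing it round-trips."""
    prot = cdna = None
    if v.prot_pos is not None:
        prot = f"p.{v.prot_ref}{v.prot_pos}{v.prot_alt}"
    if v.cdna_pos is not None:
        if v.kind is VariantKind.DUPLICATION:
            cdna = f"c.{v.cdna_pos}dup{v.cdna_alt or ''}"
        else:
            cdna = f"c.{v.cdna_pos}{v.cdna_ref}>{v.cdna_alt}"
    if prot and cdna:
        return f"{prot} ({cdna})"
    return prot or cdna or v.label


@dataclass(frozen=True)
class HaplotypeLabel:
    """One of the three AGXT haplotype classes seen in the family.

    AGT_MA is the normal major allele (no mutation, no intron-1 tag);
    AGT_Ma is a mutation-bearing major allele; AGT_Mi is a mutation-bearing
    minor allele and therefore always carries the IVS1+74bp duplication.
    """

    name: str  # "AGT_MA" | "AGT_Ma" | "AGT_Mi"
    carried_variants: frozenset[str] = field(default_factory=frozenset)
    carries_ivs1_74bp: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("AGT_MA", "AGT_Ma", "AGT_Mi"):
            raise ValueError(f"unknown haplotype label {self.name!r}")
        if self.name == "AGT_MA" and (self.carried_variants or self.carries_ivs1_74bp):
            raise ValueError("AGT_MA is the normal major allele: it carries nothing")
        if self.name == "AGT_Mi" and not self.carries_ivs1_74bp:
            raise ValueError("AGT_Mi is defined by the IVS1+74bp duplication")


def read_variants_tsv(path: str | Path) -> list[Variant]:
    """Read a variants TSV with columns ``label, kind, cdna, protein``.

    Lines starting with "#" are skipped.  The ``label`` column is
    authoritative; ``cdna``/``protein`` columns, when non-empty, are merged
    into a paired label before parsing.
    """
    variants: list[Variant] = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise VariantParseError(f"{path}: empty variants file")
    header: list[str] | None = None
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        cells = [c.strip() for c in line.split("\t")]
        if header is None:
            header = [c.lower() for c in cells]
            continue
        row = dict(zip(header, cells))
        label = row.get("label", "")
        prot, cdna = row.get("protein", ""), row.get("cdna", "")
        if prot and cdna:
            label = f"{prot} ({cdna})"
        elif prot or cdna:
            label = prot or cdna
        variants.append(parse_variant(label))
    return variants


def write_variants_tsv(variants: Iterable[Variant], path: str | Path) -> None:
    rows = ["label\tkind\tcdna\tprotein"]
    for v in variants:
        prot = f"p.{v.prot_ref}{v.prot_pos}{v.prot_alt}" if v.prot_pos else ""
        if v.cdna_pos and v.cdna_ref:
            cdna = f"c.{v.cdna_pos}{v.cdna_ref}>{v.cdna_alt}"
        elif v.cdna_pos:
            cdna = f"c.{v.cdna_pos}dup{v.cdna_alt or ''}"
        else:
            cdna = ""
        rows.append(f"{format_variant(v)}\t{v.kind.value}\t{cdna}\t{prot}")
    Path(path).write_text("\n".join(rows) + "\n")
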