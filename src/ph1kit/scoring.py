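"""Combined Grantham-distance / MSA-conservation pathogenicity rubric.

A missense substitution is scored on two axes and the points are summed:

* **Grantham points** from the physicochemical distance between the
  reference and alternate residues (Grantham's 1974 chemical distance,
  embedded below as the published integer matrix): distance < 60.0 gives
  1 point, 60.0-78.3 gives 2, 78.4-93.4 gives 3, > 93.4 gives 4, and any
  substitution involving cysteine gives 5 points regardless of distance
  (disulfide bonds make cysteine exchanges categorically disruptive).

* **MSA points** from cross-species conservation of the reference residue
  in an alignment of 8 homologous proteins (reference included):
  conserved in all 8 species gives 5 points, 6-7 gives 4, 4-5 gives 3,
  1-3 gives 1.

The total (2..10) classifies the variant: >= 8 high pathogenicity, 6-7
moderate, <= 5 probably non-pathogenic (polymorphism-like).  A total of
exactly 8 sits on the printed boundary between the "high" and "moderate"
bands; "high" takes precedence here and the event is logged.

Nonsense variants are not scored by the rubric: a premature stop is a null
allele and presumed deleterious without scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from Bio.Align import MultipleSeqAlignment

from .variants import AA1, Variant, VariantKind

logger = logging.getLogger("ph1kit")

__all__ = [
    "GRANTHAM",
    "ConservationResult",
    "ScoreCard",
    "grantham_distance",
    "grantham_points",
    "map_position_to_column",
    "conservation_count",
    "msa_points",
    "classify_total",
    "score_variant",
]

GAP = "-"

# Published Grantham (1974) chemical-distance matrix, upper triangle in the
# original row order S R L P T A V G I F Y C H Q N K D E M W.  Values are
# the printed integers (the canonical matrix used by annotation tools).
_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_GRANTHAM_UPPER: dict[str, dict[str, int]] = {
    "S": dict(R=110, L=145, P=74, T=58, A=99, V=124, G=56, I=142, F=155,
              Y=144, C=112, H=89, Q=68, N=46, K=121, D=65, E=80, M=135, W=177),
    "R": dict(L=102, P=103, T=71, A=112, V=96, G=125, I=97, F=97, Y=77,
              C=180, H=29, Q=43, N=86, K=26, D=96, E=54, M=91, W=101),
    "L": dict(P=98, T=92, A=96, V=32, G=138, I=5, F=22, Y=36, C=198, H=99,
              Q=113, N=153, K=107, D=172, E=138, M=15, W=61),
    "P": dict(T=38, A=27, V=68, G=42, I=95, F=114, Y=110, C=169, H=77,
              Q=76, N=91, K=103, D=108, E=93, M=87, W=147),
    "T": dict(A=58, V=69, G=59, I=89, F=103, Y=92, C=149, H=47, Q=42,
              N=65, K=78, D=85, E=65, M=81, W=128),
    "A": dict(V=64, G=60, I=94, F=113, Y=112, C=195, H=86, Q=91, N=111,
              K=106, D=126, E=107, M=84, W=148),
    "V": dict(G=109, I=29, F=50, Y=55, C=192, H=84, Q=96, N=133, K=97,
              D=152, E=121, M=21, W=88),
    "G": dict(I=135, F=153, Y=147, C=159, H=98, Q=87, N=80, K=127, D=94,
              E=98, M=127, W=184),
    "I": dict(F=21, Y=33, C=198, H=94, Q=109, N=149, K=102, D=168, E=134,
              M=10, W=61),
    "F": dict(Y=22, C=205, H=100, Q=116, N=158, K=102, D=177, E=140,
              M=28, W=40),
    "Y": dict(C=194, H=83, Q=99, N=143, K=85, D=160, E=122, M=36, W=37),
    "C": dict(H=174, Q=154, N=139, K=202, D=154, E=170, M=196, W=215),
    "H": dict(Q=24, N=68, K=32, D=81, E=40, M=87, W=115),
    "Q": dict(N=46, K=53, D=61, E=29, M=101, W=130),
    "N": dict(K=94, D=23, E=42, M=142, W=174),
    "K": dict(D=101, E=56, M=95, W=110),
    "D": dict(E=45, M=160, W=181),
    "E": dict(M=126, W=152),
    "M": dict(W=67),
}


def _build_full_matrix() -> dict[tuple[str, str], int]:
    full: dict[tuple[str, str], int] = {(a, a): 0 for a in _GRANTHAM_ORDER}
    for a, row in _GRANTHAM_UPPER.items():
        for b, d in row.items():
            full[(a, b)] = d
            full[(b, a)] = d
    return full


#: Symmetric 20x20 Grantham distance lookup keyed by residue pair.
GRANTHAM: Mapping[tuple[str, str], int] = _build_full_matrix()


def grantham_distance(ref: str, alt: str) -> int:
    """Grantham chemical distance between two distinct standard residues."""
    ref, alt = ref.upper(), alt.upper()
    for res in (ref, alt):
        if res not in AA1:
            raise ValueError(f"{res!r} is not a standard amino acid")
    if ref == alt:
        raise ValueError(
            f"synonymous pair ({ref}, {alt}): the rubric scores substitutions only"
        )
    return GRANTHAM[(ref, alt)]


def grantham_points(distance: float, ref: str, alt: str) -> int:
    """Bin a Grantham distance into rubric points.

    The cysteine rule is checked first: any substitution to or from
    cysteine scores 5 points, overriding the distance bins.  The printed
    bins leave (78.3, 78.4) uncovered; the integer matrix never lands
    there, but such a distance is mapped to 3 points with a warning.
    """
    if distance < 0:
        raise ValueError(f"negative Grantham distance {distance}")
    if "C" in (ref.upper(), alt.upper()):
        return 5
    if distance < 60.0:
        return 1
    if distance <= 78.3:
        return 2
    if distance < 78.4:
        logger.warning(
            "Grantham distance %s falls in the uncovered bin gap (78.3, 78.4); "
            "assigning 3 points", distance,
        )
        return 3
    if distance <= 93.4:
        return 3
    return 4


def _reference_row(alignment: MultipleSeqAlignment, reference_id: str) -> str:
    for rec in alignment:
        if rec.id == reference_id:
            return str(rec.seq)
    raise KeyError(f"reference sequence {reference_id!r} not found in alignment")


def map_position_to_column(
    alignment: MultipleSeqAlignment, reference_id: str, prot_pos: int
) -> int:
    """0-based alignment column of the ``prot_pos``-th non-gap residue of
    the reference row."""
    if prot_pos < 1:
        raise ValueError(f"protein position must be >= 1, got {prot_pos}")
    row = _reference_row(alignment, reference_id)
    seen = 0
    for col, ch in enumerate(row):
        if ch != GAP:
            seen += 1
            if seen == prot_pos:
                return col
    raise IndexError(
        f"protein position {prot_pos} beyond the {seen} residues of "
        f"reference {reference_id!r}"
    )


@dataclass(frozen=True)
class ConservationResult:
    """Cross-species conservation of one reference position.

    ``n_conserved`` counts rows (reference included) whose residue at the
    mapped column equals the reference residue; gaps never count.  The
    reference matches itself, so 1 <= n_conserved <= n_species.
    """

    prot_pos: int
    n_conserved: int
    n_species: int
    column_index: int


def conservation_count(
    alignment: MultipleSeqAlignment, reference_id: str, prot_pos: int
) -> ConservationResult:
    """Count species whose aligned residue matches the reference residue."""
    if len(alignment) == 0:
        raise ValueError("empty alignment")
    col = map_position_to_column(alignment, reference_id, prot_pos)
    ref_res = _reference_row(alignment, reference_id)[col].upper()
    n = sum(
        1
        for rec in alignment
        if str(rec.seq[col]).upper() == ref_res and str(rec.seq[col]) != GAP
    )
    return ConservationResult(
        prot_pos=prot_pos, n_conserved=n, n_species=len(alignment), column_index=col
    )


def msa_points(n_conserved: int, n_species: int = 8, *, mode: str = "strict8") -> int:
    """Conservation-count rubric points.

    ``strict8`` mode implements the published 8-species bins (8 -> 5,
    6-7 -> 4, 4-5 -> 3, 1-3 -> 1) and requires ``n_species == 8``.
    ``proportional`` mode extrapolates the same bins as fractions
    (>=100% -> 5, >=75% -> 4, >=50% -> 3, else 1) for other alignment
    sizes and logs that it is extrapolating.
    """
    if not 1 <= n_conserved <= n_species:
        raise ValueError(
            f"n_conserved must be in [1, {n_species}], got {n_conserved}"
        )
    if mode == "strict8":
        if n_species != 8:
            raise ValueError(
                "strict8 mode requires an 8-species alignment; "
                "use mode='proportional' for other sizes"
            )
        if n_conserved == 8:
            return 5
        if n_conserved >= 6:
            return 4
        if n_conserved >= 4:
            return 3
        return 1
    if mode == "proportional":
        logger.info(
            "msa_points proportional mode extrapolates the 8-species rubric "
            "to %d species", n_species,
        )
        frac = n_conserved / n_species
        if frac >= 1.0:
            return 5
        if frac >= 0.75:
            return 4
        if frac >= 0.5:
            return 3
        return 1
    raise ValueError(f"unknown msa_points mode {mode!r}")


def classify_total(total: int) -> str:
    """Map a total rubric score to a pathogenicity class.

    >= 8 is "high", 6-7 "moderate", <= 5 "probably_nonpathogenic".  The
    published bands overlap at exactly 8 ("high" >= 8 vs "moderate" 6-8);
    high takes precedence and the boundary hit is logged.
    """
    if not 2 <= total <= 10:
        raise ValueError(f"total rubric score must be in [2, 10], got {total}")
    if total == 8:
        logger.info(
            "total score 8 sits on the high/moderate boundary; classifying as high"
        )
    if total >= 8:
        return "high"
    if total >= 6:
        return "moderate"
    return "probably_nonpathogenic"


@dataclass(frozen=True)
class ScoreCard:
    """Full rubric result for one missense variant."""

    variant: Variant
    grantham_distance: int
    grantham_points: int
    n_conserved: int
    n_species: int
    msa_points: int
    total: int
    pathogenicity_class: str

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.label,
            "grantham": self.grantham_distance,
            "grantham_pts": self.grantham_points,
            "conserved": f"{self.n_conserved}/{self.n_species}",
            "msa_pts": self.msa_points,
            "total": self.total,
            "class": self.pathogenicity_class,
        }


def score_variant(
    variant: Variant,
    alignment: MultipleSeqAlignment,
    reference_id: str,
    *,
    mode: str = "strict8",
) -> ScoreCard:
    """Score a missense variant with the combined rubric.

    The reference residue at ``variant.prot_pos`` must equal
    ``variant.prot_ref`` (guards against coordinate off-by-one errors).
    Nonsense and other non-missense variants are rejected: a premature stop
    is a null allele, presumed deleterious without rubric scoring.
    """
    if variant.kind is not VariantKind.MISSENSE:
        raise ValueError(
            f"{variant.label!r} is {variant.kind.value}, not missense: the rubric "
            "scores missense substitutions only (nonsense variants are null "
            "alleles, presumed deleterious)"
        )
    cons = conservation_count(alignment, reference_id, variant.prot_pos)
    found = _reference_row(alignment, reference_id)[cons.column_index].upper()
    if found != variant.prot_ref:
        raise ValueError(
            f"reference residue mismatch at position {variant.prot_pos}: "
            f"variant says {variant.prot_ref}, alignment has {found}"
        )
    dist = grantham_distance(variant.prot_ref, variant.prot_alt)
    g_pts = grantham_points(dist, variant.prot_ref, variant.prot_alt)
    m_pts = msa_points(cons.n_conserved, cons.n_species, mode=mode)
    total = g_pts + m_pts
    return ScoreCard(
        variant=variant,
        grantham_distance=dist,
        grantham_points=g_pts,
        n_conserved=cons.n_conserved,
        n_species=cons.n_species,
        msa_points=m_pts,
        total=total,
        pathogenicity_class=classify_total(total),
    )
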