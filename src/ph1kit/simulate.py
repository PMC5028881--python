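"""Synthetic inputs for every pipeline stage, plus the hard-coded study
family.

Three generators plant known ground truth so recovery can be tested
without external data:

* :func:`simulate_pedigree` transmits whole founder haplotypes (no
  recombination) through a multi-generation family and assigns the
  phenotype from genotype (biallelic => affected, fully penetrant).
* :func:`simulate_msa` writes an 8-species-style protein alignment with an
  exact, planted conservation count at chosen columns.
* :func:`simulate_cohort` builds a diploid control cohort with exact
  heterozygote / homozygote counts per variant.

All three are deterministic under their spec's seed.  The 20-member study
family itself is encoded directly in :func:`make_family_fixture` from the
published genotype statements, not stored as a data file.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pedigree import (
    FOUNDER,
    Affection,
    Genotype,
    Individual,
    Pedigree,
    Sex,
)
from .variants import AA1

__all__ = [
    "M49L",
    "N72I",
    "R333X",
    "IVS1_74BP",
    "FAMILY_VARIANTS",
    "PedigreeSpec",
    "MsaSpec",
    "CohortSpec",
    "make_family_fixture",
    "simulate_pedigree",
    "simulate_msa",
    "simulate_cohort",
]

# The four markers genotyped in the study family.  The minor-allele
# haplotype AGT-Mi carries the two linked mutations plus the intron-1 tag;
# the mutated major haplotype AGT-Ma carries only p.N72I.
M49L = "p.M49L"
N72I = "p.N72I"
R333X = "p.R333*"
IVS1_74BP = "IVS1+74bp"
FAMILY_VARIANTS = [M49L, N72I, R333X, IVS1_74BP]
MI_HAPLOTYPE = frozenset({M49L, R333X, IVS1_74BP})
MA_HAPLOTYPE = frozenset({N72I})

_AA_LIST = sorted(AA1)


def _genotypes(doses: dict[str, int | None]) -> dict[str, Genotype]:
    return {v: Genotype.from_dose(d) for v, d in doses.items()}


def make_family_fixture() -> Pedigree:
    """The 20-member, 3-generation PH1 family encoded from the published
    genotype statements.

    Three affected siblings (IIa, IIe, IIf) are compound heterozygotes
    carrying AGT-Mi ({p.M49L, p.R333*, IVS1+74bp}) and AGT-Ma ({p.N72I}).
    Ia, IIc, IIIc and IIIf carry AGT-Mi; IIb, IIIa and IIIe carry AGT-Ma;
    nine members are reference at every marker; the deceased founder Ib is
    untyped (missing at all markers).  Individuals not named in the
    genotype statements are encoded reference-at-all; the spousal/offspring
    wiring is chosen to be Mendelian-consistent with those statements.
    """
    mi = {M49L: 1, R333X: 1, IVS1_74BP: 1, N72I: 0}
    ma = {M49L: 0, R333X: 0, IVS1_74BP: 0, N72I: 1}
    compound = {M49L: 1, R333X: 1, IVS1_74BP: 1, N72I: 1}
    ref = {v: 0 for v in FAMILY_VARIANTS}
    missing = {v: None for v in FAMILY_VARIANTS}

    male, female = Sex.MALE, Sex.FEMALE
    aff, unaff, unk = Affection.AFFECTED, Affection.UNAFFECTED, Affection.UNKNOWN

    def ind(id, sex, father, mother, affected, doses):
        return Individual(
            id=id,
            father_id=father,
            mother_id=mother,
            sex=sex,
            affected=affected,
            genotypes=_genotypes(doses),
        )

    members = [
        # generation I: Ia carries AGT-Mi; her husband Ib died unsequenced
        ind("Ia", female, FOUNDER, FOUNDER, unaff, mi),
        ind("Ib", male, FOUNDER, FOUNDER, unk, missing),
        # generation II: five siblings (children of Ia x Ib) and spouses
        ind("IIa", female, "Ib", "Ia", aff, compound),
        ind("IIb", male, "Ib", "Ia", unaff, ma),
        ind("IIc", female, "Ib", "Ia", unaff, mi),
        ind("IId", male, FOUNDER, FOUNDER, unaff, ref),    # spouse of IIc
        ind("IIe", male, "Ib", "Ia", aff, compound),
        ind("IIf", female, "Ib", "Ia", aff, compound),
        ind("IIg", male, FOUNDER, FOUNDER, unaff, ref),    # spouse of IIa
        ind("IIh", female, FOUNDER, FOUNDER, unaff, ref),  # spouse of IIe
        ind("IIi", male, FOUNDER, FOUNDER, unaff, ref),    # spouse of IIf
        ind("IIj", female, FOUNDER, FOUNDER, unaff, ref),  # spouse of IIb
        # generation III
        ind("IIIa", male, "IIg", "IIa", unaff, ma),
        ind("IIIb", female, "IIb", "IIj", unaff, ref),
        ind("IIIc", male, "IId", "IIc", unaff, mi),
        ind("IIId", male, "IIb", "IIj", unaff, ref),
        ind("IIIe", female, "IIe", "IIh", unaff, ma),
        ind("IIIf", female, "IIi", "IIf", unaff, mi),
        ind("IIIg", female, "IId", "IIc", unaff, ref),
        ind("IIIh", male, "IId", "IIc", unaff, ref),
    ]
    return Pedigree(members, FAMILY_VARIANTS)


@dataclass
class PedigreeSpec:
    """Conditions for a simulated family.

    ``founder_haplotypes`` assigns each named generation-1 founder a pair
    of variant sets; consecutive founders are paired into couples.  Every
    child marries a wild-type spouse and has ``offspring_per_couple``
    children until ``n_generations`` is reached.  The phenotype rule is
    fixed: biallelic (both haplotypes mutant) => affected.
    """

    founder_haplotypes: dict[str, tuple[frozenset, frozenset]]
    variant_labels: list[str]
    n_generations: int = 3
    offspring_per_couple: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.offspring_per_couple < 0:
            raise ValueError("offspring_per_couple must be >= 0")
        if len(self.founder_haplotypes) % 2:
            raise ValueError("founders must pair into couples (even count)")


def simulate_pedigree(spec: PedigreeSpec) -> tuple[Pedigree, dict[str, tuple[frozenset, frozenset]]]:
    """Simulate haplotype transmission through a family.

    Each child inherits one whole haplotype from each parent uniformly at
    random (complete linkage).  Returns the pedigree (genotypes derived
    from haplotypes) and the ground-truth haplotype pair per individual.
    """
    rng = np.random.default_rng(spec.seed)
    truth: dict[str, tuple[frozenset, frozenset]] = {
        fid: (frozenset(h[0]), frozenset(h[1]))
        for fid, h in spec.founder_haplotypes.items()
    }
    sexes: dict[str, Sex] = {}
    members: list[Individual] = []

    def add(ind_id: str, father: str, mother: str, sex: Sex) -> None:
        haps = truth[ind_id]
        doses = {
            v: (v in haps[0]) + (v in haps[1]) for v in spec.variant_labels
        }
        biallelic = bool(haps[0]) and bool(haps[1])
        members.append(
            Individual(
                id=ind_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affected=Affection.AFFECTED if biallelic else Affection.UNAFFECTED,
                genotypes=_genotypes(doses),
            )
        )
        sexes[ind_id] = sex

    founder_ids = list(spec.founder_haplotypes)
    for i, fid in enumerate(founder_ids):
        add(fid, FOUNDER, FOUNDER, Sex.MALE if i % 2 == 0 else Sex.FEMALE)
    couples = [
        (founder_ids[i], founder_ids[i + 1]) for i in range(0, len(founder_ids), 2)
    ]

    letters = string.ascii_lowercase
    for gen in range(2, spec.n_generations + 1):
        next_couples: list[tuple[str, str]] = []
        child_idx = 0
        for father, mother in couples:
            for _ in range(spec.offspring_per_couple):
                cid = f"G{gen}{letters[child_idx % 26]}{child_idx // 26 or ''}"
                child_idx += 1
                pat = truth[father][int(rng.integers(2))]
                mat = truth[mother][int(rng.integers(2))]
                truth[cid] = (pat, mat)
                sex = Sex.MALE if rng.integers(2) else Sex.FEMALE
                add(cid, father, mother, sex)
                if gen < spec.n_generations:
                    sid = f"{cid}sp"
                    truth[sid] = (frozenset(), frozenset())
                    spouse_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                    add(sid, FOUNDER, FOUNDER, spouse_sex)
                    next_couples.append(
                        (cid, sid) if sex is Sex.MALE else (sid, cid)
                    )
        couples = next_couples
    return Pedigree(members, spec.variant_labels), truth


@dataclass
class MsaSpec:
    """Conditions for a planted-conservation protein alignment.

    ``planted_conservation`` maps 0-based columns to the exact number of
    rows (reference included) that must equal the reference residue there.
    Elsewhere each non-reference row matches the reference with probability
    ``background_identity`` (resampled on accidental matches, so planted
    counts are exact rather than expected).  The default of 8 species
    mirrors the vertebrate homolog panel used for the rubric; the default
    background identity of 0.7 is typical of such a panel.
    """

    length: int
    planted_conservation: dict[int, int] = field(default_factory=dict)
    n_species: int = 8
    background_identity: float = 0.7
    reference_id: str = "ref"
    reference_seq: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0.0 <= self.background_identity <= 1.0:
            raise ValueError("background_identity must be in [0, 1]")
        for col, k in self.planted_conservation.items():
            if not 0 <= col < self.length:
                raise ValueError(f"planted column {col} outside [0, {self.length})")
            if not 1 <= k <= self.n_species:
                raise ValueError(
                    f"planted conservation {k} at column {col} outside "
                    f"[1, {self.n_species}]"
                )
        if self.reference_seq is not None and len(self.reference_seq) != self.length:
            raise ValueError("reference_seq length must equal alignment length")


def _different_residue(rng: np.random.Generator, ref_res: str) -> str:
    res = _AA_LIST[int(rng.integers(20))]
    while res == ref_res:
        res = _AA_LIST[int(rng.integers(20))]
    return res


def simulate_msa(spec: MsaSpec) -> MultipleSeqAlignment:
    """Generate an ungapped protein alignment with exact planted
    conservation counts."""
    rng = np.random.default_rng(spec.seed)
    if spec.reference_seq is not None:
        ref = list(spec.reference_seq.upper())
    else:
        ref = [_AA_LIST[int(i)] for i in rng.integers(20, size=spec.length)]
    n_others = spec.n_species - 1
    rows = [[None] * spec.length for _ in range(n_others)]
    for col in range(spec.length):
        ref_res = ref[col]
        if col in spec.planted_conservation:
            k = spec.planted_conservation[col]  # includes the reference
            matched = rng.choice(n_others, size=k - 1, replace=False)
            matched = set(int(i) for i in matched)
            for r in range(n_others):
                rows[r][col] = (
                    ref_res if r in matched else _different_residue(rng, ref_res)
                )
        else:
            for r in range(n_others):
                if rng.random() < spec.background_identity:
                    rows[r][col] = ref_res
                else:
                    rows[r][col] = _different_residue(rng, ref_res)
    records = [SeqRecord(Seq("".join(ref)), id=spec.reference_id, description="")]
    for r in range(n_others):
        records.append(
            SeqRecord(Seq("".join(rows[r])), id=f"species{r + 1}", description="")
        )
    return MultipleSeqAlignment(records)


@dataclass
class CohortSpec:
    """Conditions for a diploid control cohort with exact carrier counts.

    The default size of 100 matches a typical single-centre healthy
    control panel.
    """

    n_individuals: int = 100
    het_carriers: dict[str, int] = field(default_factory=dict)
    hom_alt: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("cohort must have at least one individual")
        variants = set(self.het_carriers) | set(self.hom_alt)
        for v in variants:
            het = self.het_carriers.get(v, 0)
            hom = self.hom_alt.get(v, 0)
            if het < 0 or hom < 0:
                raise ValueError(f"{v}: negative carrier count")
            if het + hom > self.n_individuals:
                raise ValueError(
                    f"{v}: {het} het + {hom} hom exceeds cohort size "
                    f"{self.n_individuals}"
                )


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Genotype-dose table (rows = individuals, columns = variants) with
    exactly the requested het/hom counts, positions shuffled under seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    variants = sorted(set(spec.het_carriers) | set(spec.hom_alt))
    data = {}
    for v in variants:
        het = spec.het_carriers.get(v, 0)
        hom = spec.hom_alt.get(v, 0)
        doses = np.zeros(n, dtype=int)
        doses[:hom] = 2
        doses[hom:hom + het] = 1
        rng.shuffle(doses)
        data[v] = doses
    index = [f"ctrl{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(data, index=index)
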