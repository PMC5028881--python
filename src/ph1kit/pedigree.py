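"""Pedigree representation, Mendelian checks, cis/trans phasing and
autosomal-recessive co-segregation.

Phasing assumes complete linkage within the gene (AGXT spans ~10 kb, so
no recombination is modelled between its variants): every individual's
two gene copies are whole haplotypes inherited intact from the parents.
Phase is inferred by exhaustive enumeration of founder haplotypes and
transmission choices, pruned against every observed genotype; a unique
surviving cis/trans partition is "resolved", several are "ambiguous",
none is "inconsistent".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Genotype",
    "Individual",
    "Pedigree",
    "PhaseResult",
    "SegregationReport",
    "MendelianViolation",
    "check_mendelian",
    "phase_variants",
    "cosegregation_test",
    "allele_frequency",
]

FOUNDER = "0"  # PED founder marker for an absent parent


class Genotype(str, Enum):
    """Diploid call at one biallelic site."""

    REF = "ref/ref"
    HET = "ref/alt"
    HOM = "alt/alt"
    MISSING = "missing"

    @property
    def dose(self) -> int | None:
        """Alt-allele count, or None when missing."""
        return {"ref/ref": 0, "ref/alt": 1, "alt/alt": 2, "missing": None}[self.value]

    @classmethod
    def from_dose(cls, dose: int | None) -> "Genotype":
        if dose is None:
            return cls.MISSING
        return {0: cls.REF, 1: cls.HET, 2: cls.HOM}[dose]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass
class Individual:
    id: str
    family_id: str = "FAM1"
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER

    def genotype(self, variant: str) -> Genotype:
        return self.genotypes.get(variant, Genotype.MISSING)

    def is_typed(self, variants: Iterable[str]) -> bool:
        """True if at least one genotype is non-missing."""
        return any(self.genotype(v) is not Genotype.MISSING for v in variants)


class Pedigree:
    """An ordered collection of individuals with per-variant genotypes."""

    def __init__(self, individuals: Sequence[Individual], variant_labels: Sequence[str]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self.individuals[ind.id] = ind
        self.variant_labels = list(variant_labels)
        for ind in individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid != FOUNDER and pid not in self.individuals:
                    raise ValueError(f"{ind.id}: unknown parent id {pid!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order = self.topological_order()
        if len(order) != len(self.individuals):
            raise ValueError("pedigree contains an ancestry cycle")

    def topological_order(self) -> list[Individual]:
        """Founders first, every parent before its children."""
        placed: dict[str, Individual] = {}
        pending = list(self.individuals.values())
        while pending:
            progress = False
            remaining = []
            for ind in pending:
                ready = all(
                    pid == FOUNDER or pid in placed
                    for pid in (ind.father_id, ind.mother_id)
                )
                if ready:
                    placed[ind.id] = ind
                    progress = True
                else:
                    remaining.append(ind)
            if not progress:
                break
            pending = remaining
        return list(placed.values())

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[ind_id]


@dataclass(frozen=True)
class MendelianViolation:
    individual_id: str
    variant: str
    detail: str


def _transmissible(g: Genotype) -> set[int]:
    """Alleles (0=ref, 1=alt) a parent with genotype ``g`` can pass on."""
    return {
        Genotype.REF: {0},
        Genotype.HET: {0, 1},
        Genotype.HOM: {1},
        Genotype.MISSING: {0, 1},
    }[g]


def check_mendelian(pedigree: Pedigree) -> list[MendelianViolation]:
    """Flag child genotypes impossible under biparental transmission.

    Missing genotypes (child or parent) never flag; an absent parent is
    treated as able to transmit either allele.
    """
    violations: list[MendelianViolation] = []
    for ind in pedigree:
        for variant in pedigree.variant_labels:
            child = ind.genotype(variant)
            if child.dose is None:
                continue
            pat = (
                pedigree[ind.father_id].genotype(variant)
                if ind.father_id != FOUNDER
                else Genotype.MISSING
            )
            mat = (
                pedigree[ind.mother_id].genotype(variant)
                if ind.mother_id != FOUNDER
                else Genotype.MISSING
            )
            ok = any(
                a + b == child.dose
                for a in _transmissible(pat)
                for b in _transmissible(mat)
            )
            if not ok:
                violations.append(
                    MendelianViolation(
                        individual_id=ind.id,
                        variant=variant,
                        detail=(
                            f"child {child.value} incompatible with parents "
                            f"{pat.value} x {mat.value}"
                        ),
                    )
                )
    return violations


@dataclass
class PhaseResult:
    """Cis/trans assignment of the observed alt alleles to two haplotypes.

    ``haplotypes`` partitions the phased variant labels into the two
    founder mutant haplotype classes (one may be empty when everything is
    in cis).  ``status`` is "resolved" for a unique consistent partition,
    "ambiguous" when several survive (all listed in ``candidates``), and
    "inconsistent" when none does.
    """

    status: str
    haplotypes: tuple[frozenset[str], frozenset[str]] | None
    candidates: list[tuple[frozenset[str], frozenset[str]]]
    supporting_individuals: list[str]

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "haplotypes": (
                [sorted(h) for h in self.haplotypes] if self.haplotypes else None
            ),
            "candidates": [[sorted(h) for h in c] for c in self.candidates],
            "supporting_individuals": self.supporting_individuals,
        }


class PhaseEnumerationError(ValueError):
    """Raised when the phase search space is too large to enumerate."""


MAX_PHASE_FOUNDERS = 10
MAX_PHASE_VARIANTS = 6
MAX_PHASE_NODES = 5_000_000  # search-tree visit budget


def _founder_haplotype_choices(
    ind: Individual, variants: Sequence[str]
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """All (hapA, hapB) pairs consistent with a founder's own genotype.

    Untyped variants distribute freely over the two haplotypes.
    """
    per_variant: list[list[tuple[bool, bool]]] = []
    for v in variants:
        dose = ind.genotype(v).dose
        if dose == 0:
            per_variant.append([(False, False)])
        elif dose == 1:
            per_variant.append([(True, False), (False, True)])
        elif dose == 2:
            per_variant.append([(True, True)])
        else:  # missing: any placement
            per_variant.append([(False, False), (True, False), (False, True), (True, True)])
    choices = []
    seen: set[frozenset[frozenset[str]]] = set()
    for combo in itertools.product(*per_variant):
        hap_a = frozenset(v for v, (a, _) in zip(variants, combo) if a)
        hap_b = frozenset(v for v, (_, b) in zip(variants, combo) if b)
        key = frozenset((hap_a, hap_b))  # the pair is unordered
        if key not in seen:
            seen.add(key)
            choices.append((hap_a, hap_b))
    return choices


def phase_variants(
    pedigree: Pedigree, variant_labels: Sequence[str] | None = None
) -> PhaseResult:
    """Infer the cis/trans configuration of tightly linked variants.

    Enumerates founder haplotypes (pruned by each founder's own genotype)
    and, for every non-founder, the four possible transmissions; any
    assignment contradicting an observed genotype is discarded.  The
    partition of observed alt variants into haplotype classes is read off
    the haplotypes carried by typed individuals, so untransmitted
    haplotypes of untyped founders cannot create spurious phase claims.
    """
    all_labels = list(variant_labels) if variant_labels else pedigree.variant_labels
    # restrict to variants actually observed alt somewhere: others carry no
    # phase information and only inflate the enumeration
    observed = [
        v
        for v in all_labels
        if any((ind.genotype(v).dose or 0) > 0 for ind in pedigree)
    ]
    typed_ids = [i.id for i in pedigree if i.is_typed(all_labels)]
    if not typed_ids:
        raise ValueError("no genotyped individual in the pedigree")
    if not observed:
        return PhaseResult(
            status="resolved",
            haplotypes=(frozenset(), frozenset()),
            candidates=[(frozenset(), frozenset())],
            supporting_individuals=[],
        )
    # individuals that are typed or have a typed descendant are the only
    # ones that constrain phase; everyone else is excluded from the search
    children: dict[str, list[str]] = {iid: [] for iid in pedigree.individuals}
    for ind in pedigree:
        for pid in (ind.father_id, ind.mother_id):
            if pid != FOUNDER:
                children[pid].append(ind.id)
    typed_set = set(typed_ids)
    relevant: set[str] = set()

    def is_relevant(iid: str) -> bool:
        if iid in relevant:
            return True
        if iid in typed_set or any(is_relevant(c) for c in children[iid]):
            relevant.add(iid)
            return True
        return False

    for iid in pedigree.individuals:
        is_relevant(iid)

    founders = [f for f in pedigree.founders if f.id in relevant]
    if len(founders) > MAX_PHASE_FOUNDERS or len(observed) > MAX_PHASE_VARIANTS:
        raise PhaseEnumerationError(
            f"phase enumeration refused: {len(founders)} founders x "
            f"{len(observed)} variants exceeds the "
            f"{MAX_PHASE_FOUNDERS} x {MAX_PHASE_VARIANTS} limit"
        )

    order = pedigree.topological_order()
    non_founders = [i for i in order if not i.is_founder and i.id in relevant]
    founder_choices = {f.id: _founder_haplotype_choices(f, observed) for f in founders}

    solutions: set[frozenset[frozenset[str]]] = set()
    assignment: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    visits = [0]

    def tick() -> None:
        visits[0] += 1
        if visits[0] > MAX_PHASE_NODES:
            raise PhaseEnumerationError(
                f"phase enumeration exceeded the {MAX_PHASE_NODES} node budget"
            )

    def genotype_ok(ind: Individual, haps: tuple[frozenset[str], frozenset[str]]) -> bool:
        for v in observed:
            dose = ind.genotype(v).dose
            if dose is None:
                continue
            if (v in haps[0]) + (v in haps[1]) != dose:
                return False
        return True

    def record_solution() -> None:
        carried = frozenset(
            h
            for iid in typed_ids
            for h in assignment[iid]
            if h
        )
        solutions.add(carried)

    def descend(idx: int) -> None:
        if idx == len(non_founders):
            record_solution()
            return
        ind = non_founders[idx]
        # identical parental haplotypes are interchangeable: enumerating
        # only distinct ones avoids exploring duplicate assignments
        pat = set(assignment[ind.father_id])
        mat = set(assignment[ind.mother_id])
        for a, b in itertools.product(pat, mat):
            tick()
            haps = (a, b)
            if genotype_ok(ind, haps):
                assignment[ind.id] = haps
                descend(idx + 1)
        assignment.pop(ind.id, None)

    def assign_founders(idx: int) -> None:
        if idx == len(founders):
            descend(0)
            return
        f = founders[idx]
        for haps in founder_choices[f.id]:
            tick()
            assignment[f.id] = haps
            assign_founders(idx + 1)
        assignment.pop(f.id, None)

    assign_founders(0)

    supporting = [
        iid
        for iid in typed_ids
        if any((pedigree[iid].genotype(v).dose or 0) > 0 for v in observed)
    ]

    def as_partition(
        sol: frozenset[frozenset[str]],
    ) -> tuple[frozenset[str], frozenset[str]] | None:
        haps = sorted(sol, key=lambda h: (len(h), sorted(h)))
        if len(haps) > 2:
            return None
        while len(haps) < 2:
            haps.append(frozenset())
        union = haps[0] | haps[1]
        if haps[0] & haps[1] or union != frozenset(observed):
            return None
        return (haps[0], haps[1])

    partitions = sorted(
        {p for sol in solutions if (p := as_partition(sol)) is not None},
        key=lambda pr: (sorted(pr[0]), sorted(pr[1])),
    )
    if not partitions:
        return PhaseResult(
            status="inconsistent",
            haplotypes=None,
            candidates=[],
            supporting_individuals=supporting,
        )
    if len(partitions) == 1:
        return PhaseResult(
            status="resolved",
            haplotypes=partitions[0],
            candidates=partitions,
            supporting_individuals=supporting,
        )
    return PhaseResult(
        status="ambiguous",
        haplotypes=None,
        candidates=partitions,
        supporting_individuals=supporting,
    )


@dataclass
class SegregationReport:
    """Autosomal-recessive co-segregation summary.

    Individuals are classified from genotype alone: biallelic (mutant
    alleles from both haplotype classes, or homozygous for any variant),
    carrier (mutant content from exactly one class), noncarrier, untyped.
    ``n_affected_biallelic`` counts the biallelic class, whose members are
    all expected affected under the fully penetrant AR model; departures
    in either direction appear in ``violations`` (or ``warnings`` when
    complete penetrance is not assumed).  Counts always sum to pedigree
    size.
    """

    model: str
    n_affected_biallelic: int
    n_carriers: int
    n_noncarriers: int
    n_untyped: int
    violations: list[tuple[str, str]]
    warnings: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_affected_biallelic": self.n_affected_biallelic,
            "n_carriers": self.n_carriers,
            "n_noncarriers": self.n_noncarriers,
            "n_untyped": self.n_untyped,
            "violations": self.violations,
            "warnings": self.warnings,
        }

    @property
    def consistent(self) -> bool:
        return not self.violations


def cosegregation_test(
    pedigree: Pedigree,
    phase: PhaseResult,
    *,
    complete_penetrance: bool = True,
) -> SegregationReport:
    """Check autosomal-recessive biallelic co-segregation given a resolved
    phase.

    AR consistency requires every affected individual to be biallelic and
    no unaffected individual to be biallelic.  With
    ``complete_penetrance=False`` the unaffected-biallelic rule is
    downgraded to a warning (reduced penetrance); affected individuals
    without a biallelic genotype always remain violations.
    """
    if phase.status != "resolved":
        raise ValueError(f"phase must be resolved, got status {phase.status!r}")
    h1, h2 = phase.haplotypes
    variants = sorted(h1 | h2)

    n_bi = n_car = n_non = n_untyped = 0
    violations: list[tuple[str, str]] = []
    warnings: list[tuple[str, str]] = []
    for ind in pedigree:
        if not ind.is_typed(pedigree.variant_labels):
            n_untyped += 1
            continue
        doses = {v: ind.genotype(v).dose or 0 for v in variants}
        carries_h1 = any(doses[v] > 0 for v in h1)
        carries_h2 = any(doses[v] > 0 for v in h2)
        homozygous = any(d == 2 for d in doses.values())
        biallelic = (carries_h1 and carries_h2) or homozygous
        if biallelic:
            n_bi += 1
        elif carries_h1 or carries_h2:
            n_car += 1
        else:
            n_non += 1
        if ind.affected is Affection.AFFECTED and not biallelic:
            violations.append(
                (ind.id, "affected individual is not biallelic under the AR model")
            )
        if ind.affected is Affection.UNAFFECTED and biallelic:
            entry = (ind.id, "unaffected individual is biallelic under the AR model")
            (violations if complete_penetrance else warnings).append(entry)
    return SegregationReport(
        model="autosomal recessive, biallelic",
        n_affected_biallelic=n_bi,
        n_carriers=n_car,
        n_noncarriers=n_non,
        n_untyped=n_untyped,
        violations=violations,
        warnings=warnings,
    )


def allele_frequency(cohort: pd.DataFrame, variant_label: str) -> float:
    """Alt-allele frequency in a diploid cohort genotype table.

    ``cohort`` holds one row per individual and one column per variant with
    alt-allele doses 0/1/2 (NaN = missing).  Missing genotypes are excluded
    from the denominator.
    """
    if variant_label not in cohort.columns:
        raise KeyError(f"variant {variant_label!r} not in cohort table")
    doses = pd.to_numeric(cohort[variant_label], errors="coerce").dropna()
    if doses.empty:
        raise ValueError(f"all genotypes missing for {variant_label!r}")
    if not doses.isin([0, 1, 2]).all():
        raise ValueError(f"{variant_label!r}: doses must be 0, 1 or 2")
    return float(doses.sum() / (2 * len(doses)))
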