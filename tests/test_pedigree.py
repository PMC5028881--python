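import pandas as pd
import pytest

from ph1kit import (
    CohortSpec,
    Genotype,
    Individual,
    Pedigree,
    PedigreeSpec,
    allele_frequency,
    check_mendelian,
    cosegregation_test,
    phase_variants,
    simulate_cohort,
    simulate_pedigree,
)
from ph1kit.pedigree import Affection, PhaseEnumerationError
from ph1kit.simulate import FAMILY_VARIANTS, MA_HAPLOTYPE, MI_HAPLOTYPE


def _ind(iid, father="0", mother="0", affected=Affection.UNKNOWN, **doses):
    return Individual(
        id=iid,
        father_id=father,
        mother_id=mother,
        affected=affected,
        genotypes={v: Genotype.from_dose(d) for v, d in doses.items()},
    )


# ---------------------------------------------------------------- mendelian

def test_mendelian_flags_de_novo():
    ped = Pedigree(
        [
            _ind("dad", v1=0),
            _ind("mum", v1=0),
            _ind("kid", father="dad", mother="mum", v1=1),
        ],
        ["v1"],
    )
    violations = check_mendelian(ped)
    assert [(mv.individual_id, mv.variant) for mv in violations] == [("kid", "v1")]


def test_mendelian_missing_parent_never_flags():
    ped = Pedigree(
        [
            _ind("dad", v1=0),
            _ind("mum", v1=None),
            _ind("kid", father="dad", mother="mum", v1=1),
        ],
        ["v1"],
    )
    assert check_mendelian(ped) == []


def test_mendelian_homozygote_cases():
    ped = Pedigree(
        [
            _ind("dad", v1=2),
            _ind("mum", v1=0),
            _ind("ok", father="dad", mother="mum", v1=1),
            _ind("bad", father="dad", mother="mum", v1=0),  # must get alt from dad
            _ind("bad2", father="dad", mother="mum", v1=2),  # cannot get alt from mum
        ],
        ["v1"],
    )
    flagged = {mv.individual_id for mv in check_mendelian(ped)}
    assert flagged == {"bad", "bad2"}


def test_simulated_pedigrees_have_no_mendelian_violations(family):
    """Whole-haplotype transmission can never violate biparental rules."""
    assert check_mendelian(family) == []
    spec_haps = {
        "f1": (MI_HAPLOTYPE, frozenset()),
        "f2": (MA_HAPLOTYPE, frozenset()),
    }
    for seed in range(500):
        ped, _ = simulate_pedigree(
            PedigreeSpec(
                founder_haplotypes=spec_haps,
                variant_labels=FAMILY_VARIANTS,
                n_generations=3,
                offspring_per_couple=2,
                seed=seed,
            )
        )
        assert check_mendelian(ped) == []


# ------------------------------------------------------------------ phasing

def test_family_phase_resolves_to_published_cis_trans(family):
    result = phase_variants(family)
    assert result.status == "resolved"
    assert set(result.haplotypes) == {MI_HAPLOTYPE, MA_HAPLOTYPE}
    # every mutation carrier constrains the phase
    assert set(result.supporting_individuals) == {
        "Ia", "IIa", "IIb", "IIc", "IIe", "IIf",
        "IIIa", "IIIc", "IIIe", "IIIf",
    }


def test_isolated_double_heterozygote_is_ambiguous():
    ped = Pedigree([_ind("solo", v1=1, v2=1)], ["v1", "v2"])
    result = phase_variants(ped)
    assert result.status == "ambiguous"
    assert len(result.candidates) == 2
    cands = {tuple(sorted(map(tuple, map(sorted, c)))) for c in result.candidates}
    assert cands == {((), ("v1", "v2")), (("v1",), ("v2",))}


def test_trio_resolves_trans_phase():
    ped = Pedigree(
        [
            _ind("dad", v1=1, v2=0),
            _ind("mum", v1=0, v2=1),
            _ind("kid", father="dad", mother="mum", v1=1, v2=1),
        ],
        ["v1", "v2"],
    )
    result = phase_variants(ped)
    assert result.status == "resolved"
    assert set(result.haplotypes) == {frozenset({"v1"}), frozenset({"v2"})}


def test_phase_inconsistent_genotypes_detected():
    # child het at v1 although neither parent carries it, and parents typed
    ped = Pedigree(
        [
            _ind("dad", v1=0, v2=0),
            _ind("mum", v1=0, v2=0),
            _ind("kid", father="dad", mother="mum", v1=1, v2=1),
        ],
        ["v1", "v2"],
    )
    assert phase_variants(ped).status == "inconsistent"


def test_phase_refuses_oversized_enumeration():
    labels = [f"v{i}" for i in range(7)]
    ped = Pedigree([_ind("solo", **{v: 1 for v in labels})], labels)
    with pytest.raises(PhaseEnumerationError):
        phase_variants(ped)


def test_phase_recovery_matches_planted_truth():
    """Resolved phases equal the planted founder haplotypes, every time."""
    spec_haps = {
        "f1": (MI_HAPLOTYPE, frozenset()),
        "f2": (MA_HAPLOTYPE, frozenset()),
    }
    n_resolved = 0
    for seed in range(200):
        ped, truth = simulate_pedigree(
            PedigreeSpec(
                founder_haplotypes=spec_haps,
                variant_labels=FAMILY_VARIANTS,
                n_generations=3,
                offspring_per_couple=2,
                seed=seed,
            )
        )
        result = phase_variants(ped)
        if result.status != "resolved":
            continue
        n_resolved += 1
        truth_classes = {h for pair in truth.values() for h in pair if h}
        observed = {h for h in result.haplotypes if h}
        assert observed == truth_classes
    assert n_resolved > 100  # most of these pedigrees are informative


def test_phase_ambiguity_declines_with_pedigree_size():
    """A lone double heterozygote is unphaseable; genotyping relatives
    progressively disambiguates.  Ambiguity rate over seeds is monotone
    non-increasing in the number of typed members."""
    rates = []
    for n_typed in (1, 3, 10, 20):
        ambiguous = 0
        n_seeds = 25
        for seed in range(n_seeds):
            ped, _ = simulate_pedigree(
                PedigreeSpec(
                    founder_haplotypes={
                        "f1": (frozenset({"v1", "v2"}), frozenset()),
                        "f2": (frozenset(), frozenset()),
                    },
                    variant_labels=["v1", "v2"],
                    n_generations=3,
                    offspring_per_couple=4,
                    seed=seed,
                )
            )
            # keep only the first n_typed members genotyped (f1 first)
            for i, ind in enumerate(ped.topological_order()):
                if i >= n_typed:
                    ind.genotypes = {v: Genotype.MISSING for v in ped.variant_labels}
            if phase_variants(ped).status == "ambiguous":
                ambiguous += 1
        rates.append(ambiguous / n_seeds)
    assert all(a >= b for a, b in zip(rates, rates[1:]))
    assert rates[0] > rates[-1]


# -------------------------------------------------------------- segregation

def test_family_cosegregation_counts(family):
    result = phase_variants(family)
    report = cosegregation_test(family, result)
    assert report.n_affected_biallelic == 3
    assert report.n_carriers == 7
    assert report.n_noncarriers == 9
    assert report.n_untyped == 1
    assert report.violations == []
    assert report.consistent
    total = (report.n_affected_biallelic + report.n_carriers
             + report.n_noncarriers + report.n_untyped)
    assert total == len(family)


def test_unaffected_biallelic_is_a_violation(family):
    individuals = []
    for ind in family:
        individuals.append(
            Individual(
                id=ind.id, family_id=ind.family_id, father_id=ind.father_id,
                mother_id=ind.mother_id, sex=ind.sex, affected=ind.affected,
                genotypes=dict(ind.genotypes),
            )
        )
    # turn the unaffected spouse IIg into a compound heterozygote; the
    # phase from the pristine family isolates the AR rule being tested
    ped = Pedigree(individuals, family.variant_labels)
    ped["IIg"].genotypes = {v: Genotype.HET for v in FAMILY_VARIANTS}
    result = phase_variants(family)
    report = cosegregation_test(ped, result)
    assert [v[0] for v in report.violations] == ["IIg"]
    # reduced-penetrance mode downgrades it to a warning
    relaxed = cosegregation_test(ped, result, complete_penetrance=False)
    assert relaxed.violations == []
    assert [w[0] for w in relaxed.warnings] == ["IIg"]


def test_cosegregation_invariant_to_order_and_class_relabeling(family):
    result = phase_variants(family)
    report = cosegregation_test(family, result)
    reordered = Pedigree(
        sorted(family, key=lambda i: i.id, reverse=True), family.variant_labels
    )
    swapped = type(result)(
        status="resolved",
        haplotypes=(result.haplotypes[1], result.haplotypes[0]),
        candidates=result.candidates,
        supporting_individuals=result.supporting_individuals,
    )
    report2 = cosegregation_test(reordered, swapped)
    assert report2.to_dict() == report.to_dict()


def test_fully_penetrant_simulations_never_violate():
    spec_haps = {
        "f1": (MI_HAPLOTYPE, MA_HAPLOTYPE),
        "f2": (MI_HAPLOTYPE, frozenset()),
    }
    for seed in range(50):
        ped, _ = simulate_pedigree(
            PedigreeSpec(
                founder_haplotypes=spec_haps,
                variant_labels=FAMILY_VARIANTS,
                n_generations=2,
                offspring_per_couple=4,
                seed=seed,
            )
        )
        result = phase_variants(ped)
        if result.status == "resolved":
            assert cosegregation_test(ped, result).violations == []


def test_cosegregation_requires_resolved_phase(family):
    ambiguous = phase_variants(Pedigree([_ind("solo", v1=1, v2=1)], ["v1", "v2"]))
    with pytest.raises(ValueError):
        cosegregation_test(family, ambiguous)


# ----------------------------------------------------------- allele freqs

def test_allele_frequency_reported_control_mafs():
    cohort = simulate_cohort(
        CohortSpec(
            n_individuals=100,
            het_carriers={"IVS1+74bp": 6, "p.P11L": 4, "p.I340M": 16},
            seed=5,
        )
    )
    assert allele_frequency(cohort, "IVS1+74bp") == pytest.approx(0.03)
    assert allele_frequency(cohort, "p.P11L") == pytest.approx(0.02)
    assert allele_frequency(cohort, "p.I340M") == pytest.approx(0.08)


def test_allele_frequency_edge_cases():
    cohort = pd.DataFrame({"v": [0, 0, 0]})
    assert allele_frequency(cohort, "v") == 0.0
    hets = pd.DataFrame({"v": [1, 1, 1, 1]})
    assert allele_frequency(hets, "v") == 0.5
    with pytest.raises(ValueError):
        allele_frequency(pd.DataFrame({"v": [None, None]}), "v")
    with pytest.raises(KeyError):
        allele_frequency(cohort, "nope")


def test_allele_frequency_matches_brute_force_tally():
    import random

    rng = random.Random(31)
    for _ in range(100):
        n = rng.randint(1, 60)
        doses = [rng.choice([0, 0, 0, 1, 1, 2, None]) for _ in range(n)]
        if all(d is None for d in doses):
            continue
        cohort = pd.DataFrame({"v": doses}, dtype="object")
        typed = [d for d in doses if d is not None]
        brute = sum(typed) / (2 * len(typed))
        assert allele_frequency(cohort, "v") == pytest.approx(brute)
        assert 0.0 <= allele_frequency(cohort, "v") <= 1.0
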