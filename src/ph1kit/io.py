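"""File formats, run configuration and the end-to-end pipeline.

Formats (all plain text):

* **Aligned FASTA** — equal-length rows, "-" as the gap character, unique
  record ids; read via Biopython.
* **PED dialect** — whitespace-separated, six leading columns (family, id,
  father, mother, sex, affection) then two allele columns per variant
  (1 = ref, 2 = alt, 0 = missing).  The variant order is declared in a
  leading ``#variants:`` header line.  Sex codes: 1 male, 2 female,
  0 unknown.  Affection codes: 2 affected, 1 unaffected, 0/-9 unknown.
* **Cohort TSV** — one row per individual, ``id`` column then one
  alt-allele-dose column (0/1/2, NA missing) per variant.
* **Clinical TSV** — Table-style patient rows (id, sex, age, creatinine,
  OCR, stone flags, confirmatory flags).

Protein and cDNA positions are 1-based everywhere in serialized output;
alignment column indices are 0-based and labelled as such.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from . import clinical, pedigree as ped, scoring, simulate
from .clinical import ClinicalRecord
from .pedigree import (
    FOUNDER,
    Affection,
    Genotype,
    Individual,
    Pedigree,
    Sex,
)
from .variants import Variant, parse_variant

logger = logging.getLogger("ph1kit")

__all__ = [
    "RunConfig",
    "read_alignment",
    "write_alignment",
    "read_pedigree",
    "write_pedigree",
    "read_cohort",
    "write_cohort",
    "read_clinical_records",
    "write_clinical_records",
    "scorecards_to_tsv",
    "run_pipeline",
    "demo_inputs",
]


@dataclass
class RunConfig:
    """Pipeline configuration; the defaults reproduce the published
    rubric and clinical conventions (8-species strict MSA bins, classic
    186-coefficient MDRD)."""

    reference_id: str = "ref"
    n_species: int = 8
    msa_mode: str = "strict8"        # "strict8" | "proportional"
    mdrd_variant: str = "classic186"  # "classic186" | "idms175"
    output_dir: Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.msa_mode not in ("strict8", "proportional"):
            raise ValueError(f"unknown msa_mode {self.msa_mode!r}")
        if self.mdrd_variant not in ("classic186", "idms175"):
            raise ValueError(f"unknown mdrd_variant {self.mdrd_variant!r}")


# ---------------------------------------------------------------- alignment

def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA; rows must be equal length and ids unique."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty alignment file")
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sequence ids in alignment")
    return aln


def write_alignment(aln: MultipleSeqAlignment, path: str | Path) -> None:
    AlignIO.write(aln, str(path), "fasta")


# --------------------------------------------------------------------- PED

_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_CODE_TO_SEX = {v: k for k, v in _SEX_TO_CODE.items()}
_AFF_TO_CODE = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}
_CODE_TO_AFF = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED,
                "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}


def _alleles(g: Genotype) -> tuple[str, str]:
    return {
        Genotype.REF: ("1", "1"),
        Genotype.HET: ("1", "2"),
        Genotype.HOM: ("2", "2"),
        Genotype.MISSING: ("0", "0"),
    }[g]


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    lines = ["#variants: " + " ".join(pedigree.variant_labels)]
    for ind in pedigree:
        cols = [
            ind.family_id,
            ind.id,
            ind.father_id,
            ind.mother_id,
            _SEX_TO_CODE[ind.sex],
            _AFF_TO_CODE[ind.affected],
        ]
        for v in pedigree.variant_labels:
            cols.extend(_alleles(ind.genotype(v)))
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_pedigree(
    path: str | Path, variant_labels: Sequence[str] | None = None
) -> Pedigree:
    """Read the PED dialect; the variant order comes from the
    ``#variants:`` header unless passed explicitly."""
    lines = Path(path).read_text().splitlines()
    labels = list(variant_labels) if variant_labels else None
    individuals: list[Individual] = []
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.lower().startswith("#variants:") and labels is None:
                labels = line.split(":", 1)[1].split()
            continue
        cols = line.split()
        if labels is None:
            raise ValueError(
                f"{path}: variant order not declared (no #variants: header)"
            )
        expected = 6 + 2 * len(labels)
        if len(cols) != expected:
            raise ValueError(
                f"{path}: expected {expected} columns "
                f"(6 + 2 per variant), got {len(cols)}: {line!r}"
            )
        fam, iid, father, mother, sex_code, aff_code = cols[:6]
        if sex_code not in _CODE_TO_SEX:
            raise ValueError(f"{path}: bad sex code {sex_code!r} for {iid}")
        if aff_code not in _CODE_TO_AFF:
            raise ValueError(f"{path}: bad affection code {aff_code!r} for {iid}")
        genotypes: dict[str, Genotype] = {}
        for j, label in enumerate(labels):
            a1, a2 = cols[6 + 2 * j], cols[7 + 2 * j]
            if "0" in (a1, a2):
                genotypes[label] = Genotype.MISSING
            else:
                try:
                    dose = sum({"1": 0, "2": 1}[a] for a in (a1, a2))
                except KeyError:
                    raise ValueError(
                        f"{path}: bad allele code in {(a1, a2)} for {iid}/{label}"
                    ) from None
                genotypes[label] = Genotype.from_dose(dose)
        individuals.append(
            Individual(
                id=iid,
                family_id=fam,
                father_id=father,
                mother_id=mother,
                sex=_CODE_TO_SEX[sex_code],
                affected=_CODE_TO_AFF[aff_code],
                genotypes=genotypes,
            )
        )
    return Pedigree(individuals, labels or [])


# ------------------------------------------------------------------ tables

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index_label="id")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id", comment="#")


_CLINICAL_COLS = [
    "id", "sex", "age_years", "scr_umol_per_l", "ocr_mmol_per_mmol",
    "has_nephrolithiasis", "has_nephrocalcinosis",
    "biallelic_pathogenic", "agt_activity_deficient",
]


def _tribool(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes")


def read_clinical_records(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for _, row in df.iterrows():
        ocr = row.get("ocr_mmol_per_mmol")
        records.append(
            ClinicalRecord(
                id=str(row["id"]),
                sex=str(row["sex"]).strip().lower(),
                age_years=float(row["age_years"]),
                scr_umol_per_l=float(row["scr_umol_per_l"]),
                ocr_mmol_per_mmol=None if pd.isna(ocr) else float(ocr),
                has_nephrolithiasis=bool(_tribool(row.get("has_nephrolithiasis"))),
                has_nephrocalcinosis=bool(_tribool(row.get("has_nephrocalcinosis"))),
                biallelic_pathogenic=_tribool(row.get("biallelic_pathogenic")),
                agt_activity_deficient=_tribool(row.get("agt_activity_deficient")),
            )
        )
    return records


def write_clinical_records(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "sex": r.sex,
            "age_years": r.age_years,
            "scr_umol_per_l": r.scr_umol_per_l,
            "ocr_mmol_per_mmol": r.ocr_mmol_per_mmol,
            "has_nephrolithiasis": r.has_nephrolithiasis,
            "has_nephrocalcinosis": r.has_nephrocalcinosis,
            "biallelic_pathogenic": r.biallelic_pathogenic,
            "agt_activity_deficient": r.agt_activity_deficient,
        })
    pd.DataFrame(rows, columns=_CLINICAL_COLS).to_csv(path, sep="\t", index=False)


def scorecards_to_tsv(cards: Iterable[scoring.ScoreCard], path: str | Path) -> None:
    rows = [c.to_dict() for c in cards]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- pipeline

def demo_inputs(seed: int = 0) -> dict:
    """The study-family demonstration inputs.

    Bundles the encoded 20-member pedigree, a synthetic 8-species
    alignment fully conserved at the two mutated positions (Met49, Asn72),
    the 100-subject control cohort with the reported carrier counts
    (IVS1+74bp 3%, P11L 2%, I340M 8% alt-allele frequency), the three
    patients' clinical rows, and the three study variants.
    """
    rng_seed = seed % 2**31
    length = 120
    ref = list(simulate.simulate_msa(simulate.MsaSpec(length=length, seed=rng_seed)))
    ref_seq = list(str(ref[0].seq))
    ref_seq[48] = "M"   # position 49, 1-based
    ref_seq[71] = "N"   # position 72
    msa = simulate.simulate_msa(
        simulate.MsaSpec(
            length=length,
            planted_conservation={48: 8, 71: 8},
            reference_seq="".join(ref_seq),
            seed=rng_seed,
        )
    )
    cohort = simulate.simulate_cohort(
        simulate.CohortSpec(
            n_individuals=100,
            het_carriers={"IVS1+74bp": 6, "p.P11L": 4, "p.I340M": 16},
            seed=rng_seed,
        )
    )
    records = [
        ClinicalRecord(id="IIa", sex="female", age_years=52, scr_umol_per_l=1044,
                       ocr_mmol_per_mmol=None, has_nephrolithiasis=True,
                       has_nephrocalcinosis=True, biallelic_pathogenic=True),
        ClinicalRecord(id="IIe", sex="male", age_years=38, scr_umol_per_l=210,
                       ocr_mmol_per_mmol=None, has_nephrolithiasis=True,
                       has_nephrocalcinosis=False, biallelic_pathogenic=True),
        ClinicalRecord(id="IIf", sex="female", age_years=37, scr_umol_per_l=94,
                       ocr_mmol_per_mmol=0.35, has_nephrolithiasis=True,
                       has_nephrocalcinosis=False, biallelic_pathogenic=True),
    ]
    variants = [
        parse_variant("p.M49L (c.145A > C)"),
        parse_variant("p.N72I (c.215A > T)"),
        parse_variant("p.R333*"),
    ]
    return {
        "pedigree": simulate.make_family_fixture(),
        "alignment": msa,
        "cohort": cohort,
        "clinical_records": records,
        "variants": variants,
    }


def run_pipeline(config: RunConfig, inputs: dict) -> dict:
    """Run parse -> score -> phase -> segregate -> clinical metrics and
    return a JSON-serializable report bundle.

    ``inputs`` holds any of: ``variants`` (list of Variant or labels),
    ``alignment``, ``pedigree``, ``cohort``, ``clinical_records``.  Stages
    whose inputs are absent are skipped; an empty input set is an error.
    """
    if not inputs or not any(
        inputs.get(k) is not None
        for k in ("variants", "alignment", "pedigree", "cohort", "clinical_records")
    ):
        raise ValueError("no pipeline inputs provided")
    bundle: dict = {"config": {
        "reference_id": config.reference_id,
        "msa_mode": config.msa_mode,
        "mdrd_variant": config.mdrd_variant,
    }}

    variants: list[Variant] = [
        v if isinstance(v, Variant) else parse_variant(v)
        for v in inputs.get("variants", [])
    ]
    aln = inputs.get("alignment")
    if variants and aln is not None:
        cards = []
        skipped = []
        for v in variants:
            if v.is_missense:
                cards.append(
                    scoring.score_variant(
                        v, aln, config.reference_id, mode=config.msa_mode
                    )
                )
            else:
                skipped.append(
                    {"variant": v.label, "kind": v.kind.value,
                     "note": "null allele, presumed deleterious; not rubric-scored"}
                )
        bundle["scores"] = [c.to_dict() for c in cards]
        bundle["unscored"] = skipped

    pedigree = inputs.get("pedigree")
    if pedigree is not None:
        bundle["mendelian_violations"] = [
            {"individual": mv.individual_id, "variant": mv.variant, "detail": mv.detail}
            for mv in ped.check_mendelian(pedigree)
        ]
        phase = ped.phase_variants(pedigree)
        bundle["phase"] = phase.to_dict()
        if phase.status == "resolved":
            bundle["segregation"] = ped.cosegregation_test(pedigree, phase).to_dict()

    cohort = inputs.get("cohort")
    if cohort is not None:
        bundle["maf"] = {
            v: ped.allele_frequency(cohort, v) for v in cohort.columns
        }

    records = inputs.get("clinical_records")
    if records:
        rows = []
        for r in records:
            egfr = clinical.egfr_mdrd(
                r.scr_umol_per_l, r.age_years, r.sex, variant=config.mdrd_variant
            )
            row = {"id": r.id, "egfr_ml_min": egfr,
                   "diagnosis": clinical.diagnose_ph1(r).value}
            if r.ocr_mmol_per_mmol is not None:
                row["ocr_flag"] = clinical.ocr_flag(r.ocr_mmol_per_mmol)
            rows.append(row)
        bundle["clinical"] = rows

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
        (out / "report.txt").write_text(render_report(bundle))
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable summary of a pipeline bundle."""
    lines: list[str] = []
    for card in bundle.get("scores", []):
        lines.append(
            f"{card['variant']}: Grantham {card['grantham']} "
            f"({card['grantham_pts']} pt), conserved {card['conserved']} "
            f"({card['msa_pts']} pt), total {card['total']} -> {card['class']}"
        )
    for item in bundle.get("unscored", []):
        lines.append(f"{item['variant']}: {item['note']}")
    phase = bundle.get("phase")
    if phase:
        if phase["status"] == "resolved":
            h1, h2 = sorted(phase["haplotypes"], key=len, reverse=True)
            lines.append(
                f"phase resolved: {{{', '.join(h1)}}} in cis, "
                f"with {{{', '.join(h2)}}} in trans"
            )
        else:
            lines.append(f"phase {phase['status']}")
    seg = bundle.get("segregation")
    if seg:
        lines.append(
            f"segregation ({seg['model']}): {seg['n_affected_biallelic']} biallelic, "
            f"{seg['n_carriers']} carriers, {seg['n_noncarriers']} noncarriers, "
            f"{seg['n_untyped']} untyped; "
            f"{'consistent' if not seg['violations'] else 'VIOLATIONS: ' + str(seg['violations'])}"
        )
    for v, f in bundle.get("maf", {}).items():
        lines.append(f"MAF {v}: {f:.1%}")
    for row in bundle.get("clinical", []):
        extra = f", OCR {row['ocr_flag']}" if "ocr_flag" in row else ""
        lines.append(
            f"{row['id']}: eGFR {row['egfr_ml_min']} ml/min{extra} -> {row['diagnosis']}"
        )
    return "\n".join(lines) + "\n"
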