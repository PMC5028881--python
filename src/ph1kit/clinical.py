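"""Clinical quantities anchoring a PH1 diagnosis.

* MDRD eGFR from serum creatinine, age and sex.  The 4-variable MDRD
  equation with the classic 186 coefficient is the default:
  ``eGFR = 186 x (Scr[mg/dL])^-1.154 x age^-0.203 (x 0.742 if female)``,
  with creatinine converted from µmol/L via division by 88.4.  The
  IDMS-traceable 175-coefficient variant is available as an option.

* Random urinary oxalate-to-creatinine ratio (OCR, mmol/mmol — the ratio
  is dimensionless, so mol/mol is the same number): above 0.04 is
  abnormal in adults; 0.04 itself is normal.

* Pyridoxine responsiveness: a reduction of more than 30% in random OCR
  on vitamin B6 therapy (strict inequality).

* The adult PH1 diagnostic rule: bilateral nephrocalcinosis or recurrent
  urolithiasis, plus at least one of (i) abnormal OCR, (ii) deficient AGT
  catalytic activity in liver tissue, (iii) pathogenic mutations on both
  AGXT alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ClinicalRecord",
    "Diagnosis",
    "egfr_mdrd",
    "ocr_flag",
    "pyridoxine_response",
    "diagnose_ph1",
    "OCR_THRESHOLD",
    "PYRIDOXINE_RESPONSE_PCT",
    "UMOL_PER_MGDL",
]

OCR_THRESHOLD = 0.04          # mmol/mmol; adult normal is <= 0.04
PYRIDOXINE_RESPONSE_PCT = 30  # responsive means a reduction of MORE than 30%
UMOL_PER_MGDL = 88.4          # creatinine unit conversion

_MDRD_COEF = {"classic186": 186.0, "idms175": 175.0}


class Diagnosis(str, Enum):
    MEETS_CRITERIA = "meets_criteria"
    DOES_NOT_MEET = "does_not_meet"
    INSUFFICIENT_DATA = "insufficient_data"


@dataclass
class ClinicalRecord:
    """Per-patient inputs for eGFR and the diagnostic rule set.

    ``biallelic_pathogenic`` and ``agt_activity_deficient`` are tri-state:
    True / False / None (unknown).  OCR may be absent (None).
    """

    scr_umol_per_l: float
    age_years: float
    sex: str  # "male" | "female"
    ocr_mmol_per_mmol: float | None = None
    has_nephrolithiasis: bool = False
    has_nephrocalcinosis: bool = False
    biallelic_pathogenic: bool | None = None
    agt_activity_deficient: bool | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.scr_umol_per_l <= 0:
            raise ValueError(f"serum creatinine must be > 0, got {self.scr_umol_per_l}")
        if self.age_years <= 0:
            raise ValueError(f"age must be > 0, got {self.age_years}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.ocr_mmol_per_mmol is not None and self.ocr_mmol_per_mmol < 0:
            raise ValueError(f"OCR must be >= 0, got {self.ocr_mmol_per_mmol}")


def egfr_mdrd(
    scr_umol_per_l: float,
    age_years: float,
    sex: str,
    *,
    variant: str = "classic186",
    precision: int | None = 1,
) -> float:
    """Estimated GFR (ml/min) from the 4-variable MDRD equation.

    Creatinine is given in µmol/L and converted to mg/dL internally.  The
    result is rounded to ``precision`` decimals for reporting (pass
    ``precision=None`` for the raw value).  The Black-ethnicity factor is
    not applied.
    """
    if scr_umol_per_l <= 0 or age_years <= 0:
        raise ValueError("serum creatinine and age must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    try:
        coef = _MDRD_COEF[variant]
    except KeyError:
        raise ValueError(f"unknown MDRD variant {variant!r}") from None
    scr_mgdl = scr_umol_per_l / UMOL_PER_MGDL
    egfr = coef * scr_mgdl**-1.154 * age_years**-0.203
    if sex == "female":
        egfr *= 0.742
    return round(egfr, precision) if precision is not None else egfr


def ocr_flag(ocr: float) -> str:
    """"abnormal" for OCR strictly above 0.04 mmol/mmol, else "normal"."""
    if ocr < 0:
        raise ValueError(f"OCR must be >= 0, got {ocr}")
    return "abnormal" if ocr > OCR_THRESHOLD else "normal"


def pyridoxine_response(ocr_before: float, ocr_after: float) -> tuple[float, bool]:
    """Percent OCR reduction on pyridoxine and whether it exceeds 30%.

    Returns ``(percent_reduction, responsive)``; responsiveness requires a
    reduction of strictly more than 30%.
    """
    if ocr_before <= 0:
        raise ValueError(f"baseline OCR must be > 0, got {ocr_before}")
    if ocr_after < 0:
        raise ValueError(f"post-treatment OCR must be >= 0, got {ocr_after}")
    pct = 100.0 * (ocr_before - ocr_after) / ocr_before
    # epsilon keeps an exactly-30% reduction non-responsive despite
    # floating-point noise in the subtraction
    return pct, pct > PYRIDOXINE_RESPONSE_PCT + 1e-9


def diagnose_ph1(record: ClinicalRecord) -> Diagnosis:
    """Apply the adult PH1 diagnostic rule set to one record.

    The stone prong (nephrolithiasis or nephrocalcinosis) must hold; it is
    then confirmed by abnormal OCR, deficient AGT activity, or biallelic
    pathogenic AGXT mutations.  If the stone prong holds but no
    confirmatory item is known true and at least one is unknown, the
    verdict is ``insufficient_data``; when all three are known negative it
    is ``does_not_meet``.
    """
    stone_prong = record.has_nephrolithiasis or record.has_nephrocalcinosis
    if not stone_prong:
        return Diagnosis.DOES_NOT_MEET
    ocr_abnormal: bool | None = (
        None
        if record.ocr_mmol_per_mmol is None
        else record.ocr_mmol_per_mmol > OCR_THRESHOLD
    )
    confirmatory = (
        ocr_abnormal,
        record.agt_activity_deficient,
        record.biallelic_pathogenic,
    )
    if any(c is True for c in confirmatory):
        return Diagnosis.MEETS_CRITERIA
    if all(c is False for c in confirmatory):
        return Diagnosis.DOES_NOT_MEET
    return Diagnosis.INSUFFICIENT_DATA
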