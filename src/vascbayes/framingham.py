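"""Vascular-risk variable construction.

Mean arterial pressure, rule-based resolution of hypertension / diabetes /
high cholesterol from medication use, self-reported diagnosis and measured
values, smoking categorisation, and the sex-specific Framingham 10-year
general cardiovascular disease risk (lipid-based variant):

    risk = 1 - S0 ** exp(L - Lbar)

where L is a linear predictor in ln(age), ln(total cholesterol), ln(HDL),
ln(SBP) (with separate coefficients for treated and untreated blood
pressure), a current-smoker indicator and a diabetes indicator, and S0 is
the sex-specific 10-year baseline survival.  Coefficients live in a
versioned JSON data file guarded by a checksum.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional

__all__ = [
    "SubjectVitals",
    "ResolvedConditions",
    "FraminghamCoefficients",
    "load_framingham_coefficients",
    "mean_arterial_pressure",
    "smoking_category",
    "resolve_condition",
    "resolve_all_conditions",
    "framingham_cvd_10yr",
]

_COEFF_FILE = "framingham_general_cvd_2008.json"
_COEFF_SHA256 = "123a97bae69c1a5ca6cad097cff573ed4c09f956257f385ce0d23c54049b4d84"

CONDITIONS = ("hypertension", "diabetes", "high_cholesterol")

# threshold fallback rules: (measurement fields, predicate)
_SBP_HTN = 130.0
_DBP_HTN = 80.0
_GLUCOSE_DM = 125.0   # strictly greater
_CHOL_HIGH = 200.0


@dataclass(frozen=True)
class SubjectVitals:
    """Raw per-subject vascular measurements and self-report flags.

    Tri-state flags (``med_*``, ``dx_*``) use True / False / None, where
    None means the questionnaire answer is missing.
    """

    age: float
    sex: str                      # 'female' | 'male'
    sbp: float
    dbp: float
    total_chol: float
    hdl: float
    ldl: float
    triglycerides: float
    fasting_glucose: float
    bmi: float
    smoking: str                  # 'never' | 'former' | 'current'
    med_htn: Optional[bool] = None
    med_dm: Optional[bool] = None
    med_chol: Optional[bool] = None
    dx_htn: Optional[bool] = None
    dx_dm: Optional[bool] = None
    dx_chol: Optional[bool] = None

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not self.sbp > self.dbp > 0:
            raise ValueError("require SBP > DBP > 0")
        if self.age <= 0:
            raise ValueError("age must be positive")
        for name in ("total_chol", "hdl", "ldl", "triglycerides",
                     "fasting_glucose", "bmi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        smoking_category(self.smoking)  # validates the token


@dataclass(frozen=True)
class ResolvedConditions:
    hypertension: bool
    diabetes: bool
    high_cholesterol: bool
    provenance: dict  # condition -> 'medication' | 'self_report' | 'threshold'


@dataclass(frozen=True)
class FraminghamCoefficients:
    """Sex-specific risk-equation parameters."""

    betas: dict          # sex -> {term: beta}
    s0_10yr: dict        # sex -> baseline 10-year survival
    mean_lp: dict        # sex -> mean linear predictor

    def __post_init__(self):
        for sex in ("female", "male"):
            if sex not in self.betas:
                raise ValueError(f"missing coefficient block for {sex}")
            if not 0 < self.s0_10yr[sex] < 1:
                raise ValueError("baseline survival must lie in (0, 1)")


def load_framingham_coefficients(verify: bool = True) -> FraminghamCoefficients:
    """Load the packaged coefficient table, verifying its checksum."""
    raw = resources.files("vascbayes.data").joinpath(_COEFF_FILE).read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _COEFF_SHA256:
            raise RuntimeError(
                f"coefficient file checksum mismatch ({digest}); "
                "the packaged table has been altered")
    data = json.loads(raw)
    return FraminghamCoefficients(
        betas={s: data[s]["betas"] for s in ("female", "male")},
        s0_10yr={s: data[s]["s0_10yr"] for s in ("female", "male")},
        mean_lp={s: data[s]["mean_lp"] for s in ("female", "male")},
    )


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = DBP + (SBP - DBP) / 3."""
    if not sbp > dbp > 0:
        raise ValueError("require SBP > DBP > 0")
    return dbp + (sbp - dbp) / 3.0


def smoking_category(status) -> str:
    """Normalise a smoking-status token to 'never' / 'former' / 'current'."""
    if status is None:
        raise ValueError("smoking status is missing")
    token = str(status).strip().lower()
    if token in ("never", "never smoked", "non-smoker", "no"):
        return "never"
    if token in ("former", "ex", "ex-smoker", "past", "quit"):
        return "former"
    if token in ("current", "smoker", "yes", "current smoker"):
        return "current"
    raise ValueError(f"unrecognised smoking status {status!r}")


def resolve_condition(med: Optional[bool], dx: Optional[bool],
                      measurements: dict, rule: str,
                      subject_id=None) -> tuple[bool, str]:
    """Resolve one condition with the precedence
    medication-use -> self-reported diagnosis -> measurement threshold.

    Threshold rules: hypertension SBP >= 130 or DBP >= 80; diabetes fasting
    glucose > 125 (strict); high cholesterol total cholesterol >= 200.
    """
    if rule not in CONDITIONS:
        raise ValueError(f"unknown condition {rule!r}")
    if med is True:
        return True, "medication"
    if dx is not None:
        return bool(dx), "self_report"

    def need(key):
        if key not in measurements or measurements[key] is None or (
                isinstance(measurements[key], float)
                and math.isnan(measurements[key])):
            who = f" for subject {subject_id}" if subject_id is not None else ""
            raise ValueError(
                f"cannot resolve {rule}{who}: no medication or diagnosis "
                f"report and measurement {key!r} is missing")
        return float(measurements[key])

    if rule == "hypertension":
        value = need("sbp") >= _SBP_HTN or need("dbp") >= _DBP_HTN
    elif rule == "diabetes":
        value = need("fasting_glucose") > _GLUCOSE_DM
    else:
        value = need("total_chol") >= _CHOL_HIGH
    return bool(value), "threshold"


def resolve_all_conditions(vitals: SubjectVitals,
                           subject_id=None) -> ResolvedConditions:
    meas = {"sbp": vitals.sbp, "dbp": vitals.dbp,
            "fasting_glucose": vitals.fasting_glucose,
            "total_chol": vitals.total_chol}
    flags, prov = {}, {}
    for rule, med, dx in (
            ("hypertension", vitals.med_htn, vitals.dx_htn),
            ("diabetes", vitals.med_dm, vitals.dx_dm),
            ("high_cholesterol", vitals.med_chol, vitals.dx_chol)):
        flags[rule], prov[rule] = resolve_condition(med, dx, meas, rule,
                                                    subject_id=subject_id)
    return ResolvedConditions(hypertension=flags["hypertension"],
                              diabetes=flags["diabetes"],
                              high_cholesterol=flags["high_cholesterol"],
                              provenance=prov)


def framingham_cvd_10yr(vitals: SubjectVitals,
                        conditions: ResolvedConditions | None = None,
                        coeffs: FraminghamCoefficients | None = None) -> float:
    """10-year probability of general cardiovascular disease.

    Antihypertensive treatment is taken from ``med_htn`` with a missing
    answer read as untreated.  The diabetes indicator comes from the resolved
    conditions (computed on the fly when not supplied); the smoker indicator
    is current smoking only.
    """
    if coeffs is None:
        coeffs = load_framingham_coefficients()
    if conditions is None:
        conditions = resolve_all_conditions(vitals)
    sex = vitals.sex
    if sex not in coeffs.betas:
        raise ValueError(f"unknown sex {sex!r}")
    b = coeffs.betas[sex]
    for name, value in (("age", vitals.age), ("SBP", vitals.sbp),
                        ("total cholesterol", vitals.total_chol),
                        ("HDL", vitals.hdl)):
        if value <= 0:
            raise ValueError(f"nonpositive {name} cannot enter a log term")
    treated = vitals.med_htn is True  # missing -> untreated
    sbp_term = b["ln_sbp_treated"] if treated else b["ln_sbp_untreated"]
    lp = (b["ln_age"] * math.log(vitals.age)
          + b["ln_total_chol"] * math.log(vitals.total_chol)
          + b["ln_hdl"] * math.log(vitals.hdl)
          + sbp_term * math.log(vitals.sbp)
          + b["smoker"] * (smoking_category(vitals.smoking) == "current")
          + b["diabetes"] * conditions.diabetes)
    risk = 1.0 - coeffs.s0_10yr[sex] ** math.exp(lp - coeffs.mean_lp[sex])
    return min(max(risk, 1e-12), 1 - 1e-12)
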