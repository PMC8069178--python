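"""Ten-year general cardiovascular disease risk (Framingham, lipid-based).

The score is a sex-specific Cox proportional-hazards model on log age, log
total cholesterol, log HDL cholesterol, log systolic blood pressure
(separate coefficients for treated and untreated hypertension), current
smoking, and diabetes:

    risk% = 100 · (1 − S0^exp(LP − mean LP))

where ``LP`` is the linear predictor, ``mean LP`` its population mean and
``S0`` the baseline 10-year event-free survival. Coefficients ship with the
package as a versioned JSON file and are validated in the test suite against
the source publication's worked example. Lipid inputs to the model are in
mg/dL; cohort records in mmol/L are converted internally
(1 mmol/L = 38.67 mg/dL cholesterol).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .containers import ClinicalRecord

__all__ = [
    "FraminghamCoefficients",
    "FraminghamResult",
    "load_coefficients",
    "framingham_risk",
    "framingham_risk_mgdl",
    "dichotomize_framingham",
    "score_cohort",
    "CHOL_MGDL_PER_MMOL",
    "FRAMINGHAM_CUTOFF",
]

CHOL_MGDL_PER_MMOL = 38.67
#: Percent risk at or above which a subject counts as "high Framingham".
FRAMINGHAM_CUTOFF = 12.0

_REQUIRED = ("ln_age", "ln_total_chol", "ln_hdl", "ln_sbp_untreated",
             "ln_sbp_treated", "smoker", "diabetes", "s0_10yr", "mean_lp")


@dataclass(frozen=True)
class FraminghamCoefficients:
    """Sex-specific coefficient sets plus baseline survival and mean LP."""

    by_sex: dict

    def __post_init__(self) -> None:
        for sex, coefs in self.by_sex.items():
            missing = [k for k in _REQUIRED if k not in coefs]
            if missing:
                raise ValueError(f"{sex} coefficient set lacks {missing}")
            if not (0 < coefs["s0_10yr"] < 1):
                raise ValueError(f"{sex} baseline survival outside (0,1)")

    def for_sex(self, sex: str) -> dict:
        try:
            return self.by_sex[sex]
        except KeyError:
            raise ValueError(f"no coefficients for sex {sex!r}") from None


def load_coefficients(path: str | Path | None = None) -> FraminghamCoefficients:
    """Load the shipped (or a user-supplied) coefficient JSON."""
    if path is None:
        text = (resources.files("metsynkit") / "data" /
                "framingham_general_cvd_2008.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    by_sex = {k: v for k, v in raw.items() if k in ("male", "female")}
    return FraminghamCoefficients(by_sex)


_DEFAULT_COEFS = load_coefficients()


def framingham_risk_mgdl(*, sex: str, age: float, total_chol: float, hdl: float,
                         sbp: float, bp_treated: bool, smoker: bool,
                         diabetes: bool,
                         coefs: FraminghamCoefficients | None = None) -> float:
    """10-year CVD risk in percent, lipids already in mg/dL."""
    coefs = coefs or _DEFAULT_COEFS
    c = coefs.for_sex(sex)
    for name, value in (("age", age), ("total_chol", total_chol),
                        ("hdl", hdl), ("sbp", sbp)):
        if value is None or not math.isfinite(value) or value <= 0:
            raise ValueError(f"covariate {name} must be positive and finite, got {value!r}")
    sbp_coef = c["ln_sbp_treated"] if bp_treated else c["ln_sbp_untreated"]
    lp = (c["ln_age"] * math.log(age)
          + c["ln_total_chol"] * math.log(total_chol)
          + c["ln_hdl"] * math.log(hdl)
          + sbp_coef * math.log(sbp)
          + c["smoker"] * bool(smoker)
          + c["diabetes"] * bool(diabetes))
    risk = 100.0 * (1.0 - c["s0_10yr"] ** math.exp(lp - c["mean_lp"]))
    return float(risk)


def framingham_risk(record: ClinicalRecord,
                    coefs: FraminghamCoefficients | None = None) -> float:
    """10-year CVD risk (percent) for a clinical record (lipids in mmol/L).

    Raises a ``ValueError`` naming the offending covariate when any required
    component is missing or non-positive, mirroring how subjects without a
    complete covariate set are excluded from scoring.
    """
    return framingham_risk_mgdl(
        sex=record.sex,
        age=record.age,
        total_chol=record.total_chol * CHOL_MGDL_PER_MMOL,
        hdl=record.hdl * CHOL_MGDL_PER_MMOL,
        sbp=record.sbp,
        bp_treated=record.bp_treated,
        smoker=record.smoker,
        diabetes=record.diabetes,
        coefs=coefs,
    )


@dataclass(frozen=True)
class FraminghamResult:
    subject_id: str
    risk_percent: float
    group: str  # "high" | "low"


def dichotomize_framingham(risk_percent: float,
                           cutoff: float = FRAMINGHAM_CUTOFF) -> str:
    """Split at the cutoff: risk ≥ cutoff is "high", below it "low"."""
    if not math.isfinite(risk_percent):
        raise ValueError("risk must be finite")
    return "high" if risk_percent >= cutoff else "low"


def score_cohort(records: list[ClinicalRecord],
                 coefs: FraminghamCoefficients | None = None,
                 cutoff: float = FRAMINGHAM_CUTOFF) -> pd.DataFrame:
    """Score every record; DataFrame indexed by subject with risk and group."""
    rows = []
    for r in records:
        risk = framingham_risk(r, coefs)
        rows.append((r.subject_id, risk, dichotomize_framingham(risk, cutoff)))
    df = pd.DataFrame(rows, columns=["subject_id", "risk_percent", "group"])
    return df.set_index("subject_id")
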