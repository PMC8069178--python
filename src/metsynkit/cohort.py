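"""Synthetic metabolic-syndrome cohorts with known ground truth.

Generates the three inputs the analysis pipeline consumes — a clinical
table, a metabolite abundance matrix with pathway annotations, and clamp
tracer time courses — for a cohort emulating treatment-naive men with
metabolic syndrome (default n = 132, 917 annotated metabolites):

* clinical covariates drawn independently from distributions calibrated to
  the study population's reported medians/IQRs (BMI ≈ 34 kg/m², fasting
  insulin ≈ 109 pmol/L, SBP ≈ 144 mmHg, ...), all male by default;
* insulin-resistance labels (Rd < 37.3 μmol·kg⁻¹·min⁻¹) with
  group-conditional Rd draws, and per-subject glycerol-Ra suppression
  centered on 68.1% and negatively coupled to HOMA-IR;
* log-normal metabolite abundances with planted group shifts (IR effect),
  planted rank correlations with the Framingham risk driver and with
  lipolysis suppression, and left-censored missingness below a per-column
  detection limit;
* a forward-simulated one-pool tracer model (analytic solution of the
  linear mass balance) producing concentration and enrichment curves that
  the Steele estimators can be validated against.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalRecord, MetaboliteTable, clinical_frame
from .kinetics import ClampSeries
from . import framingham as _fram

__all__ = ["SimConfig", "SimTruth", "gen_clinical", "gen_metabolites",
           "gen_clamp", "generate_cohort", "write_cohort"]

_Z_IQR = 0.6744897501960817  # standard-normal quantile at 0.75


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching a median and interquartile range."""
    return np.log(median), (np.log(q3) - np.log(q1)) / (2 * _Z_IQR)


@dataclass
class SimConfig:
    """Ground-truth configuration for one synthetic cohort.

    Effect-metabolite index lists must be disjoint subsets of
    ``range(n_metabolites)``. ``ir_effect_size`` is a standardized log-scale
    mean shift; ``fram_effect_size`` and ``supp_effect_size`` are latent
    correlation strengths in [−1, 1]. ``missing_rate`` is the censoring
    probability for cells whose latent abundance falls below the column's
    ``detection_limit_quantile``.
    """

    n_subjects: int = 132
    n_metabolites: int = 917
    seed: int = 0

    # insulin-resistance structure
    ir_fraction: float = 92 / 132
    ir_effect_metabolites: tuple = tuple(range(14))
    ir_effect_size: float = 1.0

    # CVD-risk structure
    fram_effect_metabolites: tuple = tuple(range(14, 47))
    fram_effect_size: float = 0.4

    # lipolysis-suppression structure
    supp_effect_metabolites: tuple = (60,)
    supp_effect_size: float = 0.6

    # missingness (left-censoring below detection limit)
    missing_rate: float = 0.6
    detection_limit_quantile: float = 0.25

    # clamp kinetics
    clamp_true_suppression: float = 68.1   # percent, cohort center
    clamp_suppression_sd: float = 8.0      # percent, between-subject spread
    suppression_homa_rho: float = 0.6      # strength of HOMA-IR ↔ Ra-supp coupling
    clamp_noise_cv: float = 0.05
    clamp_half_time: float = 30.0          # min, Ra decline half-time under insulin
    clamp_v_dist: float = 0.23             # L/kg
    clamp_tracer_rate: float = 0.1         # μmol·kg⁻¹·min⁻¹
    clamp_basal_concentration: float = 80.0  # μmol/L basal glycerol
    clamp_ra_basal_median: float = 2.5     # μmol·kg⁻¹·min⁻¹
    clamp_sample_times: tuple | None = None  # default: basal −30..0, clamp 20..240

    # demographics
    sex: str = "male"
    smoking_prevalence: float = 0.25
    diabetes_prevalence: float = 0.0
    bp_treated_prevalence: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ir_fraction", "missing_rate", "detection_limit_quantile",
                     "smoking_prevalence", "diabetes_prevalence",
                     "bp_treated_prevalence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.clamp_true_suppression <= 100.0):
            raise ValueError("clamp_true_suppression must lie in [0, 100]")
        if self.clamp_noise_cv < 0:
            raise ValueError("clamp_noise_cv must be non-negative")
        for name in ("fram_effect_size", "supp_effect_size"):
            if not (-1.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [-1, 1]")
        self.ir_effect_metabolites = tuple(int(i) for i in self.ir_effect_metabolites)
        self.fram_effect_metabolites = tuple(int(i) for i in self.fram_effect_metabolites)
        self.supp_effect_metabolites = tuple(int(i) for i in self.supp_effect_metabolites)
        sets = [set(self.ir_effect_metabolites), set(self.fram_effect_metabolites),
                set(self.supp_effect_metabolites)]
        if len(sets[0] | sets[1] | sets[2]) < sum(len(s) for s in sets):
            raise ValueError("effect metabolite index lists must be disjoint")
        for s in sets:
            if s and (min(s) < 0 or max(s) >= self.n_metabolites):
                raise ValueError("effect metabolite index out of range")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SimTruth:
    """Everything the generator knows that an analyst would not."""

    ir_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    rd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    ra_basal: np.ndarray = field(default_factory=lambda: np.zeros(0))
    true_suppression: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fram_driver: np.ndarray = field(default_factory=lambda: np.zeros(0))
    affected_metabolites: dict = field(default_factory=dict)
    half_time: float = 30.0
    latent_abundances: pd.DataFrame | None = None
    detection_limits: pd.Series | None = None

    def ra_schedule(self, subject: int, t) -> np.ndarray:
        """True glycerol Ra(t): basal constant, exponential decline after t=0."""
        t = np.asarray(t, dtype=float)
        ra_b = self.ra_basal[subject]
        plateau = ra_b * (1.0 - self.true_suppression[subject] / 100.0)
        lam = np.log(2.0) / self.half_time
        ra = np.where(t <= 0, ra_b, plateau + (ra_b - plateau) * np.exp(-lam * np.maximum(t, 0)))
        return ra if ra.ndim else float(ra)


def _truncated_lognormal(rng, mu, sigma, size, low=-np.inf, high=np.inf):
    """Rejection-sample a log-normal restricted to (low, high)."""
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.lognormal(mu, sigma, todo.size)
        ok = (draw > low) & (draw < high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def gen_clinical(config: SimConfig) -> tuple[list[ClinicalRecord], SimTruth]:
    """Draw the clinical table plus the ground truth behind it.

    Covariates are sampled from independent distributions whose medians and
    IQRs match the study population; no attempt is made to reproduce the
    real covariance structure beyond the planted couplings (Rd ↔ IR label,
    insulin ↔ IR label, suppression ↔ HOMA-IR).
    """
    n = config.n_subjects
    if n <= 0:
        return [], SimTruth(half_time=config.clamp_half_time)
    rng = config.rng(0)

    ir = rng.random(n) < config.ir_fraction

    age = np.clip(rng.normal(53.83, 9.38, n), 30, 80)
    sbp = np.clip(rng.normal(143.61, 18.20, n), 100, 220)
    dbp = np.clip(rng.normal(89.45, 11.11, n), 55, None)
    dbp = np.minimum(dbp, sbp - 15.0)
    glucose = np.clip(rng.normal(5.72, 0.66, n), 3.5, None)

    def group_lognormal(par_ir, par_nir):
        x = np.empty(n)
        mu, s = _lognormal_params(*par_ir)
        x[ir] = rng.lognormal(mu, s, ir.sum())
        mu, s = _lognormal_params(*par_nir)
        x[~ir] = rng.lognormal(mu, s, (~ir).sum())
        return x

    bmi = group_lognormal((34.50, 31.58, 38.69), (33.40, 30.82, 35.00))
    weight = group_lognormal((117.70, 105.45, 130.32), (108.45, 99.95, 118.17))
    insulin = group_lognormal((123.0, 93.0, 158.5), (69.0, 54.75, 87.0))

    hba1c = rng.lognormal(*_lognormal_params(39.0, 36.0, 41.0), n)
    total_chol = rng.lognormal(*_lognormal_params(5.00, 4.59, 5.89), n)
    ldl = rng.lognormal(*_lognormal_params(3.30, 2.70, 4.10), n)
    hdl = rng.lognormal(*_lognormal_params(1.08, 0.93, 1.23), n)
    trig = rng.lognormal(*_lognormal_params(1.40, 1.12, 1.79), n)

    smoker = rng.random(n) < config.smoking_prevalence
    diabetes = rng.random(n) < config.diabetes_prevalence
    bp_treated = rng.random(n) < config.bp_treated_prevalence

    # Rd consistent with the planted IR labels by truncation at the cutoff
    mu, s = _lognormal_params(27.00, 19.86, 33.01)
    rd = np.empty(n)
    rd[ir] = _truncated_lognormal(rng, mu, s, ir.sum(), high=37.3)
    mu, s = _lognormal_params(48.10, 41.08, 55.45)
    rd[~ir] = _truncated_lognormal(rng, mu, s, (~ir).sum(), low=37.3)

    # per-subject lipolysis suppression, anti-correlated with HOMA-IR
    homa = glucose * (insulin / 6.945) / 22.5
    z_homa = _standardize(np.log(homa))
    rho = config.suppression_homa_rho
    eps = rng.standard_normal(n)
    supp = (config.clamp_true_suppression
            + config.clamp_suppression_sd * (-rho * z_homa + np.sqrt(1 - rho**2) * eps))
    supp = np.clip(supp, 0.0, 100.0)

    ra_basal = rng.lognormal(np.log(config.clamp_ra_basal_median), 0.2, n)

    records = []
    for i in range(n):
        records.append(ClinicalRecord(
            subject_id=f"S{i:04d}", age=float(age[i]), sex=config.sex,
            bmi=float(bmi[i]), weight=float(weight[i]), sbp=float(sbp[i]),
            dbp=float(dbp[i]), fasting_glucose=float(glucose[i]),
            fasting_insulin=float(insulin[i]), hba1c=float(hba1c[i]),
            total_chol=float(total_chol[i]), ldl=float(ldl[i]),
            hdl=float(hdl[i]), triglycerides=float(trig[i]),
            smoker=bool(smoker[i]), diabetes=bool(diabetes[i]),
            bp_treated=bool(bp_treated[i]), rd=float(rd[i]),
        ))

    risks = np.array([_fram.framingham_risk(r) for r in records])
    truth = SimTruth(
        ir_labels=ir, rd=rd, ra_basal=ra_basal, true_suppression=supp,
        fram_driver=_standardize(np.log(risks)),
        affected_metabolites={
            "ir": {"indices": list(config.ir_effect_metabolites),
                   "effect_size": config.ir_effect_size},
            "fram": {"indices": list(config.fram_effect_metabolites),
                     "effect_size": config.fram_effect_size},
            "supp": {"indices": list(config.supp_effect_metabolites),
                     "effect_size": config.supp_effect_size},
        },
        half_time=config.clamp_half_time,
    )
    return records, truth


# Superpathway proportions loosely following an untargeted plasma panel;
# with the default 917 metabolites the Lipid family has exactly 451 members.
_SUPERPATHWAYS = (
    ("Lipid", 451), ("Amino Acid", 180), ("Xenobiotics", 80), ("Peptide", 47),
    ("Carbohydrate", 40), ("Cofactors and Vitamins", 40), ("Nucleotide", 30),
    ("Energy", 20), ("Partially Characterized Molecules", 29),
)


def _annotations(n: int) -> pd.DataFrame:
    total = sum(c for _, c in _SUPERPATHWAYS)
    supers: list[str] = []
    for name, count in _SUPERPATHWAYS:
        k = int(round(count / total * n))
        supers.extend([name] * k)
    supers = supers[:n]
    while len(supers) < n:
        supers.append("Partially Characterized Molecules")
    ids = [f"met_{i:04d}" for i in range(n)]
    sub = [f"{sp} subpathway {i % 8 + 1}" for i, sp in enumerate(supers)]
    return pd.DataFrame(
        {"biochemical_name": [f"metabolite {i}" for i in range(n)],
         "subpathway": sub, "superpathway": supers},
        index=pd.Index(ids, name="metabolite_id"),
    )


def gen_metabolites(records: list[ClinicalRecord], truth: SimTruth,
                    config: SimConfig) -> MetaboliteTable:
    """Log-normal abundance matrix with planted effects and left-censoring.

    IR-effect columns are shifted by ``ir_effect_size`` standard deviations
    (log scale) in IR-labeled subjects; Framingham- and suppression-effect
    columns share latent Gaussian structure with the respective per-subject
    drivers at the configured correlation. Cells whose latent value falls
    below the column's ``detection_limit_quantile`` are censored to missing
    with probability ``missing_rate``.
    """
    if not records:
        raise ValueError("records must be nonempty")
    n, m = len(records), config.n_metabolites
    rng = config.rng(1)

    mu = rng.uniform(np.log(50.0), np.log(5000.0), m)
    sigma = rng.uniform(0.3, 0.8, m)
    z = rng.standard_normal((n, m))

    r = config.fram_effect_size
    if config.fram_effect_metabolites and r != 0:
        idx = list(config.fram_effect_metabolites)
        z[:, idx] = (r * truth.fram_driver[:, None]
                     + np.sqrt(1 - r**2) * z[:, idx])
    r = config.supp_effect_size
    if config.supp_effect_metabolites and r != 0:
        idx = list(config.supp_effect_metabolites)
        z_supp = _standardize(truth.true_suppression)
        z[:, idx] = r * z_supp[:, None] + np.sqrt(1 - r**2) * z[:, idx]
    if config.ir_effect_metabolites and config.ir_effect_size != 0:
        idx = list(config.ir_effect_metabolites)
        z[np.ix_(truth.ir_labels, idx)] += config.ir_effect_size

    latent = np.exp(mu + sigma * z)

    if config.detection_limit_quantile > 0:
        limits = np.quantile(latent, config.detection_limit_quantile, axis=0)
    else:
        limits = np.full(m, -np.inf)
    censor = (latent < limits) & (rng.random((n, m)) < config.missing_rate)
    abundances = latent.copy()
    abundances[censor] = np.nan

    ann = _annotations(m)
    sample_ids = [rec.subject_id for rec in records]
    ab = pd.DataFrame(abundances, index=pd.Index(sample_ids, name="sample_id"),
                      columns=ann.index)
    truth.latent_abundances = pd.DataFrame(latent, index=ab.index, columns=ab.columns)
    truth.detection_limits = pd.Series(limits, index=ab.columns)
    return MetaboliteTable(ab, ann)


def _default_times() -> np.ndarray:
    return np.concatenate([np.array([-30.0, -20.0, -10.0, 0.0]),
                           np.arange(20.0, 241.0, 20.0)])


def gen_clamp(records: list[ClinicalRecord], truth: SimTruth,
              config: SimConfig) -> list[ClampSeries]:
    """Forward-simulate the one-pool tracer experiment for each subject.

    The pool (volume V, L/kg) receives endogenous glycerol at Ra(t) — basal
    constant, declining mono-exponentially to the suppressed plateau after
    insulin start — and tracer at constant rate F from t = −120 min. Total
    disposal is clearance-like (Rd = CL·C), which makes the tracer and
    tracee mass balances linear with rate constant k = CL/V and admits an
    exact closed-form solution; no integrator is involved. Measurement noise
    is multiplicative log-normal with CV ``clamp_noise_cv`` on both C and E.
    """
    if not records:
        raise ValueError("records must be nonempty")
    rng = config.rng(2)
    times = (np.asarray(config.clamp_sample_times, dtype=float)
             if config.clamp_sample_times is not None else _default_times())
    V = config.clamp_v_dist
    F = config.clamp_tracer_rate
    lam = np.log(2.0) / config.clamp_half_time
    t_tracer_start = -120.0

    out = []
    for i, rec in enumerate(records):
        ra_b = truth.ra_basal[i]
        supp = truth.true_suppression[i]
        if not (0.0 <= supp <= 100.0):
            raise ValueError(f"suppression {supp} outside [0, 100]")
        ra_p = ra_b * (1.0 - supp / 100.0)
        # clearance fixed by the basal steady state at the target concentration
        k = (ra_b + F) / (config.clamp_basal_concentration * V)

        t = times
        # tracer amount: zero at infusion start, relaxes to F/k
        qt = (F / k) * (1.0 - np.exp(-k * (t - t_tracer_start)))
        # tracee amount: basal steady state Ra_b/k for t<=0, then the exact
        # solution of dQe/dt = Ra(t) − k·Qe with exponential Ra decline
        qe = np.empty_like(t)
        pre = t <= 0
        qe[pre] = ra_b / k
        tp = t[~pre]
        if tp.size:
            if abs(k - lam) < 1e-12:
                b = (ra_b - ra_p) * tp * np.exp(-k * tp)
                qe[~pre] = ra_p / k + (ra_b / k - ra_p / k) * np.exp(-k * tp) + b
            else:
                B = (ra_b - ra_p) / (k - lam)
                A = ra_b / k - ra_p / k - B
                qe[~pre] = ra_p / k + A * np.exp(-k * tp) + B * np.exp(-lam * tp)

        q = qe + qt
        C = q / V
        E = qt / q
        if config.clamp_noise_cv > 0:
            C = C * np.exp(config.clamp_noise_cv * rng.standard_normal(t.size))
            E = E * np.exp(config.clamp_noise_cv * rng.standard_normal(t.size))
            E = np.clip(E, 1e-9, 1 - 1e-9)
        phase = np.where(t <= 0, "basal", "step1").astype(object)
        out.append(ClampSeries(rec.subject_id, t, phase,
                               np.full(t.size, F), C, E, np.zeros(t.size)))
    return out


def generate_cohort(config: SimConfig):
    """Convenience: (records, truth, metabolite table, clamp series)."""
    records, truth = gen_clinical(config)
    if not records:
        return records, truth, None, []
    table = gen_metabolites(records, truth, config)
    clamps = gen_clamp(records, truth, config)
    return records, truth, table, clamps


def write_cohort(out_dir: str | Path, config: SimConfig) -> dict:
    """Generate and write all cohort files; returns the paths written."""
    from .kinetics import write_clamp_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth, table, clamps = generate_cohort(config)
    paths = {
        "clinical": out / "clinical.csv",
        "abundances": out / "metabolites.tsv",
        "annotations": out / "annotations.tsv",
        "clamp": out / "clamp.csv",
        "truth": out / "truth.json",
    }
    clinical_frame(records).to_csv(paths["clinical"])
    if table is not None:
        table.to_tsv(paths["abundances"], paths["annotations"])
    write_clamp_csv(clamps, paths["clamp"])
    truth_json = {
        "config": asdict(config),
        "ir_labels": truth.ir_labels.astype(int).tolist(),
        "rd": truth.rd.tolist(),
        "ra_basal": truth.ra_basal.tolist(),
        "true_suppression": truth.true_suppression.tolist(),
        "affected_metabolites": truth.affected_metabolites,
    }
    paths["truth"].write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
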