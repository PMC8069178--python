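"""End-to-end study replica: cohort → preprocessing → fluxes → risk →
screens → nested-CV models → overlap and lipolysis sections.

``run_study`` wires every stage together on a (by default synthetic) cohort
and emits the study's result surfaces: the IR metabolite screen, the
Framingham correlation screen, the all-features and top-20 nested-CV
models with their overlap list, and the lipolysis section (metabolite and
clinical correlates of glycerol-Ra suppression, with family-specific FDR).
All stochastic stages are seeded from one master seed, so a repeated run
writes byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SimConfig, generate_cohort
from .containers import MetaboliteTable, clinical_frame
from .framingham import FRAMINGHAM_CUTOFF, dichotomize_framingham, score_cohort
from .harness import CVConfig, NestedCVResult, rerun_on_subset, run_nested_cv, \
    sanity_report, select_top_features
from .kinetics import RD_IR_CUTOFF, GLYCEROL_PARAMS, SteeleParams, classify_ir, \
    estimate_suppression
from .preprocess import preprocess
from .screen import ScreenResult, bh_fdr, homa_ir, screen_correlation, \
    screen_frame, screen_groups, significant, spearman_rho

__all__ = ["StudyConfig", "StudyReport", "overlap_features",
           "lipolysis_analysis", "run_study"]

#: Clinical parameters correlated against Ra-supp (their own FDR family).
CLINICAL_FAMILY = ("homa_ir", "insulin", "glucose", "ldl", "hdl", "bmi",
                   "age", "triglycerides")


@dataclass
class StudyConfig:
    """Thresholds and stage settings for one full study run."""

    sim: SimConfig = field(default_factory=SimConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    rd_cutoff: float = RD_IR_CUTOFF
    fram_cutoff: float = FRAMINGHAM_CUTOFF
    alpha_q: float = 0.05
    top_k: int = 20
    clamp_subset_size: int = 39
    steele: SteeleParams = GLYCEROL_PARAMS


@dataclass
class LipolysisSection:
    screen_all: list
    screen_lipid: list
    clinical_correlates: pd.DataFrame
    suppressions: pd.Series


@dataclass
class StudyReport:
    ir_screen: list
    fram_correlates: list
    ml_all: NestedCVResult
    ml_top20: NestedCVResult
    overlap: list
    lipolysis: LipolysisSection
    framingham: pd.DataFrame
    ir_labels: pd.Series


def overlap_features(top_features, screen: list[ScreenResult],
                     alpha_q: float = 0.05) -> list:
    """Intersection of model top-features and screen hits, by ascending q.

    Both inputs must come from the same metabolite namespace; a top feature
    absent from the screen indicates mismatched inputs and is an error.
    """
    by_id = {r.metabolite_id: r for r in screen}
    unknown = [f for f in top_features if f not in by_id]
    if unknown:
        raise ValueError(f"features not present in the screen namespace: {unknown[:5]}")
    hits = [f for f in top_features if by_id[f].q_value < alpha_q]
    return sorted(hits, key=lambda f: (by_id[f].q_value, str(f)))


def lipolysis_analysis(table: MetaboliteTable, suppressions: pd.Series,
                       clinical: pd.DataFrame, *, alpha_q: float = 0.05
                       ) -> LipolysisSection:
    """Correlates of glycerol-Ra suppression in the clamp subset.

    Runs the Spearman screen twice — once over all annotated metabolites and
    once restricted to the Lipid superpathway — because the FDR family
    changes which associations survive correction; and correlates a fixed
    clinical parameter list (HOMA-IR, insulin, glucose, LDL, HDL, BMI, age,
    triglycerides) with suppression, corrected within those eight tests.
    """
    subjects = list(suppressions.index)
    sub = table.subset_samples(subjects)
    supp = suppressions.to_numpy(dtype=float)

    screen_all = screen_correlation(sub, supp, alpha_q=alpha_q)
    lipid = sub.lipid_family()
    screen_lipid = screen_correlation(lipid, supp, alpha_q=alpha_q)

    clin = clinical.loc[subjects]
    values = {
        "homa_ir": homa_ir(clin["fasting_glucose"], clin["fasting_insulin"]),
        "insulin": clin["fasting_insulin"].to_numpy(),
        "glucose": clin["fasting_glucose"].to_numpy(),
        "ldl": clin["ldl"].to_numpy(),
        "hdl": clin["hdl"].to_numpy(),
        "bmi": clin["bmi"].to_numpy(),
        "age": clin["age"].to_numpy(),
        "triglycerides": clin["triglycerides"].to_numpy(),
    }
    rows = []
    for name in CLINICAL_FAMILY:
        rho, p = spearman_rho(values[name], supp)
        rows.append((name, rho, p))
    df = pd.DataFrame(rows, columns=["parameter", "rho", "p"]).set_index("parameter")
    df["q"] = bh_fdr(df["p"].to_numpy())
    return LipolysisSection(screen_all, screen_lipid, df,
                            pd.Series(supp, index=subjects, name="ra_supp"))


def run_study(config: StudyConfig | None = None, *, seed: int | None = None,
              out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full pipeline on a synthetic cohort.

    ``seed`` (when given) overrides the master seed, from which every
    stochastic stage derives its own stream. With ``out_dir`` set, all
    result tables plus a ``summary.json`` are written there.
    """
    config = config or StudyConfig()
    if seed is not None:
        config = dataclasses.replace(
            config,
            sim=dataclasses.replace(config.sim, seed=int(seed)),
            cv=dataclasses.replace(config.cv, base_seed=int(seed)),
        )

    records, truth, table, clamps = generate_cohort(config.sim)
    if table is None:
        raise ValueError("empty cohort: n_subjects must be positive")
    clinical = clinical_frame(records)
    pre = preprocess(table)

    # insulin-resistance classification from Rd, and its metabolite screen
    ir_labels = pd.Series(
        [classify_ir(r.rd, config.rd_cutoff) for r in records],
        index=clinical.index, name="ir_status")
    ir_screen = screen_groups(pre, ir_labels.to_numpy(), alpha_q=config.alpha_q)

    # Framingham scoring, correlation screen and classification models
    fram = score_cohort(records, cutoff=config.fram_cutoff)
    fram_correlates = screen_correlation(
        pre, fram["risk_percent"].to_numpy(), alpha_q=config.alpha_q)
    y_high = (fram["group"] == "high").astype(int).to_numpy()
    ml_all = run_nested_cv(pre.abundances, y_high, config.cv)
    top = select_top_features(ml_all, config.top_k)
    ml_top20 = rerun_on_subset(pre.abundances, y_high, top, config.cv)
    overlap = overlap_features(top, fram_correlates, config.alpha_q)

    # lipolysis section on the clamp subset
    n_clamp = min(config.clamp_subset_size, len(clamps))
    supp = pd.Series(
        {s.subject_id: estimate_suppression(s, config.steele).ra_supp
         for s in clamps[:n_clamp]}, name="ra_supp")
    lipolysis = lipolysis_analysis(pre, supp, clinical, alpha_q=config.alpha_q)

    report = StudyReport(ir_screen, fram_correlates, ml_all, ml_top20,
                         overlap, lipolysis, fram, ir_labels)
    if out_dir is not None:
        _write_report(Path(out_dir), report, table.annotations, config)
    return report


def _summary_dict(report: StudyReport, config: StudyConfig) -> dict:
    ir_hits = significant(report.ir_screen, config.alpha_q)
    fram_hits = significant(report.fram_correlates, config.alpha_q)
    lip = report.lipolysis
    return {
        "n_subjects": int(len(report.ir_labels)),
        "n_ir": int((report.ir_labels == "IR").sum()),
        "n_high_framingham": int((report.framingham["group"] == "high").sum()),
        "ir_screen_hits": [r.metabolite_id for r in ir_hits],
        "fram_correlate_hits": [r.metabolite_id for r in fram_hits],
        "overlap": [str(f) for f in report.overlap],
        "auc_all": {"mean": report.ml_all.mean_auc, "sd": report.ml_all.sd_auc},
        "auc_top20": {"mean": report.ml_top20.mean_auc, "sd": report.ml_top20.sd_auc},
        "sanity": {
            "all_features": sanity_report(report.ml_all),
            "top20": sanity_report(report.ml_top20),
        },
        "median_ra_supp": float(np.median(lip.suppressions.to_numpy())),
        "lipolysis_hits_all": [r.metabolite_id
                               for r in significant(lip.screen_all, config.alpha_q)],
        "lipolysis_hits_lipid": [r.metabolite_id
                                 for r in significant(lip.screen_lipid, config.alpha_q)],
        "clinical_correlates": {
            name: {"rho": float(row["rho"]), "p": float(row["p"]),
                   "q": float(row["q"])}
            for name, row in lip.clinical_correlates.iterrows()
        },
    }


def _write_report(out: Path, report: StudyReport, annotations: pd.DataFrame,
                  config: StudyConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    screen_frame(report.ir_screen, annotations).to_csv(out / "ir_screen.csv")
    screen_frame(report.fram_correlates, annotations).to_csv(out / "fram_correlates.csv")
    screen_frame(report.lipolysis.screen_all, annotations).to_csv(
        out / "lipolysis_screen_all.csv")
    screen_frame(report.lipolysis.screen_lipid, annotations).to_csv(
        out / "lipolysis_screen_lipid.csv")
    report.lipolysis.clinical_correlates.to_csv(out / "clinical_correlates.csv")
    report.lipolysis.suppressions.rename_axis("subject_id").to_csv(
        out / "suppression.csv")
    report.framingham.to_csv(out / "framingham.csv")
    report.ir_labels.rename_axis("subject_id").to_csv(out / "ir_labels.csv")
    (out / "ml_all.json").write_text(
        json.dumps(report.ml_all.to_dict(), indent=1, sort_keys=True))
    (out / "ml_top20.json").write_text(
        json.dumps(report.ml_top20.to_dict(), indent=1, sort_keys=True))
    (out / "summary.json").write_text(
        json.dumps(_summary_dict(report, config), indent=1, sort_keys=True))


# -- optional figures ---------------------------------------------------------

def plot_radar(table: MetaboliteTable, labels, metabolite_ids, path) -> None:
    """Radar chart of group-median abundances for a metabolite shortlist."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    groups = np.unique(labels)
    ids = list(metabolite_ids)
    angles = np.linspace(0, 2 * np.pi, len(ids), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for g in groups:
        med = table.abundances.loc[labels == g, ids].median(axis=0).to_numpy()
        ax.plot(np.append(angles, angles[0]), np.append(med, med[0]), label=str(g))
    ax.set_xticks(angles)
    ax.set_xticklabels(ids, fontsize=6)
    ax.legend(loc="upper right", fontsize=6)
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_correlogram(screen: list[ScreenResult], path, alpha_q: float = 0.05) -> None:
    """Bar plot of significant screen correlations, sorted by rho."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hits = significant(screen, alpha_q)
    hits = sorted(hits, key=lambda r: r.statistic)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(hits))))
    ax.barh([r.metabolite_id for r in hits], [r.statistic for r in hits])
    ax.set_xlabel("Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
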