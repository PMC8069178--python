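"""Nonparametric metabolite screening with FDR control, plus HOMA-IR.

Group contrasts use the Mann–Whitney U test (exact null distribution for
small tie-free samples, tie-corrected normal approximation otherwise);
metabolite–outcome associations use Spearman's rank correlation. Each
screen is corrected for multiple testing with Benjamini–Hochberg step-up
q-values computed within the metabolite family actually screened (all
annotated metabolites, the lipid superpathway only, a clinical parameter
list, ...), since the family choice changes which hits survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MetaboliteTable

__all__ = ["ScreenResult", "mann_whitney_u", "spearman_rho", "bh_fdr",
           "screen_groups", "screen_correlation", "homa_ir",
           "INSULIN_PMOL_PER_MICROU"]

#: pmol/L per μU/mL for human insulin.
INSULIN_PMOL_PER_MICROU = 6.945

#: Sample-size bound below which the exact U distribution is enumerated.
EXACT_MAX_N = 20


@dataclass(frozen=True)
class ScreenResult:
    metabolite_id: str
    statistic: float           # U (group screen) or rho (correlation screen)
    p_value: float
    q_value: float
    direction: int             # sign of the effect
    n_used: int


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of the first sample, p).

    The exact permutation null is used when n+m ≤ 20 and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p.

    A constant input vector makes the correlation undefined: rho is
    returned as NaN with p = 1 (flagged rather than erroring, so screens
    over many columns keep running).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), 1.0
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def by_fdr(p_values) -> np.ndarray:
    """Benjamini–Yekutieli q-values (valid under arbitrary dependence)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def _results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("metabolite_id")


def screen_groups(table: MetaboliteTable, labels, *, alpha_q: float = 0.05,
                  fdr_method: str = "bh") -> list[ScreenResult]:
    """Mann–Whitney screen of every metabolite between two groups.

    ``labels`` is a sequence (aligned with the table's samples) with exactly
    two distinct values; the U statistic reported is that of the first group
    in sorted label order, and direction is the sign of the group median
    difference. The table must be fully imputed (no missing cells).
    """
    labels = np.asarray(labels)
    if labels.size != table.n_samples:
        raise ValueError("labels must cover all samples")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    values = table.abundances.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("table contains missing values; preprocess first")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]

    if a.shape[0] + b.shape[0] > EXACT_MAX_N:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", axis=0)
        U, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    else:
        U = np.empty(values.shape[1])
        p = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            U[j], p[j] = mann_whitney_u(a[:, j], b[:, j])

    q = bh_fdr(p) if fdr_method == "bh" else by_fdr(p)
    direction = np.sign(np.median(a, axis=0) - np.median(b, axis=0)).astype(int)
    n_used = a.shape[0] + b.shape[0]
    return [ScreenResult(mid, float(U[j]), float(p[j]), float(q[j]),
                         int(direction[j]), n_used)
            for j, mid in enumerate(table.metabolite_ids)]


def screen_correlation(table: MetaboliteTable, outcome, *, alpha_q: float = 0.05,
                       fdr_method: str = "bh") -> list[ScreenResult]:
    """Spearman screen of every metabolite against a continuous outcome.

    Samples with a missing outcome are dropped pairwise. The q-values are
    computed within this screen's metabolite family only.
    """
    outcome = np.asarray(outcome, dtype=float)
    if outcome.size != table.n_samples:
        raise ValueError("outcome must cover all samples")
    keep = np.isfinite(outcome)
    values = table.abundances.to_numpy(dtype=float)[keep]
    if np.isnan(values).any():
        raise ValueError("table contains missing values; preprocess first")
    out = outcome[keep]
    n = out.size
    if n < 3:
        raise ValueError("need at least 3 samples with a finite outcome")

    # vectorized Spearman: Pearson on average ranks, t-approximation p
    rank_x = stats.rankdata(values, axis=0)
    rank_y = stats.rankdata(out)
    rx = rank_x - rank_x.mean(axis=0)
    ry = rank_y - rank_y.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, rx.T @ ry / np.where(denom > 0, denom, 1.0), np.nan)
        t = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    p = np.where(np.isnan(rho), 1.0,
                 2 * stats.t.sf(np.abs(np.nan_to_num(t)), df=n - 2))
    p = np.minimum(p, 1.0)
    q = bh_fdr(p) if fdr_method == "bh" else by_fdr(p)
    direction = np.where(np.isnan(rho), 0, np.sign(np.nan_to_num(rho))).astype(int)
    return [ScreenResult(mid, float(rho[j]), float(p[j]), float(q[j]),
                         int(direction[j]), n)
            for j, mid in enumerate(table.metabolite_ids)]


def significant(results: list[ScreenResult], alpha_q: float = 0.05) -> list[ScreenResult]:
    """Hits at the q-value threshold, sorted by ascending q."""
    hits = [r for r in results if r.q_value < alpha_q]
    return sorted(hits, key=lambda r: (r.q_value, r.p_value, r.metabolite_id))


def screen_frame(results: list[ScreenResult],
                 annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate screen results, optionally joining pathway annotations."""
    df = _results_frame(results)
    if annotations is not None:
        df = df.join(annotations[["subpathway", "superpathway"]])
    return df


def homa_ir(glucose, insulin) -> float:
    """Homeostatic model assessment of insulin resistance.

    ``glucose`` in mmol/L, ``insulin`` in pmol/L (converted internally to
    μU/mL at 6.945 pmol/L per μU/mL): HOMA-IR = glucose · insulin / 22.5.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(glucose <= 0) or np.any(insulin <= 0):
        raise ValueError("glucose and insulin must be positive")
    out = glucose * (insulin / INSULIN_PMOL_PER_MICROU) / 22.5
    return out if out.ndim else float(out)
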