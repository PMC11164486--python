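"""Risk stratification and the survival evaluation battery.

Covers: maximally selected log-rank cutpoints with a minimum group
proportion, Kaplan-Meier curves, log-rank tests, cumulative/dynamic
time-dependent ROC with inverse-probability-of-censoring weights (marginal
Kaplan-Meier weights), Harrell's C-index, the multivariable clinical Cox
model whose linear predictor is the numeric core of a nomogram, calibration
of predicted survival against observed Kaplan-Meier estimates, and
rank-based group comparisons with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _cox
from .model_training import SurvivalData

logger = logging.getLogger("mpps")

__all__ = [
    "RiskStratification",
    "KMCurve",
    "PrognosticModel",
    "adjust_bh",
    "optimal_cutpoint",
    "kaplan_meier",
    "logrank_test",
    "time_dependent_auc",
    "concordance_index",
    "multivariable_prognostic_model",
    "calibration_curve",
    "compare_groups",
]


# ---------------------------------------------------------------- cutpoint

@dataclass
class RiskStratification:
    """A score cutpoint and the induced high/low grouping.

    "high" means score strictly greater than the cutpoint. Cutpoints are
    cohort-specific and must never be transferred between cohorts.
    """

    scores: pd.Series
    cutpoint: float
    group: pd.Series  # "high" / "low"
    minprop: float
    zstat: float

    def __post_init__(self):
        counts = self.group.value_counts()
        if counts.get("high", 0) == 0 or counts.get("low", 0) == 0:
            raise ValueError("risk stratification produced an empty group")


def optimal_cutpoint(scores: pd.Series, surv: SurvivalData, minprop: float = 0.1) -> RiskStratification:
    """Maximally selected log-rank cutpoint over the observed score values.

    Every unique observed score is a candidate; candidates leaving either
    group below ceil(minprop * n) samples are inadmissible. The returned
    cutpoint maximises |standardized log-rank statistic| for (score > c) vs
    (score <= c); ties go to the smallest cutpoint.
    """
    if not (0 < minprop < 0.5):
        raise ValueError(f"minprop must be in (0, 0.5), got {minprop}")
    s = scores.reindex(surv.sample_ids)
    if s.isna().any():
        missing = s.index[s.isna()].tolist()
        raise ValueError(f"scores missing for samples: {missing[:5]}")
    if surv.n_events < 2:
        raise ValueError("need at least 2 events to select a cutpoint")
    x = s.to_numpy(dtype=float)
    n = len(x)
    min_group = int(np.ceil(minprop * n))
    time, event = surv.time, surv.event

    best_c = None
    best_abs = -np.inf
    best_z = 0.0
    for c in np.unique(x):
        high = x > c
        n_high = int(high.sum())
        if n_high < min_group or n - n_high < min_group:
            continue
        z = _cox.logrank_zstat(high, time, event)
        if abs(z) > best_abs + 1e-12:
            best_abs = abs(z)
            best_z = z
            best_c = float(c)
    if best_c is None:
        raise ValueError(
            f"no cutpoint leaves both groups with >= {min_group} samples (minprop={minprop}, n={n})"
        )
    group = pd.Series(np.where(x > best_c, "high", "low"), index=s.index, name="group")
    return RiskStratification(scores=s, cutpoint=best_c, group=group, minprop=minprop, zstat=best_z)


# ---------------------------------------------------------------- KM / log-rank

@dataclass
class KMCurve:
    """Product-limit estimate on the grid of distinct observed times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood

    def survival_at(self, t: float) -> float:
        """Right-continuous step lookup; S(t) = 1 before the first time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(surv: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are kept in the risk set for that
    event (censoring handled after the event, the standard convention).
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index and surv.time.min() > 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    events = table["observed"].to_numpy(dtype=float)
    surv_est = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    # Greenwood: Var(S) = S^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > events, events / (at_risk * (at_risk - events)), np.inf)
    variance = surv_est**2 * np.cumsum(terms)
    variance = np.where(np.isfinite(variance), variance, 0.0)
    return KMCurve(times=times, at_risk=at_risk, events=events, survival=surv_est, variance=variance)


def logrank_test(surv: SurvivalData, labels: pd.Series):
    """Log-rank test across groups; returns (chi-square statistic, p-value).

    Two or more groups; chi-square has (#groups - 1) degrees of freedom.
    """
    from lifelines.statistics import multivariate_logrank_test

    lab = labels.reindex(surv.sample_ids)
    if lab.isna().any():
        raise ValueError("group label missing for some samples")
    counts = lab.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError(f"need >= 2 non-empty groups, got sizes {counts.to_dict()}")
    if surv.n_events < 1:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(surv.time, lab.to_numpy(), surv.event)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------- time-dependent ROC

def _censoring_survival(time: np.ndarray, event: np.ndarray):
    """KM estimate of the censoring distribution G(t) as step arrays."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    ts = kmf.survival_function_.index.to_numpy(dtype=float)
    vals = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return ts, vals

def _step_eval(ts, vals, t, left_limit=False):
    side = "left" if left_limit else "right"
    idx = np.searchsorted(ts, t, side=side) - 1
    idx = np.atleast_1d(idx)
    out = np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])
    return out if np.ndim(t) else float(out[0])


def time_dependent_auc(scores: pd.Series, surv: SurvivalData, t: float):
    """Cumulative/dynamic AUC(t) with marginal KM censoring weights (IPCW).

    Cases are subjects with an event by time t (weight 1/G(T_i-)); controls
    are subjects still event-free beyond t (weight 1/G(t)), where G is the
    Kaplan-Meier estimate of the censoring survival function. Tied scores
    contribute 1/2 to the AUC. Also returns the weighted ROC points.
    """
    s = scores.reindex(surv.sample_ids).to_numpy(dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores missing for some samples")
    time, event = surv.time, surv.event
    case = (time <= t) & (event == 1)
    ctrl = time > t
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValueError(f"horizon t={t}: need at least one event by t and one subject at risk past t")

    ts, vals = _censoring_survival(time, event)
    g_case = _step_eval(ts, vals, time[case], left_limit=True)
    g_t = _step_eval(ts, vals, t, left_limit=False)
    if np.any(g_case <= 0) or g_t <= 0:
        bad = np.flatnonzero(g_case <= 0)
        logger.warning("dropping %d case(s) with zero censoring weight at t=%g", len(bad), t)
        keepers = g_case > 0
        g_case = g_case[keepers]
        case_idx = np.flatnonzero(case)[keepers]
        case = np.zeros_like(case)
        case[case_idx] = True
        if case.sum() == 0 or g_t <= 0:
            raise ValueError(f"horizon t={t}: censoring weights vanish; AUC undefined")

    w_case = 1.0 / g_case
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / g_t)
    sc, st = s[case], s[ctrl]

    diff = sc[:, None] - st[None, :]
    wprod = w_case[:, None] * w_ctrl[None, :]
    auc = float((wprod * ((diff > 0) + 0.5 * (diff == 0))).sum() / wprod.sum())

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1], [-np.inf]))
    tpr = [(w_case[sc > c].sum() / w_case.sum()) for c in thresholds]
    fpr = [(w_ctrl[st > c].sum() / w_ctrl.sum()) for c in thresholds]
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return auc, roc


def concordance_index(scores: pd.Series, surv: SurvivalData) -> float:
    """Harrell's C over permissible pairs, risk-oriented.

    Higher score is expected to predict shorter survival; tied scores count
    one half.
    """
    from lifelines.utils import concordance_index as _ci

    s = scores.reindex(surv.sample_ids).to_numpy(dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores missing for some samples")
    try:
        return float(_ci(surv.time, -s, surv.event))
    except ZeroDivisionError as e:
        raise ValueError("no permissible pairs: C-index undefined") from e


# ---------------------------------------------------------------- clinical model

@dataclass
class PrognosticModel:
    """Multivariable Cox fit: per-covariate effects plus per-sample predictions."""

    summary: pd.DataFrame  # coef, hr, ci_lower, ci_upper, p per design column
    linear_predictor: pd.Series
    fitter: object  # lifelines CoxPHFitter, exposes baseline survival

    def predict_survival(self, horizons) -> pd.DataFrame:
        """P(T > t | covariates) at each horizon, samples x horizons."""
        sf = self.fitter.predict_survival_function(self._design, times=list(horizons))
        out = sf.T
        out.columns = list(horizons)
        return out

    _design: pd.DataFrame = None


def expand_covariates(covariates: pd.DataFrame, reference: dict | None = None) -> pd.DataFrame:
    """Dummy-code categorical columns against a stated reference level."""
    reference = reference or {}
    parts = []
    for col in covariates.columns:
        ser = covariates[col]
        if ser.dtype.kind in "ifu" and col not in reference:
            parts.append(ser.astype(float))
            continue
        levels = sorted(ser.astype(str).unique())
        ref = str(reference.get(col, levels[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in column {col!r}")
        for lev in levels:
            if lev == ref:
                continue
            parts.append((ser.astype(str) == lev).astype(float).rename(f"{col}[{lev}]"))
    out = pd.concat(parts, axis=1)
    return out


def multivariable_prognostic_model(
    surv: SurvivalData,
    covariates: pd.DataFrame | None = None,
    reference: dict | None = None,
) -> PrognosticModel:
    """Multivariable Cox regression on clinical covariates (and/or the risk score).

    Categorical columns are expanded against a reference level. The linear
    predictor plus the Efron baseline survival gives predicted survival at
    any horizon — the numeric core of a prognostic nomogram.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cov = covariates if covariates is not None else surv.covariates
    if cov.shape[1] == 0:
        raise ValueError("no covariates supplied")
    design = expand_covariates(cov.loc[surv.sample_ids], reference)
    const = [c for c in design.columns if design[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate column(s): {const}")

    df = design.copy()
    df["time"] = surv.time
    df["event"] = surv.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as e:
        raise ValueError(f"Cox model failed to converge on covariates {list(design.columns)}: {e}") from e

    summ = cph.summary
    summary = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_lower": summ["exp(coef) lower 95%"],
            "ci_upper": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    lp = pd.Series(
        design.to_numpy(float) @ summ["coef"].to_numpy(float), index=design.index, name="linear_predictor"
    )
    model = PrognosticModel(summary=summary, linear_predictor=lp, fitter=cph)
    model._design = design
    return model


def calibration_curve(predicted: pd.Series, surv: SurvivalData, t: float, bins: int = 3) -> pd.DataFrame:
    """Observed (KM) vs mean predicted survival at time t, by prediction quantile bin.

    Bins that cannot be formed because of tied predictions are merged (via
    quantile cuts with duplicate edges dropped), with a warning.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p = predicted.reindex(surv.sample_ids)
    arr = p.to_numpy(dtype=float)
    if np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1:
        raise ValueError("predictions must be probabilities in [0, 1] for every sample")
    try:
        binned = pd.qcut(p, q=bins, duplicates="drop")
        if binned.isna().all() or binned.nunique() == 0:
            raise ValueError("degenerate bins")
    except ValueError:
        binned = pd.Series(["all"] * len(p), index=p.index)
    if binned.nunique() < bins:
        logger.warning("calibration: only %d distinct bin(s) formed from %d requested", binned.nunique(), bins)

    rows = []
    for label, idx in p.groupby(binned, observed=True).groups.items():
        sub = surv.loc(list(idx))
        km = kaplan_meier(sub)
        obs = km.survival_at(t)
        pos = np.searchsorted(km.times, t, side="right") - 1
        var = float(km.variance[pos]) if pos >= 0 else 0.0
        half = 1.96 * np.sqrt(var)
        rows.append(
            {
                "bin": str(label),
                "n": len(idx),
                "mean_predicted": float(p.loc[idx].mean()),
                "observed": obs,
                "ci_lower": max(0.0, obs - half),
                "ci_upper": min(1.0, obs + half),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- group comparisons

def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def compare_groups(values: pd.DataFrame, labels: pd.Series, adjust: str = "BH") -> pd.DataFrame:
    """Rank-based tests of each variable across groups with optional FDR control.

    Two groups dispatch the two-sided Wilcoxon rank-sum (Mann-Whitney U)
    test; three or more dispatch Kruskal-Wallis. With adjust="BH", p-values
    are Benjamini-Hochberg adjusted across variables.
    """
    from scipy import stats

    if adjust not in ("BH", "none"):
        raise ValueError(f"adjust must be 'BH' or 'none', got {adjust!r}")
    lab = labels.reindex(values.index)
    if lab.isna().any():
        raise ValueError("group label missing for some samples")
    groups = {g: values.loc[lab == g] for g in lab.unique()}
    if any(len(v) == 0 for v in groups.values()) or len(groups) < 2:
        raise ValueError("every group must be non-empty and there must be at least two")

    rows = []
    for col in values.columns:
        samples = [g[col].to_numpy(dtype=float) for g in groups.values()]
        if len(samples) == 2:
            stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        else:
            stat, p = stats.kruskal(*samples)
        rows.append((col, float(stat), float(p)))
    out = pd.DataFrame(rows, columns=["variable", "statistic", "p"]).set_index("variable")
    if adjust == "BH":
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
    else:
        out["p_adj"] = out["p"]
    return out
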