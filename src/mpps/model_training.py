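"""The three-stage pair-selection chain and the pathway-pair risk score.

Candidate binary pair features pass through (1) a univariable Cox screen,
(2) L1-penalized (LASSO) Cox regression with the penalty chosen by
cross-validated partial-likelihood deviance, and (3) stepwise elimination
of terms by the Akaike information criterion in a multivariable Cox model.
The surviving pairs and their multivariable coefficients form the portable
signature; a sample's score (MPPS) is

    score(s) = sum_i coef_i * value_i(s),

the coefficient-weighted sum of its binary pair values. All partial
likelihoods use the Efron tie approximation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _cox
from .pair_features import PairMatrix, pair_id

logger = logging.getLogger("mpps")

MODEL_SCHEMA_VERSION = 1

__all__ = [
    "SurvivalData",
    "ScreenResult",
    "MPPSModel",
    "univariable_cox_screen",
    "lasso_cox_select",
    "stepwise_aic_cox",
    "compute_mpps",
    "save_model",
    "load_model",
]


@dataclass
class SurvivalData:
    """Per-sample follow-up time, event indicator and optional covariates.

    `frame` is indexed by sample ID with columns ``time`` (positive, one
    unit per cohort) and ``event`` (1 = event, 0 = right-censored); any
    further columns are covariates.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        for col in ("time", "event"):
            if col not in self.frame.columns:
                raise ValueError(f"survival frame lacks required column {col!r}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample IDs in survival data")
        t = self.frame["time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("survival times must be finite and strictly positive")
        e = self.frame["event"].to_numpy()
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")

    @classmethod
    def from_arrays(cls, sample_ids, time, event, **covariates) -> "SurvivalData":
        frame = pd.DataFrame({"time": time, "event": event, **covariates}, index=pd.Index(sample_ids))
        return cls(frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(dtype=int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame.drop(columns=["time", "event"])

    def loc(self, sample_ids) -> "SurvivalData":
        return SurvivalData(self.frame.loc[sample_ids])

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def align_pairs_survival(pm: PairMatrix, surv: SurvivalData):
    """Match pair-matrix columns with survival rows; IDs must agree exactly."""
    pm_ids = set(pm.sample_ids)
    sv_ids = set(surv.sample_ids)
    if pm_ids != sv_ids:
        only_pm = sorted(pm_ids - sv_ids)
        only_sv = sorted(sv_ids - pm_ids)
        raise ValueError(
            "sample IDs do not match between pair matrix and survival data: "
            f"{len(only_pm)} only in pair matrix (e.g. {only_pm[:5]}), "
            f"{len(only_sv)} only in survival data (e.g. {only_sv[:5]})"
        )
    X = pm.values.T.loc[surv.sample_ids].to_numpy(dtype=float)
    return X, surv.time, surv.event


@dataclass
class ScreenResult:
    """Per-pair univariable Cox results: HR, 95% CI, Wald p, pass flag."""

    table: pd.DataFrame
    p_threshold: float

    @property
    def passed_pairs(self) -> list[tuple[str, str]]:
        sub = self.table[self.table["passed"]]
        return list(zip(sub["a"], sub["b"]))


def univariable_cox_screen(pm: PairMatrix, surv: SurvivalData, p_threshold: float = 0.05) -> ScreenResult:
    """Fit one single-covariate Cox model per pair; flag pairs with p < threshold.

    Pairs with zero variance across samples carry no information and are
    skipped with a warning rather than fitted.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    X, time, event = align_pairs_survival(pm, surv)
    if event.sum() < 2:
        raise ValueError(f"need at least 2 events to screen pairs, got {int(event.sum())}")

    rows = []
    from scipy import stats

    z975 = stats.norm.ppf(0.975)
    for j, (a, b) in enumerate(pm.pairs):
        x = X[:, j]
        if x.min() == x.max():
            logger.warning("pair %s has zero variance; skipped in univariable screen", pair_id(a, b))
            rows.append((a, b, np.nan, np.nan, np.nan, np.nan, False, True))
            continue
        fit = _cox.fit_cox(x[:, None], time, event)
        coef = fit.coef[0]
        se = fit.se[0]
        p = float(fit.wald_p()[0]) if np.isfinite(se) and se > 0 else np.nan
        hr = float(np.exp(coef))
        lo = float(np.exp(coef - z975 * se))
        hi = float(np.exp(coef + z975 * se))
        passed = bool(np.isfinite(p) and p < p_threshold)
        rows.append((a, b, hr, lo, hi, p, passed, False))

    table = pd.DataFrame(
        rows,
        columns=["a", "b", "hr", "ci_lower", "ci_upper", "p", "passed", "skipped"],
        index=[pair_id(a, b) for a, b in pm.pairs],
    )
    logger.info("univariable screen: %d of %d pairs pass p < %g", int(table["passed"].sum()), len(table), p_threshold)
    return ScreenResult(table=table, p_threshold=p_threshold)


def _fold_deviance(X, time, event, train_idx, betas: np.ndarray) -> np.ndarray:
    """glmnet-style CV deviance: -2 [ pl_all(beta) - pl_train(beta) ] per path column."""
    out = np.empty(betas.shape[1])
    for k in range(betas.shape[1]):
        beta = betas[:, k]
        ll_all = _cox.cox_loglik(X, time, event, beta)
        ll_train = _cox.cox_loglik(X[train_idx], time[train_idx], event[train_idx], beta)
        out[k] = -2.0 * (ll_all - ll_train)
    return out


def lasso_cox_select(
    pm: PairMatrix,
    surv: SurvivalData,
    folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    lambda_: float | None = None,
):
    """L1-penalized Cox path with the penalty picked by cross-validation.

    The full-data coefficient path comes from the pathwise coordinate-descent
    solver; each fold refits the path on its training portion and contributes
    a partial-likelihood deviance curve. `lambda_rule` "min" takes the
    deviance-minimising penalty, "1se" the largest penalty within one
    standard error of that minimum. Binary pair features share a scale and
    are deliberately not standardized. Pass `lambda_` to skip CV and use a
    fixed penalty.

    Returns (selected_pairs, lambda_used, coefficients Series over all pairs).
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if lambda_rule not in ("min", "1se"):
        raise ValueError(f"lambda_rule must be 'min' or '1se', got {lambda_rule!r}")
    if len(pm.pairs) < 2:
        raise ValueError(f"need at least 2 candidate pairs for LASSO selection, got {len(pm.pairs)}")
    X, time, event = align_pairs_survival(pm, surv)
    n = len(time)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if lambda_ is not None:
        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lambda_], normalize=False, fit_baseline_model=False)
        net.fit(X, y)
        coefs = pd.Series(net.coef_[:, 0], index=pm.pair_ids)
        selected = [p for p, c in zip(pm.pairs, coefs) if c != 0.0]
        return selected, float(lambda_), coefs

    if folds < 3:
        raise ValueError(f"need at least 3 cross-validation folds, got {folds}")
    if n <= folds:
        raise ValueError(f"need more samples ({n}) than folds ({folds})")

    net = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=60, alpha_min_ratio=0.01, normalize=False, fit_baseline_model=False)
    net.fit(X, y)
    alphas = np.asarray(net.alphas_)

    # find a shuffle in which every training and test portion has events
    fold_indices = None
    for attempt in range(10):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        candidate = list(kf.split(X))
        ok = all(event[tr].sum() >= 2 and event[te].sum() >= 1 for tr, te in candidate)
        if ok:
            if attempt > 0:
                logger.warning("refolded cross-validation %d time(s) to keep events in every fold", attempt)
            fold_indices = candidate
            break
    if fold_indices is None:
        raise ValueError("could not construct cross-validation folds with events in every fold")

    deviances = np.empty((folds, len(alphas)))
    for f, (tr, te) in enumerate(fold_indices):
        fold_net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), normalize=False, fit_baseline_model=False)
        fold_net.fit(X[tr], Surv.from_arrays(event=event[tr].astype(bool), time=time[tr]))
        betas = np.zeros((X.shape[1], len(alphas)))
        fitted = {a: i for i, a in enumerate(fold_net.alphas_)}
        for k, a in enumerate(alphas):
            if a in fitted:
                betas[:, k] = fold_net.coef_[:, fitted[a]]
        deviances[f] = _fold_deviance(X, time, event, tr, betas)

    mean_dev = deviances.mean(axis=0)
    se_dev = deviances.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_dev))
    if lambda_rule == "min":
        chosen = best
    else:
        within = np.flatnonzero(mean_dev <= mean_dev[best] + se_dev[best])
        chosen = int(within[np.argmax(alphas[within])])  # alphas descend; largest penalty
    lam = float(alphas[chosen])
    coefs = pd.Series(net.coef_[:, chosen], index=pm.pair_ids)
    selected = [p for p, c in zip(pm.pairs, coefs) if c != 0.0]
    logger.info("LASSO: lambda(%s)=%.6g selects %d of %d pairs", lambda_rule, lam, len(selected), len(pm.pairs))
    return selected, lam, coefs


@dataclass
class MPPSModel:
    """A trained pathway-pair signature: oriented pairs plus Cox coefficients.

    Coefficients are multivariable Cox log hazard ratios; `training_meta`
    records every setting needed to re-score an arbitrary cohort.
    """

    pairs: list[tuple[str, str]]
    coefficients: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValueError("pairs and coefficients must have equal length")
        if len(self.coefficients) and (
            not np.all(np.isfinite(self.coefficients)) or np.any(self.coefficients == 0)
        ):
            raise ValueError("model coefficients must be finite and non-zero")

    @property
    def pair_ids(self) -> list[str]:
        return [pair_id(a, b) for a, b in self.pairs]


def stepwise_aic_cox(pm: PairMatrix, surv: SurvivalData, direction: str = "backward", training_meta: dict | None = None) -> MPPSModel:
    """Stepwise AIC refinement of the multivariable Cox model on selected pairs.

    Starting from all candidate pairs, terms are removed (and, with
    direction="both", re-admitted) one at a time whenever the move lowers
    AIC = -2 log PL + 2k. Candidate fits that fail to converge count as
    AIC = +inf. The final coefficients populate the returned model.
    """
    if direction not in ("backward", "both"):
        raise ValueError(f"direction must be 'backward' or 'both', got {direction!r}")
    if len(pm.pairs) == 0:
        raise ValueError("stepwise selection needs at least one candidate pair")
    X, time, event = align_pairs_survival(pm, surv)
    all_pairs = list(pm.pairs)

    cache: dict[frozenset, float] = {}

    def aic_of(idx: tuple) -> float:
        key = frozenset(idx)
        if key in cache:
            return cache[key]
        if not idx:
            # null model: AIC = -2 * null log partial likelihood
            ll0 = _cox.cox_loglik(np.zeros((len(time), 1)), time, event, np.zeros(1))
            val = -2.0 * ll0
        else:
            fit = _cox.fit_cox(X[:, list(idx)], time, event)
            if not fit.converged or not np.all(np.isfinite(fit.coef)):
                logger.warning("candidate Cox fit on %d terms failed to converge; treated as AIC=+inf", len(idx))
                val = np.inf
            else:
                val = fit.aic
        cache[key] = val
        return val

    current = tuple(range(len(all_pairs)))
    current_aic = aic_of(current)
    while True:
        moves = []
        for j in current:
            cand = tuple(i for i in current if i != j)
            moves.append((aic_of(cand), cand))
        if direction == "both":
            for j in range(len(all_pairs)):
                if j not in current:
                    cand = tuple(sorted(current + (j,)))
                    moves.append((aic_of(cand), cand))
        if not moves:
            break
        best_aic, best_set = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-10:
            current, current_aic = best_set, best_aic
        else:
            break

    kept = list(current)
    if kept:
        final = _cox.fit_cox(X[:, kept], time, event)
        coefs = final.coef
    else:
        logger.warning("stepwise AIC removed every pair; model is empty")
        coefs = np.empty(0)
    meta = dict(training_meta or {})
    meta.setdefault("aic_direction", direction)
    meta["aic_final"] = float(current_aic)
    model = MPPSModel(pairs=[all_pairs[i] for i in kept], coefficients=coefs, training_meta=meta)
    logger.info("stepwise AIC (%s): %d of %d pairs retained", direction, len(kept), len(all_pairs))
    return model


def compute_mpps(model: MPPSModel, pv: PairMatrix) -> pd.Series:
    """Per-sample score: coefficient-weighted sum of the model's pair values.

    `pv` must contain exactly the model's pairs, in model order and with
    the model's orientation.
    """
    if pv.pairs != model.pairs:
        raise ValueError(
            "pair matrix does not match the model's pairs "
            f"(model: {model.pair_ids[:3]}..., got: {pv.pair_ids[:3]}...)"
        )
    if not model.pairs:
        return pd.Series(0.0, index=pv.sample_ids, name="mpps")
    vals = pv.values.to_numpy(dtype=float)
    return pd.Series(model.coefficients @ vals, index=pv.values.columns, name="mpps")


def save_model(model: MPPSModel, path) -> None:
    """Serialize the signature to JSON (full float precision, stable key order)."""
    payload = {
        "version": MODEL_SCHEMA_VERSION,
        "pairs": [{"a": a, "b": b} for a, b in model.pairs],
        "coefficients": [float(c) for c in model.coefficients],
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> MPPSModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r} (expected {MODEL_SCHEMA_VERSION})")
    for key in ("pairs", "coefficients"):
        if key not in payload:
            raise ValueError(f"model file {path} is missing required key {key!r}")
    pairs = [(p["a"], p["b"]) for p in payload["pairs"]]
    return MPPSModel(
        pairs=pairs,
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        training_meta=payload.get("training_meta", {}),
    )
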