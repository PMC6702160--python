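"""Outcome modeling: baseline-augmented logistic / Cox fits, five-fold
cross-validated univariable ranking with nested best-subset selection by
AIC, consensus refit with a likelihood-ratio test, and median-split risk
stratification.

The protocol models two endpoints on the cohort table: pathologic complete
response (pCR, logistic regression scored by AUC) and recurrence-free
survival (RFS, Cox proportional hazards scored by Harrell's C-statistic).
Candidate imaging features are evaluated as additions to a baseline model of
age, race, hormone-receptor status and early-treatment functional tumor
volume.  In each cross-validation fold the candidates are ranked by the
training performance of baseline+candidate, a nested sequence of models
(baseline + top-j candidates) is built, the training-AIC minimizer is chosen
and scored on the held-out fold.  Features selected in at least 80% of folds
form the consensus set, refit on the full table and compared to the baseline
by a likelihood-ratio test.  For survival, the fitted linear predictor (the
risk signature) is dichotomized at the cohort median into high/low-risk
groups compared by Kaplan-Meier curves and the log-rank test.

Continuous covariates are z-scored before fitting (so odds/hazard ratios are
per standardized unit); race enters as a binary indicator and
hormone-receptor status as a single ordinal score 1-3 following the
HR+/HER2-, HER2+, triple-negative coding (a two-dummy categorical mode is
available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

BASELINE_COVARIATES = ("age", "race", "hormone_status", "ftv2_cm3")

#: Covariates entered without z-scoring (binary / ordinal codes).
_UNSCALED = {"race", "hormone_status", "hormone_2", "hormone_3"}


# ---------------------------------------------------------------------------
# Design matrices and fits
# ---------------------------------------------------------------------------

def _analysis_rows(table: pd.DataFrame, family: str) -> pd.DataFrame:
    if family == "logistic":
        return table[table["pcr"].notna()].reset_index(drop=True)
    if family == "cox":
        return table.reset_index(drop=True)
    raise ValueError(f"unknown family {family!r}")


def _expand_covariates(table: pd.DataFrame, covariates, hormone_coding: str):
    """Resolve the covariate list, expanding hormone status if categorical."""
    df = table.copy()
    cols = []
    for c in covariates:
        if c == "hormone_status" and hormone_coding == "categorical":
            df["hormone_2"] = (df["hormone_status"] == 2).astype(float)
            df["hormone_3"] = (df["hormone_status"] == 3).astype(float)
            cols += ["hormone_2", "hormone_3"]
        else:
            cols.append(c)
    return df, cols


def _build_design(
    df: pd.DataFrame, cols, scaler: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Z-score continuous columns; return (X, scaler) with scaler reusable
    on new data (means/sds from the fitting set)."""
    X = df[cols].astype(float).copy()
    if scaler is None:
        scaler = {}
        for c in cols:
            if c in _UNSCALED:
                continue
            mu, sd = float(X[c].mean()), float(X[c].std(ddof=0))
            scaler[c] = (mu, sd if sd > 1e-12 else 1.0)
    for c, (mu, sd) in scaler.items():
        if c in X:
            X[c] = (X[c] - mu) / sd
    return X, scaler


@dataclass
class FitResult:
    """A fitted outcome model with everything downstream stages need."""

    family: str
    covariates: list[str]
    coef: pd.Series
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    n: int
    scaler: dict
    hormone_coding: str = "ordinal"
    flags: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return not self.flags

    @property
    def k_params(self) -> int:
        return len(self.coef)

    def ratios(self) -> pd.Series:
        """Odds ratios (logistic) or hazard ratios (cox) per covariate."""
        keep = [c for c in self.coef.index if c != "const"]
        return np.exp(self.coef[keep])

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        """Risk score for new rows using the training-set standardization."""
        df, cols = _expand_covariates(table, self.covariates, self.hormone_coding)
        X, _ = _build_design(df, cols, scaler=self.scaler)
        lp = np.zeros(len(X))
        for c in cols:
            lp += self.coef.get(c, 0.0) * X[c].to_numpy()
        lp += self.coef.get("const", 0.0)
        return lp


def _flagged_fit(family, covariates, scaler, hormone_coding, n, reason) -> FitResult:
    idx = pd.Index(list(covariates) + (["const"] if family == "logistic" else []))
    nanvec = pd.Series(np.nan, index=idx)
    return FitResult(family, list(covariates), nanvec, nanvec.copy(), nanvec.copy(),
                     nanvec.copy(), nanvec.copy(), np.nan, np.inf, n, scaler,
                     hormone_coding, [reason])


def fit_outcome_model(
    table: pd.DataFrame,
    covariates,
    family: str,
    hormone_coding: str = "ordinal",
) -> FitResult:
    """Maximum-likelihood logistic or partial-likelihood Cox fit.

    Continuous covariates are z-scored on the analyzed rows; perfect
    separation / non-convergence yields a flagged result (AIC = +inf) rather
    than an exception.
    """
    data = _analysis_rows(table, family)
    if len(data) < 10:
        raise ValueError("need at least 10 analyzable rows")
    df, cols = _expand_covariates(data, list(covariates), hormone_coding)
    X, scaler = _build_design(df, cols)

    if family == "logistic":
        y = df["pcr"].astype(float).to_numpy()
        Xc = sm.add_constant(X, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", False) or not np.all(
                np.isfinite(res.params)
            ) or not np.all(np.isfinite(res.bse)):
                return _flagged_fit(family, cols, scaler, hormone_coding, len(df),
                                    "non_convergence")
        except Exception:
            return _flagged_fit(family, cols, scaler, hormone_coding, len(df),
                                "separation_or_failure")
        ci = res.conf_int(alpha=0.05)
        loglik = float(res.llf)
        k = len(res.params)
        return FitResult(family, list(covariates), res.params, res.bse,
                         ci[0], ci[1], res.pvalues, loglik, 2 * k - 2 * loglik,
                         len(df), scaler, hormone_coding)

    if family == "cox":
        if df["rfs_event"].sum() < 1:
            raise ValueError("cox fit needs at least one event")
        cdf = X.copy()
        cdf["rfs_time"] = df["rfs_time"].to_numpy()
        cdf["rfs_event"] = df["rfs_event"].to_numpy()
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(cdf, duration_col="rfs_time", event_col="rfs_event")
        except Exception:
            return _flagged_fit(family, cols, scaler, hormone_coding, len(df),
                                "separation_or_failure")
        ci = cph.confidence_intervals_
        loglik = float(cph.log_likelihood_)
        k = len(cph.params_)
        return FitResult(family, list(covariates), cph.params_,
                         cph.standard_errors_, ci.iloc[:, 0], ci.iloc[:, 1],
                         cph.summary["p"], loglik, 2 * k - 2 * loglik,
                         len(df), scaler, hormone_coding)

    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Performance metrics (rank formulations)
# ---------------------------------------------------------------------------

def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation; score ties count 0.5.

    Raises if only one class is present.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: single class")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def harrell_c(times: np.ndarray, events: np.ndarray, scores: np.ndarray) -> float:
    """Harrell's concordance over usable pairs.

    A pair is usable when the shorter observed time is an event; it is
    concordant when that patient has the higher risk score, with score ties
    counting 0.5.  Pairs censored before the other's event are excluded.
    Raises if no usable pairs exist.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    s = np.asarray(scores, dtype=float)
    # usable: t_i < t_j and e_i = 1
    ti, tj = t[:, None], t[None, :]
    usable = (ti < tj) & (e[:, None] == 1)
    if not usable.any():
        raise ValueError("Harrell's C undefined: no usable pairs")
    si, sj = s[:, None], s[None, :]
    conc = np.where(si > sj, 1.0, np.where(si == sj, 0.5, 0.0))
    return float(conc[usable].sum() / usable.sum())


def performance(scores: np.ndarray, table: pd.DataFrame, family: str) -> float:
    """Model performance: AUC (logistic) or Harrell's C (cox)."""
    if family == "logistic":
        return auc_score(table["pcr"].to_numpy(), scores)
    if family == "cox":
        return harrell_c(table["rfs_time"].to_numpy(), table["rfs_event"].to_numpy(), scores)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Cross-validated selection protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    ranked: list[str]
    selected: list[str]
    test_metric: float


@dataclass
class CVReport:
    family: str
    folds: list[FoldResult]
    mean_metric: float
    sd_metric: float
    selection_counts: dict[str, int]
    n_folds: int
    seed: int
    refolds: int = 0

    def consensus(self, frac: float = 0.8) -> list[str]:
        """Features selected in at least ``frac`` of the folds."""
        need = int(np.ceil(frac * self.n_folds))
        return sorted(f for f, c in self.selection_counts.items() if c >= need)


def _stratified_folds(strata: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment (0..k-1 per row) stratified on the given labels."""
    n = len(strata)
    assign = np.empty(n, dtype=int)
    start = int(rng.integers(0, k))
    offset = 0
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        assign[idx] = (np.arange(len(idx)) + start + offset) % k
        offset += len(idx)
    return assign


def cv_select(
    table: pd.DataFrame,
    baseline_covariates,
    candidate_features,
    family: str,
    k: int = 5,
    seed: int = 0,
    hormone_coding: str = "ordinal",
    max_refolds: int = 20,
) -> CVReport:
    """Cross-validated univariable ranking + nested best-subset selection.

    Per fold, on training rows only: each candidate is ranked by the
    training performance of baseline+candidate (ties broken by lower
    training AIC, then name); the nested models baseline + top-j candidates
    (j = 1..m) are fit and the training-AIC minimizer chosen; the chosen
    model is scored on the held-out fold.  Folds are stratified by outcome
    (pCR) or event indicator (RFS); a Cox fold whose training rows carry no
    event triggers a fresh stratified draw (logged in ``refolds``).  A fixed
    seed makes the report fully reproducible.
    """
    candidates = list(candidate_features)
    if not candidates:
        raise ValueError("candidate_features must be nonempty")
    if k < 2:
        raise ValueError("k must be >= 2")
    baseline = list(baseline_covariates)
    data = _analysis_rows(table, family)
    strata = (data["pcr"] if family == "logistic" else data["rfs_event"]).to_numpy()

    rng = np.random.default_rng(seed)
    refolds = 0
    for _ in range(max_refolds):
        assign = _stratified_folds(strata, k, rng)
        if family != "cox":
            break
        ok = all(
            data.loc[assign != f, "rfs_event"].sum() >= 1
            and data.loc[assign == f, "rfs_event"].sum() >= 1
            for f in range(k)
        )
        if ok:
            break
        refolds += 1
    else:
        raise RuntimeError("could not build folds with events in every fold")

    folds: list[FoldResult] = []
    counts = {c: 0 for c in candidates}
    metrics = []
    for f in range(k):
        train = data[assign != f].reset_index(drop=True)
        test = data[assign == f].reset_index(drop=True)

        scored = []
        for cand in candidates:
            fit = fit_outcome_model(train, baseline + [cand], family, hormone_coding)
            if fit.converged:
                perf = performance(fit.linear_predictor(train), train, family)
                scored.append((-perf, fit.aic, cand))
            else:
                scored.append((np.inf, np.inf, cand))
        scored.sort()
        ranked = [c for _, _, c in scored]

        best_aic, best_fit, best_j = np.inf, None, 0
        for j in range(1, len(ranked) + 1):
            fit = fit_outcome_model(train, baseline + ranked[:j], family, hormone_coding)
            if fit.aic < best_aic:
                best_aic, best_fit, best_j = fit.aic, fit, j
        if best_fit is None:  # every nested fit failed; fall back to baseline
            best_fit = fit_outcome_model(train, baseline, family, hormone_coding)
            best_j = 0

        selected = ranked[:best_j]
        for c in selected:
            counts[c] += 1
        test_metric = performance(best_fit.linear_predictor(test), test, family)
        folds.append(FoldResult(f, ranked, selected, test_metric))
        metrics.append(test_metric)

    metrics = np.array(metrics)
    return CVReport(family, folds, float(metrics.mean()), float(metrics.std(ddof=1)),
                    counts, k, seed, refolds)


def consensus_refit(
    report: CVReport,
    table: pd.DataFrame,
    baseline_covariates,
    family: str,
    hormone_coding: str = "ordinal",
) -> tuple[FitResult, FitResult, float]:
    """Refit the consensus feature set on the full table and compare to the
    baseline model by a likelihood-ratio test.

    Consensus = features selected in >= 80% of folds (4 of 5).  Returns
    (full_fit, baseline_fit, lrt_p); an empty consensus set returns the
    baseline twice with p = 1.
    """
    baseline = list(baseline_covariates)
    base_fit = fit_outcome_model(table, baseline, family, hormone_coding)
    consensus = report.consensus()
    if not consensus:
        return base_fit, base_fit, 1.0
    full_fit = fit_outcome_model(table, baseline + consensus, family, hormone_coding)
    lrt_p = likelihood_ratio_p(full_fit, base_fit, df=len(consensus))
    return full_fit, base_fit, lrt_p


def likelihood_ratio_p(full: FitResult, reduced: FitResult, df: int) -> float:
    """Chi-square p-value of the nested likelihood-ratio test."""
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    return float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Risk stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskStratification:
    groups: np.ndarray  # 1 = high risk, 0 = low risk
    km_low: pd.DataFrame
    km_high: pd.DataFrame
    logrank_p: float
    survival_ratio_at_median_time: float
    median_time: float
    flags: list[str] = field(default_factory=list)


def risk_stratify(fit: FitResult, table: pd.DataFrame) -> RiskStratification:
    """Median-split survival stratification of the model's risk signature.

    The linear predictor (covariates weighted by the Cox coefficients) is
    dichotomized at the cohort median (ties to low risk); the two groups are
    compared by Kaplan-Meier curves, the two-sided log-rank test, and the
    ratio of their survival estimates at the median follow-up time
    (low-risk survival over high-risk survival).
    """
    if fit.family != "cox":
        raise ValueError("risk_stratify requires a cox-family fit")
    data = _analysis_rows(table, "cox")
    lp = fit.linear_predictor(data)
    flags: list[str] = []
    if np.ptp(lp) < 1e-12:
        flags.append("constant_risk_signature")
        groups = np.zeros(len(lp), dtype=int)
    else:
        med = float(np.median(lp))
        groups = (lp > med).astype(int)  # ties to low risk

    t = data["rfs_time"].to_numpy()
    e = data["rfs_event"].to_numpy()
    median_time = float(np.median(t))

    def km(mask):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        surv = kmf.survival_function_
        surv.columns = ["survival"]
        return surv.reset_index().rename(columns={surv.index.name or "index": "time"}), kmf

    if flags:
        km_all, _ = km(np.ones(len(t), dtype=bool))
        return RiskStratification(groups, km_all, km_all.copy(), np.nan, np.nan,
                                  median_time, flags)

    low, high = groups == 0, groups == 1
    km_low, kmf_low = km(low)
    km_high, kmf_high = km(high)
    lr = logrank_test(t[low], t[high], event_observed_A=e[low], event_observed_B=e[high])
    s_low = float(kmf_low.predict(median_time))
    s_high = float(kmf_high.predict(median_time))
    ratio = s_low / s_high if s_high > 0 else np.inf
    return RiskStratification(groups, km_low, km_high, float(lr.p_value), ratio,
                              median_time, flags)
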