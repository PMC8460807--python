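"""PSI-based prognostic modelling.

Feature selection is an L1-penalized Cox proportional-hazards fit over all
gene PSI columns with clinical covariates left unpenalized; the penalty is
chosen by k-fold cross-validated held-out partial likelihood (Breslow ties).
The prognosis index of sample k is PI_k = sum_i beta_i * chi_ik over the
selected genes only, where beta_i comes from an unpenalized multivariate Cox
fit with covariates and chi_ik is the sample's PSI. Samples are split at the
median PI and compared by a two-sided log-rank test. Following the source
convention for this index, samples with PI above the median are labelled
"low-risk" by default; the conventional orientation is available via
``orientation="conventional"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .config import SurvivalConfig

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "race", "stage")


def design_matrix(survival: pd.DataFrame,
                  covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES
                  ) -> pd.DataFrame:
    """Numeric covariate design: categoricals one-hot with first level
    dropped, numerics passed through."""
    cols = [c for c in covariates if c in survival.columns]
    if not cols:
        return pd.DataFrame(index=survival.index)
    sub = survival[cols]
    out = pd.get_dummies(sub, drop_first=True, dtype=float)
    return out.astype(float)


def cox_log_partial_likelihood(X: np.ndarray, time: np.ndarray,
                               event: np.ndarray, beta: np.ndarray) -> float:
    """Breslow log partial likelihood at a fixed coefficient vector."""
    lp = X @ beta
    order = np.argsort(-time, kind="stable")  # descending time
    lp_o, t_o, e_o = lp[order], time[order], event[order]
    log_risk = np.logaddexp.accumulate(lp_o)
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        d = e_o[i:j].sum()
        if d > 0:
            ll += lp_o[i:j][e_o[i:j] == 1].sum() - d * log_risk[j - 1]
        i = j
    return float(ll)


def _gene_design(psi: pd.DataFrame, survival: pd.DataFrame,
                 covariates, config: SurvivalConfig
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Complete-case gene matrix (samples x genes), covariate design, and the
    matching survival rows."""
    shared = [s for s in survival.index if s in psi.columns]
    genes = psi.loc[:, shared].T  # samples x genes
    miss = genes.isna().mean(axis=0)
    genes = genes.loc[:, miss <= config.max_missing_rate]
    complete = genes.dropna(axis=0)
    surv = survival.loc[complete.index]
    cov = design_matrix(surv, covariates)
    return complete, cov, surv


def select_features_lasso(psi: pd.DataFrame, survival: pd.DataFrame,
                          covariates=DEFAULT_COVARIATES,
                          config: SurvivalConfig | None = None,
                          seed: int = 0,
                          alpha: float | None = None) -> list[str]:
    """Genes with nonzero coefficients in the L1-Cox fit at the CV-chosen
    penalty (or at ``alpha`` when given). Covariates enter unpenalized."""
    config = config or SurvivalConfig()
    genes, cov, surv = _gene_design(psi, survival, covariates, config)
    n = len(genes)
    if n < config.min_samples:
        raise ValueError(f"{n} complete-case samples "
                         f"(minimum {config.min_samples})")
    if surv["event"].sum() == 0:
        raise ValueError("no events in the survival data")

    gmean, gstd = genes.mean(), genes.std(ddof=0).replace(0, 1.0)
    Xg = (genes - gmean) / gstd
    X = pd.concat([Xg, cov], axis=1).to_numpy(dtype=float)
    pf = np.r_[np.ones(Xg.shape[1]), np.zeros(cov.shape[1])]
    y = Surv.from_arrays(event=surv["event"].astype(bool).to_numpy(),
                         time=surv["time"].to_numpy(dtype=float))

    def _fit(alphas=None):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, penalty_factor=pf, alphas=alphas,
            n_alphas=config.penalty_grid_size, alpha_min_ratio=0.01,
            max_iter=200_000)
        try:
            model.fit(X, y)
        except (ArithmeticError, ValueError) as exc:
            raise RuntimeError(
                f"L1-Cox did not converge (n={n}, p={X.shape[1]}, "
                f"events={int(surv['event'].sum())}): {exc}") from exc
        return model

    if alpha is not None:
        model = _fit(alphas=[alpha])
        coefs = model.coef_[: Xg.shape[1], 0]
        return [g for g, c in zip(Xg.columns, coefs) if c != 0]

    path = _fit()
    alphas = list(path.alphas_)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    scores = np.zeros(len(alphas))
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        if event[train].sum() == 0 or event[test].sum() == 0:
            continue
        fold = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, penalty_factor=pf, alphas=alphas,
            max_iter=200_000)
        try:
            fold.fit(X[train], y[train])
        except (ArithmeticError, ValueError):
            continue
        for j in range(fold.coef_.shape[1]):
            beta = fold.coef_[:, j]
            scores[j] += cox_log_partial_likelihood(
                X[test], time[test], event[test], beta)
    best = int(np.argmax(scores))
    coefs = path.coef_[: Xg.shape[1], best]
    return [g for g, c in zip(Xg.columns, coefs) if c != 0]


@dataclass
class PrognosticModel:
    """Selected genes, their Cox log-hazard coefficients, and per-sample PI
    (gene terms only: PI_k = sum_i beta_i chi_ik)."""

    genes: list[str]
    beta: pd.Series
    covariate_coef: pd.Series
    pi: pd.Series
    fitter: CoxPHFitter = field(repr=False, default=None)

    def predict_pi(self, psi: pd.DataFrame) -> pd.Series:
        """PI for new samples from a gene x sample PSI matrix."""
        chi = psi.loc[self.genes].T.astype(float)
        return (chi * self.beta).sum(axis=1, skipna=False).rename("pi")


def fit_pi_model(psi: pd.DataFrame, survival: pd.DataFrame,
                 covariates=DEFAULT_COVARIATES,
                 selected: list[str] | None = None) -> PrognosticModel:
    """Unpenalized multivariate Cox on the selected genes' PSI plus
    covariates; PI uses the gene terms only."""
    genes = selected if selected is not None else list(psi.index)
    if not genes:
        raise ValueError("no selected genes")
    shared = [s for s in survival.index if s in psi.columns]
    chi = psi.loc[genes, shared].T.astype(float).dropna(axis=0)
    surv = survival.loc[chi.index]
    cov = design_matrix(surv, covariates)
    df = pd.concat([chi, cov,
                    surv[["time", "event"]].astype(float)], axis=1)

    constant = [c for c in df.columns[:-2] if df[c].nunique() <= 1]
    if constant:
        raise ValueError(f"singular design; constant columns: {constant}")
    rank = np.linalg.matrix_rank(df.iloc[:, :-2].to_numpy(dtype=float))
    if rank < df.shape[1] - 2:
        corr = df.iloc[:, :-2].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"singular design; collinear columns: {list(worst)}")

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = cph.params_[genes]
    covariate_coef = cph.params_.drop(genes)
    pi = (chi * beta).sum(axis=1, skipna=False).rename("pi")
    return PrognosticModel(genes=list(genes), beta=beta,
                           covariate_coef=covariate_coef, pi=pi, fitter=cph)


def loocv_prognostic_index(psi: pd.DataFrame, survival: pd.DataFrame,
                           selected: list[str],
                           covariates=DEFAULT_COVARIATES) -> pd.Series:
    """Held-out PI per sample: refit the PI model without the sample, then
    score it with the refit coefficients. Non-convergent folds yield NaN."""
    shared = [s for s in survival.index if s in psi.columns]
    if len(shared) < 10:
        raise ValueError(f"LOOCV needs >= 10 samples, got {len(shared)}")
    out = {}
    for k in shared:
        rest = [s for s in shared if s != k]
        try:
            model = fit_pi_model(psi[rest], survival.loc[rest],
                                 covariates, selected)
            out[k] = float(model.predict_pi(psi[[k]]).iloc[0])
        except (ConvergenceError, ValueError) as exc:
            log.warning("LOOCV fold for %s failed: %s", k, exc)
            out[k] = np.nan
    return pd.Series(out, name="pi").loc[shared]


@dataclass
class LogRankReport:
    groups: pd.Series           # 'high-risk' / 'low-risk' per sample
    chi2: float
    p: float
    hazard_ratio: float | None = None
    hazard_ratio_p: float | None = None
    by_level: dict = field(default_factory=dict)


def stratify_and_logrank(pi: pd.Series, survival: pd.DataFrame,
                         covariates=DEFAULT_COVARIATES,
                         orientation: str = "source",
                         group_col: str | None = None) -> LogRankReport:
    """Median split of PI (ties join the at-or-below group) and a two-sided
    log-rank test; also reports the covariate-adjusted Cox hazard ratio of
    high- vs low-risk, optionally within levels of ``group_col``."""
    pi = pi.dropna()
    if pi.nunique() <= 1:
        raise ValueError("all PI values identical; no median split possible")
    surv = survival.loc[pi.index]
    above = pi > pi.median()
    if orientation == "source":
        labels = above.map({True: "low-risk", False: "high-risk"})
    elif orientation == "conventional":
        labels = above.map({True: "high-risk", False: "low-risk"})
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    log.info("risk orientation %r: PI > median -> %s", orientation,
             labels[above].iloc[0] if above.any() else "n/a")

    a = labels == "high-risk"
    res = logrank_test(surv.loc[a, "time"], surv.loc[~a, "time"],
                       event_observed_A=surv.loc[a, "event"],
                       event_observed_B=surv.loc[~a, "event"])
    hr = hr_p = None
    try:
        hr, hr_p = _group_hr(a, surv, covariates)
    except (ConvergenceError, ValueError) as exc:
        log.warning("group HR fit failed: %s", exc)

    by_level = {}
    if group_col is not None:
        for level, idx in surv.groupby(group_col).groups.items():
            try:
                by_level[level] = _group_hr(a.loc[idx], surv.loc[idx],
                                            [c for c in covariates
                                             if c != group_col])
            except (ConvergenceError, ValueError) as exc:
                log.warning("HR for %s=%s failed: %s", group_col, level, exc)
                by_level[level] = (np.nan, np.nan)

    return LogRankReport(groups=labels, chi2=float(res.test_statistic),
                         p=float(res.p_value), hazard_ratio=hr,
                         hazard_ratio_p=hr_p, by_level=by_level)


def _group_hr(high_risk: pd.Series, surv: pd.DataFrame,
              covariates) -> tuple[float, float]:
    cov = design_matrix(surv, covariates)
    df = pd.concat([high_risk.astype(float).rename("high_risk"), cov,
                    surv[["time", "event"]].astype(float)], axis=1)
    keep = [c for c in df.columns
            if c in ("time", "event") or df[c].nunique() > 1]
    df = df[keep]
    if "high_risk" not in df.columns:
        raise ValueError("risk groups degenerate")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return (float(np.exp(cph.params_["high_risk"])),
            float(cph.summary.loc["high_risk", "p"]))
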