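"""Survival modelling: screening, LASSO-Cox signature fitting, risk scores.

The prognostic workflow is the standard one for expression signatures:
a stratified train/test split, per-gene Kaplan-Meier median-split
log-rank and univariate Cox screens, an L1-penalised Cox path with the
penalty chosen by cross-validated partial likelihood and an unpenalised
multivariate refit of the surviving genes, the linear risk score
sum(beta_i * expression_i), median-split KM comparison, IPCW
cumulative/dynamic time-dependent AUC, and joint covariate Cox tables.

Ties are handled by Efron's method throughout.  The packaged default
signature is the printed 15-gene panel (RNASE1 ... NDUFB1); it is loaded
from a versioned data file and never refit silently.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .containers import ExpressionMatrix, RiskSignature, SurvivalTable

__all__ = [
    "load_packaged_signature",
    "split_cohort",
    "km_logrank",
    "unicox",
    "gene_survival_screen",
    "fit_signature",
    "risk_score",
    "time_dependent_auc",
    "covariate_cox",
    "cox_partial_loglik",
]


def load_packaged_signature() -> RiskSignature:
    """The shipped 15-gene prognostic risk signature."""
    text = (
        resources.files("fatestrat.data")
        .joinpath("risk_signature_15gene.json")
        .read_text()
    )
    payload = json.loads(text)
    coeffs = [(str(g), float(b)) for g, b in payload["coefficients"]]
    return RiskSignature(coefficients=coeffs, provenance="packaged")


def split_cohort(
    survival: SurvivalTable, ratio: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Event-stratified, seeded ~ratio train/test split of the sample ids."""
    if len(survival.samples) < 10:
        raise ValueError("need at least 10 samples to split")
    if survival.event.sum() == 0:
        raise ValueError("all-censored cohort cannot be split for model fitting")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for value in (1, 0):
        ids = survival.samples[survival.event == value].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_train = int(round(ratio * len(ids)))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return sorted(train), sorted(test)


def km_logrank(
    values: pd.Series, survival: SurvivalTable, cutoff: float | None = None
) -> dict:
    """Median-split (or explicit-cutoff) two-group log-rank comparison.

    Returns group labels ("high"/"low"), the 1-df log-rank chi-square and
    p-value, and the two KM step functions.
    """
    values = values.loc[survival.samples]
    cut = float(values.median()) if cutoff is None else float(cutoff)
    high = values > cut
    if high.all() or (~high).all():
        raise ValueError("degenerate split: one group is empty")
    t, e = survival.time, survival.event
    res = logrank_test(t[high], t[~high], e[high], e[~high])
    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        curves[name] = kmf.survival_function_
    labels = pd.Series(np.where(high, "high", "low"), index=values.index, name="group")
    return {
        "labels": labels,
        "statistic": float(res.test_statistic),
        "pvalue": float(res.p_value),
        "curves": curves,
        "cutoff": cut,
    }


def unicox(values: pd.Series, survival: SurvivalTable) -> dict:
    """Univariate Cox PH fit (Efron ties): beta, HR, Wald p.

    Perfect separation (monotone likelihood) is flagged; the Wald p from
    the boundary fit is reported with a warning rather than failing.
    """
    values = values.loc[survival.samples]
    if survival.event.sum() < 2:
        raise ValueError("need at least 2 events")
    if float(values.std()) == 0:
        raise ValueError("constant covariate")
    df = pd.DataFrame(
        {"x": values, "time": survival.time, "event": survival.event}
    )
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            flagged = True
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    if abs(beta) > 10:
        flagged = True
    if flagged:
        warnings.warn("monotone likelihood suspected; boundary fit reported", stacklevel=2)
    return {
        "beta": beta,
        "hr": float(np.exp(beta)),
        "se": float(cph.standard_errors_["x"]),
        "pvalue": float(cph.summary.loc["x", "p"]),
        "flagged": flagged,
    }


def gene_survival_screen(
    expr: ExpressionMatrix, survival: SurvivalTable
) -> pd.DataFrame:
    """Per-gene KM median-split log-rank p and univariate Cox beta/HR/p."""
    rows = []
    for gene in expr.genes:
        values = expr.values.loc[gene, survival.samples]
        try:
            km_p = km_logrank(values, survival)["pvalue"]
        except ValueError:
            km_p = np.nan
        try:
            cox = unicox(values, survival)
            rows.append((gene, km_p, cox["beta"], cox["hr"], cox["pvalue"]))
        except ValueError:
            rows.append((gene, km_p, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["gene", "km_p", "beta", "hr", "cox_p"]
    ).set_index("gene")


def cox_partial_loglik(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> float:
    """Efron partial log-likelihood of coefficients ``beta`` on (X, time, event)."""
    eta = X @ beta
    order = np.argsort(time, kind="stable")
    time, event, eta = time[order], event[order], eta[order]
    exp_eta = np.exp(eta)
    ll = 0.0
    i = 0
    n = len(time)
    # risk set sum from the end
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = [k for k in range(i, j) if event[k] == 1]
        if deaths:
            risk_sum = exp_eta[i:].sum()
            tie_sum = exp_eta[deaths].sum()
            d = len(deaths)
            ll += eta[deaths].sum()
            for ell in range(d):
                ll -= np.log(risk_sum - ell / d * tie_sum)
        i = j
    return float(ll)


def _multivariate_cox(
    expr: ExpressionMatrix, survival: SurvivalTable, genes: list[str]
) -> pd.Series:
    df = expr.values.loc[genes, survival.samples].T.copy()
    df["time"] = survival.time
    df["event"] = survival.event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph.params_


def fit_signature(
    expr: ExpressionMatrix,
    survival: SurvivalTable,
    candidates: list[str] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    screen_p: float = 0.001,
    alpha_override: float | None = None,
) -> RiskSignature:
    """Screen -> L1 Cox path -> CV partial likelihood -> unpenalised refit.

    ``screen_p`` is the univariate screen threshold (0.001 by default;
    0.05 is the documented permissive variant).  ``alpha_override``
    bypasses cross-validation with a fixed penalty; near-zero values give
    the unpenalised multivariate limit.
    """
    candidates = list(candidates) if candidates is not None else list(expr.genes)
    screened = []
    for gene in candidates:
        try:
            if unicox(expr.values.loc[gene, survival.samples], survival)["pvalue"] < screen_p:
                screened.append(gene)
        except ValueError:
            continue
    if not screened:
        warnings.warn("no gene passed the univariate screen", stacklevel=2)
        return RiskSignature(coefficients=[], provenance="fitted")

    X = expr.values.loc[screened, survival.samples].to_numpy().T
    y = Surv.from_arrays(
        event=survival.event.to_numpy().astype(bool), time=survival.time.to_numpy()
    )
    time = survival.time.to_numpy()
    event = survival.event.to_numpy()

    if alpha_override is not None:
        best_alpha = float(alpha_override)
    else:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=30)
        path.fit(X, y)
        alphas = path.alphas_
        rng = np.random.default_rng(seed)
        folds = rng.integers(0, cv_folds, size=len(time))
        cv_ll = np.zeros(len(alphas))
        for f in range(cv_folds):
            train = folds != f
            if event[~train].sum() == 0 or event[train].sum() == 0:
                continue
            model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
            model.fit(X[train], y[train])
            for a_idx in range(len(alphas)):
                beta = model.coef_[:, a_idx]
                # held-out contribution: full-data minus train-data likelihood
                cv_ll[a_idx] += cox_partial_loglik(
                    X, time, event, beta
                ) - cox_partial_loglik(X[train], time[train], event[train], beta)
        best_alpha = float(alphas[int(np.argmax(cv_ll))])

    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=[max(best_alpha, 1e-12)], fit_baseline_model=False
    )
    model.fit(X, y)
    beta = model.coef_[:, 0]
    selected = [g for g, b in zip(screened, beta) if b != 0.0]
    if not selected:
        warnings.warn("full shrinkage: empty signature", stacklevel=2)
        return RiskSignature(coefficients=[], provenance="fitted")
    refit = _multivariate_cox(expr, survival, selected)
    return RiskSignature(
        coefficients=[(g, float(refit[g])) for g in selected], provenance="fitted"
    )


def risk_score(expr: ExpressionMatrix, signature: RiskSignature) -> pd.Series:
    """Linear risk score sum(beta_i * expression_i) per sample."""
    missing = [g for g in signature.genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"signature gene(s) missing from matrix: {missing}")
    sub = expr.values.loc[signature.genes].to_numpy()
    scores = signature.betas @ sub
    return pd.Series(scores, index=expr.samples, name="risk_score")


def time_dependent_auc(
    score: pd.Series,
    survival: SurvivalTable,
    horizons: list[float] = (1.0, 2.0, 3.0),
) -> dict[float, float]:
    """Cumulative/dynamic AUC(t) with IPCW from the censoring KM curve.

    Horizons with no prior event, or outside the observed follow-up, are
    reported as NaN.
    """
    score = score.loc[survival.samples].to_numpy()
    time = survival.time.to_numpy()
    event = survival.event.to_numpy().astype(bool)
    y = Surv.from_arrays(event=event, time=time)
    out: dict[float, float] = {}
    t_max = time[event].max() if event.any() else 0.0
    for t in horizons:
        evaluable = event[time <= t].any() and t < time.max() and t <= t_max
        if not evaluable:
            out[float(t)] = float("nan")
            continue
        auc, _ = cumulative_dynamic_auc(y, y, score, [t])
        out[float(t)] = float(auc[0])
    return out


def covariate_cox(
    score: pd.Series, covariates: pd.DataFrame, survival: SurvivalTable
) -> dict[str, pd.DataFrame]:
    """Univariate fits per term plus one joint multivariate Cox fit.

    Collinear covariates (correlation 1 with an earlier column) are
    dropped from the joint fit with a warning.
    """
    frame = pd.DataFrame({"risk_score": score.loc[survival.samples]})
    for col in covariates.columns:
        frame[col] = pd.to_numeric(covariates.loc[survival.samples, col])

    uni_rows = []
    for col in frame.columns:
        res = unicox(frame[col], survival)
        uni_rows.append(
            (col, res["beta"], res["hr"], res["se"], res["pvalue"])
        )
    uni = pd.DataFrame(
        uni_rows, columns=["term", "beta", "hr", "se", "pvalue"]
    ).set_index("term")

    keep = []
    for col in frame.columns:
        if any(abs(frame[col].corr(frame[k])) > 1 - 1e-12 for k in keep):
            warnings.warn(f"dropping collinear covariate {col!r}", stacklevel=2)
            continue
        keep.append(col)
    joint = frame[keep].copy()
    joint["time"] = survival.time
    joint["event"] = survival.event
    cph = CoxPHFitter()
    cph.fit(joint, duration_col="time", event_col="event")
    multi = cph.summary[["coef", "exp(coef)", "se(coef)", "p"]].rename(
        columns={"coef": "beta", "exp(coef)": "hr", "se(coef)": "se", "p": "pvalue"}
    )
    return {"univariate": uni, "multivariate": multi}
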