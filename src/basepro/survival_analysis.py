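"""Cox modelling, Kaplan-Meier stratification and concordance.

Univariate Cox fits quantify each score's prognostic value (hazard ratio,
Wald p); clinically adjusted fits add age, stage, lymph-node status, grade
and size.  Kaplan-Meier curves compare median-dichotomised score groups with
the log-rank test.  The concordance index counts comparable patient pairs
(both events, or one event before the other's censoring) ordered
consistently by predicted risk (risk ties count 1/2).  Stepwise selection
builds a multi-score Cox model; trained models assign validation patients
to tertile risk groups by their linear predictor.

Cox fitting and Kaplan-Meier estimation are delegated to lifelines (Efron
tie handling); the concordance index is computed in-package to honour the
exact pair conventions above.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger("basepro.survival")


@dataclass
class CoxModelResult:
    summary: pd.DataFrame  # per covariate: coef, hazard_ratio, se, p
    log_likelihood: float
    concordance: float  # on the fitting data
    covariates: list[str]

    @property
    def coefs(self) -> pd.Series:
        return self.summary["coef"]


@dataclass
class RiskGroups:
    groups: pd.Series  # low / intermediate / high (k=3)
    linear_predictor: pd.Series
    cuts: list[float]  # linear-predictor boundaries between groups


@dataclass
class KMResult:
    curves: dict  # group -> DataFrame(timeline, survival)
    statistic: float
    p_value: float


def _clean(covariates: pd.DataFrame, time, event):
    df = covariates.copy().astype(float)
    df["_time"] = np.asarray(time, float)
    df["_event"] = np.asarray(event, int)
    complete = df.notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d sample(s) with missing covariates", int((~complete).sum()))
        df = df[complete]
    if df["_event"].sum() < 1:
        raise ValueError("no events in the data")
    return df


def cox_fit(
    covariates: pd.DataFrame, time, event, ties: str = "efron", penalizer: float = 0.0
) -> CoxModelResult:
    """Maximum partial-likelihood Cox model (Efron ties by default).

    Serves both the univariate (single score) and the clinically adjusted
    (score + clinical covariates) use.  Monotone likelihood / separation is
    retried with a small ridge penalty and reported.
    """
    df = _clean(covariates, time, event)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError:
        logger.warning("Cox fit did not converge; refitting with ridge penalty 0.1")
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hazard_ratio": np.exp(s["coef"]),
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
    return CoxModelResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        concordance=float(cph.concordance_index_),
        covariates=list(covariates.columns),
    )


def km_logrank(group_labels: pd.Series, time, event) -> KMResult:
    """Product-limit curves per group and the log-rank test across groups."""
    groups = pd.Series(group_labels)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    uniq = groups.unique()
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    curves = {}
    for gname in uniq:
        mask = (groups == gname).to_numpy()
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask], label=str(gname))
        curves[gname] = pd.DataFrame(
            {"timeline": km.survival_function_.index,
             "survival": km.survival_function_.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(time, groups.to_numpy(), event)
    return KMResult(curves=curves, statistic=float(res.test_statistic), p_value=float(res.p_value))


def dichotomize_median(score: pd.Series) -> pd.Series:
    """Split at the median: score <= median -> 'low', above -> 'high'."""
    score = pd.Series(score)
    if score.nunique() < 2:
        raise ValueError("constant score cannot be dichotomised")
    med = score.median()
    return pd.Series(np.where(score <= med, "low", "high"), index=score.index)


def concordance_index(risk, time, event) -> float:
    """Concordance between predicted risk and survival time.

    A pair is comparable if both patients have events, or if one has an
    event strictly before the other is censored.  A comparable pair is
    concordant when the higher-risk patient has the shorter survival; tied
    risks (or tied event times) count 1/2.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int).astype(bool)
    n = len(risk)
    ti = time[:, None]
    tj = time[None, :]
    ei = event[:, None]
    ej = event[None, :]
    # orderable: i's event observed strictly before j's time
    orderable = (ti < tj) & ei
    both_tied = (ti == tj) & ei & ej
    upper = np.triu(np.ones((n, n), bool), k=1)
    comparable = (orderable | orderable.T | both_tied) & upper
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    ri = risk[:, None]
    rj = risk[None, :]
    # concordant: shorter survival has higher risk
    conc = np.where(ti < tj, ri > rj, np.where(tj < ti, rj > ri, False))
    tied_risk = ri == rj
    half = (tied_risk | (both_tied & ~tied_risk)) & comparable
    score = (conc & comparable & ~half).sum() + 0.5 * half.sum()
    return float(score / n_comp)


def stepwise_cox(
    candidate_features: pd.DataFrame,
    time,
    event,
    enter_p: float = 0.15,
    stay_p: float = 0.15,
    forced_clinical: pd.DataFrame | None = None,
    max_iter: int = 50,
) -> tuple[list[str], CoxModelResult]:
    """Forward stepwise Cox selection with backward checks.

    At each round the candidate with the smallest Wald p below ``enter_p``
    is added, then any included (non-forced) covariate with p above
    ``stay_p`` is dropped.  ``forced_clinical`` covariates are always in the
    model and never dropped.  Deterministic; raises on non-convergence.
    """
    if candidate_features.shape[1] == 0:
        raise ValueError("no candidate features")
    forced = list(forced_clinical.columns) if forced_clinical is not None else []
    data = candidate_features.copy()
    if forced_clinical is not None:
        data = pd.concat([data, forced_clinical], axis=1)
    included: list[str] = []
    trace = []
    for it in range(max_iter):
        changed = False
        # forward step
        best_name, best_p = None, np.inf
        for cand in candidate_features.columns:
            if cand in included:
                continue
            fit = cox_fit(data[forced + included + [cand]], time, event)
            p = float(fit.summary.loc[cand, "p"])
            if p < best_p:
                best_name, best_p = cand, p
        if best_name is not None and best_p < enter_p:
            included.append(best_name)
            trace.append(("add", best_name, best_p))
            changed = True
        # backward step(s)
        while included:
            fit = cox_fit(data[forced + included], time, event)
            pvals = fit.summary.loc[included, "p"]
            worst = pvals.idxmax()
            if float(pvals[worst]) > stay_p:
                included.remove(worst)
                trace.append(("drop", worst, float(pvals[worst])))
                changed = True
            else:
                break
        if not changed:
            final_cols = forced + included
            if not final_cols:
                raise ValueError("no feature met the entry criterion")
            return included, cox_fit(data[final_cols], time, event)
    raise RuntimeError(f"stepwise selection did not converge; trace: {trace}")


def _group_names(n_groups: int) -> list[str]:
    if n_groups == 2:
        return ["low", "high"]
    if n_groups == 3:
        return ["low", "intermediate", "high"]
    return [f"group{i + 1}" for i in range(n_groups)]


def predict_risk_groups(
    trained_model: CoxModelResult,
    new_covariates: pd.DataFrame,
    n_groups: int = 3,
    drop_covariates: list[str] | None = None,
) -> RiskGroups:
    """Rank validation samples by linear predictor into equal risk groups.

    Group sizes differ by at most one; remainders go to the lower-risk
    groups (n=10, k=3 -> sizes 4/3/3 low to high).  ``drop_covariates``
    zeroes those terms of the already-fitted model before predicting (used
    to remove clinical covariates without refitting).
    """
    coefs = trained_model.coefs.copy()
    if drop_covariates:
        coefs[coefs.index.intersection(drop_covariates)] = 0.0
    for name in coefs.index:
        if name not in new_covariates.columns:
            raise KeyError(f"covariate {name!r} missing from new data")
    lp = pd.Series(
        new_covariates[coefs.index].astype(float).to_numpy() @ coefs.to_numpy(),
        index=new_covariates.index,
        name="linear_predictor",
    )
    n = len(lp)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    order = np.argsort(lp.to_numpy(), kind="stable")
    names = _group_names(n_groups)
    labels = np.empty(n, dtype=object)
    cuts = []
    pos = 0
    for size, name in zip(sizes, names):
        labels[order[pos : pos + size]] = name
        pos += size
        if pos < n:
            cuts.append(float(lp.to_numpy()[order[pos - 1]]))
    return RiskGroups(groups=pd.Series(labels, index=lp.index), linear_predictor=lp, cuts=cuts)


def cross_validated_concordance(
    features: pd.DataFrame, time, event, k: int = 10, seed: int = 0
) -> float:
    """Pooled out-of-fold concordance of a Cox model over k folds.

    Folds are re-randomised (up to 10 attempts) if a training fold has no
    events; the pooled linear predictors are scored once.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(features)
    for attempt in range(10):
        rng = np.random.default_rng(seed + attempt)
        fold_of = rng.permutation(np.arange(n) % k)
        if all(event[fold_of != f].sum() >= 1 for f in range(k)):
            break
    else:
        raise ValueError("could not build folds with events in every training split")
    lp = np.empty(n)
    for f in range(k):
        tr = fold_of != f
        fit = cox_fit(features[tr], time[tr], event[tr])
        lp[~tr] = features[~tr].astype(float).to_numpy() @ fit.coefs.to_numpy()
    return concordance_index(lp, time, event)
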