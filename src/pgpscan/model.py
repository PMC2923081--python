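"""Logistic-regression model of CRM activity along the A/P axis.

The predicted activity of CRM ``l`` in bin ``b`` is

    Ehat_{l,b} = sig( alpha_l + sum_i w_i * (c_{i,b} * S_{i,l})^order_i )

where ``c_{i,b}`` is the concentration of TF ``i`` in bin ``b``,
``S_{i,l}`` its motif score in the CRM, ``w_i`` the shared regression
weight (positive for activators, negative for repressors), ``alpha_l``
a per-CRM basal level, and ``sig(x) = 1/(1+exp(-x))``.  Order-2 terms
square the covariate of a factor (used for the steep anterior morphogen
gradient); every order-2 term must accompany the order-1 term for the
same factor.

Parameters are trained by iteratively reweighted least squares (IWLS)
on a Bernoulli likelihood of the binary target patterns, with a tiny
ridge penalty (default 1e-6) so that the frequent perfect separation of
small binary data sets leaves all coefficients finite.  The ratio of a
trained weight to its estimated standard error is treated as a z score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AxisProfile

RIDGE_DEFAULT = 1e-6
_MU_EPS = 1e-10


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def term_name(tf: str, order: int) -> str:
    return tf if order == 1 else f"{tf}^{order}"


def default_covariate_spec(
    tf_names: Sequence[str], squared: Sequence[str] = ()
) -> list[dict]:
    """One order-1 term per TF plus optional squared terms."""
    spec = [{"tf": tf, "order": 1} for tf in tf_names]
    spec += [{"tf": tf, "order": 2} for tf in squared]
    return spec


def _validate_spec(covariate_spec: Sequence[Mapping]) -> list[dict]:
    spec = [dict(t) for t in covariate_spec]
    order1 = {t["tf"] for t in spec if t.get("order", 1) == 1}
    for t in spec:
        order = t.get("order", 1)
        if order not in (1, 2):
            raise ValueError(f"unsupported covariate order {order}")
        t["order"] = order
        if order == 2 and t["tf"] not in order1:
            raise ValueError(
                f"order-2 term for {t['tf']!r} lacks a matching order-1 term"
            )
    return spec


def _conc_frame(concentrations) -> pd.DataFrame:
    if isinstance(concentrations, pd.DataFrame):
        return concentrations.astype(float)
    rows = {}
    for tf, prof in concentrations.items():
        rows[tf] = prof.values if isinstance(prof, AxisProfile) else np.asarray(prof, float)
    return pd.DataFrame(rows).T


def _target_frame(targets) -> pd.DataFrame:
    if isinstance(targets, pd.DataFrame):
        return targets.astype(float)
    rows = {}
    for crm, prof in targets.items():
        rows[crm] = prof.values if isinstance(prof, AxisProfile) else np.asarray(prof, float)
    return pd.DataFrame(rows).T


@dataclass
class ExpressionModel:
    """A fitted (or constructed) CRM activity model."""

    tf_weights: dict[str, float]
    baselines: dict[str, float]
    covariate_spec: list[dict]
    standard_errors: dict[str, float] = field(default_factory=dict)
    ridge: float = RIDGE_DEFAULT
    converged: bool = True
    separation_flagged: bool = False
    dropped_terms: list[str] = field(default_factory=list)

    def term_names(self) -> list[str]:
        return [term_name(t["tf"], t["order"]) for t in self.covariate_spec]

    def linear_predictor(
        self,
        s_row: Mapping[str, float],
        concentrations,
        alpha: float,
    ) -> np.ndarray:
        conc = _conc_frame(concentrations)
        eta = np.full(conc.shape[1], float(alpha))
        for t in self.covariate_spec:
            tf, order = t["tf"], t["order"]
            if tf not in s_row:
                raise KeyError(f"no motif score for TF {tf!r}")
            if tf not in conc.index:
                raise KeyError(f"no concentration profile for TF {tf!r}")
            cov = conc.loc[tf].to_numpy() * float(s_row[tf])
            eta += self.tf_weights.get(term_name(tf, order), 0.0) * cov**order
        return eta

    def to_json(self) -> str:
        return json.dumps(
            {
                "tf_weights": self.tf_weights,
                "baselines": self.baselines,
                "covariate_spec": self.covariate_spec,
                "standard_errors": self.standard_errors,
                "ridge": self.ridge,
                "converged": self.converged,
                "separation_flagged": self.separation_flagged,
                "dropped_terms": self.dropped_terms,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExpressionModel":
        d = json.loads(text)
        return cls(**d)

    def mean_baseline(self) -> float:
        return float(np.mean(list(self.baselines.values())))


@dataclass
class FitReport:
    rmse: float
    mean_cc: float
    aic: float
    loglik: float
    n_params: int
    n_cc_excluded: int
    z: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)


def predict_expression(
    model: ExpressionModel,
    crm: str | None,
    s_row: Mapping[str, float],
    concentrations,
    alpha: float | None = None,
    label: str = "",
) -> AxisProfile:
    """Predicted activity profile of one CRM (values strictly in (0,1)).

    ``alpha`` overrides the stored per-CRM baseline; for sequences never
    seen in training (e.g. scan windows) pass the mean trained baseline.
    """
    if alpha is None:
        if crm is None or crm not in model.baselines:
            raise KeyError(f"no baseline for CRM {crm!r}; pass alpha")
        alpha = model.baselines[crm]
    eta = model.linear_predictor(s_row, concentrations, alpha)
    mu = np.clip(sigmoid(eta), _MU_EPS, 1 - _MU_EPS)
    return AxisProfile(mu, "continuous", label or (crm or "prediction"))


def _design(S: pd.DataFrame, conc: pd.DataFrame, spec: list[dict]):
    """Design matrix over CRM x bin cells (CRM-major ordering).

    Columns: one indicator per CRM (baselines) followed by one column
    per covariate term.
    """
    crms = list(S.index)
    n_bins = conc.shape[1]
    n_cells = len(crms) * n_bins
    n_base = len(crms)
    names = [term_name(t["tf"], t["order"]) for t in spec]
    X = np.zeros((n_cells, n_base + len(spec)))
    for li, crm in enumerate(crms):
        rows = slice(li * n_bins, (li + 1) * n_bins)
        X[rows, li] = 1.0
        for ti, t in enumerate(spec):
            tf, order = t["tf"], t["order"]
            cov = conc.loc[tf].to_numpy() * float(S.loc[crm, tf])
            X[rows, n_base + ti] = cov**order
    return X, crms, names


def bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _penalized_ll(X, y, beta, ridge):
    return bernoulli_loglik(y, sigmoid(X @ beta)) - 0.5 * ridge * beta @ beta


def _iwls(X, y, ridge, max_iter=100, tol=1e-8):
    """Ridge-penalized IWLS (damped Newton) for the Bernoulli GLM.

    Step-halving guards against the overshoot of undamped Newton steps
    on (near-)separable binary data; the penalized objective is concave,
    so damped Newton converges to the unique optimum.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = _penalized_ll(X, y, beta, ridge)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(sigmoid(eta), _MU_EPS, 1 - _MU_EPS)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        A = XtW @ X + ridge * np.eye(p)
        proposal = np.linalg.solve(A, XtW @ z)
        step = proposal - beta
        ll = _penalized_ll(X, y, proposal, ridge)
        t = 1.0
        while ll < ll_old and t > 1e-8:
            t *= 0.5
            proposal = beta + t * step
            ll = _penalized_ll(X, y, proposal, ridge)
        beta = proposal
        if abs(ll - ll_old) <= tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = np.clip(sigmoid(eta), _MU_EPS, 1 - _MU_EPS)
    w = mu * (1 - mu)
    A = (X.T * w) @ X + ridge * np.eye(X.shape[1])
    se = np.sqrt(np.diag(np.linalg.inv(A)))
    return beta, se, converged


def fit_model(
    S: pd.DataFrame,
    concentrations,
    targets,
    covariate_spec: Sequence[Mapping] | None = None,
    ridge: float = RIDGE_DEFAULT,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[ExpressionModel, FitReport]:
    """Fit weights and per-CRM baselines by ridge-stabilized IWLS.

    ``S`` is the CRM x TF motif-score matrix, ``targets`` the binary
    100-bin expression profile of each CRM.  Deterministic given the
    data.  Zero-variance covariates are dropped with a warning; perfect
    separation is flagged (coefficients stay finite via the ridge).
    """
    conc = _conc_frame(concentrations)
    targ = _target_frame(targets).loc[S.index]
    if not np.all(np.isin(targ.to_numpy(), (0.0, 1.0))):
        raise ValueError("targets must be binary 0/1 profiles")
    if covariate_spec is None:
        covariate_spec = default_covariate_spec(list(S.columns))
    spec = _validate_spec(covariate_spec)
    X, crms, names = _design(S, conc, spec)
    y = targ.to_numpy().ravel()
    n_base = len(crms)
    # drop covariate columns with zero variance
    keep, dropped = [], []
    for ti, nm in enumerate(names):
        col = X[:, n_base + ti]
        if np.ptp(col) == 0:
            dropped.append(nm)
            warnings.warn(f"dropping zero-variance covariate {nm!r}")
        else:
            keep.append(ti)
    cols = list(range(n_base)) + [n_base + ti for ti in keep]
    Xk = X[:, cols]
    beta, se, converged = _iwls(Xk, y, ridge, max_iter=max_iter, tol=tol)
    baselines = {crm: float(beta[i]) for i, crm in enumerate(crms)}
    weights, ses = {}, {}
    for j, ti in enumerate(keep):
        weights[names[ti]] = float(beta[n_base + j])
        ses[names[ti]] = float(se[n_base + j])
    for nm in dropped:
        weights[nm] = 0.0
        ses[nm] = float("nan")
    for i, crm in enumerate(crms):
        ses[f"alpha[{crm}]"] = float(se[i])
    mu = sigmoid(Xk @ beta)
    separation = bool(np.max(np.abs(beta)) > 30) or bool(
        np.all(np.abs(y - mu) < 1e-6)
    )
    kept_spec = [spec[ti] for ti in keep] + [
        t for t in spec if term_name(t["tf"], t["order"]) in dropped
    ]
    model = ExpressionModel(
        tf_weights=weights,
        baselines=baselines,
        covariate_spec=kept_spec,
        standard_errors=ses,
        ridge=ridge,
        converged=converged,
        separation_flagged=separation,
        dropped_terms=dropped,
    )
    report = goodness_of_fit(model, S, conc, targ)
    return model, report


def coefficient_significance(model: ExpressionModel) -> pd.DataFrame:
    """Per-term z = w/SE and two-sided normal p-value.

    Terms with SE = 0 (or dropped terms with undefined SE) report NaN.
    """
    rows = []
    for t in model.covariate_spec:
        nm = term_name(t["tf"], t["order"])
        w = model.tf_weights.get(nm, 0.0)
        se = model.standard_errors.get(nm, float("nan"))
        if se == 0 or not np.isfinite(se):
            z = p = float("nan")
        else:
            z = w / se
            p = 2 * stats.norm.sf(abs(z))
        rows.append({"term": nm, "weight": w, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows).set_index("term")


def goodness_of_fit(model: ExpressionModel, S, concentrations, targets) -> FitReport:
    """RMSE over all CRM x bin cells, mean per-CRM Pearson CC, and
    AIC = 2k - 2 loglik with k = number of TF terms + baselines."""
    S = S if isinstance(S, pd.DataFrame) else pd.DataFrame(S)
    conc = _conc_frame(concentrations)
    targ = _target_frame(targets).loc[S.index]
    preds = []
    for crm in S.index:
        prof = predict_expression(model, crm, S.loc[crm].to_dict(), conc)
        preds.append(prof.values)
    P = np.array(preds)
    Y = targ.to_numpy()
    rmse = float(np.sqrt(np.mean((P - Y) ** 2)))
    ccs = []
    excluded = 0
    for i in range(len(P)):
        if np.std(P[i]) == 0 or np.std(Y[i]) == 0:
            excluded += 1
            continue
        ccs.append(float(np.corrcoef(P[i], Y[i])[0, 1]))
    mean_cc = float(np.mean(ccs)) if ccs else float("nan")
    ll = bernoulli_loglik(Y.ravel(), P.ravel())
    k = len(model.covariate_spec) + len(model.baselines)
    aic = 2 * k - 2 * ll
    sig = coefficient_significance(model)
    return FitReport(
        rmse=rmse,
        mean_cc=mean_cc,
        aic=aic,
        loglik=ll,
        n_params=k,
        n_cc_excluded=excluded,
        z=sig["z"].to_dict(),
        p=sig["p"].to_dict(),
    )


def cross_validate(
    S: pd.DataFrame,
    concentrations,
    targets,
    covariate_spec: Sequence[Mapping] | None = None,
    folds: int = 2,
    reps: int = 1000,
    shuffle: bool = False,
    seed: int = 0,
    ridge: float = RIDGE_DEFAULT,
) -> np.ndarray:
    """Replicated cell-wise cross-validation of the expression model.

    Each replicate partitions the CRM x bin cells at random, trains on
    the complement of a held-out fraction ``1/folds`` and reports the
    test RMSE.  ``shuffle`` first permutes the matching between CRMs and
    their expression profiles (the overfitting control).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    conc = _conc_frame(concentrations)
    targ = _target_frame(targets).loc[S.index]
    if covariate_spec is None:
        covariate_spec = default_covariate_spec(list(S.columns))
    spec = _validate_spec(covariate_spec)
    rng = np.random.default_rng(seed)
    X, crms, _ = _design(S, conc, spec)
    n_cells = X.shape[0]
    n_test = n_cells // folds
    out = np.empty(reps)
    for r in range(reps):
        Yr = targ.to_numpy()
        if shuffle:
            Yr = Yr[rng.permutation(len(crms))]
        y = Yr.ravel()
        perm = rng.permutation(n_cells)
        test = perm[:n_test]
        train = perm[n_test:]
        beta, _, _ = _iwls(X[train], y[train], ridge)
        mu = sigmoid(X[test] @ beta)
        out[r] = float(np.sqrt(np.mean((mu - y[test]) ** 2)))
    return out


def knockdown(
    model: ExpressionModel,
    tf: str,
    crm: str | None,
    s_row: Mapping[str, float],
    concentrations,
    alpha: float | None = None,
) -> AxisProfile:
    """In-silico knockdown: re-predict with the TF's concentration zeroed."""
    conc = _conc_frame(concentrations).copy()
    if tf not in conc.index:
        raise KeyError(f"unknown TF {tf!r}")
    conc.loc[tf] = 0.0
    return predict_expression(
        model, crm, s_row, conc, alpha=alpha,
        label=f"{crm or 'prediction'}:{tf}-KD",
    )
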