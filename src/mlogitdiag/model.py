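"""Survey-weighted multinomial logistic regression.

The model relates a three-level outcome (LBW/NBW/HBW) to categorical
covariates through J-1 log-odds equations against a reference category:

    log[ pi_j(x) / pi_ref(x) ] = beta_j' x,   j != ref,

with category probabilities given by the softmax over the linear
predictors (the reference predictor fixed at zero). Estimation maximises
the survey pseudo-likelihood, in which each child's log-likelihood
contribution is multiplied by its design weight w_i = N_c/n_c
(``weighting="pseudo"``); variance estimation uses the delete-one-cluster
jackknife grouped by stratum. A ``"literal"`` mode that instead scales the
linear predictor by w_i is available for comparing weighting conventions.

The numerical core is exposed as a scikit-learn estimator
(:class:`SurveyMultinomialLogit`); the module-level functions layer the
survey bookkeeping (design building, cluster jackknife, AIC model
selection) on top of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .datamodel import COVARIATE_LEVELS, OUTCOME_LEVELS, ModelSpec, SurveyDataset
from .exceptions import (
    ConvergenceError,
    SchemaError,
    SeparationError,
    ValidationError,
)
from .weights import compute_weights

__all__ = [
    "DesignMatrix",
    "FitResult",
    "ModelSelection",
    "SurveyMultinomialLogit",
    "build_design",
    "fit",
    "goodness_of_fit",
    "jackknife_vcov",
    "predict_probs",
    "select_model",
]


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Reference-coded design matrix with an explicit intercept column."""

    X: np.ndarray
    columns: list
    spec: ModelSpec

    @property
    def n_params_per_category(self):
        return self.X.shape[1]


def build_design(data, spec):
    """Build the dummy-coded design matrix for a model specification.

    Column order is deterministic: intercept first, then each term in spec
    order with its levels in declared order, skipping the reference level.
    A level absent from the data yields an all-zero column, which is
    retained with a warning (the coefficient is inestimable and the fit
    will report separation).
    """
    rec = data.records if isinstance(data, SurveyDataset) else data
    cols = [np.ones(len(rec))]
    names = ["intercept"]
    for term in spec.terms:
        if term not in rec.columns:
            raise SchemaError(f"term {term!r} not present in the data")
        ref = spec.references[term]
        values = rec[term].to_numpy(dtype=object)
        for level in COVARIATE_LEVELS[term]:
            if level == ref:
                continue
            col = (values == level).astype(float)
            if not col.any():
                warnings.warn(
                    f"level {level!r} of {term!r} has no observations; "
                    "column retained but its coefficient is inestimable",
                    stacklevel=2,
                )
            cols.append(col)
            names.append(f"{term}[{level}]")
    return DesignMatrix(X=np.column_stack(cols), columns=names, spec=spec)


# ---------------------------------------------------------------------------
# numerical core
# ---------------------------------------------------------------------------

def _full_eta(X, B, ref_idx, J):
    eta = np.zeros((X.shape[0], J))
    nonref = [j for j in range(J) if j != ref_idx]
    eta[:, nonref] = X @ B.T
    return eta


def _log_probs(eta):
    return eta - special.logsumexp(eta, axis=1, keepdims=True)


def _loglik(B, X, y_idx, w, ref_idx, J):
    logp = _log_probs(_full_eta(X, B, ref_idx, J))
    return float(w @ logp[np.arange(len(y_idx)), y_idx])


def _fit_core(X, y_idx, w, J, ref_idx, tol=1e-8, max_iter=100, guard=30.0,
              beta0=None):
    """Newton-Raphson with step halving on the stacked (J-1)*p parameters.

    The gradient max-norm criterion is scaled by the total weight, so the
    same ``tol`` is meaningful across sample sizes; an ill-conditioned
    Hessian triggers a ridge retry and then an L-BFGS fallback.
    """
    n, p = X.shape
    nonref = [j for j in range(J) if j != ref_idx]
    J1 = len(nonref)
    counts = np.bincount(y_idx, weights=w, minlength=J)
    if (counts > 0).sum() < 2:
        raise SeparationError("all records fall in a single outcome category")
    if (counts == 0).any():
        empty = [j for j in range(J) if counts[j] == 0]
        raise SeparationError(
            f"outcome categories {empty} have no observations (separation)"
        )
    Y = (y_idx[:, None] == np.asarray(nonref)[None, :]).astype(float)
    B = np.zeros((J1, p)) if beta0 is None else np.array(beta0, dtype=float)
    scale = max(1.0, float(w.sum()))
    ll = _loglik(B, X, y_idx, w, ref_idx, J)
    for it in range(1, max_iter + 1):
        P = np.exp(_log_probs(_full_eta(X, B, ref_idx, J)))[:, nonref]
        G = ((Y - P) * w[:, None]).T @ X
        if np.abs(G).max() <= tol * scale:
            return B, ll, it - 1, True
        H = np.empty((J1 * p, J1 * p))
        for a in range(J1):
            for b in range(a, J1):
                v = w * (P[:, a] * (1.0 if a == b else 0.0) - P[:, a] * P[:, b])
                blk = X.T @ (X * v[:, None])
                H[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
                if a != b:
                    H[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk.T
        try:
            delta = np.linalg.solve(H, G.ravel())
        except np.linalg.LinAlgError:
            try:
                ridge = 1e-8 * (np.trace(H) / H.shape[0] + 1.0)
                delta = np.linalg.solve(H + ridge * np.eye(H.shape[0]), G.ravel())
            except np.linalg.LinAlgError:
                return _fit_lbfgs(X, y_idx, w, J, ref_idx, tol, B, scale, guard)
        if not np.isfinite(delta).all():
            return _fit_lbfgs(X, y_idx, w, J, ref_idx, tol, B, scale, guard)
        step = 1.0
        for _ in range(40):
            B_new = B + step * delta.reshape(J1, p)
            ll_new = _loglik(B_new, X, y_idx, w, ref_idx, J)
            if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            step /= 2.0
        B, ll = B_new, ll_new
        if np.abs(B).max() > guard:
            raise SeparationError(
                "coefficient magnitude exceeded the separation guard "
                f"({guard}); the data are (quasi-)separated"
            )
    raise ConvergenceError(
        f"no convergence in {max_iter} Newton iterations", last_beta=B
    )


def _fit_lbfgs(X, y_idx, w, J, ref_idx, tol, B0, scale, guard):
    """Quasi-Newton fallback used when the Hessian is ill-conditioned."""
    n, p = X.shape
    nonref = [j for j in range(J) if j != ref_idx]
    J1 = len(nonref)
    Y = (y_idx[:, None] == np.asarray(nonref)[None, :]).astype(float)

    def objective(flat):
        B = flat.reshape(J1, p)
        logp = _log_probs(_full_eta(X, B, ref_idx, J))
        ll = float(w @ logp[np.arange(n), y_idx])
        P = np.exp(logp)[:, nonref]
        G = ((Y - P) * w[:, None]).T @ X
        return -ll, -G.ravel()

    res = optimize.minimize(
        objective, B0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": tol * scale},
    )
    B = res.x.reshape(J1, p)
    if np.abs(B).max() > guard:
        raise SeparationError("separation detected in quasi-Newton fallback")
    _, neg_grad = objective(res.x)
    converged = np.abs(neg_grad).max() <= 10 * tol * scale
    ll = _loglik(B, X, y_idx, w, ref_idx, J)
    if not converged:
        raise ConvergenceError("quasi-Newton fallback did not converge",
                               last_beta=B)
    return B, ll, int(res.nit), True


def predict_probs(beta, X, reference=0, n_categories=None):
    """Category probabilities from a coefficient matrix (softmax, Eq. form).

    ``beta`` is (J-1) x p with rows for the non-reference categories in
    storage order; the reference category's linear predictor is fixed at 0.
    Computation is log-sum-exp guarded, so extreme predictors saturate at
    0/1 instead of overflowing.
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    J = (beta.shape[0] + 1) if n_categories is None else int(n_categories)
    eta = _full_eta(X, beta, reference, J)
    return np.exp(_log_probs(eta))


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class SurveyMultinomialLogit(BaseEstimator):
    """Multinomial logistic regression with survey pseudo-likelihood weights.

    Parameters
    ----------
    categories : sequence, optional
        Outcome category labels in storage order. Defaults to the sorted
        unique values of ``y`` at fit time.
    reference : label, optional
        Baseline category (its linear predictor is 0). Defaults to the
        first category.
    weighting : {"pseudo", "literal", "none"}
        ``"pseudo"`` multiplies each record's log-likelihood term by its
        sample weight (the standard survey convention); ``"literal"``
        instead multiplies the linear predictor by the weight;
        ``"none"`` ignores weights.
    fit_intercept : bool
        Prepend an intercept column to ``X``. Set False when ``X`` already
        carries one.
    tol : float
        Convergence tolerance on the gradient max-norm, scaled by the
        total weight.
    max_iter : int
        Newton iteration budget.
    beta_guard : float
        Coefficient magnitude at which the fit is declared separated.

    Attributes
    ----------
    classes_ : ndarray of category labels in storage order.
    reference_ : the baseline category label.
    beta_ : ndarray (J-1, p), coefficients including the intercept column
        first (when ``fit_intercept``); rows follow the non-reference
        categories in storage order.
    coef_, intercept_ : sklearn-style views of ``beta_``.
    loglik_, aic_, n_iter_, converged_ : fit summaries.
    """

    def __init__(self, *, categories=None, reference=None, weighting="pseudo",
                 fit_intercept=True, tol=1e-8, max_iter=100, beta_guard=30.0):
        self.categories = categories
        self.reference = reference
        self.weighting = weighting
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.beta_guard = beta_guard

    # -- helpers ------------------------------------------------------
    def _encode_y(self, y):
        y = np.asarray(y)
        if self.categories is None:
            classes = np.unique(y)
        else:
            classes = np.asarray(list(self.categories))
        lookup = {c: i for i, c in enumerate(classes.tolist())}
        try:
            y_idx = np.array([lookup[v] for v in y.tolist()])
        except KeyError as exc:
            raise ValidationError(f"unknown outcome label {exc.args[0]!r}")
        return classes, y_idx

    def _design(self, X):
        X = check_array(X, dtype=float)
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    # -- estimator API ------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        if self.weighting not in ("pseudo", "literal", "none"):
            raise ValidationError(f"unknown weighting mode {self.weighting!r}")
        Xd = self._design(X)
        classes, y_idx = self._encode_y(y)
        if len(Xd) != len(y_idx):
            raise ValidationError("X and y have different lengths")
        J = len(classes)
        if J < 2:
            raise SeparationError("need at least two outcome categories")
        ref = classes[0] if self.reference is None else self.reference
        if ref not in classes.tolist():
            raise ValidationError(f"reference {ref!r} not among categories")
        ref_idx = int(np.flatnonzero(classes == ref)[0])
        n, p = Xd.shape
        if n <= (J - 1) * p:
            raise ValidationError(
                f"n={n} does not exceed the parameter count {(J - 1) * p}"
            )
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if (w <= 0).any() or not np.isfinite(w).all():
                raise ValidationError("sample weights must be positive, finite")
        if self.weighting == "literal":
            X_fit, w_fit, w_ll = Xd * w[:, None], np.ones(n), np.ones(n)
        elif self.weighting == "none":
            X_fit, w_fit, w_ll = Xd, np.ones(n), np.ones(n)
        else:
            # mean-one internal rescale: same argmax, stable tolerance scale
            X_fit, w_fit, w_ll = Xd, w / w.mean(), w
        B, _, n_iter, converged = _fit_core(
            X_fit, y_idx, w_fit, J, ref_idx, tol=self.tol,
            max_iter=self.max_iter, guard=self.beta_guard,
        )
        self.classes_ = classes
        self.reference_ = ref
        self._ref_idx = ref_idx
        self._X_fit = X_fit
        self._y_idx = y_idx
        self.beta_ = B
        self.n_features_in_ = Xd.shape[1] - (1 if self.fit_intercept else 0)
        if self.fit_intercept:
            self.intercept_ = B[:, 0].copy()
            self.coef_ = B[:, 1:].copy()
        else:
            self.intercept_ = np.zeros(J - 1)
            self.coef_ = B.copy()
        # pseudo-log-likelihood at the raw weights (linear in w)
        self.loglik_ = _loglik(B, X_fit, y_idx, w_ll, ref_idx, J)
        self.aic_ = -2.0 * self.loglik_ + 2.0 * (J - 1) * Xd.shape[1]
        self.n_iter_ = n_iter
        self.converged_ = converged
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "beta_")
        Xd = self._design(X)
        if self.weighting == "literal":
            warnings.warn(
                "literal weighting ties probabilities to record weights; "
                "predict_proba uses unweighted predictors", stacklevel=2,
            )
        return predict_probs(self.beta_, Xd, reference=self._ref_idx,
                             n_categories=len(self.classes_))

    def predict(self, X):
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]

    def score(self, X, y, sample_weight=None):
        """Mean per-record log-likelihood (higher is better)."""
        check_is_fitted(self, "beta_")
        P = self.predict_proba(X)
        _, y_idx = self._encode_y(y)
        ll = np.log(np.clip(P[np.arange(len(y_idx)), y_idx], 1e-300, None))
        if sample_weight is None:
            return float(ll.mean())
        sw = np.asarray(sample_weight, dtype=float)
        return float((sw * ll).sum() / sw.sum())


# ---------------------------------------------------------------------------
# survey-layer fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A fitted survey multinomial logit with its design bookkeeping."""

    beta: np.ndarray
    categories: list
    reference: str
    nonref_categories: list
    columns: list
    loglik: float
    aic: float
    rrr: np.ndarray
    fitted_probs: np.ndarray
    converged: bool
    n_iter: int
    weighting: str
    spec: ModelSpec
    X: np.ndarray = field(repr=False, default=None)
    y_idx: np.ndarray = field(repr=False, default=None)
    w: np.ndarray = field(repr=False, default=None)
    vcov: Optional[np.ndarray] = field(repr=False, default=None)
    se: Optional[np.ndarray] = None
    pvalues: Optional[np.ndarray] = None

    @property
    def n_params(self):
        return self.beta.size

    @property
    def effective_design(self):
        """(X, w) as they enter the information matrix / leverage.

        Pseudo-weighting keeps the raw design and weights; literal
        weighting folds the weights into the design; unweighted fits use
        unit weights.
        """
        if self.weighting == "literal":
            return self.X * self.w[:, None], np.ones(len(self.X))
        if self.weighting == "none":
            return self.X, np.ones(len(self.X))
        return self.X, self.w

    def coef_table(self):
        """Long-format coefficient table (term, category, beta, RRR, se, p)."""
        rows = []
        for r, cat in enumerate(self.nonref_categories):
            for k, col in enumerate(self.columns):
                rows.append({
                    "term": col,
                    "category": cat,
                    "beta": self.beta[r, k],
                    "rrr": self.rrr[r, k],
                    "se": self.se[r, k] if self.se is not None else np.nan,
                    "p_value": (self.pvalues[r, k]
                                if self.pvalues is not None else np.nan),
                })
        return pd.DataFrame(rows)


def fit(data, spec, w=None, *, weighting="pseudo", vcov=None,
        tol=1e-8, max_iter=100, beta_guard=30.0):
    """Fit the survey-weighted multinomial logit defined by ``spec``.

    ``w`` defaults to the N_c/n_c design weights computed from the cluster
    table (ignored under ``weighting="none"``). ``vcov="jackknife"``
    additionally computes the delete-one-cluster jackknife covariance and
    Wald p-values.
    """
    design = build_design(data, spec)
    y_idx = data.outcome_codes()
    if (y_idx < 0).any():
        raise ValidationError(
            "records with missing outcome present; apply drop_missing_outcome"
        )
    if w is None and weighting != "none":
        w = compute_weights(data)
    est = SurveyMultinomialLogit(
        categories=OUTCOME_LEVELS, reference=spec.outcome_reference,
        weighting=weighting, fit_intercept=False, tol=tol,
        max_iter=max_iter, beta_guard=beta_guard,
    )
    est.fit(design.X, np.asarray(data.records["outcome"]), sample_weight=w)
    nonref = [c for c in OUTCOME_LEVELS if c != spec.outcome_reference]
    probs = predict_probs(est.beta_, est._X_fit, reference=est._ref_idx,
                          n_categories=3)
    result = FitResult(
        beta=est.beta_.copy(),
        categories=list(OUTCOME_LEVELS),
        reference=spec.outcome_reference,
        nonref_categories=nonref,
        columns=list(design.columns),
        loglik=est.loglik_,
        aic=est.aic_,
        rrr=np.exp(est.beta_),
        fitted_probs=probs,
        converged=est.converged_,
        n_iter=est.n_iter_,
        weighting=weighting,
        spec=spec,
        X=design.X,
        y_idx=y_idx,
        w=(np.ones(len(design.X)) if w is None else np.asarray(w, float)),
    )
    if vcov == "jackknife":
        V = jackknife_vcov(data, spec, result.w, result)
        _attach_vcov(result, V)
    return result


def _attach_vcov(result, V):
    result.vcov = V
    K = result.beta.size
    se = np.sqrt(np.clip(np.diag(V), 0.0, None)).reshape(result.beta.shape)
    result.se = se
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, result.beta / se, np.inf * np.sign(result.beta))
    result.pvalues = 2.0 * stats.norm.sf(np.abs(z))
    assert V.shape == (K, K)


def jackknife_vcov(data, spec, w, fit_result, *, tol=1e-8, max_iter=100):
    """Delete-one-cluster jackknife covariance of the flattened beta.

    For each cluster ``c`` in stratum ``h`` (with ``n_h`` sampled
    clusters), the model is refitted without ``c`` and with the remaining
    weights in ``h`` rescaled by ``n_h/(n_h - 1)``; the covariance is

        V = sum_h (n_h - 1)/n_h * sum_{c in h} (b_(c) - b)(b_(c) - b)'

    with ``b`` the full-sample estimate. Replicates that fail to converge
    (or separate) are dropped with a warning. The flattening is row-major
    over (non-reference category, design column).
    """
    clu = data.clusters
    strata = clu.set_index("cluster_id")["stratum"]
    n_by_stratum = clu["stratum"].value_counts().to_dict()
    single = [s for s, k in n_by_stratum.items() if k < 2]
    if single:
        raise ValidationError(
            f"strata {single} contain a single cluster; collapse strata "
            "before jackknifing"
        )
    X = fit_result.X
    y_idx = fit_result.y_idx
    w = np.asarray(w, dtype=float)
    rec_cluster = data.records["cluster_id"].to_numpy()
    rec_stratum = data.records["stratum"].to_numpy()
    ref_idx = OUTCOME_LEVELS.index(fit_result.reference)
    J = len(OUTCOME_LEVELS)
    B_full = fit_result.beta
    K = B_full.size
    V = np.zeros((K, K))
    n_failed = 0
    for cid in clu["cluster_id"]:
        h = strata[cid]
        n_h = n_by_stratum[h]
        keep = rec_cluster != cid
        w_rep = w.copy()
        w_rep[rec_stratum == h] *= n_h / (n_h - 1.0)
        w_rep = w_rep[keep]
        if fit_result.weighting == "literal":
            X_rep, w_fit = X[keep] * w_rep[:, None], np.ones(keep.sum())
        elif fit_result.weighting == "none":
            X_rep, w_fit = X[keep], np.ones(keep.sum())
        else:
            X_rep, w_fit = X[keep], w_rep / w_rep.mean()
        try:
            B_c, _, _, _ = _fit_core(
                X_rep, y_idx[keep], w_fit, J, ref_idx, tol=tol,
                max_iter=max_iter, beta0=B_full,
            )
        except (ConvergenceError, SeparationError):
            n_failed += 1
            continue
        d = (B_c - B_full).ravel()
        V += ((n_h - 1.0) / n_h) * np.outer(d, d)
    if n_failed:
        warnings.warn(
            f"{n_failed} jackknife replicate(s) failed to converge and were "
            "dropped", stacklevel=2,
        )
    return V


# ---------------------------------------------------------------------------
# model selection and goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class ModelSelection:
    results: list
    table: pd.DataFrame
    best_index: int

    @property
    def best(self):
        return self.results[self.best_index]


def select_model(data, specs, w=None, *, weighting="pseudo", vcov=None,
                 **fit_kwargs):
    """Fit a ladder of specifications and pick the lowest-AIC model.

    Ties are broken by the smaller parameter count, then by position in
    the list. Specifications that fail to fit are excluded with a warning;
    an error is raised only if none fit.
    """
    specs = list(specs)
    if not specs:
        raise ValidationError("no model specifications supplied")
    results, rows = [], []
    for i, spec in enumerate(specs):
        try:
            res = fit(data, spec, w, weighting=weighting, vcov=vcov,
                      **fit_kwargs)
        except (ConvergenceError, SeparationError, ValidationError) as exc:
            warnings.warn(f"model {i} failed to fit: {exc}", stacklevel=2)
            res = None
        results.append(res)
        rows.append({
            "model": i,
            "terms": "+".join(spec.terms) if spec.terms else "intercept",
            "n_params": (res.n_params if res is not None else np.nan),
            "loglik": (res.loglik if res is not None else np.nan),
            "aic": (res.aic if res is not None else np.nan),
        })
    table = pd.DataFrame(rows)
    fitted = [i for i, r in enumerate(results) if r is not None]
    if not fitted:
        raise ConvergenceError("every candidate model failed to fit")
    # lexicographic: AIC (rounded to break float noise), params, position
    best = min(fitted, key=lambda i: (round(results[i].aic, 9),
                                      results[i].n_params, i))
    return ModelSelection(results=results, table=table, best_index=best)


def goodness_of_fit(diag, fit_result):
    """Pearson chi-square goodness-of-fit from the residual matrix.

    The statistic is the sum of squared Pearson cell residuals over every
    observation and category; degrees of freedom are n(J-1) minus the
    number of free parameters. For individual-level (single-trial) data
    the chi-square reference distribution is approximate.
    """
    r = np.asarray(diag.pearson, dtype=float)
    n, J = r.shape
    df = n * (J - 1) - fit_result.n_params
    if df <= 0:
        raise ValidationError("model is saturated; GOF degrees of freedom <= 0")
    statistic = float((r ** 2).sum())
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p
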