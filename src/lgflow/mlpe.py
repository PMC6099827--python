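"""Maximum-likelihood population-effects (MLPE) regression and model selection.

Pairwise genetic differentiation is regressed on pairwise resistance with a
linear mixed model that accounts for the non-independence of distance-matrix
data: every observation ``y_ij`` receives the random effects of *both* of its
populations,

    y_ij = beta0 + sum_k beta_k x_k,ij + u_i + u_j + eps_ij,
    u_g ~ N(0, sigma_u^2) iid,  eps_ij ~ N(0, sigma^2) iid,

so the marginal covariance is ``sigma^2 I + sigma_u^2 Z Z'`` with ``Z`` the
pair-population incidence matrix (exactly two ones per row).  The variance
ratio ``phi = sigma_u^2 / sigma^2`` is profiled out of the (restricted)
likelihood via one eigendecomposition of ``Z Z'`` per pair structure, and the
remaining one-dimensional problem is solved by bounded scalar minimization.

Model comparison uses AIC/AICc with ``p = #fixed effects + 2`` (both variance
components counted) and ``n =`` number of pairs.  ML is the default because
models differing in fixed effects are compared; REML is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .matrices import PairwiseMatrix, aligned

log = logging.getLogger(__name__)

Z975 = 1.959963984540054  # normal 97.5% quantile for Wald intervals


class MLPEError(ValueError):
    pass


class MLPERegressor(BaseEstimator, RegressorMixin):
    """Linear mixed model for pairwise (distance-matrix) data.

    Parameters
    ----------
    method : {"ML", "REML"}
        Likelihood used to estimate the variance ratio. ML by default so
        that models with different fixed effects are AIC-comparable.
    standardize : bool
        Z-score the predictor columns before fitting; coefficients are then
        standardized effect sizes.
    standardize_y : bool
        Also z-score the response (off by default).

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : fixed effects on the (possibly standardized) scale
    se_, ci_ : Wald standard errors and 95% intervals for [intercept, slopes]
    sigma_u2_, sigma2_ : variance components
    loglik_, aic_, aicc_ : fit statistics
    n_pairs_, n_groups_ : problem size
    """

    def __init__(
        self,
        method: str = "ML",
        standardize: bool = True,
        standardize_y: bool = False,
        max_log_ratio: float = 12.0,
    ):
        self.method = method
        self.standardize = standardize
        self.standardize_y = standardize_y
        self.max_log_ratio = max_log_ratio

    # ------------------------------------------------------------------
    def _profile(self, phi, X, y, lam, Qty, QtX):
        """Profiled negative log-likelihood at variance ratio phi >= 0."""
        n, p = X.shape
        w = 1.0 / (1.0 + phi * lam)  # eigenvalues of V0^{-1}
        logdet_v = float(np.sum(np.log1p(phi * lam)))
        XtVX = QtX.T @ (w[:, None] * QtX)
        XtVy = QtX.T @ (w * Qty)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        r = Qty - QtX @ beta
        quad = float(r @ (w * r))
        if quad <= 0:
            quad = 1e-300
        if self.method == "REML":
            dof = n - p
            sigma2 = quad / dof
            sign, logdet_xvx = np.linalg.slogdet(XtVX)
            ll = -0.5 * (
                dof * np.log(2 * np.pi * sigma2)
                + logdet_v
                + logdet_xvx
                + dof
            )
        else:
            sigma2 = quad / n
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_v + n)
        return -ll, beta, sigma2, XtVX

    def fit(self, X, y, pairs=None):
        """Fit the model.

        ``X``: (n_pairs, k) predictors; ``y``: (n_pairs,) response;
        ``pairs``: (n_pairs, 2) integer population indices of each pair.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if pairs is None:
            raise MLPEError("pairs (population indices per observation) required")
        pairs = np.asarray(pairs, dtype=int)
        n = len(y)
        if X.shape[0] != n or pairs.shape != (n, 2):
            raise MLPEError("X, y and pairs must agree in length")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise MLPEError("non-finite values in model input")
        groups = np.unique(pairs)
        n_groups = len(groups)
        if n_groups < 3:
            raise MLPEError("need at least three populations")
        gidx = {g: i for i, g in enumerate(groups)}

        self._x_mean = X.mean(axis=0)
        self._x_std = X.std(axis=0)
        if self.standardize:
            std = np.where(self._x_std > 0, self._x_std, 1.0)
            Xs = (X - self._x_mean) / std
        else:
            Xs = X
        self._y_mean, self._y_std = y.mean(), y.std()
        ys = (y - self._y_mean) / self._y_std if (
            self.standardize_y and self._y_std > 0
        ) else y

        Xd = np.column_stack([np.ones(n), Xs])
        Z = np.zeros((n, n_groups))
        for row, (a, b) in enumerate(pairs):
            Z[row, gidx[a]] = 1.0
            Z[row, gidx[b]] = 1.0
        K = Z @ Z.T
        lam, Q = np.linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        Qty = Q.T @ ys
        QtX = Q.T @ Xd

        def nll_of(u):
            return self._profile(np.exp(u), Xd, ys, lam, Qty, QtX)[0]

        res = optimize.minimize_scalar(
            nll_of,
            bounds=(-self.max_log_ratio, self.max_log_ratio),
            method="bounded",
            options={"xatol": 1e-10},
        )
        cand = [(res.fun, float(np.exp(res.x)))]
        cand.append((self._profile(0.0, Xd, ys, lam, Qty, QtX)[0], 0.0))
        nll, phi = min(cand, key=lambda t: t[0])
        if not np.isfinite(nll):
            raise MLPEError("likelihood optimization failed to converge")

        nll, beta, sigma2, XtVX = self._profile(phi, Xd, ys, lam, Qty, QtX)
        p_fixed = Xd.shape[1]
        cov = sigma2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.diag(cov))

        self.coef_ = beta[1:]
        self.intercept_ = float(beta[0])
        self.se_ = se
        self.ci_ = np.column_stack([beta - Z975 * se, beta + Z975 * se])
        self.sigma2_ = float(sigma2)
        self.sigma_u2_ = float(phi * sigma2)
        self.loglik_ = float(-nll)
        n_params = p_fixed + 2
        self.aic_ = float(2 * nll + 2 * n_params)
        if n - n_params - 1 > 0:
            self.aicc_ = self.aic_ + 2 * n_params * (n_params + 1) / (
                n - n_params - 1
            )
        else:
            self.aicc_ = float("inf")
        self.n_pairs_ = n
        self.n_groups_ = n_groups
        self.n_params_ = n_params
        return self

    def predict(self, X):
        """Fixed-effects-only prediction (random effects of unseen
        populations are zero by assumption)."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.standardize:
            std = np.where(self._x_std > 0, self._x_std, 1.0)
            X = (X - self._x_mean) / std
        yhat = self.intercept_ + X @ self.coef_
        if self.standardize_y and self._y_std > 0:
            yhat = yhat * self._y_std + self._y_mean
        return yhat


@dataclass
class MLPEFit:
    """A fitted MLPE model over labeled pairwise matrices."""

    predictor_names: list[str]
    model: MLPERegressor
    labels: list[str]
    pair_mask: np.ndarray = field(repr=False)

    @property
    def slopes(self) -> np.ndarray:
        return self.model.coef_

    @property
    def slope_cis(self) -> np.ndarray:
        return self.model.ci_[1:]

    @property
    def aic(self) -> float:
        return self.model.aic_

    @property
    def aicc(self) -> float:
        return self.model.aicc_

    @property
    def loglik(self) -> float:
        return self.model.loglik_

    def to_dict(self) -> dict:
        m = self.model
        return {
            "predictors": list(self.predictor_names),
            "intercept": m.intercept_,
            "coef": list(map(float, m.coef_)),
            "se": list(map(float, m.se_)),
            "ci": [list(map(float, row)) for row in m.ci_],
            "sigma_u2": m.sigma_u2_,
            "sigma2": m.sigma2_,
            "loglik": m.loglik_,
            "aic": m.aic_,
            "aicc": m.aicc_,
            "n_pairs": m.n_pairs_,
            "n_groups": m.n_groups_,
        }


def _design_from_matrices(y: PairwiseMatrix, predictors: list[PairwiseMatrix]):
    mats = aligned(y, *predictors)
    ym, preds = mats[0], mats[1:]
    pairs = ym.pair_index()
    yv = ym.condensed()
    Xcols = [p.condensed() for p in preds]
    ok = np.isfinite(yv)
    for c in Xcols:
        ok &= np.isfinite(c)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("excluding %d pairs with non-finite entries", n_dropped)
    X = np.column_stack(Xcols)[ok]
    return X, yv[ok], pairs[ok], ym.labels, ok


def fit_mlpe(
    y: PairwiseMatrix,
    predictors: list[PairwiseMatrix],
    names: list[str] | None = None,
    standardize: bool = True,
    method: str = "ML",
) -> MLPEFit:
    """Fit GenDist ~ predictors with MLPE random effects."""
    if names is None:
        names = [p.statistic for p in predictors]
    X, yv, pairs, labels, ok = _design_from_matrices(y, predictors)
    model = MLPERegressor(method=method, standardize=standardize)
    model.fit(X, yv, pairs=pairs)
    return MLPEFit(list(names), model, labels, ok)


def model_table(fits: dict) -> pd.DataFrame:
    """AICc ranking table: label -> MLPEFit, including the distance null.

    Columns: surface, AICc, dAICc, weight, cum_weight, loglik — the layout
    used for reporting top models of pairwise differentiation.
    """
    rows = [
        {"surface": label, "AICc": f.aicc, "loglik": f.loglik}
        for label, f in fits.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["AICc", "surface"], kind="mergesort", ignore_index=True
    )
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["dAICc"].to_numpy())
    df["weight"] = rel / rel.sum()
    df["cum_weight"] = df["weight"].cumsum()
    return df[["surface", "AICc", "dAICc", "weight", "cum_weight", "loglik"]]


@dataclass
class SignificanceDecision:
    significant: bool
    ci_single: tuple
    ci_with_distance: tuple
    collinear: bool
    fit_single: MLPEFit
    fit_both: MLPEFit | None


def significance_over_distance(
    y: PairwiseMatrix,
    rd: PairwiseMatrix,
    geo_null: PairwiseMatrix,
    method: str = "ML",
    collinearity_r: float = 0.999,
) -> SignificanceDecision:
    """Two-model significance rule for a resistance predictor.

    The predictor is significant when the 95% CI of its standardized
    coefficient stays above zero both in ``y ~ RD`` and in
    ``y ~ RD + distance``.  A predictor (near-)identical to the null is
    flagged collinear and declared not significant.
    """
    fit1 = fit_mlpe(y, [rd], names=["rd"], method=method)
    va, vb = rd.condensed(), aligned(rd, geo_null)[1].condensed()
    ok = np.isfinite(va) & np.isfinite(vb)
    r = (
        float(np.corrcoef(va[ok], vb[ok])[0, 1])
        if np.std(va[ok]) > 0 and np.std(vb[ok]) > 0
        else 1.0
    )
    if abs(r) > collinearity_r:
        log.warning("resistance predictor collinear with distance (r=%.4f)", r)
        return SignificanceDecision(
            False, tuple(fit1.slope_cis[0]), (np.nan, np.nan), True, fit1, None
        )
    fit2 = fit_mlpe(y, [rd, geo_null], names=["rd", "distance"], method=method)
    lo1 = fit1.slope_cis[0][0]
    lo2 = fit2.slope_cis[0][0]
    return SignificanceDecision(
        bool(lo1 > 0 and lo2 > 0),
        tuple(fit1.slope_cis[0]),
        tuple(fit2.slope_cis[0]),
        False,
        fit1,
        fit2,
    )


@dataclass
class WithinVariableResult:
    best_label: str
    best_fit: MLPEFit
    delta_aic_vs_distance: float
    decision: SignificanceDecision
    table: pd.DataFrame
    null_correlations: dict


def within_variable_selection(
    y: PairwiseMatrix,
    candidates: dict,
    geo_null: PairwiseMatrix,
    method: str = "ML",
) -> WithinVariableResult:
    """Pick the best threshold/resistance surface for one variable.

    ``candidates``: surface label -> resistance PairwiseMatrix (normally six:
    three thresholds x two resistance values).  The best candidate by AIC of
    ``y ~ RD`` is then tested for significance over distance; the audit also
    records each candidate's correlation with the geographic null.
    """
    if not candidates:
        raise MLPEError("no candidate surfaces")
    fits = {}
    for label in sorted(candidates):
        fits[label] = fit_mlpe(y, [candidates[label]], names=["rd"], method=method)
    null_fit = fit_mlpe(y, [geo_null], names=["distance"], method=method)
    fits_table = dict(fits)
    fits_table["distance"] = null_fit
    table = model_table(fits_table)
    ranked = sorted(fits, key=lambda lab: (fits[lab].aic, lab))
    best = ranked[0]
    decision = significance_over_distance(
        y, candidates[best], geo_null, method=method
    )
    corrs = {}
    for label in sorted(candidates):
        va = candidates[label].condensed()
        vb = aligned(candidates[label], geo_null)[1].condensed()
        ok = np.isfinite(va) & np.isfinite(vb)
        corrs[label] = (
            float(np.corrcoef(va[ok], vb[ok])[0, 1])
            if np.std(va[ok]) > 0 and np.std(vb[ok]) > 0
            else 1.0
        )
    return WithinVariableResult(
        best_label=best,
        best_fit=fits[best],
        delta_aic_vs_distance=float(null_fit.aic - fits[best].aic),
        decision=decision,
        table=table,
        null_correlations=corrs,
    )


def between_variable_selection(
    y: PairwiseMatrix,
    candidates: dict,
    geo_null: PairwiseMatrix,
    method: str = "ML",
) -> pd.DataFrame:
    """Rank the retained predictors (significant landscape variables, the
    additive combined surface, habitat surfaces) against the distance null
    in one AICc table."""
    if not candidates:
        raise MLPEError("no candidate predictors")
    fits = {
        label: fit_mlpe(y, [m], names=[label], method=method)
        for label, m in sorted(candidates.items())
    }
    fits["distance"] = fit_mlpe(y, [geo_null], names=["distance"], method=method)
    return model_table(fits)
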