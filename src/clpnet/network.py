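"""Cross-lagged panel network (CLPN) estimation by node-wise LASSO.

Each of the 24 wave-2 node scores is regressed on all 24 wave-1 node scores
plus socio-demographic covariates with an L1 penalty; the coefficient
vectors are assembled column-wise into the directed weight matrix W, where
``W[i, j]`` is the standardized lagged effect of wave-1 node i on wave-2
node j and the diagonal holds the autoregressive effects.

Covariates adjust but never shrink by default: they are projected out of the
response and the wave-1 predictors before the LASSO (exact for a partially
penalized L1 objective, by Frisch–Waugh–Lovell) and their coefficients are
recovered by ordinary least squares afterwards. They never enter W.

The penalty weight lambda follows scikit-learn's convention, i.e. the
objective per node is ``(1/2n) * ||y - X b||^2 + lambda * ||b||_1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from . import nodes as _nd
from .scoring import NodeScores


# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass
class FitConfig:
    """Node-wise regression settings for CLPN estimation."""

    penalty: str = "lasso"
    lambda_selection: str = "cv_min"  # {cv_min, cv_1se, fixed}
    cv_folds: int = 10
    seed: int = 0
    standardize: bool = True
    penalize_covariates: bool = False
    fixed_lambda: float | None = None
    n_alphas: int = 100
    max_iter: int = 10000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.penalty != "lasso":
            raise ValueError("only the lasso penalty is supported")
        if self.lambda_selection not in {"cv_min", "cv_1se", "fixed"}:
            raise ValueError(f"unknown lambda_selection {self.lambda_selection!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_selection == "fixed":
            if self.fixed_lambda is None or self.fixed_lambda < 0:
                raise ValueError("fixed lambda_selection needs fixed_lambda >= 0")


@dataclass
class CLPNetwork:
    """Directed 24x24 cross-lagged weight matrix with metadata."""

    weights: np.ndarray  # W[i, j]: wave-1 node i -> wave-2 node j
    node_labels: list[str]
    construct_labels: list[str]
    lambdas: np.ndarray  # selected penalty per outcome node
    n: int
    covariate_coefs: pd.DataFrame | None = None  # covariates x nodes

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.node_labels)
        if self.weights.shape != (p, p):
            raise ValueError(f"weights must be {p}x{p}")
        if not np.isfinite(self.weights).all():
            raise ValueError("network weights must be finite")
        if len(self.construct_labels) != p:
            raise ValueError("construct labels must match node labels")

    @property
    def autoregressive(self) -> np.ndarray:
        return np.diag(self.weights).copy()

    @property
    def cross_lagged(self) -> np.ndarray:
        """W with the autoregressive diagonal zeroed (a copy)."""
        w = self.weights.copy()
        np.fill_diagonal(w, 0.0)
        return w

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.node_labels, columns=self.node_labels
        )

    def node_index(self, node: str) -> int:
        try:
            return self.node_labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None


@dataclass
class NodeFit:
    """One node-wise regression: lagged coefficients and adjustment terms."""

    coef: np.ndarray
    lambda_: float
    covariate_coef: np.ndarray
    covariate_names: list[str]


# ---------------------------------------------------------------------------
# building blocks


def standardize_nodes(scores):
    """Z-score every node column (population SD). Idempotent.

    Accepts and returns a :class:`NodeScores`, DataFrame or ndarray. Raises
    on zero-variance columns, naming the offending node.
    """
    if isinstance(scores, NodeScores):
        return NodeScores(scores.wave, standardize_nodes(scores.data))
    if isinstance(scores, pd.DataFrame):
        x = scores.to_numpy(dtype=float)
        labels = list(scores.columns)
    else:
        x = np.asarray(scores, dtype=float)
        labels = [str(i) for i in range(x.shape[1])]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population convention (ddof=0)
    dead = np.flatnonzero(sd <= 0)
    if dead.size:
        raise ValueError(
            f"zero-variance node column(s): {[labels[i] for i in dead]}"
        )
    z = (x - mu) / sd
    if isinstance(scores, pd.DataFrame):
        return pd.DataFrame(z, index=scores.index, columns=scores.columns)
    return z


def _encode_covariates(covariates) -> tuple[np.ndarray, list[str]]:
    """Dummy-code categoricals (first level reference) and z-score columns."""
    if covariates is None:
        return np.zeros((0, 0)), []
    df = pd.DataFrame(covariates)
    df = pd.get_dummies(df, drop_first=True, dtype=float)
    z = df.to_numpy(dtype=float)
    mu, sd = z.mean(axis=0), z.std(axis=0)
    keep = sd > 0
    z = (z[:, keep] - mu[keep]) / sd[keep]
    return z, [c for c, k in zip(df.columns, keep) if k]


def _select_and_fit(y, x, config: FitConfig, node_seed: int):
    """Return (coef, lambda) for one residualized node regression."""
    if config.lambda_selection == "fixed":
        lam = float(config.fixed_lambda)
        if lam == 0.0:
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            return coef, 0.0
        model = Lasso(
            alpha=lam, fit_intercept=False, precompute=True,
            max_iter=config.max_iter, tol=config.tol,
        ).fit(x, y)
        return model.coef_, lam

    folds = KFold(config.cv_folds, shuffle=True, random_state=node_seed)
    cv = LassoCV(
        alphas=config.n_alphas, cv=folds, fit_intercept=False,
        max_iter=config.max_iter, tol=config.tol,
    ).fit(x, y)
    if config.lambda_selection == "cv_min":
        return cv.coef_, float(cv.alpha_)
    # cv_1se: largest lambda within one standard error of the minimum
    mean = cv.mse_path_.mean(axis=1)
    se = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
    i_min = int(np.argmin(mean))
    ok = np.flatnonzero(mean <= mean[i_min] + se[i_min])
    lam = float(cv.alphas_[ok.min()])  # alphas_ is decreasing
    model = Lasso(
        alpha=lam, fit_intercept=False, precompute=True,
        max_iter=config.max_iter, tol=config.tol,
    ).fit(x, y)
    return model.coef_, lam


def fit_node_regression(
    y: np.ndarray,
    x: np.ndarray,
    covariates=None,
    config: FitConfig | None = None,
    node_seed: int | None = None,
) -> NodeFit:
    """L1-penalized regression of one wave-2 node on the wave-1 nodes.

    ``y`` and ``x`` are assumed already standardized when the caller wants
    standardized weights. Covariates (plus an implicit intercept) are
    unpenalized by default: both y and x are projected onto their orthogonal
    complement before the LASSO, and the covariate coefficients are
    recovered by OLS on the lasso residual. With
    ``config.penalize_covariates`` they instead enter the penalized design.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("x must be a 2-d matrix with at least one column")
    n = len(y)
    if config.lambda_selection != "fixed" and n <= 2 * config.cv_folds:
        raise ValueError("need n > 2 * cv_folds for cross-validation")
    sd = x.std(axis=0)
    if (sd <= 0).any():
        raise ValueError(
            f"degenerate predictor column(s) at index {np.flatnonzero(sd <= 0).tolist()}"
        )
    z, znames = _encode_covariates(covariates)
    seed = config.seed if node_seed is None else node_seed

    if config.penalize_covariates and z.size:
        design = np.hstack([x, z])
        coef_all, lam = _select_and_fit(y - y.mean(), design - design.mean(axis=0), config, seed)
        return NodeFit(coef_all[: x.shape[1]], lam, coef_all[x.shape[1]:], znames)

    zc = np.hstack([np.ones((n, 1)), z]) if z.size else np.ones((n, 1))
    beta_z, *_ = np.linalg.lstsq(zc, np.column_stack([y, x]), rcond=None)
    resid = np.column_stack([y, x]) - zc @ beta_z
    yr, xr = resid[:, 0], resid[:, 1:]
    coef, lam = _select_and_fit(yr, xr, config, seed)
    gamma, *_ = np.linalg.lstsq(zc, y - x @ coef, rcond=None)
    return NodeFit(coef, lam, gamma[1:], znames)


# ---------------------------------------------------------------------------
# the estimator


class CrossLaggedPanelNetwork(RegressorMixin, BaseEstimator):
    """Node-wise LASSO estimator of a cross-lagged panel network.

    Fit with ``fit(X, Y, covariates=...)`` where ``X`` holds the wave-1 node
    scores (n x 24) and ``Y`` the wave-2 node scores, same participants and
    order. Both are z-scored internally by default so edge weights are
    comparable across nodes.

    Parameters mirror :class:`FitConfig`; ``random_state`` seeds the
    cross-validation folds (one derived seed per outcome node).

    Attributes
    ----------
    W_ : ndarray of shape (p, p)
        ``W_[i, j]`` is the lagged effect of node i on node j; the diagonal
        holds autoregressive effects.
    lambdas_ : ndarray of shape (p,)
        Selected penalty per outcome node.
    covariate_coefs_ : DataFrame (covariates x nodes)
        Unpenalized adjustment coefficients; excluded from ``W_``.
    """

    def __init__(
        self,
        lambda_selection: str = "cv_min",
        cv_folds: int = 10,
        fixed_lambda: float | None = None,
        standardize: bool = True,
        penalize_covariates: bool = False,
        n_alphas: int = 100,
        max_iter: int = 10000,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.lambda_selection = lambda_selection
        self.cv_folds = cv_folds
        self.fixed_lambda = fixed_lambda
        self.standardize = standardize
        self.penalize_covariates = penalize_covariates
        self.n_alphas = n_alphas
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            lambda_selection=self.lambda_selection,
            cv_folds=self.cv_folds,
            seed=self.random_state,
            standardize=self.standardize,
            penalize_covariates=self.penalize_covariates,
            fixed_lambda=self.fixed_lambda,
            n_alphas=self.n_alphas,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    @staticmethod
    def _coerce(block, default_prefix):
        if isinstance(block, NodeScores):
            return block.data.to_numpy(dtype=float), list(block.data.columns)
        if isinstance(block, pd.DataFrame):
            return block.to_numpy(dtype=float), list(block.columns)
        arr = np.asarray(block, dtype=float)
        return arr, [f"{default_prefix}{i}" for i in range(arr.shape[1])]

    def fit(self, X, y=None, *, covariates=None, construct_labels=None):
        """Fit one penalized regression per wave-2 node and assemble W."""
        config = self._config()
        x, labels = self._coerce(X, "node")
        yv, ylabels = self._coerce(y, "node")
        if x.shape != yv.shape:
            raise ValueError(
                f"wave-1 {x.shape} and wave-2 {yv.shape} shapes differ"
            )
        if isinstance(X, (pd.DataFrame, NodeScores)) and isinstance(
            y, (pd.DataFrame, NodeScores)
        ):
            xi = X.data.index if isinstance(X, NodeScores) else X.index
            yi = y.data.index if isinstance(y, NodeScores) else y.index
            if not xi.equals(yi):
                raise ValueError("participant indices differ between waves")
        if np.isnan(x).any() or np.isnan(yv).any():
            raise ValueError("node scores contain missing values; use complete cases")
        if labels != ylabels:
            raise ValueError("node labels differ between waves")
        if construct_labels is None:
            construct_labels = (
                list(_nd.CONSTRUCT_LABELS)
                if labels == list(_nd.NODE_LABELS)
                else ["all"] * len(labels)
            )

        if config.standardize:
            x = standardize_nodes(pd.DataFrame(x, columns=labels)).to_numpy()
            yv = standardize_nodes(pd.DataFrame(yv, columns=labels)).to_numpy()

        p = x.shape[1]
        w = np.zeros((p, p))
        lambdas = np.zeros(p)
        cov_rows = None
        for j in range(p):
            node_seed = (config.seed * 1000003 + j) % (2**31)
            try:
                nf = fit_node_regression(
                    yv[:, j], x, covariates, config, node_seed=node_seed
                )
            except Exception as exc:
                raise RuntimeError(
                    f"node-wise regression failed for node {labels[j]!r}: {exc}"
                ) from exc
            w[:, j] = nf.coef
            lambdas[j] = nf.lambda_
            if cov_rows is None:
                cov_rows = np.zeros((len(nf.covariate_coef), p))
                cov_names = nf.covariate_names
            cov_rows[:, j] = nf.covariate_coef

        self.W_ = w
        self.lambdas_ = lambdas
        self.node_labels_ = labels
        self.construct_labels_ = list(construct_labels)
        self.n_samples_ = x.shape[0]
        self.n_features_in_ = p
        self.covariate_coefs_ = (
            pd.DataFrame(cov_rows, index=cov_names, columns=labels)
            if cov_rows is not None and cov_rows.size
            else None
        )
        return self

    @property
    def network_(self) -> CLPNetwork:
        return CLPNetwork(
            weights=self.W_,
            node_labels=self.node_labels_,
            construct_labels=self.construct_labels_,
            lambdas=self.lambdas_,
            n=self.n_samples_,
            covariate_coefs=self.covariate_coefs_,
        )

    def predict(self, X):
        """Predicted standardized wave-2 node scores (adjustments at mean)."""
        if not hasattr(self, "W_"):
            raise RuntimeError("estimator is not fitted")
        x, _ = self._coerce(X, "node")
        if self.standardize:
            x = (x - x.mean(axis=0)) / x.std(axis=0)
        return x @ self.W_


# ---------------------------------------------------------------------------
# functional surface


def fit_clpn(
    wave1, wave2, covariates=None, config: FitConfig | None = None
) -> CLPNetwork:
    """Estimate the CLPN from two waves of node scores (complete cases)."""
    config = config or FitConfig()
    est = CrossLaggedPanelNetwork(
        lambda_selection=config.lambda_selection,
        cv_folds=config.cv_folds,
        fixed_lambda=config.fixed_lambda,
        standardize=config.standardize,
        penalize_covariates=config.penalize_covariates,
        n_alphas=config.n_alphas,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
    )
    est.fit(wave1, wave2, covariates=covariates)
    return est.network_


def display_threshold(net: CLPNetwork, threshold: float = 0.05) -> pd.DataFrame:
    """Edge list with |weight| >= threshold, for plotting/export only.

    The network itself is never modified; the default 0.05 matches the
    usual visual-clarity cut for dense panel networks.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = []
    p = len(net.node_labels)
    for i in range(p):
        for j in range(p):
            wij = net.weights[i, j]
            if wij != 0 and abs(wij) >= threshold:
                rows.append(
                    {
                        "source": net.node_labels[i],
                        "target": net.node_labels[j],
                        "weight": wij,
                        "source_construct": net.construct_labels[i],
                        "target_construct": net.construct_labels[j],
                        "autoregressive": i == j,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "source", "target", "weight",
            "source_construct", "target_construct", "autoregressive",
        ],
    )
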