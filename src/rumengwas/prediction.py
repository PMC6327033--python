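"""Cross-population phenotype prediction with an L1-penalized linear model.

The model is y_i = y_0 + x_i beta + e_i with beta estimated by minimizing

    O_lambda(y, X; beta) = 1/2 ||y - X beta||^2 + n * lambda * ||beta||_1

(n = training-set size), solved by cyclic coordinate descent with
soft-thresholding on z-standardized features; coefficients are mapped back to
the original CPM scale.  Validation animals are scored as
yhat* = y_0 + x* beta-hat and accuracy is the Pearson correlation between
predicted and observed phenotypes.  The observed accuracy is benchmarked
against a null distribution obtained by refitting the model on random contig
subsets of the same size drawn from the full post-prevalence-filter universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AbundanceMatrix, DataError

logger = logging.getLogger("rumengwas")


# ---------------------------------------------------------------------------
# LASSO coordinate descent
# ---------------------------------------------------------------------------

@dataclass
class LassoModel:
    intercept: float
    coefficients: pd.Series          # nonzero coefficients on the original scale
    lam: float
    n_train: int
    feature_ids: list                # full training feature set, in order
    feature_means: np.ndarray
    feature_sds: np.ndarray
    residual_sd: float

    @property
    def n_active(self) -> int:
        return int((self.coefficients != 0).sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        beta = self.coefficients.reindex(self.feature_ids, fill_value=0.0).to_numpy()
        return self.intercept + X @ beta


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every coefficient is exactly zero.

    Computed on standardized features: max_j |x_j^T (y - ybar)| / n.
    """
    Xs, _, sd = _standardize(np.asarray(X, dtype=float))
    yc = y - y.mean()
    grad = np.abs(Xs.T @ yc)
    grad[sd == 0] = 0.0
    return float(grad.max() / len(y))


def _cd_solve(Xs: np.ndarray, yc: np.ndarray, lam: float,
              tol: float = 1e-8, max_sweeps: int = 2000,
              check_objective: bool = False,
              beta0: np.ndarray | None = None,
              gram: np.ndarray | None = None,
              xty: np.ndarray | None = None,
              criterion: str = "coef",
              yty: float | None = None) -> np.ndarray:
    """Cyclic coordinate descent on standardized X, centered y.

    Uses Gram-matrix (covariance) updates: with G = X^T X and q = X^T y, the
    coordinate gradient is rho_j = q_j - G_j beta + G_jj beta_j and the update
    beta_j <- S(rho_j, n*lam) / G_jj.  ``beta0`` warm-starts the solve.

    Convergence ``criterion``: ``coef`` stops when the largest coefficient
    change in a sweep is below ``tol`` (the strict rule used for final fits);
    ``fit`` stops when the largest per-coordinate change in fitted values,
    max_j G_jj * delta_j^2, drops below tol * ||y||^2 — robust when
    correlated columns make the coefficient split wander while the fit is
    already converged (used inside cross-validation paths).
    """
    n, p = Xs.shape
    G = gram if gram is not None else Xs.T @ Xs
    q = xty if xty is not None else Xs.T @ yc
    diag = np.diag(G).copy()
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    gb = G @ beta if beta0 is not None else np.zeros(p)  # G @ beta, kept in sync
    thresh = n * lam
    fit_tol = tol * (yty if yty is not None else float(yc @ yc))
    prev_obj = math.inf
    for sweep in range(max_sweeps):
        max_delta = 0.0
        max_fit_delta = 0.0
        for j in range(p):
            if diag[j] == 0:
                continue
            rho = q[j] - gb[j] + diag[j] * beta[j]
            new = math.copysign(max(abs(rho) - thresh, 0.0), rho) / diag[j]
            delta = new - beta[j]
            if delta != 0.0:
                gb += delta * G[:, j]
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
                max_fit_delta = max(max_fit_delta, diag[j] * delta * delta)
        if check_objective:
            r = yc - Xs @ beta
            obj = 0.5 * float(r @ r) + thresh * float(np.abs(beta).sum())
            assert obj <= prev_obj + 1e-9, "coordinate descent increased the objective"
            prev_obj = obj
        if criterion == "fit":
            if max_fit_delta < fit_tol:
                break
        elif max_delta < tol:
            break
    else:
        logger.debug("coordinate descent hit max_sweeps=%d (lam=%g, tol=%g)",
                     max_sweeps, lam, tol)
    return beta


def _cd_path(Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray,
             tol: float = 1e-7) -> np.ndarray:
    """Warm-started solutions along a descending penalty path; rows align with lambdas."""
    n, p = Xs.shape
    G = Xs.T @ Xs
    q = Xs.T @ yc
    yty = float(yc @ yc)
    betas = np.empty((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = _cd_solve(Xs, yc, lam, tol=tol, beta0=beta, gram=G, xty=q,
                         criterion="fit", yty=yty, max_sweeps=500)
        betas[i] = beta
    return betas


def fit_lasso(X: pd.DataFrame | np.ndarray, y: np.ndarray, lam: float,
              feature_ids=None, tol: float = 1e-8, debug: bool = False) -> LassoModel:
    """Fit the L1-penalized linear model at penalty ``lam`` (> 0).

    Features are z-standardized internally and coefficients mapped back to the
    original scale; the intercept absorbs the centering.  ``debug=True``
    asserts the objective never increases across sweeps.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = list(range(X.shape[1]))
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise DataError("non-finite values in LASSO inputs")
    if lam <= 0:
        raise DataError("lambda must be > 0 (use a tiny lambda explicitly for an OLS-like fit)")
    n = len(y)
    if n < 3:
        raise DataError("need at least 3 training animals")
    Xs, mu, sd = _standardize(X)
    Xs[:, sd == 0] = 0.0
    ybar = y.mean()
    yc = y - ybar
    # warm start down a short geometric path from lambda_max (glmnet-style)
    lmax = float(np.abs(Xs.T @ yc).max() / n) if Xs.size else 0.0
    beta_std = np.zeros(Xs.shape[1])
    if lmax > lam:
        for step in np.geomspace(lmax, lam, 8)[1:-1]:
            beta_std = _cd_solve(Xs, yc, float(step), tol=1e-4, beta0=beta_std)
    beta_std = _cd_solve(Xs, yc, lam, tol=tol, beta0=beta_std, check_objective=debug)
    sd_safe = np.where(sd == 0, 1.0, sd)
    beta = beta_std / sd_safe
    intercept = ybar - float(mu @ beta)
    resid = y - (intercept + X @ beta)
    nonzero = pd.Series(beta, index=feature_ids)
    nonzero = nonzero[nonzero != 0.0]
    return LassoModel(
        intercept=float(intercept), coefficients=nonzero, lam=float(lam),
        n_train=n, feature_ids=list(feature_ids), feature_means=mu,
        feature_sds=sd, residual_sd=float(np.std(resid, ddof=0)),
    )


def kkt_violation(model: LassoModel, X: pd.DataFrame | np.ndarray, y: np.ndarray) -> float:
    """Largest KKT violation at the fitted solution, on the standardized scale.

    Zero coefficients require |x_j^T r| <= n*lambda; active ones require
    x_j^T r = n*lambda*sign(beta_j).  Returns the max absolute violation.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, _, sd = _standardize(X)
    Xs[:, sd == 0] = 0.0
    beta_std = model.coefficients.reindex(model.feature_ids, fill_value=0.0).to_numpy() \
        * np.where(sd == 0, 1.0, sd)
    r = (y - y.mean()) - Xs @ beta_std
    grad = Xs.T @ r
    nl = model.n_train * model.lam
    viol = np.where(beta_std == 0.0,
                    np.maximum(np.abs(grad) - nl, 0.0),
                    np.abs(grad - nl * np.sign(beta_std)))
    viol[sd == 0] = 0.0
    return float(viol.max()) if len(viol) else 0.0


# ---------------------------------------------------------------------------
# Penalty selection
# ---------------------------------------------------------------------------

def lambda_grid(X, y, n_points: int = 30, decades: float = 4.0) -> np.ndarray:
    lmax = lambda_max(X, y)
    if lmax == 0:
        return np.array([1e-8])
    return np.geomspace(lmax, lmax * 10 ** (-decades), n_points)


def select_lambda(X: pd.DataFrame | np.ndarray, y: np.ndarray, strategy: str = "cv",
                  folds: int = 5, seed: int = 0, fixed_value: float | None = None,
                  n_points: int = 30) -> float:
    """Choose the penalty by k-fold cross-validation, or pass a fixed value through.

    The CV grid runs on a log scale from lambda_max down 4 decades; the value
    minimizing mean out-of-fold squared error wins (ties to the larger,
    sparser, penalty since the grid descends).
    """
    if strategy == "fixed":
        if fixed_value is None or fixed_value <= 0:
            raise DataError("fixed strategy needs a positive lambda value")
        return float(fixed_value)
    if strategy != "cv":
        raise DataError(f"unknown lambda strategy {strategy!r}")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds > n:
        raise DataError(f"folds={folds} exceeds n={n}")
    grid = lambda_grid(X, y, n_points=n_points)
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(n) % folds
    errs = np.zeros((folds, len(grid)))
    for f in range(folds):
        test = assignment == f
        Xtr, ytr = X[~test], y[~test]
        Xte, yte = X[test], y[test]
        Xs, mu, sd = _standardize(Xtr)
        Xs[:, sd == 0] = 0.0
        ybar = ytr.mean()
        betas_std = _cd_path(Xs, ytr - ybar, grid, tol=1e-6)
        sd_safe = np.where(sd == 0, 1.0, sd)
        for g in range(len(grid)):
            beta = betas_std[g] / sd_safe
            pred = ybar - mu @ beta + Xte @ beta
            errs[f, g] = float(np.mean((yte - pred) ** 2))
    mean_err = errs.mean(axis=0)
    return float(grid[int(np.argmin(mean_err))])


# ---------------------------------------------------------------------------
# Validation and the random-contig null
# ---------------------------------------------------------------------------

def align_validation(model: LassoModel, Xval: AbundanceMatrix | pd.DataFrame) -> np.ndarray:
    """Validation design aligned to the training feature set by id.

    Features missing from the validation matrix are imputed as 0 CPM; the
    mapped fraction is logged.
    """
    df = Xval.data if isinstance(Xval, AbundanceMatrix) else Xval
    present = [f for f in model.feature_ids if f in df.columns]
    if len(present) < len(model.feature_ids):
        logger.info("validation set maps %d/%d training features (%.0f%%); rest zero-filled",
                    len(present), len(model.feature_ids),
                    100 * len(present) / len(model.feature_ids))
    aligned = df.reindex(columns=model.feature_ids, fill_value=0.0)
    return aligned.to_numpy(dtype=float)


def predict_validation(model: LassoModel, Xval: AbundanceMatrix | pd.DataFrame,
                       yval: np.ndarray) -> tuple[float, np.ndarray]:
    """Predict the validation phenotypes and score by Pearson correlation.

    Returns (r, predictions); r is NaN (all-shrunk model, zero-variance
    predictions) with a log message when correlation is undefined.
    """
    X = align_validation(model, Xval)
    yval = np.asarray(yval, dtype=float)
    pred = model.predict(X)
    if np.ptp(pred) == 0 or np.ptp(yval) == 0:
        logger.info("validation accuracy undefined: zero variance in %s",
                       "predictions (all coefficients shrunk to zero)" if np.ptp(pred) == 0
                       else "observed phenotypes")
        return float("nan"), pred
    r = float(stats.pearsonr(pred, yval)[0])
    return r, pred


@dataclass
class NullDistribution:
    """Validation accuracies from random same-size contig subsets."""

    accuracies: np.ndarray
    subset_size: int
    observed: float
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.accuracies)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.accuracies, ddof=1))

    @property
    def interval95(self) -> tuple[float, float]:
        lo, hi = np.nanquantile(self.accuracies, [0.025, 0.975])
        return float(lo), float(hi)

    @property
    def observed_percentile(self) -> float:
        """Percentile rank of the observed accuracy within the null sample."""
        acc = self.accuracies[~np.isnan(self.accuracies)]
        return float(100.0 * np.mean(acc <= self.observed))

    @property
    def n_undefined(self) -> int:
        """Replicates whose model shrank to intercept-only (undefined r, excluded)."""
        return int(np.isnan(self.accuracies).sum())

    def summary(self) -> dict:
        lo, hi = self.interval95
        return {
            "n_replicates": self.n_replicates, "n_undefined": self.n_undefined,
            "subset_size": self.subset_size,
            "mean": self.mean, "sd": self.sd, "q2.5": lo, "q97.5": hi,
            "observed": self.observed, "observed_percentile": self.observed_percentile,
        }


def random_contig_null(Xtrain: AbundanceMatrix | pd.DataFrame, y: np.ndarray,
                       Xval: AbundanceMatrix | pd.DataFrame, yval: np.ndarray,
                       subset_size: int, observed: float,
                       n_replicates: int = 1000, seed: int = 0,
                       lambda_strategy: str = "cv", lambda_value: float | None = None,
                       cv_folds: int = 5, cv_points: int = 30) -> NullDistribution:
    """Null distribution of validation accuracy from random contig subsets.

    Per replicate: sample ``subset_size`` contigs uniformly without replacement
    from the full training feature universe, refit the LASSO (same penalty
    strategy), and record the validation Pearson r.
    """
    dtr = Xtrain.data if isinstance(Xtrain, AbundanceMatrix) else Xtrain
    dval = Xval.data if isinstance(Xval, AbundanceMatrix) else Xval
    p = dtr.shape[1]
    if subset_size > p:
        raise DataError(f"subset_size {subset_size} exceeds {p} available features")
    y = np.asarray(y, dtype=float)
    yval = np.asarray(yval, dtype=float)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_replicates)
    for rep in range(n_replicates):
        idx = rng.choice(p, size=subset_size, replace=False)
        cols = dtr.columns[idx]
        Xsub = dtr.loc[:, cols]
        cv_seed = int(rng.integers(2 ** 31)) if lambda_strategy == "cv" else 0
        lam = select_lambda(Xsub, y, strategy=lambda_strategy,
                            fixed_value=lambda_value, folds=cv_folds,
                            seed=cv_seed, n_points=cv_points)
        model = fit_lasso(Xsub, y, lam, tol=1e-6)
        r, _ = predict_validation(model, dval, yval)
        accs[rep] = r
    return NullDistribution(accuracies=accs, subset_size=subset_size,
                            observed=float(observed), seed=seed)


def write_model_tsv(model: LassoModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# intercept\t{model.intercept!r}\n")
        fh.write(f"# lambda\t{model.lam!r}\n")
        fh.write(f"# n_train\t{model.n_train}\n")
        fh.write("feature_id\tcoefficient\n")
        for fid, b in model.coefficients.items():
            fh.write(f"{fid}\t{b!r}\n")


def write_null_tsv(null: NullDistribution, path) -> None:
    with open(path, "w") as fh:
        for key, val in null.summary().items():
            fh.write(f"# {key}\t{val}\n")
        fh.write("replicate\taccuracy\n")
        for i, a in enumerate(null.accuracies):
            fh.write(f"{i}\t{a!r}\n")
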