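"""Genomic prediction by RR-BLUP with optional fixed covariates.

All markers enter as random effects with a common variance,

    y = X beta + Z u + e,   u ~ N(0, I sigma_u^2),  e ~ N(0, I sigma_e^2),

which is the ridge regression BLUP (equivalently GBLUP with the
genomic relationship Z Z').  Fixed covariates X can carry an
intercept, a major-QTL dosage and/or a measured surrogate trait such
as SPAD greenness.  The shrinkage ratio lambda = sigma_e^2 / sigma_u^2
is estimated by REML on the spectral form of Z Z', or fixed by the
caller.  Accuracy is evaluated by k-fold cross-validation as the
Pearson correlation between trait BLUPs and out-of-fold predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._mixed import fit_variance_components

__all__ = ["RRBLUP", "RRBLUPResults", "CVResult", "cross_validate",
           "marker_effect_profile", "run_prediction_models"]


class RRBLUP:
    """Ridge-regression BLUP model.

    Parameters
    ----------
    y : (n,) array
        Trait values (typically line BLUPs).
    Z : (n, m) array
        Marker dosages; columns are centered internally (the centering
        constant is absorbed by the intercept).
    X : (n, q) array, optional
        Fixed-effect design; defaults to an intercept-only column.
        Must be full column rank.
    """

    def __init__(self, y, Z, X=None):
        self.y = np.asarray(y, dtype=float).ravel()
        Zr = np.asarray(Z, dtype=float)
        if Zr.ndim != 2 or Zr.shape[0] != self.y.size:
            raise ValueError("Z must be (n, m) with rows matching y")
        self._z_means = Zr.mean(axis=0)
        self.Z = Zr - self._z_means
        if X is None:
            X = np.ones((self.y.size, 1))
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows must match y")
        r = np.linalg.matrix_rank(self.X)
        if r < self.X.shape[1]:
            # identify a collinear column for the error message
            bad = []
            for j in range(1, self.X.shape[1] + 1):
                if np.linalg.matrix_rank(self.X[:, :j]) < j:
                    bad.append(j - 1)
            raise ValueError(f"fixed design X is rank deficient (columns {bad})")
        if self.y.size < 2 * self.X.shape[1]:
            raise ValueError("need n >= 2 * number of fixed-effect columns")

    def fit(self, lambda_: float | None = None, eig=None) -> "RRBLUPResults":
        """Solve the mixed-model equations.

        With ``lambda_`` given, (beta, u) are the exact fixed-ratio
        solution u = Z'(ZZ' + lambda I)^(-1) (y - X beta); otherwise
        lambda is first estimated by REML on the spectral form of ZZ'.
        """
        Z, X, y = self.Z, self.X, self.y
        G = Z @ Z.T
        if lambda_ is None:
            res = fit_variance_components(y, X, G=G, eig=eig)
            sigma_u2, sigma_e2 = res["Vg"], res["Ve"]
            lam = res["delta"]
        else:
            lam = float(lambda_)
            sigma_u2 = sigma_e2 = float("nan")
        n = y.size
        H = G + lam * np.eye(n)
        Hi = np.linalg.inv(H)
        XtHiX = X.T @ Hi @ X
        beta = np.linalg.solve(XtHiX, X.T @ Hi @ y)
        alpha = Hi @ (y - X @ beta)
        u = Z.T @ alpha
        if lambda_ is not None:
            # variance scale at a caller-fixed ratio, from the residuals
            resid = y - X @ beta - G @ alpha
            sigma_e2 = float(resid @ resid) / max(n - X.shape[1], 1)
            sigma_u2 = sigma_e2 / lam if lam > 0 else float("nan")
        return RRBLUPResults(
            model=self, beta=beta, u=u, sigma_u2=float(sigma_u2),
            sigma_e2=float(sigma_e2), lambda_=float(lam),
        )


@dataclass
class RRBLUPResults:
    """Fixed effects, shrunken marker effects and variance components."""

    model: RRBLUP
    beta: np.ndarray
    u: np.ndarray
    sigma_u2: float
    sigma_e2: float
    lambda_: float

    @property
    def fitted(self) -> np.ndarray:
        return self.model.X @ self.beta + self.model.Z @ self.u

    def predict(self, X_new=None, Z_new=None) -> np.ndarray:
        """GEBV of new lines: X_new beta + (Z_new - training means) u."""
        if Z_new is None:
            return self.fitted
        Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
        if Z_new.shape[1] != self.u.size:
            raise ValueError(
                f"Z_new has {Z_new.shape[1]} markers, model has {self.u.size}"
            )
        Zc = Z_new - self.model._z_means
        if X_new is None:
            X_new = np.ones((Z_new.shape[0], 1))
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.beta.size:
            raise ValueError("X_new column count differs from the training design")
        return X_new @ self.beta + Zc @ self.u

    def summary(self) -> str:
        return (
            "RR-BLUP fit\n"
            f"  n / m:          {self.model.y.size} / {self.u.size}\n"
            f"  sigma_u^2:      {self.sigma_u2:.6g}\n"
            f"  sigma_e^2:      {self.sigma_e2:.6g}\n"
            f"  lambda:         {self.lambda_:.6g}\n"
            f"  fixed effects:  {np.array2string(self.beta, precision=4)}"
        )


@dataclass
class CVResult:
    """k-fold cross-validation outcome."""

    fold_of: np.ndarray  # fold index per line
    predictions: np.ndarray  # pooled out-of-fold predictions
    accuracy: float  # Pearson r(y, predictions)
    fold_accuracies: np.ndarray
    seed: int


def cross_validate(y, Z, X=None, k: int = 10, seed: int = 0,
                   lambda_: float | None = None) -> CVResult:
    """k-fold CV accuracy of an RR-BLUP model.

    Lines are partitioned by a seeded shuffle; the model is refit on
    each training set (lambda re-estimated by REML unless fixed) and
    held-out lines are predicted using their genotypes and — when X
    has covariate columns — their measured fixed covariates, which are
    observable without the phenotype being predicted.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k > n:
        raise ValueError("k must not exceed the number of lines")
    Z = np.asarray(Z, dtype=float)
    X = np.ones((n, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % k
    preds = np.empty(n)
    fold_acc = np.full(k, np.nan)
    for f in range(k):
        te = fold_of == f
        tr = ~te
        model = RRBLUP(y[tr], Z[tr], X[tr])
        fit = model.fit(lambda_=lambda_)
        preds[te] = fit.predict(X_new=X[te], Z_new=Z[te])
        if te.sum() >= 3 and np.std(preds[te]) > 0 and np.std(y[te]) > 0:
            fold_acc[f] = stats.pearsonr(y[te], preds[te])[0]
    accuracy = float(stats.pearsonr(y, preds)[0])
    return CVResult(fold_of=fold_of, predictions=preds, accuracy=accuracy,
                    fold_accuracies=fold_acc, seed=seed)


def marker_effect_profile(fit: RRBLUPResults, chrom, pos,
                          snp_ids=None) -> pd.DataFrame:
    """Genome-ordered marker-effect track (chromosome, position, effect)."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    if chrom.size != fit.u.size or pos.size != fit.u.size:
        raise ValueError("map length must equal the number of markers")
    df = pd.DataFrame(
        {
            "snp": snp_ids if snp_ids is not None else np.arange(fit.u.size),
            "chrom": chrom,
            "pos": pos,
            "effect": fit.u,
        }
    )
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def run_prediction_models(
    y, Z, qtl_dosage=None, surrogate=None, k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """CV accuracy of the standard model ladder.

    Rows mirror the usual comparison: markers-random-only, then the
    major-QTL dosage as a fixed covariate, then the surrogate trait,
    then both.  Returns a table (model, accuracy).
    """
    n = np.asarray(y).size
    ladder = {"random_only": [np.ones((n, 1))]}
    if qtl_dosage is not None:
        ladder["qtl_fixed"] = [np.ones((n, 1)),
                               np.asarray(qtl_dosage, float).reshape(-1, 1)]
    if surrogate is not None:
        ladder["surrogate_fixed"] = [np.ones((n, 1)),
                                     np.asarray(surrogate, float).reshape(-1, 1)]
    if qtl_dosage is not None and surrogate is not None:
        ladder["qtl_surrogate_fixed"] = [
            np.ones((n, 1)),
            np.asarray(qtl_dosage, float).reshape(-1, 1),
            np.asarray(surrogate, float).reshape(-1, 1),
        ]
    rows = []
    for name, cols in ladder.items():
        X = np.hstack(cols)
        cv = cross_validate(y, Z, X=X, k=k, seed=seed)
        rows.append({"model": name, "accuracy": cv.accuracy})
    return pd.DataFrame(rows)
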