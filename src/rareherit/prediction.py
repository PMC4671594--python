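"""GBLUP genomic prediction and its validation metrics.

Genetic merits for unphenotyped (validation) animals are best linear
unbiased predictions under y = X beta + sum_c u_c + e with
u_c ~ N(0, sigma_c^2 M_c): for a new animal, g_hat = sum_c sigma_c^2
K_c(new, train) P y, which is the solution of the mixed-model equations
solved jointly over all random components.  Validation phenotypes never
enter the right-hand side.

Accuracy is reported as the Pearson correlation between predicted merit
and observed daughter trait deviation, the calibration slope of observed on
predicted (1 = unbiased), and the mean squared error scaled by the pedigree
additive variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import Pedigree, PhenotypeSet
from .greml import GREML, VarianceModel


class GBLUP(BaseEstimator, RegressorMixin):
    """Best linear unbiased prediction with precomputed relationship kernels.

    Parameters
    ----------
    variance_components : array-like or None
        Variances (sigma_1^2, ..., sigma_c^2, sigma_e^2).  When None they
        are estimated on the training data by :class:`~rareherit.greml.GREML`
        (no leakage from validation animals).
    jitter : float
        Diagonal jitter when factorizing V.

    ``fit(X, y, sample_weight=...)`` takes train x train kernels (a single
    (n, n) matrix, a list, or a (c, n, n) stack); ``predict(X)`` takes the
    matching new x train cross-kernels and returns predicted genetic merits
    (deviations; the fixed-effect mean is not added).
    """

    def __init__(self, variance_components=None, jitter: float = 1e-8,
                 max_iter: int = 200, tol: float = 1e-8):
        self.variance_components = variance_components
        self.jitter = jitter
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, sample_weight=None):
        mats = GREML._as_matrix_list(X)
        y = np.asarray(y, dtype=float)
        n = y.size
        c = len(mats)
        if sample_weight is None:
            D = np.eye(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if np.any(w <= 0):
                raise ValueError("sample_weight must be strictly positive")
            D = np.diag(1.0 / w)

        if self.variance_components is None:
            reml = GREML(max_iter=self.max_iter, tol=self.tol)
            reml.fit(mats, y, sample_weight=sample_weight)
            sigma2 = np.asarray(reml.sigma2_, dtype=float)
            self.reml_ = reml
        else:
            sigma2 = np.asarray(self.variance_components, dtype=float)
            if sigma2.size != c + 1:
                raise ValueError(
                    f"expected {c + 1} variance components (incl. residual), "
                    f"got {sigma2.size}"
                )

        V = sigma2[-1] * D
        for s, M in zip(sigma2[:-1], mats):
            V += s * M
        ones = np.ones((n, 1))
        try:
            cf = linalg.cho_factor(V + self.jitter * np.eye(n), lower=True)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(f"V is singular even after jitter: {err}") from err
        Viy = linalg.cho_solve(cf, y)
        Vi1 = linalg.cho_solve(cf, ones)[:, 0]
        denom = float(ones[:, 0] @ Vi1)
        self.mu_ = float(ones[:, 0] @ Viy) / denom
        self.alpha_ = Viy - Vi1 * (float(Vi1 @ y) / denom)  # P y
        self.sigma2_ = sigma2
        self.n_components_ = c
        self.n_train_ = n
        return self

    def predict(self, X):
        """Predicted genetic merit = sum of component BLUPs for new animals."""
        if isinstance(X, np.ndarray) and X.ndim == 2:
            mats = [X]
        else:
            mats = [np.asarray(M, dtype=float) for M in X]
        if len(mats) != self.n_components_:
            raise ValueError(
                f"expected {self.n_components_} cross-kernels, got {len(mats)}"
            )
        g = np.zeros(mats[0].shape[0])
        for s, K in zip(self.sigma2_[:-1], mats):
            if K.shape[1] != self.n_train_:
                raise ValueError("cross-kernel column count must match training size")
            g += s * (K @ self.alpha_)
        return g

    def blup_components(self, X) -> np.ndarray:
        """Per-component BLUPs, one row per new animal, one column per component."""
        mats = [X] if (isinstance(X, np.ndarray) and X.ndim == 2) else list(X)
        return np.column_stack(
            [s * (np.asarray(K, float) @ self.alpha_) for s, K in zip(self.sigma2_[:-1], mats)]
        )


def split_train_validation(
    pedigree: Pedigree,
    phenotypes: PhenotypeSet,
    n_validation: int,
) -> tuple[list[str], list[str]]:
    """Hold out the latest-born phenotyped animals as the validation set.

    Deterministic: animals are ranked by pedigree birth order with ties
    broken by id; the ``n_validation`` latest form the validation set.
    """
    ids = list(phenotypes.ids)
    if n_validation >= len(ids):
        raise ValueError("n_validation must be smaller than the number of phenotypes")
    order = pedigree.birth_order
    ranked = sorted(ids, key=lambda a: (order[a], a))
    if n_validation == 0:
        return ranked, []
    return ranked[:-n_validation], ranked[-n_validation:]


@dataclass
class PredictionResult:
    predicted: np.ndarray
    observed: np.ndarray
    cor: float
    slope: float
    mse_sd: float
    mse_scale: str = "variance"  # divided by sigma_a^2 ("variance") or sigma_a ("sd")


def evaluate(
    predicted: np.ndarray,
    observed: np.ndarray,
    sigma_a2: float,
    mse_scale: str = "variance",
) -> PredictionResult:
    """Pearson correlation, calibration slope, and scaled MSE.

    slope = cov(observed, predicted) / var(predicted) — the coefficient of
    regressing observed on predicted, so 1 means unbiased prediction.
    MSE is divided by the pedigree additive variance sigma_a^2 by default
    (``mse_scale="sd"`` divides by sigma_a instead).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size or predicted.size < 3:
        raise ValueError("need >= 3 paired validation records")
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be positive")
    var_pred = float(np.var(predicted))
    if var_pred == 0.0:
        warnings.warn("predicted values have zero variance; slope/cor undefined",
                      RuntimeWarning)
        cor = np.nan
        slope = np.nan
    else:
        cor = float(stats.pearsonr(observed, predicted).statistic)
        slope = float(np.cov(observed, predicted, ddof=0)[0, 1] / var_pred)
    mse = float(np.mean((observed - predicted) ** 2))
    denom = sigma_a2 if mse_scale == "variance" else float(np.sqrt(sigma_a2))
    return PredictionResult(
        predicted=predicted,
        observed=observed,
        cor=cor,
        slope=slope,
        mse_sd=mse / denom,
        mse_scale=mse_scale,
    )


def gblup_predict(
    phenotypes_train: PhenotypeSet,
    model: VarianceModel,
    validation_ids: list[str],
    variance_components: dict[str, float] | None = None,
) -> np.ndarray:
    """Predict merits for validation animals from a fitted or refitted model.

    ``model.components`` must hold relationship matrices spanning training
    and validation animals.  When ``variance_components`` (label -> value,
    incl. "residual") is omitted, components are re-estimated by REML on
    the training records only.
    """
    train_ids = phenotypes_train.ids
    mats_train = [rm.align(train_ids) for _, rm in model.components]
    if variance_components is not None:
        labels = [label for label, _ in model.components]
        vc = np.array([variance_components[lab] for lab in labels]
                      + [variance_components["residual"]])
    else:
        vc = None
    est = GBLUP(variance_components=vc)
    est.fit(mats_train, phenotypes_train.values, sample_weight=phenotypes_train.weights)
    cross = [rm.cross(validation_ids, train_ids) for _, rm in model.components]
    return est.predict(cross)
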