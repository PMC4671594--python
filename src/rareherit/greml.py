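"""Restricted maximum likelihood for multi-component animal models.

Model: y = X beta + sum_c u_c + e, with u_c ~ N(0, sigma_c^2 M_c) for
relationship matrices M_c (genomic G and/or pedigree A) and
e ~ N(0, sigma_e^2 D), D = diag(1/w_i) so that an animal with residual
weight w_i (effective daughter contribution) has residual variance
sigma_e^2 / w_i.

The REML log-likelihood

    l = -0.5 [ log|V| + log|X' V^-1 X| + y' P y ],
    V = sum_c sigma_c^2 M_c + sigma_e^2 D,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

is maximized by average-information (AI) updates with projection onto the
non-negative orthant, step halving to keep the likelihood non-decreasing,
and exact EM fallback steps (which cannot decrease the likelihood) when an
AI step fails.  Components driven to zero are pinned at the boundary.
Standard errors come from the inverse AI matrix at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .datatypes import PhenotypeSet, RelationshipMatrix


@dataclass
class VarianceModel:
    """Which covariance structures enter the model, and with what weights."""

    components: list[tuple[str, RelationshipMatrix]]
    residual_weights: np.ndarray | None = None
    fixed_effects: np.ndarray | None = None  # defaults to an intercept column


@dataclass
class REMLResult:
    sigma2: dict[str, float]
    se: dict[str, float]
    loglik: float
    proportions: dict[str, float]  # percent of total genetic variance
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)


class _State:
    """Factorized quantities of V at a parameter vector theta."""

    def __init__(self, theta, mats, Xf, y, jitter):
        n = y.size
        V = np.zeros((n, n))
        for t, M in zip(theta, mats):
            if t != 0.0:
                V += t * M
        eps = 0.0
        for _ in range(40):
            try:
                cf = linalg.cho_factor(V + eps * np.eye(n), lower=True)
                break
            except linalg.LinAlgError:
                eps = jitter if eps == 0.0 else eps * 10.0
        else:
            raise linalg.LinAlgError("V not positive definite after jitter retries")
        self.logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
        self.Vinv = linalg.cho_solve(cf, np.eye(n))
        self.ViX = self.Vinv @ Xf
        XtViX = Xf.T @ self.ViX
        sign, self.logdet_XtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise linalg.LinAlgError("X'V^-1X not positive definite")
        self.XtViX_inv = np.linalg.inv(XtViX)
        Viy = self.Vinv @ y
        self.beta = self.XtViX_inv @ (Xf.T @ Viy)
        self.Py = Viy - self.ViX @ (self.XtViX_inv @ (self.ViX.T @ y))
        self.yPy = float(y @ self.Py)
        self.loglik = -0.5 * (self.logdet_V + self.logdet_XtViX + self.yPy)

    def project(self, v: np.ndarray) -> np.ndarray:
        """P v for a vector v."""
        return self.Vinv @ v - self.ViX @ (self.XtViX_inv @ (self.ViX.T @ v))

    def tr_PM(self, M: np.ndarray) -> float:
        tr_ViM = float(np.sum(self.Vinv * M))  # tr(V^-1 M), M symmetric
        corr = float(np.trace(self.XtViX_inv @ (self.ViX.T @ (M @ self.ViX))))
        return tr_ViM - corr


class GREML(BaseEstimator):
    """Variance-component estimation with precomputed relationship matrices.

    Parameters
    ----------
    max_iter : int
        Iteration cap.
    tol : float
        Relative log-likelihood convergence tolerance.
    param_tol : float
        Parameter-change tolerance, relative to var(y).
    jitter : float
        Diagonal jitter used when a factorization fails.

    ``fit(X, y, sample_weight=...)`` takes ``X`` as one (n, n) relationship
    matrix, a list of them, or a (c, n, n) stack (precomputed-kernel
    convention); ``sample_weight`` holds the residual weights w_i.

    Attributes (after fit)
    ----------------------
    sigma2_ : ndarray, variance per component followed by the residual.
    se_ : ndarray, approximate standard errors (inverse AI).
    loglik_ : float, REML log-likelihood at the optimum.
    proportions_ : ndarray, percent of total genetic variance per component.
    converged_, n_iter_, loglik_trace_, beta_ : diagnostics.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-8,
                 param_tol: float = 1e-6, jitter: float = 1e-8, verbose: int = 0):
        self.max_iter = max_iter
        self.tol = tol
        self.param_tol = param_tol
        self.jitter = jitter
        self.verbose = verbose

    @staticmethod
    def _as_matrix_list(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            mats = [X]
        else:
            mats = [np.asarray(M, dtype=float) for M in X]
        n = mats[0].shape[0]
        for M in mats:
            if M.shape != (n, n):
                raise ValueError("all relationship matrices must be (n, n)")
        return mats

    @staticmethod
    def _bend_psd(M: np.ndarray) -> tuple[np.ndarray, float]:
        """Project an indefinite relationship matrix onto the PSD cone.

        Marker-based G built from few or very rare markers can be
        indefinite (the homozygosity-corrected diagonal is not a
        cross-product), and a Gaussian likelihood over an indefinite kernel
        is not well-defined.  Negative eigenvalues are clipped to zero
        ("bending"), which perturbs the matrix far less than a diagonal
        shift of |lambda_min|.  Returns the bent matrix and |lambda_min|
        (0 when the input was already PSD).
        """
        lam, vec = np.linalg.eigh(M)
        if lam[0] >= 0.0:
            return M, 0.0
        bent = (vec * np.maximum(lam, 0.0)) @ vec.T
        return 0.5 * (bent + bent.T), float(-lam[0])

    def fit(self, X, y, sample_weight=None, fixed_effects=None, start=None):
        mats = self._as_matrix_list(X)
        y = np.asarray(y, dtype=float)
        n = y.size
        if mats[0].shape[0] != n:
            raise ValueError("matrix dimension does not match y")
        if sample_weight is None:
            D = np.eye(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if np.any(w <= 0):
                raise ValueError("sample_weight must be strictly positive")
            D = np.diag(1.0 / w)
        Xf = np.ones((n, 1)) if fixed_effects is None else np.asarray(fixed_effects, float)
        if Xf.ndim == 1:
            Xf = Xf[:, None]

        bends = []
        bent = []
        for M in mats:
            Mb, shift = self._bend_psd(M)
            bent.append(Mb)
            bends.append(shift)
        mats = bent
        self.bends_ = np.array(bends)

        all_mats = mats + [D]
        c = len(mats)
        vary = float(np.var(y))
        if vary == 0.0:
            self.sigma2_ = np.zeros(c + 1)
            self.se_ = np.full(c + 1, np.nan)
            self.loglik_ = np.nan
            self.converged_ = True
            self.n_iter_ = 0
            self.loglik_trace_ = []
            self.beta_ = np.zeros(Xf.shape[1])
            self.proportions_ = np.full(c, np.nan)
            return self

        theta = np.full(c + 1, vary / (c + 1)) if start is None else np.asarray(start, float).copy()
        floor = 1e-12 * vary
        pinned = np.zeros(c + 1, dtype=bool)

        state = _State(theta, all_mats, Xf, y, self.jitter)
        trace = [state.loglik]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            free = np.flatnonzero(~pinned)
            # score and AI on free components
            u = [all_mats[k] @ state.Py for k in free]
            Pu = [state.project(uk) for uk in u]
            score = np.array([
                -0.5 * (state.tr_PM(all_mats[k]) - float(state.Py @ u[i]))
                for i, k in enumerate(free)
            ])
            AI = 0.5 * np.array([[float(u[i] @ Pu[j]) for j in range(len(free))]
                                 for i in range(len(free))])

            def em_step():
                new = theta.copy()
                for i, k in enumerate(free):
                    new[k] = theta[k] + 2.0 * theta[k] ** 2 * score[i] / n
                return np.maximum(new, 0.0)

            try:
                delta = np.linalg.solve(AI + 1e-12 * np.eye(len(free)) * max(AI.max(), 1.0),
                                        score)
            except np.linalg.LinAlgError:
                delta = None

            accepted = None
            if delta is not None:
                step = 1.0
                for _ in range(20):
                    cand = theta.copy()
                    cand[free] = np.maximum(theta[free] + step * delta, 0.0)
                    # keep residual away from an exact zero (likelihood is
                    # unbounded there when residuals vanish)
                    cand[c] = max(cand[c], floor)
                    try:
                        cand_state = _State(cand, all_mats, Xf, y, self.jitter)
                    except linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if cand_state.loglik >= state.loglik - 1e-10:
                        accepted = (cand, cand_state)
                        break
                    step *= 0.5
            if accepted is None:
                cand = em_step()
                cand[c] = max(cand[c], floor)
                cand_state = _State(cand, all_mats, Xf, y, self.jitter)
                if cand_state.loglik < state.loglik - 1e-8 * (1.0 + abs(state.loglik)):
                    # no ascent direction left: stationary point reached
                    converged = True
                    break
                accepted = (cand, cand_state)

            new_theta, new_state = accepted
            d_ll = new_state.loglik - state.loglik
            d_par = np.max(np.abs(new_theta - theta))
            # pin genetic components stuck at the boundary with a
            # negative gradient (they want to go negative)
            for i, k in enumerate(free):
                if k < c and new_theta[k] <= floor and score[i] < 0:
                    new_theta[k] = 0.0
                    pinned[k] = True
            theta, state = new_theta, new_state
            trace.append(state.loglik)
            if self.verbose:
                print(f"iter {it}: loglik={state.loglik:.6f} theta={theta}")
            if abs(d_ll) < self.tol * (1.0 + abs(state.loglik)) and d_par < self.param_tol * vary:
                converged = True
                break

        # standard errors from the full AI matrix at the optimum
        u_all = [all_mats[k] @ state.Py for k in range(c + 1)]
        Pu_all = [state.project(uk) for uk in u_all]
        AI_full = 0.5 * np.array([[float(u_all[i] @ Pu_all[j]) for j in range(c + 1)]
                                  for i in range(c + 1)])
        try:
            cov = np.linalg.pinv(AI_full)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(c + 1, np.nan)

        self.sigma2_ = theta
        self.se_ = se
        self.loglik_ = state.loglik
        self.converged_ = converged
        self.n_iter_ = it
        self.loglik_trace_ = trace
        self.beta_ = state.beta
        total_g = theta[:c].sum()
        self.proportions_ = (100.0 * theta[:c] / total_g) if total_g > 0 else np.full(c, np.nan)
        return self


def reml_fit(
    phenotypes: PhenotypeSet,
    model: VarianceModel,
    max_iter: int = 200,
    tol: float = 1e-8,
    start=None,
) -> REMLResult:
    """Fit a :class:`VarianceModel` to a :class:`PhenotypeSet` by REML.

    Relationship matrices are aligned to the phenotype id order; the fixed
    part defaults to an intercept.
    """
    ids = phenotypes.ids
    labels = [label for label, _ in model.components]
    mats = [rm.align(ids) for _, rm in model.components]
    est = GREML(max_iter=max_iter, tol=tol)
    est.fit(
        mats,
        phenotypes.values,
        sample_weight=model.residual_weights
        if model.residual_weights is not None
        else phenotypes.weights,
        fixed_effects=model.fixed_effects,
        start=start,
    )
    sigma2 = {lab: float(v) for lab, v in zip(labels, est.sigma2_[:-1])}
    sigma2["residual"] = float(est.sigma2_[-1])
    se = {lab: float(v) for lab, v in zip(labels, est.se_[:-1])}
    se["residual"] = float(est.se_[-1])
    props = {lab: float(p) for lab, p in zip(labels, est.proportions_)}
    return REMLResult(
        sigma2=sigma2,
        se=se,
        loglik=float(est.loglik_),
        proportions=props,
        converged=bool(est.converged_),
        n_iter=est.n_iter_,
        loglik_trace=list(est.loglik_trace_),
    )


def lrt_critical_value(alpha: float = 0.005, boundary_mixture: bool = True) -> float:
    """Critical value for a one-extra-variance-component likelihood test.

    Under the boundary null the statistic is a 50:50 mixture of chi^2_0 and
    chi^2_1, so the alpha-level critical value c solves
    0.5 * P(chi^2_1 >= c) = alpha; at alpha = 0.005 this is 6.635.  The
    plain chi^2_1 quantile is available with ``boundary_mixture=False``.
    """
    if boundary_mixture:
        return float(chi2.isf(2.0 * alpha, df=1))
    return float(chi2.isf(alpha, df=1))


def loglik_ratio_test(
    null: REMLResult | float,
    alt: REMLResult | float,
    alpha: float = 0.005,
    boundary_mixture: bool = True,
) -> tuple[float, bool]:
    """2(l_alt - l_null), clipped at zero, against the boundary threshold."""
    l0 = null.loglik if isinstance(null, REMLResult) else float(null)
    l1 = alt.loglik if isinstance(alt, REMLResult) else float(alt)
    if l1 < l0 - 1e-6:
        warnings.warn(
            f"alternative log-likelihood ({l1:.6f}) below null ({l0:.6f}); "
            "optimizer failure suspected",
            RuntimeWarning,
        )
    stat = max(0.0, 2.0 * (l1 - l0))
    return stat, stat > lrt_critical_value(alpha, boundary_mixture)


def missing_heritability(sigma_a2: float, sigma_g2: float) -> float:
    """(sigma_a^2 - sigma_g^2) / sigma_a^2: pedigree variance not captured by markers.

    May be negative when markers capture more variance than pedigree;
    reported as-is.
    """
    if sigma_a2 <= 0:
        raise ValueError("pedigree additive variance must be positive")
    return (sigma_a2 - sigma_g2) / sigma_a2


def partition_report(result: REMLResult) -> pd.DataFrame:
    """Per-component variance/SE/percent table over the genetic components."""
    if not result.converged:
        warnings.warn("partitioning a non-converged REML result", RuntimeWarning)
    genetic = {k: v for k, v in result.sigma2.items() if k != "residual"}
    total = sum(genetic.values())
    if total <= 0:
        raise ValueError("all genetic components are zero; proportions undefined")
    rows = [
        {
            "component": k,
            "variance": v,
            "se": result.se.get(k, np.nan),
            "percent": 100.0 * v / total,
        }
        for k, v in genetic.items()
    ]
    df = pd.DataFrame(rows)
    df.attrs["total_additive_variance"] = total
    return df
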