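"""Normal-theory maximum-likelihood estimation of confirmatory factor models.

Fits a CFA with a fixed free/fixed loading pattern to a sample covariance
matrix by minimizing the ML discrepancy

    F_ML = ln|Sigma(theta)| - ln|S| + tr[S Sigma(theta)^-1] - p,

with factor variances fixed to 1 for identification.  The likelihood-ratio
statistic is T_ML = F_hat * (N - 1).  Gradients and the Jacobian
d sigma / d theta' are analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .basis import p_star, vech, vech_indices
from .exceptions import EstimationError, InvalidModelError
from .population import PRIMARY_LOADINGS, SECONDARY_LOADINGS

__all__ = [
    "AnalysisModelSpec",
    "FitResult",
    "correct_spec",
    "misspecified_spec",
    "null_spec",
    "fit_ml",
    "delta_jacobian",
    "implied_sigma",
    "t_ml",
    "sample_cov",
]

GRAD_TOL = 1e-8         # convergence: projected gradient infinity norm
RESID_FLOOR = 1e-6      # lower bound on residual variances (Heywood guard)
MAX_ITER = 500


@dataclass(frozen=True)
class AnalysisModelSpec:
    """Free/fixed pattern of a CFA.

    Parameters are ordered free loadings (row-major over the mask), then
    factor correlations (lower triangle, column-major), then residual
    variances.  Factor variances are fixed to 1.  ``h = 0`` denotes the
    independence (null) model whose only parameters are the p residual
    variances.
    """

    loading_mask: np.ndarray  # (p, h) boolean
    name: str = "cfa"

    def __post_init__(self):
        mask = np.asarray(self.loading_mask, dtype=bool)
        object.__setattr__(self, "loading_mask", mask)
        if self.h > 0:
            # every factor needs at least one indicator, else not identified
            if not mask.any(axis=0).all():
                raise InvalidModelError("every factor must load on >= 1 indicator")

    @property
    def p(self) -> int:
        return self.loading_mask.shape[0]

    @property
    def h(self) -> int:
        return self.loading_mask.shape[1]

    @property
    def n_free_loadings(self) -> int:
        return int(self.loading_mask.sum())

    @property
    def n_factor_corr(self) -> int:
        return self.h * (self.h - 1) // 2

    @property
    def q(self) -> int:
        """Number of free parameters."""
        return self.n_free_loadings + self.n_factor_corr + self.p

    @property
    def df(self) -> int:
        """Degrees of freedom, p(p+1)/2 - q."""
        df = p_star(self.p) - self.q
        if df <= 0:
            raise InvalidModelError(f"model is not overidentified (df={df})")
        return df

    def free_loading_indices(self) -> np.ndarray:
        """(n_free, 2) array of (indicator, factor) positions, row-major."""
        return np.argwhere(self.loading_mask)

    def default_start(self) -> np.ndarray:
        """Neutral, reproducible starting values: primary loadings 0.5,
        secondary loadings 0, factor correlations 0.2, residual variances 0.5."""
        primary = {(i, j) for i, j, _ in PRIMARY_LOADINGS}
        lam0 = np.array(
            [0.5 if (i, j) in primary else 0.0 for i, j in self.free_loading_indices()]
        )
        return np.concatenate(
            [lam0, np.full(self.n_factor_corr, 0.2), np.full(self.p, 0.5)]
        )


def correct_spec(p: int = 15, h: int = 3) -> AnalysisModelSpec:
    """Analysis model freeing all 21 non-zero population loadings."""
    mask = np.zeros((p, h), dtype=bool)
    for i, j, _ in PRIMARY_LOADINGS + SECONDARY_LOADINGS:
        mask[i, j] = True
    return AnalysisModelSpec(mask, name="correct")


def misspecified_spec(p: int = 15, h: int = 3) -> AnalysisModelSpec:
    """Analysis model freeing only the 15 primary loadings (no secondary)."""
    mask = np.zeros((p, h), dtype=bool)
    for i, j, _ in PRIMARY_LOADINGS:
        mask[i, j] = True
    return AnalysisModelSpec(mask, name="misspecified")


def null_spec(p: int = 15) -> AnalysisModelSpec:
    """Independence model: all covariances zero, free variances only."""
    return AnalysisModelSpec(np.zeros((p, 0), dtype=bool), name="null")


@dataclass
class FitResult:
    """Outcome of an ML fit.

    ``t_ml = fmin * (n - 1)`` always holds; ``converged`` implies the
    projected gradient infinity norm fell below :data:`GRAD_TOL`.
    """

    spec: AnalysisModelSpec
    theta: np.ndarray
    sigma: np.ndarray
    fmin: float
    n: int
    converged: bool
    iterations: int
    grad_norm: float
    heywood: bool = False
    start: np.ndarray = field(repr=False, default=None)

    @property
    def t_ml(self) -> float:
        return self.fmin * (self.n - 1)

    def loadings(self) -> np.ndarray:
        lam = np.zeros((self.spec.p, self.spec.h))
        lam[self.spec.loading_mask] = self.theta[: self.spec.n_free_loadings]
        return lam

    def factor_corr(self) -> np.ndarray:
        h = self.spec.h
        phi = np.eye(h)
        nl = self.spec.n_free_loadings
        iu = np.triu_indices(h, 1)
        phi[iu] = self.theta[nl : nl + self.spec.n_factor_corr]
        return np.triu(phi) + np.triu(phi, 1).T

    def residual_vars(self) -> np.ndarray:
        return self.theta[self.spec.n_free_loadings + self.spec.n_factor_corr :]


def _unpack(spec: AnalysisModelSpec, theta: np.ndarray):
    nl = spec.n_free_loadings
    lam = np.zeros((spec.p, spec.h))
    lam[spec.loading_mask] = theta[:nl]
    phi = np.eye(spec.h)
    iu = np.triu_indices(spec.h, 1)
    phi[iu] = theta[nl : nl + spec.n_factor_corr]
    phi = np.triu(phi) + np.triu(phi, 1).T
    psi = theta[nl + spec.n_factor_corr :]
    return lam, phi, psi


def implied_sigma(spec: AnalysisModelSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance Lambda Phi Lambda' + diag(psi)."""
    lam, phi, psi = _unpack(spec, theta)
    return lam @ phi @ lam.T + np.diag(psi)


def _value_and_grad(theta, spec, s_mat, logdet_s):
    lam, phi, psi = _unpack(spec, theta)
    sigma = lam @ phi @ lam.T + np.diag(psi)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    sigma_inv = np.linalg.inv(sigma)
    f = (
        2.0 * np.log(np.diag(chol)).sum()
        - logdet_s
        + np.sum(sigma_inv * s_mat)
        - spec.p
    )
    # dF = tr[(Sigma^-1 - Sigma^-1 S Sigma^-1) dSigma]
    a_mat = sigma_inv - sigma_inv @ s_mat @ sigma_inv
    lam_phi = lam @ phi
    grad_lam = 2.0 * (a_mat @ lam_phi)[spec.loading_mask]
    iu = np.triu_indices(spec.h, 1)
    grad_phi = 2.0 * (lam.T @ a_mat @ lam)[iu]
    grad_psi = np.diag(a_mat)
    return f, np.concatenate([grad_lam, grad_phi, grad_psi])


def _projected_grad_norm(theta, grad, bounds):
    """Infinity norm of the gradient projected onto the feasible directions."""
    g = grad.copy()
    for k, (lo, hi) in enumerate(bounds):
        if lo is not None and theta[k] <= lo + 1e-12 and g[k] > 0:
            g[k] = 0.0
        if hi is not None and theta[k] >= hi - 1e-12 and g[k] < 0:
            g[k] = 0.0
    return float(np.abs(g).max())


def _newton_polish(theta, spec, s_mat, logdet_s, bounds, max_steps: int = 8):
    """Damped Newton steps using a finite-difference Hessian of the gradient."""
    fval, grad = _value_and_grad(theta, spec, s_mat, logdet_s)
    gnorm = _projected_grad_norm(theta, grad, bounds)
    steps = 0
    q = theta.size
    step_h = 1e-6
    while gnorm >= GRAD_TOL and steps < max_steps:
        hess = np.empty((q, q))
        for k in range(q):
            hi, lo = theta.copy(), theta.copy()
            hi[k] += step_h
            lo[k] -= step_h
            hess[:, k] = (
                _value_and_grad(hi, spec, s_mat, logdet_s)[1]
                - _value_and_grad(lo, spec, s_mat, logdet_s)[1]
            ) / (2 * step_h)
        hess = (hess + hess.T) / 2
        ridge = 0.0
        for _ in range(6):
            try:
                direction = np.linalg.solve(hess + ridge * np.eye(q), -grad)
            except np.linalg.LinAlgError:
                ridge = max(10 * ridge, 1e-8)
                continue
            candidate = theta + direction
            for k, (lo_b, hi_b) in enumerate(bounds):
                if lo_b is not None:
                    candidate[k] = max(candidate[k], lo_b)
                if hi_b is not None:
                    candidate[k] = min(candidate[k], hi_b)
            f_new, g_new = _value_and_grad(candidate, spec, s_mat, logdet_s)
            if f_new <= fval + 1e-12:
                theta, fval, grad = candidate, f_new, g_new
                break
            ridge = max(10 * ridge, 1e-8)
        else:
            break
        gnorm = _projected_grad_norm(theta, grad, bounds)
        steps += 1
    return theta, fval, gnorm, steps


def sample_cov(data: np.ndarray) -> np.ndarray:
    """Sample covariance with the (N - 1) divisor (Wishart convention)."""
    data = np.asarray(data, dtype=float)
    return np.cov(data, rowvar=False)


def fit_ml(
    spec: AnalysisModelSpec,
    s_mat: np.ndarray,
    n: int,
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit the CFA to a covariance matrix by normal-theory ML.

    Parameters
    ----------
    spec : AnalysisModelSpec
        Free/fixed pattern.
    s_mat : (p, p) ndarray
        Sample (or population) covariance matrix; must be symmetric positive
        definite.
    n : int
        Sample size, used only to scale T_ML.
    start : ndarray, optional
        Starting values; defaults to :meth:`AnalysisModelSpec.default_start`.

    Notes
    -----
    The independence model (h = 0) has the closed-form solution
    Sigma = diag(S); it is returned exactly rather than iterated.
    Residual variances are bounded below at 1e-6; an active bound is
    reported through the ``heywood`` flag.
    """
    s_mat = np.asarray(s_mat, dtype=float)
    if s_mat.shape != (spec.p, spec.p) or not np.allclose(s_mat, s_mat.T):
        raise ValueError("S must be a symmetric p x p matrix")
    sign, logdet_s = np.linalg.slogdet(s_mat)
    if sign <= 0:
        raise ValueError("S must be positive definite")

    if spec.h == 0:
        psi = np.diag(s_mat).copy()
        fmin = float(np.sum(np.log(psi)) - logdet_s)
        return FitResult(
            spec=spec, theta=psi, sigma=np.diag(psi), fmin=fmin, n=n,
            converged=True, iterations=0, grad_norm=0.0,
        )

    theta0 = spec.default_start() if start is None else np.asarray(start, float)
    bounds = (
        [(None, None)] * spec.n_free_loadings
        + [(-0.999, 0.999)] * spec.n_factor_corr
        + [(RESID_FLOOR, None)] * spec.p
    )
    theta, nit = theta0, 0
    fval, grad = _value_and_grad(theta, spec, s_mat, logdet_s)
    gnorm = _projected_grad_norm(theta, grad, bounds)
    # L-BFGS-B with cold restarts: restarting clears the Hessian memory and
    # usually brings the gradient close to GRAD_TOL
    for _ in range(3):
        res = optimize.minimize(
            _value_and_grad, theta, args=(spec, s_mat, logdet_s), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=MAX_ITER, ftol=1e-15, gtol=1e-12),
        )
        theta, fval = res.x, float(res.fun)
        nit += res.nit
        gnorm = _projected_grad_norm(theta, res.jac, bounds)
        if gnorm < GRAD_TOL:
            break
    if gnorm >= GRAD_TOL:
        # Newton polish on flat curvature: finite-difference Hessian of the
        # analytic gradient, quadratic convergence near the optimum
        theta, fval, gnorm, extra = _newton_polish(theta, spec, s_mat, logdet_s, bounds)
        nit += extra
    psi = theta[spec.n_free_loadings + spec.n_factor_corr :]
    return FitResult(
        spec=spec, theta=theta, sigma=implied_sigma(spec, theta),
        fmin=max(fval, 0.0), n=n, converged=bool(gnorm < GRAD_TOL),
        iterations=nit, grad_norm=gnorm,
        heywood=bool(np.any(psi <= RESID_FLOOR * (1 + 1e-9))),
        start=theta0,
    )


def t_ml(fit: FitResult) -> float:
    """Likelihood-ratio statistic T_ML = F_hat * (N - 1)."""
    if not fit.converged:
        raise EstimationError("fit did not converge; T_ML undefined")
    return fit.t_ml


def delta_jacobian(spec: AnalysisModelSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d vech(Sigma(theta)) / d theta', shape (p*, q).

    Column order matches the parameter vector: free loadings, factor
    correlations, residual variances.  The residual-variance columns are
    indicator vectors selecting the diagonal elements of vech.
    """
    lam, phi, _ = _unpack(spec, theta)
    p = spec.p
    lam_phi = lam @ phi
    cols = []
    for a, b in spec.free_loading_indices():
        d_mat = np.zeros((p, p))
        d_mat[a, :] += lam_phi[:, b]
        d_mat[:, a] += lam_phi[:, b]
        cols.append(vech(d_mat))
    iu = np.triu_indices(spec.h, 1)
    for b, c in zip(*iu):
        d_mat = np.outer(lam[:, b], lam[:, c])
        cols.append(vech(d_mat + d_mat.T))
    rows, cvech = vech_indices(p)
    diag_pos = np.flatnonzero(rows == cvech)
    for a in range(p):
        col = np.zeros(p_star(p))
        col[diag_pos[a]] = 1.0
        cols.append(col)
    delta = np.column_stack(cols)
    if np.linalg.matrix_rank(delta) < spec.q:
        import warnings

        warnings.warn("Jacobian is rank deficient: model may be unidentified",
                      RuntimeWarning, stacklevel=2)
    return delta
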