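"""Population factor model and population-level fit quantities.

The population is a correlated three-factor model with p = 15 standardized
indicators, 15 primary loadings and 6 non-zero secondary loadings.  The
population covariance matrix is

    Sigma0 = Lambda Phi Lambda' + Theta,

with Theta diagonal and chosen so that every indicator has unit variance.
From Sigma0 the module derives the quantities a power analysis needs before
any data are simulated: the population minimum F0 of the ML discrepancy
under a misspecified analysis model, the population RMSEA and CFI, and the
expected power of the likelihood-ratio test via a noncentral chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidModelError

__all__ = [
    "PopulationModel",
    "PRIMARY_LOADINGS",
    "SECONDARY_LOADINGS",
    "FACTOR_CORR",
    "default_population",
    "build_sigma0",
    "population_minimum",
    "null_model_minimum",
    "rmsea0",
    "cfi0",
    "expected_power",
]

#: (indicator, factor, value) triplets of the 15 primary loadings.
PRIMARY_LOADINGS: tuple[tuple[int, int, float], ...] = (
    (0, 0, 0.70), (1, 0, 0.70), (2, 0, 0.50), (3, 0, 0.45), (4, 0, 0.40),
    (5, 1, 0.80), (6, 1, 0.65), (7, 1, 0.55), (8, 1, 0.50), (9, 1, 0.40),
    (10, 2, 0.70), (11, 2, 0.60), (12, 2, 0.55), (13, 2, 0.50), (14, 2, 0.45),
)

#: (indicator, factor, value) triplets of the 6 non-zero secondary loadings.
SECONDARY_LOADINGS: tuple[tuple[int, int, float], ...] = (
    (1, 1, -0.25), (2, 2, 0.25), (6, 0, 0.25),
    (8, 2, -0.25), (12, 0, -0.25), (13, 1, 0.25),
)

#: Factor correlation matrix Phi (unit diagonal).
FACTOR_CORR = np.array([
    [1.0, 0.3, 0.2],
    [0.3, 1.0, 0.3],
    [0.2, 0.3, 1.0],
])


@dataclass(frozen=True)
class PopulationModel:
    """Ground-truth factor model: Lambda, Phi, Theta and implied Sigma0.

    Attributes
    ----------
    loadings : (p, h) ndarray
        Standardized loading matrix Lambda.
    factor_corr : (h, h) ndarray
        Factor correlation matrix Phi (unit diagonal, positive definite).
    residual_vars : (p,) ndarray
        Diagonal of Theta; equals 1 - communality for unit indicator
        variances.
    sigma0 : (p, p) ndarray
        Implied population covariance Lambda Phi Lambda' + Theta.
    """

    loadings: np.ndarray
    factor_corr: np.ndarray
    residual_vars: np.ndarray
    sigma0: np.ndarray

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def h(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.residual_vars


def build_sigma0(loadings: np.ndarray, factor_corr: np.ndarray) -> PopulationModel:
    """Construct the population model implied by Lambda and Phi.

    Residual variances are set to 1 - (Lambda Phi Lambda')_ii so that every
    indicator has exactly unit variance.

    Raises
    ------
    InvalidModelError
        If Phi is not a valid correlation matrix or any communality is >= 1
        (which would force a non-positive residual variance).
    """
    loadings = np.asarray(loadings, dtype=float)
    factor_corr = np.asarray(factor_corr, dtype=float)
    if not np.allclose(factor_corr, factor_corr.T):
        raise InvalidModelError("factor correlation matrix must be symmetric")
    if not np.allclose(np.diag(factor_corr), 1.0):
        raise InvalidModelError("factor correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(factor_corr).min() <= 0:
        raise InvalidModelError("factor correlation matrix must be positive definite")
    common = loadings @ factor_corr @ loadings.T
    communality = np.diag(common)
    if np.any(communality >= 1.0):
        bad = np.flatnonzero(communality >= 1.0)
        raise InvalidModelError(
            f"communality >= 1 for indicator(s) {bad.tolist()}; "
            "residual variance would be non-positive"
        )
    residual_vars = 1.0 - communality
    sigma0 = common + np.diag(residual_vars)
    return PopulationModel(loadings, factor_corr, residual_vars, sigma0)


def default_population() -> PopulationModel:
    """The 15-indicator, three-factor population model used throughout."""
    lam = np.zeros((15, 3))
    for i, j, v in PRIMARY_LOADINGS + SECONDARY_LOADINGS:
        lam[i, j] = v
    return build_sigma0(lam, FACTOR_CORR)


def save_sigma0(pop: PopulationModel, path) -> None:
    """Export the population covariance as CSV (variables as header row)."""
    import pandas as pd

    cols = [f"x{i + 1}" for i in range(pop.p)]
    pd.DataFrame(pop.sigma0, columns=cols).to_csv(path, index=False)


def load_population(loadings_csv, factor_corr_csv) -> PopulationModel:
    """Build a population model from delimited-text Lambda and Phi."""
    import pandas as pd

    lam = pd.read_csv(loadings_csv, header=None).to_numpy(dtype=float)
    phi = pd.read_csv(factor_corr_csv, header=None).to_numpy(dtype=float)
    return build_sigma0(lam, phi)


def population_minimum(spec, sigma0: np.ndarray) -> float:
    """Minimum of the ML discrepancy F(Sigma0, Sigma(theta)) over theta.

    This is the population misfit F0 of an analysis model: zero exactly when
    the model can reproduce Sigma0, strictly positive under misspecification.
    Uses the same estimation engine (and convergence settings) as sample
    fits, with Sigma0 in place of the sample covariance.
    """
    from .cfa import fit_ml  # local import: cfa depends on this module

    fit = fit_ml(spec, sigma0, n=1000)
    if not fit.converged:
        from .exceptions import EstimationError

        raise EstimationError(
            f"population minimization did not converge (grad norm "
            f"{fit.grad_norm:.2e} after {fit.iterations} iterations)"
        )
    return float(fit.fmin)


def null_model_minimum(sigma: np.ndarray) -> float:
    """Population misfit of the independence (null) model.

    The ML minimum of a diagonal covariance model fitted to ``sigma`` has the
    closed form ``sum(log diag) - log det``, i.e. minus the log-determinant of
    the correlation matrix.
    """
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise InvalidModelError("sigma must be positive definite")
    return float(np.sum(np.log(np.diag(sigma))) - logdet)


def rmsea0(f0: float, df: int) -> float:
    """Population RMSEA, sqrt(F0 / df)."""
    if f0 < 0:
        raise ValueError("population misfit F0 must be nonnegative")
    if df <= 0:
        raise ValueError("df must be positive")
    return float(np.sqrt(f0 / df))


def cfi0(f0: float, f_nm: float) -> float:
    """Population CFI, (F_nm - F0) / F_nm, against the independence null."""
    if f_nm <= 0:
        raise ValueError("null-model misfit must be positive for the CFI")
    return float((f_nm - f0) / f_nm)


def expected_power(f0: float, df: int, n: int, alpha: float = 0.05) -> float:
    """Expected power of the likelihood-ratio test.

    Probability that a noncentral chi-square with ``df`` degrees of freedom
    and noncentrality ``F0 * (n - 1)`` exceeds the central chi-square
    critical value at level ``alpha``.  The (n - 1) multiplier matches the
    Wishart statistic T_ML = F_hat * (N - 1).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if f0 < 0:
        raise ValueError("F0 must be nonnegative")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    return float(stats.ncx2.sf(crit, df, f0 * (n - 1)))
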