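"""Samples with covariance Sigma0 whose non-normality has a chosen source.

Each indicator is the sum X_i = L_i + E_i of a correlated component and an
independent component.  The source of non-normality decides which part is
non-normal while the marginal kurtosis of every X_i is held at the target k:

``latent``
    All L_i are non-normal (drawn with NORTA from quantile mixtures), all
    E_i are independent normals.  The shares of the correlated part are
    uniform at 1 - lambda_min(Sigma0)/2 (see :func:`latent_shares` for why
    uniformity is structurally forced); Cov(L) = Sigma0 - diag(1 - s) stays
    comfortably positive definite.
``error``
    L = Lambda f with normal factors (the common part of the population
    model, rank h), and each E_i is an independent non-normal variable
    carrying the residual variance Theta_ii, with its own mixture weights.
``marginal``
    The classical Vale-Maurelli route: third-order Fleishman polynomials in
    correlated normals, applied directly to the indicators.  k = 3 is the
    exact multivariate normal control (spectral factorization of Sigma0).
``normal``
    Alias for the multivariate normal control.

Fourth-cumulant additivity ties the mixture target to the variance split:
if the non-normal part carries share s of a unit-variance indicator, its
mixture must have kurtosis 3 + (k - 3)/s^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import CalibrationError
from .mixtures import (
    _pair_corr_fun,
    fit_mixture_weights,
    fleishman_coefficients,
    fleishman_intermediate_corr,
)
from .population import PopulationModel

__all__ = [
    "ConditionSpec",
    "Dataset",
    "SOURCES",
    "KURTOSIS_LEVELS",
    "SAMPLE_SIZES",
    "LATENT_COMPONENTS",
    "ERROR_COMPONENTS",
    "latent_shares",
    "generate",
    "realized_moments",
    "save_dataset",
    "load_dataset",
]

SOURCES = ("latent", "error", "marginal", "normal")
KURTOSIS_LEVELS = (3.0, 10.0, 17.0)
SAMPLE_SIZES = (200, 400, 600, 1000)

#: Mixture components per kurtosis level when the latent part is non-normal.
LATENT_COMPONENTS = {
    3.0: ("t4.1", "uniform"),
    10.0: ("lognormal", "exponential"),
    17.0: ("lognormal", "exponential"),
}

#: Mixture components per kurtosis level when the errors are non-normal.
ERROR_COMPONENTS = {
    3.0: ("cubic_normal", "uniform", "normal"),
    10.0: ("lognormal", "exponential"),
    17.0: ("normal", "lognormal", "neg_lognormal"),
}


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the simulation design."""

    source: str
    kurtosis: float
    n: int
    specification: str = "correct"
    reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}")
        if self.specification not in ("correct", "misspecified"):
            raise ValueError("specification must be 'correct' or 'misspecified'")
        if self.source == "normal" and self.kurtosis != 3.0:
            raise ValueError("the normal control requires kurtosis 3")
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if self.reps < 1:
            raise ValueError("reps must be positive")

    @property
    def label(self) -> str:
        return f"{self.source}_k{self.kurtosis:g}_N{self.n}_{self.specification}"


@dataclass
class Dataset:
    """Generated sample plus its provenance and realized marginal moments."""

    values: np.ndarray
    condition: ConditionSpec
    moments: pd.DataFrame = field(default=None)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def realized_moments(values: np.ndarray) -> pd.DataFrame:
    """Per-variable mean, variance, skewness and (Pearson) kurtosis."""
    return pd.DataFrame(
        {
            "mean": values.mean(axis=0),
            "variance": values.var(axis=0, ddof=1),
            "skewness": stats.skew(values, axis=0),
            "kurtosis": stats.kurtosis(values, axis=0, fisher=False),
        },
        index=[f"x{i + 1}" for i in range(values.shape[1])],
    )


#: Cap on the mixture kurtosis target, safely inside the pure-lognormal
#: maximum of e^4 + 2e^3 + 3e^2 - 3 ~= 113.94.
_MIX_KURT_CAP = 110.0


def latent_shares(pop: PopulationModel, k: float) -> np.ndarray:
    """Variance shares of the correlated non-normal part, per indicator.

    A uniform share 1 - lambda_min(Sigma0)/2 for every indicator.  Uniformity
    is forced, not convenient: Cov(L) = Sigma0 - diag(1-s) has its
    off-diagonals pinned at Sigma0's, so heterogeneous shares drive
    same-factor pairs toward correlation 1 while their kurtosis targets
    3 + (k-3)/s_i^2 would demand *different* marginals -- impossible for
    (near-)comonotone variables.  In particular the factor-model reading
    s_i = communality_i makes same-factor common parts perfectly correlated
    scaled copies and cannot carry per-indicator kurtosis targets at all.
    The uniform level keeps Cov(L) positive definite with a factor-two
    margin and every mixture target well inside the attainable range.
    """
    share = 1.0 - float(np.linalg.eigvalsh(pop.sigma0).min()) / 2.0
    target = 3.0 + (k - 3.0) / share**2
    if target > _MIX_KURT_CAP:
        raise CalibrationError(f"mixture kurtosis target {target:.1f} exceeds cap")
    return np.full(pop.p, share)


# --- per-condition setups, cached because calibration is deterministic ----

_SETUP_CACHE: dict = {}


def _pop_key(pop: PopulationModel) -> bytes:
    return np.round(pop.sigma0, 12).tobytes()


def _spectral_root(sigma: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(sigma)
    if evals.min() <= 0:
        raise CalibrationError("Sigma0 not positive definite")
    return evecs * np.sqrt(evals)


def _solve_intermediate(corr_target: np.ndarray, ppfs) -> np.ndarray:
    """NORTA intermediate correlations, cached per (marginal pair, target).

    ``ppfs`` is one standardized inverse CDF per column (possibly shared
    objects); returns a factor root of the intermediate matrix.
    """
    m = corr_target.shape[0]
    inter = np.eye(m)
    pair_funs: dict[tuple, callable] = {}
    cache: dict[tuple, float] = {}
    for i in range(m):
        for j in range(i):
            pkey = (id(ppfs[i]), id(ppfs[j]))
            key = (round(float(corr_target[i, j]), 12), *sorted(pkey))
            if key not in cache:
                if pkey not in pair_funs:
                    pair_funs[pkey] = _pair_corr_fun(ppfs[i], ppfs[j])
                fun = pair_funs[pkey]
                target = corr_target[i, j]
                cache[key] = optimize.brentq(
                    lambda r: fun(r) - target, -0.9995, 0.9995, xtol=1e-6
                )
            inter[i, j] = inter[j, i] = cache[key]
    evals = np.linalg.eigvalsh(inter)
    if evals.min() < -1e-6:
        raise CalibrationError("intermediate correlation matrix indefinite")
    if evals.min() <= 0:
        evals_c, evecs = np.linalg.eigh(inter)
        return evecs * np.sqrt(np.clip(evals_c, 0.0, None))
    return np.linalg.cholesky(inter)


def _latent_setup(pop: PopulationModel, k: float):
    shares = latent_shares(pop, k)
    mixtures = {}
    per_var = []
    for s in shares:
        key = round(float(s), 12)
        if key not in mixtures:
            mixtures[key] = fit_mixture_weights(
                LATENT_COMPONENTS[k], k, variance_share=s
            )
        per_var.append(mixtures[key])
    corr_l = pop.sigma0 / np.sqrt(np.outer(shares, shares))
    np.fill_diagonal(corr_l, 1.0)
    root = _solve_intermediate(corr_l, [m.ppf for m in per_var])
    return {"mixtures": per_var, "root": root, "shares": shares}


def _error_setup(pop: PopulationModel, k: float):
    mixtures = [
        fit_mixture_weights(ERROR_COMPONENTS[k], k, variance_share=theta)
        for theta in pop.residual_vars
    ]
    return {
        "mixtures": mixtures,
        "chol_phi": np.linalg.cholesky(pop.factor_corr),
        "loadings": pop.loadings,
        "theta": pop.residual_vars,
    }


def _marginal_setup(pop: PopulationModel, k: float):
    # the VM targets reuse the marginal moments implied by the latent route,
    # so the marginal-transform condition matches the other sources' first
    # four marginal moments, variable by variable
    lat = _cached_setup(pop, "latent", k)
    skews = np.array(
        [s**1.5 * mix.skewness for s, mix in zip(lat["shares"], lat["mixtures"])]
    )
    coef_cache: dict[float, tuple] = {}
    coefs = []
    for sk in skews:
        key = round(float(sk), 12)
        if key not in coef_cache:
            coef_cache[key] = fleishman_coefficients(sk, k)
        coefs.append(coef_cache[key])
    m = pop.p
    inter = np.eye(m)
    cache: dict[tuple, float] = {}
    for i in range(m):
        for j in range(i):
            key = (round(float(pop.sigma0[i, j]), 12), coefs[i], coefs[j])
            if key not in cache:
                cache[key] = fleishman_intermediate_corr(
                    pop.sigma0[i, j], coefs[i], coefs[j]
                )
            inter[i, j] = inter[j, i] = cache[key]
    evals = np.linalg.eigvalsh(inter)
    if evals.min() <= 0:
        raise CalibrationError("VM intermediate correlation matrix not PD")
    return {"coefs": coefs, "root": np.linalg.cholesky(inter), "skews": skews}


def _cached_setup(pop: PopulationModel, source: str, k: float):
    key = (_pop_key(pop), source, float(k))
    if key not in _SETUP_CACHE:
        if source in ("normal",) or (source == "marginal" and k == 3.0):
            _SETUP_CACHE[key] = {"root": _spectral_root(pop.sigma0)}
        elif source == "latent":
            _SETUP_CACHE[key] = _latent_setup(pop, k)
        elif source == "error":
            _SETUP_CACHE[key] = _error_setup(pop, k)
        elif source == "marginal":
            _SETUP_CACHE[key] = _marginal_setup(pop, k)
    return _SETUP_CACHE[key]


def generate(
    condition: ConditionSpec,
    pop: PopulationModel,
    rng=None,
    with_moments: bool = True,
) -> Dataset:
    """Draw one sample for a condition.

    ``rng`` may be a numpy Generator, a seed, or None (then
    ``condition.seed`` is used).  Identical condition and seed give a
    bit-identical dataset.
    """
    if rng is None:
        rng = condition.seed
    rng = np.random.default_rng(rng)
    n, p = condition.n, pop.p
    setup = _cached_setup(pop, condition.source, condition.kurtosis)

    if condition.source == "normal" or (
        condition.source == "marginal" and condition.kurtosis == 3.0
    ):
        values = rng.standard_normal((n, p)) @ setup["root"].T
    elif condition.source == "latent":
        z = rng.standard_normal((n, p)) @ setup["root"].T
        u = stats.norm.cdf(z)
        shares = setup["shares"]
        l_part = np.column_stack(
            [
                np.sqrt(shares[i]) * setup["mixtures"][i].ppf(u[:, i])
                for i in range(p)
            ]
        )
        values = l_part + np.sqrt(1.0 - shares) * rng.standard_normal((n, p))
    elif condition.source == "error":
        factors = rng.standard_normal((n, pop.h)) @ setup["chol_phi"].T
        l_part = factors @ setup["loadings"].T
        u = stats.norm.cdf(rng.standard_normal((n, p)))
        e_part = np.column_stack(
            [
                np.sqrt(setup["theta"][i]) * setup["mixtures"][i].ppf(u[:, i])
                for i in range(p)
            ]
        )
        values = l_part + e_part
    else:  # marginal, k > 3: Vale-Maurelli
        z = rng.standard_normal((n, p)) @ setup["root"].T
        coefs = np.array(setup["coefs"])  # (p, 4) of (a, b, c, d)
        values = (
            coefs[:, 0] + coefs[:, 1] * z + coefs[:, 2] * z**2 + coefs[:, 3] * z**3
        )

    if not np.all(np.isfinite(values)):
        raise CalibrationError("generator produced non-finite values")
    return Dataset(
        values=values,
        condition=condition,
        moments=realized_moments(values) if with_moments else None,
    )


def save_dataset(dataset: Dataset, path) -> None:
    """Write the sample as CSV with a JSON sidecar of condition + moments."""
    path = Path(path)
    cols = [f"x{i + 1}" for i in range(dataset.values.shape[1])]
    pd.DataFrame(dataset.values, columns=cols).to_csv(path, index=False)
    meta = {
        "condition": {
            "source": dataset.condition.source,
            "kurtosis": dataset.condition.kurtosis,
            "n": dataset.condition.n,
            "specification": dataset.condition.specification,
            "seed": dataset.condition.seed,
        },
        "realized_moments": dataset.moments.to_dict() if dataset.moments is not None else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def load_dataset(path) -> Dataset:
    """Read a sample written by :func:`save_dataset`."""
    path = Path(path)
    values = pd.read_csv(path).to_numpy(dtype=float)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    condition = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        cond = meta["condition"]
        condition = ConditionSpec(
            source=cond["source"], kurtosis=cond["kurtosis"], n=cond["n"],
            specification=cond["specification"], seed=cond["seed"],
        )
    return Dataset(values=values, condition=condition, moments=realized_moments(values))
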