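"""Quantile-mixture marginals, Fleishman polynomials and NORTA machinery.

Non-normal marginals are built as quantile mixtures

    F^{-1}(u) = sum_m beta_m F_m^{-1}(u),    beta on the simplex,

whose first four moments follow from cross-moments of the component
quantile functions evaluated at a common uniform variate.  Pure component
moments are closed form; mixed cross-moments are integrated over (0,1) with
tanh-sinh (double-exponential) quadrature, which handles the heavy-tailed
endpoint behaviour of quantiles such as t(4.1) or the lognormal.  The
weights beta are then solved so the mixture attains a prescribed kurtosis.

Correlated non-normal vectors are produced with NORTA ("normal to
anything"): correlated standard normals are pushed through Phi and the
target inverse CDF, with the intermediate normal correlations calibrated by
Gauss-Hermite quadrature and bisection so the output correlations match the
target.  The Vale-Maurelli route (third-order polynomials in normals with
matched intermediate correlations) is provided for marginal-transform
conditions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize, special, stats

from .exceptions import CalibrationError, InfeasibleTargetError

__all__ = [
    "QuantileComponent",
    "COMPONENTS",
    "QuantileMixture",
    "fit_mixture_weights",
    "fleishman_coefficients",
    "fleishman_intermediate_corr",
    "norta_intermediate_corr",
    "norta_sample",
]

_E = math.e


def _clip_u(u):
    return np.clip(u, 1e-300, 1.0 - 1e-16)


@dataclass(frozen=True)
class QuantileComponent:
    """A mixture component: inverse CDF plus closed-form raw moments 1..4."""

    name: str
    ppf: callable
    raw_moments: tuple[float, float, float, float]


_NU = 4.1  # Student-t df used in the k=3 latent mixture; kurtosis 3 + 6/(nu-4) = 63

COMPONENTS: dict[str, QuantileComponent] = {
    "t4.1": QuantileComponent(
        "t4.1",
        lambda u: stats.t.ppf(_clip_u(u), _NU),
        (0.0, _NU / (_NU - 2), 0.0, 3 * _NU**2 / ((_NU - 2) * (_NU - 4))),
    ),
    "uniform": QuantileComponent(
        "uniform", lambda u: np.asarray(u, dtype=float), (1 / 2, 1 / 3, 1 / 4, 1 / 5)
    ),
    "normal": QuantileComponent(
        "normal", lambda u: special.ndtri(_clip_u(u)), (0.0, 1.0, 0.0, 3.0)
    ),
    # Z^3 standardized to unit variance (E[Z^6] = 15)
    "cubic_normal": QuantileComponent(
        "cubic_normal",
        lambda u: special.ndtri(_clip_u(u)) ** 3 / math.sqrt(15.0),
        (0.0, 1.0, 0.0, 10395.0 / 225.0),
    ),
    "lognormal": QuantileComponent(
        "lognormal",
        lambda u: np.exp(special.ndtri(_clip_u(u))),
        (_E**0.5, _E**2, _E**4.5, _E**8),
    ),
    # mirror image -X of a lognormal(0,1); quantile is -Q_ln(1-u)
    "neg_lognormal": QuantileComponent(
        "neg_lognormal",
        lambda u: -np.exp(-special.ndtri(_clip_u(u))),
        (-(_E**0.5), _E**2, -(_E**4.5), _E**8),
    ),
    "exponential": QuantileComponent(
        "exponential", lambda u: -np.log1p(-_clip_u(u)), (1.0, 2.0, 6.0, 24.0)
    ),
}


def _tanh_sinh_nodes(step: float = 0.02, t_max: float = 3.8):
    t = np.arange(-t_max, t_max + step / 2, step)
    u = 0.5 * (1.0 + np.tanh(0.5 * np.pi * np.sinh(t)))
    w = step * 0.25 * np.pi * np.cosh(t) / np.cosh(0.5 * np.pi * np.sinh(t)) ** 2
    keep = (u > 1e-300) & (u < 1.0 - 1e-16)
    return u[keep], w[keep]


_TS_U, _TS_W = _tanh_sinh_nodes()


@lru_cache(maxsize=32)
def _cross_tensors(names: tuple[str, ...]):
    """E[prod Q_i(U)] for all index multisets up to order 4.

    Pure powers use the components' closed-form moments; genuinely mixed
    products are tanh-sinh quadratures of the node values.
    """
    comps = [COMPONENTS[n] for n in names]
    vals = [c.ppf(_TS_U) for c in comps]
    tensors = {}
    for order in range(1, 5):
        for idx in itertools.combinations_with_replacement(range(len(names)), order):
            if len(set(idx)) == 1:
                tensors[idx] = comps[idx[0]].raw_moments[order - 1]
            else:
                prod = np.ones_like(_TS_U)
                for i in idx:
                    prod = prod * vals[i]
                tensors[idx] = float(_TS_W @ prod)
    return tensors


def _mixture_raw_moments(tensors, beta):
    m = np.zeros(4)
    n_comp = len(beta)
    for order in range(1, 5):
        for idx in itertools.combinations_with_replacement(range(n_comp), order):
            count = math.factorial(order)
            for g in set(idx):
                count //= math.factorial(idx.count(g))
            m[order - 1] += count * math.prod(beta[i] for i in idx) * tensors[idx]
    return m


def _central_stats(tensors, beta):
    m1, m2, m3, m4 = _mixture_raw_moments(tensors, beta)
    var = m2 - m1**2
    mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
    mu4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4
    return m1, var, mu3 / var**1.5, mu4 / var**2


@dataclass(frozen=True)
class QuantileMixture:
    """A standardized quantile mixture with fitted simplex weights.

    ``ppf(u)`` returns the mean-0 / variance-1 mixture quantile; the raw
    (unstandardized) mixture is sum_m beta_m * component_ppf_m(u).
    """

    components: tuple[str, ...]
    beta: np.ndarray
    mean: float
    var: float
    skewness: float
    kurtosis: float

    def raw_ppf(self, u):
        return sum(
            b * COMPONENTS[n].ppf(u) for b, n in zip(self.beta, self.components)
        )

    def ppf(self, u):
        return (self.raw_ppf(u) - self.mean) / math.sqrt(self.var)


def _kurtosis_range(tensors, n_comp, grid: int = 12):
    """Approximate attainable kurtosis range over the beta simplex."""
    best_lo, best_hi = np.inf, -np.inf
    ticks = np.linspace(0.0, 1.0, grid)
    for combo in itertools.product(ticks, repeat=n_comp - 1):
        rest = 1.0 - sum(combo)
        if rest < -1e-12:
            continue
        beta = np.array(list(combo) + [max(rest, 0.0)])
        if beta.sum() <= 0:
            continue
        beta = beta / beta.sum()
        k = _central_stats(tensors, beta)[3]
        best_lo, best_hi = min(best_lo, k), max(best_hi, k)
    return best_lo, best_hi


def fit_mixture_weights(
    components,
    target_kurtosis: float,
    variance_share: float = 1.0,
    tol: float = 0.1,
) -> QuantileMixture:
    """Solve the simplex weights so an indicator X = L + E hits its kurtosis.

    When the non-normal part carries ``variance_share`` of the unit indicator
    variance (the remainder normal and independent), fourth-cumulant
    additivity requires the mixture itself to have kurtosis
    3 + (target - 3) / variance_share**2; that is the value solved for here.

    Two components: exact bisection.  Three or more: the kurtosis constraint
    leaves slack, resolved by maximum entropy of beta (ties between mirror
    solutions broken toward nonnegative skewness).

    Raises
    ------
    InfeasibleTargetError
        If no simplex weight vector attains the required kurtosis; the
        achievable range is attached for diagnostics.
    """
    names = tuple(components)
    if not 0 < variance_share <= 1:
        raise ValueError("variance_share must be in (0, 1]")
    mix_target = 3.0 + (target_kurtosis - 3.0) / variance_share**2
    tensors = _cross_tensors(names)
    if len(names) == 1:
        beta = np.array([1.0])
        if abs(_central_stats(tensors, beta)[3] - mix_target) > tol:
            raise InfeasibleTargetError(
                f"single component has kurtosis {_central_stats(tensors, beta)[3]:.2f}, "
                f"target {mix_target:.2f}",
                achievable_range=(_central_stats(tensors, beta)[3],) * 2,
            )
    elif len(names) == 2:
        beta = _solve_two(tensors, mix_target)
    else:
        beta = _solve_maxent(tensors, mix_target, len(names))
    m1, var, skew, kurt = _central_stats(tensors, beta)
    if abs(kurt - mix_target) > tol:
        raise InfeasibleTargetError(
            f"kurtosis {kurt:.3f} misses target {mix_target:.3f} beyond tol {tol}",
            achievable_range=_kurtosis_range(tensors, len(names)),
        )
    return QuantileMixture(names, beta, m1, var, skew, kurt)


def _solve_two(tensors, mix_target):
    def f(b):
        return _central_stats(tensors, np.array([b, 1.0 - b]))[3] - mix_target

    grid = np.linspace(1e-9, 1.0 - 1e-9, 41)
    vals = np.array([f(b) for b in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise InfeasibleTargetError(
            f"two-component mixture cannot reach kurtosis {mix_target:.2f}",
            achievable_range=(vals.min() + mix_target, vals.max() + mix_target),
        )
    k = sign_change[0]
    b = optimize.brentq(f, grid[k], grid[k + 1], xtol=1e-13)
    return np.array([b, 1.0 - b])


def _solve_maxent(tensors, mix_target, n_comp):
    def neg_entropy(b):
        return float(np.sum(b * np.log(np.maximum(b, 1e-12))))

    def kurt_err(b):
        return _central_stats(tensors, b)[3] - mix_target

    starts = [np.full(n_comp, 1.0 / n_comp)]
    for j in range(n_comp):
        s = np.full(n_comp, 0.02)
        s[j] = 1.0 - 0.02 * (n_comp - 1)
        starts.append(s)
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_entropy, x0, method="SLSQP", bounds=[(0.0, 1.0)] * n_comp,
            constraints=[
                {"type": "eq", "fun": lambda b: b.sum() - 1.0},
                {"type": "eq", "fun": kurt_err},
            ],
            options=dict(maxiter=500, ftol=1e-14),
        )
        if res.success and abs(kurt_err(res.x)) < 0.05:
            skew = _central_stats(tensors, res.x)[2]
            key = (round(res.fun, 9), -skew)  # max entropy, then prefer right skew
            if best is None or key < best[0]:
                best = (key, res.x)
    if best is None:
        raise InfeasibleTargetError(
            f"max-entropy search found no weights with kurtosis {mix_target:.2f}",
            achievable_range=_kurtosis_range(tensors, n_comp),
        )
    return np.clip(best[1], 0.0, 1.0) / best[1].sum()


# ---------------------------------------------------------------------------
# Fleishman / Vale-Maurelli


def fleishman_coefficients(skew: float, kurt: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) with Y = a + bZ + cZ^2 + dZ^3 standardized.

    Y has mean 0, variance 1, the given skewness and (Pearson) kurtosis;
    a = -c by the mean-zero constraint.

    Raises
    ------
    InfeasibleTargetError
        If (skew, kurt) lies outside the attainable region of third-order
        polynomials in a standard normal.
    """
    ex = kurt - 3.0
    if kurt < 1.0 + skew**2:  # impossible for any distribution
        raise InfeasibleTargetError(f"(skew={skew}, kurt={kurt}) violates kurt >= 1+skew^2")

    def eqs(q):
        b, c, d = q
        return [
            b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1.0,
            2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2) - skew,
            24 * (b * d + c**2 * (1 + b**2 + 28 * b * d)
                  + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2)) - ex,
        ]

    for x0 in ([1.0, 0.0, 0.0], [0.9, 0.1, 0.05], [0.7, 0.2, 0.1], [0.5, 0.2, 0.15]):
        sol, info, ier, _ = optimize.fsolve(eqs, x0, xtol=1e-13, full_output=True)
        if ier == 1 and np.max(np.abs(info["fvec"])) < 1e-9 and sol[0] > 0:
            b, c, d = sol
            return (-c, b, c, d)
    raise InfeasibleTargetError(
        f"no Fleishman solution for skew={skew:.3f}, kurtosis={kurt:.3f}"
    )


def fleishman_intermediate_corr(target_r: float, coef_i, coef_j) -> float:
    """Normal correlation rho reproducing ``target_r`` after the polynomials.

    Solves the Vale-Maurelli cubic
    r = rho (b_i b_j + 3 b_i d_j + 3 d_i b_j + 9 d_i d_j)
        + 2 rho^2 c_i c_j + 6 rho^3 d_i d_j.
    """
    _, bi, ci, di = coef_i
    _, bj, cj, dj = coef_j
    lin = bi * bj + 3 * bi * dj + 3 * di * bj + 9 * di * dj

    def f(r):
        return r * lin + 2 * r**2 * ci * cj + 6 * r**3 * di * dj - target_r

    try:
        return optimize.brentq(f, -0.9999, 0.9999, xtol=1e-12)
    except ValueError as exc:
        raise CalibrationError(
            f"Vale-Maurelli correlation {target_r} out of attainable range"
        ) from exc


# ---------------------------------------------------------------------------
# NORTA

_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(96)
_GH_W = _GH_W / np.sqrt(2.0 * np.pi)


def _pair_corr_fun(ppf_i, ppf_j):
    gi = ppf_i(stats.norm.cdf(_GH_X))

    def r_of_rho(rho):
        z2 = rho * _GH_X[:, None] + math.sqrt(max(1.0 - rho**2, 0.0)) * _GH_X[None, :]
        gj = ppf_j(stats.norm.cdf(z2))
        return float(_GH_W @ ((gi[:, None] * gj) @ _GH_W))

    return r_of_rho


def norta_intermediate_corr(target_r: float, ppf_i, ppf_j, tol: float = 1e-6) -> float:
    """Solve E[G_i(Phi(Z1)) G_j(Phi(Z2))] = target_r for corr(Z1, Z2).

    The marginal ppfs must be standardized (mean 0, variance 1).  Bisection
    on 2-D Gauss-Hermite quadrature.
    """
    fun = _pair_corr_fun(ppf_i, ppf_j)
    try:
        return optimize.brentq(lambda r: fun(r) - target_r, -0.9995, 0.9995, xtol=tol)
    except ValueError as exc:
        lo, hi = fun(-0.9995), fun(0.9995)
        raise CalibrationError(
            f"target correlation {target_r:.4f} outside attainable "
            f"range [{lo:.4f}, {hi:.4f}] for these marginals"
        ) from exc


def norta_sample(target_corr: np.ndarray, marginals, n: int, rng) -> np.ndarray:
    """Draw n rows with given standardized marginals and target correlations.

    Parameters
    ----------
    target_corr : (m, m) ndarray
        Desired correlation matrix of the output (positive semidefinite;
        slight indefiniteness of the calibrated intermediate matrix is
        repaired by eigenvalue clipping).
    marginals : sequence of callables
        Standardized inverse CDFs, one per column (a single callable is
        broadcast to all columns).
    n : int
        Number of rows.
    rng : numpy Generator or int seed.
    """
    rng = np.random.default_rng(rng)
    target_corr = np.asarray(target_corr, dtype=float)
    m = target_corr.shape[0]
    if callable(marginals):
        marginals = [marginals] * m
    if len(marginals) != m:
        raise ValueError("need one marginal per column")

    inter = np.eye(m)
    cache: dict[tuple, float] = {}
    for i in range(m):
        for j in range(i):
            key = (round(target_corr[i, j], 12), id(marginals[i]), id(marginals[j]))
            if key not in cache:
                cache[key] = norta_intermediate_corr(
                    target_corr[i, j], marginals[i], marginals[j]
                )
            inter[i, j] = inter[j, i] = cache[key]

    evals, evecs = np.linalg.eigh(inter)
    if evals.min() < -1e-6:
        raise CalibrationError(
            f"intermediate correlation matrix strongly indefinite "
            f"(min eigenvalue {evals.min():.2e})"
        )
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((n, m)) @ root.T
    out = np.empty((n, m))
    u = stats.norm.cdf(z)
    for j in range(m):
        out[:, j] = marginals[j](u[:, j])
    if not np.all(np.isfinite(out)):
        raise CalibrationError("non-finite draws produced by NORTA transform")
    return out
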