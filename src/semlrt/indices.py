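"""Sample RMSEA and CFI for the uncorrected and corrected test statistics.

Each corrected statistic gets its own index formula so that the sample index
approximates the same population quantity (RMSEA0 = sqrt(F0/df),
CFI0 = (F_nm - F0)/F_nm) that the uncorrected index targets.  The rescaling
factors are c = tr(UG)/df for T_M / T_MB, b = tr(UG)/d for T_MV1,
a = sqrt(tr[(UG)^2]/df) for T_MV2 and g = tr(UG)/v for T_MS; the mixture
variant uses the uncorrected formulas with df replaced by tr(UG).  Within
any condition the same correction is applied to the null model, so the CFI
denominators use the null model's own scaling factors.
"""

from __future__ import annotations

import numpy as np

from .corrections import ScalingFactors, TestStatistic

__all__ = ["rmsea_sample", "cfi_sample", "condition_point_estimate", "fit_index_set"]


def _check_scaling(scal: ScalingFactors) -> None:
    # coherence identities: b*d = tr(UG), g*v = tr(UG), a^2*df = tr[(UG)^2]
    assert abs(scal.b * scal.d - scal.trace1) < 1e-8 * max(1.0, scal.trace1)
    assert abs(scal.g * scal.v - scal.trace1) < 1e-8 * max(1.0, scal.trace1)
    assert abs(scal.a**2 * scal.df - scal.trace2) < 1e-8 * max(1.0, scal.trace2)


def _rmsea_terms(name: str, stat: TestStatistic, scal: ScalingFactors):
    """(scale factor, df-like quantity) entering the RMSEA/CFI numerators."""
    df = scal.df
    if name in ("ML",):
        return 1.0, float(df)
    if name in ("M", "MB"):
        return scal.c, float(df)
    if name == "MV1":
        return scal.b, scal.d
    if name == "MV2":
        return scal.a, float(df)
    if name == "MS":
        return scal.g, scal.v
    if name == "mix":
        return 1.0, scal.trace1
    raise ValueError(f"unknown statistic name {name!r}")


def rmsea_sample(name: str, stat: TestStatistic, scal: ScalingFactors, n: int) -> float:
    """Sample RMSEA for the named statistic.

    The uncorrected version is sqrt(max(0, (T_ML - df) / ((N-1) df)));
    corrected versions rescale the excess over their own reference df so all
    variants estimate the same population RMSEA.
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    _check_scaling(scal)
    scale, df_like = _rmsea_terms(name, stat, scal)
    if df_like <= 0:
        raise ValueError("reference df must be positive")
    excess = scale * (stat.value - df_like)
    return float(np.sqrt(max(0.0, excess / ((n - 1) * df_like))))


def cfi_sample(
    name: str,
    stat: TestStatistic,
    null_stat: TestStatistic,
    scal: ScalingFactors,
    null_scal: ScalingFactors,
    floor_uncorrected: bool = False,
) -> float:
    """Sample CFI for the named statistic against the independence null.

    Corrected variants floor the misfit ratio at zero (hence CFI <= 1); the
    uncorrected and mixture variants use the plain ratio unless
    ``floor_uncorrected`` is set, preserving the asymmetry of the printed
    formulas.  A degenerate null model (null statistic at or below its
    reference df) yields NaN.
    """
    _check_scaling(scal)
    _check_scaling(null_scal)
    scale, df_like = _rmsea_terms(name, stat, scal)
    nscale, ndf_like = _rmsea_terms(name, null_stat, null_scal)
    denom = nscale * (null_stat.value - ndf_like)
    if denom <= 0:
        return float("nan")
    ratio = scale * (stat.value - df_like) / denom
    if name in ("ML", "mix") and not floor_uncorrected:
        return float(1.0 - ratio)
    return float(1.0 - max(0.0, ratio))


def condition_point_estimate(values) -> float:
    """Point estimate across replications: the median."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replications supplied")
    return float(np.median(arr))


def fit_index_set(
    statistics: dict[str, TestStatistic],
    null_statistics: dict[str, TestStatistic],
    scal: ScalingFactors,
    null_scal: ScalingFactors,
    n: int,
) -> dict[str, dict[str, float]]:
    """RMSEA and CFI for every statistic name present in ``statistics``."""
    out: dict[str, dict[str, float]] = {}
    for name, stat in statistics.items():
        null_name = name if name in null_statistics else "ML"
        out[name] = {
            "rmsea": rmsea_sample(name, stat, scal, n),
            "cfi": cfi_sample(name, stat, null_statistics[null_name], scal, null_scal),
        }
    return out
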