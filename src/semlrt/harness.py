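"""Monte Carlo harness: condition grid, replication loop, aggregation.

A condition is one design cell (source of non-normality x kurtosis x sample
size x specification status).  Each replication draws a fresh sample,
fits the analysis and null models, and records every statistic with its
p-value, RMSEA and CFI.  Non-convergent fits are replaced by a redraw (new
seed, never a restart of the same sample), so each condition aggregates
exactly ``reps`` valid replications; replacements are logged and counted.
Rejection rates are the percentage of p-values at or below alpha, flagged
against Bradley's liberal robustness interval [alpha/2, 3*alpha/2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corrections import STATISTIC_NAMES, analyze
from .cfa import correct_spec, misspecified_spec
from .datagen import (
    KURTOSIS_LEVELS,
    SAMPLE_SIZES,
    ConditionSpec,
    generate,
)
from .exceptions import SemlrtError
from .population import PopulationModel, default_population

logger = logging.getLogger(__name__)

__all__ = ["ConditionResult", "bradley_check", "run_replication", "run_condition",
           "run_study", "DEFAULT_GRID", "replication_rng"]

#: The full study grid: 3 sources x 3 kurtoses x 4 sample sizes x 2 specs.
DEFAULT_GRID = {
    "sources": ("latent", "error", "marginal"),
    "kurtosis": KURTOSIS_LEVELS,
    "sample_sizes": SAMPLE_SIZES,
    "specifications": ("correct", "misspecified"),
    "reps": 1000,
    "alpha": 0.05,
}

_SOURCE_CODE = {"latent": 1, "error": 2, "marginal": 3, "normal": 4}
_SPEC_CODE = {"correct": 1, "misspecified": 2}


def replication_rng(condition: ConditionSpec, rep: int, attempt: int = 0):
    """Deterministic per-replication generator.

    Seeded by (master seed, condition coordinates, replication index,
    attempt counter) so any single replication is reconstructible in
    isolation and redraws never reuse a stream.
    """
    return np.random.default_rng(
        [
            condition.seed,
            _SOURCE_CODE[condition.source],
            int(condition.kurtosis * 10),
            condition.n,
            _SPEC_CODE[condition.specification],
            rep,
            attempt,
        ]
    )


def bradley_check(rate_percent: float, alpha: float = 0.05) -> bool:
    """Bradley's liberal criterion: rate within [alpha/2, 3 alpha/2] (closed)."""
    if not 0 <= rate_percent <= 100:
        raise ValueError("rate must be a percentage in [0, 100]")
    return 100 * alpha * 0.5 <= rate_percent <= 100 * alpha * 1.5


@dataclass
class ConditionResult:
    """Aggregated outcome of one design cell."""

    condition: ConditionSpec
    rejection_rates: dict[str, float]          # percent, per statistic
    bradley: dict[str, bool]
    median_rmsea: dict[str, float]
    median_cfi: dict[str, float]
    attempted: int
    nonconvergent: int
    replications: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.rejection_rates:
            rows.append(
                {
                    "source": self.condition.source,
                    "kurtosis": self.condition.kurtosis,
                    "n": self.condition.n,
                    "specification": self.condition.specification,
                    "statistic": name,
                    "rejection_rate": self.rejection_rates[name],
                    "bradley_ok": self.bradley[name],
                    "median_rmsea": self.median_rmsea[name],
                    "median_cfi": self.median_cfi[name],
                    "attempted": self.attempted,
                    "nonconvergent": self.nonconvergent,
                }
            )
        return pd.DataFrame(rows)


def run_replication(
    condition: ConditionSpec,
    pop: PopulationModel,
    rep: int,
    attempt: int = 0,
    with_mixture: bool = True,
):
    """One replication: draw, fit, compute statistics and indices.

    Returns None when the fit does not converge (caller redraws).
    """
    rng = replication_rng(condition, rep, attempt)
    data = generate(condition, pop, rng=rng, with_moments=False)
    spec = (
        correct_spec(pop.p, pop.h)
        if condition.specification == "correct"
        else misspecified_spec(pop.p, pop.h)
    )
    record = analyze(data.values, spec, with_mixture=with_mixture)
    if not record["converged"]:
        return None
    return record


def run_condition(
    condition: ConditionSpec,
    pop: PopulationModel | None = None,
    alpha: float = 0.05,
    with_mixture: bool = True,
    keep_replications: bool = True,
    retry_factor: int = 10,
) -> ConditionResult:
    """Run all replications of a condition and aggregate.

    Non-convergent draws are replaced (attempt counter bumps the stream)
    up to ``retry_factor * reps`` total attempts.
    """
    pop = default_population() if pop is None else pop
    rows = []
    attempted = nonconv = 0
    budget = retry_factor * condition.reps
    for rep in range(condition.reps):
        record = None
        attempt = 0
        while record is None:
            if attempted >= budget:
                raise SemlrtError(
                    f"retry budget exhausted in {condition.label} "
                    f"({nonconv} non-convergent fits)"
                )
            attempted += 1
            record = run_replication(condition, pop, rep, attempt, with_mixture)
            if record is None:
                nonconv += 1
                attempt += 1
                logger.info("redraw in %s rep %d (attempt %d)",
                            condition.label, rep, attempt)
        names = [n for n in STATISTIC_NAMES if n in record["statistics"]]
        for name in names:
            stat = record["statistics"][name]
            idx = record["indices"][name]
            rows.append(
                {
                    "rep": rep,
                    "statistic": name,
                    "value": stat.value,
                    "ref_df": stat.df,
                    "pvalue": stat.pvalue,
                    "rmsea": idx["rmsea"],
                    "cfi": idx["cfi"],
                    "c": record["scaling"].c,
                }
            )
    reps_df = pd.DataFrame(rows)
    rates, brad, med_r, med_c = {}, {}, {}, {}
    for name, grp in reps_df.groupby("statistic", sort=False):
        rates[name] = 100.0 * float((grp["pvalue"] <= alpha).mean())
        brad[name] = bradley_check(rates[name], alpha)
        med_r[name] = float(grp["rmsea"].median())
        med_c[name] = float(grp["cfi"].median())
    return ConditionResult(
        condition=condition,
        rejection_rates=rates,
        bradley=brad,
        median_rmsea=med_r,
        median_cfi=med_c,
        attempted=attempted,
        nonconvergent=nonconv,
        replications=reps_df if keep_replications else None,
    )


def run_study(
    config: dict | None = None,
    pop: PopulationModel | None = None,
    seed: int = 0,
    progress: bool = False,
):
    """Run a condition grid and return (conditions table, replications table).

    ``config`` overrides entries of :data:`DEFAULT_GRID`.  The run is fully
    reproducible from ``seed``; conditions are independent, so aggregation
    is invariant to execution order.  Failures in single cells are logged
    and recorded, and the run continues.
    """
    cfg = dict(DEFAULT_GRID)
    if config:
        cfg.update(config)
    pop = default_population() if pop is None else pop
    cond_frames, rep_frames, failures = [], [], []
    for source in cfg["sources"]:
        for k in cfg["kurtosis"]:
            if source == "normal" and k != 3.0:
                continue
            for n in cfg["sample_sizes"]:
                for spec_status in cfg["specifications"]:
                    cond = ConditionSpec(
                        source=source, kurtosis=float(k), n=int(n),
                        specification=spec_status, reps=int(cfg["reps"]),
                        seed=seed,
                    )
                    if progress:
                        print(f"running {cond.label} ...", flush=True)
                    try:
                        result = run_condition(cond, pop, alpha=cfg["alpha"])
                    except SemlrtError as exc:
                        logger.error("condition %s failed: %s", cond.label, exc)
                        failures.append((cond.label, str(exc)))
                        continue
                    cond_frames.append(result.to_frame())
                    reps = result.replications.assign(
                        source=source, kurtosis=k, n=n, specification=spec_status
                    )
                    rep_frames.append(reps)
    conditions = pd.concat(cond_frames, ignore_index=True) if cond_frames else pd.DataFrame()
    replications = pd.concat(rep_frames, ignore_index=True) if rep_frames else pd.DataFrame()
    if failures:
        conditions.attrs["failures"] = failures
    return conditions, replications


def summarize(replications: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate a raw replication table into per-condition rows."""
    out = []
    keys = ["source", "kurtosis", "n", "specification", "statistic"]
    for key, grp in replications.groupby(keys, sort=False):
        rate = 100.0 * float((grp["pvalue"] <= alpha).mean())
        out.append(
            dict(
                zip(keys, key),
                rejection_rate=rate,
                bradley_ok=bradley_check(rate, alpha),
                median_rmsea=float(grp["rmsea"].median()),
                median_cfi=float(grp["cfi"].median()),
                reps=int(grp["rep"].nunique()),
            )
        )
    return pd.DataFrame(out)
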