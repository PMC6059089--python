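"""Seasonal reference intervals following veterinary clinical-pathology practice.

Per analyte and season partition the procedure is:

1. outlier screen by Horn's method — Box–Cox transform toward symmetry,
   then Tukey interquartile fences (k = 1.5) on the transformed scale;
2. descriptive statistics and a normality label (Shapiro–Wilk gating,
   Kolmogorov–Smirnov reported alongside);
3. the central 95% nonparametric reference interval via the rank-index
   estimator p·(n+1) with linear interpolation, clamped to the observed
   range;
4. 90% percentile-bootstrap confidence intervals around each interval
   bound (5000 with-replacement resamples by default);
5. the WCI/WRI precision ratio per bound — the width of a bound's CI over
   the width of the interval; ratios above 0.2 flag the partition as
   needing a larger sample.

Partitions below a minimum n (default 20) report descriptive statistics
only, with no interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ANALYTES, SEASONS
from .correction import ANALYTE_TO_CORRECTED

logger = logging.getLogger("ectogas")

#: Box–Cox λ grid searched by maximum likelihood in Horn's screen.
BOXCOX_LAMBDA_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.05), 2)


@dataclass(frozen=True)
class HornResult:
    retained: np.ndarray
    outliers: np.ndarray
    outlier_mask: np.ndarray  # True where the input value was flagged
    lam: float | None  # Box–Cox λ used (None if screen not applied)


@dataclass(frozen=True)
class DistributionAssessment:
    label: str | None  # "gaussian" | "non_gaussian" | None (n too small)
    shapiro_stat: float | None = None
    shapiro_p: float | None = None
    ks_stat: float | None = None
    ks_p: float | None = None


@dataclass
class ReferenceInterval:
    """One analyte × partition row of the reference table."""

    analyte: str
    partition: str
    n: int
    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    min: float | None = None
    max: float | None = None
    distribution: str | None = None
    lower: float | None = None
    upper: float | None = None
    ci_lower: tuple[float, float] | None = None
    ci_upper: tuple[float, float] | None = None
    wci_wri_lower: float | None = None
    wci_wri_upper: float | None = None
    imprecise: bool = False
    computed: bool = False
    n_outliers: int = 0


@dataclass(frozen=True)
class RISettings:
    """Knobs of the reference-interval procedure."""

    coverage: float = 0.95
    ci_level: float = 0.90
    bootstrap_reps: int = 5000
    min_n: int = 20
    alpha: float = 0.05  # normality-test level
    wci_wri_threshold: float = 0.2
    tukey_k: float = 1.5
    seed: int = 0
    analytes: tuple[str, ...] = ANALYTES
    partitions: tuple[str, ...] = SEASONS


def _boxcox_mle_lambda(x: np.ndarray, grid: np.ndarray = BOXCOX_LAMBDA_GRID) -> float:
    llf = np.array([stats.boxcox_llf(lam, x) for lam in grid])
    return float(grid[int(np.argmax(llf))])


def horn_outliers(values: Sequence[float], k: float = 1.5) -> HornResult:
    """Horn's outlier screen: Box–Cox toward symmetry, then Tukey fences.

    λ is chosen by maximum likelihood over a grid [−3, 3] (step 0.05).
    Data containing values ≤ 0 are shifted by (1 − min) before the
    transform (the fences are applied on the transformed scale, so the
    shift is never undone).  Fewer than 3 finite values, or a constant
    vector, retain everything.  One pass only — no iteration.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        raise ValueError("horn_outliers requires finite values")
    if x.size < 3:
        warnings.warn("fewer than 3 values: outlier screen skipped", stacklevel=2)
        return HornResult(x, x[:0], np.zeros(x.size, dtype=bool), None)
    if np.ptp(x) == 0.0:
        return HornResult(x, x[:0], np.zeros(x.size, dtype=bool), None)
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    xs = x + shift
    lam = _boxcox_mle_lambda(xs)
    z = stats.boxcox(xs, lmbda=lam)
    q1, q3 = np.percentile(z, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    mask = (z < lo) | (z > hi)
    return HornResult(x[~mask], x[mask], mask, lam)


def assess_distribution(values: Sequence[float], alpha: float = 0.05) -> DistributionAssessment:
    """Normality label: Shapiro–Wilk gates; KS (vs fitted normal) reported."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 8:
        warnings.warn("n < 8: distribution not assessed", stacklevel=2)
        return DistributionAssessment(label=None)
    sw = stats.shapiro(x)
    mu, sd = x.mean(), x.std(ddof=1)
    ks = stats.kstest(x, "norm", args=(mu, sd)) if sd > 0 else None
    label = "gaussian" if sw.pvalue >= alpha else "non_gaussian"
    return DistributionAssessment(
        label=label,
        shapiro_stat=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        ks_stat=float(ks.statistic) if ks else None,
        ks_p=float(ks.pvalue) if ks else None,
    )


def nonparametric_ri(
    values: Sequence[float], coverage: float = 0.95
) -> tuple[float, float]:
    """Central-``coverage`` nonparametric interval, rank index p·(n+1).

    Linear interpolation between order statistics; indices beyond the
    sample clamp to the observed min/max (so at moderate n the interval
    can coincide with the sample range).
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    p_lo = (1.0 - coverage) / 2.0
    lower, upper = np.quantile(x, [p_lo, 1.0 - p_lo], method="weibull")
    return float(lower), float(upper)


def bootstrap_bound_ci(
    values: Sequence[float],
    which: str,
    coverage: float = 0.95,
    reps: int = 5000,
    level: float = 0.90,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for one reference-interval bound.

    With-replacement resamples of size n; the chosen bound is recomputed on
    each resample and the central ``level`` percentile interval of those
    bound replicates is returned.  Deterministic given ``seed``.
    """
    if which not in ("lower", "upper"):
        raise ValueError("which must be 'lower' or 'upper'")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    x = np.asarray(list(values), dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = (1.0 - coverage) / 2.0 if which == "lower" else 1.0 - (1.0 - coverage) / 2.0
    idx = rng.integers(0, x.size, size=(reps, x.size))
    bounds = np.quantile(x[idx], p, axis=1, method="weibull")
    tail = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(bounds, [tail, 100.0 - tail])
    return float(lo), float(hi)


def wci_wri(ri: tuple[float, float], ci: tuple[float, float]) -> float:
    """CI width over reference-interval width; precision diagnostic."""
    lower, upper = ri
    if upper <= lower:
        raise ValueError("reference interval must have positive width")
    return (ci[1] - ci[0]) / (upper - lower)


def _descriptives(x: np.ndarray) -> dict:
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def reference_interval_for(
    values: Sequence[float],
    analyte: str,
    partition: str,
    settings: RISettings,
    rng: np.random.Generator | None = None,
) -> ReferenceInterval:
    """Run the full per-partition procedure on one analyte's values."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    x = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    row = ReferenceInterval(analyte=analyte, partition=partition, n=int(x.size))
    if x.size == 0:
        return row
    horn = horn_outliers(x, k=settings.tukey_k) if x.size >= 3 else HornResult(
        x, x[:0], np.zeros(x.size, dtype=bool), None
    )
    if horn.outliers.size:
        logger.info(
            "%s/%s: Horn's method excluded %d value(s): %s",
            analyte,
            partition,
            horn.outliers.size,
            np.round(horn.outliers, 4).tolist(),
        )
    kept = horn.retained
    row.n = int(kept.size)
    row.n_outliers = int(horn.outliers.size)
    for key, val in _descriptives(kept).items():
        setattr(row, key, val)
    if kept.size >= 8:
        row.distribution = assess_distribution(kept, settings.alpha).label
    if kept.size < settings.min_n:
        logger.info(
            "%s/%s: n=%d below min_n=%d, interval not computed",
            analyte,
            partition,
            kept.size,
            settings.min_n,
        )
        return row
    row.lower, row.upper = nonparametric_ri(kept, settings.coverage)
    row.ci_lower = bootstrap_bound_ci(
        kept, "lower", settings.coverage, settings.bootstrap_reps, settings.ci_level, rng
    )
    row.ci_upper = bootstrap_bound_ci(
        kept, "upper", settings.coverage, settings.bootstrap_reps, settings.ci_level, rng
    )
    if row.upper > row.lower:
        row.wci_wri_lower = wci_wri((row.lower, row.upper), row.ci_lower)
        row.wci_wri_upper = wci_wri((row.lower, row.upper), row.ci_upper)
        row.imprecise = (
            max(row.wci_wri_lower, row.wci_wri_upper) > settings.wci_wri_threshold
        )
    row.computed = True
    return row


def build_reference_table(
    corrected: pd.DataFrame,
    settings: RISettings = RISettings(),
    partition_col: str = "season",
) -> list[ReferenceInterval]:
    """Reference intervals for every analyte × partition of a corrected cohort.

    ``corrected`` must carry the corrected analyte columns (see
    ``correction.ANALYTE_TO_CORRECTED``) and the partition column; absent
    values are dropped per analyte.  Each analyte × partition cell gets its
    own bootstrap stream derived from ``settings.seed``, so the table is
    reproducible and perturbing one cell never changes any other row.
    """
    rows: list[ReferenceInterval] = []
    for ai, analyte in enumerate(settings.analytes):
        col = ANALYTE_TO_CORRECTED[analyte]
        for pi, part in enumerate(settings.partitions):
            rng = np.random.default_rng([settings.seed, ai, pi])
            vals = corrected.loc[corrected[partition_col] == part, col].dropna()
            rows.append(
                reference_interval_for(vals.to_numpy(), analyte, part, settings, rng)
            )
    return rows


#: Per-analyte decimal places used when emitting the report table.
REPORT_ROUNDING = {
    "ph": 2,
    "po2": 0,
    "pco2": 1,
    "hco3": 1,
    "tco2": 0,
    "lactate": 2,
    "be": 1,
}


def reference_table_frame(rows: Iterable[ReferenceInterval]) -> pd.DataFrame:
    """Flatten :class:`ReferenceInterval` rows to a report DataFrame."""
    records = []
    for r in rows:
        dp = REPORT_ROUNDING.get(r.analyte, 2)
        rnd = lambda v: (None if v is None else round(float(v), dp))  # noqa: E731
        records.append(
            {
                "analyte": r.analyte,
                "season": r.partition,
                "n": r.n,
                "n_outliers": r.n_outliers,
                "mean": rnd(r.mean),
                "sd": rnd(r.sd),
                "median": rnd(r.median),
                "min": rnd(r.min),
                "max": rnd(r.max),
                "distribution": r.distribution,
                "lower": rnd(r.lower),
                "upper": rnd(r.upper),
                "ci_lower_low": rnd(r.ci_lower[0]) if r.ci_lower else None,
                "ci_lower_high": rnd(r.ci_lower[1]) if r.ci_lower else None,
                "ci_upper_low": rnd(r.ci_upper[0]) if r.ci_upper else None,
                "ci_upper_high": rnd(r.ci_upper[1]) if r.ci_upper else None,
                "wci_wri_lower": None
                if r.wci_wri_lower is None
                else round(r.wci_wri_lower, 3),
                "wci_wri_upper": None
                if r.wci_wri_upper is None
                else round(r.wci_wri_upper, 3),
                "imprecise": r.imprecise,
                "computed": r.computed,
            }
        )
    return pd.DataFrame.from_records(records)
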