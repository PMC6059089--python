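"""General linear models, AICc ranking and DAG-adjusted effect estimates.

For each corrected analyte a fixed candidate set of ordinary-least-squares
models is fitted on a shared complete-case dataset and ranked by the
small-sample Akaike information criterion

    AICc = −2·lnL + 2k + 2k(k+1)/(n − k − 1),

where k counts the intercept, slopes, factor dummies *and* the residual
variance (so the intercept-only model has k = 2).  Evidence is summarised
by Akaike weights w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2) with
Δ_i = AICc_i − min AICc.

Default candidates (season replaces air temperature, which sits downstream
of season and is strongly collinear with it):

    Null | Activity | Season | PCV + Season | Activity + PCV + Season

Effect estimates are coefficients from multivariable fits whose adjustment
sets come from a causal diagram: season and activity are exogenous
(unadjusted); air temperature adjusts for season; PCV adjusts for season
and air temperature.  Season contrasts are pairwise differences of
model-adjusted season means with t-based standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SEASON_REFERENCE = "spring"
ACTIVITY_REFERENCE = "bright"

#: Predictor -> design columns it contributes (dummy coding, reference
#: levels dropped).
_TERM_COLUMNS = {
    "activity": ["activity_quiet"],
    "season": ["season_summer", "season_fall"],
    "pcv": ["pcv_pct"],
    "ta": ["ta_c"],
}

#: Source cohort columns a predictor needs for complete-case filtering.
_TERM_SOURCE = {
    "activity": ["activity"],
    "season": ["season"],
    "pcv": ["pcv_pct"],
    "ta": ["ta_c"],
}


@dataclass(frozen=True)
class CandidateModel:
    name: str
    response: str
    terms: tuple[str, ...] = ()


def default_candidates(response: str) -> list[CandidateModel]:
    """The five-model candidate set used for every analyte."""
    return [
        CandidateModel("Null", response, ()),
        CandidateModel("Activity", response, ("activity",)),
        CandidateModel("Season", response, ("season",)),
        CandidateModel("PCV + Season", response, ("pcv", "season")),
        CandidateModel("Activity + PCV + Season", response, ("activity", "pcv", "season")),
    ]


@dataclass
class GlmFit:
    """An OLS fit plus the bookkeeping AICc needs."""

    model: CandidateModel
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    rss: float
    loglik: float
    adj_r2: float
    p_overall: float
    n: int
    k: int  # coefficients + 1 for the residual variance
    design_columns: tuple[str, ...]
    data_index: pd.Index


@dataclass
class ModelRank:
    model: CandidateModel
    n: int
    k: int
    aicc: float
    delta: float
    weight: float
    adj_r2: float
    p_overall: float


@dataclass(frozen=True)
class EffectEstimate:
    response: str
    exposure: str
    estimate: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    adjusted_for: tuple[str, ...]
    n_used: int


#: Default DAG-derived adjustment sets per exposure.
DEFAULT_ADJUSTMENT_SETS: Mapping[str, tuple[str, ...]] = {
    "season": (),
    "activity": (),
    "ta": ("season",),
    "pcv": ("season", "ta"),
}


def _design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {"const": np.ones(len(data))}
    for term in terms:
        if term == "activity":
            cols["activity_quiet"] = (data["activity"] == "quiet").astype(float).to_numpy()
        elif term == "season":
            cols["season_summer"] = (data["season"] == "summer").astype(float).to_numpy()
            cols["season_fall"] = (data["season"] == "fall").astype(float).to_numpy()
        elif term == "pcv":
            cols["pcv_pct"] = data["pcv_pct"].to_numpy(dtype=float)
        elif term == "ta":
            cols["ta_c"] = data["ta_c"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown model term {term!r}")
    return pd.DataFrame(cols, index=data.index)


def fit_glm(data: pd.DataFrame, response: str, terms: Sequence[str]) -> GlmFit:
    """OLS fit of a corrected analyte on the given predictor terms.

    ``data`` must already be complete-case for the response and all terms.
    Raises on rank-deficient designs, naming the aliased columns.
    """
    y = data[response].to_numpy(dtype=float)
    X = _design_matrix(data, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p} coefficients")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify columns whose removal restores full rank
        aliased = [
            c
            for c in X.columns[1:]
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    res = sm.OLS(y, X).fit()
    if terms:
        p_overall = float(res.f_pvalue)
    else:
        p_overall = 1.0
    return GlmFit(
        model=CandidateModel(" + ".join(terms) if terms else "Null", response, tuple(terms)),
        params=res.params,
        bse=res.bse,
        pvalues=pd.Series(res.pvalues, index=res.params.index),
        cov=pd.DataFrame(res.cov_params(), index=res.params.index, columns=res.params.index),
        rss=float(res.ssr),
        loglik=float(res.llf),
        adj_r2=float(res.rsquared_adj) if terms else 0.0,
        p_overall=p_overall,
        n=int(n),
        k=int(p) + 1,
        design_columns=tuple(X.columns),
        data_index=data.index,
    )


def aicc(fit: GlmFit) -> float:
    """Small-sample-corrected AIC of a fit; requires n − k − 1 > 0."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(deltas: Sequence[float]) -> np.ndarray:
    """Akaike weights from ΔAICc values (normalised evidence)."""
    d = np.asarray(deltas, dtype=float)
    w = np.exp(-d / 2.0)
    return w / w.sum()


def rank_models(fits: Sequence[GlmFit]) -> list[ModelRank]:
    """Rank fits by AICc with Δ and Akaike weights.

    All fits must share the same complete-case dataset (identical n);
    ties in AICc are broken toward the smaller k.
    """
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(
            f"fits have differing n={sorted(ns)}; apply case-wise deletion before fitting"
        )
    vals = np.array([aicc(f) for f in fits])
    deltas = vals - vals.min()
    weights = akaike_weights(deltas)
    ranked = sorted(
        zip(fits, vals, deltas, weights), key=lambda t: (t[1], t[0].k)
    )
    return [
        ModelRank(
            model=f.model,
            n=f.n,
            k=f.k,
            aicc=float(a),
            delta=float(d),
            weight=float(w),
            adj_r2=f.adj_r2,
            p_overall=f.p_overall,
        )
        for f, a, d, w in ranked
    ]


def complete_cases(
    data: pd.DataFrame, response: str, candidates: Sequence[CandidateModel]
) -> pd.DataFrame:
    """Case-wise deletion over the response and every candidate's predictors."""
    needed = {response}
    for c in candidates:
        for term in c.terms:
            needed.update(_TERM_SOURCE[term])
    return data.dropna(subset=sorted(needed))


def candidate_table(
    data: pd.DataFrame,
    response: str,
    candidates: Sequence[CandidateModel] | None = None,
    min_n: int = 20,
) -> list[ModelRank]:
    """Fit and rank the candidate set for one analyte on shared data.

    Rows missing the response or *any* predictor used by *any* candidate
    are dropped first so every model sees the same n.
    """
    if candidates is None:
        candidates = default_candidates(response)
    cc = complete_cases(data, response, candidates)
    if len(cc) < min_n:
        raise ValueError(
            f"only {len(cc)} complete cases for {response}; need >= {min_n}"
        )
    fits = []
    for cand in candidates:
        fit = fit_glm(cc, response, cand.terms)
        fit.model = cand
        fits.append(fit)
    return rank_models(fits)


def collinearity_screen(
    data: pd.DataFrame, predictors: Sequence[str], threshold: float = 0.5
) -> list[dict]:
    """Pairwise Pearson r among continuous predictors; |r| > threshold flags."""
    if len(predictors) < 2:
        raise ValueError("need at least two continuous predictors")
    out = []
    for a, b in combinations(predictors, 2):
        sub = data[[a, b]].dropna()
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            import warnings

            warnings.warn(f"constant column in pair ({a}, {b}); r undefined", stacklevel=2)
            out.append({"pair": (a, b), "r": np.nan, "flagged": False})
            continue
        r, _ = stats.pearsonr(sub[a], sub[b])
        out.append({"pair": (a, b), "r": float(r), "flagged": bool(abs(r) > threshold)})
    return out


def _t_inference(est: float, se: float, dof: int) -> tuple[float, float, float]:
    t = est / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    half = stats.t.ppf(0.975, dof) * se
    return float(p), float(est - half), float(est + half)


def adjusted_effect(
    data: pd.DataFrame,
    response: str,
    exposure: str,
    adjustment_set: Sequence[str] | None = None,
) -> EffectEstimate | list[EffectEstimate]:
    """Confounder-adjusted effect of one exposure on one analyte.

    Fits response ~ exposure + adjustment_set by OLS on complete cases and
    returns the exposure coefficient (continuous exposure) or the
    level-vs-reference difference (categorical).  A 3-level categorical
    exposure (season) returns one estimate per non-reference level.
    """
    if adjustment_set is None:
        adjustment_set = DEFAULT_ADJUSTMENT_SETS.get(exposure, ())
    if exposure in adjustment_set:
        raise ValueError(f"exposure {exposure!r} cannot appear in its adjustment set")
    terms = (exposure, *adjustment_set)
    needed = sorted({response, *(c for t in terms for c in _TERM_SOURCE[t])})
    cc = data.dropna(subset=needed)
    fit = fit_glm(cc, response, terms)
    dof = fit.n - (fit.k - 1)
    results = []
    for col in _TERM_COLUMNS[exposure]:
        est, se = float(fit.params[col]), float(fit.bse[col])
        p, lo, hi = _t_inference(est, se, dof)
        results.append(
            EffectEstimate(
                response=response,
                exposure=col,
                estimate=est,
                se=se,
                p=p,
                ci_low=lo,
                ci_high=hi,
                adjusted_for=tuple(adjustment_set),
                n_used=fit.n,
            )
        )
    return results[0] if len(results) == 1 else results


def season_contrasts(fit: GlmFit, response: str | None = None) -> list[EffectEstimate]:
    """All pairwise differences of model-adjusted season means.

    Under the additive dummy-coded fit the adjusted mean differences are
    linear combinations of the season coefficients (continuous covariates
    drop out); SEs come from the coefficient covariance, p-values from the
    t distribution.  No multiplicity adjustment by default.
    """
    if "season_summer" not in fit.params.index:
        raise ValueError("fit does not include season")
    response = response or fit.model.response
    dof = fit.n - (fit.k - 1)
    # contrast vectors over (season_summer, season_fall)
    specs = {
        "summer - spring": np.array([1.0, 0.0]),
        "fall - spring": np.array([0.0, 1.0]),
        "fall - summer": np.array([-1.0, 1.0]),
    }
    idx = ["season_summer", "season_fall"]
    beta = fit.params[idx].to_numpy(dtype=float)
    cov = fit.cov.loc[idx, idx].to_numpy(dtype=float)
    out = []
    for name, c in specs.items():
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        p, lo, hi = _t_inference(est, se, dof)
        out.append(
            EffectEstimate(
                response=response,
                exposure=f"season:{name}",
                estimate=est,
                se=se,
                p=p,
                ci_low=lo,
                ci_high=hi,
                adjusted_for=tuple(t for t in fit.model.terms if t != "season"),
                n_used=fit.n,
            )
        )
    return out


def rank_table_frame(ranks: Sequence[ModelRank]) -> pd.DataFrame:
    """Flatten ranked models to a report table (weights at 2 dp)."""
    return pd.DataFrame(
        [
            {
                "response": r.model.response,
                "model": r.model.name,
                "n": r.n,
                "k": r.k,
                "aicc": round(r.aicc, 2),
                "delta": round(r.delta, 2),
                "weight": round(r.weight, 2),
                "adj_r2": round(r.adj_r2, 3),
                "p_overall": r.p_overall,
            }
            for r in ranks
        ]
    )
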