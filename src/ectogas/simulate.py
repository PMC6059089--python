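"""Seeded synthetic cohorts with the study's effect structure.

The generator emulates a ~100-animal, three-season field study: per season
a sample size, a mean daily air temperature distribution, a Bernoulli
quiet/bright activity mix, a PCV linear model (season offsets plus a
within-season temperature slope), and per-analyte linear models with
additive season, activity and PCV effects and Gaussian residuals.  Defaults
carry the printed effect sizes of the study being emulated (quiet pH −0.19,
quiet pO2 −9.3 mmHg, quiet pCO2 +15 mmHg, summer−spring pCO2 +10 mmHg,
summer−spring lactate +2.36 mmol/l, summer−spring PCV +7%, summer−spring
air temperature +5.47 °C, summer−fall BE −4.71 mmol/l, ...).

True analyte values are generated on the temperature-corrected scale for
pH, pO2, pCO2, lactate and BE; bicarbonate and total CO2 are then *derived*
from corrected pH/pCO2 through the same Henderson–Hasselbalch machinery the
analysis uses — exactly as a blood gas analyzer calculates them — so the
true panels satisfy the corrected-panel identities, and their seasonal
structure is emergent rather than configured.  Instrument-scale (37 °C)
panels are produced by exact algebraic inversion of the correction
formulas, which makes the correction stage a nontrivial, testable step.

Artifact injection adds instrument-style missingness (independent per
field) and gross multi-analyte outlier animals (displacement by a multiple
of the residual SD on ≥2 analytes) with a log for oracle checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import BloodGasPanel, SEASONS, TurtleObservation
from .correction import (
    ANALYZER_TEMP_C,
    CorrectedPanel,
    PH_COEFFS,
    PCO2_EXP_COEFF,
    PO2_EXP_COEFF,
    REFERENCE_PH,
    alpha_co2,
    pka,
    recompute_hco3,
    recompute_tco2,
)

#: PCV value (%) the analyte intercepts are anchored at.
PCV_CENTER = 25.0

#: Analytes generated from their own linear models (corrected scale).
FREE_ANALYTES = ("ph", "po2", "pco2", "lactate", "be")
#: Analytes derived from pH/pCO2 via Henderson–Hasselbalch.
DERIVED_ANALYTES = ("hco3", "tco2")


@dataclass(frozen=True)
class AnalyteModel:
    """Additive linear model for one analyte on the corrected scale.

    value = intercept + season_offset + quiet·quiet_offset
            + pcv_slope·(PCV − 25) + Normal(0, sd)

    ``floor``, when set, truncates draws from below (lactate and the
    pressures cannot be negative).
    """

    intercept: float
    season_offsets: Mapping[str, float]
    quiet_offset: float
    pcv_slope: float
    sd: float
    floor: float | None = None

    def linear_predictor(self, season: str, quiet, pcv) -> np.ndarray:
        off = np.asarray(self.season_offsets.get(season, 0.0), dtype=float)
        return (
            self.intercept
            + off
            + self.quiet_offset * np.asarray(quiet, dtype=float)
            + self.pcv_slope * (np.asarray(pcv, dtype=float) - PCV_CENTER)
        )


@dataclass(frozen=True)
class PcvModel:
    """PCV (%) linear model: season offsets plus within-season T_A slope."""

    intercept: float
    season_offsets: Mapping[str, float]
    ta_slope: float  # %/°C on the within-season temperature anomaly
    sd: float


@dataclass(frozen=True)
class SimulationConfig:
    n_per_season: Mapping[str, int]
    ta_mean: Mapping[str, float]
    ta_sd: float
    p_quiet: float
    pcv_model: PcvModel
    analyte_models: Mapping[str, AnalyteModel]
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 8.0
    outlier_n_analytes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_quiet <= 1.0:
            raise ValueError("p_quiet must be a probability")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be a probability")
        if any(n < 0 for n in self.n_per_season.values()):
            raise ValueError("n_per_season entries must be >= 0")
        if self.ta_sd <= 0 or self.pcv_model.sd <= 0:
            raise ValueError("standard deviations must be positive")
        for name, m in self.analyte_models.items():
            if m.sd <= 0:
                raise ValueError(f"analyte {name}: sd must be positive")
        for f, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {f} must be a probability")


def default_config(seed: int) -> SimulationConfig:
    """Study-calibrated defaults; the seed must be given explicitly.

    Sample sizes 40/42/20 across spring/summer/fall, seasonal temperature
    means separated by the printed contrasts (summer−spring +5.47 °C,
    summer−fall +7.82 °C), a 67.3% quiet fraction, PCV near 25% in spring
    with +7% in summer, and the printed analyte effect sizes.  Residual SDs
    are backed out from the printed per-season marginal SDs net of the
    explained components (they are not printed directly) and, for lactate,
    kept small enough that the additive-Gaussian surrogate respects the
    strictly positive observed range.
    """
    return SimulationConfig(
        n_per_season={"spring": 40, "summer": 42, "fall": 20},
        ta_mean={"spring": 19.18, "summer": 24.65, "fall": 16.83},
        ta_sd=2.5,
        p_quiet=0.673,
        pcv_model=PcvModel(
            intercept=21.7,
            season_offsets={"spring": 0.0, "summer": 7.0, "fall": 2.3},
            ta_slope=0.2,
            sd=7.3,
        ),
        analyte_models={
            "ph": AnalyteModel(7.62, {"summer": -0.13, "fall": 0.09}, -0.19, -0.01, 0.14),
            "po2": AnalyteModel(63.3, {}, -9.3, -0.8, 18.0, floor=1.0),
            "pco2": AnalyteModel(22.7, {"summer": 10.0, "fall": -7.5}, 15.0, 0.8, 10.0, floor=1.0),
            "lactate": AnalyteModel(4.97, {"summer": 2.36, "fall": -0.36}, 0.0, 0.08, 2.2, floor=0.1),
            "be": AnalyteModel(1.9, {"summer": -3.07, "fall": 1.64}, 0.0, -0.3, 4.5),
        },
        missing_rates={
            "pcv_pct": 0.02,
            "activity": 0.04,
            "be_i": 0.02,
            "lactate_i": 0.01,
        },
        outlier_rate=0.03,
        outlier_magnitude_sd=8.0,
        outlier_n_analytes=2,
        seed=seed,
    )


def invert_panel(true_panel: CorrectedPanel, ta: float) -> BloodGasPanel:
    """Exact algebraic inverse of the correction: corrected → instrument scale.

    The pH correction is linear in the instrument pH and is solved in
    closed form; the pressure corrections divide out their base-10
    factors.  Instrument HCO3/TCO2 are regenerated at 37 °C from the
    instrument pH and pCO2 via Henderson–Hasselbalch, mirroring how an
    analyzer computes them.  BE and lactate copy through.
    """
    d = ta - ANALYZER_TEMP_C
    a, b = PH_COEFFS
    denom = 1.0 - b * d
    if denom == 0.0:
        raise ValueError("pH inversion singular at this temperature")
    ph_i = None
    if true_panel.ph_c is not None:
        ph_i = (true_panel.ph_c - (-a + b * REFERENCE_PH) * d) / denom
    po2_i = None
    if true_panel.po2_c is not None:
        po2_i = true_panel.po2_c / 10.0 ** (PO2_EXP_COEFF * d)
    pco2_i = None
    if true_panel.pco2_c is not None:
        pco2_i = true_panel.pco2_c / 10.0 ** (PCO2_EXP_COEFF * d)
    hco3_i = tco2_i = None
    if ph_i is not None and pco2_i is not None:
        alpha37 = alpha_co2(ANALYZER_TEMP_C)
        pka37 = pka(ph_i, ANALYZER_TEMP_C)
        hco3_i = recompute_hco3(alpha37, pco2_i, ph_i, pka37)
        tco2_i = recompute_tco2(hco3_i, alpha37, pco2_i)
    return BloodGasPanel(
        ph_i=ph_i,
        po2_i=po2_i,
        pco2_i=pco2_i,
        hco3_i=hco3_i,
        tco2_i=tco2_i,
        be_i=true_panel.be,
        lactate_i=true_panel.lactate,
    )


def _derive_panel(ph_c, po2_c, pco2_c, be, lactate, ta) -> CorrectedPanel:
    alpha = alpha_co2(ta)
    pka_val = pka(ph_c, ta)
    hco3_c = recompute_hco3(alpha, pco2_c, ph_c, pka_val)
    return CorrectedPanel(
        ph_c=ph_c,
        po2_c=po2_c,
        pco2_c=pco2_c,
        alpha_co2=alpha,
        pka=pka_val,
        hco3_c=hco3_c,
        tco2_c=recompute_tco2(hco3_c, alpha, pco2_c),
        be=be,
        lactate=lactate,
    )


@dataclass
class SimulatedCohort:
    observations: list[TurtleObservation]
    truth: pd.DataFrame  # true corrected panels + covariates, one row per animal
    injection_log: dict = field(default_factory=lambda: {"outliers": [], "missing": []})


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a clean cohort (no artifacts) deterministically from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    obs_list: list[TurtleObservation] = []
    truth_rows: list[dict] = []
    i = 0
    for season in SEASONS:
        n = int(config.n_per_season.get(season, 0))
        if n == 0:
            continue
        ta = rng.normal(config.ta_mean[season], config.ta_sd, size=n)
        quiet = rng.random(n) < config.p_quiet
        pm = config.pcv_model
        pcv = (
            pm.intercept
            + pm.season_offsets.get(season, 0.0)
            + pm.ta_slope * (ta - config.ta_mean[season])
            + rng.normal(0.0, pm.sd, size=n)
        )
        pcv = np.clip(pcv, 1.0, 60.0)
        free = {}
        for name in FREE_ANALYTES:
            m = config.analyte_models[name]
            v = m.linear_predictor(season, quiet, pcv) + rng.normal(0.0, m.sd, size=n)
            if m.floor is not None:
                v = np.maximum(v, m.floor)
            free[name] = v
        for j in range(n):
            animal_id = f"t{i:04d}"
            true_panel = _derive_panel(
                float(free["ph"][j]),
                float(free["po2"][j]),
                float(free["pco2"][j]),
                float(free["be"][j]),
                float(free["lactate"][j]),
                float(ta[j]),
            )
            panel = invert_panel(true_panel, float(ta[j]))
            obs_list.append(
                TurtleObservation(
                    id=animal_id,
                    state="sim",
                    site="sim",
                    season=season,
                    sex="unknown",
                    age_class="adult",
                    activity="quiet" if quiet[j] else "bright",
                    pcv_pct=float(pcv[j]),
                    ta_c=float(ta[j]),
                    panel=panel,
                )
            )
            truth_rows.append(
                {
                    "id": animal_id,
                    "season": season,
                    "ta_c": float(ta[j]),
                    "activity": "quiet" if quiet[j] else "bright",
                    "pcv_pct": float(pcv[j]),
                    "ph_c": true_panel.ph_c,
                    "po2_c": true_panel.po2_c,
                    "pco2_c": true_panel.pco2_c,
                    "alpha_co2": true_panel.alpha_co2,
                    "pka": true_panel.pka,
                    "hco3_c": true_panel.hco3_c,
                    "tco2_c": true_panel.tco2_c,
                    "be": true_panel.be,
                    "lactate": true_panel.lactate,
                }
            )
            i += 1
    return SimulatedCohort(obs_list, pd.DataFrame(truth_rows))


#: Panel/covariate fields eligible for independent blanking.
_BLANKABLE_FIELDS = (
    "pcv_pct",
    "activity",
    "ph_i",
    "po2_i",
    "pco2_i",
    "hco3_i",
    "tco2_i",
    "be_i",
    "lactate_i",
)


def inject_artifacts(cohort: SimulatedCohort, config: SimulationConfig) -> SimulatedCohort:
    """Add outlier animals and instrument missingness; returns a new cohort.

    Outlier animals (Bernoulli ``outlier_rate``) get ``outlier_n_analytes``
    of the freely generated analytes displaced by ±magnitude·residual-SD on
    the true (corrected) scale; bicarbonate/total CO2 are re-derived and
    the instrument panel re-inverted, so displaced pH/pCO2 propagate to the
    calculated analytes just as on a real analyzer.  Missingness then
    blanks each field independently at its configured rate.  The injection
    log records every action for oracle checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    obs_out: list[TurtleObservation] = []
    truth = cohort.truth.set_index("id")
    log: dict = {"outliers": [], "missing": []}
    for obs in cohort.observations:
        new_obs = obs
        if config.outlier_rate > 0 and rng.random() < config.outlier_rate:
            chosen = [
                str(a)
                for a in rng.choice(
                    FREE_ANALYTES, size=config.outlier_n_analytes, replace=False
                )
            ]
            signs = rng.choice([-1.0, 1.0], size=len(chosen))
            row = truth.loc[obs.id]
            vals = {
                "ph": row["ph_c"],
                "po2": row["po2_c"],
                "pco2": row["pco2_c"],
                "lactate": row["lactate"],
                "be": row["be"],
            }
            for j, (a, s) in enumerate(zip(chosen, signs)):
                m = config.analyte_models[a]
                shift = config.outlier_magnitude_sd * m.sd
                # a displacement clipped at the physical floor is no longer a
                # gross extreme; direct it upward instead
                if m.floor is not None and vals[a] - shift <= m.floor:
                    s = 1.0
                    signs[j] = s
                vals[a] = vals[a] + s * shift
            if vals["ph"] <= 0 or vals["ph"] >= 14:
                vals["ph"] = min(max(vals["ph"], 6.0), 8.5)
            displaced = _derive_panel(
                vals["ph"], vals["po2"], vals["pco2"], vals["be"], vals["lactate"], obs.ta_c
            )
            new_obs = replace(obs, panel=invert_panel(displaced, obs.ta_c))
            for col, val in {
                "ph_c": displaced.ph_c,
                "po2_c": displaced.po2_c,
                "pco2_c": displaced.pco2_c,
                "hco3_c": displaced.hco3_c,
                "tco2_c": displaced.tco2_c,
                "be": displaced.be,
                "lactate": displaced.lactate,
            }.items():
                truth.loc[obs.id, col] = val
            log["outliers"].append(
                {"id": obs.id, "analytes": sorted(chosen), "signs": signs.tolist()}
            )
        if config.missing_rates:
            panel_kwargs = {
                f: getattr(new_obs.panel, f)
                for f in (
                    "ph_i",
                    "po2_i",
                    "pco2_i",
                    "hco3_i",
                    "tco2_i",
                    "be_i",
                    "lactate_i",
                )
            }
            obs_kwargs = {}
            for fname in _BLANKABLE_FIELDS:
                rate = config.missing_rates.get(fname, 0.0)
                if rate <= 0:
                    continue
                if rng.random() < rate:
                    if fname in panel_kwargs:
                        panel_kwargs[fname] = None
                    else:
                        obs_kwargs[fname] = None
                    log["missing"].append({"id": new_obs.id, "field": fname})
            if obs_kwargs or any(
                panel_kwargs[f] is None and getattr(new_obs.panel, f) is not None
                for f in panel_kwargs
            ):
                new_obs = replace(
                    new_obs, panel=BloodGasPanel(**panel_kwargs), **obs_kwargs
                )
        obs_out.append(new_obs)
    return SimulatedCohort(obs_out, truth.reset_index(), log)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort and apply the configured artifacts."""
    return inject_artifacts(generate_cohort(config), config)
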