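"""Temperature correction of 37 °C blood gas panels to animal temperature.

Point-of-care analyzers warm the sample to 37 °C before measuring, which in
a closed system shifts pH, pO2 and pCO2 away from their values at the
animal's own temperature.  For ectotherms the panel is therefore corrected
back to an animal-relevant temperature ``ta`` (here: mean daily air
temperature, °C):

    pH(ta)   = pH_i − 0.0147·(ta−37) + 0.0065·(7.4−pH_i)·(ta−37)
    pO2(ta)  = pO2_i · 10^(−0.0058·(ta−37))
    pCO2(ta) = pCO2_i · 10^(0.0019·(ta−37))

Bicarbonate and total CO2 are then *recalculated* (not corrected) from the
corrected pH and pCO2 through the Henderson–Hasselbalch equation with a
temperature-dependent CO2 solubility αCO2(ta) and apparent dissociation
constant pKa(pH, ta) derived for sea turtles:

    HCO3(ta) = αCO2 · pCO2(ta) · 10^(pH(ta) − pKa)
    TCO2(ta) = HCO3(ta) + αCO2 · pCO2(ta)

Base excess cannot be recalculated without hemoglobin and is passed through
as raw instrument output, as is lactate.

The pKa expression ends in a log term whose quotient grouping is taken as

    pKa = poly(ta) − log10[ (1.011 + 10^(pH+0.011·ta−10.241))
                            / (1 + 10^(pH+0.001·ta−8.889)) ]

(see :func:`pka_log_quotient`); this is the only grouping of the published
constants that forms a dimensionless quotient and yields physiologic pKa
values (≈5.8–6.5 over the relevant pH/temperature range).  The quotient is
isolated in its own function so an alternative reading could be swapped in.

All scalar functions also accept numpy arrays.  ``None`` inputs propagate
to ``None`` outputs (instrument errors stay missing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ANALYZER_TEMP_C = 37.0
REFERENCE_PH = 7.4

#: pH correction coefficients (per °C; per °C per pH unit).
PH_COEFFS = (0.0147, 0.0065)
#: Base-10 exponent slopes per °C for the pressure corrections.
PO2_EXP_COEFF = -0.0058
PCO2_EXP_COEFF = 0.0019
#: αCO2 cubic in ta (mmol·l⁻¹·mmHg⁻¹): a0 + a1·ta + a2·ta² + a3·ta³.
ALPHA_POLY = (9.174e-2, -3.269e-3, 6.364e-5, -5.378e-7)
#: pKa cubic polynomial part in ta.
PKA_POLY = (6.398, -1.341e-2, 2.282e-4, -1.516e-6)
#: Constants of the pKa log-quotient term.
PKA_LOG_CONSTANTS = (1.011, 0.011, 10.241, 0.001, 8.889)


@dataclass(frozen=True)
class CorrectionConstants:
    """Read-only bundle of the published correction coefficients."""

    analyzer_temp: float = ANALYZER_TEMP_C
    reference_ph: float = REFERENCE_PH
    ph_coeffs: tuple[float, float] = PH_COEFFS
    po2_exp_coeff: float = PO2_EXP_COEFF
    pco2_exp_coeff: float = PCO2_EXP_COEFF
    alpha_poly: tuple[float, ...] = ALPHA_POLY
    pka_poly: tuple[float, ...] = PKA_POLY
    pka_log_constants: tuple[float, ...] = PKA_LOG_CONSTANTS


CONSTANTS = CorrectionConstants()


@dataclass(frozen=True)
class CorrectedPanel:
    """Panel at animal temperature plus the derived constants.

    ``be`` and ``lactate`` are raw instrument pass-through.  Fields are
    ``None`` when an instrument input they depend on was missing.
    """

    ph_c: float | None = None
    po2_c: float | None = None
    pco2_c: float | None = None
    alpha_co2: float | None = None
    pka: float | None = None
    hco3_c: float | None = None
    tco2_c: float | None = None
    be: float | None = None
    lactate: float | None = None


def correct_ph(ph_i, ta):
    """Corrected pH at temperature ``ta`` from the 37 °C instrument pH."""
    if ph_i is None:
        return None
    d = np.asarray(ta, dtype=float) - ANALYZER_TEMP_C
    a, b = PH_COEFFS
    out = np.asarray(ph_i, dtype=float) - a * d + b * (REFERENCE_PH - np.asarray(ph_i, dtype=float)) * d
    return float(out) if np.ndim(out) == 0 else out


def correct_po2(po2_i, ta):
    """Corrected pO2 (mmHg) at ``ta``; multiplicative base-10 form."""
    if po2_i is None:
        return None
    d = np.asarray(ta, dtype=float) - ANALYZER_TEMP_C
    out = np.asarray(po2_i, dtype=float) * 10.0 ** (PO2_EXP_COEFF * d)
    return float(out) if np.ndim(out) == 0 else out


def correct_pco2(pco2_i, ta):
    """Corrected pCO2 (mmHg) at ``ta``; multiplicative base-10 form."""
    if pco2_i is None:
        return None
    d = np.asarray(ta, dtype=float) - ANALYZER_TEMP_C
    out = np.asarray(pco2_i, dtype=float) * 10.0 ** (PCO2_EXP_COEFF * d)
    return float(out) if np.ndim(out) == 0 else out


def alpha_co2(ta):
    """CO2 plasma solubility αCO2(ta), mmol·l⁻¹·mmHg⁻¹ (cubic in ta)."""
    t = np.asarray(ta, dtype=float)
    a0, a1, a2, a3 = ALPHA_POLY
    out = a0 + a1 * t + a2 * t**2 + a3 * t**3
    return float(out) if np.ndim(out) == 0 else out


def pka_log_quotient(ph_ta, ta):
    """The dimensionless quotient inside the pKa log term.

    Grouping: (c0 + 10^(pH + c1·ta − c2)) / (1 + 10^(pH + c3·ta − c4)).
    """
    c0, c1, c2, c3, c4 = PKA_LOG_CONSTANTS
    ph = np.asarray(ph_ta, dtype=float)
    t = np.asarray(ta, dtype=float)
    return (c0 + 10.0 ** (ph + c1 * t - c2)) / (1.0 + 10.0 ** (ph + c3 * t - c4))


def pka(ph_ta, ta):
    """Apparent carbonic-acid pKa at ``ta`` given *already corrected* pH."""
    if ph_ta is None:
        return None
    t = np.asarray(ta, dtype=float)
    b0, b1, b2, b3 = PKA_POLY
    out = b0 + b1 * t + b2 * t**2 + b3 * t**3 - np.log10(pka_log_quotient(ph_ta, ta))
    return float(out) if np.ndim(out) == 0 else out


def recompute_hco3(alpha, pco2_c, ph_c, pka_val):
    """Bicarbonate (mmol/l) from Henderson–Hasselbalch at animal temperature."""
    if any(v is None for v in (alpha, pco2_c, ph_c, pka_val)):
        return None
    out = (
        np.asarray(alpha, dtype=float)
        * np.asarray(pco2_c, dtype=float)
        * 10.0 ** (np.asarray(ph_c, dtype=float) - np.asarray(pka_val, dtype=float))
    )
    return float(out) if np.ndim(out) == 0 else out


def recompute_tco2(hco3_c, alpha, pco2_c):
    """Total CO2 (mmol/l): bicarbonate plus dissolved CO2."""
    if any(v is None for v in (hco3_c, alpha, pco2_c)):
        return None
    out = np.asarray(hco3_c, dtype=float) + np.asarray(alpha, dtype=float) * np.asarray(
        pco2_c, dtype=float
    )
    return float(out) if np.ndim(out) == 0 else out


def correct_panel(panel, ta) -> CorrectedPanel:
    """Correct a full instrument panel to temperature ``ta``.

    pH, pO2 and pCO2 are corrected; αCO2 and pKa evaluated; HCO3 and TCO2
    recomputed from the corrected values (NOT from the instrument's own
    human-algorithm HCO3/TCO2, which are discarded); BE and lactate pass
    through unchanged.  Missing instrument fields yield missing corrected
    fields for everything that depends on them.
    """
    if ta is None or not np.isfinite(ta):
        raise ValueError("animal temperature ta is required to correct a panel")
    ph_c = correct_ph(panel.ph_i, ta)
    po2_c = correct_po2(panel.po2_i, ta)
    pco2_c = correct_pco2(panel.pco2_i, ta)
    alpha = alpha_co2(ta)
    pka_val = pka(ph_c, ta)
    hco3_c = recompute_hco3(alpha, pco2_c, ph_c, pka_val)
    tco2_c = recompute_tco2(hco3_c, alpha, pco2_c)
    return CorrectedPanel(
        ph_c=ph_c,
        po2_c=po2_c,
        pco2_c=pco2_c,
        alpha_co2=alpha,
        pka=pka_val,
        hco3_c=hco3_c,
        tco2_c=tco2_c,
        be=panel.be_i,
        lactate=panel.lactate_i,
    )


#: Corrected-analyte column names in reporting order.
CORRECTED_COLUMNS = (
    "ph_c",
    "po2_c",
    "pco2_c",
    "alpha_co2",
    "pka",
    "hco3_c",
    "tco2_c",
    "be",
    "lactate",
)

#: Map short analyte name -> corrected column used by downstream statistics.
ANALYTE_TO_CORRECTED = {
    "ph": "ph_c",
    "po2": "po2_c",
    "pco2": "pco2_c",
    "hco3": "hco3_c",
    "tco2": "tco2_c",
    "lactate": "lactate",
    "be": "be",
}


def correct_frame(df, ta_col: str = "ta_c"):
    """Vectorised panel correction over a cohort DataFrame.

    Expects instrument columns ``ph_i, po2_i, pco2_i, be_i, lactate_i`` and
    the temperature column; returns a copy with the corrected columns of
    :data:`CORRECTED_COLUMNS` appended.  NaNs propagate like ``None``.
    """
    out = df.copy()
    ta = out[ta_col].to_numpy(dtype=float)
    ph_c = correct_ph(out["ph_i"].to_numpy(dtype=float), ta)
    pco2_c = correct_pco2(out["pco2_i"].to_numpy(dtype=float), ta)
    alpha = alpha_co2(ta)
    pka_val = pka(ph_c, ta)
    hco3_c = recompute_hco3(alpha, pco2_c, ph_c, pka_val)
    out["ph_c"] = ph_c
    out["po2_c"] = correct_po2(out["po2_i"].to_numpy(dtype=float), ta)
    out["pco2_c"] = pco2_c
    out["alpha_co2"] = alpha
    out["pka"] = pka_val
    out["hco3_c"] = hco3_c
    out["tco2_c"] = recompute_tco2(hco3_c, alpha, pco2_c)
    out["be"] = out["be_i"]
    out["lactate"] = out["lactate_i"]
    return out
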