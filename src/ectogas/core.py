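"""Domain types, cohort CSV I/O and eligibility screening.

The unit of observation is one free-living turtle sampled once: demographic
strata (state, site, season, sex, age class), physiologic covariates (mass,
packed cell volume, activity level), the mean daily air temperature at the
capture site, physical-exam abnormality codes, and a point-of-care venous
blood gas panel measured by the analyzer at 37 °C.

Two screening steps gate which animals contribute to downstream statistics:

* health screening drops animals with active disease processes from
  reference-interval construction;
* multi-analyte outlier screening drops animals whose panel is flagged as an
  outlier for two or more analytes (suspected genuine acid–base pathology)
  from both modelling and reference intervals.

Both produce :class:`EligibilityReport` records with machine-readable
reasons so that every per-partition ``n`` in the report tables can be
audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("ectogas")

SEASONS = ("spring", "summer", "fall")
SEXES = ("male", "female", "unknown")
AGE_CLASSES = ("adult", "juvenile")
ACTIVITY_LEVELS = ("bright", "quiet")

#: Analytes carried on the instrument panel, in reporting order.
ANALYTES = ("ph", "po2", "pco2", "hco3", "tco2", "lactate", "be")

#: Exam codes treated as evidence of an active disease process.  Healed
#: shell lesions and asymmetrical nares are deliberately NOT in this set:
#: animals carrying only those remain reference-eligible.
DEFAULT_ACTIVE_LESION_CODES = frozenset(
    {
        "open_mouth_breathing",
        "ocular_swelling_nasal_discharge_diarrhea",
        "necrotic_shell_fracture",
    }
)

#: Default physiologic window for mean daily air temperature (°C); values
#: outside it draw a warning, not an error — field data contain extremes.
DEFAULT_TA_WINDOW = (-10.0, 45.0)


class SchemaError(ValueError):
    """The cohort CSV is missing a mandatory column."""


@dataclass(frozen=True)
class BloodGasPanel:
    """Instrument-scale (37 °C) analyte values; ``None`` marks a device error.

    Pressures are mmHg, concentrations mmol/l.  Any field may be absent —
    handheld analyzers drop individual results on cartridge errors.
    """

    ph_i: float | None = None
    po2_i: float | None = None
    pco2_i: float | None = None
    hco3_i: float | None = None
    tco2_i: float | None = None
    be_i: float | None = None
    lactate_i: float | None = None

    def __post_init__(self) -> None:
        if self.ph_i is not None and not 0.0 < self.ph_i < 14.0:
            raise ValueError(f"ph_i out of (0, 14): {self.ph_i}")
        for name in ("po2_i", "pco2_i"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class TurtleObservation:
    """One sampled animal with demographics, physiology and its 37 °C panel."""

    id: str
    state: str
    site: str
    season: str
    sex: str = "unknown"
    age_class: str = "adult"
    mass_g: float | None = None
    activity: str | None = None
    pcv_pct: float | None = None
    ta_c: float | None = None
    health_flags: frozenset[str] = field(default_factory=frozenset)
    panel: BloodGasPanel = field(default_factory=BloodGasPanel)

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(
                f"season must be one of {SEASONS}, got {self.season!r}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(
                f"age_class must be one of {AGE_CLASSES}, got {self.age_class!r}"
            )
        if self.activity is not None and self.activity not in ACTIVITY_LEVELS:
            raise ValueError(
                f"activity must be one of {ACTIVITY_LEVELS}, got {self.activity!r}"
            )
        if self.pcv_pct is not None and not 0.0 <= self.pcv_pct <= 100.0:
            raise ValueError(f"pcv_pct out of [0, 100]: {self.pcv_pct}")
        if self.mass_g is not None and self.mass_g <= 0:
            raise ValueError(f"mass_g must be positive, got {self.mass_g}")
        if self.ta_c is not None and not (
            DEFAULT_TA_WINDOW[0] <= self.ta_c <= DEFAULT_TA_WINDOW[1]
        ):
            logger.warning(
                "animal %s: ta_c=%.2f outside physiologic window %s",
                self.id,
                self.ta_c,
                DEFAULT_TA_WINDOW,
            )


@dataclass(frozen=True)
class EligibilityReport:
    """Per-animal screening outcome with machine-readable reasons."""

    id: str
    eligible_ri: bool = True
    eligible_model: bool = True
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        excluded = not (self.eligible_ri and self.eligible_model)
        if excluded and not self.reasons:
            raise ValueError("excluded record must carry at least one reason")
        if not excluded and self.reasons:
            raise ValueError("eligible record must not carry reasons")


@dataclass(frozen=True)
class RowError:
    """A malformed CSV row: 1-based data row number plus a message."""

    row: int
    message: str


@dataclass
class CohortReadResult:
    observations: list[TurtleObservation]
    errors: list[RowError]


_MANDATORY_COLUMNS = ("id", "state", "site", "season", "ta_c")
_NUMERIC_COLUMNS = (
    "mass_g",
    "pcv_pct",
    "ta_c",
    "ph_i",
    "po2_i",
    "pco2_i",
    "hco3_i",
    "tco2_i",
    "be_i",
    "lactate_i",
)
_PANEL_COLUMNS = (
    "ph_i",
    "po2_i",
    "pco2_i",
    "hco3_i",
    "tco2_i",
    "be_i",
    "lactate_i",
)

#: Full cohort CSV column order used by :func:`write_cohort`.
COHORT_COLUMNS = (
    "id",
    "state",
    "site",
    "season",
    "sex",
    "age_class",
    "mass_g",
    "activity",
    "pcv_pct",
    "ta_c",
    "health_flags",
) + _PANEL_COLUMNS


def _parse_optional_float(raw: object, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if not s:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable numeric in column {column!r}: {s!r}") from exc


def _parse_enum(raw: object, column: str, allowed: Sequence[str], *, optional: bool = False) -> str | None:
    s = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw).strip().lower()
    if not s:
        if optional:
            return None
        raise ValueError(f"missing value in column {column!r}")
    if s not in allowed:
        raise ValueError(
            f"invalid value {s!r} in column {column!r}; allowed: {', '.join(allowed)}"
        )
    return s


def read_cohort(path: str | Path, schema_options: Mapping | None = None) -> CohortReadResult:
    """Read a cohort CSV into observations, collecting malformed rows.

    Empty cells become absent values; enumeration columns are normalised to
    lowercase; ``health_flags`` is a semicolon-separated list.  A missing
    mandatory column raises :class:`SchemaError`; a malformed row is skipped
    and recorded in :attr:`CohortReadResult.errors` with its 1-based data row
    number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort CSV is missing mandatory column {col!r}")

    observations: list[TurtleObservation] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            flags_raw = str(row.get("health_flags", "") or "").strip()
            flags = frozenset(
                f.strip().lower() for f in flags_raw.split(";") if f.strip()
            )
            panel = BloodGasPanel(
                **{
                    col[:-2] + "_i": _parse_optional_float(row.get(col), col)
                    for col in _PANEL_COLUMNS
                }
            )
            obs = TurtleObservation(
                id=str(row["id"]).strip(),
                state=str(row["state"]).strip(),
                site=str(row["site"]).strip(),
                season=_parse_enum(row["season"], "season", SEASONS),
                sex=_parse_enum(row.get("sex"), "sex", SEXES, optional=True) or "unknown",
                age_class=_parse_enum(
                    row.get("age_class"), "age_class", AGE_CLASSES, optional=True
                )
                or "adult",
                mass_g=_parse_optional_float(row.get("mass_g"), "mass_g"),
                activity=_parse_enum(
                    row.get("activity"), "activity", ACTIVITY_LEVELS, optional=True
                ),
                pcv_pct=_parse_optional_float(row.get("pcv_pct"), "pcv_pct"),
                ta_c=_parse_optional_float(row.get("ta_c"), "ta_c"),
                health_flags=flags,
                panel=panel,
            )
        except ValueError as exc:
            errors.append(RowError(row=i, message=str(exc)))
            continue
        observations.append(obs)
    if errors:
        logger.info("read_cohort: %d malformed rows skipped", len(errors))
    return CohortReadResult(observations=observations, errors=errors)


def cohort_to_frame(observations: Iterable[TurtleObservation]) -> pd.DataFrame:
    """Flatten observations to a DataFrame with :data:`COHORT_COLUMNS`."""
    rows = []
    for obs in observations:
        row: dict[str, object] = {
            "id": obs.id,
            "state": obs.state,
            "site": obs.site,
            "season": obs.season,
            "sex": obs.sex,
            "age_class": obs.age_class,
            "mass_g": obs.mass_g,
            "activity": obs.activity,
            "pcv_pct": obs.pcv_pct,
            "ta_c": obs.ta_c,
            "health_flags": ";".join(sorted(obs.health_flags)),
        }
        for col in _PANEL_COLUMNS:
            row[col] = getattr(obs.panel, col[:-2] + "_i")
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(observations: Iterable[TurtleObservation], path: str | Path) -> None:
    """Write observations as a cohort CSV (UTF-8, missing = empty cell)."""
    cohort_to_frame(observations).to_csv(path, index=False)


def write_table(rows, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a report table (DataFrame or list of dicts) as CSV.

    Column order is preserved; floats use ``float_format`` so re-reading
    reproduces values to the written precision.  An empty table yields a
    header-only file when columns are known.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=float_format)


def screen_health(
    obs: TurtleObservation,
    active_lesion_codes: frozenset[str] | set[str] = DEFAULT_ACTIVE_LESION_CODES,
) -> EligibilityReport:
    """Flag animals with active disease processes as reference-ineligible.

    Exam codes not in ``active_lesion_codes`` (e.g. healed carapacial
    lesions) do not exclude.  Health exclusions gate reference intervals
    only; such animals still enter the predictor models.
    """
    matches = sorted(obs.health_flags & frozenset(active_lesion_codes))
    if matches:
        logger.info("animal %s excluded from RI: active lesions %s", obs.id, matches)
        return EligibilityReport(
            id=obs.id,
            eligible_ri=False,
            eligible_model=True,
            reasons=tuple(f"active_lesion:{m}" for m in matches),
        )
    return EligibilityReport(id=obs.id)


def screen_multi_analyte_outliers(
    flags: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
    threshold: int = 2,
) -> list[EligibilityReport]:
    """Exclude animals whose panel is an outlier for >= ``threshold`` analytes.

    ``flags`` maps animal id to the set of analytes flagged by the
    per-analyte outlier screen.  Animals at or above the threshold are
    interpreted as genuinely pathologic and excluded from both modelling and
    reference intervals; animals below it are retained (their individual
    outlying values are still handled per-analyte downstream).
    """
    items = flags.items() if isinstance(flags, Mapping) else flags
    reports = []
    for animal_id, analytes in items:
        analytes = sorted(set(analytes))
        if len(analytes) >= threshold:
            logger.info(
                "animal %s excluded (outlier in %d analytes: %s)",
                animal_id,
                len(analytes),
                analytes,
            )
            reports.append(
                EligibilityReport(
                    id=animal_id,
                    eligible_ri=False,
                    eligible_model=False,
                    reasons=tuple(f"multi_analyte_outlier:{a}" for a in analytes),
                )
            )
        else:
            reports.append(EligibilityReport(id=animal_id))
    return reports


def apply_eligibility(
    observations: Sequence[TurtleObservation],
    reports: Iterable[EligibilityReport],
    which: str,
) -> list[TurtleObservation]:
    """Filter observations by ``eligible_ri`` or ``eligible_model`` flags."""
    if which not in ("ri", "model"):
        raise ValueError("which must be 'ri' or 'model'")
    attr = "eligible_ri" if which == "ri" else "eligible_model"
    reports = list(reports)
    ineligible = {r.id for r in reports if not getattr(r, attr)}
    return [o for o in observations if o.id not in ineligible]
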