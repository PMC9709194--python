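"""Trait-stratified linear area-to-weight calibration.

Dishes are grouped into three morphology traits — block/thick-bar,
slice/silk, grain/granule — and each trait gets its own simple linear
model ``weight_g = slope * area_cm2 + intercept`` fitted on
machine-recognised areas.  The module ships the published default
coefficients for the three traits, a machine-area-to-actual-area
correction line, an OLS fitter for user calibration data, and CSV/JSON
interchange for calibration records and models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ModelError

__all__ = [
    "TraitClass",
    "LinearModel",
    "CalibrationRecord",
    "WeightEstimate",
    "default_models",
    "predict_weight",
    "area_correction_model",
    "correct_area",
    "fit_model",
    "read_calibration_csv",
    "write_calibration_csv",
]


class TraitClass(Enum):
    """The three food-morphology categories, each with its own
    area-to-weight line."""

    BLOCK_THICK_BAR = "Block/Thick bar"
    SLICE_SILK = "Slice/Silk"
    GRAIN_GRANULE = "Grain/Granule"

    @classmethod
    def parse(cls, value) -> "TraitClass":
        if isinstance(value, cls):
            return value
        text = str(value).strip()
        for member in cls:
            if text in (member.name, member.value):
                return member
        lowered = text.lower().replace("-", "_").replace(" ", "_").replace("/", "_")
        for member in cls:
            if lowered == member.name.lower():
                return member
        raise ModelError(f"unknown trait class {value!r}")


@dataclass(frozen=True)
class LinearModel:
    """A simple linear calibration ``y = slope * x + intercept`` with
    its fit quality.

    For the trait models x is machine-recognised area (cm^2) and y is
    weight (g); for the area-correction line both are areas.  ``source``
    distinguishes the shipped default coefficients from models fitted on
    user data; standard errors are available only for fitted models.
    """

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n_obs: int
    slope_se: Optional[float] = None
    intercept_se: Optional[float] = None
    source: str = "fitted"

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ModelError(f"pearson_r {self.pearson_r} outside [-1, 1]")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ModelError(f"r_squared {self.r_squared} outside [0, 1]")

    def predict(self, x: float) -> float:
        """Raw (unclipped) linear prediction."""
        return self.slope * x + self.intercept

    def conf_int(self, level: float = 0.95) -> tuple[tuple[float, float], tuple[float, float]]:
        """(slope_lo, slope_hi), (intercept_lo, intercept_hi) Student-t
        confidence intervals; requires a fitted model with n >= 3."""
        if self.slope_se is None or self.intercept_se is None:
            raise ModelError("confidence intervals need a fitted model with standard errors")
        tcrit = sps.t.ppf(0.5 + level / 2.0, df=self.n_obs - 2)
        return (
            (self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se),
            (self.intercept - tcrit * self.intercept_se, self.intercept + tcrit * self.intercept_se),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearModel":
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CalibrationRecord:
    """One calibration observation: a dish, its trait class, the
    machine-recognised area, optionally the physically measured area,
    and the scale-measured weight."""

    food: str
    trait: TraitClass
    machine_area: float  # cm^2
    measured_weight: float  # g
    actual_area: Optional[float] = None  # cm^2

    def __post_init__(self) -> None:
        object.__setattr__(self, "trait", TraitClass.parse(self.trait))
        if self.machine_area <= 0 or self.measured_weight <= 0:
            raise ModelError("calibration areas and weights must be positive")
        if self.actual_area is not None and self.actual_area <= 0:
            raise ModelError("actual area, when given, must be positive")


@dataclass(frozen=True)
class WeightEstimate:
    """A predicted weight, with the model that produced it and whether
    the raw linear prediction had to be clipped at zero."""

    weight: float  # g
    model_id: str
    area: float  # cm^2
    clipped: bool


# Shipped default coefficients per trait: (slope g/cm^2, intercept g,
# Pearson r, R^2), each fitted on 204 observations.
_DEFAULT_COEFFS: dict[TraitClass, tuple[float, float, float, float]] = {
    TraitClass.BLOCK_THICK_BAR: (2.5757, -49.03, 0.986, 0.971),
    TraitClass.SLICE_SILK: (1.9684, -46.3, 0.937, 0.878),
    TraitClass.GRAIN_GRANULE: (2.2069, -62.13, 0.972, 0.944),
}

_DEFAULT_N_OBS = 204

# Machine-recognised area regressed on actual area:
# machine = 0.7378 * actual + 12.765 (cm^2), R^2 = 0.9591 on 612 images.
# Machine areas are systematically smaller than actual areas for dishes
# larger than ~48.7 cm^2, which is why the inverse map enlarges them.
_AREA_CORRECTION = LinearModel(
    slope=0.7378,
    intercept=12.765,
    pearson_r=0.979,
    r_squared=0.9591,
    n_obs=612,
    source="shipped-default",
)


def default_models() -> dict[TraitClass, LinearModel]:
    """The three shipped trait models mapping machine-recognised area
    (cm^2) to weight (g)."""
    return {
        trait: LinearModel(
            slope=s, intercept=b, pearson_r=r, r_squared=r2,
            n_obs=_DEFAULT_N_OBS, source="shipped-default",
        )
        for trait, (s, b, r, r2) in _DEFAULT_COEFFS.items()
    }


def predict_weight(
    area: float,
    trait: TraitClass,
    models: Optional[Mapping[TraitClass, LinearModel]] = None,
) -> WeightEstimate:
    """Predict a food's weight from its real-world area and trait.

    The shipped intercepts are negative, so very small areas would
    predict negative grams; those are clipped to zero and flagged.
    """
    if area < 0:
        raise ModelError(f"area must be non-negative, got {area}")
    trait = TraitClass.parse(trait)
    models = models if models is not None else default_models()
    if trait not in models:
        raise ModelError(f"no model registered for trait {trait}")
    model = models[trait]
    raw = model.predict(area)
    clipped = raw < 0
    return WeightEstimate(
        weight=max(0.0, raw),
        model_id=f"{trait.name}:{model.source}",
        area=area,
        clipped=clipped,
    )


def area_correction_model() -> LinearModel:
    """The shipped machine-area vs actual-area line
    (y = machine area, x = actual area)."""
    return _AREA_CORRECTION


def correct_area(machine_area: float) -> float:
    """Invert the machine-vs-actual line to recover an actual-area
    estimate from a machine-recognised area, floored at zero.

    Disabled by default in the pipeline: the shipped trait models are
    regressions *on* machine-recognised area, so correcting before
    predicting would double-count the bias.  Enable via config only
    when using models calibrated against physically measured areas.
    """
    if machine_area < 0:
        raise ModelError(f"machine area must be non-negative, got {machine_area}")
    m = _AREA_CORRECTION
    return max(0.0, (machine_area - m.intercept) / m.slope)


def fit_model(records: Iterable[CalibrationRecord], trait: TraitClass) -> LinearModel:
    """Ordinary least squares of measured weight on machine-recognised
    area for one trait class.

    Requires at least three records of the trait and non-degenerate
    area variance.  Reports slope/intercept with standard errors,
    Pearson r and R^2 (= r^2 for a simple linear fit).
    """
    trait = TraitClass.parse(trait)
    sub = [r for r in records if r.trait is trait]
    if len(sub) < 3:
        raise ModelError(f"need >= 3 records for trait {trait.name}, got {len(sub)}")
    x = np.array([r.machine_area for r in sub], dtype=float)
    y = np.array([r.measured_weight for r in sub], dtype=float)
    if np.ptp(x) == 0:
        raise ModelError("zero variance in areas: cannot fit a line")
    res = sps.linregress(x, y)
    return LinearModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        n_obs=len(sub),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        source="fitted",
    )


# ---------------------------------------------------------------------------
# CSV interchange

_CSV_COLUMNS = ["food", "trait", "machine_area_cm2", "actual_area_cm2", "weight_g"]


def read_calibration_csv(path) -> list[CalibrationRecord]:
    """Read calibration records from CSV with columns
    food,trait,machine_area_cm2,actual_area_cm2,weight_g (actual area
    optional/blank)."""
    df = pd.read_csv(path)
    missing = {"food", "trait", "machine_area_cm2", "weight_g"} - set(df.columns)
    if missing:
        raise ModelError(f"calibration CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        actual = getattr(row, "actual_area_cm2", None)
        if actual is not None and pd.isna(actual):
            actual = None
        records.append(
            CalibrationRecord(
                food=str(row.food),
                trait=TraitClass.parse(row.trait),
                machine_area=float(row.machine_area_cm2),
                measured_weight=float(row.weight_g),
                actual_area=None if actual is None else float(actual),
            )
        )
    return records


def write_calibration_csv(records: Sequence[CalibrationRecord], path) -> None:
    df = pd.DataFrame(
        {
            "food": [r.food for r in records],
            "trait": [r.trait.value for r in records],
            "machine_area_cm2": [r.machine_area for r in records],
            "actual_area_cm2": [r.actual_area for r in records],
            "weight_g": [r.measured_weight for r in records],
        }
    )
    df.to_csv(path, index=False)
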