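"""Allometric total-body-length (TBL) estimation for snakes.

Vertebral width scales tightly with body length in extant snakes, so an
isolated trunk vertebra of a fossil taxon can be converted to a TBL
estimate through a regression fitted on extant comparative material.
Three predictive equations calibrated on extant snakes ship as built-in
models, all operating in millimetres:

* ``A60`` — TBL on trans-postzygapophyseal width (poW), boine vertebrae
  from 60% along the column: ``y = 100.72 x + 436.24``;
* ``A65`` — as above at the 65% position: ``y = 105.98 x + 390``;
* ``C``  — TBL on trans-prezygapophyseal width (prW) across a broad
  sample of extant snakes, log10–log10:
  ``log10(y) = 1.0739 log10(x) + 1.9842``.

New models can be fitted by ordinary least squares from a comparative
dataset, with prediction intervals on the fitted scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from paleosnake.errors import DegenerateDesignError, ValidationError


class ModelForm(Enum):
    LINEAR = "LINEAR"
    LOG10LOG10 = "LOG10LOG10"


class Provenance(Enum):
    BUILTIN = "BUILTIN"
    FITTED = "FITTED"


def meters(tbl_mm: float) -> float:
    """Render a length in mm as metres, rounded half-up to 0.1 m."""
    return float(
        Decimal(repr(tbl_mm / 1000.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class AllometricModel:
    """A TBL-on-width regression.

    LINEAR models predict ``y = slope*x + intercept`` with x, y in mm.
    LOG10LOG10 models predict ``log10(y) = slope*log10(x) + intercept``,
    again with x, y in mm; the slope is then the allometric exponent.
    """

    model_id: str
    form: ModelForm
    predictor: str  # "poW" or "prW"
    slope: float
    intercept: float
    n: Optional[int] = None
    r2: Optional[float] = None
    p_slope: Optional[float] = None
    se_pred: Optional[float] = None  # residual SE on the response scale, mm
    se_slope: Optional[float] = None
    se_intercept: Optional[float] = None
    provenance: Provenance = Provenance.FITTED
    units_in: str = "mm"
    units_out: str = "mm"

    def predict_tbl(self, width_mm: float) -> float:
        return predict_tbl(self, width_mm)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["form"] = self.form.value
        d["provenance"] = self.provenance.value
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AllometricModel":
        d = json.loads(text)
        d["form"] = ModelForm(d["form"])
        d["provenance"] = Provenance(d["provenance"])
        return cls(**d)


def builtin_models() -> list[AllometricModel]:
    """The three built-in predictive equations (coefficients in mm units)."""
    return [
        AllometricModel(
            model_id="A60",
            form=ModelForm.LINEAR,
            predictor="poW",
            slope=100.72,
            intercept=436.24,
            provenance=Provenance.BUILTIN,
        ),
        AllometricModel(
            model_id="A65",
            form=ModelForm.LINEAR,
            predictor="poW",
            slope=105.98,
            intercept=390.0,
            provenance=Provenance.BUILTIN,
        ),
        AllometricModel(
            model_id="C",
            form=ModelForm.LOG10LOG10,
            predictor="prW",
            slope=1.0739,
            intercept=1.9842,
            provenance=Provenance.BUILTIN,
        ),
    ]


def get_builtin(model_id: str) -> AllometricModel:
    for m in builtin_models():
        if m.model_id == model_id:
            return m
    raise ValidationError(f"no built-in model {model_id!r}")


def predict_tbl(model: AllometricModel, width_mm: float) -> float:
    """Predicted total body length in mm for a vertebral width in mm."""
    if not width_mm > 0:
        raise ValidationError(f"width_mm must be > 0, got {width_mm}")
    if model.form is ModelForm.LINEAR:
        return model.slope * width_mm + model.intercept
    return 10.0 ** (model.slope * math.log10(width_mm) + model.intercept)


def inverse_width(model: AllometricModel, tbl_mm: float) -> float:
    """Vertebral width implied by a total body length (algebraic inverse)."""
    if model.form is ModelForm.LINEAR:
        if not tbl_mm > model.intercept:
            raise ValidationError(
                f"tbl_mm must exceed the intercept {model.intercept} for a "
                f"positive width, got {tbl_mm}"
            )
        return (tbl_mm - model.intercept) / model.slope
    if not tbl_mm > 0:
        raise ValidationError(f"tbl_mm must be > 0, got {tbl_mm}")
    return 10.0 ** ((math.log10(tbl_mm) - model.intercept) / model.slope)


@dataclass
class ComparativeDataset:
    """Width/TBL pairs for extant comparative taxa (all mm, all > 0)."""

    frame: pd.DataFrame  # columns: taxon, width_mm, tbl_mm
    source_tag: str = ""

    def __post_init__(self) -> None:
        required = {"taxon", "width_mm", "tbl_mm"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"dataset needs columns {sorted(required)}")
        if (self.frame["width_mm"] <= 0).any() or (self.frame["tbl_mm"] <= 0).any():
            raise ValidationError("widths and TBLs must be strictly positive")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path: str | Path, source_tag: str = "") -> "ComparativeDataset":
        frame = pd.read_csv(path, comment="#")
        return cls(frame=frame, source_tag=source_tag or str(path))

    def to_csv(self, path: str | Path, header_comment: str = "") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.to_csv(fh, index=False)


def _design(data: ComparativeDataset, form: ModelForm):
    x = data.frame["width_mm"].to_numpy(float)
    y = data.frame["tbl_mm"].to_numpy(float)
    if form is ModelForm.LOG10LOG10:
        x, y = np.log10(x), np.log10(y)
    return x, y


def fit_allometry(
    data: ComparativeDataset,
    form: ModelForm = ModelForm.LOG10LOG10,
    predictor: str = "prW",
    model_id: str = "fitted",
) -> AllometricModel:
    """Ordinary-least-squares fit of TBL on width.

    For the LOG10LOG10 form both variables are log10-transformed before the
    fit (the standard normalisation for allometric data); the LINEAR form
    regresses raw mm on raw mm.  The slope p-value is the two-sided t-test
    with n-2 degrees of freedom.  ``se_pred`` is the residual standard
    error expressed on the response (mm) scale; for log10 fits it is
    converted by the delta method at the mean predictor.
    """
    if len(data) < 3:
        raise ValidationError(f"need n >= 3 rows to fit, got {len(data)}")
    x, y = _design(data, form)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in predictor")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    rse = math.sqrt(res.ssr / res.df_resid) if res.df_resid > 0 else 0.0
    if form is ModelForm.LOG10LOG10:
        # delta method: sd on mm scale ~ ln(10) * rse * yhat at mean log-x
        yhat = 10.0 ** (slope * float(np.mean(x)) + intercept)
        se_pred = math.log(10.0) * rse * yhat
    else:
        se_pred = rse
    return AllometricModel(
        model_id=model_id,
        form=form,
        predictor=predictor,
        slope=float(slope),
        intercept=float(intercept),
        n=len(data),
        r2=float(res.rsquared),
        p_slope=float(res.pvalues[1]),
        se_pred=float(se_pred),
        se_slope=float(res.bse[1]),
        se_intercept=float(res.bse[0]),
        provenance=Provenance.FITTED,
    )


def prediction_interval(
    model: AllometricModel,
    data: ComparativeDataset,
    width_mm: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """OLS prediction interval for a new observation at ``width_mm``.

    The interval is symmetric on the fitted scale (raw mm or log10 mm) and
    back-transformed to mm for LOG10LOG10 models.  Built-in models carry no
    design matrix, so intervals are only available for FITTED models.
    """
    if model.provenance is Provenance.BUILTIN:
        raise ValidationError(
            "prediction intervals need the fitting data; built-in models "
            "carry only their coefficients"
        )
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if not width_mm > 0:
        raise ValidationError(f"width_mm must be > 0, got {width_mm}")
    x, y = _design(data, model.form)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    x0 = math.log10(width_mm) if model.form is ModelForm.LOG10LOG10 else width_mm
    pred = res.get_prediction([1.0, x0])
    frame = pred.summary_frame(alpha=1 - level)
    lo, hi = float(frame["obs_ci_lower"].iloc[0]), float(frame["obs_ci_upper"].iloc[0])
    if model.form is ModelForm.LOG10LOG10:
        lo, hi = 10.0**lo, 10.0**hi
    return lo, hi
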