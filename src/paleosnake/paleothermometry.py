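"""Metabolic-scaling paleothermometry for poikilotherms.

The largest body size a poikilotherm lineage can reach is limited by
ambient temperature: resting metabolic rate scales with mass (exponent
``alpha``) and rises with temperature by a factor ``Q10`` per 10 degrees
Celsius.  Inverting that relationship, the maximum body length of a fossil
snake, compared with the maximum length of its closest modern analogue
living at a known mean annual temperature (MAT), yields a mean annual
paleotemperature (MAPT):

    MAPT = MAT + 3*alpha*10 * log10(TBL_v / TBL_M) / log10(Q10)

Defaults follow the reticulated python (*Malayopython reticulatus*) as the
modern analogue: MAT = 26.5 C, maximum length TBL_M = 10.05 m, pythonid
Q10 = 2.6, scaling exponent alpha = 0.17.  With these values the leading
coefficient 3*alpha*10 equals 5.1 and log10(2.6) ~= 0.41, giving the
widely quoted simplified form ``MAPT = MAT + 5.1 * log10(TBL_v/TBL_M) / 0.41``.
The EXACT form (full log10(Q10)) is the default; the SIMPLIFIED form with
the truncated constants is provided for comparison, and reports show both.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from enum import Enum

from paleosnake.errors import ValidationError


class MaptForm(Enum):
    EXACT = "EXACT"
    SIMPLIFIED = "SIMPLIFIED"


#: Constants of the simplified published form.
SIMPLIFIED_COEFF_C = 5.1
SIMPLIFIED_LOG10_Q10 = 0.41


@dataclass(frozen=True)
class MetabolicScalingParams:
    """Inputs of the MAPT equation (temperatures in C, lengths in m)."""

    mat_c: float = 26.5
    tbl_max_modern_m: float = 10.05
    q10: float = 2.6
    alpha_scaling: float = 0.17
    form: MaptForm = MaptForm.EXACT

    def __post_init__(self) -> None:
        if not self.tbl_max_modern_m > 0:
            raise ValidationError("tbl_max_modern_m must be > 0")
        if not self.q10 > 1:
            raise ValidationError("q10 must be > 1")
        if not 0 < self.alpha_scaling < 1:
            raise ValidationError("alpha_scaling must be in (0, 1)")

    def with_form(self, form: MaptForm) -> "MetabolicScalingParams":
        return replace(self, form=form)


def mapt(params: MetabolicScalingParams, tbl_v_m: float) -> float:
    """Mean annual paleotemperature (C) implied by a maximum body length (m)."""
    if not tbl_v_m > 0:
        raise ValidationError(f"tbl_v_m must be > 0, got {tbl_v_m}")
    ratio = math.log10(tbl_v_m / params.tbl_max_modern_m)
    if params.form is MaptForm.SIMPLIFIED:
        return params.mat_c + SIMPLIFIED_COEFF_C * (ratio / SIMPLIFIED_LOG10_Q10)
    coeff = 3.0 * params.alpha_scaling * 10.0
    return params.mat_c + coeff * (ratio / math.log10(params.q10))


def delta_t(params: MetabolicScalingParams, tbl_v_m: float) -> float:
    """Warming relative to the present MAT; zero iff tbl_v equals TBL_M."""
    return mapt(params, tbl_v_m) - params.mat_c


def mapt_report(params: MetabolicScalingParams, tbl_v_m: float) -> dict:
    """Evaluate both equation forms side by side (one-decimal rendering)."""
    exact = mapt(params.with_form(MaptForm.EXACT), tbl_v_m)
    simplified = mapt(params.with_form(MaptForm.SIMPLIFIED), tbl_v_m)
    return {
        "tbl_v_m": tbl_v_m,
        "params": {
            "mat_c": params.mat_c,
            "tbl_max_modern_m": params.tbl_max_modern_m,
            "q10": params.q10,
            "alpha_scaling": params.alpha_scaling,
        },
        "mapt_exact_c": round(exact, 1),
        "mapt_simplified_c": round(simplified, 1),
        "form_difference_c": round(exact - simplified, 3),
        "delta_t_exact_c": round(exact - params.mat_c, 1),
        "delta_t_simplified_c": round(simplified - params.mat_c, 1),
    }


def mapt_report_json(params: MetabolicScalingParams, tbl_v_m: float) -> str:
    return json.dumps(mapt_report(params, tbl_v_m), indent=2)
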