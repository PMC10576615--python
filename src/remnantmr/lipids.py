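"""Derived lipid exposures and unit/SD rescalings.

Triglyceride-rich-lipoprotein (TRL) remnant cholesterol cannot be assayed
directly in large biobanks.  It is operationalised from the standard lipid
panel as

    non-HDL-C      = total cholesterol - HDL-C
    TRL/remnant-C  = non-HDL-C - directly measured LDL-C

i.e. the cholesterol left after removing the HDL and LDL fractions, which by
exclusion resides in VLDL, IDL, chylomicron remnants and Lp(a).  A second,
fully computed estimate of TRL cholesterol ("VLDL-C") comes from the Sampson
two-variable equation in TG and non-HDL-C.

Causal and observational effect estimates are reported both per 1.0 unit
(mmol/L for lipids, g/L for apoB) and per population standard deviation,
linked by ``OR_sd = OR_unit ** sd`` (log-scale linearity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SdTable",
    "non_hdl_c",
    "trl_remnant_c",
    "vldl_c_sampson",
    "or_per_sd",
    "or_per_unit_from_sd",
    "convert_apob_units",
    "derive_lipid_columns",
    "SAMPSON_COEFFS",
]

#: Population SDs used for per-SD rescaling (fixed reference values).
#: Units: mmol/L except apoB (g/L).
FIXED_SD = {
    "trl_remnant_c": 0.30,
    "ldl_c": 0.82,
    "tg": 1.00,
    "apob": 0.23,
    "vldl_c": 0.43,
}

# --- Sampson two-variable VLDL-C equation -----------------------------------
# Transcribed from the published equation; native units are mg/dL:
#   VLDL-C[mg/dL] = TG/8.56 + TG*nonHDL/2140 - TG^2/16100
# The constant term of the companion LDL-C equation (9.44 mg/dL) belongs to the
# LDL-C estimate, not the VLDL-C term, so VLDL-C(TG=0) = 0.
SAMPSON_COEFFS = {
    "tg_linear": 1.0 / 8.56,       # per mg/dL TG
    "tg_nonhdl": 1.0 / 2140.0,     # per (mg/dL)^2
    "tg_squared": -1.0 / 16100.0,  # per (mg/dL)^2
    "tg_validity_max_mg_dl": 800.0,
}
MGDL_PER_MMOL_TG = 88.57    # molecular weight conversion for triglyceride
MGDL_PER_MMOL_CHOL = 38.67  # molecular weight conversion for cholesterol


@dataclass
class SdTable:
    """Trait -> population SD mapping used for per-SD reporting.

    mode='fixed_reference_values' uses the fixed reference SDs above;
    mode='estimated_from_cohort' recomputes them from a cohort table.
    """

    mode: str = "fixed_reference_values"
    sds: dict[str, float] = field(default_factory=lambda: dict(FIXED_SD))

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_reference_values", "estimated_from_cohort"):
            raise ValueError(f"unknown SdTable mode {self.mode!r}")
        for trait, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"SD for {trait!r} must be > 0, got {sd}")

    @classmethod
    def from_cohort(cls, subjects: pd.DataFrame) -> "SdTable":
        cols = {
            "trl_remnant_c": "trl_remnant_c",
            "ldl_c": "ldl_c_direct",
            "tg": "tg",
            "apob": "apob",
            "vldl_c": "vldl_c",
        }
        sds = {
            trait: float(subjects[col].std(ddof=1))
            for trait, col in cols.items()
            if col in subjects.columns
        }
        return cls(mode="estimated_from_cohort", sds=sds)

    def __getitem__(self, trait: str) -> float:
        return self.sds[trait]


def _check_non_negative(name: str, x: np.ndarray) -> None:
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be non-negative")


def non_hdl_c(tc, hdl_c):
    """Non-HDL cholesterol (mmol/L): total cholesterol minus HDL-C.

    Returns ``(values, flagged)`` where ``flagged`` marks physically impossible
    negative results (assay error); flagged records are excluded downstream
    rather than clamped.
    """
    tc = np.asarray(tc, dtype=float)
    hdl_c = np.asarray(hdl_c, dtype=float)
    _check_non_negative("tc", tc)
    _check_non_negative("hdl_c", hdl_c)
    out = tc - hdl_c
    return out, out < 0


def trl_remnant_c(non_hdl, ldl_c_direct):
    """TRL/remnant cholesterol (mmol/L): non-HDL-C minus direct LDL-C.

    Negative results (assay noise when true remnant-C is near zero) are
    flagged, not clamped.
    """
    non_hdl = np.asarray(non_hdl, dtype=float)
    ldl = np.asarray(ldl_c_direct, dtype=float)
    _check_non_negative("non_hdl", non_hdl)
    _check_non_negative("ldl_c_direct", ldl)
    out = non_hdl - ldl
    return out, out < 0


def vldl_c_sampson(tg, non_hdl, warn_out_of_range: bool = True):
    """VLDL cholesterol (mmol/L) from the Sampson TG/non-HDL-C equation.

    Inputs in mmol/L; internally converted to mg/dL (the equation's native
    units, see :data:`SAMPSON_COEFFS`) and back.  TG above the equation's
    stated validity range (800 mg/dL ~ 9.0 mmol/L) triggers a warning but is
    still computed.  Output floored at 0.
    """
    tg = np.asarray(tg, dtype=float)
    non_hdl = np.asarray(non_hdl, dtype=float)
    _check_non_negative("tg", tg)
    _check_non_negative("non_hdl", non_hdl)
    tg_mg = tg * MGDL_PER_MMOL_TG
    nh_mg = non_hdl * MGDL_PER_MMOL_CHOL
    if warn_out_of_range and np.any(tg_mg > SAMPSON_COEFFS["tg_validity_max_mg_dl"]):
        warnings.warn(
            "TG above the Sampson equation's stated validity range "
            "(800 mg/dL); computing anyway",
            stacklevel=2,
        )
    c = SAMPSON_COEFFS
    vldl_mg = c["tg_linear"] * tg_mg + c["tg_nonhdl"] * tg_mg * nh_mg + c["tg_squared"] * tg_mg**2
    return np.maximum(vldl_mg / MGDL_PER_MMOL_CHOL, 0.0)


def or_per_sd(or_unit, sd):
    """Rescale an odds (or hazard) ratio per 1.0 unit to per population SD.

    ``OR_sd = exp(sd * ln(OR_unit)) = OR_unit ** sd``.  Rounding to the
    2-decimal presentation convention is left to the caller.
    """
    or_unit = np.asarray(or_unit, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(or_unit <= 0):
        raise ValueError("or_unit must be > 0")
    if np.any(sd <= 0):
        raise ValueError("sd must be > 0")
    out = np.exp(sd * np.log(or_unit))
    return float(out) if out.ndim == 0 else out


def or_per_unit_from_sd(or_sd, sd):
    """Inverse of :func:`or_per_sd`: recover the per-unit OR from a per-SD OR."""
    or_sd = np.asarray(or_sd, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(or_sd <= 0):
        raise ValueError("or_sd must be > 0")
    if np.any(sd <= 0):
        raise ValueError("sd must be > 0")
    out = np.exp(np.log(or_sd) / sd)
    return float(out) if out.ndim == 0 else out


def convert_apob_units(value, from_unit: str):
    """Convert apoB between g/L and mg/dL (1 g/L = 100 mg/dL exactly)."""
    value = np.asarray(value, dtype=float)
    if from_unit == "g/L":
        out = value * 100.0
    elif from_unit == "mg/dL":
        out = value / 100.0
    else:
        raise ValueError(f"unknown apoB unit {from_unit!r}; use 'g/L' or 'mg/dL'")
    return float(out) if out.ndim == 0 else out


def derive_lipid_columns(subjects: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns non_hdl_c, trl_remnant_c, vldl_c and a
    ``lipid_flag`` marking records with negative derived concentrations
    (excluded from analyses that use the affected trait)."""
    out = subjects.copy()
    nh, f1 = non_hdl_c(out["tc"].to_numpy(), out["hdl_c"].to_numpy())
    rem, f2 = trl_remnant_c(np.maximum(nh, 0.0), out["ldl_c_direct"].to_numpy())
    out["non_hdl_c"] = nh
    out["trl_remnant_c"] = rem
    out["vldl_c"] = vldl_c_sampson(out["tg"].to_numpy(), np.maximum(nh, 0.0))
    out["lipid_flag"] = f1 | f2
    return out
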