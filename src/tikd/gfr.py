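"""Estimated glomerular filtration rate (eGFR) from serum creatinine.

Two creatinine-based estimating equations are provided: the 2009 CKD-EPI
equation and the IDMS-traceable 4-variable MDRD study equation. Both return
eGFR in mL/min/1.73 m² from serum creatinine (mg/dL), age (years) and sex.

The CKD-EPI race multiplier is intentionally omitted: the registry this
package models is described as ethnically homogeneous (European ancestry),
and current nephrology practice has abandoned the race term altogether.
"""

from __future__ import annotations

import math

from .errors import DataError

__all__ = ["egfr_ckdepi", "egfr_mdrd"]

_SEXES = ("male", "female")


def _check(serum_creatinine: float, age: float, sex: str) -> None:
    if sex not in _SEXES:
        raise DataError(f"sex must be one of {_SEXES}, got {sex!r}")
    if not serum_creatinine > 0:
        raise DataError(f"serum creatinine must be positive, got {serum_creatinine}")
    if age < 18:
        raise DataError(f"adult equations require age >= 18, got {age}")


def egfr_ckdepi(serum_creatinine: float, age: float, sex: str) -> float:
    """2009 CKD-EPI creatinine equation (race term omitted).

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209
               * 0.993^age * (1.018 if female)

    with k = 0.7 (female) / 0.9 (male) and alpha = -0.329 / -0.411.
    Strictly decreasing in both creatinine and age.
    """
    _check(serum_creatinine, age, sex)
    if sex == "female":
        kappa, alpha, sex_factor = 0.7, -0.329, 1.018
    else:
        kappa, alpha, sex_factor = 0.9, -0.411, 1.0
    ratio = serum_creatinine / kappa
    egfr = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * sex_factor
    )
    return egfr


def egfr_mdrd(serum_creatinine: float, age: float, sex: str) -> float:
    """IDMS-traceable 4-variable MDRD study equation.

    eGFR = 175 * Scr^-1.154 * age^-0.203 * (0.742 if female)
    """
    _check(serum_creatinine, age, sex)
    egfr = 175.0 * serum_creatinine ** -1.154 * age ** -0.203
    if sex == "female":
        egfr *= 0.742
    return egfr
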