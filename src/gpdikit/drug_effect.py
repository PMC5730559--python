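"""Single-drug exposure-response models.

The work-horse is the sigmoidal maximum-effect (Hill) model

    E(C) = Emax * C**H / (EC50**H + C**H)

with ``Emax`` the maximal fractional effect (1 = full growth inhibition on the
turbidity scale used throughout this package), ``EC50`` the potency
(concentration at half-maximal effect) and ``H`` the Hill factor controlling
sigmoidicity.  When the highest studied concentration sits well below the
EC50, the curve is indistinguishable from its low-concentration limit and a
linear slope model ``E = SLOPE*C`` or power model ``E = SLOPE*C**H`` is used
instead.

Evaluation is done on the logistic scale, ``E = Emax * expit(H*(ln C - ln
EC50))``, which is exact and immune to overflow for any ``C/EC50`` ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "FORMS",
    "SingleDrugPD",
    "WrongFormError",
    "effect",
    "hill_effect",
    "slope_or_power_effect",
]

FORMS = ("sigmoid_emax", "slope", "power")


class WrongFormError(TypeError):
    """An operation was applied to a parameter set of the wrong model form."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SingleDrugPD:
    """Pharmacodynamic parameters of one drug's exposure-response curve.

    Parameters
    ----------
    drug_id : str
        Identifier of the drug.
    emax : float
        Maximal fractional effect (dimensionless; 0-1 on the growth
        inhibition scale).
    ec50 : float
        Concentration producing half-maximal effect; same units as the
        concentrations the model is evaluated at.
    hill : float
        Hill factor (sigmoidicity). Fixed at 1 for ``form="slope"``.
    form : {"sigmoid_emax", "slope", "power"}
        Structural form of the exposure-response curve.
    slope : float, optional
        Effect per concentration unit; required for slope/power forms, where
        it stands in for Emax/EC50 (slope) or Emax/EC50**H (power).
    """

    drug_id: str
    emax: float = 1.0
    ec50: float = 1.0
    hill: float = 1.0
    form: str = "sigmoid_emax"
    slope: float | None = None

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        if self.form == "slope":
            object.__setattr__(self, "hill", 1.0)
        for name in ("emax", "ec50", "hill"):
            object.__setattr__(self, name, _check_finite(name, getattr(self, name)))
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.hill <= 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")
        if self.emax < 0:
            raise ValueError(f"emax must be >= 0, got {self.emax}")
        if self.form in ("slope", "power"):
            if self.slope is None:
                raise ValueError(f"form={self.form!r} requires a slope")
            object.__setattr__(self, "slope", _check_finite("slope", self.slope))
            if self.slope < 0:
                raise ValueError(f"slope must be >= 0, got {self.slope}")


def _as_conc(conc):
    arr = np.asarray(conc, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("concentrations must be finite and non-negative")
    return arr


def hill_effect(conc, emax, ec50, hill):
    """Sigmoidal Emax model evaluated on the logistic scale.

    ``emax``/``ec50`` may be arrays broadcastable against ``conc`` (used when
    interaction terms shift a parameter well-by-well). ``conc=0`` maps to
    effect 0 exactly for any Hill factor (the 0**0 ambiguity is resolved by
    the limit from above).
    """
    conc = _as_conc(conc)
    with np.errstate(divide="ignore"):
        log_ratio = hill * (np.log(conc) - np.log(ec50))
    out = emax * expit(log_ratio)
    return out if out.ndim else float(out)


def slope_or_power_effect(params: SingleDrugPD, conc):
    """Linear slope (``E = SLOPE*C``) or power (``E = SLOPE*C**H``) effect."""
    if params.form == "slope":
        out = params.slope * _as_conc(conc)
    elif params.form == "power":
        out = params.slope * _as_conc(conc) ** params.hill
    else:
        raise WrongFormError(
            f"slope_or_power_effect requires form in ('slope', 'power'), "
            f"got {params.form!r} for drug {params.drug_id!r}"
        )
    return out if np.ndim(out) else float(out)


def effect(params: SingleDrugPD, conc):
    """Fractional effect of a single drug at concentration(s) ``conc``."""
    if params.form == "sigmoid_emax":
        return hill_effect(conc, params.emax, params.ec50, params.hill)
    return slope_or_power_effect(params, conc)
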