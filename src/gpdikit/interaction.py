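"""Saturable parameter-shift interaction terms and their composition.

A pharmacodynamic interaction is modelled as a *perpetrator* drug shifting a
PD parameter theta (EC50 or Emax) of a *victim* drug through a saturable
(Emax-type) term,

    theta -> theta * (1 + INT * C_perp**H_INT / (EC50_INT**H_INT + C_perp**H_INT))

with INT in [-1, inf) the maximum fractional change, EC50_INT the interaction
potency and H_INT the interaction sigmoidicity.  INT = 0 means no
interaction; -1 < INT < 0 decreases the parameter; INT > 0 increases it.
Several perpetrators acting on the same victim parameter compose as a product
of such factors.  Third-drug ("emergent") effects are captured by modulation
terms that scale another term's INT by the same functional form.

Shifts applied to EC50 yield competitive-type behaviour (compatible with both
Loewe Additivity and Bliss Independence); shifts on Emax yield allosteric-type
behaviour (Bliss only).  The shifted EC50 enters the victim's Hill model
before exponentiation: ``(EC50*factor)**H``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .drug_effect import SingleDrugPD, WrongFormError, _as_conc, _check_finite, hill_effect

__all__ = [
    "GPDITerm",
    "InteractionModel",
    "SlopeShiftEffect",
    "gpdi_shift",
    "modulated_effect",
    "perturbed_effect",
    "slope_model_shift",
]

TARGETS = ("EC50", "Emax", "INT")

CRITERIA = ("loewe", "bliss", "effect_addition", "hsa")


def _saturation(conc, ec50_int, h_int):
    """C**H / (EC50**H + C**H) on the logistic scale; 0 at C=0."""
    conc = _as_conc(conc)
    with np.errstate(divide="ignore"):
        log_ratio = h_int * (np.log(conc) - np.log(ec50_int))
    return expit(log_ratio)


@dataclass(frozen=True)
class GPDITerm:
    """One directed interaction term: ``perpetrator`` shifts a PD parameter of
    ``victim`` by at most the fraction ``int_value``.

    ``target_param="INT"`` marks a modulation term acting on another term's
    INT; ``modulated_pair`` then identifies the modulated term by its chain of
    drug ids ``(perpetrator, victim)`` for a pairwise term, optionally
    extended by the target (``(perp, victim, "EC50")``) when the pair carries
    terms on both parameters, or by further modulator ids for nested
    modulation (``(perp, victim, modulator_id)``).
    """

    perpetrator_id: str
    victim_id: str
    int_value: float
    ec50_int: float
    h_int: float = 1.0
    target_param: str = "EC50"
    modulated_pair: tuple | None = None

    def __post_init__(self) -> None:
        if self.target_param not in TARGETS:
            raise ValueError(f"target_param must be one of {TARGETS}")
        object.__setattr__(self, "int_value", _check_finite("int_value", self.int_value))
        object.__setattr__(self, "ec50_int", _check_finite("ec50_int", self.ec50_int))
        object.__setattr__(self, "h_int", _check_finite("h_int", self.h_int))
        if self.int_value < -1:
            raise ValueError(
                f"int_value must be >= -1 (shift factor would become non-positive), "
                f"got {self.int_value}"
            )
        if self.ec50_int <= 0:
            raise ValueError(f"ec50_int must be > 0, got {self.ec50_int}")
        if self.h_int <= 0:
            raise ValueError(f"h_int must be > 0, got {self.h_int}")
        if (self.target_param == "INT") != (self.modulated_pair is not None):
            raise ValueError("modulated_pair is required iff target_param='INT'")
        if self.modulated_pair is not None:
            object.__setattr__(self, "modulated_pair", tuple(self.modulated_pair))

    @property
    def chain(self) -> tuple:
        """Identity of this term in the modulation hierarchy."""
        if self.target_param == "INT":
            return self.modulated_pair + (self.perpetrator_id,)
        return (self.perpetrator_id, self.victim_id)


def gpdi_shift(term: GPDITerm, perp_conc):
    """Multiplicative shift factor ``1 + INT*sat(C)`` on the victim parameter.

    Equals 1 at zero perpetrator concentration and saturates at ``1 + INT``.
    """
    return 1.0 + term.int_value * _saturation(perp_conc, term.ec50_int, term.h_int)


@dataclass(frozen=True)
class InteractionModel:
    """A set of single-drug models plus interaction terms and a combination
    criterion (``loewe``, ``bliss``, ``effect_addition`` or ``hsa``)."""

    drugs: tuple[SingleDrugPD, ...]
    terms: tuple[GPDITerm, ...] = ()
    criterion: str = "bliss"

    def __post_init__(self) -> None:
        drugs = tuple(self.drugs)
        terms = tuple(self.terms)
        object.__setattr__(self, "drugs", drugs)
        object.__setattr__(self, "terms", terms)
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        ids = [d.drug_id for d in drugs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate drug ids: {ids}")
        keys = [(t.perpetrator_id, t.victim_id, t.target_param, t.modulated_pair) for t in terms]
        if len(set(keys)) != len(keys):
            raise ValueError("at most one term per (perpetrator, victim, target, modulated_pair)")
        if self.criterion == "loewe":
            bad = [t for t in terms if t.target_param == "Emax"]
            if bad:
                raise ValueError(
                    "Loewe Additivity supports competitive-type (EC50-level) "
                    f"interaction terms only; found Emax-target terms: {bad}"
                )
        known = set(ids)
        for t in terms:
            if t.victim_id not in known and t.target_param != "INT":
                raise KeyError(f"victim {t.victim_id!r} not among model drugs {sorted(known)}")
            if t.perpetrator_id not in known:
                raise KeyError(f"perpetrator {t.perpetrator_id!r} not among model drugs")
        # modulation terms must reference an existing term's chain
        chains = {t.chain for t in terms}
        for t in terms:
            if t.target_param == "INT" and self._resolve_parent(t) is None:
                raise ValueError(
                    f"modulation term {t} references no existing term "
                    f"(chains available: {sorted(chains)})"
                )

    def _resolve_parent(self, term: GPDITerm) -> GPDITerm | None:
        pair = term.modulated_pair
        candidates = []
        for other in self.terms:
            if other is term:
                continue
            if other.chain == pair:
                candidates.append(other)
            elif (
                other.target_param != "INT"
                and len(pair) == 3
                and pair[:2] == other.chain
                and pair[2] == other.target_param
            ):
                candidates.append(other)
        if not candidates:
            return None
        if len(candidates) > 1:
            raise ValueError(f"ambiguous modulated_pair {pair} matches {candidates}")
        return candidates[0]

    @property
    def drug_map(self) -> dict[str, SingleDrugPD]:
        return {d.drug_id: d for d in self.drugs}

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(d.drug_id for d in self.drugs)

    def terms_on(self, victim_id: str, target: str | None = None):
        return tuple(
            t
            for t in self.terms
            if t.victim_id == victim_id
            and t.target_param != "INT"
            and (target is None or t.target_param == target)
        )

    def with_criterion(self, criterion: str) -> "InteractionModel":
        return replace(self, criterion=criterion)

    def effective_int(self, term: GPDITerm, conc_map) -> float:
        """INT of ``term`` after applying all modulation terms acting on it,
        recursively (a modulator's own INT may itself be modulated)."""
        value = term.int_value
        for mod in self.terms:
            if mod.target_param == "INT" and self._resolve_parent(mod) is term:
                sat = _saturation(conc_map[mod.perpetrator_id], mod.ec50_int, mod.h_int)
                value = value * (1.0 + self.effective_int(mod, conc_map) * sat)
        return value

    def victim_effect(self, victim_id: str, conc_map, modulation: bool = True):
        """Effect of the victim drug with its PD parameters shifted by all
        applicable perpetrator terms (product composition)."""
        try:
            pd = self.drug_map[victim_id]
        except KeyError:
            raise KeyError(f"drug {victim_id!r} not in model") from None
        ec50_factor = 1.0
        emax_factor = 1.0
        for t in self.terms_on(victim_id):
            int_eff = self.effective_int(t, conc_map) if modulation else t.int_value
            sat = _saturation(conc_map[t.perpetrator_id], t.ec50_int, t.h_int)
            factor = 1.0 + int_eff * sat
            if np.any(np.asarray(factor) <= 0):
                raise ValueError(
                    f"shift factor on {t.target_param} of {victim_id!r} became "
                    f"non-positive (effective INT < -1 after modulation)"
                )
            if t.target_param == "EC50":
                ec50_factor = ec50_factor * factor
            else:
                emax_factor = emax_factor * factor
        if pd.form != "sigmoid_emax":
            raise WrongFormError(
                "victim_effect composes shifts on Emax/EC50 of the sigmoidal "
                "form; use slope_model_shift for slope/power drugs"
            )
        return hill_effect(
            conc_map[victim_id], pd.emax * emax_factor, pd.ec50 * ec50_factor, pd.hill
        )


def perturbed_effect(model: InteractionModel, victim_id: str, conc_map):
    """Victim effect under pairwise interaction terms only (modulation terms,
    if any, are held at their unmodulated INT)."""
    return model.victim_effect(victim_id, conc_map, modulation=False)


def modulated_effect(model: InteractionModel, victim_id: str, conc_map):
    """Victim effect with modulation terms applied on top of the pairwise
    terms; reduces to :func:`perturbed_effect` at zero modulator exposure."""
    return model.victim_effect(victim_id, conc_map, modulation=True)


@dataclass(frozen=True)
class SlopeShiftEffect:
    """Result of applying an interaction term to a slope/power drug."""

    effect: float
    placement: str
    interpretation: str = field(default="")


def slope_model_shift(
    params: SingleDrugPD, term: GPDITerm, conc, perp_conc, placement: str = "denominator"
) -> SlopeShiftEffect:
    """Interaction shift for slope/power single-drug forms.

    ``placement="denominator"`` divides the slope by the shift factor (INT
    reads as a fractional EC50 change; approximate for the power form where
    SLOPE = Emax/EC50**H); ``placement="numerator"`` multiplies the effect by
    the factor (INT reads as a fractional Emax change, with opposite
    polarity).
    """
    from .drug_effect import slope_or_power_effect

    if placement not in ("numerator", "denominator"):
        raise ValueError("placement must be 'numerator' or 'denominator'")
    base = slope_or_power_effect(params, conc)
    factor = gpdi_shift(term, perp_conc)
    if placement == "numerator":
        value = base * factor
        note = "Emax-like (allosteric); INT polarity opposite to EC50 placement"
    else:
        value = base / factor
        note = "EC50-like (competitive)"
        if params.form == "power":
            note += "; approximate: slope of the power model is Emax/EC50**H"
    return SlopeShiftEffect(effect=float(value), placement=placement, interpretation=note)
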