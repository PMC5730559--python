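"""Combination rules turning single-drug effects into a combined effect.

Four null-interaction criteria are supported:

* ``bliss``            -- Bliss Independence, ``E = 1 - prod(1 - E_i)``;
* ``effect_addition``  -- plain sum, optionally clipped at a ceiling;
* ``hsa``              -- highest single agent, ``E = max(E_i)``;
* ``loewe``            -- Loewe Additivity (dose substitution): the combined
  effect is the root of the implicit equation

      1 = sum_i C_i / (EC50_i * f_i * (E / (Emax_i - E))**(1/H_i))

  where ``f_i`` is the product of interaction shift factors on drug i's EC50.
  The right-hand side is strictly decreasing in E on (0, min Emax), so the
  root is unique and is found by a bracketed Brent search (scalar API) or a
  fixed-iteration vectorised bisection (surface evaluation over grids).

Interaction terms perturb each drug's effect *before* combination, so any
criterion can carry the same directional interaction parameters.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq

from .interaction import InteractionModel, _saturation

__all__ = [
    "LoeweBracketError",
    "combine_bliss",
    "combine_effect_addition",
    "combine_hsa",
    "combine_loewe",
    "combined_effect",
    "effect_surface",
    "surface_table",
]

_EPS = 1e-12


class LoeweBracketError(RuntimeError):
    """The implicit dose-substitution equation had no sign change in the
    search bracket (reported with the bracket endpoints)."""


def _stack(effects):
    effects = [np.asarray(e, dtype=float) for e in effects]
    if not effects:
        raise ValueError("need at least one effect")
    return np.broadcast_arrays(*effects)


def combine_bliss(effects):
    """Bliss Independence: ``1 - prod(1 - E_i)``; requires effects in [0, 1]."""
    arrs = _stack(effects)
    for a in arrs:
        if np.any((a < 0) | (a > 1)):
            raise ValueError("Bliss Independence requires effects on the [0, 1] scale")
    out = 1.0 - np.prod([1.0 - a for a in arrs], axis=0)
    return out if np.ndim(out) else float(out)


def combine_effect_addition(effects, ceiling: float | None = 1.0):
    """Simple effect addition ``sum(E_i)``, clipped at ``ceiling`` (pass
    ``ceiling=None`` to disable clipping)."""
    arrs = _stack(effects)
    for a in arrs:
        if np.any(a < 0):
            raise ValueError("effects must be non-negative")
    out = np.sum(arrs, axis=0)
    if ceiling is not None:
        out = np.minimum(out, ceiling)
    return out if np.ndim(out) else float(out)


def combine_hsa(effects):
    """Highest single agent: ``max(E_i)``."""
    arrs = _stack(effects)
    for a in arrs:
        if np.any(a < 0):
            raise ValueError("effects must be non-negative")
    out = np.max(arrs, axis=0)
    return out if np.ndim(out) else float(out)


def _loewe_denominators(model: InteractionModel, conc_map):
    """Per-drug effective EC50 (EC50 times the product of shift factors)."""
    denoms = {}
    for d in model.drugs:
        f = 1.0
        for t in model.terms_on(d.drug_id, target="EC50"):
            int_eff = model.effective_int(t, conc_map)
            f = f * (1.0 + int_eff * _saturation(conc_map[t.perpetrator_id], t.ec50_int, t.h_int))
        denoms[d.drug_id] = d.ec50 * f
    return denoms


def _warn_unequal_emax(model):
    emaxes = [d.emax for d in model.drugs]
    if max(emaxes) > 0 and (max(emaxes) - min(emaxes)) / max(emaxes) > 0.01:
        warnings.warn(
            "Loewe Additivity presumes a mutual maximum effect; Emax values "
            f"differ by more than 1% ({emaxes}); the combined effect is capped "
            "below min(Emax)",
            stacklevel=3,
        )


def combine_loewe(model: InteractionModel, conc_map, residual_tol: float = 1e-10):
    """Combined effect under Loewe Additivity for the drugs in ``model`` at
    the (scalar) concentrations in ``conc_map``.

    Zero-concentration margins short-circuit: with a single active drug the
    perturbed single-drug effect is returned, with none the effect is 0.
    When the dose-fraction sum exceeds 1 even at the upper bracket end (doses
    far beyond equivalence), the value is capped just below ``min(Emax)``.
    """
    active = [d for d in model.drugs if conc_map[d.drug_id] > 0]
    if not active:
        return 0.0
    if len(active) == 1:
        return float(model.victim_effect(active[0].drug_id, conc_map))
    if any(d.emax <= 0 for d in active):
        raise ValueError("Loewe Additivity requires Emax > 0 for every active drug")
    _warn_unequal_emax(model)
    emax_min = min(d.emax for d in active)
    denoms = _loewe_denominators(model, conc_map)

    def g(e):
        total = 0.0
        for d in active:
            frac = ((d.emax - e) / e) ** (1.0 / d.hill)
            total += conc_map[d.drug_id] / denoms[d.drug_id] * frac
        return total - 1.0

    lo = emax_min * _EPS
    hi = emax_min * (1.0 - _EPS)
    g_hi = g(hi)
    if g_hi > 0:
        # effect pinned at the mutual maximum; flag via warning, cap below it
        warnings.warn(
            f"Loewe dose-fraction sum exceeds 1 at E={hi:g}; combined effect "
            "capped just below min(Emax)",
            stacklevel=2,
        )
        return hi
    with np.errstate(over="ignore", divide="ignore"):
        g_lo = g(lo)
    if not (g_lo > 0):
        raise LoeweBracketError(
            f"no sign change on bracket [{lo:g}, {hi:g}]: g(lo)={g_lo:g}, g(hi)={g_hi:g}"
        )
    root = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    if abs(g(root)) > residual_tol:
        raise LoeweBracketError(
            f"root residual {g(root):g} exceeds tolerance {residual_tol:g} "
            f"on bracket [{lo:g}, {hi:g}]"
        )
    return float(root)


def _loewe_bisect(model: InteractionModel, conc_map, iters: int = 90):
    """Vectorised Loewe solver over concentration arrays (one well per entry).

    Fixed-iteration bisection on the strictly decreasing dose-fraction sum;
    90 halvings shrink the bracket below 1e-27 in effect units.  Wells whose
    fraction sum exceeds 1 everywhere converge onto the upper cap naturally.
    """
    ids = model.drug_ids
    conc = {i: np.asarray(conc_map[i], dtype=float) for i in ids}
    shape = np.broadcast_shapes(*(c.shape for c in conc.values()))
    conc = {i: np.broadcast_to(c, shape) for i, c in conc.items()}
    out = np.zeros(shape, dtype=float)

    active = {i: conc[i] > 0 for i in ids}
    n_active = np.sum([active[i] for i in ids], axis=0)

    # single-active wells: perturbed single-drug effect
    for i in ids:
        mask = active[i] & (n_active == 1)
        if np.any(mask):
            sub = {j: conc[j][mask] for j in ids}
            out[mask] = model.victim_effect(i, sub)

    multi = n_active >= 2
    if not np.any(multi):
        return out
    _warn_unequal_emax(model)
    sub = {j: conc[j][multi] for j in ids}
    denoms = _loewe_denominators(model, sub)
    emax_min = min(d.emax for d in model.drugs)
    lo = np.full(int(np.sum(multi)), emax_min * _EPS)
    hi = np.full_like(lo, emax_min * (1.0 - _EPS))

    def g(e):
        total = -1.0
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            for d in model.drugs:
                frac = np.where(
                    sub[d.drug_id] > 0,
                    sub[d.drug_id]
                    / denoms[d.drug_id]
                    * ((np.maximum(d.emax - e, 0.0)) / e) ** (1.0 / d.hill),
                    0.0,
                )
                total = total + frac
        return total

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos = g(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    out[multi] = 0.5 * (lo + hi)
    return out


def combined_effect(model: InteractionModel, conc_map, criterion: str | None = None):
    """Scalar combined effect at one concentration combination under the
    model's (or an overriding) additivity criterion."""
    criterion = criterion or model.criterion
    if criterion == "loewe":
        return combine_loewe(model, conc_map)
    effects = [model.victim_effect(d.drug_id, conc_map) for d in model.drugs]
    if criterion == "bliss":
        return combine_bliss(effects)
    if criterion == "effect_addition":
        return combine_effect_addition(effects)
    if criterion == "hsa":
        return combine_hsa(effects)
    raise ValueError(f"unknown criterion {criterion!r}")


def effect_surface(model: InteractionModel, conc_map, criterion: str | None = None,
                   clip: bool = False):
    """Vectorised combined effect over arrays of well concentrations.

    ``conc_map`` maps every drug id to an array (broadcastable shapes); the
    return value has the broadcast shape.  ``clip=True`` clips each drug's
    effect into [0, 1] before probabilistic combination (used while fitting,
    where an estimated Emax may transiently exceed 1).
    """
    criterion = criterion or model.criterion
    if criterion == "loewe":
        return _loewe_bisect(model, conc_map)
    effects = [model.victim_effect(d.drug_id, conc_map) for d in model.drugs]
    if clip:
        effects = [np.clip(e, 0.0, 1.0) for e in effects]
    if criterion == "bliss":
        return combine_bliss(effects)
    if criterion == "effect_addition":
        return combine_effect_addition(effects)
    if criterion == "hsa":
        return combine_hsa(effects)
    raise ValueError(f"unknown criterion {criterion!r}")


def surface_table(model: InteractionModel, tiers_a, tiers_b, criterion: str | None = None):
    """Full-grid combined-effect surface as a tidy DataFrame with columns
    ``c_a``, ``c_b``, ``e_comb`` (CSV-ready for plotting)."""
    import pandas as pd

    id_a, id_b = model.drug_ids[:2]
    ca, cb = np.meshgrid(np.asarray(tiers_a, float), np.asarray(tiers_b, float), indexing="ij")
    surf = effect_surface(model, {id_a: ca.ravel(), id_b: cb.ravel()}, criterion)
    return pd.DataFrame({"c_a": ca.ravel(), "c_b": cb.ravel(), "e_comb": surf})
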