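"""Conventional single-parameter interaction models used as comparators.

* Greco response-surface model (Loewe-based): the combined effect solves

      1 = C_A/(EC50_A*(E/(Emax_A-E))**(1/H_A))
        + C_B/(EC50_B*(E/(Emax_B-E))**(1/H_B))
        + alpha*C_A*C_B/(EC50_A*EC50_B*(E/(Emax-E))**(1/(2H_A)+1/(2H_B)))

  with a single interaction index alpha: alpha = 0 is Loewe Additivity,
  alpha > 0 synergy, alpha < 0 antagonism.  The unsubscripted Emax of the
  interaction term is taken as min(Emax_A, Emax_B) (the model presumes a
  mutual maximum effect).

* Empiric Bliss model: ``E = E_A + E_B - beta*E_A*E_B``; beta = 1 is Bliss
  Independence, beta > 1 antagonism, beta < 1 synergy.

* Isobole curvature score on MIC-normalised concentration pairs (x, y):
  ``gamma = logit(x) - logit(y)``; gamma = 0 means linear (additive)
  isoboles, gamma < 0 synergy, gamma > 0 antagonism (the pairing of signs to
  calls follows the convention's sentence order and is configurable at the
  classification step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .drug_effect import SingleDrugPD, hill_effect

__all__ = [
    "IsobolePoint",
    "empiric_bliss_effect",
    "extract_isobole_points",
    "greco_effect",
    "greco_surface",
    "isobole_gamma",
]

_EPS = 1e-12


def _greco_g(e, pd_a, pd_b, alpha, c_a, c_b, emax_int):
    total = -1.0
    if c_a > 0:
        total += c_a / (pd_a.ec50 * (e / (pd_a.emax - e)) ** (1.0 / pd_a.hill))
    if c_b > 0:
        total += c_b / (pd_b.ec50 * (e / (pd_b.emax - e)) ** (1.0 / pd_b.hill))
    if c_a > 0 and c_b > 0 and alpha != 0.0:
        expo = 0.5 / pd_a.hill + 0.5 / pd_b.hill
        total += (alpha * c_a * c_b) / (
            pd_a.ec50 * pd_b.ec50 * (e / (emax_int - e)) ** expo
        )
    return total


def greco_effect(
    pd_a: SingleDrugPD, pd_b: SingleDrugPD, alpha: float, c_a: float, c_b: float
) -> float:
    """Combined effect of the Greco model at one concentration pair.

    alpha = 0 reproduces interaction-free Loewe Additivity exactly.  For
    strongly negative alpha the implicit equation can lose its root in
    (0, min Emax); the nearer boundary value is then returned with a warning
    so that batch fits proceed.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if c_a < 0 or c_b < 0:
        raise ValueError("concentrations must be non-negative")
    if c_a == 0 and c_b == 0:
        return 0.0
    if c_a == 0:
        return float(hill_effect(c_b, pd_b.emax, pd_b.ec50, pd_b.hill))
    if c_b == 0:
        return float(hill_effect(c_a, pd_a.emax, pd_a.ec50, pd_a.hill))
    emax_min = min(pd_a.emax, pd_b.emax)
    lo = emax_min * _EPS
    hi = emax_min * (1.0 - _EPS)
    args = (pd_a, pd_b, alpha, c_a, c_b, emax_min)
    with np.errstate(over="ignore", divide="ignore"):
        g_lo = _greco_g(lo, *args)
        g_hi = _greco_g(hi, *args)
    if np.sign(g_lo) == np.sign(g_hi):
        boundary = hi if g_hi > 0 else lo
        warnings.warn(
            f"Greco equation has no root in (0, {emax_min:g}) at alpha={alpha:g}, "
            f"C=({c_a:g}, {c_b:g}); returning boundary value {boundary:g}",
            stacklevel=2,
        )
        return float(boundary)
    root = brentq(lambda e: _greco_g(e, *args), lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    return float(root)


def greco_surface(pd_a, pd_b, alpha, c_a, c_b, iters: int = 90) -> np.ndarray:
    """Vectorised Greco solver over concentration arrays (fixed-iteration
    bisection; rootless wells converge onto the nearer boundary)."""
    c_a = np.asarray(c_a, float)
    c_b = np.asarray(c_b, float)
    shape = np.broadcast_shapes(c_a.shape, c_b.shape)
    c_a = np.broadcast_to(c_a, shape)
    c_b = np.broadcast_to(c_b, shape)
    out = np.zeros(shape, float)
    only_a = (c_a > 0) & (c_b == 0)
    only_b = (c_b > 0) & (c_a == 0)
    out[only_a] = hill_effect(c_a[only_a], pd_a.emax, pd_a.ec50, pd_a.hill)
    out[only_b] = hill_effect(c_b[only_b], pd_b.emax, pd_b.ec50, pd_b.hill)
    both = (c_a > 0) & (c_b > 0)
    if not np.any(both):
        return out
    ca, cb = c_a[both], c_b[both]
    emax_min = min(pd_a.emax, pd_b.emax)
    expo = 0.5 / pd_a.hill + 0.5 / pd_b.hill
    lo = np.full(ca.shape, emax_min * _EPS)
    hi = np.full(ca.shape, emax_min * (1.0 - _EPS))

    def g(e):
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            t = (
                ca / (pd_a.ec50 * (e / (pd_a.emax - e)) ** (1.0 / pd_a.hill))
                + cb / (pd_b.ec50 * (e / (pd_b.emax - e)) ** (1.0 / pd_b.hill))
                + (alpha * ca * cb)
                / (pd_a.ec50 * pd_b.ec50 * (e / np.maximum(emax_min - e, _EPS)) ** expo)
            )
        return t - 1.0

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pos = g(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    out[both] = 0.5 * (lo + hi)
    return out


def empiric_bliss_effect(e_a, e_b, beta: float, clip: bool = True):
    """Empiric Bliss model ``E = E_A + E_B - beta*E_A*E_B``.

    beta = 1 reproduces Bliss Independence.  With ``clip=True`` (default) the
    result is clipped to [0, 1] and a warning is emitted when clipping
    actually occurred.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    e_a = np.asarray(e_a, float)
    e_b = np.asarray(e_b, float)
    if np.any((e_a < 0) | (e_a > 1) | (e_b < 0) | (e_b > 1)):
        raise ValueError("component effects must lie in [0, 1]")
    out = e_a + e_b - beta * e_a * e_b
    if clip:
        clipped = np.clip(out, 0.0, 1.0)
        n_clip = int(np.sum(clipped != out))
        if n_clip:
            warnings.warn(f"empiric Bliss effect clipped to [0, 1] at {n_clip} point(s)")
        out = clipped
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class IsobolePoint:
    """A point on an equal-effect contour, with both coordinates normalised
    by the respective drug's MIC-like monotherapy-equivalent concentration."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 < self.x < 1.0 and 0.0 < self.y < 1.0):
            raise ValueError("isobole coordinates must lie strictly inside (0, 1)")


def isobole_gamma(point: IsobolePoint, base: float = np.e) -> float:
    """Isobole curvature score ``logit(x) - logit(y)``.

    Antisymmetric under swapping the two coordinates; the logarithm base
    (natural by default) rescales the score without changing its sign.
    """
    scale = np.log(base)
    return float(
        (np.log(point.x / (1 - point.x)) - np.log(point.y / (1 - point.y))) / scale
    )


def extract_isobole_points(tiers_a, tiers_b, surface, level: float):
    """Convenience equal-effect contour extractor on a checkerboard surface.

    For each row concentration ``c_a`` the crossing ``c_b`` where the combined
    effect passes ``level`` is located by linear interpolation; both
    coordinates are normalised by the monotherapy crossing concentration of
    the respective drug.  Points falling outside (0, 1) after normalisation
    (no crossing, or at/above the monotherapy equivalent) are dropped.
    """
    tiers_a = np.asarray(tiers_a, float)
    tiers_b = np.asarray(tiers_b, float)
    surface = np.asarray(surface, float)
    if surface.shape != (tiers_a.size, tiers_b.size):
        raise ValueError("surface must have shape (len(tiers_a), len(tiers_b))")

    def crossing(conc, eff):
        above = eff >= level
        if not above.any() or above[0]:
            return None
        k = int(np.argmax(above))
        c0, c1, e0, e1 = conc[k - 1], conc[k], eff[k - 1], eff[k]
        if e1 == e0:
            return None
        return c0 + (level - e0) * (c1 - c0) / (e1 - e0)

    mic_a = crossing(tiers_a, surface[:, 0])
    mic_b = crossing(tiers_b, surface[0, :])
    if mic_a is None or mic_b is None:
        return []
    points = []
    for i, ca in enumerate(tiers_a):
        if ca <= 0:
            continue
        cb = crossing(tiers_b, surface[i, :])
        if cb is None:
            continue
        x, y = ca / mic_a, cb / mic_b
        if 0 < x < 1 and 0 < y < 1:
            points.append(IsobolePoint(x=float(x), y=float(y)))
    return points
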