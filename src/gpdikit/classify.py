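"""Interaction calling from fitted parameter shifts.

A fitted directional term is summarised by the fractional change of the
victim's EC50 evaluated at the perpetrator's own EC50,

    shift = INT * EC50_perp**H_INT / (EC50_INT**H_INT + EC50_perp**H_INT),

reported alongside its percent-of-baseline form ``(1 + shift) * 100%``.
Shifts inside an additivity margin — (-0.5, +0.5) by default, calibrated from
sham (drug-vs-itself) experiments — are called additive; the two directions
of a pair then map onto a six-way classification: additive, bidirectional
synergy/antagonism (both shifts outside, same polarity), monodirectional
synergy/antagonism (exactly one outside), and bidirectional asymmetric
(both outside, opposite polarity, i.e. concentration-dependent synergy or
antagonism).  Boundary values count as within the margin (conservative
calling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drug_effect import SingleDrugPD
from .interaction import GPDITerm, _saturation

__all__ = [
    "AdditivityMargin",
    "FractionalShift",
    "InteractionCall",
    "calls_table",
    "classify_conventional",
    "classify_fit",
    "classify_pair",
    "derive_margin",
    "fractional_shift_at_perpetrator_ec50",
]

CLASSES = (
    "additive",
    "bidirectional_synergy",
    "bidirectional_antagonism",
    "monodirectional_synergy",
    "monodirectional_antagonism",
    "bidirectional_asymmetric",
)


@dataclass(frozen=True)
class FractionalShift:
    """Fractional EC50 change of the victim at the perpetrator's EC50."""

    perpetrator_id: str
    victim_id: str
    shift_at_ec50: float

    def __post_init__(self) -> None:
        if self.shift_at_ec50 < -1:
            raise ValueError("a fractional EC50 shift cannot fall below -1")

    @property
    def pct_of_baseline(self) -> float:
        """Victim EC50 as a percentage of its no-interaction value."""
        return (1.0 + self.shift_at_ec50) * 100.0


@dataclass(frozen=True)
class AdditivityMargin:
    """Interval of fractional shifts called additive; values exactly on a
    bound are (configurably) treated as within."""

    lower: float = -0.5
    upper: float = 0.5
    source: str = "fixed"
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.lower < 0 < self.upper:
            raise ValueError("margin must contain 0 (lower < 0 < upper)")

    def contains(self, shift: float) -> bool:
        if self.inclusive:
            return self.lower <= shift <= self.upper
        return self.lower < shift < self.upper


@dataclass(frozen=True)
class InteractionCall:
    """Six-way interaction class of one drug pair under one criterion."""

    pair: tuple[str, str]
    shift_ab: float  # fractional EC50 change of drug A caused by drug B
    shift_ba: float
    label: str
    criterion: str = "loewe"

    def swapped(self) -> "InteractionCall":
        return InteractionCall(
            pair=(self.pair[1], self.pair[0]), shift_ab=self.shift_ba,
            shift_ba=self.shift_ab, label=self.label, criterion=self.criterion,
        )


def fractional_shift_at_perpetrator_ec50(
    term: GPDITerm, perpetrator: SingleDrugPD
) -> FractionalShift:
    """Evaluate a fitted term at the perpetrator's EC50.

    In the reduced model (interaction potency pinned to the perpetrator's
    EC50, H_INT = 1) this is exactly INT/2; saturation is always partial for
    a positive interaction potency, so ``|shift| < |INT|``.
    """
    sat = float(_saturation(perpetrator.ec50, term.ec50_int, term.h_int))
    return FractionalShift(
        perpetrator_id=term.perpetrator_id,
        victim_id=term.victim_id,
        shift_at_ec50=term.int_value * sat,
    )


def derive_margin(sham_shifts, method: str = "fixed",
                  fallback=(-0.5, 0.5)) -> AdditivityMargin:
    """Additivity margin from sham-combination shift values.

    ``method="sham_percentiles"`` takes the 10th-90th percentile band of the
    sham shifts; the default keeps the fixed conventional margin.  Degenerate
    or empty inputs fall back to the fixed bounds with a warning.
    """
    shifts = np.asarray([float(s) for s in sham_shifts], dtype=float)
    if method == "fixed":
        return AdditivityMargin(lower=fallback[0], upper=fallback[1], source="fixed")
    if method != "sham_percentiles":
        raise ValueError("method must be 'fixed' or 'sham_percentiles'")
    if shifts.size < 2:
        warnings.warn("fewer than 2 sham shifts; falling back to the fixed margin")
        return AdditivityMargin(lower=fallback[0], upper=fallback[1], source="fixed")
    lower = float(np.percentile(shifts, 10))
    upper = float(np.percentile(shifts, 90))
    if not lower < 0 < upper:
        warnings.warn(
            f"sham percentile band ({lower:.3g}, {upper:.3g}) does not straddle 0; "
            "falling back to the fixed margin"
        )
        return AdditivityMargin(lower=fallback[0], upper=fallback[1], source="fixed")
    return AdditivityMargin(lower=lower, upper=upper, source="sham_percentiles")


def classify_pair(
    shift_ab: float,
    shift_ba: float,
    margin: AdditivityMargin | None = None,
    pair: tuple[str, str] = ("A", "B"),
    criterion: str = "loewe",
) -> InteractionCall:
    """Six-way call from the two directional shifts of a pair.

    ``shift_ab`` is the fractional EC50 change of the first drug of ``pair``
    caused by the second (and vice versa for ``shift_ba``).
    """
    margin = margin or AdditivityMargin()
    if not (np.isfinite(shift_ab) and np.isfinite(shift_ba)):
        raise ValueError("shifts must be finite")
    in_ab = margin.contains(shift_ab)
    in_ba = margin.contains(shift_ba)
    if in_ab and in_ba:
        label = "additive"
    elif in_ab or in_ba:
        out = shift_ba if in_ab else shift_ab
        label = "monodirectional_synergy" if out < 0 else "monodirectional_antagonism"
    elif shift_ab < 0 and shift_ba < 0:
        label = "bidirectional_synergy"
    elif shift_ab > 0 and shift_ba > 0:
        label = "bidirectional_antagonism"
    else:
        label = "bidirectional_asymmetric"
    return InteractionCall(pair=tuple(pair), shift_ab=float(shift_ab),
                           shift_ba=float(shift_ba), label=label, criterion=criterion)


def classify_conventional(value: float, kind: str,
                          margin: tuple[float, float] | None = None) -> str:
    """Three-way call for a conventional interaction index.

    ``kind="greco"``: additive within the margin (default the sham-derived
    (-0.45, 0.82) band), synergy above, antagonism below.
    ``kind="beta"``: the empiric Bliss index, additive within a margin
    around 1 (default (0.5, 1.5)), antagonism above, synergy below.
    ``kind="gamma"``: isobole curvature, synergy below the margin (default
    a point margin at 0), antagonism above.
    """
    if kind == "greco":
        lo, hi = margin if margin is not None else (-0.45, 0.82)
        if lo <= value <= hi:
            return "additive"
        return "synergy" if value > hi else "antagonism"
    if kind == "beta":
        lo, hi = margin if margin is not None else (0.5, 1.5)
        if lo <= value <= hi:
            return "additive"
        return "antagonism" if value > hi else "synergy"
    if kind == "gamma":
        lo, hi = margin if margin is not None else (0.0, 0.0)
        if lo <= value <= hi:
            return "additive"
        return "antagonism" if value > hi else "synergy"
    raise ValueError("kind must be 'greco', 'beta' or 'gamma'")


def classify_fit(fit, margin: AdditivityMargin | None = None,
                 gate_significance: bool = True) -> InteractionCall:
    """Interaction call from a stepwise fit result.

    Each directional term of the final model is evaluated at its
    perpetrator's EC50; a shift whose parameter did not pass the likelihood
    ratio test during the stepwise build is treated as 0 (no interaction)
    when ``gate_significance`` is on.
    """
    margin = margin or AdditivityMargin()
    model = fit.model
    a, b = model.drug_ids[:2]
    shifts = {}
    for victim, perp in ((a, b), (b, a)):
        terms = [t for t in model.terms_on(victim, target="EC50")
                 if t.perpetrator_id == perp]
        if not terms:
            shifts[victim] = 0.0
            continue
        term = terms[0]
        if gate_significance:
            name = f"int_{victim}.{perp}"
            sig = fit.significant.get(name, fit.significant.get("int", True))
            if not sig:
                shifts[victim] = 0.0
                continue
        shifts[victim] = fractional_shift_at_perpetrator_ec50(
            term, model.drug_map[perp]
        ).shift_at_ec50
    criterion = fit.extra.get("criterion", model.criterion)
    return classify_pair(shifts[a], shifts[b], margin, pair=(a, b), criterion=criterion)


def calls_table(calls) -> pd.DataFrame:
    """Tidy classification table (CSV-ready, shift-plane coordinates)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "drug_a": c.pair[0],
                "drug_b": c.pair[1],
                "criterion": c.criterion,
                "shift_ab": c.shift_ab,
                "shift_ba": c.shift_ba,
                "pct_ab": (1 + c.shift_ab) * 100.0,
                "pct_ba": (1 + c.shift_ba) * 100.0,
                "class": c.label,
            }
        )
    return pd.DataFrame(rows)
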