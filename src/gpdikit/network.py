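"""Directed perpetrator-to-victim interaction networks.

Each outside-margin directional shift becomes one edge from the perpetrator
to the victim, with synergistic polarity when the victim's EC50 was decreased
(shift < 0) and antagonistic when increased.  To avoid committing to a single
additivity criterion, calls obtained under Loewe Additivity and Bliss
Independence can be *exclusively joined*: a directed edge survives only if it
is outside the margin with the same polarity under both criteria (the Loewe
shift is carried as the primary edge value, the Bliss shift as a secondary
attribute; polarity conflicts are dropped and logged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .classify import AdditivityMargin, InteractionCall

__all__ = ["DrugProfile", "JoinError", "build_network", "join_exclusive", "profiles_table"]


class JoinError(ValueError):
    """The two call sets do not cover the same drug pairs."""


@dataclass
class DrugProfile:
    """Perpetrator/victim edge tallies of one drug in a network."""

    drug_id: str
    n_perpetrator_edges: int = 0
    n_victim_edges: int = 0
    n_synergy_out: int = 0
    n_antagonism_out: int = 0
    n_synergy_in: int = 0
    n_antagonism_in: int = 0

    @property
    def sole_perpetrator(self) -> bool:
        return self.n_perpetrator_edges > 0 and self.n_victim_edges == 0

    @property
    def sole_victim(self) -> bool:
        return self.n_victim_edges > 0 and self.n_perpetrator_edges == 0


def _directed_shifts(call: InteractionCall):
    """(perpetrator, victim, shift) for both directions of a call."""
    a, b = call.pair
    return ((b, a, call.shift_ab), (a, b, call.shift_ba))


def join_exclusive(calls_loewe, calls_bliss,
                   margin: AdditivityMargin | None = None) -> pd.DataFrame:
    """Keep only directed shifts outside the margin under BOTH criteria with
    the same polarity; edge values come from the Loewe fit, the Bliss shift
    is carried alongside.  Returns the joined edge table."""
    margin = margin or AdditivityMargin()
    by_pair_l = {frozenset(c.pair): c for c in calls_loewe}
    by_pair_b = {frozenset(c.pair): c for c in calls_bliss}
    orphans = set(by_pair_l) ^ set(by_pair_b)
    if orphans:
        raise JoinError(
            f"call sets cover different pairs; orphans: "
            f"{sorted(tuple(sorted(p)) for p in orphans)}"
        )
    rows = []
    for key, call_l in by_pair_l.items():
        call_b = by_pair_b[key]
        if tuple(call_b.pair) != tuple(call_l.pair):
            call_b = call_b.swapped()
        for (perp, victim, s_l), (_, _, s_b) in zip(
            _directed_shifts(call_l), _directed_shifts(call_b)
        ):
            out_l = not margin.contains(s_l)
            out_b = not margin.contains(s_b)
            if not (out_l and out_b):
                continue
            if (s_l < 0) != (s_b < 0):
                warnings.warn(
                    f"polarity conflict {perp}->{victim}: Loewe shift {s_l:.3g} vs "
                    f"Bliss shift {s_b:.3g}; edge dropped"
                )
                continue
            rows.append(
                {
                    "perpetrator": perp,
                    "victim": victim,
                    "polarity": "synergistic" if s_l < 0 else "antagonistic",
                    "shift_loewe": s_l,
                    "shift_bliss": s_b,
                }
            )
    return pd.DataFrame(rows, columns=["perpetrator", "victim", "polarity",
                                       "shift_loewe", "shift_bliss"])


def build_network(calls_or_edges, margin: AdditivityMargin | None = None):
    """Directed interaction graph plus per-drug perpetrator/victim profiles.

    Accepts either a joined edge table (from :func:`join_exclusive`) or an
    iterable of calls under a single criterion (outside-margin directions
    become edges).  Returns ``(graph, profiles)`` with ``graph`` a
    :class:`networkx.DiGraph` and ``profiles`` a dict keyed by drug id.
    """
    margin = margin or AdditivityMargin()
    if isinstance(calls_or_edges, pd.DataFrame):
        edges = calls_or_edges
    else:
        rows = []
        for call in calls_or_edges:
            for perp, victim, shift in _directed_shifts(call):
                if margin.contains(shift):
                    continue
                rows.append(
                    {
                        "perpetrator": perp,
                        "victim": victim,
                        "polarity": "synergistic" if shift < 0 else "antagonistic",
                        "shift_loewe": shift,
                        "shift_bliss": float("nan"),
                    }
                )
        edges = pd.DataFrame(rows, columns=["perpetrator", "victim", "polarity",
                                            "shift_loewe", "shift_bliss"])
    graph = nx.DiGraph()
    profiles: dict[str, DrugProfile] = {}

    def profile(d):
        return profiles.setdefault(d, DrugProfile(drug_id=d))

    if not isinstance(calls_or_edges, pd.DataFrame):
        for call in calls_or_edges:
            for d in call.pair:
                profile(d)
                graph.add_node(d)
    for _, row in edges.iterrows():
        attrs = {"polarity": row["polarity"], "shift": float(row["shift_loewe"])}
        if np.isfinite(row["shift_bliss"]):  # absent for single-criterion calls
            attrs["shift_bliss"] = float(row["shift_bliss"])
        graph.add_edge(row["perpetrator"], row["victim"], **attrs)
        p = profile(row["perpetrator"])
        v = profile(row["victim"])
        p.n_perpetrator_edges += 1
        v.n_victim_edges += 1
        if row["polarity"] == "synergistic":
            p.n_synergy_out += 1
            v.n_synergy_in += 1
        else:
            p.n_antagonism_out += 1
            v.n_antagonism_in += 1
    return graph, profiles


def profiles_table(profiles: dict) -> pd.DataFrame:
    """Per-drug profile table (CSV-ready)."""
    rows = []
    for p in profiles.values():
        rows.append(
            {
                "drug_id": p.drug_id,
                "n_perpetrator_edges": p.n_perpetrator_edges,
                "n_victim_edges": p.n_victim_edges,
                "n_synergy_out": p.n_synergy_out,
                "n_antagonism_out": p.n_antagonism_out,
                "n_synergy_in": p.n_synergy_in,
                "n_antagonism_in": p.n_antagonism_in,
                "sole_perpetrator": p.sole_perpetrator,
                "sole_victim": p.sole_victim,
            }
        )
    return pd.DataFrame(rows)
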