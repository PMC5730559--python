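"""Checkerboard designs and observed/simulated checkerboard datasets."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthParams
from .interaction import InteractionModel

__all__ = ["CheckerboardDataset", "CheckerboardDesign"]


@dataclass(frozen=True)
class CheckerboardDesign:
    """A factorial two-drug concentration grid (both axes include 0).

    The canonical screening layout is an 8x8 grid with tiers from 0 to a top
    concentration in two-fold (log2) dilution steps; a linear layout with
    equal spacing is provided for design comparisons.
    """

    tiers_a: tuple
    tiers_b: tuple
    scheme: str = "custom"

    def __post_init__(self) -> None:
        for name in ("tiers_a", "tiers_b"):
            tiers = np.asarray(getattr(self, name), dtype=float)
            if tiers.ndim != 1 or tiers.size < 2:
                raise ValueError(f"{name} must be a 1-d vector of >= 2 tiers")
            if np.any(np.diff(tiers) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
            if tiers[0] != 0:
                raise ValueError(f"{name} must include the zero-concentration tier")
            object.__setattr__(self, name, tuple(tiers))

    @classmethod
    def log2(cls, c_max: float = 8.0, n_tiers: int = 8) -> "CheckerboardDesign":
        """0 plus ``n_tiers - 1`` two-fold steps ending at ``c_max``
        (default: 0, 0.125, 0.25, 0.5, 1, 2, 4, 8)."""
        tiers = (0.0,) + tuple(c_max / 2 ** np.arange(n_tiers - 2, -1, -1, dtype=float))
        return cls(tiers_a=tiers, tiers_b=tiers, scheme="log2")

    @classmethod
    def linear(cls, c_max: float = 8.0, n_tiers: int = 8) -> "CheckerboardDesign":
        """0 to ``c_max`` in equal steps."""
        tiers = tuple(np.linspace(0.0, c_max, n_tiers))
        return cls(tiers_a=tiers, tiers_b=tiers, scheme="linear")

    @property
    def c_max(self) -> float:
        return max(self.tiers_a[-1], self.tiers_b[-1])

    def grid(self):
        """Flattened well concentrations ``(conc_a, conc_b)`` row-major."""
        ca, cb = np.meshgrid(self.tiers_a, self.tiers_b, indexing="ij")
        return ca.ravel(), cb.ravel()

    @property
    def n_wells(self) -> int:
        return len(self.tiers_a) * len(self.tiers_b)


@dataclass
class CheckerboardDataset:
    """Checkerboard observations plus generation metadata.

    ``df`` holds one row per observation:

    * endpoint mode: columns ``well_id, conc_a, conc_b, effect``;
    * timecourse mode: columns ``well_id, conc_a, conc_b, time_h, od``.

    ``truth`` (the generating interaction model), ``growth``, ``sigma`` and
    ``seed`` are present for synthetic data so that any fit can be checked
    against the parameters that produced the observations and the dataset can
    be replayed bit-identically.
    """

    drugs: tuple[str, str]
    df: pd.DataFrame
    mode: str = "endpoint"
    design: CheckerboardDesign | None = None
    sigma: float | None = None
    seed: int | None = None
    truth: InteractionModel | None = None
    growth: GrowthParams | None = None
    n_truncated: int = 0
    times: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("endpoint", "timecourse"):
            raise ValueError("mode must be 'endpoint' or 'timecourse'")
        need = {"well_id", "conc_a", "conc_b"}
        need |= {"time_h", "od"} if self.mode == "timecourse" else {"effect"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset frame lacks columns {sorted(missing)}")
        obs = self.df["od" if self.mode == "timecourse" else "effect"]
        if (obs < 0).any():
            raise ValueError("observations must be non-negative")

    @property
    def obs_column(self) -> str:
        return "od" if self.mode == "timecourse" else "effect"

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def conc(self, drug_id: str) -> np.ndarray:
        idx = self.drugs.index(drug_id)
        return self.df[f"conc_{'ab'[idx]}"].to_numpy()

    def monotherapy(self, drug_id: str) -> pd.DataFrame:
        """Rows where only ``drug_id`` (or no drug) is present."""
        idx = self.drugs.index(drug_id)
        other = self.df[f"conc_{'ab'[1 - idx]}"].to_numpy()
        return self.df[other == 0]

    def combination(self) -> pd.DataFrame:
        """Rows where both drugs are present."""
        return self.df[(self.df["conc_a"] > 0) & (self.df["conc_b"] > 0)]

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(1, "drug_a", self.drugs[0])
        out.insert(3, "drug_b", self.drugs[1])
        cols = ["well_id", "drug_a", "conc_a", "drug_b", "conc_b"]
        cols += ["time_h", "od"] if self.mode == "timecourse" else ["effect"]
        out[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CheckerboardDataset":
        df = pd.read_csv(Path(path))
        mode = "timecourse" if "time_h" in df.columns else "endpoint"
        drugs = (str(df["drug_a"].iloc[0]), str(df["drug_b"].iloc[0]))
        keep = ["well_id", "conc_a", "conc_b"]
        keep += ["time_h", "od"] if mode == "timecourse" else ["effect"]
        return cls(drugs=drugs, df=df[keep].copy(), mode=mode)
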