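"""Design identifiability: expected Fisher information and anticipated RSEs.

For an additive Gaussian observation model with SD sigma, the expected
Fisher information of the parameter vector theta over a design is

    FIM = (1/sigma^2) * J^T J

with J the Jacobian of the predicted responses at every design point with
respect to theta (central finite differences, relative step 1e-6).
Anticipated standard errors are the square roots of the diagonal of the
inverse FIM, normalised by the parameter value to give relative standard
errors (RSE, %).

The bundled simulation study emulates design evaluation for two-drug
checkerboards: a symmetric Bliss-based interaction model (both drugs share
Emax, EC50 and H; one joint interaction fraction INT with a shared potency
EC50_INT acts in both directions, interaction sigmoidicity fixed at 1) is
drawn repeatedly from uniform parameter ranges, and the distribution of
anticipated RSEs across draws summarises how well a log2-dilution versus a
linear-dilution 8x8 checkerboard identifies the interaction parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CheckerboardDesign

__all__ = ["FIMResult", "expected_fim", "identifiability_study", "study_table"]

#: uniform sampling ranges of the simulation study (the INT range is the
#: union of an inhibitory and a potentiating band, drawn with equal weight)
STUDY_RANGES = {
    "emax": (0.5, 1.0),
    "ec50": (0.5, 2.0),
    "hill": (1.0, 4.0),
    "int": ((-0.9, -0.5), (0.5, 20.0)),
    "ec50_int": (0.1, 1.0),
}


@dataclass
class FIMResult:
    """Expected information matrix and anticipated parameter precision."""

    fim: np.ndarray
    names: tuple[str, ...]
    rse_pct: dict[str, float]
    singular: bool

    def __post_init__(self) -> None:
        f = np.asarray(self.fim)
        if f.shape[0] != f.shape[1]:
            raise ValueError("FIM must be square")


def expected_fim(predict_fn, theta: dict, sigma: float,
                 free: list[str] | None = None, rel_step: float = 1e-6) -> FIMResult:
    """Expected FIM of ``theta`` for the design baked into ``predict_fn``.

    ``predict_fn(theta) -> 1-d array`` returns the model prediction at every
    design point.  ``free`` restricts the information matrix to a subset of
    parameters (default: all).  Singular information is reported with
    infinite RSEs rather than raised.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    names = tuple(free if free is not None else theta.keys())
    base = np.asarray(predict_fn(theta), dtype=float)
    cols = []
    for name in names:
        step = rel_step * max(abs(theta[name]), 1e-12)
        hi = dict(theta)
        lo = dict(theta)
        hi[name] = theta[name] + step
        lo[name] = theta[name] - step
        cols.append((np.asarray(predict_fn(hi)) - np.asarray(predict_fn(lo))) / (2 * step))
    jac = np.column_stack(cols)
    fim = jac.T @ jac / sigma**2
    fim = 0.5 * (fim + fim.T)
    try:
        cov = np.linalg.inv(fim)
        diag = np.diag(cov)
        singular = bool(np.any(diag <= 0) or np.any(~np.isfinite(diag)))
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        rse = {n: np.inf for n in names}
    else:
        rse = {
            n: float(100.0 * np.sqrt(d) / abs(theta[n])) if theta[n] != 0 else np.inf
            for n, d in zip(names, diag)
        }
    return FIMResult(fim=fim, names=names, rse_pct=rse, singular=singular)


def _symmetric_bliss_predictor(design: CheckerboardDesign):
    """Endpoint combined-effect surface of the symmetric two-drug model,
    vectorised over the design wells."""
    ca, cb = design.grid()

    def predict(theta):
        emax, ec50, hill = theta["emax"], theta["ec50"], theta["hill"]
        int_v, ec50i = theta["int"], theta["ec50_int"]
        f_a = 1.0 + int_v * cb / (ec50i + cb)  # shift on drug A's EC50 by B
        f_b = 1.0 + int_v * ca / (ec50i + ca)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            e_a = np.where(
                ca > 0, emax / (1.0 + (ec50 * f_a / np.maximum(ca, 1e-300)) ** hill), 0.0
            )
            e_b = np.where(
                cb > 0, emax / (1.0 + (ec50 * f_b / np.maximum(cb, 1e-300)) ** hill), 0.0
            )
        return e_a + e_b - e_a * e_b

    return predict


def _draw_parameters(rng: np.random.Generator, scheme: str, c_max: float) -> dict:
    lo, hi = STUDY_RANGES["emax"]
    theta = {"emax": rng.uniform(lo, hi)}
    if scheme == "linear":
        # a linear layout is judged with the potencies centred in the studied
        # range: both EC50-type parameters drawn within 40-60% of the top
        # concentration (a linear grid has no tiers near a sub-unit potency)
        theta["ec50"] = rng.uniform(0.4, 0.6) * c_max
    else:
        theta["ec50"] = rng.uniform(*STUDY_RANGES["ec50"])
    theta["hill"] = rng.uniform(*STUDY_RANGES["hill"])
    neg, pos = STUDY_RANGES["int"]
    theta["int"] = rng.uniform(*neg) if rng.random() < 0.5 else rng.uniform(*pos)
    if scheme == "linear":
        theta["ec50_int"] = rng.uniform(0.4, 0.6) * c_max
    else:
        theta["ec50_int"] = rng.uniform(*STUDY_RANGES["ec50_int"])
    return theta


def identifiability_study(
    n_sims: int = 1000,
    scheme: str = "log2",
    seed=None,
    sigma: float = 0.03,
    design: CheckerboardDesign | None = None,
) -> pd.DataFrame:
    """Anticipated-RSE distribution over random model draws on a design.

    Returns one row per free parameter with the median and 10th/90th
    percentile RSE (%), plus the number of singular draws (excluded from the
    percentiles and tallied in the ``n_singular`` column).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if scheme not in ("log2", "linear"):
        raise ValueError("scheme must be 'log2' or 'linear'")
    rng = np.random.default_rng(seed)
    if design is None:
        design = (
            CheckerboardDesign.log2() if scheme == "log2" else CheckerboardDesign.linear()
        )
    predict = _symmetric_bliss_predictor(design)
    names = ("emax", "ec50", "hill", "int", "ec50_int")
    rse_draws = {n: [] for n in names}
    n_singular = 0
    for _ in range(n_sims):
        theta = _draw_parameters(rng, scheme, design.c_max)
        res = expected_fim(predict, theta, sigma, free=list(names))
        if res.singular or any(~np.isfinite(res.rse_pct[n]) for n in names):
            n_singular += 1
            continue
        for n in names:
            rse_draws[n].append(res.rse_pct[n])
    rows = []
    for n in names:
        draws = np.asarray(rse_draws[n])
        if draws.size == 0:
            rows.append({"parameter": n, "median_rse_pct": np.nan,
                         "p10_rse_pct": np.nan, "p90_rse_pct": np.nan})
            continue
        rows.append(
            {
                "parameter": n,
                "median_rse_pct": float(np.median(draws)),
                "p10_rse_pct": float(np.percentile(draws, 10)),
                "p90_rse_pct": float(np.percentile(draws, 90)),
            }
        )
    out = pd.DataFrame(rows)
    out["n_singular"] = n_singular
    out["scheme"] = scheme
    out["n_sims"] = n_sims
    return out


def study_table(n_sims: int = 1000, seed=None, sigma: float = 0.03) -> pd.DataFrame:
    """Both design schemes side by side (log2 first)."""
    rng = np.random.default_rng(seed)
    log2 = identifiability_study(n_sims, "log2", seed=rng.integers(2**31 - 1), sigma=sigma)
    lin = identifiability_study(n_sims, "linear", seed=rng.integers(2**31 - 1), sigma=sigma)
    return pd.concat([log2, lin], ignore_index=True)
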