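"""Synthetic checkerboard study generator.

Emulates high-throughput two-drug interaction screens: an 8x8 log2-dilution
checkerboard, a known ("truth") interaction model, and either endpoint effect
read-outs or longitudinal optical-density read-outs from the lag + logistic
growth model, with additive Gaussian noise (sigma = 0.03 on the effect scale
by default, a typical in-vitro variability).  Sham combinations (a drug
crossed with itself) are generated from the dose-addition surface
``E(C_A + C_B)`` — the physical truth for a drug combined with itself — and
are what downstream analyses use to calibrate the additivity margin.

Negative noisy observations are truncated at zero and the truncation count is
recorded on the dataset.  Identical seeds reproduce datasets bit-identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .criteria import effect_surface
from .datasets import CheckerboardDataset, CheckerboardDesign
from .drug_effect import SingleDrugPD, effect
from .growth import GrowthParams, simulate_wells
from .interaction import InteractionModel

__all__ = ["generate_checkerboard", "generate_sham", "DEFAULT_TIMES"]

#: 20 read-outs over a 24 h incubation.
DEFAULT_TIMES = tuple(np.linspace(0.0, 24.0, 20))


def _noisy(clean: np.ndarray, sigma: float, rng: np.random.Generator):
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    obs = clean + rng.normal(0.0, sigma, size=clean.shape) if sigma > 0 else clean.copy()
    n_trunc = int(np.sum(obs < 0))
    return np.maximum(obs, 0.0), n_trunc


def generate_checkerboard(
    truth: InteractionModel,
    design: CheckerboardDesign | None = None,
    sigma: float = 0.03,
    seed: int | None = None,
    mode: str = "endpoint",
    growth: GrowthParams | None = None,
    times=None,
) -> CheckerboardDataset:
    """Simulate one checkerboard experiment under a known interaction model.

    Endpoint mode observes the combined-effect surface per well; timecourse
    mode pushes the per-well combined effect through the growth system and
    observes OD at every time point.  Noise is iid additive Gaussian.
    """
    design = design or CheckerboardDesign.log2()
    rng = np.random.default_rng(seed)
    id_a, id_b = truth.drug_ids[:2]
    ca, cb = design.grid()
    e_wells = np.asarray(effect_surface(truth, {id_a: ca, id_b: cb}), dtype=float)
    well_ids = [f"w{i:03d}" for i in range(len(ca))]

    if mode == "endpoint":
        obs, n_trunc = _noisy(e_wells, sigma, rng)
        df = pd.DataFrame(
            {"well_id": well_ids, "conc_a": ca, "conc_b": cb, "effect": obs}
        )
        times_arr = None
    elif mode == "timecourse":
        growth = growth or GrowthParams()
        times_arr = np.asarray(times if times is not None else DEFAULT_TIMES, dtype=float)
        od = simulate_wells(growth, e_wells, times_arr)
        obs, n_trunc = _noisy(od, sigma, rng)
        df = pd.DataFrame(
            {
                "well_id": np.repeat(well_ids, len(times_arr)),
                "conc_a": np.repeat(ca, len(times_arr)),
                "conc_b": np.repeat(cb, len(times_arr)),
                "time_h": np.tile(times_arr, len(ca)),
                "od": obs.ravel(),
            }
        )
    else:
        raise ValueError("mode must be 'endpoint' or 'timecourse'")

    return CheckerboardDataset(
        drugs=(id_a, id_b),
        df=df,
        mode=mode,
        design=design,
        sigma=sigma,
        seed=seed,
        truth=truth,
        growth=growth if mode == "timecourse" else None,
        n_truncated=n_trunc,
        times=times_arr,
    )


def generate_sham(
    drug: SingleDrugPD,
    design: CheckerboardDesign | None = None,
    sigma: float = 0.03,
    seed: int | None = None,
    mode: str = "endpoint",
    growth: GrowthParams | None = None,
    times=None,
) -> CheckerboardDataset:
    """Simulate a sham combination: the same drug on both checkerboard axes.

    The generating surface is dose addition, ``E(C_A + C_B)``, which is what
    a drug truly does when combined with itself.  Fitting these data under
    Loewe Additivity should recover a null interaction; under Bliss
    Independence an apparent self-synergy is expected, and the spread of
    fitted shifts across sham replicates calibrates the additivity margin.
    """
    design = design or CheckerboardDesign.log2()
    rng = np.random.default_rng(seed)
    id_a, id_b = f"{drug.drug_id}#a", f"{drug.drug_id}#b"
    ca, cb = design.grid()
    clean = np.asarray(effect(drug, ca + cb), dtype=float)

    truth = InteractionModel(
        drugs=(
            SingleDrugPD(id_a, emax=drug.emax, ec50=drug.ec50, hill=drug.hill),
            SingleDrugPD(id_b, emax=drug.emax, ec50=drug.ec50, hill=drug.hill),
        ),
        terms=(),
        criterion="loewe",
    )
    well_ids = [f"w{i:03d}" for i in range(len(ca))]

    if mode == "endpoint":
        obs, n_trunc = _noisy(clean, sigma, rng)
        df = pd.DataFrame(
            {"well_id": well_ids, "conc_a": ca, "conc_b": cb, "effect": obs}
        )
        times_arr = None
    elif mode == "timecourse":
        growth = growth or GrowthParams()
        times_arr = np.asarray(times if times is not None else DEFAULT_TIMES, dtype=float)
        od = simulate_wells(growth, clean, times_arr)
        obs, n_trunc = _noisy(od, sigma, rng)
        df = pd.DataFrame(
            {
                "well_id": np.repeat(well_ids, len(times_arr)),
                "conc_a": np.repeat(ca, len(times_arr)),
                "conc_b": np.repeat(cb, len(times_arr)),
                "time_h": np.tile(times_arr, len(ca)),
                "od": obs.ravel(),
            }
        )
    else:
        raise ValueError("mode must be 'endpoint' or 'timecourse'")

    return CheckerboardDataset(
        drugs=(id_a, id_b),
        df=df,
        mode=mode,
        design=design,
        sigma=sigma,
        seed=seed,
        truth=truth,
        growth=growth if mode == "timecourse" else None,
        n_truncated=n_trunc,
        times=times_arr,
    )
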