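"""Maximum-likelihood fitting and the stepwise interaction model build.

All model families (directional parameter-shift interaction models under
Loewe/Bliss, the Greco model, the empiric Bliss model) are fitted by
Gaussian maximum likelihood on endpoint-effect or optical-density time-course
checkerboards.  With an additive residual and the residual SD profiled out,
the ML estimates coincide with nonlinear least squares, so the optimiser is
``scipy.optimize.least_squares`` (trust-region reflective) on transformed
parameters (log for potencies, Hill factors, rates and sigma; log(1+INT) for
interaction fractions so the shift factor stays positive), restarted from 5
jittered initial points.  The objective reported is OFV = -2 log L; AIC =
OFV + 2 * n_params.

The stepwise build follows four steps: (1) single-drug parameters from
monotherapy wells only; (2) with those fixed, a reduced one-parameter
interaction model (joint INT, interaction potency pinned to the perpetrator's
EC50) fitted on combination wells and expanded parameter-by-parameter
(directional INT split, free interaction potencies, optionally interaction
sigmoidicities), each addition kept only when the objective drops by at least
3.84 (chi-square, 1 df, alpha = 0.05); (3) modulation terms on trio data with
lower-order parameters fixed; (4) a joint re-estimation of every retained
parameter for final standard errors (Gauss-Newton observed information).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .criteria import effect_surface
from .conventional import greco_surface
from .datasets import CheckerboardDataset
from .drug_effect import SingleDrugPD, hill_effect
from .growth import GrowthParams, simulate_wells
from .interaction import GPDITerm, InteractionModel

__all__ = [
    "FitResult",
    "IdentifiabilityError",
    "Param",
    "ResidualModel",
    "StepwiseConfig",
    "compare_models",
    "fit_empiric_bliss",
    "fit_gpdi_stepwise",
    "fit_greco",
    "fit_single_drugs",
    "test_modulator",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class IdentifiabilityError(ValueError):
    """The data cannot identify the requested parameters (e.g. fewer than 3
    non-zero monotherapy concentrations for a drug)."""


@dataclass
class ResidualModel:
    """Additive Gaussian residual on the observation scale.

    ``sigma=None`` profiles the residual SD out of the likelihood (it is then
    reported as an estimated parameter); a fixed positive value conditions
    the fit on a known assay SD.
    """

    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.sigma is not None and not self.sigma > 0:
            raise ValueError("sigma must be > 0 (or None to estimate it)")


@dataclass
class StepwiseConfig:
    """Settings of the stepwise interaction-model build."""

    alpha: float = 0.05
    lrt_threshold: float = 3.84
    start_reduced: bool = True
    estimate_h_int: bool = False
    max_rounds: int = 8

    def __post_init__(self) -> None:
        if self.lrt_threshold <= 0:
            raise ValueError("lrt_threshold must be > 0")


@dataclass
class FitResult:
    """Estimates, objective bookkeeping and the fitted model object."""

    estimates: dict[str, float]
    fixed: dict[str, bool]
    ofv: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    se: dict[str, float] | None = None
    rse_pct: dict[str, float] | None = None
    history: list = field(default_factory=list)
    model: InteractionModel | None = None
    growth: GrowthParams | None = None
    sigma: float | None = None
    significant: dict[str, bool] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Parameter table: parameter, estimate, se, rse_pct, fixed_flag."""
        rows = []
        for name, value in self.estimates.items():
            se = (self.se or {}).get(name)
            rse = (self.rse_pct or {}).get(name)
            rows.append(
                {
                    "parameter": name,
                    "estimate": value,
                    "se": se,
                    "rse_pct": rse,
                    "fixed_flag": self.fixed.get(name, False),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter transforms and the generic least-squares ML core
# ---------------------------------------------------------------------------

_FWD = {
    "log": np.log,
    "shifted_log": np.log1p,  # INT >= -1 maps to the whole real line
    "identity": lambda x: x,
}
_BWD = {
    "log": np.exp,
    "shifted_log": np.expm1,
    "identity": lambda z: z,
}
_DERIV = {  # d(value)/d(z) evaluated at the fitted value
    "log": lambda v: abs(v),
    "shifted_log": lambda v: 1.0 + v,
    "identity": lambda v: 1.0,
}


@dataclass
class Param:
    name: str
    value: float
    transform: str = "log"
    fixed: bool = False


def _ofv_from_rss(rss: float, n: int, sigma: float | None) -> float:
    rss = max(rss, 1e-300)
    if sigma is None:
        return n * (_LOG2PI + np.log(rss / n)) + n
    return n * (_LOG2PI + 2.0 * np.log(sigma)) + rss / sigma**2


def _ml_core(residual_fn, params, sigma=None, n_starts=5, rng=None, jitter=0.3):
    """Minimise the Gaussian -2logL via (multi-start) least squares.

    ``residual_fn`` maps a {name: value} dict to the raw residual vector.
    Parameter-space excursions that break model validation are absorbed as
    large residuals so the trust region backs off rather than aborting.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    free = [p for p in params if not p.fixed]
    fixed_vals = {p.name: p.value for p in params if p.fixed}

    def unpack(z):
        vals = dict(fixed_vals)
        for p, zi in zip(free, z):
            vals[p.name] = float(_BWD[p.transform](zi))
        return vals

    r0 = np.asarray(residual_fn(unpack([_FWD[p.transform](p.value) for p in free])), float)
    n = r0.size

    if not free:
        rss = float(np.sum(r0**2))
        return SimpleNamespace(
            values=dict(fixed_vals), free=[], rss=rss, n=n,
            ofv=_ofv_from_rss(rss, n, sigma), jac=None, success=True,
        )

    def rfun(z):
        try:
            r = np.asarray(residual_fn(unpack(z)), float)
        except (ValueError, KeyError, OverflowError):
            return np.full(n, 1e6)
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    z0 = np.array([_FWD[p.transform](p.value) for p in free])
    best = None
    for k in range(max(1, n_starts)):
        z_start = z0 if k == 0 else z0 + rng.normal(0.0, jitter, z0.size)
        try:
            sol = least_squares(
                rfun, z_start, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=400 * (len(free) + 1),
            )
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-13:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("all optimiser starts failed")
    rss, sol = best
    return SimpleNamespace(
        values=unpack(sol.x), free=list(free), rss=rss, n=n,
        ofv=_ofv_from_rss(rss, n, sigma), jac=sol.jac, success=bool(sol.success),
    )


def _standard_errors(core, sigma):
    """Delta-method SEs on the natural scale from the Gauss-Newton
    approximation ``cov = s2 * (J'J)^-1`` in transformed coordinates."""
    if core.jac is None or not core.free:
        return None, None
    s2 = sigma**2 if sigma is not None else core.rss / core.n
    jtj = core.jac.T @ core.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return None, None
    diag = np.diag(cov)
    if np.any(diag < 0) or np.any(~np.isfinite(diag)):
        return None, None
    se, rse = {}, {}
    for i, p in enumerate(core.free):
        v = core.values[p.name]
        se_i = float(np.sqrt(diag[i]) * _DERIV[p.transform](v))
        se[p.name] = se_i
        rse[p.name] = float(100.0 * se_i / abs(v)) if v != 0 else np.inf
    return se, rse


# ---------------------------------------------------------------------------
# model construction from a flat parameter dict
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Structure:
    """Which interaction parameters are individually estimated."""

    split_int: bool = False
    free_ec50int: frozenset = frozenset()
    free_h_int: frozenset = frozenset()


def _pair_key(victim: str, perp: str) -> str:
    return f"{victim}.{perp}"


def _build_model(values, ids, criterion, structure: _Structure | None) -> InteractionModel:
    drugs = tuple(
        SingleDrugPD(
            i, emax=values[f"emax_{i}"], ec50=values[f"ec50_{i}"], hill=values[f"hill_{i}"]
        )
        for i in ids
    )
    terms = ()
    if structure is not None:
        a, b = ids

        def term(victim, perp):
            key = _pair_key(victim, perp)
            int_v = values[f"int_{key}"] if structure.split_int else values["int"]
            ec50i = (
                values[f"ec50int_{key}"]
                if key in structure.free_ec50int
                else values[f"ec50_{perp}"]
            )
            h_i = values[f"hint_{key}"] if key in structure.free_h_int else 1.0
            return GPDITerm(
                perpetrator_id=perp, victim_id=victim, int_value=int_v,
                ec50_int=ec50i, h_int=h_i,
            )

        terms = (term(a, b), term(b, a))
    return InteractionModel(drugs=drugs, terms=terms, criterion=criterion)


def _interaction_params(values, ids, structure: _Structure, config) -> list[Param]:
    a, b = ids
    out = []
    if structure.split_int:
        for key in (_pair_key(a, b), _pair_key(b, a)):
            out.append(Param(f"int_{key}", values.get(f"int_{key}", values.get("int", 0.0)),
                             "shifted_log"))
    else:
        out.append(Param("int", values.get("int", 0.0), "shifted_log"))
    for key in sorted(structure.free_ec50int):
        perp = key.split(".")[1]
        out.append(Param(f"ec50int_{key}", values.get(f"ec50int_{key}", values[f"ec50_{perp}"]),
                         "log"))
    for key in sorted(structure.free_h_int):
        out.append(Param(f"hint_{key}", values.get(f"hint_{key}", 1.0), "log"))
    return out


# ---------------------------------------------------------------------------
# observation layout helpers
# ---------------------------------------------------------------------------


def _timecourse_grid(df: pd.DataFrame):
    """Pivot a long time-course frame to (wells, times) matrices; the fitting
    path requires a complete common time grid across wells."""
    wells = df[["well_id", "conc_a", "conc_b"]].drop_duplicates("well_id")
    times = np.sort(df["time_h"].unique())
    pivot = df.pivot_table(index="well_id", columns="time_h", values="od", sort=True)
    pivot = pivot.loc[wells["well_id"].to_numpy()]
    if pivot.isna().any().any():
        raise ValueError("time-course fitting requires a complete common time grid")
    return (
        wells["conc_a"].to_numpy(),
        wells["conc_b"].to_numpy(),
        times,
        pivot.to_numpy(),
    )


def _make_residual(df, mode, ids, criterion, structure, predictor=None):
    """Residual closure for an endpoint or time-course sub-frame.

    ``predictor(values, conc_a, conc_b)`` overrides the combined-effect
    surface (used by the conventional comparator models).
    """
    if mode == "endpoint":
        ca = df["conc_a"].to_numpy()
        cb = df["conc_b"].to_numpy()
        obs = df["effect"].to_numpy()

        def residual(values):
            if predictor is not None:
                pred = predictor(values, ca, cb)
            else:
                model = _build_model(values, ids, criterion, structure)
                pred = effect_surface(model, {ids[0]: ca, ids[1]: cb}, clip=True)
            return obs - pred

        return residual

    ca, cb, times, obs = _timecourse_grid(df)

    def residual(values):
        if predictor is not None:
            e_wells = predictor(values, ca, cb)
        else:
            model = _build_model(values, ids, criterion, structure)
            e_wells = effect_surface(model, {ids[0]: ca, ids[1]: cb}, clip=True)
        gp = GrowthParams(
            k_lag=values["k_lag"], k_growth=values["k_growth"],
            b_max=values["b_max"], s1_0=values["s1_0"],
        )
        pred = simulate_wells(gp, np.clip(e_wells, 0.0, 1.0), times, method="rk4")
        return (obs - pred).ravel()

    return residual


# ---------------------------------------------------------------------------
# step 1: single-drug characterisation
# ---------------------------------------------------------------------------


def _resolve_fix_emax(fix_emax, mode):
    # turbidity time-courses cannot see effects beyond full growth stasis,
    # so Emax is pinned to 1 there by default; endpoint effects estimate it
    if fix_emax == "auto":
        return 1.0 if mode == "timecourse" else None
    return fix_emax


def _ec50_start(conc, obs, emax0):
    nz = conc > 0
    if not nz.any():
        return 1.0
    half = emax0 / 2.0
    order = np.argsort(conc[nz])
    c_sorted = conc[nz][order]
    o_sorted = obs[nz][order]
    k = int(np.argmin(np.abs(o_sorted - half)))
    return float(max(c_sorted[k], 1e-6))


def fit_single_drugs(
    dataset: CheckerboardDataset,
    residual: ResidualModel | None = None,
    fix_emax="auto",
    n_starts: int = 5,
    random_state=None,
) -> FitResult:
    """Characterise each drug's exposure-response from monotherapy wells only
    (combination wells are excluded); with time-course data the shared growth
    parameters are estimated jointly with the drugs' potencies."""
    residual = residual or ResidualModel()
    rng = np.random.default_rng(random_state)
    ids = dataset.drugs
    emax_fix = _resolve_fix_emax(fix_emax, dataset.mode)

    for i, d in enumerate(ids):
        sub = dataset.monotherapy(d)
        conc = sub[f"conc_{'ab'[i]}"].to_numpy()
        if np.unique(conc[conc > 0]).size < 3:
            raise IdentifiabilityError(
                f"drug {d!r} needs >= 3 distinct non-zero monotherapy "
                "concentrations to identify (Emax, EC50, H)"
            )

    mono_mask = (dataset.df["conc_a"] == 0) | (dataset.df["conc_b"] == 0)
    mono = dataset.df[mono_mask]

    if dataset.mode == "endpoint":
        estimates, fixed_flags, params_all = {}, {}, []
        se_all, rse_all = {}, {}
        converged = True
        for i, d in enumerate(ids):
            sub = dataset.monotherapy(d)
            conc = sub[f"conc_{'ab'[i]}"].to_numpy()
            obs = sub["effect"].to_numpy()
            emax0 = emax_fix if emax_fix is not None else float(np.clip(obs.max(), 0.2, 2.0))
            params = [
                Param(f"emax_{d}", emax0, "log", fixed=emax_fix is not None),
                Param(f"ec50_{d}", _ec50_start(conc, obs, emax0), "log"),
                Param(f"hill_{d}", 1.0, "log"),
            ]

            def resid(values, conc=conc, obs=obs, d=d):
                return obs - hill_effect(
                    conc, values[f"emax_{d}"], values[f"ec50_{d}"], values[f"hill_{d}"]
                )

            core = _ml_core(resid, params, sigma=residual.sigma, n_starts=n_starts, rng=rng)
            se, rse = _standard_errors(core, residual.sigma)
            estimates.update(core.values)
            se_all.update(se or {})
            rse_all.update(rse or {})
            fixed_flags.update({p.name: p.fixed for p in params})
            params_all += params
            converged &= core.success
        growth = None
    else:
        ca, cb, times, obs_mat = _timecourse_grid(mono)
        od0 = float(np.nanmean(obs_mat[:, 0])) if obs_mat.size else 0.01
        ctrl = obs_mat[(ca == 0) & (cb == 0)]
        bmax0 = float(max(np.max(obs_mat), 0.05))
        params = [
            Param("k_lag", 1.0, "log"),
            Param("k_growth", 0.5, "log"),
            Param("b_max", bmax0, "log"),
            Param("s1_0", max(od0, 1e-4), "log"),
        ]
        # crude per-well inhibition proxy for potency starts
        end_ctrl = float(np.mean(ctrl[:, -1])) if ctrl.size else bmax0
        for i, d in enumerate(ids):
            cvec = (ca, cb)[i]
            own = cvec > 0
            proxy = 1.0 - obs_mat[own, -1] / max(end_ctrl, 1e-9)
            emax0 = emax_fix if emax_fix is not None else float(np.clip(proxy.max(), 0.2, 2.0))
            params += [
                Param(f"emax_{d}", emax0, "log", fixed=emax_fix is not None),
                Param(f"ec50_{d}", _ec50_start(cvec[own], np.clip(proxy, 0, None), emax0), "log"),
                Param(f"hill_{d}", 1.0, "log"),
            ]

        def resid(values):
            e_wells = np.zeros_like(ca)
            for i, d in enumerate(ids):
                cvec = (ca, cb)[i]
                e_wells = e_wells + np.where(
                    cvec > 0,
                    hill_effect(cvec, values[f"emax_{d}"], values[f"ec50_{d}"],
                                values[f"hill_{d}"]),
                    0.0,
                )
            gp = GrowthParams(
                k_lag=values["k_lag"], k_growth=values["k_growth"],
                b_max=values["b_max"], s1_0=values["s1_0"],
            )
            pred = simulate_wells(gp, np.clip(e_wells, 0.0, 1.0), times, method="rk4")
            return (obs_mat - pred).ravel()

        core = _ml_core(resid, params, sigma=residual.sigma, n_starts=n_starts, rng=rng)
        se_all, rse_all = _standard_errors(core, residual.sigma)
        se_all = se_all or {}
        rse_all = rse_all or {}
        estimates = core.values
        fixed_flags = {p.name: p.fixed for p in params}
        converged = core.success
        growth = GrowthParams(
            k_lag=estimates["k_lag"], k_growth=estimates["k_growth"],
            b_max=estimates["b_max"], s1_0=estimates["s1_0"],
        )

    # pooled objective over the union of monotherapy rows
    resid_all = _make_residual(mono, dataset.mode, ids, "bliss", None)
    core_all = _ml_core(resid_all, [Param(k, v, "identity", fixed=True)
                                    for k, v in estimates.items()],
                        sigma=residual.sigma, n_starts=1, rng=rng)
    n_free = sum(not f for f in fixed_flags.values())
    n_params = n_free + (1 if residual.sigma is None else 0)
    sigma_hat = residual.sigma if residual.sigma is not None else float(
        np.sqrt(core_all.rss / core_all.n)
    )
    model = _build_model(estimates, ids, "bliss", None)
    return FitResult(
        estimates=estimates,
        fixed=fixed_flags,
        ofv=core_all.ofv,
        aic=core_all.ofv + 2 * n_params,
        n_obs=core_all.n,
        n_params=n_params,
        converged=converged,
        se=se_all,
        rse_pct=rse_all,
        history=[{"step": 1, "note": "single-drug characterisation"}],
        model=model,
        growth=growth,
        sigma=sigma_hat,
    )


# ---------------------------------------------------------------------------
# steps 2-4: stepwise interaction build and joint re-estimation
# ---------------------------------------------------------------------------


def fit_gpdi_stepwise(
    dataset: CheckerboardDataset,
    criterion: str = "bliss",
    config: StepwiseConfig | None = None,
    residual: ResidualModel | None = None,
    single: FitResult | None = None,
    fix_emax="auto",
    n_starts: int = 5,
    random_state=None,
) -> FitResult:
    """Four-step stepwise build of the directional interaction model.

    Returns the joint re-estimated fit; ``history`` records every candidate
    expansion with its objective drop and acceptance decision, and
    ``significant`` flags which interaction parameters passed the likelihood
    ratio test.
    """
    config = config or StepwiseConfig()
    residual = residual or ResidualModel()
    rng = np.random.default_rng(random_state)
    ids = dataset.drugs
    a, b = ids
    if single is None:
        single = fit_single_drugs(
            dataset, residual=residual, fix_emax=fix_emax, n_starts=n_starts,
            random_state=rng.integers(2**31 - 1),
        )
    emax_fix = _resolve_fix_emax(fix_emax, dataset.mode)

    combo = dataset.combination()
    if combo.empty:
        raise IdentifiabilityError("no combination wells available for step 2")

    fixed_single = [Param(k, v, "identity", fixed=True) for k, v in single.estimates.items()]
    history = list(single.history)

    def fit_structure(structure, start_values):
        params = fixed_single + _interaction_params(start_values, ids, structure, config)
        resid = _make_residual(combo, dataset.mode, ids, criterion, structure)
        return _ml_core(resid, params, sigma=residual.sigma, n_starts=n_starts, rng=rng)

    # objective of the no-interaction surface on the combination wells
    null_resid = _make_residual(combo, dataset.mode, ids, criterion,
                                _Structure(), None)
    null_core = _ml_core(
        lambda v: null_resid({**v, "int": 0.0}),
        fixed_single, sigma=residual.sigma, n_starts=1, rng=rng,
    )

    if config.start_reduced:
        structure = _Structure()
    else:
        structure = _Structure(
            split_int=True,
            free_ec50int=frozenset({_pair_key(a, b), _pair_key(b, a)}),
        )
    current = fit_structure(structure, single.estimates)
    significant: dict[str, bool] = {}
    red_dofv = null_core.ofv - current.ofv
    reduced_ok = red_dofv >= config.lrt_threshold - 1e-9
    history.append(
        {"step": 2, "candidate": "reduced_int_vs_null", "dofv": red_dofv,
         "accepted": bool(reduced_ok), "ofv": current.ofv}
    )

    for _ in range(config.max_rounds):
        candidates = []
        if not structure.split_int:
            candidates.append(("split_int", replace(structure, split_int=True)))
        for key in (_pair_key(a, b), _pair_key(b, a)):
            if key not in structure.free_ec50int:
                candidates.append(
                    (f"ec50int_{key}",
                     replace(structure,
                             free_ec50int=structure.free_ec50int | {key}))
                )
            if config.estimate_h_int and key not in structure.free_h_int:
                candidates.append(
                    (f"hint_{key}",
                     replace(structure, free_h_int=structure.free_h_int | {key}))
                )
        if not candidates:
            break
        trials = []
        for name, new_structure in candidates:
            core = fit_structure(new_structure, current.values)
            dofv = current.ofv - core.ofv
            trials.append((name, new_structure, core, dofv))
            history.append(
                {"step": 2, "candidate": name, "dofv": dofv,
                 "accepted": False, "ofv": core.ofv}
            )
        # ties: directional split first, then lexicographic
        trials.sort(key=lambda t: (-t[3], 0 if t[0] == "split_int" else 1, t[0]))
        name, new_structure, core, dofv = trials[0]
        if dofv >= config.lrt_threshold - 1e-9:
            structure, current = new_structure, core
            for rec in history[-len(trials):]:
                if rec["candidate"] == name:
                    rec["accepted"] = True
            significant[name] = True
        else:
            break

    # significance bookkeeping for the directional INT parameters
    if structure.split_int:
        significant[f"int_{_pair_key(a, b)}"] = True
        significant[f"int_{_pair_key(b, a)}"] = True
    else:
        significant["int"] = bool(reduced_ok)

    # step 4: joint re-estimation of every retained parameter
    single_params = [
        Param(name, value, "log", fixed=bool(single.fixed.get(name, False)))
        for name, value in single.estimates.items()
    ]
    params4 = single_params + _interaction_params(current.values, ids, structure, config)
    resid4 = _make_residual(dataset.df, dataset.mode, ids, criterion, structure)
    core4 = _ml_core(resid4, params4, sigma=residual.sigma, n_starts=n_starts, rng=rng)
    se, rse = _standard_errors(core4, residual.sigma)
    n_free = sum(not p.fixed for p in params4)
    n_params = n_free + (1 if residual.sigma is None else 0)
    sigma_hat = residual.sigma if residual.sigma is not None else float(
        np.sqrt(core4.rss / core4.n)
    )
    model = _build_model(core4.values, ids, criterion, structure)
    growth = None
    if dataset.mode == "timecourse":
        growth = GrowthParams(
            k_lag=core4.values["k_lag"], k_growth=core4.values["k_growth"],
            b_max=core4.values["b_max"], s1_0=core4.values["s1_0"],
        )
    history.append({"step": 4, "note": "joint re-estimation", "ofv": core4.ofv})
    return FitResult(
        estimates=core4.values,
        fixed={p.name: p.fixed for p in params4},
        ofv=core4.ofv,
        aic=core4.ofv + 2 * n_params,
        n_obs=core4.n,
        n_params=n_params,
        converged=core4.success,
        se=se,
        rse_pct=rse,
        history=history,
        model=model,
        growth=growth,
        sigma=sigma_hat,
        significant=significant,
        extra={"structure": structure, "criterion": criterion},
    )


# ---------------------------------------------------------------------------
# step 3: modulation terms on trio data
# ---------------------------------------------------------------------------


def test_modulator(
    df3: pd.DataFrame,
    model: InteractionModel,
    modulated_pair: tuple,
    modulator_id: str,
    config: StepwiseConfig | None = None,
    residual: ResidualModel | None = None,
    n_starts: int = 5,
    random_state=None,
) -> FitResult:
    """Test one modulation term on three-drug endpoint data.

    ``df3`` holds columns ``conc_<drug_id>`` for every drug of ``model`` plus
    ``effect``; all lower-order parameters stay fixed and only the modulation
    fraction is estimated (its potency is pinned to the modulator's EC50).
    The likelihood ratio against the unmodulated model decides inclusion.
    """
    config = config or StepwiseConfig()
    residual = residual or ResidualModel()
    rng = np.random.default_rng(random_state)
    conc = {d: df3[f"conc_{d}"].to_numpy() for d in model.drug_ids}
    obs = df3["effect"].to_numpy()
    mod_ec50 = model.drug_map[modulator_id].ec50

    def resid(values):
        mod = GPDITerm(
            perpetrator_id=modulator_id, victim_id=modulated_pair[1],
            int_value=values["int_mod"], ec50_int=mod_ec50,
            target_param="INT", modulated_pair=tuple(modulated_pair),
        )
        extended = InteractionModel(
            drugs=model.drugs, terms=model.terms + (mod,), criterion=model.criterion
        )
        return obs - effect_surface(extended, conc)

    base = _ml_core(lambda v: obs - effect_surface(model, conc), [],
                    sigma=residual.sigma, n_starts=1, rng=rng)
    core = _ml_core(resid, [Param("int_mod", 0.0, "shifted_log")],
                    sigma=residual.sigma, n_starts=n_starts, rng=rng)
    dofv = base.ofv - core.ofv
    accepted = dofv >= config.lrt_threshold - 1e-9
    se, rse = _standard_errors(core, residual.sigma)
    n_params = 1 + (1 if residual.sigma is None else 0)
    return FitResult(
        estimates=core.values,
        fixed={"int_mod": False},
        ofv=core.ofv,
        aic=core.ofv + 2 * n_params,
        n_obs=core.n,
        n_params=n_params,
        converged=core.success,
        se=se,
        rse_pct=rse,
        history=[{"step": 3, "candidate": f"int_{modulated_pair}|{modulator_id}",
                  "dofv": dofv, "accepted": bool(accepted), "ofv": core.ofv}],
        significant={"int_mod": bool(accepted)},
        extra={"dofv": dofv},
    )


# ---------------------------------------------------------------------------
# conventional comparator fits
# ---------------------------------------------------------------------------


def _conventional_fit(dataset, kind, residual, single, fix_emax, n_starts, random_state):
    residual = residual or ResidualModel()
    rng = np.random.default_rng(random_state)
    ids = dataset.drugs
    if single is None:
        single = fit_single_drugs(
            dataset, residual=residual, fix_emax=fix_emax, n_starts=n_starts,
            random_state=rng.integers(2**31 - 1),
        )

    def predictor(values, ca, cb):
        pd_a = SingleDrugPD(ids[0], emax=values[f"emax_{ids[0]}"],
                            ec50=values[f"ec50_{ids[0]}"], hill=values[f"hill_{ids[0]}"])
        pd_b = SingleDrugPD(ids[1], emax=values[f"emax_{ids[1]}"],
                            ec50=values[f"ec50_{ids[1]}"], hill=values[f"hill_{ids[1]}"])
        if kind == "greco":
            return greco_surface(pd_a, pd_b, values["alpha"], ca, cb)
        e_a = hill_effect(ca, pd_a.emax, pd_a.ec50, pd_a.hill)
        e_b = hill_effect(cb, pd_b.emax, pd_b.ec50, pd_b.hill)
        return e_a + e_b - values["beta"] * e_a * e_b

    index_param = Param("alpha", 0.0, "identity") if kind == "greco" else Param(
        "beta", 1.0, "identity"
    )
    fixed_single = [Param(k, v, "identity", fixed=True) for k, v in single.estimates.items()]
    combo = dataset.combination()
    resid2 = _make_residual(combo, dataset.mode, ids, "bliss", None, predictor=predictor)
    core2 = _ml_core(resid2, fixed_single + [index_param], sigma=residual.sigma,
                     n_starts=n_starts, rng=rng)

    # joint re-estimation for comparability with the stepwise final models
    params4 = [
        Param(name, value, "log", fixed=bool(single.fixed.get(name, False)))
        for name, value in single.estimates.items()
    ] + [replace(index_param, value=core2.values[index_param.name])]
    resid4 = _make_residual(dataset.df, dataset.mode, ids, "bliss", None,
                            predictor=predictor)
    core4 = _ml_core(resid4, params4, sigma=residual.sigma, n_starts=n_starts, rng=rng)
    se, rse = _standard_errors(core4, residual.sigma)
    n_free = sum(not p.fixed for p in params4)
    n_params = n_free + (1 if residual.sigma is None else 0)
    sigma_hat = residual.sigma if residual.sigma is not None else float(
        np.sqrt(core4.rss / core4.n)
    )
    return FitResult(
        estimates=core4.values,
        fixed={p.name: p.fixed for p in params4},
        ofv=core4.ofv,
        aic=core4.ofv + 2 * n_params,
        n_obs=core4.n,
        n_params=n_params,
        converged=core4.success,
        se=se,
        rse_pct=rse,
        history=[{"step": "conventional", "model": kind}],
        model=_build_model(core4.values, ids, "bliss", None),
        sigma=sigma_hat,
        extra={index_param.name: core4.values[index_param.name], "kind": kind},
    )


def fit_greco(dataset, residual=None, single=None, fix_emax="auto", n_starts=5,
              random_state=None) -> FitResult:
    """Fit the Greco response-surface model (single interaction index alpha)."""
    return _conventional_fit(dataset, "greco", residual, single, fix_emax,
                             n_starts, random_state)


def fit_empiric_bliss(dataset, residual=None, single=None, fix_emax="auto",
                      n_starts=5, random_state=None) -> FitResult:
    """Fit the empiric Bliss model (single interaction index beta)."""
    return _conventional_fit(dataset, "empiric_bliss", residual, single, fix_emax,
                             n_starts, random_state)


def compare_models(fits, labels=None) -> pd.DataFrame:
    """Rank fits of the same data by AIC (ascending; ties keep input order)."""
    fits = list(fits)
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits observe different data (n_obs = {sorted(n_obs)})")
    labels = labels or [f"model_{i}" for i in range(len(fits))]
    frame = pd.DataFrame(
        {
            "label": labels,
            "ofv": [f.ofv for f in fits],
            "aic": [f.aic for f in fits],
            "n_params": [f.n_params for f in fits],
        }
    )
    frame = frame.sort_values("aic", kind="stable").reset_index(drop=True)
    frame["delta_aic"] = frame["aic"] - frame["aic"].iloc[0]
    return frame
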