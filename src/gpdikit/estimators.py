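"""scikit-learn style estimators over the checkerboard fitting machinery.

``X`` is an ``(n_wells, 2)`` array of the two drugs' concentrations and
``y`` the observed endpoint effect per well; the estimators compose with
sklearn pipelines and model selection (``get_params``/``set_params``,
``clone``, ``score`` = R^2).  Each ``fit`` runs the package's maximum-
likelihood pipeline (monotherapy characterisation first, then the
interaction structure) and exposes fitted attributes with trailing
underscores; ``predict`` evaluates the fitted combined-effect surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .conventional import greco_surface
from .criteria import effect_surface
from .datasets import CheckerboardDataset
from .drug_effect import hill_effect
from .estimation import (
    ResidualModel,
    StepwiseConfig,
    fit_empiric_bliss,
    fit_gpdi_stepwise,
    fit_greco,
)

__all__ = ["EmpiricBlissRegressor", "GPDIRegressor", "GrecoRegressor"]


class _CheckerboardRegressor(RegressorMixin, BaseEstimator):
    """Shared input handling: wells -> CheckerboardDataset."""

    def _validate(self, X, y):
        X, y = check_X_y(X, y, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly 2 columns (conc_a, conc_b)")
        if np.any(X < 0) or np.any(y < 0):
            raise ValueError("concentrations and effects must be non-negative")
        return X, y

    def _dataset(self, X, y) -> CheckerboardDataset:
        names = getattr(self, "drug_names", ("A", "B"))
        df = pd.DataFrame(
            {
                "well_id": [f"w{i:03d}" for i in range(len(y))],
                "conc_a": X[:, 0],
                "conc_b": X[:, 1],
                "effect": y,
            }
        )
        return CheckerboardDataset(drugs=tuple(names), df=df, mode="endpoint",
                                   sigma=self.sigma)


class GPDIRegressor(_CheckerboardRegressor):
    """Directional parameter-shift interaction model fitted stepwise.

    Parameters
    ----------
    criterion : {"bliss", "loewe"}
        Additivity criterion the interaction terms are embedded in.
    stepwise : bool
        Start from the reduced one-parameter interaction model and expand by
        likelihood ratio testing; ``False`` fits the full directional model
        straight away.
    lrt_threshold : float
        Objective-function drop required to keep an added parameter
        (3.84 = chi-square, 1 df, alpha = 0.05).
    estimate_h_int : bool
        Also consider free interaction sigmoidicities (off by default).
    sigma : float or None
        Fixed residual SD; ``None`` estimates it.
    fix_emax : float, None or "auto"
        Pin each drug's Emax (e.g. 1.0 on the growth-inhibition scale);
        ``"auto"`` estimates it for endpoint data.
    """

    def __init__(self, criterion="bliss", stepwise=True, lrt_threshold=3.84,
                 estimate_h_int=False, sigma=None, fix_emax="auto", n_starts=5,
                 random_state=None, drug_names=("A", "B")):
        self.criterion = criterion
        self.stepwise = stepwise
        self.lrt_threshold = lrt_threshold
        self.estimate_h_int = estimate_h_int
        self.sigma = sigma
        self.fix_emax = fix_emax
        self.n_starts = n_starts
        self.random_state = random_state
        self.drug_names = drug_names

    def fit(self, X, y):
        X, y = self._validate(X, y)
        dataset = self._dataset(X, y)
        config = StepwiseConfig(
            lrt_threshold=self.lrt_threshold,
            start_reduced=self.stepwise,
            estimate_h_int=self.estimate_h_int,
        )
        result = fit_gpdi_stepwise(
            dataset,
            criterion=self.criterion,
            config=config,
            residual=ResidualModel(sigma=self.sigma),
            fix_emax=self.fix_emax,
            n_starts=self.n_starts,
            random_state=self.random_state,
        )
        self.result_ = result
        self.model_ = result.model
        self.estimates_ = result.estimates
        self.ofv_ = result.ofv
        self.aic_ = result.aic
        self.history_ = result.history
        self.se_ = result.se
        self.sigma_ = result.sigma
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        ids = self.model_.drug_ids
        return np.asarray(
            effect_surface(self.model_, {ids[0]: X[:, 0], ids[1]: X[:, 1]})
        )


class GrecoRegressor(_CheckerboardRegressor):
    """Greco response-surface comparator (single interaction index alpha)."""

    def __init__(self, sigma=None, fix_emax="auto", n_starts=5, random_state=None,
                 drug_names=("A", "B")):
        self.sigma = sigma
        self.fix_emax = fix_emax
        self.n_starts = n_starts
        self.random_state = random_state
        self.drug_names = drug_names

    def fit(self, X, y):
        X, y = self._validate(X, y)
        dataset = self._dataset(X, y)
        result = fit_greco(
            dataset, residual=ResidualModel(sigma=self.sigma),
            fix_emax=self.fix_emax, n_starts=self.n_starts,
            random_state=self.random_state,
        )
        self.result_ = result
        self.model_ = result.model
        self.alpha_ = result.extra["alpha"]
        self.ofv_ = result.ofv
        self.aic_ = result.aic
        self.se_ = result.se
        self.sigma_ = result.sigma
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        pd_a, pd_b = self.model_.drugs[:2]
        return np.asarray(greco_surface(pd_a, pd_b, self.alpha_, X[:, 0], X[:, 1]))


class EmpiricBlissRegressor(_CheckerboardRegressor):
    """Empiric Bliss comparator ``E = E_A + E_B - beta*E_A*E_B``."""

    def __init__(self, sigma=None, fix_emax="auto", n_starts=5, random_state=None,
                 drug_names=("A", "B")):
        self.sigma = sigma
        self.fix_emax = fix_emax
        self.n_starts = n_starts
        self.random_state = random_state
        self.drug_names = drug_names

    def fit(self, X, y):
        X, y = self._validate(X, y)
        dataset = self._dataset(X, y)
        result = fit_empiric_bliss(
            dataset, residual=ResidualModel(sigma=self.sigma),
            fix_emax=self.fix_emax, n_starts=self.n_starts,
            random_state=self.random_state,
        )
        self.result_ = result
        self.model_ = result.model
        self.beta_ = result.extra["beta"]
        self.ofv_ = result.ofv
        self.aic_ = result.aic
        self.se_ = result.se
        self.sigma_ = result.sigma
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        pd_a, pd_b = self.model_.drugs[:2]
        e_a = hill_effect(X[:, 0], pd_a.emax, pd_a.ec50, pd_a.hill)
        e_b = hill_effect(X[:, 1], pd_b.emax, pd_b.ec50, pd_b.hill)
        return np.clip(e_a + e_b - self.beta_ * e_a * e_b, 0.0, 1.0)
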