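import numpy as np
import pandas as pd
import pytest

import gpdikit as g
from gpdikit.criteria import effect_surface
from gpdikit.conventional import greco_surface
from gpdikit.drug_effect import hill_effect
from gpdikit.estimation import (
    IdentifiabilityError,
    ResidualModel,
    StepwiseConfig,
    compare_models,
    fit_empiric_bliss,
    fit_gpdi_stepwise,
    fit_greco,
    fit_single_drugs,
)
from gpdikit.estimation import test_modulator as modulator_lrt
from gpdikit.simulate import generate_checkerboard

DRUG_A = g.SingleDrugPD("A", emax=0.9, ec50=1.0, hill=2.0)
DRUG_B = g.SingleDrugPD("B", emax=0.8, ec50=2.0, hill=1.5)
ASYM = g.InteractionModel(
    drugs=(DRUG_A, DRUG_B),
    terms=(
        g.GPDITerm("B", "A", int_value=3.0, ec50_int=1.5),
        g.GPDITerm("A", "B", int_value=0.0, ec50_int=1.0),
    ),
    criterion="bliss",
)


@pytest.fixture(scope="module")
def clean_asym():
    return generate_checkerboard(ASYM, sigma=0.0, seed=1)


@pytest.fixture(scope="module")
def clean_asym_fit(clean_asym):
    return fit_gpdi_stepwise(clean_asym, criterion="bliss", random_state=0)


@pytest.fixture(scope="module")
def noisy_asym():
    return generate_checkerboard(ASYM, sigma=0.03, seed=7)


class TestSingleDrugFit:
    def test_zero_noise_recovery(self, clean_asym):
        fit = fit_single_drugs(clean_asym, random_state=0)
        assert fit.estimates["ec50_A"] == pytest.approx(1.0, rel=1e-4)
        assert fit.estimates["ec50_B"] == pytest.approx(2.0, rel=1e-4)
        assert fit.estimates["emax_A"] == pytest.approx(0.9, rel=1e-3)
        assert fit.estimates["hill_B"] == pytest.approx(1.5, rel=1e-3)
        assert fit.converged

    def test_combination_only_data_is_unidentifiable(self, clean_asym):
        combo = clean_asym.combination().copy()
        ds = g.CheckerboardDataset(drugs=clean_asym.drugs, df=combo, mode="endpoint")
        with pytest.raises(IdentifiabilityError):
            fit_single_drugs(ds, random_state=0)

    def test_too_few_tiers_is_unidentifiable(self):
        design = g.CheckerboardDesign(tiers_a=(0.0, 1.0, 2.0), tiers_b=(0.0, 1.0, 2.0))
        ds = generate_checkerboard(
            g.InteractionModel(drugs=(DRUG_A, DRUG_B)), design, sigma=0.0, seed=0
        )
        with pytest.raises(IdentifiabilityError):
            fit_single_drugs(ds, random_state=0)

    def test_ec50_coverage_against_anticipated_se(self):
        """Monotherapy EC50 estimates stay within 3 anticipated SEs of truth
        in at least 95% of noisy replicates."""
        from gpdikit.identifiability import expected_fim

        truth = g.InteractionModel(drugs=(DRUG_A, DRUG_B))
        tiers = np.asarray(g.CheckerboardDesign.log2().tiers_a)

        def predict(theta):
            return hill_effect(tiers, theta["emax"], theta["ec50"], theta["hill"])

        fim = expected_fim(
            predict, {"emax": 0.9, "ec50": 1.0, "hill": 2.0}, sigma=0.03
        )
        se = fim.rse_pct["ec50"] / 100.0 * 1.0
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            ds = generate_checkerboard(truth, sigma=0.03, seed=1000 + i)
            fit = fit_single_drugs(ds, random_state=i, n_starts=2)
            hits += abs(fit.estimates["ec50_A"] - 1.0) <= 3 * se
        assert hits / n_rep >= 0.95


class TestStepwise:
    def test_zero_noise_recovery_of_asymmetric_truth(self, clean_asym_fit):
        est = clean_asym_fit.estimates
        assert est["int_A.B"] == pytest.approx(3.0, rel=1e-3)
        assert abs(est["int_B.A"]) < 1e-3
        assert est["ec50int_A.B"] == pytest.approx(1.5, rel=1e-3)

    def test_history_records_every_candidate_with_dofv(self, clean_asym_fit):
        step2 = [h for h in clean_asym_fit.history if h.get("step") == 2]
        names = {h["candidate"] for h in step2}
        assert "reduced_int_vs_null" in names
        assert "split_int" in names
        accepted = [h for h in step2 if h["accepted"] and h["candidate"] != "reduced_int_vs_null"]
        assert all(h["dofv"] >= 3.84 - 1e-9 for h in accepted)
        rejected = [h for h in step2 if not h["accepted"]]
        assert rejected  # at least one expansion was tested and turned down

    def test_directional_significance_covers_zero(self, noisy_asym):
        fit = fit_gpdi_stepwise(noisy_asym, criterion="bliss", random_state=0)
        est, se = fit.estimates, fit.se
        assert est["int_A.B"] == pytest.approx(3.0, rel=0.35)
        assert abs(est["int_B.A"]) <= 2 * se["int_B.A"] + 0.05

    def test_nesting_reduced_vs_full(self, clean_asym):
        reduced = fit_gpdi_stepwise(
            clean_asym, criterion="bliss", random_state=0,
            config=StepwiseConfig(max_rounds=0),
        )
        full = fit_gpdi_stepwise(
            clean_asym, criterion="bliss", random_state=0,
            config=StepwiseConfig(start_reduced=False),
        )
        assert full.ofv <= reduced.ofv + 1e-3

    def test_loewe_sham_fit_recovers_null_interaction(self):
        drug = g.SingleDrugPD("X", emax=1.0, ec50=1.0, hill=2.0)
        ds = g.generate_sham(drug, sigma=0.0, seed=3)
        fit = fit_gpdi_stepwise(ds, criterion="loewe", random_state=0, n_starts=3)
        int_names = [k for k in fit.estimates if k.startswith("int")]
        assert all(abs(fit.estimates[k]) < 1e-4 for k in int_names)
        accepted = [h for h in fit.history
                    if h.get("accepted") and h.get("candidate") != "reduced_int_vs_null"]
        assert not accepted

    def test_likelihood_value_is_gaussian_minus_two_loglik(self, clean_asym):
        """The reported OFV equals -2*sum(log N(obs | pred, sigma^2)) computed
        independently from the fitted model."""
        sigma = 0.03
        ds = generate_checkerboard(ASYM, sigma=sigma, seed=11)
        fit = fit_gpdi_stepwise(
            ds, criterion="bliss", residual=ResidualModel(sigma=sigma), random_state=0
        )
        pred = effect_surface(
            fit.model,
            {"A": ds.df["conc_a"].to_numpy(), "B": ds.df["conc_b"].to_numpy()},
            clip=True,
        )
        obs = ds.df["effect"].to_numpy()
        loglik = -0.5 * np.sum(
            np.log(2 * np.pi * sigma**2) + (obs - pred) ** 2 / sigma**2
        )
        assert fit.ofv == pytest.approx(-2 * loglik, abs=1e-8)

    def test_estimated_sigma_consistent(self):
        """Profiled residual SD recovers the generating sigma within 10% on a
        64-well x 20-time-point time-course (inoculum well above the blank so
        zero-truncation of the noise is negligible)."""
        gp = g.GrowthParams(k_lag=0.8, k_growth=0.6, b_max=1.2, s1_0=0.1)
        truth = g.InteractionModel(drugs=(
            g.SingleDrugPD("A", emax=1.0, ec50=1.0, hill=2.0),
            g.SingleDrugPD("B", emax=1.0, ec50=2.0, hill=1.5),
        ))
        ds = generate_checkerboard(
            truth, sigma=0.03, seed=21, mode="timecourse", growth=gp,
            times=np.linspace(0, 24, 20),
        )
        fit = fit_gpdi_stepwise(ds, criterion="bliss", random_state=0, n_starts=2)
        assert fit.sigma == pytest.approx(0.03, rel=0.10)

    def test_timecourse_zero_noise_recovery(self):
        gp = g.GrowthParams(k_lag=0.8, k_growth=0.6, b_max=1.2, s1_0=0.02)
        truth = g.InteractionModel(
            drugs=(
                g.SingleDrugPD("A", emax=1.0, ec50=1.0, hill=2.0),
                g.SingleDrugPD("B", emax=1.0, ec50=2.0, hill=1.5),
            ),
            terms=(
                g.GPDITerm("B", "A", int_value=2.0, ec50_int=2.0),
                g.GPDITerm("A", "B", int_value=2.0, ec50_int=1.0),
            ),
            criterion="bliss",
        )
        ds = generate_checkerboard(
            truth, g.CheckerboardDesign.log2(n_tiers=5), sigma=0.0, seed=1,
            mode="timecourse", growth=gp, times=np.linspace(0, 24, 10),
        )
        fit = fit_gpdi_stepwise(ds, criterion="bliss", random_state=0, n_starts=3)
        assert fit.estimates["k_growth"] == pytest.approx(0.6, rel=1e-3)
        assert fit.estimates["b_max"] == pytest.approx(1.2, rel=1e-3)
        assert fit.estimates["int_A.B"] == pytest.approx(2.0, rel=1e-3)
        assert fit.estimates["ec50_A"] == pytest.approx(1.0, rel=1e-3)


class TestConventionalFits:
    def test_greco_zero_noise_alpha_recovery(self):
        pd_a = g.SingleDrugPD("A", emax=0.9, ec50=1.0, hill=2.0)
        pd_b = g.SingleDrugPD("B", emax=0.8, ec50=2.0, hill=1.5)
        design = g.CheckerboardDesign.log2()
        ca, cb = design.grid()
        clean = greco_surface(pd_a, pd_b, 1.5, ca, cb)
        df = pd.DataFrame(
            {"well_id": [f"w{i}" for i in range(len(ca))],
             "conc_a": ca, "conc_b": cb, "effect": clean}
        )
        ds = g.CheckerboardDataset(drugs=("A", "B"), df=df, mode="endpoint")
        fit = fit_greco(ds, random_state=0)
        assert fit.extra["alpha"] == pytest.approx(1.5, rel=1e-3)
        assert fit.estimates["ec50_A"] == pytest.approx(1.0, rel=1e-3)

    def test_empiric_bliss_zero_noise_beta_recovery(self):
        pd_a = g.SingleDrugPD("A", emax=0.9, ec50=1.0, hill=2.0)
        pd_b = g.SingleDrugPD("B", emax=0.8, ec50=2.0, hill=1.5)
        design = g.CheckerboardDesign.log2()
        ca, cb = design.grid()
        e_a = hill_effect(ca, 0.9, 1.0, 2.0)
        e_b = hill_effect(cb, 0.8, 2.0, 1.5)
        clean = np.clip(e_a + e_b - 1.8 * e_a * e_b, 0, 1)
        df = pd.DataFrame(
            {"well_id": [f"w{i}" for i in range(len(ca))],
             "conc_a": ca, "conc_b": cb, "effect": clean}
        )
        ds = g.CheckerboardDataset(drugs=("A", "B"), df=df, mode="endpoint")
        fit = fit_empiric_bliss(ds, random_state=0)
        assert fit.extra["beta"] == pytest.approx(1.8, rel=1e-3)


class TestModelComparison:
    def test_aic_prefers_fewer_parameters_at_equal_fit(self, clean_asym_fit):
        lean = g.FitResult(estimates={}, fixed={}, ofv=-100.0, aic=-94.0, n_obs=64,
                           n_params=3, converged=True)
        rich = g.FitResult(estimates={}, fixed={}, ofv=-100.0, aic=-92.0, n_obs=64,
                           n_params=4, converged=True)
        table = compare_models([rich, lean], labels=["rich", "lean"])
        assert table["label"].iloc[0] == "lean"
        assert table["delta_aic"].iloc[1] == pytest.approx(2.0)

    def test_ties_keep_input_order(self):
        f = g.FitResult(estimates={}, fixed={}, ofv=-10.0, aic=-4.0, n_obs=10,
                        n_params=3, converged=True)
        table = compare_models([f, f], labels=["first", "second"])
        assert list(table["label"]) == ["first", "second"]

    def test_mismatched_data_rejected(self):
        f1 = g.FitResult(estimates={}, fixed={}, ofv=0, aic=0, n_obs=10,
                         n_params=1, converged=True)
        f2 = g.FitResult(estimates={}, fixed={}, ofv=0, aic=0, n_obs=20,
                         n_params=1, converged=True)
        with pytest.raises(ValueError):
            compare_models([f1, f2])

    def test_gpdi_beats_greco_on_asymmetric_truth(self, noisy_asym):
        gpdi = fit_gpdi_stepwise(noisy_asym, criterion="bliss", random_state=0)
        greco = fit_greco(noisy_asym, random_state=0)
        table = compare_models([gpdi, greco], labels=["gpdi", "greco"])
        assert table["label"].iloc[0] == "gpdi"


class TestModulator:
    def test_trio_modulator_detected_and_recovered(self):
        a = g.SingleDrugPD("A", emax=1.0, ec50=2.0, hill=1.5)
        b = g.SingleDrugPD("B", emax=1.0, ec50=1.0, hill=1.0)
        c = g.SingleDrugPD("C", emax=1.0, ec50=1.0, hill=1.0)
        pair = g.GPDITerm("B", "A", int_value=1.0, ec50_int=1.0)
        mod = g.GPDITerm("C", "A", int_value=2.0, ec50_int=1.0,
                         target_param="INT", modulated_pair=("B", "A"))
        truth = g.InteractionModel(drugs=(a, b, c), terms=(pair, mod))
        base = g.InteractionModel(drugs=(a, b, c), terms=(pair,))
        tiers = np.array([0.25, 1.0, 4.0])
        ca, cb, cc = (x.ravel() for x in np.meshgrid(tiers, tiers, tiers, indexing="ij"))
        clean = effect_surface(truth, {"A": ca, "B": cb, "C": cc})
        df3 = pd.DataFrame({"conc_A": ca, "conc_B": cb, "conc_C": cc, "effect": clean})
        res = modulator_lrt(df3, base, ("B", "A"), "C", random_state=0)
        assert res.significant["int_mod"]
        assert res.estimates["int_mod"] == pytest.approx(2.0, rel=1e-3)

    def test_absent_modulation_not_claimed(self):
        a = g.SingleDrugPD("A", emax=1.0, ec50=2.0, hill=1.5)
        b = g.SingleDrugPD("B", emax=1.0, ec50=1.0, hill=1.0)
        c = g.SingleDrugPD("C", emax=1.0, ec50=1.0, hill=1.0)
        pair = g.GPDITerm("B", "A", int_value=1.0, ec50_int=1.0)
        base = g.InteractionModel(drugs=(a, b, c), terms=(pair,))
        tiers = np.array([0.25, 1.0, 4.0])
        ca, cb, cc = (x.ravel() for x in np.meshgrid(tiers, tiers, tiers, indexing="ij"))
        clean = effect_surface(base, {"A": ca, "B": cb, "C": cc})
        df3 = pd.DataFrame({"conc_A": ca, "conc_B": cb, "conc_C": cc, "effect": clean})
        res = modulator_lrt(df3, base, ("B", "A"), "C", random_state=0)
        assert not res.significant["int_mod"]
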