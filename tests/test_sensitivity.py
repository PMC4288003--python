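"""Local sensitivity: finite-difference convergence, scale invariance,
and the in vitro ratio analysis over the OATP1B1 fractional contribution."""

import numpy as np
import pytest

from oatp_pbpk import (
    DoseRegimen,
    invitro_ratio_sensitivity,
    local_sensitivity,
    predict_genotype_profiles,
    ratio_scenario_profiles,
)
from oatp_pbpk.genotype import VARIANTS, variant_clearances, split_uptake

WINDOW = (0.0, 8.0)


class TestModelSensitivity:
    def test_forward_truncation_bounded_by_half_step_times_magnitude(
            self, physiology, pravastatin):
        # first-order truncation of the 1% forward scheme: relative error
        # ~ |S| * h / 2 for exponential phases, plus bounded curvature
        compound, _, regimens = pravastatin
        for param in ("CL_act_tot", "fu_p", "RB_P", "ka", "FaFg",
                      "CL_bile"):
            fw = local_sensitivity(compound, physiology,
                                   regimens["oral_genotyped"], param,
                                   "plasma_conc", WINDOW)
            ct = local_sensitivity(compound, physiology,
                                   regimens["oral_genotyped"], param,
                                   "plasma_conc", WINDOW,
                                   perturbation=0.001, scheme="central")
            mask = np.isfinite(fw.coefficients) \
                & (np.abs(fw.coefficients) >= 0.3)
            if not mask.any():
                continue
            err = np.abs(fw.coefficients[mask] - ct.coefficients[mask])
            bound = 0.015 * np.abs(ct.coefficients[mask]) + 0.006
            assert np.all(err <= bound), param

    def test_richardson_convergence_of_forward_steps(self, physiology,
                                                     pravastatin):
        compound, _, regimens = pravastatin
        ct = local_sensitivity(compound, physiology, regimens["oral"],
                               "CL_act_tot", "plasma_conc", WINDOW,
                               perturbation=0.001, scheme="central")
        errs = []
        for h in (0.01, 0.005, 0.0025):
            fw = local_sensitivity(compound, physiology, regimens["oral"],
                                   "CL_act_tot", "plasma_conc", WINDOW,
                                   perturbation=h)
            mask = np.abs(ct.coefficients) > 0.1
            errs.append(np.max(np.abs(
                fw.coefficients[mask] - ct.coefficients[mask])))
        assert errs[0] > errs[1] > errs[2]  # first-order decay in step

    def test_dose_doubling_leaves_coefficients_unchanged(self, physiology,
                                                         pravastatin):
        # linear model: normalization cancels scale
        compound, _, _ = pravastatin
        s1 = local_sensitivity(compound, physiology,
                               DoseRegimen("oral", 40.0), "CL_act_tot",
                               "plasma_conc", WINDOW)
        s2 = local_sensitivity(compound, physiology,
                               DoseRegimen("oral", 80.0), "CL_act_tot",
                               "plasma_conc", WINDOW)
        assert np.allclose(s1.coefficients[1:], s2.coefficients[1:],
                           rtol=1e-8, atol=1e-10)

    def test_kp_of_unperfused_tissue_has_zero_coefficient(self,
                                                          pravastatin):
        from oatp_pbpk.specs import default_human_physiology

        compound, _, regimens = pravastatin
        phys = default_human_physiology()
        flows = dict(phys.tissue_blood_flows)
        flows["lung"] -= flows["rest_of_body"]
        flows["rest_of_body"] = 0.0
        phys0 = phys.replace(tissue_blood_flows=flows)
        res = local_sensitivity(compound, phys0, regimens["oral"],
                                "Kp_rest_of_body", "plasma_conc", WINDOW)
        coeff = res.coefficients[np.isfinite(res.coefficients)]
        assert np.allclose(coeff, 0.0, atol=1e-9)

    def test_auc_output_is_scalar_and_negative_for_uptake(self, physiology,
                                                          pravastatin):
        compound, _, regimens = pravastatin
        res = local_sensitivity(compound, physiology, regimens["oral"],
                                "CL_act_tot", "AUC_plasma", WINDOW)
        assert np.isscalar(res.coefficients)
        assert res.coefficients < 0  # more uptake, lower plasma AUC

    def test_zero_parameter_requests_absolute_mode(self, physiology,
                                                   pravastatin):
        compound, _, regimens = pravastatin
        c0 = compound.replace(CL_renal=0.0)
        with pytest.raises(ValueError, match="absolute-step"):
            local_sensitivity(c0, physiology, regimens["oral"],
                              "CL_renal", "plasma_conc", WINDOW)


class TestInvitroRatioSensitivity:
    def test_zero_oatp_fraction_gives_zero_coefficients(self, pravastatin):
        _, genotype, _ = pravastatin
        df = invitro_ratio_sensitivity(genotype, [0.0], "ratio_15")
        assert np.allclose(df["coefficient"], 0.0, atol=1e-12)

    def test_pure_star1a_population_insensitive_to_ratio_1b(self,
                                                            pravastatin):
        _, genotype, _ = pravastatin
        g = genotype.replace(
            frequencies={"star1a": 1.0, "star1b": 0.0, "star15": 0.0})
        df = invitro_ratio_sensitivity(g, [0.83], "ratio_1b")
        row = df[df.variant == "star1a"].iloc[0]
        assert row.coefficient == pytest.approx(0.0, abs=1e-12)

    def test_pravastatin_pattern_only_star15_sensitive_to_ratio_15(
            self, pravastatin):
        _, genotype, _ = pravastatin
        df = invitro_ratio_sensitivity(genotype, [0.83], "ratio_15")
        by = df.set_index("variant").coefficient
        assert abs(by["star15"]) > 0.1
        assert abs(by["star1a"]) < 0.1
        assert abs(by["star1b"]) < 0.1

    def test_closed_form_oracle_at_f083(self, pravastatin):
        # analytic differentiation of the clearance algebra:
        # d log CL_tot,v / d log r15 at the pravastatin preset
        _, genotype, _ = pravastatin
        f, mean = 0.83, 1.0
        ratios = genotype.effective_ratios()
        freqs = genotype.frequencies
        W = sum(freqs[v] * ratios[v] for v in VARIANTS)
        p15r15 = freqs["star15"] * ratios["star15"]
        df = invitro_ratio_sensitivity(genotype, [f], "ratio_15",
                                       perturbation=1e-6)
        for v in VARIANTS:
            cl_tot_rel = f * ratios[v] / W + (1 - f)
            if v == "star15":
                deriv = f * (ratios[v] / W) * (1 - p15r15 / W)
            else:
                deriv = -f * (ratios[v] / W) * (p15r15 / W)
            expected = deriv / cl_tot_rel
            got = df[df.variant == v].coefficient.iloc[0]
            assert got == pytest.approx(expected, rel=1e-4), v

    def test_magnitudes_increase_with_f(self, pravastatin):
        _, genotype, _ = pravastatin
        f_grid = np.linspace(0.2, 1.0, 9)
        for target in ("ratio_1b", "ratio_15"):
            df = invitro_ratio_sensitivity(genotype, f_grid, target)
            for v in VARIANTS:
                coeffs = df[df.variant == v].sort_values("f_OATP1B1")
                mags = np.abs(coeffs.coefficient.to_numpy())
                assert np.all(np.diff(mags) > -1e-12), (target, v)

    def test_sum_rule_population_mean_held_fixed(self, pravastatin):
        # freq- and clearance-weighted sum of OATP1B1-part sensitivities
        # vanishes because the population mean is fixed by construction
        _, genotype, _ = pravastatin
        f, h = 0.7, 0.01
        cl_oatp, _ = split_uptake(1.0, f)
        base = variant_clearances(cl_oatp, genotype)
        pert = variant_clearances(
            cl_oatp, genotype.replace(
                activity_ratio_15=genotype.activity_ratio_15 * (1 + h)))
        total = sum(
            genotype.frequencies[v]
            * (pert.CL_act_OATP1B1[v] - base.CL_act_OATP1B1[v])
            for v in VARIANTS)
        assert total == pytest.approx(0.0, abs=1e-15)

    def test_empty_grid_rejected(self, pravastatin):
        _, genotype, _ = pravastatin
        with pytest.raises(ValueError, match="empty"):
            invitro_ratio_sensitivity(genotype, [], "ratio_15")


class TestRatioScenarios:
    GRID = np.arange(0.0, 24.01, 0.25)

    def test_lower_ratio_gives_higher_star15_auc(self, physiology,
                                                 pravastatin):
        compound, genotype, regimens = pravastatin
        out = ratio_scenario_profiles(compound, physiology, genotype,
                                      regimens["oral_genotyped"],
                                      [0.20, 0.50], time_grid=self.GRID)
        auc = {r: np.trapezoid(out[r]["star15"].plasma_conc, self.GRID)
               for r in (0.20, 0.50)}
        assert auc[0.20] > auc[0.50]

    def test_singleton_reproduces_direct_prediction(self, physiology,
                                                    pravastatin):
        compound, genotype, regimens = pravastatin
        out = ratio_scenario_profiles(compound, physiology, genotype,
                                      regimens["oral_genotyped"],
                                      [genotype.activity_ratio_15],
                                      time_grid=self.GRID)
        direct = predict_genotype_profiles(compound, physiology, genotype,
                                           regimens["oral_genotyped"],
                                           self.GRID, method="expm")
        scenario = out[genotype.activity_ratio_15]
        for v in VARIANTS:
            assert np.array_equal(scenario[v].plasma_conc,
                                  direct[v].plasma_conc)

    def test_unit_ratio_collapses_star15_onto_star1a(self, physiology,
                                                     pravastatin):
        compound, genotype, regimens = pravastatin
        g = genotype.replace(expression_mult_15=1.0)
        out = ratio_scenario_profiles(compound, physiology, g,
                                      regimens["oral_genotyped"], [1.0],
                                      time_grid=self.GRID)
        assert np.array_equal(out[1.0]["star15"].plasma_conc,
                              out[1.0]["star1a"].plasma_conc)
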