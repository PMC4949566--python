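"""Monte-Carlo harness: estimands, aggregation, reproducibility, known effects."""

import math

import numpy as np
import pandas as pd
import pytest

from partnest.datagen import TrialDesign
from partnest.latent_link import LatentScenario
from partnest.power import PowerRequest, PowerResult, power_prop
from partnest.sim_harness import (
    Scenario,
    compare_power,
    estimand_for,
    mc_ci,
    run_grid,
    run_scenario,
)


class TestEstimands:
    def test_null_scenario_all_zero(self):
        s = LatentScenario.from_manifest(0.3, 0.3, 0.1)
        for m in ("atp", "smt", "satt", "lgee", "lri_wald", "lri_lrt", "lrc_wald"):
            assert estimand_for(m, s) == pytest.approx(0.0, abs=1e-8)

    def test_gee_marginal_logodds(self):
        s = LatentScenario.from_manifest(0.2, 0.4, 0.07)
        assert estimand_for("lgee", s) == pytest.approx(
            math.log(0.25 / (2 / 3)), abs=1e-10
        )

    def test_lri_equals_gee_without_clustering(self):
        s = LatentScenario.from_manifest(0.2, 0.4, 0.0)
        assert estimand_for("lri_wald", s) == pytest.approx(
            estimand_for("lgee", s), abs=1e-10
        )

    def test_lri_exceeds_gee_in_magnitude_with_clustering(self):
        s = LatentScenario.from_manifest(0.2, 0.4, 0.1)
        assert abs(estimand_for("lri_wald", s)) > abs(estimand_for("lgee", s))


class TestMcCi:
    def test_printed_precision_claim(self):
        lo, hi = mc_ci(0.07, 20_000)
        assert (hi - lo) / 2 == pytest.approx(0.003536, abs=1e-5)
        assert (hi - lo) / 2 < 0.005

    def test_power_scale_precision(self):
        lo, hi = mc_ci(0.85, 40_000)
        assert (hi - lo) / 2 == pytest.approx(0.0035, abs=1e-4)

    def test_degenerate_rate(self):
        assert mc_ci(0.0, 100) == (0.0, 0.0)
        assert mc_ci(1.0, 100) == (1.0, 1.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            mc_ci(0.05, 0)
        with pytest.raises(ValueError):
            mc_ci(1.2, 100)


class TestRunScenario:
    def test_bitwise_reproducible(self):
        scen = Scenario(
            pi_g=0.3,
            pi_c=0.3,
            rho=0.05,
            design=TrialDesign.equal(10, 5, 50),
            methods=("atp",),
            n_reps=120,
            seed=42,
        )
        a = run_scenario(scen).to_frame()
        b = run_scenario(scen).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_atp_nominal_size_unclustered_null(self):
        """Large per-arm n, rho = 0: the ATP two-sided size sits at ~5%."""
        scen = Scenario(
            pi_g=0.5,
            pi_c=0.5,
            rho=0.0,
            design=TrialDesign.equal(40, 10, 400),
            methods=("atp",),
            n_reps=2000,
            seed=7,
        )
        s = run_scenario(scen)["atp"]
        assert s.ci_two[0] <= 0.05 <= s.ci_two[1] or abs(s.rate_two - 0.05) < 0.012
        assert s.n_failed == 0
        # unbiased on the proportion scale
        assert s.bias_ci[0] <= 0.0 <= s.bias_ci[1]

    def test_lri_conservative_at_rho_zero(self):
        """Empirical LRI test size sits below nominal when the true ICC is 0
        (the variance component's non-negativity inflates the estimated ICC).
        Reduced-replication spot check of the direction of the effect."""
        scen = Scenario(
            pi_g=0.3,
            pi_c=0.3,
            rho=0.0,
            design=TrialDesign.equal(20, 5, 100),
            methods=("lri_lrt",),
            n_reps=2000,
            seed=11,
        )
        s = run_scenario(scen)["lri_lrt"]
        assert s.rate_two < 0.05
        assert s.ci_two[0] < 0.05  # certainly not anti-conservative

    def test_satt_tail_asymmetry_low_prevalence(self):
        """At pi_G = pi_C = 0.1 with clustering, the lower-tail size of the
        Satterthwaite test exceeds the upper-tail size."""
        scen = Scenario(
            pi_g=0.1,
            pi_c=0.1,
            rho=0.1,
            design=TrialDesign.equal(10, 10, 100),
            methods=("satt",),
            n_reps=3000,
            seed=5,
        )
        s = run_scenario(scen)["satt"]
        assert s.rate_lower > s.rate_upper
        assert s.rate_lower + s.rate_upper == pytest.approx(s.rate_two, abs=1e-12)

    def test_failures_logged_and_excluded(self):
        """Rare event rates with a tiny control arm produce degenerate-arm
        failures for the logistic fit; they are excluded from denominators."""
        scen = Scenario(
            pi_g=0.05,
            pi_c=0.05,
            rho=0.0,
            design=TrialDesign.equal(5, 4, 20),
            methods=("lri_wald",),
            n_reps=150,
            seed=3,
        )
        s = run_scenario(scen)["lri_wald"]
        assert s.n_failed > 0
        assert s.n_used == 150 - s.n_failed
        # sensitivity option keeps failures in the denominator
        scen2 = Scenario(
            **{
                **scen.__dict__,
                "count_failures_as_nonreject": True,
            }
        )
        s2 = run_scenario(scen2)["lri_wald"]
        assert s2.n_used == 150

    def test_lrc_null_rejection_grows_with_n(self):
        """The random-coefficient inconsistency manifests as a rejection rate
        that increases with sample size under a proportion-scale null."""
        rates = []
        for k, n_c in [(10, 100), (40, 400)]:
            scen = Scenario(
                pi_g=0.1,
                pi_c=0.1,
                rho=0.1,
                design=TrialDesign.equal(k, 10, n_c),
                methods=("lrc_wald",),
                n_reps=300,
                seed=19,
            )
            rates.append(run_scenario(scen)["lrc_wald"].rate_two)
        assert rates[1] > rates[0]

    def test_run_grid_stacks_scenarios(self):
        scens = [
            Scenario(
                pi_g=0.3,
                pi_c=0.3,
                rho=r,
                design=TrialDesign.equal(5, 4, 20),
                methods=("smt",),
                n_reps=100,
                seed=1,
            )
            for r in (0.0, 0.1)
        ]
        frame = run_grid(scens)
        assert len(frame) == 2
        assert frame["scenario"].nunique() == 2

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown methods"):
            Scenario(
                pi_g=0.3,
                pi_c=0.4,
                rho=0.0,
                design=TrialDesign.equal(5, 4, 20),
                methods=("bayes",),
                n_reps=100,
            )


class TestComparePower:
    def _report(self):
        scen = Scenario(
            pi_g=0.2,
            pi_c=0.5,
            rho=0.05,
            design=TrialDesign.equal(10, 10, 100),
            methods=("atp",),
            n_reps=200,
            seed=2,
        )
        return run_scenario(scen)

    def test_identical_inputs_zero_table(self):
        report = self._report()
        emp = report["atp"].rate_two
        calc = PowerResult(
            method="prop", power=emp, n_control=100, n_group=100, k=10,
            design_effect=1.45,
        )
        table = compare_power(report, [calc])
        assert table["diff_pp"].abs().max() == 0.0

    def test_real_calculation_columns(self):
        report = self._report()
        calc = power_prop(
            PowerRequest(pi_g=0.2, pi_c=0.5, m=10, rho=0.05, n_control=100)
        )
        table = compare_power(report, [calc])
        assert set(table.columns) >= {"analysis", "calculation", "diff_pp"}
        assert table.loc[0, "diff_pp"] == pytest.approx(
            100 * (report["atp"].rate_two - calc.power)
        )

    def test_mismatched_design_rejected(self):
        report = self._report()
        calc = PowerResult(
            method="prop", power=0.8, n_control=999, n_group=100, k=10,
            design_effect=1.45,
        )
        with pytest.raises(ValueError, match="do not match"):
            compare_power(report, [calc])
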