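"""Staged calibration: self-consistency, identifiability flags, diagnostics.

Recovery at the published parameter set itself is exercised by the acceptance
suite; here each stage is checked for self-consistency at *perturbed*
generating values (the fit must follow the generator, not the defaults) and
for its degenerate-data behaviour.
"""

import numpy as np
import pytest

from conjphage import (
    Experiment,
    KineticParameters,
    integrate,
    marker_abundance,
    run_full_calibration,
    synthesize_dataset,
)
from conjphage.fitting import (
    CompetitionStageModel,
    ConjugationStageModel,
    GrowthStageModel,
    InfectionStageModel,
)
from conjphage.qpcr import MarkerSeries
from conjphage.simulate import preset_condition


def make_experiments(presets, params, system="full", noise_sd=0.0, seed=0,
                     n_replicates=1):
    exps = []
    for i, (label, variant) in enumerate(presets):
        cond = preset_condition(label, variant, params=params)
        traj = integrate(cond, params, system=system)
        series = synthesize_dataset(traj, noise_sd=noise_sd, seed=seed + i,
                                    n_replicates=n_replicates)
        exps.append(Experiment(condition=cond, series=series))
    return exps


class TestGrowthStage:
    def test_recovers_perturbed_growth_rate(self):
        """Doubled generating psi_max must be recovered, not the default."""
        truth = KineticParameters().replace(psi_max=0.07, e=7e-8)
        exps = make_experiments([("COND1", 0)], truth)
        res = GrowthStageModel(exps).fit()
        assert res.converged
        assert res.estimates["psi_max"] == pytest.approx(0.07, rel=0.01)
        assert res.estimates["e"] == pytest.approx(7e-8, rel=0.02)

    def test_flat_data_flags_boundary(self):
        """A constant series carries no growth signal: boundary estimate flagged."""
        cond = preset_condition("COND1", 0)
        flat = MarkerSeries(locus="tolC", times=cond.sampling_times(),
                            abundance=np.full(36, 1e6))
        res = GrowthStageModel([Experiment(cond, [flat])]).fit()
        assert "psi_max" in res.diagnostics["at_bound"]
        assert res.estimates["psi_max"] <= 1.1e-4

    def test_rejects_mixed_culture(self, params):
        exps = make_experiments([("COND1", 1)], params, system="conjugation_only")
        with pytest.raises(ValueError):
            GrowthStageModel(exps)


class TestConjugationStage:
    def test_recovers_halved_transfer_rate(self, params):
        truth = params.replace(gamma_max=1.5e-10)
        exps = make_experiments([("COND1", v) for v in (1, 3)], truth,
                                system="conjugation_only")
        res = ConjugationStageModel(exps, params0=params).fit()
        assert res.estimates["gamma_max"] == pytest.approx(1.5e-10, rel=0.05)

    def test_zero_transfer_hits_lower_bound(self, params):
        truth = params.replace(gamma_max=0.0)
        exps = make_experiments([("COND1", 1), ("COND1", 2)], truth,
                                system="conjugation_only")
        res = ConjugationStageModel(exps, params0=params).fit()
        assert res.estimates["gamma_max"] <= 2e-14  # at the lower bound
        assert res.residual_norm < 1e-4

    def test_single_ratio_warns_identifiability(self, params):
        exps = make_experiments([("COND1", 1)], params, system="conjugation_only")
        model = ConjugationStageModel(exps, params0=params)
        assert any("identifiability" in w for w in model._warnings)

    def test_all_donor_data_flagged_unidentifiable(self, params):
        exps = make_experiments([("COND1", 0)], params, system="conjugation_only")
        model = ConjugationStageModel(exps, params0=params)
        assert any("unidentifiable" in w for w in model._warnings)


class TestInfectionStage:
    def test_recovers_perturbed_infection_parameters(self, params):
        truth = params.replace(beta_max=6e-11, psiP_max=3.0, P_psi=0.3)
        exps = make_experiments(
            [("COND2A", 0), ("COND2A", 2), ("COND2B", 0), ("COND2B", 2)],
            truth, system="infection_only")
        res = InfectionStageModel(exps, params0=params).fit()
        assert res.converged
        assert res.estimates["beta_max"] == pytest.approx(6e-11, rel=0.10)
        assert res.estimates["psiP_max"] == pytest.approx(3.0, rel=0.10)
        assert res.estimates["P_psi"] == pytest.approx(0.3, rel=0.10)

    def test_phage_free_data_flagged(self, params):
        from conjphage import ExperimentCondition, PopulationState
        cond = ExperimentCondition("CUSTOM", PopulationState(r=100.0, n_D=3e6),
                                   duration=500.0, sampling_interval=20.0)
        traj = integrate(cond, params, system="infection_only")
        exp = Experiment(cond, synthesize_dataset(traj, noise_sd=0.0, seed=0))
        model = InfectionStageModel([exp], params0=params)
        assert any("unidentifiable" in w for w in model._warnings)


class TestCompetitionStage:
    def test_recovers_doubled_penalty(self, params):
        truth = params.replace(P_gamma=0.2)
        exps = make_experiments([("COND3", 1), ("COND3", 2)], truth)
        res = CompetitionStageModel(exps, params0=params).fit()
        assert res.estimates["P_gamma"] == pytest.approx(0.2, rel=0.10)

    def test_no_penalty_boundary_recovered(self, params):
        """P_gamma = 1 (no penalty) data must recover the boundary value."""
        truth = params.replace(P_gamma=1.0)
        exps = make_experiments([("COND3", 1), ("COND3", 2)], truth)
        res = CompetitionStageModel(exps, params0=params).fit()
        assert res.estimates["P_gamma"] == pytest.approx(1.0, rel=0.02)

    def test_m13_channel_more_sensitive_than_trai(self, params):
        """Mis-setting P_gamma distorts the M13 curve more than the traI curve."""
        cond = preset_condition("COND3", 2)
        base = integrate(cond, params)
        off = integrate(cond, params.replace(P_gamma=0.4))

        def ssr(locus):
            a = np.log10(np.clip(marker_abundance(base, locus).abundance, 1, None))
            b = np.log10(np.clip(marker_abundance(off, locus).abundance, 1, None))
            return float(np.sum((a - b) ** 2))

        assert ssr("M13") > ssr("traI")


class TestCalibrationPipeline:
    def test_objective_trace_monotone(self, params):
        exps = make_experiments([("COND1", 0)], params, system="conjugation_only")
        res = GrowthStageModel(exps).fit()
        trace = res.diagnostics["objective_trace"]
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_missing_stage_reported_absent(self, params):
        bundle = {"growth": make_experiments([("COND1", 0)], params,
                                             system="conjugation_only")}
        res = run_full_calibration(bundle, params0=params)
        assert "growth" in res.stage_results
        assert set(res.missing_stages) == {"conjugation", "infection",
                                           "competition"}
        assert res.aborted_at is None

    def test_estimates_thread_forward(self, params):
        truth = params.replace(psi_max=0.05, e=5e-8)
        bundle = {
            "growth": make_experiments([("COND1", 0)], truth,
                                       system="conjugation_only"),
            "conjugation": make_experiments([("COND1", 1)], truth,
                                            system="conjugation_only"),
        }
        res = run_full_calibration(bundle, params0=params)
        conj = res.stage_results["conjugation"]
        assert conj.fixed["psi_max"] == pytest.approx(0.05, rel=0.01)
        assert res.params.psi_max == pytest.approx(0.05, rel=0.01)

    def test_summary_and_parameter_table(self, params):
        bundle = {"growth": make_experiments([("COND1", 0)], params,
                                             system="conjugation_only")}
        res = run_full_calibration(bundle, params0=params)
        table = res.parameter_table()
        assert set(table.columns) == {"parameter", "value", "source"}
        assert table.set_index("parameter").loc["psi_max", "source"] == "growth"
        assert "Stage: growth" in res.summary()
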