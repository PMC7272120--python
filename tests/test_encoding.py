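from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

import thermocode as tc
from thermocode.encoding import _pool_intensities
from thermocode.errors import InvalidParameterError


def embedded_step(baseline=32.0, target=42.0, pre=1.5, sample_rate=200.0):
    """Baseline hold followed by the ramp-hold-ramp step; onset at t=pre."""
    p = tc.StepWaveformParams(baseline, target)
    total = pre + p.total_duration
    times = np.linspace(0.0, total, int(total * sample_rate) + 1)
    temps = np.where(times < pre, baseline, p.value_at(np.clip(times - pre, 0.0, None)))
    return tc.TemperatureTrace(times, temps, sample_rate), pre


class TestPopulationReadout:
    def test_all_silent_population_reads_zero(self, small_spec, step_trace):
        spec = replace(small_spec, thermo_fraction=0.5)
        _, records = tc.sample_population(spec, seed=0)
        trains = [tc.SpikeTrain(r.unit_id, [], (0.0, 4.0)) for r in records]
        ro = tc.population_readout(trains, records, onset=1.0, window=1.0)
        assert ro.pool_a_count == ro.pool_b_count == ro.pool_b_baseline == 0.0

    def test_warm_step_suppresses_tonic_pool(self):
        """Over repeats, the tonic pool fires less during the warm step than
        in the matched baseline window (generator contract)."""
        spec = tc.PopulationSpec(density=30.0, area=4.0, ongoing_fraction=0.8, seed=2)
        trace, onset = embedded_step()
        diffs = []
        for s in range(20):
            trains, records = tc.simulate_population(spec, trace, 32.0, seed=s)
            ro = tc.population_readout(trains, records, onset=onset, window=1.0)
            diffs.append(ro.pool_b_count - ro.pool_b_baseline)
        assert np.mean(diffs) < 0

    def test_doubling_area_doubles_expected_pooled_counts(self):
        trace, _ = embedded_step()
        lam = {}
        for area in (4.0, 8.0):
            spec = tc.PopulationSpec(density=176.0, area=area, seed=3)
            fibers, records = tc.sample_population(spec, seed=3)
            idx_a, idx_b = tc.split_pools(records)
            lam[area] = sum(_pool_intensities(fibers, idx_b, trace, 32.0, 1.0))
        assert lam[8.0] == pytest.approx(2 * lam[4.0], rel=0.35)  # identity resampled


class TestDecisionStatistic:
    def make_readout(self, a, a0, b, b0, na=10, nb=10):
        return tc.ChannelReadout(a, a0, b, b0, window=1.0, n_pool_a=na, n_pool_b=nb)

    def test_sum_mode_equals_excitation_when_suppression_zero(self):
        ro = self.make_readout(12.0, 2.0, 5.0, 5.0)
        dec = tc.DecoderParams(mode="sum")
        assert tc.decision_statistic(ro, dec) == pytest.approx(10.0)

    def test_coincidence_requires_both_channels(self):
        ro = self.make_readout(50.0, 2.0, 5.0, 5.0)  # e large, s = 0
        dec = tc.DecoderParams(mode="coincidence")
        assert tc.decision_statistic(ro, dec) <= 0.0

    def test_missing_pool_makes_coincidence_degenerate(self):
        ro = self.make_readout(50.0, 2.0, 0.0, 0.0, nb=0)
        assert tc.decision_statistic(ro, tc.DecoderParams(mode="coincidence")) == 0.0

    def test_variance_normalization(self):
        ro = self.make_readout(14.0, 2.0, 2.0, 10.0)
        dec = tc.DecoderParams(mode="coincidence")
        assert tc.decision_statistic(ro, dec, null_std=(4.0, 2.0)) == pytest.approx(3.0)


class TestDiscriminateWarmCool:
    def test_rules(self):
        dec = tc.DecoderParams(criterion=2.0)
        warm = tc.ChannelReadout(10.0, 0.0, 0.0, 10.0, 1.0, n_pool_a=5, n_pool_b=5)
        cool = tc.ChannelReadout(0.0, 0.0, 20.0, 10.0, 1.0, n_pool_a=5, n_pool_b=5)
        flat = tc.ChannelReadout(1.0, 0.0, 10.0, 10.0, 1.0, n_pool_a=5, n_pool_b=5)
        assert tc.discriminate_warm_cool(warm, dec) == "warm"
        assert tc.discriminate_warm_cool(cool, dec) == "cool"
        assert tc.discriminate_warm_cool(flat, dec) == "none"

    def test_cool_trials_never_labeled_warm(self):
        """Over >= 1,000 simulated cooling trials the model labels < 1% as
        warm: only warming excites one pool while suppressing the other."""
        res = tc.model_dprime(
            tc.PopulationSpec(), tc.StepWaveformParams(32.0, 22.0), n_trials=1000, seed=9
        )
        counts = Counter(res.labels)
        assert counts["warm"] / res.n_trials < 0.01


class TestModelDprime:
    def test_null_amplitude_gives_chance(self):
        for mode in ("sum", "coincidence"):
            res = tc.model_dprime(
                tc.PopulationSpec(),
                tc.StepWaveformParams(32.0, 32.0),
                decoder=tc.DecoderParams(mode=mode),
                n_trials=500,
                seed=1,
            )
            assert abs(res.predicted_dprime) < 0.2

    def test_monotone_in_amplitude(self):
        """Predicted d' increases with step amplitude (rank correlation > 0.9
        of the seed-averaged curve)."""
        amps = [0.5, 1.0, 2.0, 4.0, 6.0, 10.0]
        spec = tc.PopulationSpec()
        mean_d = []
        for amp in amps:
            ds = [
                tc.model_dprime(
                    spec, tc.StepWaveformParams(32.0, 32.0 + amp), n_trials=150, seed=s
                ).predicted_dprime
                for s in range(5)
            ]
            mean_d.append(np.mean(ds))
        assert spearmanr(amps, mean_d).statistic > 0.9

    def test_too_few_trials_rejected(self):
        with pytest.raises(InvalidParameterError):
            tc.model_dprime(tc.PopulationSpec(), tc.StepWaveformParams(), n_trials=10)

    def test_distribution_dprime_matches_poisson_closed_form(self):
        """Constant-rate pools, sum decoder: the distribution-based d' agrees
        with the analytic Poisson mean/variance prediction within 5%."""
        spec = tc.PopulationSpec(seed=4)
        stim = tc.StepWaveformParams(32.0, 42.0, ramp_up_dur=0.0, hold_dur=4.0, ramp_down_dur=0.0)
        dec = tc.DecoderParams(mode="sum")
        res = tc.model_dprime(spec, stim, decoder=dec, n_trials=6000, seed=5)
        fibers, records = tc.sample_population(
            spec, seed=tc.encoding.spawn_seed_for_population(spec, 5)
        )
        idx_a, idx_b = tc.split_pools(records)
        trace = tc.make_step_waveform(stim, 500.0)
        la_s, la_b = _pool_intensities(fibers, idx_a, trace, 32.0, 1.0, 32.0)
        lb_s, lb_b = _pool_intensities(fibers, idx_b, trace, 32.0, 1.0, 32.0)
        sd_a = np.sqrt(2 * la_b) if la_b > 0 else 1.0
        sd_b = np.sqrt(2 * lb_b)
        mu_stim = (la_s - la_b) / sd_a + (lb_b - lb_s) / sd_b
        var_stim = (la_s + la_b) / sd_a**2 + (lb_s + lb_b) / sd_b**2
        var_null = (2 * la_b) / sd_a**2 + (2 * lb_b) / sd_b**2
        analytic = mu_stim / np.sqrt((var_stim + var_null) / 2.0)
        assert res.predicted_dprime == pytest.approx(analytic, rel=0.05)

    def test_counts_route_matches_train_route(self):
        """The pooled Poisson count sampler and full train simulation agree on
        mean channel evidence (dual-route check on a small population)."""
        spec = tc.PopulationSpec(density=25.0, area=4.0, ongoing_fraction=0.5, seed=6)
        trace, onset = embedded_step()
        fibers, records = tc.sample_population(spec, seed=6)
        # refractory off: the check targets Poisson superposition, not the
        # (separately tested) refractory bias
        fibers = [replace(f, refractory=0.0) for f in fibers]
        idx_a, idx_b = tc.split_pools(records)
        stim_only = tc.TemperatureTrace(
            trace.times[trace.times >= onset] - onset,
            trace.temps[trace.times >= onset],
            trace.sample_rate,
        )
        la_s, la_b = _pool_intensities(fibers, idx_a, stim_only, 32.0, 1.0)
        lb_s, lb_b = _pool_intensities(fibers, idx_b, stim_only, 32.0, 1.0)
        e, s = [], []
        for rep in range(150):
            rng = np.random.default_rng(rep)
            trains = [tc.simulate_fiber(f, trace, 32.0, seed=rng) for f in fibers]
            ro = tc.population_readout(trains, records, onset=onset, window=1.0)
            e.append(ro.excitation_evidence)
            s.append(ro.suppression_evidence)
        se_e = np.std(e) / np.sqrt(len(e))
        se_s = np.std(s) / np.sqrt(len(s))
        assert np.mean(e) == pytest.approx(la_s - la_b, abs=3 * se_e + 0.4)
        assert np.mean(s) == pytest.approx(lb_b - lb_s, abs=3 * se_s + 0.4)


class TestLesionExperiment:
    def test_trpm8_lesion_abolishes_warm_detection(self):
        """Removing the tonic cool-driven pool sends the coincidence-mode warm
        d' to 0 while wildtype exceeds 1.5 at the 10 degC step."""
        table = tc.lesion_experiment(
            ["wildtype", "trpm8_null"], [10.0], n_trials=300, seed=0
        )
        wt = table[table["genotype"] == "wildtype"]["predicted_dprime"].iloc[0]
        m8 = table[table["genotype"] == "trpm8_null"]["predicted_dprime"].iloc[0]
        assert wt > 1.5
        assert abs(m8) < 0.3
        assert table[table["genotype"] == "trpm8_null"]["degenerate"].iloc[0]

    def test_suppression_only_regime_still_detectable(self):
        """At a 22 degC baseline the 10 degC step recruits almost no
        warm-excited fibers, yet wildtype and the noxious-heat knockout both
        detect it through the suppression channel."""
        for genotype in ("wildtype", "tko"):
            spec = replace(tc.PopulationSpec(), genotype=genotype)
            res = tc.model_dprime(spec, tc.StepWaveformParams(22.0, 32.0), n_trials=300, seed=2)
            assert res.predicted_dprime > 0.3

    def test_unknown_genotype_rejected(self):
        with pytest.raises(InvalidParameterError):
            tc.lesion_experiment(["trpx_null"], [10.0], n_trials=100, seed=0)


class TestSpatialSummation:
    def test_dprime_grows_with_area(self):
        """Predicted d' is monotone in stimulated area (rank corr > 0.9) and
        the behavioral contrast (8x8 vs 3x3 mm probe) is reproduced."""
        areas = [4.5, 9.0, 22.0, 44.0]
        curves = []
        for s in range(5):
            table = tc.spatial_summation_curve(
                tc.PopulationSpec(), areas, tc.StepWaveformParams(32.0, 42.0), n_trials=150, seed=s
            )
            curves.append(table["predicted_dprime"].to_numpy())
        mean_d = np.mean(curves, axis=0)
        assert spearmanr(areas, mean_d).statistic > 0.9
        assert mean_d[2] > mean_d[1]  # 22 mm^2 beats 9 mm^2

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            tc.spatial_summation_curve(
                tc.PopulationSpec(), [0.0], tc.StepWaveformParams(), n_trials=100, seed=0
            )


class TestFiberBudget:
    def test_reference_innervation_arithmetic(self):
        budget = tc.informative_fiber_budget(176.0, 0.36, 22.0)
        assert budget["per_mm2"] == pytest.approx(63.36)
        assert budget["per_mm2"] > 60.0
        assert budget["total"] == pytest.approx(1393.92)
        assert budget["total"] > 1300.0

    def test_zero_thermo_fraction(self):
        assert tc.informative_fiber_budget(176.0, 0.0, 22.0)["total"] == 0.0
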