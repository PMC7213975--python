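"""Ground-truth fidelity of the synthetic-data generators."""

import numpy as np
import pytest

from statephys.locomotion import angle_to_velocity
from statephys.simulate import (
    BandComponent,
    default_cohort_spec,
    gen_behavior_cohort,
    gen_feature_clouds,
    gen_marble_masks,
    gen_outcome_cohort,
    gen_state_lfp,
    gen_state_spikes,
    gen_three_chamber_trajectory,
    gen_wheel_trace,
    random_bout_spec,
)
from statephys.spectral import compute_psd, relative_band_power


class TestWheelGenerator:
    def test_no_bouts_no_noise_constant_angle(self):
        wheel, bouts = gen_wheel_trace(60.0, [], noise_sd_cm_s=0.0, seed=0)
        assert bouts == []
        assert np.allclose(wheel.angle, wheel.angle[0])
        v = angle_to_velocity(wheel)
        assert np.allclose(v.v, 0.0)

    def test_single_bout_arc_length(self):
        # 5 cm/s for 10 s with 0.5-s trapezoidal ramps covers
        # 5 * (10 - 0.5) = 47.5 cm; unwrapped angle grows by distance/radius
        wheel, _ = gen_wheel_trace(20.0, [(5.0, 15.0, 5.0)], noise_sd_cm_s=0.0, seed=0)
        arc = np.unwrap(wheel.angle) * 7.5
        assert abs((arc[-1] - arc[0]) - 47.5) < 0.1

    def test_velocity_histogram_bimodal(self):
        # independent finite-difference oracle on the emitted angle trace
        spec = random_bout_spec(600.0, 8, seed=7, speed_range_cm_s=(6.0, 6.0))
        wheel, bouts = gen_wheel_trace(600.0, spec, noise_sd_cm_s=0.3, seed=7)
        v = np.gradient(np.unwrap(wheel.angle) * 7.5, wheel.t)
        in_bout = np.zeros(wheel.t.size, dtype=bool)
        for on, off in bouts:
            in_bout |= (wheel.t >= on + 0.5) & (wheel.t < off - 0.5)
        assert abs(np.median(v[in_bout]) - 6.0) < 0.5
        assert abs(np.median(v[~in_bout])) < 0.2

    def test_seed_determinism(self):
        spec = random_bout_spec(300.0, 4, seed=3)
        w1, _ = gen_wheel_trace(300.0, spec, seed=11)
        w2, _ = gen_wheel_trace(300.0, spec, seed=11)
        assert np.array_equal(w1.angle, w2.angle)

    def test_overlapping_bouts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_wheel_trace(60.0, [(5.0, 20.0, 5.0), (15.0, 30.0, 5.0)])


class TestLFPGenerator:
    def test_gain_one_means_no_state_modulation(self):
        comp = [BandComponent("gamma", 40.0, 55.0, 2.0)]
        bouts = [(30.0, 60.0)]
        lfp = gen_state_lfp(120.0, 1000.0, comp, {"gamma": 1.0}, bouts, noise_sd=0.0, seed=4)
        p_q = compute_psd(lfp, [(0.0, 30.0)])
        p_l = compute_psd(lfp, [(30.0, 60.0)])
        g_q = relative_band_power(p_q, (40, 55)).relative_power
        g_l = relative_band_power(p_l, (40, 55)).relative_power
        assert abs(g_q - g_l) < 0.05

    def test_absent_band_has_no_power(self):
        comp = [
            BandComponent("low", 3.0, 6.0, 3.0),
            BandComponent("gamma", 40.0, 55.0, 0.0),
        ]
        lfp = gen_state_lfp(120.0, 1000.0, comp, {}, [], noise_sd=0.0, seed=4)
        ps = compute_psd(lfp, [(0.0, 120.0)])
        assert relative_band_power(ps, (40, 55)).relative_power < 1e-6

    def test_amplitude_halving_quarters_band_power(self):
        # periodogram oracle on raw samples: power scales as amplitude^2
        comp_full = [BandComponent("gamma", 40.0, 55.0, 2.0)]
        comp_half = [BandComponent("gamma", 40.0, 55.0, 1.0)]
        a = gen_state_lfp(200.0, 1000.0, comp_full, {}, [], noise_sd=0.0, seed=9)
        b = gen_state_lfp(200.0, 1000.0, comp_half, {}, [], noise_sd=0.0, seed=9)
        ratio = np.var(b.samples) / np.var(a.samples)
        assert abs(ratio - 0.25) < 0.01

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            gen_state_lfp(10.0, 100.0, [BandComponent("x", 40.0, 60.0, 1.0)], {}, [])


class TestSpikeGenerator:
    def test_homogeneous_count(self):
        train = gen_state_spikes(5.0, 5.0, [], 100.0, seed=2)
        assert abs(train.n_spikes - 500) < 3 * np.sqrt(500)

    def test_silent_in_bouts(self):
        bouts = [(20.0, 40.0), (60.0, 80.0)]
        train = gen_state_spikes(5.0, 0.0, bouts, 100.0, seed=2, rate_lead_s=0.0)
        for on, off in bouts:
            assert np.count_nonzero(
                (train.spike_times >= on) & (train.spike_times < off)
            ) == 0

    def test_expected_count_state_weighted(self):
        bouts = [(100.0 * i + 50.0, 100.0 * i + 80.0) for i in range(10)]  # 30 % of 1000 s
        counts = [
            gen_state_spikes(5.0, 10.0, bouts, 1000.0, seed=s, rate_lead_s=0.0).n_spikes
            for s in range(20)
        ]
        expected = 5.0 * 700.0 + 10.0 * 300.0
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected / 20)

    def test_locking_makes_phases_nonuniform(self):
        from statephys.simulate.ephys import band_phase

        comp = [BandComponent("gamma", 39.0, 41.0, 2.0)]
        lfp = gen_state_lfp(200.0, 1000.0, comp, {}, [], noise_sd=0.0, seed=5)
        locked = gen_state_spikes(
            8.0, 8.0, [], 200.0, locking=(40.0, 3.0), lfp=lfp, seed=5
        )
        phase = band_phase(lfp, 40.0)
        ph = np.interp(locked.spike_times, np.arange(phase.size) / 1000.0, phase)
        # Rayleigh-style resultant length: uniform phases give ~1/sqrt(n)
        r = np.abs(np.mean(np.exp(1j * ph)))
        assert r > 10.0 / np.sqrt(ph.size)


class TestFeatureClouds:
    def test_small_cluster_rejected(self):
        with pytest.raises(ValueError):
            gen_feature_clouds(n_cluster=4, n_noise=10, dim=4, separation=1.0)

    def test_separation_zero_overlaps(self):
        from statephys.units import isolation_distance

        cloud = gen_feature_clouds(200, 200, 4, separation=0.0, seed=1)
        near = isolation_distance(cloud)
        far = isolation_distance(gen_feature_clouds(200, 200, 4, separation=10.0, seed=1))
        assert near < far


class TestCohortGenerators:
    def test_zero_hazard_all_censored(self):
        spec = default_cohort_spec(seed=1, n_per_group=4)
        from statephys.simulate import CohortSpec, GroupEffect

        eff = GroupEffect(mortality_hazard_per_d=0.0, seizure_hazard_per_d=0.0)
        spec = CohortSpec(
            groups=(("A", 6),), effects={"A": eff}, control_label="A", seed=2
        )
        records, _ = gen_outcome_cohort(spec)
        assert all(r.censored and r.death_age_d == 500.0 for r in records)

    def test_zero_preference_plants_zero_index(self):
        traj, geom = gen_three_chamber_trajectory(0.0, seed=8, duration_s=1200.0)
        from statephys.behavior import score_sociability

        res = score_sociability(traj, geom)
        assert abs(res.time_index) < 0.25  # ~80 dwell blocks of sampling noise

    def test_planted_preference_recovered_across_animals(self):
        # +0.4 vs -0.4 groups, n = 10 each: scorer recovers the means
        from statephys.behavior import score_sociability

        means = {}
        for sign, base_seed in ((0.4, 100), (-0.4, 200)):
            vals = [
                score_sociability(
                    *gen_three_chamber_trajectory(sign, seed=base_seed + i)
                ).time_index
                for i in range(10)
            ]
            means[sign] = np.mean(vals)
        # block-sampling SE per animal ~0.16 -> SE of the mean ~0.05
        assert abs(means[0.4] - 0.4) < 0.15
        assert abs(means[-0.4] + 0.4) < 0.15
        assert means[0.4] > means[-0.4]

    def test_truth_sidecar_matches_effects(self):
        spec = default_cohort_spec(seed=5, n_per_group=2)
        _, truth = gen_behavior_cohort(spec)
        assert set(truth["group"]) == {"CON", "PV_mut", "VIP_mut"}
        mut = truth[truth.group == "VIP_mut"]
        con = truth[truth.group == "CON"]
        assert mut["sociability_index"].mean() < con["sociability_index"].mean()


class TestMarbleMasks:
    def test_analytic_area_ratios(self):
        cov = [0.9, 0.5, 0.0]
        before, after = gen_marble_masks(cov, marble_radius_px=10)
        from scipy import ndimage

        lab_b, n = ndimage.label(before)
        assert n == 3
        areas_b = ndimage.sum_labels(before, lab_b, np.arange(1, n + 1))
        # exposure is a concentric disc of area (1 - coverage) x original
        lab_a, _ = ndimage.label(after)
        for i, c in enumerate(cov):
            region = lab_b == i + 1
            exposed = np.count_nonzero(after & region)
            assert abs(exposed / areas_b[i] - (1 - c)) < 0.07
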