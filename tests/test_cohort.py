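"""Synthetic cohort: profile coupling, schedules, sung responses, and the
EEG forward model's observable properties."""

import numpy as np
import pytest
from scipy import stats as sps

from erdvoice.acoustics import score_accuracy
from erdvoice.cohort import (ErdGroundTruth, ParticipantProfile,
                             SimulationParams, make_cohort, make_schedule,
                             simulate_eeg, simulate_sung_response)
from erdvoice.melody import generate_melody_set
from erdvoice.montage import Montage, default_montage
from erdvoice.preprocess import epoch


def spearman_of(profiles):
    x = [p.vocal_inaccuracy_cents for p in profiles]
    y = [p.beta_humanness_effect for p in profiles]
    return sps.spearmanr(x, y).statistic


class TestMakeCohort:
    def test_reproducible_from_seed(self):
        assert make_cohort(10, rng_seed=3) == make_cohort(10, rng_seed=3)

    def test_null_coupling_centers_on_zero(self):
        rhos = [spearman_of(make_cohort(19, rng_seed=i, coupling_rho=0.0))
                for i in range(200)]
        assert abs(np.mean(rhos)) < 0.05

    def test_perfect_coupling_is_monotone(self):
        for i in range(5):
            assert spearman_of(make_cohort(12, rng_seed=i, coupling_rho=1.0)) == 1.0

    def test_target_coupling_recovered_at_study_size(self):
        # Monte-Carlo oracle of the copula: replicate-mean Spearman at the
        # study's configured rho = 0.49, n = 18
        rhos = [spearman_of(make_cohort(18, rng_seed=i, coupling_rho=0.49))
                for i in range(500)]
        assert 0.39 <= np.mean(rhos) <= 0.59

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(2, rng_seed=0)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(10, rng_seed=0, coupling_rho=1.5)


class TestSchedule:
    def test_balanced_and_non_overlapping(self):
        s = make_schedule(120, rng_seed=0)
        assert s.n_trials == 120
        assert sum(c == "vocal" for c in s.conditions) == 60
        s.validate()
        assert np.all(np.diff(s.onsets_s) > 0)

    def test_odd_trial_count_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(31, rng_seed=0)


class TestErdGroundTruth:
    def test_defaults_satisfy_vocal_priority(self):
        gt = ErdGroundTruth()
        for band in ("mu", "beta"):
            v = gt.get(band, "fc", "vocal")
            nv = gt.get(band, "fc", "nonvocal")
            assert v.onset_s < nv.onset_s
            assert v.depth >= nv.depth

    def test_inverted_defaults_rejected(self):
        from erdvoice.cohort import ErdWindowParams

        with pytest.raises(ValueError):
            ErdGroundTruth(params={("mu", "fc", "vocal"): ErdWindowParams(4.0, 0.1)})


class TestSungResponse:
    def _profile(self, inacc=52.0):
        return ParticipantProfile("p0", "female", inacc, 0.15)

    def test_deterministic(self, fixed_melody):
        a = simulate_sung_response(self._profile(), fixed_melody, rng_seed=4)
        b = simulate_sung_response(self._profile(), fixed_melody, rng_seed=4)
        assert np.array_equal(a.f0, b.f0)

    def test_zero_inaccuracy_hits_tracker_floor(self, fixed_melody):
        track = simulate_sung_response(
            self._profile(1e-6), fixed_melody, rng_seed=1, frame_noise_cents=0.0
        )
        s = score_accuracy(track, fixed_melody)
        assert s.mean_abs_deviation < 2.0

    def test_configured_inaccuracy_recovered(self):
        # self-consistency oracle: 120 melodies at the study's 52 cents
        prof = self._profile(52.0)
        devs = []
        for i, mel in enumerate(generate_melody_set(120, 7)):
            track = simulate_sung_response(prof, mel, rng_seed=i)
            devs.extend(score_accuracy(track, mel).deviations)
        assert 42.0 <= np.mean(devs) <= 62.0


@pytest.fixture(scope="module")
def small_run():
    prof = ParticipantProfile("p0", "female", 52.0, 0.15)
    sched = make_schedule(10, rng_seed=1)
    raw = simulate_eeg(prof, sched, rng_seed=2)
    return prof, sched, raw


class TestSimulateEeg:
    def test_channel_layout_and_events(self, small_run):
        _, sched, raw = small_run
        assert raw.data.shape[0] == 67  # 64 scalp + 2 mastoids + EMG
        assert raw.sfreq == 512.0
        stim = [e for e in raw.events if e.label.startswith("stim_")]
        go = [e for e in raw.events if e.label == "go"]
        assert len(stim) == 10 and len(go) == 10
        assert [e.label.replace("stim_", "") for e in stim] == list(sched.conditions)

    def test_emg_bursts_locked_to_production(self, small_run):
        _, sched, raw = small_run
        emg = raw.get("EMG")
        sf = raw.sfreq

        def power(t0, t1):
            seg = emg[int(t0 * sf):int(t1 * sf)]
            return float(np.mean(seg**2))

        prod = np.mean([power(g + 0.5, g + 4.5) for g in sched.go_times_s])
        percep = np.mean([power(o, o + 3.5) for o in sched.onsets_s])
        assert prod > 5 * percep

    def test_null_ground_truth_gives_null_erd(self):
        # all depths zero, no artifacts: baseline-subtracted band power at
        # fronto-central sites should be statistically indistinguishable
        # from zero
        from erdvoice.spectral import RoiSpec, trial_band_powers
        from erdvoice.preprocess import preprocess_pipeline

        prof = ParticipantProfile("p0", "female", 52.0, 0.0)
        sched = make_schedule(60, rng_seed=0)
        raw = simulate_eeg(prof, sched, erd=ErdGroundTruth().null(),
                           rng_seed=0, artifacts=False)
        percep, _ = preprocess_pipeline(raw)
        tbl = trial_band_powers(percep, ["F1", "F2", "F3", "F4", "FC1", "FC2"])
        per_trial = tbl.groupby("trial_index").erd.mean()
        se = per_trial.std(ddof=1) / np.sqrt(len(per_trial))
        assert abs(per_trial.mean()) < 2 * se + 1e-12

    def test_no_artifacts_means_no_rejections(self):
        from erdvoice.preprocess import preprocess_pipeline

        prof = ParticipantProfile("p0", "female", 52.0, 0.15)
        sched = make_schedule(20, rng_seed=5)
        raw = simulate_eeg(prof, sched, rng_seed=6, artifacts=False)
        percep, prod = preprocess_pipeline(raw)
        assert percep.kept.all()
        assert prod.kept.all()

    def test_spike_injection_rate_within_binomial_bounds(self):
        # with spike injection at rate q the rejected fraction should sit
        # inside the binomial 95% interval around q
        q = 0.3
        prof = ParticipantProfile("p0", "female", 52.0, 0.15)
        sim = SimulationParams(spike_epoch_rate=q, blink_rate_hz=0.0)
        n_rej, n_tot = 0, 0
        from erdvoice.preprocess import preprocess_pipeline

        for seed in range(3):
            sched = make_schedule(20, rng_seed=seed)
            raw = simulate_eeg(prof, sched, rng_seed=100 + seed, sim=sim)
            percep, prod = preprocess_pipeline(raw)
            n_rej += int((~percep.kept).sum() + (~prod.kept).sum())
            n_tot += percep.n_trials + prod.n_trials
        lo, hi = sps.binom.interval(0.95, n_tot, q)
        assert lo <= n_rej <= hi

    def test_attrition_matches_target_range(self):
        # default artifact rates should leave a mean of 45-60 surviving
        # perception epochs per condition out of 60
        from erdvoice.preprocess import preprocess_pipeline

        counts = {"vocal": [], "nonvocal": []}
        for seed in range(2):
            prof = ParticipantProfile(f"p{seed}", "female", 52.0, 0.15)
            sched = make_schedule(120, rng_seed=seed)
            raw = simulate_eeg(prof, sched, rng_seed=50 + seed)
            percep, _ = preprocess_pipeline(raw)
            for cond in counts:
                kept = sum(
                    k and c == cond
                    for k, c in zip(percep.kept, percep.conditions)
                )
                counts[cond].append(kept)
        for cond, vals in counts.items():
            assert 45 <= np.mean(vals) <= 60

    def test_missing_roi_channel_rejected(self):
        bad = Montage()
        bad.scalp = [c for c in bad.scalp if c != "FC1"]
        prof = ParticipantProfile("p0", "female", 52.0, 0.15)
        sched = make_schedule(10, rng_seed=1)
        with pytest.raises(ValueError):
            simulate_eeg(prof, sched, montage=bad, rng_seed=2)
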