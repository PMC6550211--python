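"""Synthetic-cohort generator: determinism, schedule constraints, effect
recovery, and artifact ground truth."""
import numpy as np
import pytest

from phenostress.config import SimConfig
from phenostress.simulate import (
    cohort_phenotypes,
    generate_cohort,
    inject_artifacts,
    simulate_beats,
    simulate_ema,
    simulate_latent_schedule,
    simulate_sc,
    simulate_st,
    simulate_subject,
)
from phenostress.types import SECONDS_PER_DAY, Phenotype, is_night


def _tiny_config(**kw) -> SimConfig:
    return SimConfig(days=1, **kw)


class TestCohort:
    def test_partition_and_determinism(self):
        cfg = _tiny_config()
        # phenotype partition is cheap to check without simulating signals
        phenos = cohort_phenotypes(10, 0.5)
        assert sum(p is Phenotype.RESPONSIVE for p in phenos) == 5
        assert cohort_phenotypes(2, 1.0) == [Phenotype.RESPONSIVE] * 2

        a = generate_cohort(2, 0.5, seed=7, config=cfg)
        b = generate_cohort(2, 0.5, seed=7, config=cfg)
        for da, db in zip(a, b):
            assert np.array_equal(da.beats.r_peak_times, db.beats.r_peak_times)
            assert np.array_equal(da.sc.samples, db.sc.samples)
            assert np.array_equal(da.st.samples, db.st.samples)
            assert np.array_equal(da.acc.samples, db.acc.samples)
            assert [r.prompt_time for r in da.ema] == [r.prompt_time for r in db.ema]
            assert da.profile == db.profile

    @pytest.mark.parametrize("n,frac", [(0, 0.5), (1, 0.5), (5, -0.1), (5, 1.5)])
    def test_invalid_args_raise(self, n, frac):
        with pytest.raises(ValueError):
            cohort_phenotypes(n, frac)

    def test_questionnaire_scores_within_instrument_ranges(self):
        cohort = generate_cohort(6, 0.5, seed=11, config=_tiny_config())
        for d in cohort:
            p = d.profile
            assert 0 <= p.pss <= 40
            for s in (p.dass_depression, p.dass_anxiety, p.dass_stress, p.psqi):
                assert 0 <= s <= 21

    def test_responsive_effects_dominate_blunted_for_every_channel(self):
        cfg = _tiny_config()
        for key in ("hr_bpm", "scr_rate_hz", "st_c", "hrv_suppression"):
            assert abs(cfg.responsive_effects[key]) > abs(cfg.blunted_effects[key])


class TestLatentSchedule:
    def test_night_is_level_one_and_full_coverage(self):
        sched = simulate_latent_schedule(5, seed=3)
        assert sched.bounds[0] == 0.0
        assert sched.bounds[-1] == 5 * SECONDS_PER_DAY
        t = np.arange(0, 5 * SECONDS_PER_DAY, 60.0)
        levels = sched.level_at(t)
        assert np.all(levels[is_night(t)] == 1)
        assert np.all((levels >= 1) & (levels <= 5))

    def test_deterministic_given_seed(self):
        a = simulate_latent_schedule(1, seed=9)
        b = simulate_latent_schedule(1, seed=9)
        assert np.array_equal(a.bounds, b.bounds)
        assert np.array_equal(a.levels, b.levels)

    def test_days_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_latent_schedule(0, seed=1)

    def test_daytime_level_frequencies_match_configured_distribution(self):
        """Duration-weighted daytime level frequencies approach the
        configured multinomial within Monte-Carlo error."""
        cfg = SimConfig(days=60)
        sched = simulate_latent_schedule(60, seed=5, config=cfg)
        t = np.arange(0, 60 * SECONDS_PER_DAY, 60.0)
        day = ~is_night(t)
        levels = sched.level_at(t)[day]
        # segment draws are iid from the configured distribution; with ~1000
        # segments a 5% absolute tolerance is > 3 binomial SEs per level
        freq = np.bincount(levels, minlength=6)[1:] / len(levels)
        assert np.allclose(freq, cfg.day_level_probs, atol=0.05)


class TestBeats:
    def test_rr_positive_and_strictly_increasing(self, responsive_subject):
        t = responsive_subject.beats.r_peak_times
        assert np.all(np.diff(t) > 0)
        assert np.all(responsive_subject.beats.rr_intervals > 0)

    def test_zero_effect_profile_shows_no_stress_contrast(self):
        cfg = SimConfig(days=30)
        rng = np.random.default_rng(21)
        from phenostress.simulate import generate_profile
        prof = generate_profile(rng, "B", Phenotype.BLUNTED, cfg)
        prof.stress_effect = {k: 0.0 for k in prof.stress_effect}
        sched = simulate_latent_schedule(30, seed=21, config=cfg)
        beats = simulate_beats(prof, sched, seed=2, config=cfg)
        hr = self._state_mean_hr(beats, sched)
        if 5 in hr and 1 in hr:
            assert abs(hr[5] - hr[1]) < 1.5  # only Monte-Carlo noise remains

    @staticmethod
    def _state_mean_hr(beats, sched):
        t = beats.r_peak_times
        rr = np.diff(t) * 1000.0
        lv = np.asarray(sched.level_at(t[1:]), dtype=int)
        day = ~is_night(t[1:])
        out = {}
        for level in (1, 5):
            sel = (lv == level) & day
            if sel.sum() > 1000:
                out[level] = 60_000.0 / rr[sel].mean()
        return out

    def test_configured_hr_delta_recovered(self):
        """A 10-bpm full-scale stress effect is recovered by state-wise
        averaging over a long simulation."""
        cfg = SimConfig(days=30)
        from phenostress.simulate import generate_profile
        prof = generate_profile(np.random.default_rng(77), "R",
                                Phenotype.RESPONSIVE, cfg)
        sched = simulate_latent_schedule(30, seed=77, config=cfg)
        beats = simulate_beats(prof, sched, seed=78, config=cfg)
        hr = self._state_mean_hr(beats, sched)
        assert 5 in hr and 1 in hr, "need enough dwell time in both states"
        delta = hr[5] - hr[1]
        assert delta == pytest.approx(cfg.responsive_effects["hr_bpm"], abs=1.5)

    def test_night_hr_below_day_hr(self, responsive_subject):
        beats = responsive_subject.beats
        t = beats.r_peak_times[1:]
        rr = beats.rr_intervals
        hr_night = 60_000.0 / rr[is_night(t)].mean()
        hr_day = 60_000.0 / rr[~is_night(t)].mean()
        assert hr_night < hr_day


class TestSkinConductance:
    def test_zero_rate_yields_noise_floor_phasic(self):
        cfg = _tiny_config(scr_base_rate_hz=0.0)
        from phenostress.simulate import generate_profile
        sched = simulate_latent_schedule(1, seed=4, config=cfg)
        prof = generate_profile(np.random.default_rng(4), "R",
                                Phenotype.RESPONSIVE, cfg)
        prof.stress_effect = dict(prof.stress_effect, scr_rate_hz=0.0)
        rec = simulate_sc(prof, sched, seed=4, config=cfg)
        assert len(rec.meta["scr_times"]) == 0
        assert np.all(rec.samples >= 0)

    def test_doubling_rate_doubles_expected_event_count(self):
        cfg = _tiny_config()
        from phenostress.simulate import generate_profile
        sched = simulate_latent_schedule(1, seed=8, config=cfg)
        prof = generate_profile(np.random.default_rng(8), "B",
                                Phenotype.BLUNTED, cfg)
        counts = []
        for mult in (1.0, 2.0):
            c = _tiny_config(scr_base_rate_hz=cfg.scr_base_rate_hz * mult)
            n = np.mean([len(simulate_sc(prof, sched, seed=s, config=c).meta["scr_times"])
                         for s in range(5)])
            counts.append(n)
        # Poisson: ratio of mean counts ≈ 2 within sampling error
        assert counts[1] / counts[0] == pytest.approx(2.0, rel=0.15)

    def test_responsive_scr_rate_increases_with_stress(self):
        cfg = SimConfig(days=10)
        from phenostress.simulate import generate_profile
        prof = generate_profile(np.random.default_rng(99), "R",
                                Phenotype.RESPONSIVE, cfg)
        sched = simulate_latent_schedule(10, seed=99, config=cfg)
        rec = simulate_sc(prof, sched, seed=100, config=cfg)
        times = rec.meta["scr_times"]
        lv = np.asarray(sched.level_at(times), dtype=int)
        dur = {}
        for level in (1, 5):
            sel = sched.levels == level
            dur[level] = float(np.sum((sched.bounds[1:] - sched.bounds[:-1])[sel]))
        if dur.get(5, 0) > 3600:
            rate1 = np.sum(lv == 1) / dur[1]
            rate5 = np.sum(lv == 5) / dur[5]
            assert rate5 > rate1


class TestStAcc:
    def test_night_st_above_day(self, responsive_subject):
        st = responsive_subject.st
        t = st.times()
        night = is_night(t)
        assert st.samples[night].mean() > st.samples[~night].mean()

    def test_zero_activity_gives_sensor_noise_sd(self):
        cfg = _tiny_config(activity_bout_rate_per_hour=0.0)
        data = simulate_subject("B", Phenotype.BLUNTED, 31, cfg)
        sd = np.std(data.acc.samples[: 32 * 300])
        assert sd == pytest.approx(cfg.acc_base_sd, rel=0.15)

    def test_activity_bouts_exceed_threshold(self, responsive_subject):
        """Windows inside configured high-activity bouts have ACC SD > 0.04."""
        sched = responsive_subject.schedule
        acc = responsive_subject.acc
        cfg = SimConfig()
        hi = np.flatnonzero(sched.activity >= 0.3)
        assert len(hi), "fixture should include at least one bout"
        i = hi[0]
        a, b = sched.activity_bounds[i], sched.activity_bounds[i + 1]
        seg = acc.slice(a, b)
        assert np.std(seg) > 0.04


class TestEMA:
    def test_schedule_constraints(self, responsive_subject):
        times = np.array([r.prompt_time for r in responsive_subject.ema])
        assert np.all(np.diff(times) >= 1800.0 - 1e-6)
        days = (times // SECONDS_PER_DAY).astype(int)
        assert np.bincount(days).max() <= 12
        for r in responsive_subject.ema:
            assert 1 <= r.stress_likert <= 5

    def test_prompts_within_waking_window_many_days(self):
        cfg = SimConfig(days=90)
        from phenostress.simulate import generate_profile
        prof = generate_profile(np.random.default_rng(13), "R",
                                Phenotype.RESPONSIVE, cfg)
        sched = simulate_latent_schedule(90, seed=13, config=cfg)
        ema = simulate_ema(prof, sched, seed=14, config=cfg)
        times = np.array([r.prompt_time for r in ema])
        tod = times % SECONDS_PER_DAY
        assert np.all(tod >= cfg.ema_wake_start_h * 3600)
        assert np.all(tod <= cfg.ema_wake_end_h * 3600)
        per_day = np.bincount((times // SECONDS_PER_DAY).astype(int))
        assert np.all(per_day <= 12)
        gaps = np.diff(times)
        assert gaps.min() >= 1800.0 - 1e-6

    def test_zero_misreport_noise_reports_latent_level(self):
        cfg = _tiny_config(ema_misreport_prob=0.0)
        data = simulate_subject("R", Phenotype.RESPONSIVE, 17, cfg)
        for r in data.ema:
            assert r.stress_likert == int(data.schedule.level_at(r.prompt_time))

    def test_pleasure_negatively_coupled_to_stress(self):
        cfg = SimConfig(days=30)
        from phenostress.simulate import generate_profile
        prof = generate_profile(np.random.default_rng(19), "R",
                                Phenotype.RESPONSIVE, cfg)
        sched = simulate_latent_schedule(30, seed=19, config=cfg)
        ema = simulate_ema(prof, sched, seed=20, config=cfg)
        stress = np.array([r.stress_likert for r in ema])
        pleasure = np.array([r.pleasure for r in ema])
        if stress.std() > 0:
            assert np.corrcoef(stress, pleasure)[0, 1] < 0


class TestArtifacts:
    def test_flatline_recorded_in_ground_truth(self, responsive_subject):
        rec = responsive_subject.sc
        out, truth = inject_artifacts(
            rec, {"sc_flatline": {"count": 1, "duration_s": 10.0, "at_s": 1000.0}}, seed=0)
        assert truth == [("sc_flatline", 1000.0, 1010.0)]
        assert np.all(out.slice(1000.0, 1010.0) == 0.0005)

    def test_zero_rates_identity(self, responsive_subject):
        out, truth = inject_artifacts(responsive_subject.sc,
                                      {"sc_flatline": {"count": 0}}, seed=0)
        assert truth == []
        assert np.array_equal(out.samples, responsive_subject.sc.samples)

        beats_out, truth = inject_artifacts(responsive_subject.beats,
                                            {"rr_gap": {"count": 0}}, seed=0)
        assert truth == []
        assert np.array_equal(beats_out.r_peak_times,
                              responsive_subject.beats.r_peak_times)

    def test_unknown_type_raises(self, responsive_subject):
        with pytest.raises(ValueError):
            inject_artifacts(responsive_subject.sc, {"nonsense": {}}, seed=0)

    def test_rr_gap_removes_beats(self, responsive_subject):
        beats = responsive_subject.beats
        out, truth = inject_artifacts(
            beats, {"rr_gap": {"count": 1, "gap_s": 3.5, "at_s": 5000.0}}, seed=0)
        assert truth == [("rr_gap", 5000.0, 5003.5)]
        assert len(out.slice(5000.0, 5003.5)) == 0
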