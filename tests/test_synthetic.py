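"""Synthetic reef campaign generator: schedules, spectra, determinism."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import numpy as np
import pytest
from scipy import signal as sig
from scipy.stats import poisson

import reefscape as rs
from reefscape import synthetic


def _band_energy(x, sr, lo, hi):
    freqs, psd = sig.periodogram(x, fs=sr)
    mask = (freqs >= lo) & (freqs < hi)
    return psd[mask].sum()


def _count_bursts(x, threshold=0.02, min_gap=200):
    """Count separated transient events in a waveform."""
    hot = np.flatnonzero(np.abs(x) > threshold)
    if len(hot) == 0:
        return 0
    return 1 + int(np.sum(np.diff(hot) > min_gap))


class TestSnapTrain:
    def test_zero_rate_is_silent(self):
        assert np.all(synthetic.snap_train(0.0, 10.0, 44100, seed=0) == 0)

    def test_event_count_follows_poisson_law(self):
        # low rate keeps events separated so bursts are countable; the count
        # must fall in the central 99.9% Poisson interval
        rate, dur = 5.0, 60.0
        x = synthetic.snap_train(rate, dur, 44100, seed=123)
        n = _count_bursts(x)
        lo, hi = poisson.ppf([0.0005, 0.9995], rate * dur)
        assert lo <= n <= hi

    def test_same_seed_reproduces_waveform(self):
        a = synthetic.snap_train(30.0, 5.0, 44100, seed=7)
        b = synthetic.snap_train(30.0, 5.0, 44100, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_snaps_are_short_transients(self):
        x = synthetic.snap_train(1.0, 2.0, 44100, seed=1)
        hot = np.flatnonzero(np.abs(x) > 1e-6)
        assert len(hot) > 0
        # split into bursts at gaps > 200 samples; each burst spans <= 2 ms
        cuts = np.flatnonzero(np.diff(hot) > 200)
        for burst in np.split(hot, cuts + 1):
            assert burst[-1] - burst[0] <= int(0.002 * 44100)


class TestScene:
    def test_fish_only_energy_concentrates_below_1khz(self):
        cfg = synthetic.SceneConfig(
            duration_s=30.0, snap_rate_hz=0.0, fish_call_rate_hz=3.0,
            fish_band=(150.0, 450.0), ambient_level=0.0, seed=2,
        )
        x = rs.highpass(synthetic.scene(cfg), cfg.sample_rate)
        low = _band_energy(x, cfg.sample_rate, 70, 1000)
        total = _band_energy(x, cfg.sample_rate, 70, cfg.sample_rate / 2)
        assert low / total >= 0.9

    def test_boat_scene_much_louder_in_band_than_ambient(self):
        base = synthetic.SceneConfig(
            duration_s=20.0, snap_rate_hz=0.0, fish_call_rate_hz=0.0, seed=3
        )
        quiet = synthetic.scene(base)
        boat = synthetic.scene(
            synthetic.SceneConfig(
                duration_s=20.0, snap_rate_hz=0.0, fish_call_rate_hz=0.0,
                boat_intervals=((0.0, 20.0, 0.25),), seed=3,
            )
        )
        ratio = _band_energy(boat, 44100, 70, 2000) / _band_energy(quiet, 44100, 70, 2000)
        assert ratio > 10

    def test_all_components_zero_is_digital_silence(self):
        cfg = synthetic.SceneConfig(
            duration_s=5.0, snap_rate_hz=0.0, fish_call_rate_hz=0.0,
            ambient_level=0.0, seed=4,
        )
        assert np.all(synthetic.scene(cfg) == 0)

    def test_peak_never_exceeds_one(self):
        cfg = synthetic.SceneConfig(
            duration_s=5.0, snap_rate_hz=500.0, snap_level=1.0, seed=5
        )
        assert np.abs(synthetic.scene(cfg)).max() <= 1.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            synthetic.SceneConfig(fish_band=(500.0, 1500.0))
        with pytest.raises(ValueError):
            synthetic.SceneConfig(rain_intervals=((10.0, 5.0, 1.0),))
        with pytest.raises(ValueError):
            synthetic.SceneConfig(snap_rate_hz=-1.0)


class TestSchedule:
    def _oracle_starts(self, first, hours, cycle_s):
        """Calendar enumeration: starts every cycle from first to first+hours inclusive."""
        starts, t, end = [], first, first + timedelta(hours=hours)
        while t <= end:
            starts.append(t)
            t += timedelta(seconds=cycle_s)
        return starts

    def test_full_duty_cycle_matches_calendar_oracle(self):
        cfg = synthetic.bora_bora_style_config()
        slots = synthetic.enumerate_schedule(cfg)
        assert len(slots) == 1305  # 3 sites x 3 days x 145 files
        first = datetime.combine(cfg.start_date, cfg.first_start)
        oracle = self._oracle_starts(first, 24, 600)
        assert len(oracle) == 145
        one_site_day = [s.start for s in slots if s.site == "quiet" and s.replicate == "1"]
        assert one_site_day == oracle

    def test_hourly_cycle_from_midnight_gives_25_files(self):
        cfg = synthetic.CampaignConfig(
            sites={"only": synthetic.SceneConfig()},
            n_days=1,
            first_start=time(0, 0),
            cycle_period_s=3600,
        )
        assert len(synthetic.enumerate_schedule(cfg)) == 25

    def test_period_labels_follow_sunrise_sunset(self):
        cfg = synthetic.bora_bora_style_config()
        for slot in synthetic.enumerate_schedule(cfg):
            expected = "day" if time(6, 0) <= slot.start.time() < time(18, 0) else "night"
            assert slot.period == expected

    def test_replicates_numbered_by_day(self):
        cfg = synthetic.bora_bora_style_config()
        reps = {s.replicate for s in synthetic.enumerate_schedule(cfg)}
        assert reps == {"1", "2", "3"}


class TestGenerateCampaign:
    def test_metadata_rows_match_files(self, mini_campaign):
        config, csv_path = mini_campaign
        lines = csv_path.read_text().strip().splitlines()
        wavs = sorted(csv_path.parent.glob("*.wav"))
        assert len(lines) - 1 == len(wavs) == len(synthetic.enumerate_schedule(config))
        assert lines[0] == "file,start,site,replicate,period"

    def test_campaign_readable_by_campaign_io(self, mini_campaign):
        _, csv_path = mini_campaign
        entries = rs.read_campaign(csv_path)
        assert all(e.duration == pytest.approx(60.0) for e in entries)
        assert set(entries[0].labels) == {"site", "replicate", "period"}

    def test_byte_identical_regeneration(self, tmp_path):
        cfg = synthetic.CampaignConfig(
            sites={"only": synthetic.SceneConfig()},
            n_days=1,
            schedule_hours=600 / 3600,
            cycle_period_s=600,
            seed=11,
        )
        synthetic.generate_campaign(cfg, tmp_path / "a")
        synthetic.generate_campaign(cfg, tmp_path / "b")
        files_a = sorted((tmp_path / "a").iterdir())
        files_b = sorted((tmp_path / "b").iterdir())
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_rain_event_mapped_into_file_intervals(self):
        cfg = synthetic.CampaignConfig(
            sites={"only": synthetic.SceneConfig()},
            n_days=1,
            schedule_hours=1.0,
            cycle_period_s=600,
            rain_events=[
                (None, datetime(2022, 11, 16, 12, 15, 30), datetime(2022, 11, 16, 12, 25, 30), 0.5)
            ],
        )
        slot = synthetic.enumerate_schedule(cfg)[1]  # starts 12:15
        intervals = synthetic._file_rain_intervals(cfg, slot)
        assert intervals == ((30.0, 60.0, 0.5),)
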