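"""Generator properties: timelines, state-dependent EEG, blink traces."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal

from drowsecov.config import BANDS, SimulationConfig
from drowsecov.synthetic import (
    generate_ear,
    generate_eeg,
    generate_timeline,
)
from drowsecov.types import DROWSY, WAKEFUL


def cfg(**kw):
    base = dict(
        session_length=300.0,
        episode_duration_range_wakeful=(40.0, 70.0),
        episode_duration_range_drowsy=(35.0, 60.0),
        seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestTimeline:
    def test_degenerate_ranges_force_exact_layout(self):
        c = cfg(
            session_length=180.0,
            episode_duration_range_wakeful=(60.0, 60.0),
            episode_duration_range_drowsy=(30.0, 30.0),
        )
        tl = generate_timeline(c)
        assert [(e.start, e.end, e.label) for e in tl] == [
            (0.0, 60.0, 1), (60.0, 90.0, 0), (90.0, 150.0, 1), (150.0, 180.0, 0),
        ]

    def test_deterministic_under_seed(self):
        c = cfg(seed=11)
        a, b = generate_timeline(c), generate_timeline(c)
        assert [(e.start, e.end, e.label) for e in a] == [
            (e.start, e.end, e.label) for e in b
        ]

    @pytest.mark.parametrize("seed", [0, 5, 42])
    def test_alternation_and_coverage(self, seed):
        tl = generate_timeline(cfg(seed=seed))
        labels = tl.labels
        assert np.all(labels[1:] != labels[:-1])
        assert tl.start == 0.0 and tl.end == 300.0
        n_w, n_d = (labels == WAKEFUL).sum(), (labels == DROWSY).sum()
        assert abs(n_w - n_d) <= 1

    def test_session_shorter_than_one_pair_errors(self):
        with pytest.raises(ValueError, match="minimal"):
            generate_timeline(cfg(session_length=50.0))

    @given(
        w_lo=st.floats(20, 60), d_lo=st.floats(20, 60),
        extra=st.floats(0, 60), length=st.floats(150, 400), seed=st.integers(0, 100),
    )
    def test_property_alternation_and_partition(self, w_lo, d_lo, extra, length, seed):
        c = cfg(
            session_length=length,
            episode_duration_range_wakeful=(w_lo, w_lo + extra),
            episode_duration_range_drowsy=(d_lo, d_lo + extra),
            seed=seed,
        )
        tl = generate_timeline(c)
        labels = tl.labels
        assert np.all(labels[1:] != labels[:-1])
        assert tl.start == 0.0
        assert np.isclose(tl.end, length)
        # contiguity is enforced by the container; durations respect minima
        assert all(e.duration >= min(w_lo, d_lo) - 1e-9 for e in tl)


def _state_band_power(eeg, tl, band, label):
    """Welch band power pooled over all samples of one state (PSD oracle)."""
    fs = eeg.fs
    chunks = []
    for e in tl:
        if e.label == label:
            chunks.append(eeg.data[0, int(e.start * fs):int(e.end * fs)])
    x = np.concatenate(chunks)
    f, p = signal.welch(x, fs=fs, nperseg=int(4 * fs))
    mask = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[mask], f[mask])


class TestEeg:
    def test_state_dependent_band_powers(self):
        # drowsy theta weight 2x wakeful, alpha 0.5x; verify by direct PSD
        c = cfg(noise_sd=0.0)
        tl = generate_timeline(c)
        eeg = generate_eeg(tl, c)
        th_d = _state_band_power(eeg, tl, BANDS["theta"], DROWSY)
        th_w = _state_band_power(eeg, tl, BANDS["theta"], WAKEFUL)
        al_d = _state_band_power(eeg, tl, BANDS["alpha"], DROWSY)
        al_w = _state_band_power(eeg, tl, BANDS["alpha"], WAKEFUL)
        assert th_d > 1.5 * th_w
        assert al_w > 1.5 * al_d

    def test_identical_profiles_no_state_difference(self):
        from scipy import stats

        profile = {s: {"delta": 0.6, "theta": 0.5, "alpha": 0.8, "beta": 0.3}
                   for s in ("wakeful", "drowsy")}
        c = cfg(band_power_profile=profile, session_length=600.0, seed=5)
        tl = generate_timeline(c)
        eeg = generate_eeg(tl, c)
        fs = eeg.fs
        per_ep = []
        for e in tl:
            x = eeg.data[0, int(e.start * fs):int(e.end * fs)]
            f, p = signal.welch(x, fs=fs, nperseg=int(2 * fs))
            mask = (f >= 4) & (f <= 7.5)
            per_ep.append((e.label, np.trapezoid(p[mask], f[mask])))
        th_w = [v for lab, v in per_ep if lab == WAKEFUL]
        th_d = [v for lab, v in per_ep if lab == DROWSY]
        _, pval = stats.mannwhitneyu(th_w, th_d)
        assert pval > 0.01

    def test_deterministic_bit_identical(self):
        c = cfg(seed=9)
        tl = generate_timeline(c)
        a, b = generate_eeg(tl, c), generate_eeg(tl, c)
        assert np.array_equal(a.data, b.data)

    def test_all_zero_weights_error(self):
        profile = {
            "wakeful": {"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0},
            "drowsy": {"delta": 0.8, "theta": 0.8, "alpha": 0.5, "beta": 0.3},
        }
        c = cfg(band_power_profile=profile)
        with pytest.raises(ValueError, match="zero"):
            generate_eeg(generate_timeline(c), c)

    def test_recovery_oracle_theta_alpha_ordering(self):
        # noise -> 0: every drowsy episode's theta/alpha ratio beats both
        # adjacent wakeful episodes, on every channel
        c = cfg(noise_sd=0.0, session_length=600.0, seed=2)
        tl = generate_timeline(c)
        eeg = generate_eeg(tl, c)
        fs = eeg.fs
        for ci in range(6):
            ratios = []
            for e in tl:
                x = eeg.data[ci, int(e.start * fs):int(e.end * fs)]
                f, p = signal.welch(x, fs=fs, nperseg=int(2 * fs))
                th = np.trapezoid(p[(f >= 4) & (f <= 7.5)], f[(f >= 4) & (f <= 7.5)])
                al = np.trapezoid(p[(f >= 7.5) & (f <= 15)], f[(f >= 7.5) & (f <= 15)])
                ratios.append(th / al)
            for i, e in enumerate(tl):
                if e.label == DROWSY:
                    if i > 0:
                        assert ratios[i] > ratios[i - 1]
                    if i < len(ratios) - 1:
                        assert ratios[i] > ratios[i + 1]


class TestEar:
    def test_wakeful_rate_zero_baseline_only(self):
        profile = {
            "wakeful": {"rate_per_min": 0.0, "closure_mean_s": 0.2, "closure_sd_s": 0.0},
            "drowsy": {"rate_per_min": 8.0, "closure_mean_s": 2.0, "closure_sd_s": 0.5},
        }
        c = cfg(blink_profile=profile)
        tl = generate_timeline(c)
        ear = generate_ear(tl, c)
        for e in tl:
            if e.label == WAKEFUL:
                seg = ear.values[int(e.start * 30):int(e.end * 30)]
                assert np.all(np.abs(seg - 0.30) < 6 * c.ear_jitter_sd)

    def test_closed_frame_count_matches_profile(self):
        # rate 6/min, closure exactly 2 s -> ~ 6*2*30 closed frames per minute
        profile = {
            "wakeful": {"rate_per_min": 0.0, "closure_mean_s": 0.2, "closure_sd_s": 0.0},
            "drowsy": {"rate_per_min": 6.0, "closure_mean_s": 2.0, "closure_sd_s": 0.0},
        }
        c = cfg(
            blink_profile=profile, ear_jitter_sd=0.0, min_drowsy_closure_s=None,
            session_length=600.0,
            episode_duration_range_wakeful=(60.0, 60.0),
            episode_duration_range_drowsy=(60.0, 60.0),
            seed=4,
        )
        tl = generate_timeline(c)
        ear = generate_ear(tl, c)
        counts = []
        for e in tl:
            if e.label == DROWSY and e.duration == 60.0:
                seg = ear.values[int(e.start * 30):int(e.end * 30)]
                counts.append(np.sum(seg < 0.1))
        expected = 6 * 2.0 * 30  # blinks/min x s x frames/s
        assert abs(np.mean(counts) - expected) < 0.3 * expected

    def test_deterministic(self):
        c = cfg(seed=6)
        tl = generate_timeline(c)
        assert np.array_equal(generate_ear(tl, c).values, generate_ear(tl, c).values)

    def test_rate_times_duration_exceeding_episode_errors(self):
        profile = {
            "wakeful": {"rate_per_min": 15.0, "closure_mean_s": 0.15, "closure_sd_s": 0.0},
            "drowsy": {"rate_per_min": 30.0, "closure_mean_s": 3.0, "closure_sd_s": 0.0},
        }
        c = cfg(blink_profile=profile)
        with pytest.raises(ValueError, match="exceeds"):
            generate_ear(generate_timeline(c), c)

    def test_drowsy_long_closure_guarantee(self):
        profile = {
            "wakeful": {"rate_per_min": 12.0, "closure_mean_s": 0.15, "closure_sd_s": 0.02},
            "drowsy": {"rate_per_min": 4.0, "closure_mean_s": 0.3, "closure_sd_s": 0.05},
        }
        c = cfg(blink_profile=profile, min_drowsy_closure_s=1.0, ear_jitter_sd=0.0)
        tl = generate_timeline(c)
        ear = generate_ear(tl, c)
        for e in tl:
            if e.label == DROWSY:
                seg = ear.values[int(e.start * 30):int(e.end * 30)]
                closed = seg < 0.1
                runs = np.diff(np.flatnonzero(np.diff(
                    np.concatenate([[0], closed.astype(int), [0]])
                )).reshape(-1, 2), axis=1)
                assert runs.max() >= 0.9 * 30  # at least ~1 s closed
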