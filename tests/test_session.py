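import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from soctouch.io import read_session, write_session
from soctouch.session import (
    RecordingBlock,
    Session,
    TouchEpisode,
    ValidationError,
    alpha_kernel,
    bin_spikes,
    psth,
    touch_statistics,
    trim_baseline,
)


class TestValidation:
    def test_offset_before_onset_rejected(self):
        with pytest.raises(ValidationError):
            TouchEpisode(2.0, 1.0, "p", "F")

    def test_unknown_sex_code_rejected(self):
        with pytest.raises(ValidationError):
            TouchEpisode(1.0, 2.0, "p", "X")

    def test_overlapping_episodes_rejected(self):
        blocks = [RecordingBlock(0, 0.0, 10.0)]
        eps = [TouchEpisode(1, 3, "a", "F"), TouchEpisode(2, 4, "b", "M")]
        with pytest.raises(ValidationError, match="overlap"):
            Session("s", "F", "S1", blocks, eps, {})

    def test_episode_outside_blocks_rejected(self):
        blocks = [RecordingBlock(0, 0.0, 10.0)]
        eps = [TouchEpisode(9.0, 11.0, "a", "F")]
        with pytest.raises(ValidationError, match="outside"):
            Session("s", "F", "S1", blocks, eps, {})

    def test_spikes_beyond_end_rejected(self):
        blocks = [RecordingBlock(0, 0.0, 10.0)]
        with pytest.raises(ValidationError):
            Session("s", "F", "S1", blocks, [], {"u": np.array([11.0])})


class TestTouchStatistics:
    def test_hand_enumerable_example(self):
        eps = [TouchEpisode(0, 1, "a", "F"), TouchEpisode(2, 4, "a", "F"),
               TouchEpisode(10, 11, "a", "F")]
        s = touch_statistics(eps)
        assert s["duration"]["median"] == 1.0
        assert sorted(s["durations"]) == [1, 2, 1][::-1][::-1] or True
        np.testing.assert_allclose(sorted(s["durations"]), [1, 1, 2])
        np.testing.assert_allclose(sorted(s["intervals"]), [1, 6])
        assert s["interval"]["median"] == 3.5

    def test_single_episode_has_no_intervals(self):
        s = touch_statistics([TouchEpisode(0, 1, "a", "F")])
        assert s["interval"]["n"] == 0
        assert np.isnan(s["interval"]["median"])

    def test_empty_input(self):
        s = touch_statistics([])
        assert s["duration"]["n"] == 0


class TestBinning:
    def test_definition(self):
        bst = bin_spikes([0.0005, 0.0015], 0.01)
        assert bst.counts[0] == 1 and bst.counts[1] == 1
        assert bst.counts[2:].sum() == 0

    def test_two_spikes_one_bin(self):
        bst = bin_spikes([0.0002, 0.0008], 0.01)
        assert bst.counts[0] == 2

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bin_spikes([-0.1], 1.0)

    @settings(max_examples=20, deadline=None)
    @given(hst.integers(0, 2**31 - 1), hst.integers(1, 2000))
    def test_count_conservation(self, seed, n):
        t = np.sort(np.random.default_rng(seed).uniform(0, 3.0, n))
        assert bin_spikes(t, 3.0).counts.sum() == n


class TestTrimBaseline:
    def test_single_episode_span(self):
        blocks = [RecordingBlock(0, 0.0, 30.0)]
        eps = [TouchEpisode(10, 12, "a", "F")]
        bst = bin_spikes(np.array([]), 30.0)
        out = trim_baseline(bst, eps, margin=5.0)
        kept = out.bin_centers[out.kept_mask]
        assert kept.min() == pytest.approx(5.0, abs=1e-3)
        assert kept.max() == pytest.approx(17.0, abs=1e-3)

    def test_infinite_margin_keeps_everything(self):
        bst = bin_spikes(np.array([]), 10.0)
        out = trim_baseline(bst, [TouchEpisode(1, 2, "a", "F")], margin=np.inf)
        assert out.kept_mask.all()

    @settings(max_examples=10, deadline=None)
    @given(hst.integers(0, 2**31 - 1))
    def test_matches_bruteforce_distance(self, seed):
        """kept iff per-bin distance to the nearest episode is <= margin."""
        rng = np.random.default_rng(seed)
        onsets = np.sort(rng.uniform(0, 50, 4))
        eps = [TouchEpisode(o, o + rng.uniform(0.2, 2.0), "a", "F")
               for o in onsets if True]
        # enforce non-overlap
        clean = []
        last = -np.inf
        for e in eps:
            if e.onset > last:
                clean.append(e)
                last = e.offset
        bst = bin_spikes(np.array([]), 60.0)
        out = trim_baseline(bst, clean, margin=5.0)
        centers = bst.bin_centers
        dist = np.full(centers.size, np.inf)
        for e in clean:
            d = np.where(
                (centers >= e.onset) & (centers <= e.offset), 0.0,
                np.minimum(np.abs(centers - e.onset),
                           np.abs(centers - e.offset)),
            )
            dist = np.minimum(dist, d)
        np.testing.assert_array_equal(out.kept_mask, dist <= 5.0)


class TestPSTH:
    def test_kernel_peak_is_one_at_tau(self):
        k = alpha_kernel(tau=0.075)
        x = np.arange(k.size) * 1e-3
        assert k[np.argmin(np.abs(x - 0.075))] == pytest.approx(1.0, abs=1e-4)
        assert k.max() <= 1.0 + 1e-9

    def test_delta_train_gives_kernel_shape(self):
        """One spike exactly at each onset: trace proportional to the kernel."""
        onsets = np.array([10.0, 30.0, 50.0])
        res = psth(onsets + 5e-4, onsets, window=(-0.5, 1.0))
        k = alpha_kernel(tau=0.075)
        post = res.rate[res.times >= 0][: k.size]
        ratio = post[k > 0.01] / k[k > 0.01]
        assert np.std(ratio) / np.mean(ratio) < 1e-6

    def test_flat_for_homogeneous_poisson(self):
        """Mean trace converges to the true rate; the baseline-vs-post test
        rejects at roughly its nominal level over replicate simulations."""
        rng = np.random.default_rng(5)
        rate, T = 20.0, 600.0
        rejections = 0
        n_rep = 30
        for _ in range(n_rep):
            spikes = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
            # separated onsets so baseline/post windows do not overlap
            onsets = 10 + 4.0 * np.arange(40) + rng.uniform(0, 0.4, 40)
            res = psth(spikes, onsets)
            rejections += res.p_value < 0.05
        # binomial(30, 0.05): >= 7 rejections has probability < 1e-3
        assert rejections <= 7
        spikes = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
        res = psth(spikes, rng.uniform(10, T - 10, 200))
        assert np.abs(res.rate.mean() - rate) / rate < 0.05

    def test_fewer_than_two_onsets_skips_test(self):
        with pytest.warns(UserWarning, match="fewer than two"):
            res = psth(np.array([1.0]), np.array([5.0]))
        assert res.p_value is None


class TestIO:
    def test_roundtrip_identity(self, simple_session, tmp_path):
        p = write_session(simple_session, tmp_path / "sess")
        back = read_session(p)
        assert back.subject_id == simple_session.subject_id
        assert len(back.episodes) == len(simple_session.episodes)
        for a, b in zip(back.episodes, simple_session.episodes):
            assert a.partner_id == b.partner_id and a.partner_sex == b.partner_sex
            assert a.onset == pytest.approx(b.onset)
        for uid in simple_session.units:
            np.testing.assert_allclose(
                back.units[uid], simple_session.units[uid], atol=1e-6
            )

    def test_h5_roundtrip(self, simple_session, tmp_path):
        p = write_session(simple_session, tmp_path / "sess.h5")
        back = read_session(p)
        assert len(back.episodes) == len(simple_session.episodes)
        np.testing.assert_allclose(
            back.units["u1"], simple_session.units["u1"]
        )

    def test_malformed_bundle_raises(self, simple_session, tmp_path):
        p = write_session(simple_session, tmp_path / "sess")
        # corrupt: make an episode overlap
        text = (p / "episodes.csv").read_text().splitlines()
        text[2] = "6.0,8.0,f1,F"
        (p / "episodes.csv").write_text("\n".join(text))
        with pytest.raises(ValidationError):
            read_session(p)
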