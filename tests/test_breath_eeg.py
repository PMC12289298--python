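"""Breath-monitoring neural analysis: RT split, epoching, power, inversion."""

import numpy as np
import pytest

from dyadmind.breath_eeg import (
    BreathSeries,
    EEGRecording,
    NetworkROISet,
    alpha_power,
    consistency_differential,
    epoch_eeg,
    make_inverse,
    network_activity,
    prepost_contrast,
    split_consistency,
    taps_to_rts,
)


def _brute_force_split(rts):
    """Independent oracle: sort-based median/MAD and per-element comparison."""
    srt = sorted(rts)
    n = len(srt)
    med = (srt[n // 2] if n % 2 else 0.5 * (srt[n // 2 - 1] + srt[n // 2]))
    devs = sorted(abs(x - med) for x in rts)
    mad = (devs[n // 2] if n % 2 else 0.5 * (devs[n // 2 - 1] + devs[n // 2]))
    return ["high" if abs(x - med) <= mad else "low" for x in rts]


class TestTapsToRts:
    def test_uniform_taps(self):
        series = BreathSeries(blocks=(np.array([8.0, 16.0, 24.0]),))
        assert taps_to_rts(series).tolist() == [8.0, 8.0]

    def test_no_cross_block_interval(self):
        series = BreathSeries(blocks=(np.array([10.0, 20.0]), np.array([5.0, 15.0])))
        assert taps_to_rts(series).tolist() == [10.0, 10.0]

    def test_short_block_warns_and_skips(self):
        series = BreathSeries(blocks=(np.array([3.0]), np.array([1.0, 2.0])))
        with pytest.warns(UserWarning, match="fewer than 2 taps"):
            assert taps_to_rts(series).tolist() == [1.0]

    def test_non_monotone_taps_rejected(self):
        with pytest.raises(ValueError):
            BreathSeries(blocks=(np.array([2.0, 1.0]),))


class TestSplitConsistency:
    @pytest.mark.parametrize(
        "rts,labels",
        [
            ([2, 2, 2, 2, 10], ["high", "high", "high", "high", "low"]),
            ([6, 7, 8, 9, 20], ["low", "high", "high", "high", "low"]),
        ],
    )
    def test_hand_computed(self, rts, labels):
        assert split_consistency(rts).labels.tolist() == labels

    def test_constant_all_high_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            split = split_consistency([5.0] * 6)
        assert split.labels.tolist() == ["high"] * 6

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            rts = rng.exponential(4.0, size=rng.integers(4, 40)) + 1.0
            assert split_consistency(rts).labels.tolist() == _brute_force_split(rts.tolist())

    def test_shift_and_scale_invariance(self, rng):
        rts = rng.normal(8, 1, 30) ** 2 / 8 + 2
        base = split_consistency(rts).labels
        assert (split_consistency(rts + 100).labels == base).all()
        assert (split_consistency(rts * 7.3).labels == base).all()

    def test_literal_one_sided_rule(self):
        # a very fast tap is "high consistency" only under the literal rule
        rts = [2.0, 6.0, 7.0, 8.0, 9.0]
        assert split_consistency(rts, two_sided=True).labels[0] == "low"
        assert split_consistency(rts, two_sided=False).labels[0] == "high"

    def test_too_few_rts_rejected(self):
        with pytest.raises(ValueError):
            split_consistency([1.0, 2.0, 3.0])


class TestEpochEEG:
    def _eeg(self, n_samples=5000, fs=500.0, taps=(10.0,)):
        data = np.arange(2 * n_samples, dtype=float).reshape(2, n_samples)
        return EEGRecording(
            blocks=(data,), fs=fs, channel_labels=("a", "b"), tap_times=(np.array(taps),)
        )

    def test_sample_index_arithmetic(self):
        eeg = self._eeg()
        epochs, kept, dropped = epoch_eeg(eeg)
        assert epochs.shape == (1, 2, 2000)
        assert dropped == 0
        np.testing.assert_array_equal(epochs[0, 0], np.arange(3000, 5000, dtype=float))

    def test_insufficient_support_dropped_and_counted(self):
        eeg = self._eeg(taps=(2.0, 3.9, 10.0, 8.0001))
        epochs, kept, dropped = epoch_eeg(eeg)
        assert dropped == 2  # taps at 2.0 and 3.9 start before the block
        assert len(kept) == 2

    def test_no_valid_epochs_is_an_error(self):
        with pytest.raises(ValueError):
            epoch_eeg(self._eeg(taps=(1.0,)))


class TestAlphaPower:
    def test_spectral_concentration_of_alpha_sinusoid(self):
        fs, t = 250.0, np.arange(0, 4, 1 / 250.0)
        x = np.sin(2 * np.pi * 10 * t)
        assert alpha_power(x, fs) >= 10 * alpha_power(x, fs, band=(16, 20))

    def test_white_noise_band_share(self, rng):
        fs = 250.0
        epochs = rng.standard_normal((100, int(4 * fs)))
        # flat spectrum: mean PSD in any band ~ total variance / Nyquist
        expected = 1.0 / (fs / 2)
        assert alpha_power(epochs, fs).mean() == pytest.approx(expected, rel=0.2)

    def test_quadratic_amplitude_scaling(self):
        fs, t = 250.0, np.arange(0, 4, 1 / 250.0)
        x = np.sin(2 * np.pi * 10 * t)
        assert alpha_power(2 * x, fs) == pytest.approx(4 * alpha_power(x, fs), rel=0.01)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            alpha_power(np.zeros(500), fs=100.0, band=(40, 60))


class TestMakeInverse:
    def test_identity_roundtrip(self):
        np.testing.assert_allclose(make_inverse(np.eye(5), lam=0), np.eye(5), atol=1e-12)

    def test_orthonormal_columns_recover_single_source(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((10, 4)))
        src = np.zeros(4)
        src[2] = 1.7
        recovered = make_inverse(q, lam=1e-12) @ (q @ src)
        np.testing.assert_allclose(recovered, src, atol=1e-10)

    def test_regularization_shrinks_monotonically(self, rng):
        L = rng.standard_normal((6, 4))
        norms = [np.linalg.norm(make_inverse(L, lam=lam)) for lam in (0.1, 1.0, 10.0, 100.0)]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_singular_system_requires_regularization(self):
        L = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            make_inverse(L, lam=0)


class TestNetworkActivity:
    def _epochs_with_source(self, lead_field, source_idx, fs=250.0, n_trials=6,
                            amp=3.0, noise=0.1, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, 4, 1 / fs)
        epochs = []
        for _ in range(n_trials):
            src = np.zeros((lead_field.matrix.shape[1], t.size))
            src[source_idx] = amp * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
            epochs.append(lead_field.matrix @ src + noise * rng.standard_normal((24, t.size)))
        return np.stack(epochs), 250.0

    def test_dmn_injection_recovered_on_every_trial(self, lead_field, roi_set):
        dmn_idx = lead_field.source_labels.index("DMN_PCC")
        epochs, fs = self._epochs_with_source(lead_field, dmn_idx)
        inverse = make_inverse(lead_field.matrix)
        act = network_activity(epochs, inverse, roi_set, lead_field.source_labels, fs=fs)
        assert (act.power["DMN"] > act.power["FPN"]).all()
        assert (act.power["DMN"] > act.power["CON"]).all()

    def test_noise_floor_symmetric_across_networks(self, lead_field, roi_set, rng):
        epochs = rng.standard_normal((40, 24, 1000))
        inverse = make_inverse(lead_field.matrix)
        act = network_activity(epochs, inverse, roi_set, lead_field.source_labels, fs=250.0)
        means = act.power.mean()
        assert means.max() / means.min() == pytest.approx(1.0, abs=0.1)

    def test_quadratic_scaling(self, lead_field, roi_set, rng):
        epochs = rng.standard_normal((5, 24, 1000))
        inverse = make_inverse(lead_field.matrix)
        a1 = network_activity(epochs, inverse, roi_set, lead_field.source_labels, fs=250.0)
        a2 = network_activity(2 * epochs, inverse, roi_set, lead_field.source_labels, fs=250.0)
        np.testing.assert_allclose(a2.power.to_numpy(), 4 * a1.power.to_numpy(), rtol=1e-10)

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="multiple networks"):
            NetworkROISet(rois={"FPN": ("s1",), "DMN": ("s1", "s2")})


class TestConsistencyDifferential:
    def _split(self, labels):
        rts = np.where(np.array(labels) == "low", 12.0, 8.0) + np.arange(len(labels)) * 1e-3
        return split_consistency(rts)

    def test_identical_activity_gives_zero(self):
        import pandas as pd

        from dyadmind.breath_eeg import NetworkActivity
        act = NetworkActivity(power=pd.DataFrame({"FPN": [2.0] * 6, "DMN": [3.0] * 6, "CON": [1.0] * 6}))
        split = self._split(["low", "high", "high", "high", "high", "low"])
        diff = consistency_differential(act, split)
        assert all(v == 0 for v in diff.values())

    def test_antisymmetric_under_label_swap(self, rng):
        import pandas as pd

        from dyadmind.breath_eeg import ConsistencySplit, NetworkActivity
        power = pd.DataFrame(rng.random((8, 3)), columns=["FPN", "CON", "DMN"])
        labels = np.array(["low", "high"] * 4)
        rts = rng.random(8)
        fwd = ConsistencySplit(rts=rts, median=0, mad=0, labels=labels)
        swapped = ConsistencySplit(rts=rts, median=0, mad=0,
                                   labels=np.where(labels == "low", "high", "low"))
        d1 = consistency_differential(NetworkActivity(power=power), fwd)
        d2 = consistency_differential(NetworkActivity(power=power), swapped)
        for net in d1:
            assert d1[net] == pytest.approx(-d2[net])

    def test_permutation_null_centered_on_zero(self, rng):
        import pandas as pd

        from dyadmind.breath_eeg import ConsistencySplit, NetworkActivity
        power = pd.DataFrame({"DMN": rng.random(30)})
        labels = np.array(["low"] * 10 + ["high"] * 20)
        diffs = []
        for _ in range(200):
            perm = rng.permutation(labels)
            split = ConsistencySplit(rts=np.zeros(30), median=0, mad=0, labels=perm)
            diffs.append(consistency_differential(NetworkActivity(power=power), split)["DMN"])
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_empty_class_is_an_error(self):
        import pandas as pd

        from dyadmind.breath_eeg import ConsistencySplit, NetworkActivity
        act = NetworkActivity(power=pd.DataFrame({"DMN": [1.0] * 4}))
        split = ConsistencySplit(rts=np.zeros(4), median=0, mad=0, labels=np.array(["high"] * 4))
        with pytest.raises(ValueError, match="empty"):
            consistency_differential(act, split)


class TestPrepostContrast:
    def test_no_change_is_nonsignificant(self):
        vals = {f"p{i}": {"DMN": 0.5 + 0.01 * i, "FPN": 0.2} for i in range(8)}
        out = prepost_contrast(vals, vals)
        assert (out["mean_change"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_missing_participants_dropped_listwise(self):
        pre = {f"p{i}": {"DMN": float(i)} for i in range(8)}
        post = {f"p{i}": {"DMN": float(i) - 1.0 - 0.1 * i} for i in range(6)}
        out = prepost_contrast(pre, post)
        assert out.loc["DMN", "n"] == 6
        assert out.loc["DMN", "n_dropped"] == 2
        # consistent decrease: best attainable one-sided p at n=6
        assert out.loc["DMN", "p"] < 0.05

    def test_too_few_pairs_refused(self):
        vals = {f"p{i}": {"DMN": float(i)} for i in range(3)}
        with pytest.raises(ValueError, match="fewer than 4"):
            prepost_contrast(vals, vals)
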