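import numpy as np
import pytest

from fcnm.preprocess import (
    MotionTrace,
    build_nuisance_design,
    bandpass,
    discard_initial_volumes,
    framewise_displacement,
    friston24,
    motion_qc,
    nuisance_regress,
    spike_regressors,
)
from fcnm.volumes import BinaryMask, Volume4D


def trace(T=20, **kw):
    return MotionTrace(np.zeros((T, 3)), np.zeros((T, 3)))


class TestDiscard:
    def test_drops_initial_volumes(self, rng):
        vol = Volume4D(rng.standard_normal((3, 3, 3, 120)), np.eye(4))
        out = discard_initial_volumes(vol, 10)
        assert out.n_volumes == 110
        np.testing.assert_array_equal(out.data, vol.data[..., 10:])

    def test_discard_zero_is_identity(self, rng):
        vol = Volume4D(rng.standard_normal((2, 2, 2, 40)), np.eye(4))
        np.testing.assert_array_equal(discard_initial_volumes(vol, 0).data, vol.data)

    def test_too_few_volumes(self, rng):
        # guard uses T >= 30 at construction, so build a longer run and
        # discard everything
        vol = Volume4D(rng.standard_normal((2, 2, 2, 30)), np.eye(4))
        with pytest.raises(ValueError):
            discard_initial_volumes(vol, 30)


class TestMotionQC:
    def test_zero_trace_passes(self):
        ok, frames = motion_qc(trace())
        assert ok and frames.size == 0

    def test_excessive_translation_fails_and_lists_frame(self):
        t = np.zeros((20, 3))
        t[7, 0] = 2.5
        ok, frames = motion_qc(MotionTrace(t, np.zeros((20, 3))))
        assert not ok
        assert list(frames) == [7]

    def test_rotation_exactly_at_limit_passes(self):
        r = np.zeros((20, 3))
        r[3, 1] = np.deg2rad(2.0)  # exactly 2 degrees: strict "exceeding"
        ok, _ = motion_qc(MotionTrace(np.zeros((20, 3)), r))
        assert ok


class TestFD:
    def test_constant_motion_gives_zero_fd(self):
        t = np.ones((15, 3)) * 0.7
        fd = framewise_displacement(MotionTrace(t, np.ones((15, 3)) * 0.01))
        np.testing.assert_allclose(fd, 0.0)

    def test_one_mm_translation_step(self):
        t = np.zeros((10, 3))
        t[5:, 0] = 1.0
        fd = framewise_displacement(MotionTrace(t, np.zeros((10, 3))))
        assert fd[5] == pytest.approx(1.0)
        assert fd[0] == 0.0
        assert np.count_nonzero(fd) == 1

    def test_rotation_step_scaled_by_head_radius(self):
        r = np.zeros((10, 3))
        r[4:, 2] = 0.02  # radians; 50 mm * 0.02 = 1.0 mm
        fd = framewise_displacement(MotionTrace(np.zeros((10, 3)), r))
        assert fd[4] == pytest.approx(1.0)

    def test_offset_invariance(self, rng):
        t = rng.standard_normal((30, 3)) * 0.1
        r = rng.standard_normal((30, 3)) * 0.002
        fd1 = framewise_displacement(MotionTrace(t, r))
        fd2 = framewise_displacement(MotionTrace(t + 5.0, r + 0.3))
        np.testing.assert_allclose(fd1, fd2, atol=1e-12)


class TestFriston24:
    def test_zero_trace_gives_zero_matrix(self):
        np.testing.assert_array_equal(friston24(trace()), np.zeros((20, 24)))

    def test_hand_expansion_single_parameter(self):
        t = np.zeros((3, 3))
        t[:, 0] = [1.0, 2.0, 3.0]
        out = friston24(MotionTrace(t, np.zeros((3, 3))))
        np.testing.assert_allclose(out[:, 0], [1, 2, 3])       # p
        np.testing.assert_allclose(out[:, 6], [0, 1, 2])       # lag, row 0 zeroed
        np.testing.assert_allclose(out[:, 12], [1, 4, 9])      # p^2
        np.testing.assert_allclose(out[:, 18], [0, 1, 4])      # lag^2

    @pytest.mark.parametrize("T", [2, 5, 50])
    def test_shape(self, T):
        out = friston24(MotionTrace(np.zeros((T, 3)), np.zeros((T, 3))))
        assert out.shape == (T, 24)


class TestSpikes:
    def test_no_spikes_gives_zero_columns(self):
        assert spike_regressors(np.full(20, 0.3)).shape == (20, 0)

    def test_fd_exactly_at_threshold_not_flagged(self):
        fd = np.zeros(10)
        fd[4] = 0.5
        assert spike_regressors(fd, 0.5).shape[1] == 0

    def test_two_spikes_give_two_one_hot_columns(self):
        fd = np.zeros(20)
        fd[[6, 13]] = 0.8
        out = spike_regressors(fd)
        assert out.shape == (20, 2)
        np.testing.assert_array_equal(out.sum(axis=0), [1, 1])
        assert out[6, 0] == 1 and out[13, 1] == 1


class TestDesign:
    def make_design(self, T=30, gsr=True, fd=None):
        m = trace(T)
        if fd is None:
            fd = np.zeros(T)
        return build_nuisance_design(
            m, fd, np.zeros(T), np.zeros(T), np.zeros(T), include_gsr=gsr
        )

    def test_column_arithmetic_with_gsr(self):
        assert self.make_design(gsr=True).matrix.shape[1] == 29

    def test_column_arithmetic_without_gsr(self):
        assert self.make_design(gsr=False).matrix.shape[1] == 28

    def test_spike_columns_added(self):
        fd = np.zeros(30)
        fd[10] = 1.0
        design = self.make_design(fd=fd)
        assert design.matrix.shape[1] == 30
        assert "spike_10" in design.column_labels

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_nuisance_design(
                trace(30), np.zeros(30), np.zeros(29), np.zeros(30), np.zeros(30)
            )


class TestRegression:
    def test_residuals_orthogonal_to_design(self, rng):
        T = 60
        m = MotionTrace(rng.standard_normal((T, 3)) * 0.02,
                        rng.standard_normal((T, 3)) * 0.0005)
        fd = framewise_displacement(m)
        design = build_nuisance_design(
            m, fd, rng.standard_normal(T), rng.standard_normal(T), rng.standard_normal(T)
        )
        vol = Volume4D(rng.standard_normal((4, 4, 4, T)), np.eye(4))
        resid = nuisance_regress(vol, design)
        dots = np.einsum("tk,xyzt->k", design.matrix, resid.data) / T
        assert np.abs(dots).max() < 1e-8

    def test_constant_only_design_demeans(self, rng):
        from fcnm.preprocess import NuisanceDesign

        T = 40
        vol = Volume4D(rng.standard_normal((3, 3, 3, T)) + 7.0, np.eye(4))
        design = NuisanceDesign(np.ones((T, 1)), ["constant"])
        out = nuisance_regress(vol, design)
        expected = vol.data - vol.data.mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_recovers_noise_when_series_is_scaled_regressor(self, rng):
        from fcnm.preprocess import NuisanceDesign

        T = 200
        reg = rng.standard_normal(T)
        noise = rng.standard_normal(T) * 0.5
        data = np.zeros((1, 1, 1, T))
        data[0, 0, 0] = 2.0 * reg + noise
        design = NuisanceDesign(np.c_[np.ones(T), reg], ["constant", "reg"])
        resid = nuisance_regress(Volume4D(data, np.eye(4)), design).data[0, 0, 0]
        r = np.corrcoef(resid, noise)[0, 1]
        assert r > 0.99

    def test_projection_idempotent(self, rng):
        T = 50
        m = trace(T)
        design = build_nuisance_design(
            m, np.zeros(T), rng.standard_normal(T),
            rng.standard_normal(T), rng.standard_normal(T)
        )
        vol = Volume4D(rng.standard_normal((3, 3, 3, T)), np.eye(4))
        with pytest.warns(UserWarning):  # Friston-24 of a zero trace is rank-deficient
            once = nuisance_regress(vol, design)
            twice = nuisance_regress(once, design)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-8)


class TestBandpass:
    def sine_vol(self, freq, T=200, tr=2.0):
        t = np.arange(T) * tr
        data = np.zeros((1, 1, 1, T))
        data[0, 0, 0] = np.sin(2 * np.pi * freq * t)
        return Volume4D(data, np.eye(4), tr_seconds=tr)

    def amplitude_ratio(self, vol, out, freq):
        spec_in = np.abs(np.fft.rfft(vol.data[0, 0, 0]))
        spec_out = np.abs(np.fft.rfft(out.data[0, 0, 0]))
        bin_ = np.argmin(np.abs(np.fft.rfftfreq(vol.n_volumes, vol.tr_seconds) - freq))
        return spec_out[bin_] / spec_in[bin_]

    def test_passband_sine_preserved(self):
        vol = self.sine_vol(0.05)
        assert self.amplitude_ratio(vol, bandpass(vol), 0.05) >= 0.95

    def test_stopband_sine_rejected(self):
        vol = self.sine_vol(0.2)
        assert self.amplitude_ratio(vol, bandpass(vol), 0.2) <= 0.05

    def test_constant_series_zeroed(self):
        vol = Volume4D(np.full((2, 2, 2, 64), 5.0), np.eye(4), tr_seconds=2.0)
        np.testing.assert_allclose(bandpass(vol).data, 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        vol = Volume4D(rng.standard_normal((2, 2, 2, 100)), np.eye(4), tr_seconds=2.0)
        once = bandpass(vol)
        twice = bandpass(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-10)

    def test_band_above_nyquist_rejected(self, rng):
        vol = Volume4D(rng.standard_normal((1, 1, 1, 50)), np.eye(4), tr_seconds=6.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(vol, 0.01, 0.1)
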