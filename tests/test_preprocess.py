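import numpy as np
import pytest
from scipy import signal

from dyadnirs.preprocess import (
    ArtifactRemovalConfig,
    FilterSpec,
    MbllParams,
    bandpass_filter,
    mbll_convert,
    mbll_forward,
    normalize_and_baseline,
    resample_to_1hz,
    wavelet_artifact_removal,
)
from dyadnirs.session import HbTimeSeries, ODRecording, SessionEvents
from dyadnirs.simulate import generate_spike_fixture


def _od(od, fs=100.0):
    return ODRecording("p", "initial_provider", od, fs)


def _hb(values, fs=100.0, state=("converted",), chrom="HbO"):
    return HbTimeSeries("p", chrom, values, fs, state=tuple(state))


class TestMbll:
    def test_zero_od_gives_zero_concentrations(self):
        hbo, hbr = mbll_convert(_od(np.zeros((100, 2))))
        assert np.all(hbo.values == 0) and np.all(hbr.values == 0)
        assert hbo.state == ("converted",)

    def test_forward_inverse_round_trip(self, rng):
        params = MbllParams()
        hbo_true = rng.standard_normal(1000)
        hbr_true = rng.standard_normal(1000)
        od = mbll_forward(hbo_true, hbr_true, params)
        hbo, hbr = mbll_convert(_od(od), params)
        np.testing.assert_allclose(hbo.values, hbo_true, atol=1e-10)
        np.testing.assert_allclose(hbr.values, hbr_true, atol=1e-10)

    def test_round_trip_any_invertible_matrix(self, rng):
        for _ in range(5):
            E = rng.uniform(0.2, 2.0, size=(2, 2))
            if abs(np.linalg.det(E)) < 0.05:
                continue
            params = MbllParams(extinction=E, dpf=(5.0, 7.0), separation=2.5)
            conc = rng.standard_normal((50, 2))
            od = mbll_forward(conc[:, 0], conc[:, 1], params)
            hbo, hbr = mbll_convert(_od(od), params)
            np.testing.assert_allclose(hbo.values, conc[:, 0], atol=1e-10)
            np.testing.assert_allclose(hbr.values, conc[:, 1], atol=1e-10)

    def test_length_and_rate_preserved(self):
        hbo, hbr = mbll_convert(_od(np.ones((6000, 2)), fs=100.0))
        assert hbo.n_samples == hbr.n_samples == 6000
        assert hbo.sample_rate == 100.0

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError):
            MbllParams(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))


class TestArtifactRemoval:
    def test_constant_series_unchanged(self):
        x = _hb(np.full(4096, 3.7))
        out = wavelet_artifact_removal(x)
        np.testing.assert_allclose(out.values, x.values, atol=1e-10)
        assert out.state == ("converted", "artifact_removed")

    def test_spike_suppressed_on_clean_sinusoid(self):
        t = np.arange(60000) / 100.0
        clean = np.sin(2 * np.pi * 0.05 * t)
        contaminated = clean.copy()
        tau = 20.0
        profile = np.exp(-np.arange(600) / tau)
        contaminated[30000:30600] += 10 * clean.std() * profile
        out = wavelet_artifact_removal(_hb(contaminated))
        before = np.max(np.abs(contaminated - clean))
        after = np.max(np.abs(out.values - clean))
        assert after <= 0.1 * before

    def test_alpha_near_one_removes_detail(self, rng):
        x = _hb(rng.standard_normal(4096))
        out = wavelet_artifact_removal(x, ArtifactRemovalConfig(alpha=0.999))
        # nearly all detail energy removed: result close to coarse trend
        assert np.var(out.values) < 0.05 * np.var(x.values)

    def test_never_increases_rmse_on_spike_fixtures(self):
        for seed in range(30):
            clean, contaminated = generate_spike_fixture(seed, duration=120.0)
            out = wavelet_artifact_removal(contaminated)
            rmse_before = np.sqrt(np.mean((contaminated.values - clean.values) ** 2))
            rmse_after = np.sqrt(np.mean((out.values - clean.values) ** 2))
            assert rmse_after <= rmse_before

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            wavelet_artifact_removal(_hb(np.zeros(4)), ArtifactRemovalConfig(levels=8))


class TestBandpass:
    def test_zero_series_maps_to_zero(self):
        x = _hb(np.zeros(60000), state=("converted", "artifact_removed"))
        out = bandpass_filter(x)
        assert np.allclose(out.values, 0.0)
        assert out.state[-1] == "filtered"

    @pytest.mark.parametrize(
        "freq, lo, hi",
        [(0.05, 0.95, 1.0), (1.0, 0.0, 0.01)],
    )
    def test_gain_matches_analytic_squared_response(self, freq, lo, hi):
        fs = 100.0
        t = np.arange(int(3000 * fs)) / fs
        x = _hb(np.sin(2 * np.pi * freq * t), state=("converted", "artifact_removed"))
        out = bandpass_filter(x)
        core = slice(int(500 * fs), int(2500 * fs))  # avoid filter edge transients
        gain = np.sqrt(2) * out.values[core].std()
        assert lo <= gain <= hi
        sos = FilterSpec().sos(fs)
        _, h = signal.sosfreqz(sos, worN=[2 * np.pi * freq / fs])
        assert gain == pytest.approx(np.abs(h[0]) ** 2, abs=1e-3)

    def test_output_mean_near_zero(self, rng):
        x = _hb(rng.standard_normal(60000) + 5.0,
                state=("converted", "artifact_removed"))
        out = bandpass_filter(x)
        # DC (mean 5.0) is attenuated by >2 orders of magnitude; only
        # filter edge transients remain
        assert abs(out.values.mean()) < 0.05

    def test_high_cut_above_nyquist_rejected(self):
        x = _hb(np.zeros(1000), fs=0.15, state=("converted", "artifact_removed"))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(x)


class TestNormalizeBaseline:
    def _events(self):
        return SessionEvents(baseline=(0, 300),
                             phases=[("single_provider", 300, 600)])

    def test_baseline_mean_zero_and_unit_sd(self, rng):
        state = ("converted", "artifact_removed", "filtered")
        x = _hb(rng.standard_normal(60000), state=state)
        out = normalize_and_baseline(x, self._events())
        t = out.times()
        mask = (t >= 0) & (t < 300)
        assert abs(out.values[mask].mean()) < 1e-10
        # pre-baseline-shift z-scored series has unit SD; the shift
        # preserves it
        assert out.values.std() == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self, rng):
        state = ("converted", "artifact_removed", "filtered")
        base = rng.standard_normal(60000)
        out1 = normalize_and_baseline(_hb(base, state=state), self._events())
        out2 = normalize_and_baseline(_hb(3.5 * base + 17.0, state=state),
                                      self._events())
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-10)

    def test_flat_series_rejected(self):
        state = ("converted", "artifact_removed", "filtered")
        with pytest.raises(ValueError, match="variance"):
            normalize_and_baseline(_hb(np.ones(60000), state=state), self._events())


class TestResample:
    STATE = ("converted", "artifact_removed", "filtered", "normalized",
             "baseline_subtracted")

    def test_constant_series(self):
        out = resample_to_1hz(_hb(np.full(6000, 2.5), state=self.STATE))
        assert out.sample_rate == 1.0
        np.testing.assert_allclose(out.values, 2.5)
        assert out.n_samples == 60

    def test_sinusoid_matches_block_integral(self):
        f, fs = 0.05, 100.0
        t = np.arange(60000) / fs
        out = resample_to_1hz(_hb(np.sin(2 * np.pi * f * t), state=self.STATE))
        # mean of sin over [k, k+1) s, discretized at 100 Hz
        k = np.arange(600)
        w = 2 * np.pi * f
        expected = np.array([
            np.mean(np.sin(w * (kk + np.arange(100) / fs))) for kk in k
        ])
        np.testing.assert_allclose(out.values, expected, atol=1e-6)

    def test_partial_trailing_block_dropped(self, caplog):
        out = resample_to_1hz(_hb(np.ones(6050), state=self.STATE))
        assert out.n_samples == 60

    def test_non_integer_rate_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            resample_to_1hz(_hb(np.ones(100), fs=2.5, state=self.STATE))


class TestPipelineOrder:
    def test_out_of_order_step_raises(self, rng):
        x = _hb(rng.standard_normal(4096), state=())
        with pytest.raises(RuntimeError, match="pipeline-order"):
            wavelet_artifact_removal(x)  # not yet converted
        y = _hb(rng.standard_normal(4096), state=("converted",))
        with pytest.raises(RuntimeError, match="pipeline-order"):
            bandpass_filter(y)  # artifact removal skipped

    def test_repeated_step_raises(self, rng):
        x = _hb(rng.standard_normal(4096))
        once = wavelet_artifact_removal(x)
        with pytest.raises(RuntimeError, match="pipeline-order"):
            wavelet_artifact_removal(once)

    def test_filter_normalize_commute_up_to_affine(self, rng):
        """Filtering then z-scoring equals z-scoring then filtering up to
        an affine map, because both operations are linear."""
        events = SessionEvents(baseline=(0, 300),
                               phases=[("single_provider", 300, 600)])
        base = rng.standard_normal(60000)
        state = ("converted", "artifact_removed")
        filtered = bandpass_filter(_hb(base, state=state))
        a = normalize_and_baseline(filtered, events).values
        z = (base - base.mean()) / base.std()
        zf = signal.sosfiltfilt(FilterSpec().sos(100.0), z)
        # both are affine images of the filtered series: standardizing
        # each must give the same signal
        sa = (a - a.mean()) / a.std()
        sz = (zf - zf.mean()) / zf.std()
        np.testing.assert_allclose(sa, sz, atol=1e-9)
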