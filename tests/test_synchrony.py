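import numpy as np
import pytest

from dyadnirs.session import SessionEvents
from dyadnirs.synchrony import (
    CoherenceField,
    WaveletParams,
    band_mean_coherence,
    baseline_adjusted_wtc,
    cwt_morlet,
    wtc,
)
from dyadnirs.windows import AnalysisWindow

from conftest import series_1hz


def _noise_series(rng, n=900, **kw):
    return series_1hz(rng.standard_normal(n), **kw)


class TestCwt:
    def test_zero_series_gives_zero_coefficients(self):
        W = cwt_morlet(series_1hz(np.zeros(600)))
        assert np.allclose(W, 0.0)

    def test_power_peaks_at_matching_fourier_period(self):
        params = WaveletParams()
        t = np.arange(1200.0)
        x = series_1hz(np.sin(2 * np.pi * t / 20.0))
        W = cwt_morlet(x, params)
        power = np.abs(W[:, 400:800]) ** 2  # central region, no edge effects
        peak = params.periods()[np.argmax(power.mean(axis=1))]
        step = 2 ** (1 / params.voices_per_octave)
        assert 20.0 / step <= peak <= 20.0 * step

    def test_modulus_shift_invariant_for_periodic_input(self):
        params = WaveletParams()
        t = np.arange(1024.0)
        base = np.sin(2 * np.pi * t / 32.0)
        shifted = np.sin(2 * np.pi * (t + 8) / 32.0)
        W1 = np.abs(cwt_morlet(series_1hz(base), params))
        W2 = np.abs(cwt_morlet(series_1hz(shifted), params))
        core = slice(300, 700)
        i = np.argmin(np.abs(params.periods() - 32.0))
        np.testing.assert_allclose(W1[i, core], W2[i, core], rtol=0.02)

    def test_fourier_factor(self):
        # period of scale s is 4*pi*s / (w0 + sqrt(2 + w0^2)) ~ 1.033 s for w0=6
        assert WaveletParams().fourier_factor == pytest.approx(1.0330, abs=1e-4)

    def test_scale_grid_covers_band(self):
        periods = WaveletParams().periods()
        assert periods.min() <= 10.0 and periods.max() >= 100.0


class TestWtc:
    def test_self_coherence_is_one_inside_coi(self, rng):
        x = _noise_series(rng)
        f = wtc(x, x)
        mask = f.valid_mask() & f.band_mask()[:, None]
        assert f.r2[mask].min() >= 0.999

    def test_symmetry(self, rng):
        x, y = _noise_series(rng), _noise_series(rng)
        fxy, fyx = wtc(x, y), wtc(y, x)
        np.testing.assert_allclose(fxy.r2, fyx.r2, atol=1e-12)

    def test_values_bounded(self, rng):
        f = wtc(_noise_series(rng), _noise_series(rng))
        assert f.r2.min() >= 0.0 and f.r2.max() <= 1.0

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            wtc(_noise_series(rng, 900), _noise_series(rng, 800))

    def test_coi_decreases_toward_edges(self, rng):
        f = wtc(_noise_series(rng), _noise_series(rng))
        n = f.coi.size
        assert f.coi[0] == 0.0 and f.coi[n - 1] == 0.0
        assert f.coi[n // 2] == pytest.approx((n // 2) / np.sqrt(2), rel=0.01)

    def test_independent_noise_below_surrogate_null(self, rng):
        """Band-mean coherence of an independent pair must sit below the
        95th percentile of a surrogate null built from independent pairs."""
        w = AnalysisWindow("phase_full", "team", 200, 400)
        null = []
        for _ in range(60):
            f = wtc(_noise_series(rng, 600), _noise_series(rng, 600))
            null.append(band_mean_coherence(f, w)[0])
        null = np.array(null)
        q95 = np.quantile(null, 0.95)
        fresh = [
            band_mean_coherence(
                wtc(_noise_series(rng, 600), _noise_series(rng, 600)), w)[0]
            for _ in range(10)
        ]
        assert np.mean(np.array(fresh) < q95) >= 0.8

    def test_matched_spectrum_ar1_pairs_match_white_null(self, rng):
        """Autocorrelated but independent pairs should not read as more
        coherent than white-noise pairs (guards against autocorrelation
        masquerading as synchrony)."""
        w = AnalysisWindow("phase_full", "team", 200, 400)

        def ar1(n, phi=0.8):
            e = rng.standard_normal(n + 100)
            x = np.zeros(n + 100)
            for i in range(1, n + 100):
                x[i] = phi * x[i - 1] + e[i]
            return series_1hz(x[100:])

        white = [band_mean_coherence(
            wtc(_noise_series(rng, 600), _noise_series(rng, 600)), w)[0]
            for _ in range(40)]
        coloured = [band_mean_coherence(
            wtc(ar1(600), ar1(600)), w)[0] for _ in range(40)]
        # two-sample z on the means: indistinguishable at ~3 sigma
        z = (np.mean(coloured) - np.mean(white)) / np.sqrt(
            np.var(coloured) / 40 + np.var(white) / 40)
        assert abs(z) < 3.0

    def test_shared_component_coherent_at_its_scale(self, rng):
        """A shared 0.05 Hz component with weak independent noise gives
        near-total coherence at the 20 s scale."""
        t = np.arange(900.0)
        shared = np.sin(2 * np.pi * 0.05 * t)
        amp = shared.std() / np.sqrt(10)  # SNR 10
        x = series_1hz(shared + amp * rng.standard_normal(900))
        y = series_1hz(shared + amp * rng.standard_normal(900))
        f = wtc(x, y)
        i = np.argmin(np.abs(f.periods - 20.0))
        valid = f.valid_mask()[i]
        assert f.r2[i, valid].mean() >= 0.9


class TestBandMean:
    def _field(self, r2, n=600, band=(0.01, 0.1)):
        params = WaveletParams()
        scales = params.scales()
        return CoherenceField(
            scales=scales,
            times=np.arange(n, dtype=float),
            r2=r2,
            coi=np.full(n, np.inf),  # fully valid
            periods=params.periods(),
        )

    def test_field_of_ones_gives_one(self):
        params = WaveletParams()
        f = self._field(np.ones((params.scales().size, 600)))
        value, missing = band_mean_coherence(
            f, AnalysisWindow("phase_full", "team", 100, 200))
        assert value == pytest.approx(1.0) and not missing

    def test_half_low_half_high_averages(self):
        params = WaveletParams()
        n_s = params.scales().size
        r2 = np.full((n_s, 600), 0.2)
        r2[:, 300:] = 0.8
        f = self._field(r2)
        value, _ = band_mean_coherence(
            f, AnalysisWindow("phase_full", "team", 200, 400))
        assert value == pytest.approx(0.5)

    def test_edge_window_fully_outside_coi_is_missing(self, rng):
        f = wtc(_noise_series(rng, 600), _noise_series(rng, 600))
        value, missing = band_mean_coherence(
            f, AnalysisWindow("phase_full", "team", 0, 10))
        assert missing and np.isnan(value)


class TestBaselineAdjusted:
    def _events(self):
        return SessionEvents(
            baseline=(300.0, 600.0),
            phases=[("single_provider", 600.0, 1200.0),
                    ("team", 1200.0, 1800.0),
                    ("debriefing", 1800.0, 2400.0)],
        )

    def test_adjusted_is_raw_minus_baseline(self, rng):
        ev = self._events()
        x, y = _noise_series(rng, 2700), _noise_series(rng, 2700)
        wins = [AnalysisWindow("phase_full", "team", 1200, 1800)]
        (v,) = baseline_adjusted_wtc(x, y, ev, wins)
        assert v.adjusted == v.raw_mean - v.baseline_mean

    def test_identical_window_and_baseline_adjust_to_zero(self, rng):
        ev = self._events()
        x, y = _noise_series(rng, 2700), _noise_series(rng, 2700)
        wins = [AnalysisWindow("baseline", "baseline", 300.0, 600.0)]
        (v,) = baseline_adjusted_wtc(x, y, ev, wins)
        assert v.adjusted == pytest.approx(0.0, abs=1e-12)

    def test_unresampled_series_rejected(self, rng):
        ev = self._events()
        x = series_1hz(rng.standard_normal(2700), state=("converted",))
        with pytest.raises(RuntimeError, match="pipeline-order"):
            baseline_adjusted_wtc(x, x, ev, [])
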