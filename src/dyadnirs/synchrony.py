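"""Inter-brain synchrony via wavelet-transform coherence (WTC).

Two participants' 1 Hz hemoglobin series are compared in the
time–frequency plane.  Each series is expanded with a continuous Morlet
wavelet transform (central frequency ``omega0 = 6``); squared coherence
is the modulus-squared of the smoothed cross-spectrum normalized by the
smoothed auto-spectra,

    R²(s, t) = |S(W_xy / s)|² / ( S(|W_x|² / s) · S(|W_y|² / s) ),

with smoothing ``S`` Gaussian in time (SD s/√2) and boxcar in scale.
Cells inside the cone of influence (edge distance < √2·s e-folding
time) are excluded; band-mean coherence averages the surviving cells
with Fourier frequency in 0.01–0.1 Hz, and every reported value is
baseline-adjusted: window mean minus the same dyad's baseline-window
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from dyadnirs.session import HbTimeSeries, SessionEvents
from dyadnirs.windows import AnalysisWindow, baseline_window

BAND_HZ = (0.01, 0.1)


@dataclass
class WaveletParams:
    """Morlet continuous-wavelet-transform parameters.

    The scale grid is ``s0 * 2**(j / voices_per_octave)`` with enough
    octaves that the largest Fourier period reaches ``max_period_s``
    (default 200 s, covering the 10–100 s coherence band with margin).
    """

    omega0: float = 6.0
    voices_per_octave: int = 12
    s0: float = 2.0
    max_period_s: float = 200.0

    def __post_init__(self) -> None:
        if self.omega0 <= 0 or self.s0 <= 0 or self.voices_per_octave < 1:
            raise ValueError("invalid wavelet parameters")

    @property
    def fourier_factor(self) -> float:
        """Fourier period per unit scale: 4π / (ω0 + √(2 + ω0²))."""
        return 4 * np.pi / (self.omega0 + np.sqrt(2 + self.omega0 ** 2))

    def scales(self) -> np.ndarray:
        dj = 1.0 / self.voices_per_octave
        s_max = self.max_period_s / self.fourier_factor
        j_max = int(np.ceil(np.log2(s_max / self.s0) / dj))
        return self.s0 * 2.0 ** (dj * np.arange(j_max + 1))

    def periods(self) -> np.ndarray:
        return self.fourier_factor * self.scales()


@dataclass
class CoherenceField:
    """Squared wavelet coherence on a (scale, time) grid.

    ``coi`` holds, per time point, the largest scale free of edge
    effects (e-folding time √2·s); a cell is valid when its scale is at
    most ``coi[t]``.
    """

    scales: np.ndarray
    times: np.ndarray
    r2: np.ndarray  # shape (n_scales, n_times), values in [0, 1]
    coi: np.ndarray  # shape (n_times,), in scale units
    periods: np.ndarray
    band: tuple[float, float] = BAND_HZ

    #: extra edge margin (in units of scale) beyond the √2·s e-folding
    #: cone.  Any padding imposes shared deterministic structure on both
    #: series near a record edge, and the time smoothing (SD s) spreads
    #: the resulting spurious coherence well past the classic cone;
    #: measured no-coupling coherence only flattens about seven scales
    #: from the edge.  Excluding the wider margin keeps window means
    #: comparable across the record.
    smoothing_margin: float = 7.0 - float(np.sqrt(2))

    def valid_mask(self, with_smoothing_margin: bool = True) -> np.ndarray:
        boundary = self.coi[None, :]
        if with_smoothing_margin:
            boundary = boundary * np.sqrt(2) / (np.sqrt(2) + self.smoothing_margin)
        return self.scales[:, None] <= boundary

    def band_mask(self) -> np.ndarray:
        freq = 1.0 / self.periods
        return (freq >= self.band[0]) & (freq <= self.band[1])


@dataclass
class SynchronyValue:
    """Baseline-adjusted band-mean coherence for one analysis window."""

    session_id: str
    chromophore: str
    window: AnalysisWindow
    raw_mean: float
    baseline_mean: float
    missing: bool = False

    @property
    def adjusted(self) -> float:
        return self.raw_mean - self.baseline_mean


def cwt_morlet(x: HbTimeSeries, params: WaveletParams | None = None) -> np.ndarray:
    """Continuous Morlet wavelet transform of a 1 Hz series.

    Returns complex coefficients, shape (n_scales, n_samples), computed
    in the Fourier domain with zero-padding to the next power of two.
    """
    params = params or WaveletParams()
    if x.sample_rate != 1.0:
        raise ValueError("cwt_morlet expects a 1 Hz series (resample first)")
    scales = params.scales()
    if x.duration < 2 * params.max_period_s:
        import warnings

        warnings.warn(
            "record shorter than twice the largest period; the cone of "
            "influence will exclude most large-scale cells",
            stacklevel=2,
        )
    return _cwt(x.values, scales, params.omega0, dt=1.0)


def _cwt(values: np.ndarray, scales: np.ndarray, omega0: float, dt: float) -> np.ndarray:
    # mirrored circular extension: [x, reversed x] is continuous at both
    # seams, so edge coefficients see reflected data instead of a hard
    # zero envelope.  Zero padding would modulate *both* series of a pair
    # with the same deterministic decay and bias their coherence near
    # edges; reflection keeps the extension participant-specific.
    n = values.size
    x = np.concatenate([values - values.mean(), (values - values.mean())[::-1]])
    n_pad = x.size
    xh = np.fft.fft(x)
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, d=dt)

    W = np.empty((scales.size, n), dtype=complex)
    norm_const = np.pi ** -0.25
    for i, s in enumerate(scales):
        # analytic Morlet: support on positive frequencies only
        psi_hat = norm_const * np.sqrt(2 * np.pi * s / dt) * np.exp(
            -0.5 * (s * omega - omega0) ** 2
        )
        psi_hat[omega <= 0] = 0.0
        W[i] = np.fft.ifft(xh * psi_hat)[:n]
    return W


def _smooth_time(field: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Gaussian time smoothing, SD equal to the scale, per scale row.

    Implemented as a batched FFT multiplication (the Gaussian transfer
    function ``exp(-σ²ω²/2)``), normalized by the smoothed support mass
    so edge cells average only real data; padding with surrogate data
    would bias coherence near the record edges, exactly where the
    baseline window sits.
    """
    n = field.shape[1]
    pad = int(min(n, 8 * scales.max()))
    L = n + pad
    omega = 2 * np.pi * np.fft.rfftfreq(L)
    gauss = np.exp(-0.5 * (scales[:, None] * omega[None, :]) ** 2)

    F = np.fft.rfft(field, n=L, axis=1)
    num = np.fft.irfft(F * gauss, n=L, axis=1)[:, :n]
    ones_hat = np.fft.rfft(np.ones(n), n=L)
    den = np.fft.irfft(ones_hat[None, :] * gauss, n=L, axis=1)[:, :n]
    return num / den


def _smooth(field: np.ndarray, scales: np.ndarray, params: WaveletParams) -> np.ndarray:
    """Cross-wavelet smoothing: Gaussian in time (SD = s), boxcar in scale."""
    out = _smooth_time(field, scales)
    width = max(1, int(round(0.6 * params.voices_per_octave)))
    return uniform_filter1d(out, size=width, axis=0, mode="nearest")


def coi_scales(n: int, dt: float = 1.0) -> np.ndarray:
    """Largest edge-effect-free scale per time point (e-folding time √2·s)."""
    t = np.arange(n) * dt
    edge_dist = np.minimum(t, t[-1] - t)
    return edge_dist / np.sqrt(2)


def wtc(
    x: HbTimeSeries, y: HbTimeSeries, params: WaveletParams | None = None
) -> CoherenceField:
    """Squared wavelet-transform coherence between two aligned 1 Hz series."""
    params = params or WaveletParams()
    if x.n_samples != y.n_samples:
        raise ValueError("series length mismatch")
    if x.sample_rate != 1.0 or y.sample_rate != 1.0:
        raise ValueError("wtc expects 1 Hz series")
    if x.t0 != y.t0:
        raise ValueError("series must share a clock (equal t0)")

    scales = params.scales()
    Wx = _cwt(x.values, scales, params.omega0, dt=1.0)
    Wy = _cwt(y.values, scales, params.omega0, dt=1.0)
    inv_s = 1.0 / scales[:, None]

    Sxx = _smooth(np.abs(Wx) ** 2 * inv_s, scales, params)
    Syy = _smooth(np.abs(Wy) ** 2 * inv_s, scales, params)
    cross = Wx * np.conj(Wy) * inv_s
    Sxy_re = _smooth(cross.real, scales, params)
    Sxy_im = _smooth(cross.imag, scales, params)

    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (Sxy_re ** 2 + Sxy_im ** 2) / (Sxx * Syy)
    r2 = np.nan_to_num(np.clip(r2, 0.0, 1.0))

    return CoherenceField(
        scales=scales,
        times=x.times(),
        r2=r2,
        coi=coi_scales(x.n_samples),
        periods=params.periods(),
    )


def band_mean_coherence(
    f: CoherenceField, w: AnalysisWindow, min_valid_fraction: float = 0.1
) -> tuple[float, bool]:
    """Mean in-band coherence over a window, excluding COI cells.

    Returns ``(mean, missing)``; ``missing`` is set when fewer than
    ``min_valid_fraction`` of the window's in-band cells survive the
    cone-of-influence exclusion.
    """
    in_band = f.band_mask()
    in_time = (f.times >= w.start) & (f.times < w.end)
    cells = in_band[:, None] & in_time[None, :]
    n_band = int(cells.sum())
    valid = cells & f.valid_mask()
    n_valid = int(valid.sum())
    if n_band == 0 or n_valid < min_valid_fraction * n_band:
        return (float("nan"), True)
    return (float(f.r2[valid].mean()), False)


def band_scale_profile(
    f: CoherenceField, w: AnalysisWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Per-scale mean coherence over a window (COI-excluded).

    Returns ``(profile, valid)``: for each in-band scale the time-mean
    of surviving cells and whether any cell survived.  Out-of-band
    scales are NaN/False.
    """
    in_time = (f.times >= w.start) & (f.times < w.end)
    cells = f.band_mask()[:, None] & in_time[None, :] & f.valid_mask()
    counts = cells.sum(axis=1)
    with np.errstate(invalid="ignore"):
        profile = np.where(cells, f.r2, 0.0).sum(axis=1) / np.where(counts, counts, 1)
    profile[counts == 0] = np.nan
    return profile, counts > 0


def baseline_adjusted_wtc(
    x: HbTimeSeries,
    y: HbTimeSeries,
    events: SessionEvents,
    windows: list[AnalysisWindow],
    params: WaveletParams | None = None,
    session_id: str = "",
) -> list[SynchronyValue]:
    """Baseline-adjusted band-mean coherence for each analysis window.

    Both series must be fully preprocessed, 1 Hz, and on the same clock.
    The coherence field is computed once over the whole record.  Because
    the cone of influence removes different scales in different windows
    (edge windows — the baseline especially — lose the largest scales)
    and the no-coupling coherence level varies across scales, window and
    baseline are compared *at matched scales*: both means average the
    per-scale time-means over the scales that survive the COI in both
    windows, so scale composition cancels from the adjustment.
    """
    for series in (x, y):
        series.require_state("resampled")
    field = wtc(x, y, params)
    base_profile, base_valid = band_scale_profile(field, baseline_window(events))
    if not base_valid.any():
        raise ValueError("baseline window has no COI-valid coherence cells")

    out = []
    for w in windows:
        profile, valid = band_scale_profile(field, w)
        _, missing = band_mean_coherence(field, w)
        common = valid & base_valid
        if not common.any():
            missing = True
            raw = base = float("nan")
        else:
            # weight scales by effective degrees of freedom (∝ 1/s: the
            # number of independent coherence estimates per unit time);
            # identical weights on window and baseline keep the
            # adjustment unbiased while down-weighting the noisy
            # largest scales
            wts = 1.0 / field.scales[common]
            wts = wts / wts.sum()
            raw = float(wts @ profile[common])
            base = float(wts @ base_profile[common])
        out.append(
            SynchronyValue(
                session_id=session_id,
                chromophore=x.chromophore,
                window=w,
                raw_mean=raw,
                baseline_mean=base,
                missing=missing,
            )
        )
    return out


def write_coherence_field(f: CoherenceField, path: str | Path) -> None:
    """Export the r² grid plus the COI vector as delimited text."""
    path = Path(path)
    header = "periods_s\t" + "\t".join(f"t{t:g}" for t in f.times)
    rows = np.column_stack([f.periods, f.r2])
    np.savetxt(path, rows, delimiter="\t", header=header, comments="")
    np.savetxt(
        path.with_suffix(".coi.tsv"),
        np.column_stack([f.times, f.coi]),
        delimiter="\t",
        header="time_s\tcoi_scale_s",
        comments="",
    )
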