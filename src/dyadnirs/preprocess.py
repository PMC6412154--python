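"""Optical-density → hemoglobin conversion and signal cleaning.

The chain mirrors standard single-channel fNIRS practice:

1. modified Beer–Lambert law (MBLL) conversion of two-wavelength
   optical-density changes to ΔHbO/ΔHbR,
2. wavelet-based motion-artifact removal (discrete wavelet transform,
   per-level Gaussian-tail thresholding at probability ``alpha``),
3. zero-phase third-order Butterworth band-pass, 0.01–0.1 Hz,
4. per-participant z-score normalization followed by subtraction of the
   baseline-window mean,
5. block-mean resampling to 1 Hz for coherence analysis.

Each step checks and advances the series' pipeline state so stages
cannot run out of order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal, stats

from dyadnirs.session import HbTimeSeries, ODRecording, SessionEvents

log = logging.getLogger(__name__)

#: HbO/HbR molar extinction coefficients, 1/(mM·cm), at a nominal
#: 730/850 nm wavelength pair (Cope's compiled spectra, widely used as
#: fNIRS defaults).  Rows: wavelength; columns: (HbO, HbR).  Because the
#: pipeline z-scores each participant before any statistics, the absolute
#: concentration scale set by these constants cancels downstream.
DEFAULT_EXTINCTION = np.array([[0.3900, 1.1022],
                               [1.0580, 0.6916]])


@dataclass
class MbllParams:
    """Modified Beer–Lambert law parameters.

    extinction : (2, 2) array, ε[wavelength, chromophore] in 1/(mM·cm)
    dpf : differential pathlength factor per wavelength (dimensionless)
    separation : source–detector distance in cm
    """

    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    separation: float = 3.0

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ValueError("extinction must be a 2x2 matrix")
        if not all(d > 0 for d in self.dpf) or self.separation <= 0:
            raise ValueError("dpf and separation must be positive")
        cond = np.linalg.cond(self.system_matrix())
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError("singular extinction matrix")
        log.debug("MBLL system matrix condition number: %.3g", cond)

    def system_matrix(self) -> np.ndarray:
        """The 2x2 map (ΔHbO, ΔHbR) → (ΔOD λ1, ΔOD λ2)."""
        path = self.separation * np.asarray(self.dpf)
        return self.extinction * path[:, None]


@dataclass
class ArtifactRemovalConfig:
    """Wavelet motion-artifact removal settings.

    ``alpha`` is the two-sided Gaussian tail probability: per
    decomposition level, detail coefficients larger in magnitude than the
    (1 - alpha/2) Gaussian quantile of a robustly estimated scale are
    treated as artifact and zeroed.
    """

    alpha: float = 0.15
    wavelet_family: str = "db5"
    levels: int | None = None  # default: min(floor(log2 n) - 1, 8)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.levels is not None and self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass
class FilterSpec:
    """Butterworth band-pass specification (defaults 0.01–0.1 Hz, order 3)."""

    low_hz: float = 0.01
    high_hz: float = 0.1
    order: int = 3
    application: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.application not in ("zero_phase", "causal"):
            raise ValueError("application must be 'zero_phase' or 'causal'")

    def sos(self, sample_rate: float):
        if self.high_hz >= sample_rate / 2:
            raise ValueError("high_hz must be below the Nyquist frequency")
        return signal.butter(
            self.order,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=sample_rate,
            output="sos",
        )


def mbll_forward(hbo: np.ndarray, hbr: np.ndarray, params: MbllParams) -> np.ndarray:
    """Forward MBLL: concentration changes → (n, 2) optical-density changes."""
    conc = np.column_stack([np.asarray(hbo, float), np.asarray(hbr, float)])
    return conc @ params.system_matrix().T


def mbll_convert(
    od: ODRecording, params: MbllParams | None = None
) -> tuple[HbTimeSeries, HbTimeSeries]:
    """Invert the modified Beer–Lambert law sample-by-sample.

    Solves ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ) for the two
    concentration changes at each sample.  Returns (HbO, HbR) series in
    the "converted" pipeline state, same length and rate as the input.
    """
    params = params or MbllParams()
    A = params.system_matrix()
    if np.linalg.cond(A) > 1e12:
        raise ValueError("singular extinction matrix")
    conc = np.linalg.solve(A, od.od.T).T  # columns: HbO, HbR
    out = []
    for j, chrom in enumerate(("HbO", "HbR")):
        out.append(
            HbTimeSeries(
                participant_id=od.participant_id,
                chromophore=chrom,
                values=conc[:, j],
                sample_rate=od.sample_rate,
                t0=od.t0,
                state=("converted",),
            )
        )
    return out[0], out[1]


def wavelet_artifact_removal(
    x: HbTimeSeries, cfg: ArtifactRemovalConfig | None = None
) -> HbTimeSeries:
    """Remove motion artifacts by discrete-wavelet outlier rejection.

    The series is decomposed with a Daubechies-5 DWT; at each detail
    level the coefficient scale is estimated robustly (median absolute
    deviation / 0.6745) and coefficients beyond the two-sided Gaussian
    tail at probability ``alpha`` are zeroed; the inverse transform is
    returned.  Spikes and abrupt baseline shifts concentrate in few large
    detail coefficients, so they are removed while the slow hemodynamic
    signal (carried by the approximation) passes through.
    """
    cfg = cfg or ArtifactRemovalConfig()
    x.require_state("converted")
    n = x.n_samples
    levels = cfg.levels
    if levels is None:
        levels = min(max(int(np.floor(np.log2(n))) - 1, 1), 8)
    wavelet = pywt.Wavelet(cfg.wavelet_family)
    if n < 2 ** levels or n < wavelet.dec_len:
        raise ValueError("series shorter than the decomposition support")

    z = stats.norm.ppf(1 - cfg.alpha / 2)
    coeffs = pywt.wavedec(x.values, wavelet, level=levels, mode="symmetric")
    cleaned = [coeffs[0]]
    for detail in coeffs[1:]:
        sigma = np.median(np.abs(detail - np.median(detail))) / 0.6745
        d = detail.copy()
        d[np.abs(d) > z * sigma] = 0.0  # strict: a constant series is untouched
        cleaned.append(d)
    rec = pywt.waverec(cleaned, wavelet, mode="symmetric")[:n]

    return replace(x, values=rec, state=x.advance_state("artifact_removed"))


def bandpass_filter(x: HbTimeSeries, spec: FilterSpec | None = None) -> HbTimeSeries:
    """Apply the band-pass Butterworth filter (zero-phase by default).

    Zero-phase (forward–backward) application squares the magnitude
    response and preserves phase, which matters downstream: inter-brain
    coherence compares the two participants' phases.
    """
    spec = spec or FilterSpec()
    x.require_state("artifact_removed")
    if x.duration < 300:
        warnings.warn(
            f"record of {x.duration:.0f}s is short relative to the "
            f"{1 / spec.low_hz:.0f}s low-cutoff period; filter transients may dominate",
            stacklevel=2,
        )
    sos = spec.sos(x.sample_rate)
    if spec.application == "zero_phase":
        y = signal.sosfiltfilt(sos, x.values)
    else:
        y = signal.sosfilt(sos, x.values)
    return replace(x, values=y, state=x.advance_state("filtered"))


def normalize_and_baseline(x: HbTimeSeries, events: SessionEvents) -> HbTimeSeries:
    """Z-score the participant's full record, then zero the baseline mean.

    Normalization is a per-participant, per-chromophore z-score over the
    whole record (mean 0, SD 1); the mean of the normalized series over
    the baseline window is then subtracted so every value reads as a
    change from that participant's seated baseline.
    """
    x.require_state("filtered")
    sd = float(np.std(x.values))
    if sd == 0:
        raise ValueError("zero-variance series cannot be normalized")
    z = (x.values - np.mean(x.values)) / sd

    t = x.times()
    b0, b1 = events.baseline
    mask = (t >= b0) & (t < b1)
    if not mask.any():
        raise ValueError("baseline window not covered by the series")
    z = z - z[mask].mean()
    return replace(
        x, values=z, state=x.advance_state("normalized", "baseline_subtracted")
    )


def resample_to_1hz(x: HbTimeSeries) -> HbTimeSeries:
    """Resample by averaging consecutive non-overlapping 1 s blocks."""
    step = x.sample_rate
    if abs(step - round(step)) > 1e-9:
        raise ValueError("sample_rate must be an integer multiple of 1 Hz")
    step = int(round(step))
    n_blocks, remainder = divmod(x.n_samples, step)
    if remainder:
        log.warning(
            "dropping %.2f s trailing partial block during 1 Hz resampling",
            remainder / x.sample_rate,
        )
    values = x.values[: n_blocks * step].reshape(n_blocks, step).mean(axis=1)
    return replace(
        x, values=values, sample_rate=1.0, state=x.advance_state("resampled")
    )


def preprocess_recording(
    od: ODRecording,
    events: SessionEvents,
    mbll: MbllParams | None = None,
    artifact: ArtifactRemovalConfig | None = None,
    filt: FilterSpec | None = None,
    resample: bool = True,
) -> dict[str, HbTimeSeries]:
    """Run the full cleaning chain on one recording.

    Returns ``{"HbO": series, "HbR": series}``, each at 1 Hz when
    ``resample`` is true.
    """
    hbo, hbr = mbll_convert(od, mbll)
    out = {}
    for series in (hbo, hbr):
        series = wavelet_artifact_removal(series, artifact)
        series = bandpass_filter(series, filt)
        series = normalize_and_baseline(series, events)
        if resample:
            series = resample_to_1hz(series)
        out[series.chromophore] = series
    return out
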