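# Methods

This note records the models, the numerical choices, and the reasoning
behind the places where the design was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Session model

A session is a five-minute seated baseline followed by three ordered phases
— single-provider, team, debriefing — on a shared clock in seconds,
0-based at recording start. Every analysis window is half-open
`[start, end)`: a sample falling exactly on `end` belongs to the next
window, so adjacent windows never double-count a sample. Observer workload
ratings arrive at 4–6 minute random intervals during the scenario; each is
analysed through the one-minute window immediately before it.

Each participant contributes one channel of two-wavelength optical density
at 100 Hz. The device's emission wavelengths are not part of the data
model's contract; they are optional metadata, and the extinction
coefficients are configuration (defaults: Cope's compiled HbO/HbR spectra
at a nominal 730/850 nm pair, DPF 6.0, separation 3.0 cm). Because every
series is z-scored per participant before any statistic, the absolute
concentration scale set by these constants cancels downstream; only the
invertibility of the 2×2 system matters, and it is checked (condition
number < 1e12).

## Preprocessing chain

Order: MBLL conversion → wavelet artifact removal → band-pass →
normalization + baseline subtraction → 1 Hz resampling. Each series
carries its processing state and refuses out-of-order or repeated steps.

* **Artifact removal.** Daubechies-5 DWT, depth `min(⌊log2 n⌋ − 1, 8)`.
  Per level, the coefficient scale is the MAD / 0.6745 (robust to the very
  outliers being removed); coefficients beyond the two-sided Gaussian tail
  at probability α = 0.15 are zeroed (strict inequality, so a constant
  series — all-zero details, zero MAD — passes through unchanged). Spikes
  and sharp baseline shifts concentrate in few large detail coefficients;
  the slow hemodynamic band (< ~0.2 Hz at 100 Hz with depth 8) lives in the
  approximation and is untouched. Residual low-frequency energy of an
  artifact that the approximation retains is subsequently attenuated by
  the band-pass.
* **Band-pass.** Third-order Butterworth, 0.01–0.1 Hz, applied
  forward–backward (zero phase, squared magnitude response). Zero-phase
  application is chosen because the coherence stage compares the *phases*
  of the two participants' series; a causal filter would add a common lag
  but also phase distortion. A causal mode remains available.
* **Normalization.** "Normalized within each participant" is implemented
  as a z-score over the full record, then subtraction of the normalized
  series' mean over the baseline window. Both operations are affine, so
  the order relative to filtering only changes the result by an affine map
  (verified numerically in the tests); z-scoring before baseline
  subtraction keeps the unit of the reported means interpretable
  (within-participant SD units relative to baseline).
* **Resampling.** Mean over consecutive non-overlapping 1 s blocks; a
  trailing partial block is dropped and logged.

## Coherence estimation

Morlet CWT with ω₀ = 6 on a scale grid of 12 voices per octave from
s₀ = 2 s up to a 200 s Fourier period (covering the 10–100 s band with
margin). The transform is FFT-based on a mirrored circular extension of
the series; smoothing of the cross- and auto-spectra is Gaussian in time
with SD equal to the scale (the transfer function `exp(−s²ω²/2)` used by
the standard cross-wavelet packages) and a boxcar spanning 0.6 octaves in
scale. Time smoothing is a normalized convolution — divided by the
smoothed support mass — so edge cells average only real data. R² is
clamped to [0, 1]; self-coherence is exactly 1 by construction.

**Edge handling.** The reported cone of influence is the standard √2·s
e-folding boundary. Band means, however, exclude a wider margin of five
scales beyond it (total ≈ 7·s from a record edge): any finite-record
extension imposes deterministic structure shared by *both* series near an
edge, and the time smoothing spreads the resulting spurious coherence well
past the classic cone. Measured on independent pairs, the no-coupling
coherence level is inflated out to ~3 scales, undershoots around 4–6, and
is flat from ~7 scales; the margin removes the whole regime. This matters
because the baseline window sits early in the record: without the margin,
baseline-adjusted values acquire a window-position bias.

**Baseline adjustment.** Each window's band mean is reported minus the
dyad's concurrent baseline-window band mean, computed *at matched scales*
(only scales COI-valid in both windows) with identical weights, so scale
composition cancels from the adjustment. Scales are weighted by effective
degrees of freedom (∝ 1/s, the number of independent coherence estimates
per unit time), which substantially reduces the variance contributed by
the few large-scale cells without biasing the adjustment. The missing
flag is raised when fewer than 10% of a window's in-band cells survive
the cone, or when no scale is valid in both window and baseline.

## Statistical models

Gaussian linear mixed models with random intercepts, fitted by blocked
Gibbs sampling: β | rest is multivariate normal; each random-intercept
vector | rest is normal with diagonal precision; each variance component
| rest is inverse-gamma. Priors: β ~ N(0, 10⁸·I), variance components
~ IG(0.001, 0.001) — a documented stand-in for "non-informative";
both are configurable. Defaults: 13 000 iterations, 3 000 burn-in,
thinning 10, hence exactly 1 000 retained draws; fully reproducible given
the seed. Split-chain R̂ < 1.05 and effective sample size > 200 mark a
fit clean.

Summaries: the 95% HDI is the shortest contiguous interval containing
⌈0.95·N⌉ sorted draws; pMCMC = 2·max(1, min(#draws>0, #draws<0))/N,
floored at 2/N for finite chains; significance requires both 0 ∉ HDI and
pMCMC < 0.05.

Factor coding: three-level factors (phase, difficulty, and the 9-level
phase×segment crossing used by the minute-segment models) use
successive-difference (backward-difference) contrasts, so coefficients
read directly as adjacent-level differences (team − single_provider,
debriefing − team, …); two-level role and the experience covariate use
treatment coding. Listed fixed factors enter with all mutual
interactions; experience enters additively. Treatment coding is available
by configuration. "Scenario phase (with first/middle/last minute)" is
treated as a single ordered 9-level factor rather than a phase×segment
product of separate factors — the reported contrasts of interest are
adjacent-segment differences, which this coding yields directly.

The bivariate model shares the design's random intercepts per response
and samples the 2×2 residual covariance from its conditional
inverse-Wishart (ν₀ = 3, S₀ = 0.001·I); the reported correlation is the
posterior of the residual correlation.

## Synthetic data generator

The generator emulates the study conditions: 300 s baseline; a 10–20 min
scenario split into single-provider and team phases (the split fraction is
not stated by the protocol; drawn U(0.3, 0.5)); a 10–25 min debriefing;
100 Hz two-wavelength OD per participant; observer-rating times at 4–6 min
gaps. Recordings extend 300 s before the baseline and after the
debriefing (sensors are worn from setup through the end of the visit), so
the protocol windows sit away from record edges, where wavelet estimates
are excluded anyway.

Per participant, latent ΔHbO = phase/role workload offset (step function)
+ band-limited dyadic signal + physiological rhythms + random-walk drift
(0.05 a.u./√s). The band signal mixes a shared component with weight c
(the per-phase coupling) and an independent component with weight
√(1−c²), giving inter-brain correlation c² in-band. Defaults
(single-provider 0.2, team 0.6, debriefing 0.4) reproduce the qualitative
ordering reported for these sessions — synchrony highest during active
teamwork — with emergent adjusted-coherence contrasts of the magnitude
printed for the real data. Physiological rhythms (cardiac ~1.1 Hz 0.4
a.u., respiratory ~0.27 Hz 0.3, Mayer ~0.095 Hz 0.25) are sinusoids with
random-walk phase (0.15 rad/√s): real oscillations are narrowband noise,
and phase drift prevents two same-frequency tones from reading as
inter-brain coherence. ΔHbR is −0.3 × ΔHbO plus independent band noise
(typical neurovascular anti-correlation; the value is a config default).
Forward MBLL produces OD; motion artifacts — exponential-decay spikes
(0.5/min, 8× the OD column SD) and persistent baseline shifts (0.1/min,
3× SD) — are injected at the OD level and their positions recorded in the
ground truth. Band-limited components are produced by filtering white
noise with the package's own band-pass, guaranteeing in-band energy.

Workload offsets (a.u., HbO/HbR): initial provider ±0.8 from the
single-provider phase on, responder ±0.8 only from the team phase,
both ±0.3 in debriefing — the initial provider works alone first, both
work during teamwork, debriefing is lighter. The band-pass attenuates
sustained offsets heavily (only the transition transients survive), so
phase means recover the *sign* pattern at roughly 5% of the configured
amplitude; this mirrors what a 0.01 Hz high-pass does to real sustained
activation and is why the sign, not the magnitude, is the tested
quantity.

What the generator does **not** emulate: biophysical (balloon-model)
hemodynamics, head-motion kinematics, systemic physiology shared between
participants (skin blood flow responses to the same events), or
scalp/superficial contamination. Passing tests therefore show that the
pipeline recovers planted effects under plausible noise — not that the
real recordings contain such effects.

## Simulation sizes

Replicate-heavy checks use a fixed-duration session variant (600 s
single-provider, team, and debriefing phases — the protocol mid-range —
with the same 100 Hz signal model) so that Monte-Carlo runs average over
replicates rather than over incidental duration variability: 100
replicates for coupling detection and for the independent-pair null
(one session-mean value per replicate, since a session's phase values
share its baseline estimate), 100 seeds per coupling level for the
monotonicity check, 200 replicates for HDI coverage (with a 2 600
iteration chain — interval calibration is insensitive to chain length;
the draw-count and REML-agreement checks run at the full default
settings), and 20 replicates of the 12-session end-to-end analysis. The
end-to-end check configures a strong team coupling (0.9), parallel to the
detection check: at effect sizes matching the printed team-vs-single
coherence difference (~0.08), a 12-session design has only moderate
power — the original analysis used 25 sessions — so the end-to-end test
probes sign recovery, not power at field-realistic effect sizes.

## Known limitations

* Single-channel data only; no short-separation regression or
  multi-channel artifact correction is possible or attempted.
* The coherence null level depends on the smoothing constants; adjusted
  values are comparable within this pipeline but not across packages with
  different smoothing.
* The Gibbs sampler covers Gaussian responses and random intercepts only
  (no random slopes, no non-Gaussian families), matching the analysis it
  reproduces.
* Jenks classification is exact but O(k·n²); fine for tens of scenarios,
  not for large n.
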