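# Methods

## Overview

`ecpipe` estimates frequency-specific effective connectivity (EC) between
cortical sites from multichannel fNIRS oxyhemoglobin (ΔHbO2) recordings.
Each channel's band-limited oscillation is treated as a phase oscillator;
directed interactions between pairs of channels are the Fourier
coefficients of the coupling function in a stochastic phase model,
inferred by windowed recursive Bayesian estimation and calibrated against
amplitude-adjusted Fourier-transform (AAFT) surrogates.  Channel-level
networks are aggregated to six cortical regions (left/right prefrontal,
motor, occipital) and compared across age groups and postures with
rank-based statistics.

The pipeline stages are: despike → band-pass (0.005–2 Hz) → continuous
wavelet phase per band → pairwise dynamical Bayesian inference → surrogate
significance → group/region networks → statistics.

## Phase model and inference

For a channel pair, the unwrapped band phases φ₁, φ₂ are modelled as

    dφ_k/dt = Σ_b c_b^(k) Φ_b(φ₁, φ₂) + ξ_k(t),   k = 1, 2

with white Gaussian noise ξ of 2×2 covariance E and base functions Φ_b the
2-D Fourier series up to order B = 2: a constant plus sin/cos(k₁φ₁ + k₂φ₂)
for one representative of each ±(k₁,k₂) pair — 25 terms per equation.
Order 2 is the established default for this inference family and keeps the
model identifiable at 10 Hz sampling.

Phases enter as midpoint finite differences: φ̇(t+h/2) = (φ_{n+1} − φ_n)/h
regressed on base functions evaluated at (φ_{n+1} + φ_n)/2.

Inference runs per non-overlapping window.  Within a window the posterior
is found by iterating, until the coefficients change by < 1e-6 (relative)
or 100 iterations:

* noise update: E = (h/N) Σ r_n r_nᵀ from current residuals r_n;
* concentration update: Ξ = Ξ_prior + h Pᵀ E⁻¹ P (Kronecker-structured
  over the two equations);
* mean update: includes the stochastic-integral correction
  −(h/2) Σ_n ∂Φ_b/∂φ_k.

Between windows the posterior covariance is inflated,
Σ_prior = Σ_post + p_w · diag(Σ_post) with p_w = 0.2, so the prior follows
slow parameter drift.  The reported coefficient vector is the time average
of the window posterior means; E is averaged likewise.

The directed strength C_{i→j} is the Euclidean norm of the coefficients, in
the φ̇_j equation, of every term involving φ_i (cross and joint terms; the
constant and pure self terms are excluded).  Joint terms are included
because any base function containing the source phase carries directed
influence.

### Numerical safeguards

* **First-window prior.**  A zero-centred Gaussian prior with SD 2 rad/s
  per coefficient.  Hemodynamic phase velocities are O(1) rad/s, so the
  prior is effectively flat for identified coefficients; its role is to
  bound the estimate when a window is degenerate (see *Identifiability*).
  On noiseless data the posterior mean still equals ordinary least squares
  to < 1e-6 (the likelihood precision grows as 1/E → ∞).
* **Initialisation.**  The first window starts from the least-squares fit
  rather than from zero: starting at zero makes the initial residuals equal
  the (strongly correlated) phase velocities themselves, so the first noise
  estimate E is near rank-1 and its inverse is numerically wild.
* **Ridge and divergence guard.**  A relative ridge (1e-8 of the largest
  diagonal entry) keeps a near-singular concentration matrix solvable; if
  an iterate becomes non-finite or implausibly large (‖c‖ > 1e3) the last
  stable estimate is kept and the estimate is flagged non-converged rather
  than raising.

### Window length

`infer_pair` defaults to 50 s windows.  The pipeline
(`calibrated_connectivity`) widens the window per band to at least four
cycles of the band's lowest frequency — ≈77 s in band I (0.052–0.145 Hz),
≈190 s in band II (0.021–0.052 Hz) — because a 50 s window holds fewer than
two cycles of a 0.021 Hz oscillation and the slow Fourier regressors are
then unidentifiable: in simulation, band-II coupling strengths estimated
with 50 s windows are indistinguishable from the uncoupled null, while
four-cycle windows separate them cleanly.  Windows divide the usable record
evenly (each at least the nominal length), so no tail data is discarded.

### Identifiability

Coupling coefficients are identifiable only while the pair's relative
phase keeps exploring its cycle.  Two regimes defeat this:

* **Phase locking.**  If the coupling amplitude exceeds the frequency
  detuning (ε > |Δω|, the classical locking threshold), the relative phase
  settles to a fixed point, the sine/cosine regressors degenerate to
  constants, and the coefficients are confounded with the natural
  frequency.  Phase noise mitigates this by driving excursions and slips
  around the locked state.
* **Near-zero detuning.**  Independent oscillators with nearly identical
  frequencies produce a relative phase that barely moves within a window;
  the same degeneracy appears in the null.

The safeguards above keep such estimates finite and flagged, but their
magnitudes are prior-dominated rather than data-dominated; the surrogate
test (below) remains valid because surrogates share the degeneracy.

## Wavelet phase extraction

The analytic Morlet wavelet (centre frequency 1 Hz; ω₀ = 2π in the angular
convention) is applied in the frequency domain: one FFT of the signal,
multiplied per scale by 2·exp(−(sω − ω₀)²/2) on positive frequencies.
This normalisation gives a unit-amplitude sinusoid unit response at its
matched scale, so band averages weight a tone's neighbourhood evenly.
Scales map to frequencies by the spectral-peak convention s = ω₀/(2πf),
which puts a pure tone's maximal response exactly at its own frequency.

Each band is covered by a 20-voice logarithmic frequency grid.  The band
phase is the angle of the complex coefficients averaged across in-band
bins at each time point (averaging complex values is circular-statistics
safe), unwrapped by cumulative principal-value increments.  Samples inside
the cone of influence — within √2·s_max of either record edge, where
s_max is the scale of the band's lowest frequency — are trimmed
symmetrically on all channels; a record shorter than twice the COI edge is
rejected as unresolvable for that band.

Phase-extraction fidelity is limited by the wavelet's time resolution:
frequency modulation faster than ~1/s is smoothed, so coupling signatures
riding on fast beats are attenuated before inference.  This attenuation is
common to original data and surrogates and therefore cancels in the
significance test, but recovered strengths through the full signal chain
are smaller than the injected SDE coefficients.

## Preprocessing

Spikes are detected against a centred moving average and moving SD (4 s
window) at 5 SDs and replaced by cubic-spline interpolation over clean
samples; boundary outliers hold the nearest clean value.  These defaults
are conventional for fNIRS artifact removal and are configuration-exposed.
The band-pass is a 4th-order Butterworth (second-order sections) applied
forward–backward for zero phase, 0.005–2 Hz, with reflected padding over
three periods of the low corner so its slow transient settles.  Quality
control flags (never silently drops) a subject when more than 10% of
samples on at least three channels were despiked.

## Surrogate significance

For each channel, AAFT surrogates of the preprocessed series are built by
rank-remapping to a Gaussian, randomising Fourier phases, and remapping
back, so the value distribution is preserved exactly and the
autocorrelation approximately.  Surrogate k of channel i is paired with
surrogate k of channel j (the cross-product pairing is combinatorially
prohibitive and adds nothing under matched seeds), and the entire
phase-extraction + inference chain is re-run per surrogate pair.  A
directed strength is significant when it exceeds the surrogate mean by
more than 2 surrogate SDs.  The protocol default is 100 surrogates; 19 is
the accepted minimum for a stable SD and is used in fast runs with the
threshold unchanged.  Surrogate seeds derive deterministically from
(seed, subject, state, band, channel, k).

## Network statistics

* **Group networks**: an edge enters the group consensus when significant
  in strictly more than 75% of subjects; group strength is the mean over
  all subjects (config-exposed alternative: mean over significant
  subjects only).
* **Subject interregional EC**: for each ordered region pair, the mean of
  significant channel-pair strengths (source channel in region 1, target
  in region 2); missing when no pair is significant.  Six regions give 30
  directed values.
* **Main coupling direction (mCD)**: each significant channel pair votes
  by comparing C_{i→j} with C_{j→i}; exact ties are dropped with a
  warning.  Votes are pooled across subjects (per-subject mode available),
  tested against 0.5 with the exact two-sided binomial (double the smaller
  tail, capped at 1).  Significant → unidirectional, else bidirectional.
* **Contrasts**: Kruskal–Wallis rank tests per directed region pair for
  posture (within group) and age group (within posture); strengths are
  heavy-tailed, so a rank test is appropriate and the result is invariant
  to monotone transforms.  p-values are reported uncorrected, with a
  Benjamini–Hochberg column alongside.
* **Cognition**: Pearson correlation of each interregional EC with MMSE in
  the elderly group (≥4 complete observations required).
* **Demographics**: two-sample t-tests (age, BMI, MMSE) and a chi-square
  test on the sex table.

## Synthetic cohorts

The generator exists so every stage is testable by parameter recovery; it
emulates the band-limited phase dynamics of resting fNIRS, not its
biophysics (no hemodynamic response model, no optics, no physiological
systemic confounds such as Mayer waves or heart-rate leakage).

Each channel carries one oscillator per band, integrated by Euler–Maruyama
(internal step ≤ 0.01 s, decimated to 10 Hz):

    dφ = [ω + Σ ε·sin(φ_src − φ_tgt)] dt + σ dW.

Defaults (the emulated study conditions):

* 17 elderly + 19 young subjects, sitting and standing states, 600 s at
  10 Hz over the 36-channel montage;
* region-ladder natural frequencies: each region takes a centre on an
  interleaved grid across the band interior (LPFC lowest, RPFC highest,
  then motor and occipital regions between), with ±10% uniform per-channel
  jitter.  The interleaving keeps interregional pairs — in particular the
  coupled LPFC→RPFC pair — detuned by much of the band width, inside the
  identifiable running-phase regime; i.i.d. uniform draws would routinely
  produce near-degenerate pairs (see *Identifiability*);
* phase diffusion σ = 0.2 rad·s^−1/2, strong enough that couplings above
  the locking threshold keep exploring the relative-phase cycle;
* observation model: x = cos φ per band, white noise sized for 10 dB
  in-band SNR, plus a 0.002 Hz drift at half the signal amplitude (to
  exercise the band-pass) — both split across bands;
* couplings: baseline LPFC→RPFC of 0.2 rad/s in band II for every
  group/state, elevated to 0.5 rad/s in elderly standing (the posture
  contrast); per-subject amplitudes scale by 1 + 0.25·z_s with a shared
  latent z_s;
* elderly MMSE is drawn (mean 27.5, SD 1.5; young 29.3, SD 0.6, clipped to
  [0, 30]) correlated at r = 0.7 with the subject's coupling factor, so
  the cognition correlation analysis has a known ground truth.

Everything derives deterministically from one cohort seed.  The injected
couplings, per-channel frequencies and subject factors are written to a
ground-truth ledger (JSON) next to the recordings.

What passing tests on this generator do **not** show: robustness to real
fNIRS confounds (motion artifacts beyond simple spikes, superficial
hemodynamics, heart/respiratory leakage into band I), to amplitude dynamics
(the model fixes unit amplitude), or to couplings outside the identifiable
regime discussed above.

## Problem sizes in the test suite and acceptance script

The acceptance tests run the published cohort size (17 + 19 subjects, both
postures) with 6 channels (one per region), 420 s records, band II and 19
surrogates; parameter-recovery and null-calibration checks use 20 seeded
pairs of 600 s.  The standalone acceptance script uses 12 seeded pairs and
a 10 + 10-subject cohort — the same conditions at sizes chosen to keep a
single-CPU run short.  Channel-level 36×36 analyses run at full channel
count only for the combinatorial checks (1,260 directed pairs), where
record length is irrelevant.

## Known limitations

* Strength magnitudes through the full signal chain are attenuated
  relative to the generating SDE coefficients (wavelet time-smoothing of
  fast frequency modulation) and can be prior-dominated for degenerate
  pairs; between-condition comparisons and surrogate-calibrated detection
  are the supported uses.
* Pairwise (N = 2) inference only; common-input structure can induce
  spurious pairwise couplings, as in the original analysis.
* The SNIRF reader/writer covers only the concentration time series and
  time vector (the subset this pipeline consumes), not the full standard.
* The exact binomial, consensus and aggregation rules follow fixed
  conventions (strict >75%, ties dropped); alternatives are config-exposed
  where the convention is genuinely ambiguous.
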