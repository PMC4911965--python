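# Methods

## Detection task and observer model

The package measures low-contrast detectability under the
signal-known-exactly / location-known-exactly (SKE/LKE) paradigm: every ROI
either contains a centred disc of known diameter and contrast or pure noise,
and the background statistics are stationary.  The observer is the
channelised Hotelling observer (CHO), the ideal linear discriminant applied
after projection onto a small set of frequency-selective channels.  Its
template is

    w_CHO = [0.5 (K_cs + K_cn)]^-1 (g_cs - g_cn)

where g_cs, g_cn are the channel-space class means and K_cs, K_cn the
channel-space class covariances; an ROI g scores
lambda = w_CHO^T U^T g, and in an M-AFC trial the alternative with the
largest lambda is chosen.  No internal noise is added to lambda: the model is
the noiseless CHO, which is known to track — and sometimes slightly exceed —
human low-contrast performance.

Covariances are estimated directly from the channel outputs (a 10×10
problem) rather than by forming the pixel-space covariance and projecting it;
the two routes are algebraically identical (cov(U^T g) = U^T cov(g) U) and
the equivalence is asserted by a dedicated test.  Sample covariances use the
unbiased (n−1) normalisation.  Training and scoring use the same dataset
(resubstitution): with only 100 signal-present ROIs per category a
train/test split would leave both halves underpowered, and single-set
estimation is an accepted protocol for this observer; the bias it introduces
is small at these channel counts and is shared by all categories being
compared.

## DDoG channels

Channel j has the radial-frequency profile

    U_j(rho) = exp[-(rho / (W sigma_j))^2 / 2] - exp[-(rho / sigma_j)^2 / 2],
    sigma_j = sigma0 * alpha^j,  j = 1..10

with defaults W = 1.67, sigma0 = 0.005, alpha = 1.4.  Frequencies are in
cycles/pixel on the DFT grid of the ROI, which makes the observer independent
of the physical pixel pitch; sigma0 is dimensionally consistent with
cycles/pixel in the channel literature the profile comes from.  The channel
index starts at j = 1 (sigma_1 = sigma0 * alpha); a j = 0 start would merely
shift the band edges by one factor of alpha and is not offered.  Each profile
is sampled on the centred discrete-frequency grid and inverse-transformed to
a real spatial template centred on the ROI's middle pixel; because
U_j(0) = 0 every template has exactly zero mean, so all decision variables
are invariant to constant HU offsets.  No per-channel normalisation is
applied beyond the profile's own amplitude — the Hotelling template is
invariant to per-channel rescaling, so the literal profile is used.

One practical consequence of the fixed sigma0: on ROIs much smaller than the
default 41 pixels the lowest channels fall below the grid's lowest nonzero
frequency (1/side cycles/pixel) and carry no energy, making the channel
covariance numerically singular.  The training solve detects this and applies
a small ridge (1e-8 × trace/n) with a warning; analyses on small ROIs should
instead use a bank matched to the grid (fewer channels, larger sigma0), as
the test suite does for its miniature scenarios.

## Synthetic phantom

The generator emulates the study design the analysis assumes: per category,
100 signal-present and 1000 signal-absent ROIs of 41×41 pixels at
0.59 mm/pixel.  The target is rendered as a two-dimensional anti-aliased disc
(plateau at the nominal contrast, 16×16 sub-pixel area sampling at the rim)
rather than a sphere intersected with a slice: the observer mathematics is
2-D and slice positioning is not modelled.  Backgrounds are contrast-only
(0 HU): every downstream statistic is offset-invariant, so an absolute HU
pedestal would be inert.

Noise is a surrogate for reconstructed CT noise, in two flavours:

* `white` — i.i.d. Gaussian pixels of the requested SD (default);
* `nps_shaped` — a white field filtered in the frequency domain by the
  square root of a radial power spectrum ∝ rho^e · exp(−rho), a generic
  band-pass shape resembling the noise-power spectrum (NPS) of reconstructed
  CT, normalised analytically so the ensemble pixel SD equals the requested
  value exactly.

Noise magnitude follows quantum scaling with nominal dose,
sigma = sigma_ref · sqrt(dose_ref / dose).  The reference magnitude is a free
parameter with default **10 HU at 15 mGy**, a realistic noise level for a
chest-attenuation phantom at 2 mm slice thickness; at the lowest study dose
(1 mGy) this gives ≈ 39 HU.  Reconstruction strength (an integer label 1–5
standing in for a vendor's iterative-reconstruction setting) maps to a
(noise multiplier, NPS exponent) pair — by default
{1: (1.00, 1.2), 2: (0.93, 1.1), 3: (0.85, 1.0), 4: (0.78, 0.9),
5: (0.70, 0.8)} — capturing the two first-order effects of stronger
iterative reconstruction, less noise and a low-frequency-shifted NPS, without
pretending to reproduce any proprietary algorithm.  For extracted real data
the strength is pass-through metadata.

What the surrogate deliberately omits: no projection or reconstruction
simulation, no helical geometry, no non-stationarity, no non-Gaussian noise,
no object-dependent texture.  Passing tests therefore demonstrate that the
observer, AFC and bootstrap machinery are correct under the model's own
assumptions — not that any particular scanner or reconstruction behaves in a
given way.

Randomness is counter-based: each ROI draws from a Philox stream keyed by
(dataset seed, class, ROI index), so ROI i is bit-identical regardless of how
many other ROIs are generated, and the whole study is reproducible from one
master seed (per-category seeds are derived from it and the category index).

## AFC experiment and uncertainty

A pass uses each signal-present ROI exactly once in seeded-shuffled order
(100 trials with the default dataset); the m−1 noise alternatives are drawn
without replacement within a trial and with replacement across trials from
the shared 1000-ROI pool.  Presentation order is shuffled per trial and the
maximum-lambda rule decides; exact ties (probability ~0 with continuous
noise) resolve to the lowest presentation index after the shuffle, keeping
reruns bit-reproducible.

The bootstrap (default 150 replicates) resamples the signal-present
collection with replacement to its original size and reruns a full AFC pass
against the fixed noise pool; the noise pool is not resampled.  The template
is trained once on the full dataset and held fixed across replicates — the
resampling quantifies trial-composition variability, not training
variability — with `refit_per_replicate=True` exposing the alternative.  The
95 % interval is the normal approximation mean ± 1.96 SD clipped to
[0, 100]; a percentile interval is available via `ci_method="percentile"`.
Human-reader tables are summarised per category by the across-observer mean
with SE = SD/√n and a mean ± 1.96 SE interval.

The closed-form M-AFC expectation for a Gaussian decision variable,
PC(d', m) = ∫ φ(x − d') Φ(x)^(m−1) dx, is computed by adaptive quadrature
and serves purely as a validation oracle for the simulation machinery; it is
never substituted for the simulated PC.

## Numerical choices and problem sizes

* Hotelling solve: `scipy.linalg.solve` on the symmetric mean covariance, no
  explicit inverse; ridge 0 by default, auto-raised to 1e-8 × trace/n only on
  numerical singularity (with a warning).  The explicit-inverse route is kept
  as a test oracle.
* d' uses a Cholesky factorisation and raises with advice to use a ridge if
  the covariance is singular.
* NPS-shaped noise is normalised in closed form (the filter's mean-square
  value), not by Monte-Carlo calibration.
* Degenerate inputs are rejected with specific errors: even ROI sides,
  oversized discs, fewer than 2 training ROIs per class, noise pools smaller
  than m−1, fewer than 2 bootstrap replicates, ROIs crossing image
  boundaries (offending centres listed).
* Test and validation problem sizes: the factorial sweep runs the full
  32-category default grid (a few seconds); the chance-level and
  closed-form-oracle checks use 9-pixel ROIs with a grid-matched 6-channel
  bank and pools of 10^4–10^5 ROIs so that each trial uses fresh draws — with
  the study-sized 100-ROI signal pool, the conditional-on-pool PC itself
  varies by a few percentage points, which would confound a comparison
  against the fresh-draw binomial/closed-form expectation.

## Known limitations

* The synthetic noise is a statistical surrogate; absolute PC values depend
  on the chosen reference noise magnitude and transfer to real scanners only
  qualitatively.  Quantitative use requires extracting ROIs from real
  acquisitions (`choct extract`).
* Resubstitution training biases PC slightly upward relative to a held-out
  protocol; the package reports the protocol it implements rather than
  correcting for it.
* The bootstrap holds the template and the noise pool fixed, so the reported
  SD understates variability attributable to training-set and noise-pool
  sampling.
* No internal-noise calibration to human data is provided; the CHO here is
  an upper-envelope linear observer, not a fitted human surrogate.
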