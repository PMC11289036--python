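# Methods

## Preprocessing

Browser cursor logs are event-driven: positions arrive only while the
cursor moves, at 8–12 ms intervals. We place each coordinate on a
uniform grid by linear interpolation, with the grid origin at the first
observed timestamp and no extrapolation beyond the last — positions
outside the observed span would be fabricated. The default interval is
`dt = 20 ms` (Nyquist 25 Hz, comfortably above voluntary movement
frequencies). Duplicate timestamps keep the last record (browsers can
emit repeated poll times; last write wins matches event order). The two
coordinates are embedded as one complex series `z = x + iy`; lengths
are forced even (dropping at most one trailing sample) so the two-sided
spectrum index range `-N/2 .. N/2-1` is well-defined, and a cohort is
trimmed to its shortest member — taking the *first* N\* samples, a
choice the data alone cannot dictate (trimming from the end would be
equally defensible). Clicks are carried as metadata only and never
enter the spectral or DFA computations.

We deliberately avoid derivative-based kinematics (velocity,
acceleration, jerk): differencing amplifies the noise of an already
discontinuous sampling process.

## Spectral convention

The forward DFT carries the `1/N` factor and coefficients are stored
negative-frequencies-first, so the synthesis relation in the README
holds verbatim and reconstructs the series to machine precision.
Relative to `numpy.fft.fft` this is a division by `N` plus an
`fftshift`. η is invariant to this scaling, but a fixed convention
keeps persisted spectra bit-stable. Frequencies are reported in Hz
(converting `dt` from ms). No demeaning or windowing is applied before
the transform; the DC bin is retained in spectra but excluded from
log-log slope fits (log of zero frequency is undefined), which use
positive-frequency bins only, dropping and counting zero-power bins.

## Subspace and η

The cohort spectra matrix is decomposed **without mean-centering**: the
SVD is applied to `A` as-is, and centering is exposed as an
off-by-default option (`svd(..., center=True)`). Centered and
uncentered analyses coincide in their leading subspace when the cohort
mean is small relative to the dominant components, but they are not
identical; we treat the uncentered decomposition as primary and leave
the option to the user.

`k` is the smallest truncation whose cumulative squared-singular-value
fraction reaches the threshold (default 0.5). Ties among singular
values are left to solver order: the *subspace*, not the basis, is the
contract, and tests compare spans via principal angles. Persisted bases
rotate each column's largest-magnitude entry to be real-positive so
files are reproducible despite the phase ambiguity of singular vectors.
`P < N` is asserted — more participants than frequency bins would make
the thin SVD trivially complete and η meaningless.

η is computed as `||Ũ*Z|| / ||Z||` (equal to `||ŨŨ*Z|| / ||Z||` for an
orthonormal basis) and clipped into `[0,1]` against roundoff. For a
uniformly random direction in `C^N`, `η²` has expectation `k/N` — the
calibration check used in the tests and acceptance script.

## Complex DFA

Windows are forward-only, non-overlapping, with the remainder beyond
`⌊N/s⌋·s` dropped; the fluctuation normalizes by the number of covered
points. A both-ends variant (`mode="both"`, tiling from both ends so no
point is uncovered) is exposed as an option. Detrending degree defaults
to `d = 1`; the polynomial is fit by a single complex least-squares
solve, equivalent to independent real/imaginary fits on the shared
design, and residual magnitudes `|r|²` are used. The default scale grid
is ~20 geometrically spaced integer sizes in `[4, N/4]`: 4 is the
smallest window a linear fit leaves meaningful residuals in, and the
`N/4` cap keeps at least four windows per scale. Scales with exactly
zero fluctuation (perfectly detrendable profiles) are dropped from the
log-log fit with a warning rather than floored — flooring would bias
the slope. Natural log is used; the base is immaterial to α.

Interpretation: α ≤ 1 → stationary, `H = α`; α > 1 → non-stationary
(fractional Brownian motion regime), `H = α − 1`; in both regimes
H below / at / above 0.5 reads anti-correlated / uncorrelated /
positively correlated (boundary tolerance 1e-6). α outside `[0, 2)` is
outside the fractional model; H is still reported, with a warning.

## Synthetic data

The generators define the study conditions the tests run under.

**Complex fGn** uses Davies–Harte circulant embedding: the exact target
autocovariance `γ(k) = σ²/2 (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H})` is
embedded in a circulant of size 2N whose eigenvalues (nonnegative for
fGn) are obtained by FFT; filtering complex white noise through the
square root yields a proper complex Gaussian vector whose real and
imaginary parts are independent fGn samples with exactly that
covariance. Exactness matters: the DFA recovery bands (mean α within
0.08 of H over 50 replicates at N = 8192) assume an unbiased generator.
Approximate synthesizers (midpoint displacement, truncated wavelet)
would confound generator bias with estimator bias.

**Planted cohorts** draw a random orthonormal `k_true = 8` dimensional
basis in `C^512`; in-cohort spectra are unit-norm random combinations
of it, off-cohort spectra unit-norm draws from its orthogonal
complement, both plus complex Gaussian noise at relative level 0.3 and
cohort sizes 40/40 — conditions under which the fitted subspace must
separate the groups (η gap > 0.2, Welch p < 1e-4). The trace-level
variant mixes in- and off-subspace components with weight `w ~ U(0,1)`,
synthesizes time series through the inverse transform, and assigns
accuracy `w` plus N(0, 0.03) jitter, so accuracy and spectral content
are coupled by construction and the full pipeline (resample → spectra →
subspace → η → regressions) can be validated end to end.

**Gameplay agent.** The game follows the task parameters: 120 targets,
650 ms visibility, 350 ms knock-out display after a hit, a 9-hill grid
on an 800×600 px field, polling jittered uniformly in 8–12 ms, and a
target schedule drawn uniformly over hills excluding the current one,
fixed by the game seed so every agent sees the same pseudo-random
sequence. The agent is a noisy proportional controller (step fraction
`gain·Δt`, clamped to never overshoot, speed-capped at 1500 px/s,
Gaussian motor and click jitter) with a reaction latency, plus a
"camper" strategy that parks on one hill and clicks on a cadence. It is
**not** a model of human motor control; it exists to produce cursor
logs whose accuracy is known by construction, with accuracy monotone in
reaction speed. The defaults (reaction 250 ms, gain 0.012/ms, noise
1.5 px) give mid-range accuracies and ~45–110 s games (~4–11k samples,
resampling to roughly the trace lengths the preprocessing targets).

What the synthetic data does **not** emulate: real cursor logs pause
when the hand rests (event-driven gaps), have screen-resolution and
device heterogeneity, and human spectra share structure for behavioral
reasons rather than by linear-algebraic construction. Passing tests
therefore certify the estimators and the pipeline plumbing — unbiased
exponent recovery, correct projections, correct statistics — not that
any particular human cohort will separate.

## Statistics

Group splits use strict inequalities (accuracy strictly above 0.505 /
strictly below 0.12 by default; boundary values fall in the excluded
middle band). Welch's unequal-variance t-test with Welch–Satterthwaite
df contrasts η between groups; all p-values are two-sided and no
multiple-testing adjustment is applied (single planned tests). Because
"η regressed on accuracy" and "accuracy regressed on η" are both
defensible readings of the design, the pipeline computes and labels
**both** directions. DFA α is regressed on accuracy the same way.

## Numerical notes and limitations

- Resampling CSV round-trips are exact at double precision (`%.17g` on
  write, `float_precision="round_trip"` on read); read-back snaps `dt`
  against last-ulp wobble so cohorts agree on the grid exactly.
- `run_study` is deterministic given its inputs; subspace provenance
  hashes cohort ids and settings, so swapped samples never reuse a fit.
- Degenerate inputs fail loudly: constant series (DFA), zero spectra
  (η), zero-variance predictors (OLS) raise or are flagged in the
  report rather than silently producing numbers.
- Problem sizes in the test suite and acceptance script (N = 8192, 50
  replicates for exponent recovery; 512-dim planted cohorts of 40+40)
  were chosen as the smallest at which the estimators' sampling error
  is comfortably inside the stated bands.
- Single-trace DFA at small N (< ~1000) has well-known finite-size bias
  at the ends of the scale grid; the default `[4, N/4]` band mitigates
  but does not remove it. No crossover detection or multifractal
  extension is provided.
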