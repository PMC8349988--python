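# Methods

## Model

A texture image `I(x, y)` (square, side a power of two, luminance in
[0, 1]) is represented by two amplitude spectra.

**1st order.** The 2D DFT of `I` (unnormalized forward transform, `1/size`
inverse — the numpy/scipy convention, used throughout). Amplitude and
phase are kept full-size; Hermitian symmetry makes half of each redundant,
which only the representation-size accounting exploits.

**2nd order.** `I` is decomposed by a log-Gabor filter bank into analytic
subbands; the subband energy `E(x, y, ori, freq) = |response|` — the
square root of the summed squares of the even/odd quadrature pair — forms
a 4D array whose 4D DFT is the 2nd-order spectrum. Cross-orientation and
cross-scale energy correlations, which factorial texture models track as
separate statistics, appear here as autocorrelation along the `ori` and
`freq` axes, i.e. (by Wiener–Khinchin) in the 4D amplitude spectrum. The
orientation axis is physically circular with period 180°; the scale axis
is not, but the plain FFT treats both as circular. No windowing or
tapering is applied to the energy data before the transform.

## Filter bank

Filters are defined in the 2D frequency domain as the product of a
log-Gaussian radial profile, `exp(-(log2(f/f0))² / (2σ_f²))`, and a
Gaussian angular profile in wrapped angle difference. σ is set from the
half-magnitude full widths: `bw_octaves` (default 1 octave) and
`bw_ori_deg` (default 30°), so the gain is 0.5 at ±half a bandwidth from
center and exactly 1 at the center. Defaults: 8 orientations (0–157.5° in
22.5° steps) × 8 frequencies (1–128 cycles/image, 1-octave spacing) at
256 px. Configurations whose top center frequency exceeds the Nyquist
limit are rejected by name.

Quadrature pairs are realized as analytic filters: each gain map lives on
the half-plane within 90° of its center direction, and the band response
is `ifft2(2 · G · fft2(I - mean))`, a complex image whose real/imaginary
parts are the even/odd pair. The Nyquist row/column is assigned the
positive frequency `+N/2` so Nyquist-centered bands peak inside their
half-plane. All bands are kept at full resolution — the 4D transform needs
a rectangular array — so there is no pyramid downsampling.

Log-Gabor banks have no DC response and do not tile the spectrum: with
unit peak gains at 1-octave spacing the combined squared gain oscillates
between about 0.46 and 1.10 across the covered annulus (reported by
`tiling_deviation`, 0.54 for the default bank; the Nyquist row/column is
excluded from the measure because its self-conjugate samples are
double-counted by the even/odd symmetrization). Invertibility does not
depend on tiling: low/high-pass residual filters take up the complement
below the lowest and above the highest center frequency, the image mean is
carried separately, and reconstruction divides the re-filtered sum by the
combined squared gain (floored at 1e-3), which makes
`reconstruct(decompose(·))` exact to machine precision for any input. The
residual bands and the mean pass through synthesis untouched by the energy
constraint.

## Synthesis

One round of luminance–energy phase randomization, with the previous
round's output (white noise on round 1) as phase source:

1. impose the target's 1st-order amplitude on the current phase (DC phase
   forced to 0, preserving the mean; a real phase source keeps the result
   real);
2. decompose, take energies, and impose the target's energy amplitude on
   the current energy phase — one 4D FFT in `lepr4d`, per-band spatial 2D
   FFTs in `lepr2d`; the inverse transform can produce small negative
   values, which are clipped to zero (energy is non-negative by
   definition) after the construction has been verified pre-clip;
3. rebuild linear subbands as `new_energy × carrier`, where the carrier is
   the current analytic response divided by its magnitude (floored at
   1e-12 of the peak energy), and collapse them;
4. rank-order histogram matching to the target (the output's sorted pixel
   values equal the target's exactly, so this is also the last step of
   every round).

Exactly `iterations` rounds are run (default 20); convergence is recorded
in per-round traces (relative L2 distance of the 1st- and 2nd-order
amplitudes from the target's) but never tested for. Re-imposing the
1st-order amplitude every round, rather than only at initialization, keeps
the two constraints and the histogram in balance; this was a genuinely
open design point and the per-round traces justify it empirically. The
`lpr` baseline alternates step 1 and step 4 only. Uniform white noise
seeds the phase; only its phase is used, so its marginal distribution is
irrelevant. Runs are deterministic given (target, config, seed).

## Synthetic targets

The fixture generator emulates the qualitative texture classes the method
distinguishes: gratings (`0.5 + 0.5·c·sin`, closed-form spectra), plaids
(mean of two gratings — cross-orientation energy correlation, the
structure that separates the 4D from the 2D variant), band-passed noise
(spectrum-only texture), periodic tilings (strong 2nd-order periodicity,
the method's best case), and white noise. It does not emulate natural
photographs: no 1/f spectral falloff, no shading from directional
lighting (a known weak class for phase-based synthesis), no luminance
nonlinearity. Passing tests therefore demonstrate the algorithmic
contracts and the direction of the 4D-vs-2D difference, not perceptual
quality on natural images.

One analytic fact shapes the convergence fixtures: a pattern whose
spectrum sits entirely on grid harmonics with a rigid phase relation — an
integer-frequency grating, a tiling whose period divides the image size —
is an exact fixed point of the iteration after round 1 (phase
randomization merely translates it), so its trace is constant and can show
no improvement. Convergence and variant-separation measurements therefore
use off-lattice parameters: grating/plaid frequency 8.5 cycles/image, tile
period 24 on a 128-px image.

The Thurstonian rank generator draws method utilities as true scores plus
unit-SD Gaussian noise per (observer, item) cell and ranks them, matching
the standard Case V noise model; the recovery check uses 8 observers × 300
items, the design size of the perceptual experiment this pipeline serves,
with true scores 0.4 apart.

## Scaling

Win proportions `p[i, j]` count how often method `i` out-ranks `j` over
all (observer, item) cells; `p + pᵀ = 1` off the diagonal. Scores are
`Σ_j log p[i, j]` with proportions floored at `1/(2·n_comparisons)` so
empty cells stay finite, then shifted to a minimum of 0. The log is taken
of proportions (0–1), not percentages — the choice shifts all scores by a
constant that does not cancel fully under min-normalization, so it is
fixed here and documented. The classical probit (Case V) transform is
available as an option and preserves orderings. Welch's unequal-variance
t on per-observer score vectors is exposed for across-observer inference.

## Problem sizes and numerics

Analysis-stage checks (round trip, spectrum preservation) run at the
native 256 px with the default 8×8 bank. Iterated synthesis batteries run
at 128 px, where a one-octave bank can hold at most 7 bands (top center 64
cycles/image = Nyquist), with 20 iterations and ≥10 seeds per condition
in the test suite (5 in the acceptance script). Tiny 4×4(×2×2) arrays back
the brute-force DFT and Wiener–Khinchin oracles. Ties in histogram
matching and ranking are broken by stable sort order, keeping every
pipeline bit-reproducible. Degenerate inputs behave by construction: a
constant image passes through decomposition via the mean/residual path,
zero energy yields a zero carrier contribution via the ε floor, and a
constant target is its own phase-randomization.

## Limitations

The 2nd-order spectrum wraps the scale axis circularly, an approximation
flagged above; subbands are not downsampled, so memory grows as
`N²·n_ori·n_freq`; synthesis quality on natural photographs with complex
shading is outside what the synthetic fixtures can certify; and the
perceptual experiment itself (human rank data) is not reproduced — the
scaling module is validated on synthetic Thurstonian data only.
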