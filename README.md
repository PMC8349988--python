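# texspec

Two-stage spectral texture analysis and synthesis for visual neuroscience
and psychophysics.

The package implements a model of human texture perception in which a
texture is fully described by two amplitude spectra:

* the **1st-order spectrum** — amplitude and phase of the 2D Fourier
  transform of the luminance image `I(x, y)`;
* the **2nd-order spectrum** — amplitude and phase of the 4D Fourier
  transform of the subband-energy data `E(x, y, ori, freq)`, where
  `E = sqrt(even² + odd²)` is the magnitude of the quadrature-pair
  (analytic) response of a log-Gabor filter bank (by default 8 orientations,
  0–157.5° in 22.5° steps, and 8 frequency bands, 1–128 cycles/image in
  1-octave steps, with 1-octave and 30° half-magnitude bandwidths).

This is the Filter–Rectify–Filter architecture read as spectral analysis,
with the second stage extended from 2D (space only) to 4D (space ×
orientation × frequency), so that cross-orientation and cross-scale energy
correlations become ordinary autocorrelations along the two extra axes; by
the Wiener–Khinchin theorem they are encoded in the 4D amplitude spectrum.

The model is validated by synthesis: **luminance–energy phase
randomization (le-PR)** starts from white noise and iteratively imposes
(1) the target's 1st-order amplitude spectrum, (2) the target's 2nd-order
amplitude spectrum (keeping the current phases — 4D FFT in `lepr4d`,
per-band 2D FFTs in `lepr2d`), and (3) the target's pixel histogram by
rank-order matching, for 20 rounds. The `lpr` baseline imposes only (1)
and (3). If the two spectra capture texture appearance, the synthesized
image — which shares nothing with the target but those spectra and the
histogram — should look like the same texture.

A companion module scales paired-comparison rank data (observers ranking
synthesis methods per texture) into interval quality scores via a Thurstone
Case V variant: each method's score is the sum of log win proportions
against the other methods, normalized to a minimum of 0.

## Worked example

Synthesize a texture from a periodic tiling (a class the method handles
particularly well) and watch the two spectral distances fall:

```sh
texspec fixtures --kind tiles --size 128 --tile-period 24 --out tiles.png
printf 'n_freq: 7\n' > bank128.yaml   # 1–64 c/img bands fit a 128-px image
texspec synthesize tiles.png --mode lepr4d --iters 20 --seed 1 \
    --out tiles_lepr4d.png --trace trace.csv --config bank128.yaml
```

which prints

```
lepr4d: final lum distance 0.1815, final energy distance 0.3513 -> tiles_lepr4d.png
```

and writes a per-iteration trace:

```
iteration,lum_distance,energy_distance
1,0.2532366884,0.4881185235
2,0.2325410025,0.4449933582
...
20,0.1814521762,0.351266783
```

Each row gives the relative L2 distance between the current image's
1st-order (luminance) and 2nd-order (4D energy) amplitude spectra and the
target's, after that round's histogram matching. Both distances shrink as
the iteration repairs the distortion each constraint inflicts on the
others; the image `tiles_lepr4d.png` is a new tiling — same periodicity,
contrast structure and histogram, different layout. The same library calls
are available in Python (`texspec.synthesize`, `texspec.SynthesisConfig`),
and `texspec analyze`, `texspec fixtures` and `texspec scale` cover
spectrum extraction, synthetic targets and rank scaling.

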