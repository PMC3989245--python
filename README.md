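# persistlen

Persistence-length analysis of semiflexible filaments from microscopy
images.

Cytoskeletal polymers such as actin filaments and microtubules behave as
*semiflexible* polymers: at cellular length scales they undergo visible
thermally driven bending fluctuations. The standard quantitative measure
of their bending stiffness is the **persistence length** Lp = κ/kT of
the wormlike-chain model, where κ is the flexural rigidity and kT the
thermal energy. `persistlen` extracts Lp from images of surface-adsorbed
filaments or of a single freely fluctuating filament, by tracing
one-pixel-wide filament backbones in skeletonized images, reconstructing
smooth shapes, and fitting three complementary statistics:

1. **Cosine correlation** — for shapes equilibrated in two dimensions the
   tangent-angle correlation decays as

   C(s) = ⟨cos(θ(s) − θ(0))⟩ = A·exp(−s / 2Lp),

   where s is the segment (arc) length. The amplitude A is left free:
   noise in the determination of relative angles propagates
   asymmetrically through the bounded, even cosine and depresses the
   measured correlation by exp(−σ²/2), so constraining A = 1 would bias
   Lp.
2. **End-to-end distance** — the mean square end-to-end distance of a 2D
   wormlike chain obeys

   ⟨R²⟩(L) = 4·Lp·L − 8·Lp²·(1 − exp(−L / 2Lp)),

   with one data point per filament; it needs many filaments and is less
   precise, but it is an independent verification of the cosine result.
3. **Bending modes** (fluctuating filament) — decomposing each frame's
   tangent-angle profile into cosine Fourier modes aₙ, equipartition
   gives var(aₙ) = (1/Lp)·(L/nπ)² for modes n = 1…10, an Lp estimate per
   mode.

The package also ships a synthetic-data module that simulates 2D
equilibrium wormlike chains of known Lp and rasterizes them into
skeleton images (optionally with pixel gaps, spurious branches and angle
noise), so the whole pipeline is testable end to end without microscopy
data.

## Worked example

Simulate 300 chains of true Lp = 10 µm (contour lengths 5–40 µm),
rasterize them to skeleton images, then recover Lp from the images:

```
$ persistlen simulate --lp 10 --n-chains 300 --length-range 5,40 \
      --seed 1 --out demo
wrote 300 skeleton frame(s) and ground truth to demo

$ persistlen analyze demo/skeletons.tif --pixel-size-um 0.1 --out out
...
[cosine]
method: cosine
Lp = 10.42 +/- 0.016 um
amplitude A = 1.015
fit range: 0 - 82.75 um
n_samples: 35074320
flexural rigidity kappa = 4.29e-26 J*m

[end_to_end]
method: end_to_end
Lp = 10.73 +/- 0.3 um
fit range: 5.164 - 39.75 um
n_samples: 300
flexural rigidity kappa = 4.415e-26 J*m
```

Both estimators recover the true 10 µm within their expected sampling
error (the quoted ± is the fit standard error, which understates the
ensemble-to-ensemble spread because samples within one filament are
correlated). The cosine fit reports the free amplitude A ≈ 1 (clean
synthetic skeletons carry almost no angle noise) and the fit range
chosen automatically as [0, 8·Lp], the window in which a semiflexible
chain is informative about Lp. `out/` also contains the binned
correlation, per-filament (L, R²) records, traces, shapes and the
resolved configuration, all as CSV/JSON for independent refitting.

For a time series of a single fluctuating filament, add
`--mode fluctuating` to include the bending-mode analysis; raw
micrographs can be reduced to skeletons first with
`persistlen preprocess` (background subtraction, Gaussian smoothing,
contrast normalization, thresholding, thinning).

The same functionality is available as a library:

```python
from persistlen import (WLCParams, simulate_fluctuating_filament,
                        compute_mode_amplitudes)
from persistlen.wlc import fit_modes

frames = simulate_fluctuating_filament(
    WLCParams(lp=10.0, contour_length=15.0, seed=13), n_frames=2000)
fit = fit_modes(compute_mode_amplitudes(frames), modes=range(1, 6))
print(fit.report())   # Lp = 9.878 +/- 0.075 um, modes used: [1, 2, 3, 4, 5]
```

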