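# dxblink

Diffracted X-ray blinking (DXB) analysis: per-pixel autocorrelation of
time-resolved X-ray diffraction movies, plus a synthetic blinking-movie
simulator with known ground truth.

Under monochromatic X-rays, the diffraction spots that crystallites (or
gold nanocrystal labels on proteins) place on a Debye–Scherrer ring blink
on and off as the crystallites rotate in and out of the Bragg condition.
DXB reads the blinking rate out of each detector pixel's intensity series
I(t) through its normalized autocorrelation

    ACF(τ) = ⟨I(t)·I(t+τ)⟩ / ⟨I(t)⟩²,

fits the single exponential ACF(t) = y + A·exp(−Γt) (or its mirrored,
saturating form for pixels dominated by spot entry), keeps fits satisfying
A, y, Γ > 0 and residual < 1.0, and summarizes the accepted decay
constants per condition (median, Cauchy–Lorentz mode, rank-sum
comparisons). The ensemble median converts to a rotational diffusion
coefficient

    D_R = Γ · Φ_θ² / 4   [pm²/s],

with Φ_θ the calibrated rotational displacement in picometers. The target
data are photon-counting detector movies (e.g. Pilatus, 50 ms/frame,
100 s) from laboratory X-ray sources; the package is aimed at structural
biophysicists and materials scientists applying DXB to proteins, single
crystals, and crystalline polymers.

The simulator generates movies of blinking spots on a ring — two-state
telegraph kinetics (or bounded angular diffusion), 3×3-pixel footprints,
Poisson photon noise, optional linear drift — so every stage of the
analysis can be validated against known rates.

## Worked example

From `examples/analyze_per_pixel_acf.py` — simulate a movie of 76 spots
blinking at k_on = k_off = 0.3 /s and recover the rate sum from the ring
pixels:

```text
748 ring pixels analyzed, 634 accepted, 114 rejected
direction split: {'decay': 617, 'growth': 17}
median Gamma = 0.576 /s (ground truth 0.60 /s)
Lorentz mode = 0.536 /s, IQR = 0.652
```

The median accepted decay constant estimates k_on + k_off = 0.6 /s; the
wide spread (and the few-percent median offset) reflects the handful of
on/off transitions each spot undergoes in 100 s. `examples/rotational_diffusion_table.py` converts published
condition summaries into D_R:

```text
system                              2theta  d (A) phi (pm)  Gamma D_R (pm^2/s)
BSA (gold label, 3x3 binning)        38.24   2.35     3.18   0.29         0.73
AFP single crystal (1x1)             12.59   7.02     2.55   0.40         0.65
PC8FA polymer (2x2 binning)          18.51   4.79     6.51   0.31         3.28
```

The other examples cover movie simulation and the observation-time
robustness study (rank-sum significance between two conditions degrading
as recordings are split into shorter pieces).

## Command line

```sh
dxblink simulate --config run.yaml --out sim/
dxblink analyze  --config run.yaml --stack sim/movie.tif --mask sim/mask.tif --out results/
dxblink compare  results_a/dxb_accepted_gammas.csv results_b/dxb_accepted_gammas.csv --out cmp.tsv
```

Every run echoes its resolved configuration and seed, so outputs are
bit-reproducible. `analyze` writes a per-pixel CSV (0-based row/col on the
binned grid) and a schema-versioned ensemble JSON.

## Documentation

`docs/methods.md` describes the estimator, the fit constraints and
acceptance rules, the detrending test, the simulator's physical model and
its deliberate simplifications, and known limitations.
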