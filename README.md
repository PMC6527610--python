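# melabright

Melanopsin's contribution to brightness perception, as a reusable analysis
pipeline: melanopic photometry, silent-substitution metamer design on a
six-primary basis, pupil light-reflex modelling, and a two-term power-law
brightness model with its melanopsin contribution ratio — exercised
end-to-end on synthetic observers.

## Who this is for

Visual psychophysicists and lighting researchers who want to quantify how
intrinsically photosensitive retinal ganglion cells (ipRGCs, expressing the
photopigment melanopsin, peak sensitivity near 480 nm) contribute to
perceived brightness alongside the cones — and to design the metameric
white stimuli such an experiment needs.

## The model

Corneal stimulus strength is summarised by two photometric functionals of
the spectral power distribution *P*(λ):

- luminance *L* = 683 ∫ *V*(λ) *P*(λ) dλ (cd/m²), and
- melanopic luminance *M* = 4557 ∫ *i*(λ) *P*(λ) dλ (melanopic cd/m²),

with *i*(λ) the peak-normalised melanopsin sensitivity. Their ratio M/P is
a scale-invariant property of the spectrum. The pupil converts corneal to
retinal quantities through its area *S* = π(d/2)²: retinal illuminance
*E* = *L·S* (trolands, Td) and melanopic retinal illuminance *G* = *M·S*
(melanopic cd/m²·mm²). Pupil diameter follows a decreasing logistic in the
combined drive,

    d(M, L) = A / (1 + exp(k_M·M + k_L·L)) + d0,

with reference coefficients A = 1.74 mm, k_M = 0.0040, k_L = 0.0012,
d0 = 2.58 mm. Perceived brightness *R* (magnitude estimation, reference
stimulus ≡ 100) is the sum of a nearly linear melanopsin term and a
compressive cone term,

    R = a·G^α + b·E^β,

with reference coefficients a = 4.84×10⁻³, α = 1.1, b = 2.31, β = 0.48.
Because α > β, the melanopsin share of brightness — the *contribution
ratio* a·G^α / (a·G^α + b·E^β) — grows with stimulus intensity, reaching
one half and more at the top of the studied range.

Stimuli that separate the melanopsin pathway from the cones are *metamers*:
spectra with identical L-, M-, S-cone (optionally also rod) excitations
but different melanopsin excitation. The designer finds them by linear
programming over the drive weights of a six-primary projector basis
(Gaussian surrogates at the published peaks 610, 524, 438, 659, 547,
483 nm), maximising the melanopsin difference at a fixed chromaticity and
luminance. Colorimetry is cone-fundamental-based (CMFs projected onto the
cone-curve span), so cone-silent families share chromaticity and luminance
exactly.

## Worked example

```python
import melabright as mb

manifest = mb.run_all({"seed": 0})
print(manifest.summary["mp_ratios"])
print(manifest.summary["r2_full"], manifest.summary["r2_cone_only"])
```

The default run designs the seven stimulus classes (a cone-and-rod-silent
pair A/B and a cone-silent quintet C–G at chromaticity (0.328, 0.367),
luminances 22–112 cd/m²), simulates 9 observers × 3 repeats, and fits the
pupil and brightness models. With seed 0 it prints:

```
designed M/P ratios: A=6.33, B=5.32, C=8.30, D=7.18, E=6.06, F=4.94, G=3.82
melanopic contrast: cone-silent 2.17, cone-and-rod-silent 1.19
pupil fit r^2 = 0.995
brightness fit r^2: full 0.996 vs cone-only 0.885
max melanopsin contribution ratio 0.484
```

Reading: the designer achieves a 2.17-fold melanopsin modulation between
cone-metameric whites; the full melanopsin + cone model explains the
simulated ratings far better than the nested cone-only reduction; and at
the brightest, most melanopic stimulus almost half of modelled brightness
is carried by melanopsin. The same pipeline is available from the shell:

```bash
melabright design --xy 0.328 0.367 --lum 22:112:5 --mode cone-silent \
    --levels 5 --out family.json
melabright simulate                      # ratings.csv, pupil.csv
melabright fit-pupil --data pupil.csv --out pupil.json
melabright fit-brightness --data ratings.csv --model full --out fit.json
melabright run --outdir results/        # full report + manifest
```

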