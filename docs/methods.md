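# Methods

## Photometry and sensitivities

All spectral quantities live on a uniform wavelength grid (default
380–780 nm at 1 nm) and integrals use the rectangle rule Δλ·Σ, which keeps
every photometric functional exactly linear in the spectrum. Luminance is
683 ∫V(λ)P(λ)dλ; melanopic luminance is 4557 ∫i(λ)P(λ)dλ with i(λ)
peak-normalised. The 4557 scaling is treated as a fixed convention paired
with peak normalisation: absolute "melanopic" units differ between
conventions in the literature, but the M/P ratio and everything downstream
are invariant to the pairing as long as it is used consistently.

Receptor sensitivities (L/M/S cones, rod, melanopsin) are generated by a
vitamin-A1 photopigment template (alpha band) — a fixed function of
λmax/λ — at canonical corneal peak wavelengths 566, 541, 441, 507 and
480 nm. The template path keeps the package self-contained; measured
tables can be substituted through the CSV loaders. An age-dependent
ocular-media (lens) filter is available: optical density is a
two-component table, D(λ) = TL1(λ)·(1 + 0.02(age − 32)) + TL2(λ) for ages
up to 60 (steeper beyond), with density extrapolated linearly below
400 nm and zero above 650 nm; filtered curves are re-peak-normalised.

### Cone-fundamental-based colorimetry

Chromaticity and V(λ) are computed from colour-matching functions obtained
by least-squares projection of an analytic fit of the 1931 2° CMFs onto
the span of the bank's own cone curves. The projection preserves each
CMF's integral (so the equal-energy white point survives, (x, y) within
0.005 of (1/3, 1/3)), and the luminosity row is fitted with non-negative
coefficients so the derived V(λ) is non-negative. The motivation is
physical, not cosmetic: for a real observer, luminance and chromaticity
*are* linear combinations of cone excitations, so stimuli with matched
cone excitations are automatically matched in colour and luminance. With
independent tabulated CMFs this identity fails by the table-vs-template
residual, and imposing chromaticity as extra constraints would leave the
metamer designer no freedom at all (six independent functionals on six
primaries). The price is a small bias of the projected colorimetry
relative to the standard observer (V peaks at 564 nm rather than 555 nm);
for this package's purpose — internal consistency of design, simulation
and fitting — the consistent system is the right trade.

## Metamer design

Primaries are unit-peak Gaussians with the published peaks/FWHMs
(610/37, 524/26, 438/15, 659/61, 547/42, 483/37 nm), standing in for
measured projector spectra that are only available graphically; measured
CSV spectra can be substituted. A stimulus family is designed by a single
joint linear program over the stacked weight vectors of its two extreme
members: maximise the melanopsin difference subject to (a) the
melanopsin-high member hitting the tristimulus target (x, y, luminance)
expressed as linear equalities X = (x/y)Y, Z = ((1−x−y)/y)Y, and (b) the
two members agreeing exactly in the silenced receptors (L/M/S cones, plus
rods in cone-and-rod-silent mode). Optimising the pair jointly matters:
extremising melanopsin around a fixed, separately-chosen cone operating
point typically lands on a gamut vertex where melanopsin cannot move.
Intermediate family members are convex combinations of the extremes, so
every member shares the silenced excitations, chromaticity and luminance
to machine precision and melanopsin levels are exactly evenly spaced.
Families at lower luminances are uniform rescalings (M/P and all
excitation ratios invariant), mirroring how a projector dims.

LP details: HiGHS with 1e-10 feasibility tolerances on row-normalised
constraints, followed by a polish step that freezes bound-active weights
and re-solves the free ones by least squares (kept only if it improves
the residual and stays in the box). Vertex solutions activate at most as
many primaries as there are constraints, which reproduces the classic
practice of 4-of-6 primaries for cone-silent and 5-of-6 for
cone-and-rod-silent stimuli; the designer reports the active subset
rather than fixing one in advance. Degenerate (rank-deficient) primary
sets are rejected at basis construction. Infeasible targets (chromaticity
outside the gamut at the requested luminance) raise a dedicated error
naming the constraint set.

With these surrogates the designer reaches a cone-silent melanopic
contrast of 2.17 at the study chromaticity (0.328, 0.367) — comfortably
demonstrating the design principle, though below the 3.6 the original
measured primaries achieved — and a cone-and-rod-silent contrast of 1.19,
in line with the 1.148–1.22 reported for earlier silent-substitution
designs.

## Pupil and brightness models

The pupil model d = A/(1 + exp(k_M·M + k_L·L)) + d0 is fitted by
trust-region nonlinear least squares in a transformed parameterisation
(log A, log d0, softplus gains) that enforces positivity, with 5
deterministic multi-starts (fixed-seed jitter) because logistic fits are
initialisation-sensitive. It represents the *minimum* diameter during a
stimulus presentation — the quantity the retinal conversion uses — not
pupil dynamics. r² is 1 − SSres/SStot against the mean, the standard
convention.

The brightness model R = a·G^α + b·E^β (and its nested cone-only
reduction R = b·E^β) is fitted the same way on log-parameters, from five
neutral exponent initialisations with the linear coefficients pre-solved
by non-negative least squares at each trial exponent pair. Convergence
tolerances are 1e-14 on cost and step; noise-free recovery of all four
coefficients is exact to machine precision, and an independent profiled
grid-refinement oracle (closed-form coefficients on a refined 2-D
exponent grid) confirms the optimum in the tests. Rank checks warn when
M ∝ L (pupil) or G ∝ E (brightness) make terms unidentifiable. Both
estimators follow the scikit-learn protocol (fit/predict/get_params,
fitted attributes with trailing underscores) and compose with sklearn
tooling.

The equal-brightness radiance shift solves, by bracketed root-finding,
for the uniform radiance scale at which a test stimulus matches the
brightness of a reference whose melanopic excitation is raised at fixed
cone excitation, with the pupil re-adapting at each radiance. The
operating point is a free parameter because it is genuinely ambiguous;
at (L = 112 cd/m², M/P = 9.3) a +11% melanopic boost requires a +8.1%
radiance increase under the reference coefficients — the same sign and
order as the +13% consistency figure quoted for an equivalent published
comparison, with the gap attributable to the unstated operating point.

## Synthetic observers

The generator emulates the study design: 7 metameric white classes (the
rod-and-cone-silent pair A/B and the cone-silent quintet C–G, in
decreasing melanopsin), luminances 22–112 cd/m² (five levels including
102 and 112, the levels used for the pairwise statistics), 9 observers,
3 repeats. Per trial, pupil = model + Gaussian noise (σ = 0.1 mm) and
rating = corneal brightness model × lognormal noise (σ = 0.1) × a
per-observer lognormal scale (σ = 0.1). Repeats are averaged per
observer, then each observer's ratings are normalised so their reference
condition (highest-melanopsin class at top luminance) scores 100 —
exactly how magnitude estimation removes the observer's private scale,
which is why the generating coefficients are themselves re-anchored to
the reference before simulation (coefficients are only defined up to
that common scale). Noise magnitudes are conventions: the source data
report only graphical SEM bars. What the generator does *not* model:
magnitude-estimation compression differences between observers (observer
heterogeneity is a pure scale factor), dark-adaptation dynamics,
stimulus timing, or rod intrusion at low luminance. Passing round-trip
tests therefore demonstrate correctness of the estimation machinery
under the assumed generative model, not robustness to real-observer
deviations from it.

Pairwise condition contrasts use a paired two-tailed t-test across
observers with optional Bonferroni correction. At the default noise the
extreme cone-metamer pair separates decisively (Bonferroni p ≈ 1.5e-4 at
seed 0); the rod-silent pair, whose surrogate melanopic contrast is only
1.19, is underpowered at α = 0.01 (~14% over seeds) — a faithful
consequence of the surrogate primaries, not of the statistics.

## Pipeline and problem sizes

`run_all` chains design → simulate → fit (pupil; brightness full and
cone-only) → contrasts → contribution-ratio tables (including
extrapolations to everyday sources, e.g. a 5000 K white LED at M/P 4.2),
and records a manifest with the SHA-256 of the canonical configuration
and all summary metrics; every random draw flows from one root seed via
named substreams. Default problem sizes (35 conditions, 9 observers, 3
repeats; 10×10 noise-free grids for recovery checks) keep a full run
under a second while leaving every estimate deeply over-determined.

## Known limitations

- Surrogate Gaussian primaries and template sensitivities reproduce the
  design *structure*, not the exact printed M/P values (9.3…2.6) of the
  original stimuli.
- The projected colorimetry is internally consistent but offset from the
  standard observer; do not use it to certify absolute chromaticity.
- The daylight reconstruction extrapolates the daylight-locus polynomial
  below 4000 K to cover warm phases down to 2000 K.
- Lens-age corrections show that the melanopsin modulation of the
  designed stimuli is stable to <1% between ages 25 and 32, but S-cone
  metamerism drifts a few percent — narrowband surrogates are more
  age-sensitive than broadband measured spectra.
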