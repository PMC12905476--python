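# stemmorph

Outline morphometrics and simple-eye optics for dorsal views of larval
insect heads.

Predatory lacewing larvae catch prey with a pair of forward-projecting
stylets, and some lineages evolved enlarged forward-facing stemmata
(simple eyes) whose visual fields overlap in front of the head — the
geometric precondition for stereoscopic distance judgement right where the
stylets strike. Asking whether a given head shape is unusual, whether its
eyes are disproportionately large, and whether a proposed eye geometry
could have delivered binocular vision between the stylets takes three
linked quantitative analyses. This package implements all three for
researchers comparing extant and fossil larvae:

1. **Shape morphospace.** Closed head + stylet outlines are decomposed by
   elliptical Fourier analysis (EFA): constant-speed traversal of the
   outline gives periodic signals x(t), y(t), each expanded as a Fourier
   series; harmonic n is the quadruple (aₙ, bₙ, cₙ, dₙ) with power
   Pₙ = (aₙ²+bₙ²+cₙ²+dₙ²)/2. Coefficients are centered and scaled, the
   harmonic count is calibrated so cumulative power reaches 99% of the
   signal, and covariance PCA of the coefficient matrix yields a
   morphospace in which group occupancy is compared by convex hulls.
2. **Eye-size allometry.** Largest-lens diameter d versus head length L is
   fitted as log10 d = b + s·log10 L (OLS; major-axis optional), and
   specimens with residuals above a cutoff are flagged as having
   disproportionately large eyes.
3. **Visual fields.** A 2D dorsal-plane optics model: each stemma is a
   flat lens of aperture a with a retina of extent r at depth D; the field
   half-angle is arctan((r/2+a/2)/D), widened at a flat air–lens interface
   by Snell's law (sin θ_air = n·sin θ_in, default n = 1.4). The binocular
   region is the intersection of the two monocular fields, classified
   against the sector swept by the stylets.

A synthetic-data module generates head outlines, measurement tables and
eye layouts with the statistical structure these analyses assume, so the
whole pipeline runs and is tested without any external data.

## Worked example

```python
import stemmorph as sm

# synthetic study population: 20 tight "extant", 20 dispersed "fossil",
# one wide-headed large-eyed outlier ("new")
oset = sm.gen_population(sm.default_population_spec(seed=1))

n = sm.calibrate_harmonics(oset, threshold=0.99, max_harmonics=40)
pca = sm.run_pca(sm.build_matrix(oset, n_harmonics=n))
rep = sm.occupancy(pca)
print(n, sm.count_components_for_threshold(pca, 0.99))
print(round(100 * pca.variance_fraction[0], 1),
      round(100 * pca.variance_fraction[1], 1))
print(round(rep.hulls["extant"].area, 4), round(rep.hulls["fossil"].area, 4),
      rep.outside_all["new_040"])
```

prints

```
4 5
86.4 7.4
0.0024 0.0395 True
```

— 4 harmonics carry 99% of the outline power of this (smooth, synthetic)
dataset and 5 principal components carry 99% of its variance; PC1 holds
86.4% of the shape variation and PC2 another 7.4%; the extant hull
(area 0.0024 in PC1–PC2 score units) is an order of magnitude tighter
than the fossil hull (0.0395); and the implanted wide-headed specimen
falls outside both hulls.

```python
recs = sm.gen_measurements(50, sigma=0.05, outliers=[(0.2, "fossil")] * 3, seed=1)
fit = sm.fit_loglog(recs)
print(round(fit.slope, 3), round(fit.r_squared, 3),
      sm.flag_above_line(fit, threshold=0.1)[:3])

for r in sm.evaluate_scenarios(sm.gen_layout("flat_short")):
    print(r.scenario, r.mode, r.feasible, r.relation)
```

prints

```
0.834 0.958 ['O002', 'O001', 'O000']
flat_short geometric True between_stylets
flat_short refractive True between_stylets
tapering_long geometric True beyond_stylets
tapering_long refractive True between_stylets
long_clipped geometric False beyond_stylets
long_clipped refractive False beyond_stylets
tilted geometric True none
tilted refractive True none
```

— the fitted allometric slope 0.834 recovers the generating law (0.8)
despite noise, and the three implanted outliers are exactly the specimens
flagged above the line. Among the eye-geometry scenarios, only the short
flat eye is both anatomically feasible and yields stereoscopic overlap
between the stylets in either optical mode; the long tapering eye needs
refraction (n = 1.4) to pull its overlap within stylet range; the long
untapered eye does not fit in the head capsule; and the tilted eye's
fields diverge and never overlap.

The same analyses run from the shell:

```
stemmorph simulate --outdir data --seed 1
stemmorph morphometrics --manifest data/outlines/manifest.csv --outdir out
stemmorph allometry --measurements data/measurements.csv --outdir out
stemmorph vision --layout data/layout.json --outdir out
```

See `docs/methods.md` for the model details, parameter meanings and
limitations.

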