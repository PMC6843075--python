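# spheromotion

Quantification of the dynamics of salivary stem/progenitor (hS/PC)
microstructures in hyaluronate hydrogels, for researchers analyzing
time-lapse and confocal recordings of self-organizing multicellular
spheroids:

- **Rotation** — multicellular microstructures "spin" as they deposit
  basement membrane. The pipeline segments each frame, estimates the
  per-interval rigid rotation about the structure centroid by log-polar
  phase correlation, and reports the angular velocity
  ω = |Σ steps| / t / 360 in rev/h with a CW/CCW direction, applying the
  inclusion rule that only smooth, coordinated structures are quantified.
- **Coverage index** — β₁-integrin (or any marker) expression on a
  structure surface is summarized as I_C = A_marker / A_s with
  A_s = 4πr²: the summed triangulated isosurface area of all marker
  plaques over the theoretical sphere surface. I_C > 1 is expected for
  continuous shells (inner + outer faces).
- **Popping morphodynamics** — major/minor-axis series are segmented into
  contractile/tensile phases; "pops" (basement-membrane failure events)
  are detected as fast tensile intervals, yielding cycle durations (h)
  and volumetric expansions (%) from prolate-ellipsoid volumes.
- **Viability & clustering** — two-channel live/dead volumes give viable
  fractions, single-vs-clustered composition by single-linkage contact
  clustering, and half-open [k, k+1) cells-per-structure histograms.
- **Group statistics** — mean ± SEM summaries, unpaired Student's
  t-tests, one-way ANOVA + Tukey post-test, percent reductions, and the
  hydrogel modulus conversion E = 2G′(1+ν).

Because no primary imaging is distributable, a first-class synthetic
generator (`spheromotion.synthgen`) produces movies, shell stacks,
live/dead volumes and popping series with machine-readable ground truth,
and packaged benchmarks calibrate those scenes to the reported group
operating points (see `docs/methods.md`).

## Worked example

```python
from spheromotion import benchmarks, stats
from spheromotion.rotation import track_rotation
from spheromotion.synthgen import SceneConfig, SpheroidSpec, make_rotating_movie

# one synthetic structure rotating at 0.26 rev/h (92 deg/h), 15 h at 5-min frames
movie, truth = make_rotating_movie(SceneConfig(seed=7), SpheroidSpec(omega_rev_h=0.26))
track = track_rotation(movie)
print(f"omega = {track.omega_rev_h:.2f} rev/h ({track.direction}), "
      f"coordinated = {track.coordinated}")

# knockdown-style contrast on the packaged benchmarks
control = benchmarks.cohort_mean_omega(benchmarks.run_cohort("scrambled", seed=1))
treated = benchmarks.cohort_mean_omega(benchmarks.run_cohort("itgb1", seed=2))
print(f"control {control:.2f} rev/h, treated {treated:.2f} rev/h, "
      f"reduction {stats.percent_reduction(treated, control):.0f}%")
```

prints

```
omega = 0.26 rev/h (CCW), coordinated = True
control 0.25 rev/h, treated 0.04 rev/h, reduction 84%
```

The first line shows the estimator recovering the generator's true rate
and direction on a noisy, drifting movie; the second runs the full
segmentation + rotation pipeline over two calibrated cohorts (25 and 37
movies) and reports the treated-vs-control reduction in mean angular
velocity.

The same workflows are available from the shell:

```
synthgen cohort --group untreated --seed 1 --out scenes/
spheromotion rotate --movie scenes/untreated-000.ome.tif --out tracks/
spheromotion pops --series axes.csv
spheromotion stats --input omega.csv --group-col group --control scrambled
```

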