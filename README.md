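# transleak

Modeling and analysis of **transient vesicle leakage** induced by
membrane-active peptides (antimicrobial and cell-penetrating peptides).

Antimicrobial peptides permeabilize lipid vesicles transiently: a burst of dye
release that stops before the contents are exhausted, restartable by adding
more peptide. Fluorescence requenching experiments (ANTS dye co-entrapped with
the DPX quencher) classify this leakage as *graded* (every vesicle releases
part of its contents; internal quenching `Qin` rises with the released
fraction `fout`) or *all-or-none* (vesicles are intact or empty; `Qin` stays
flat). Real peptides live on a continuum between the two. `transleak`
implements a unified per-vesicle model of that continuum, together with the
supporting analyses of a typical leakage study:

- **`transleak.quench`** — ANTS/DPX quenching arithmetic
  `Q = 1/((1 + K_D[DPX])(1 + K_S[DPX]))` and the ideal graded
  (`Qin = Q([DPX]₀(1 − fout)^α)`) and all-or-none (`Qin` constant) limits.
- **`transleak.unified`** — the unified model: a vesicle leaks with
  probability `Pleak(cp)` and, if it leaks, releases the fraction `fout(cp)`,
  both saturating sigmoids (steepness `C1`, midpoint `C2`) of the normalized
  peptide dose `cp ∈ [0, 1]`. Bulk observables are remaining-dye-weighted
  population averages. Includes χ² fitting (unified: 4 parameters;
  ideal graded: 2 parameters, `[DPX]₀` and `α`) and automatic
  graded / all-or-none / mixed classification.
- **`transleak.surface`** — peptide occupancy statistics on a vesicle surface
  divided into simulation-sized patches (binomial/Poisson statistics, seeded
  random placements on a grid).
- **`transleak.kinetics`** — start-stop leakage time courses: fractional
  leakage from control-normalized fluorescence, initial burst rates (OLS slope
  over the first 10 s after each peptide addition), and the cooperative
  dose-response fit `y = 1 − 1/(1 + (x/EC₅₀)^p)`.
- **`transleak.landscape`** — pore free-energy profiles `F(ξ)` along the
  extended pore reaction coordinate: radius conversion (`r ≈ 4.22 Å × ξ` for
  `ξ ≥ 1`), and extraction of the global minimum, water-wire shoulder,
  CPP-like pore energy, metastable plateau, and local minima.
- **`transleak.synth`** — seeded generators for all of the above: requenching
  tables with leakage-dependent `Qin` noise, brute-force vesicle populations
  (the Monte-Carlo oracle for the analytic averages), two-burst leakage
  traces, and free-energy landscapes with known ground-truth features.
- **`transleak.io` / `transleak.cli`** — CSV/JSON readers, writers, and a
  `transleak` command-line interface.

## Worked example

A 100 nm vesicle with 65 Å² per lipid and a 32,500 nm² outer leaflet, probed
at lipid-to-peptide ratio 30:

```sh
$ transleak surface-stats --leaflet-area 32500 --lp 30
{
  "leaflet_area_nm2": 32500.0,
  "n_lipids": 100000,
  "n_patches": 325,
  "lp": 30.0,
  "n_peptides": 3333,
  "mean_per_patch": 10.255384615384616,
  "var_per_patch": 10.223829585798816,
  "prob_le_2": 0.0022451660001549354
}
```

The vesicle holds 100,000 lipids, or 325 patches of the 10 × 10 nm size used
in simulations; 3,333 bound peptides average 10.3 per patch, the variance
essentially equals the mean (Poisson-like placement), and even at this high
peptide load a patch holds two or fewer peptides with probability ~0.2% —
peptide coverage is intrinsically inhomogeneous.

Simulate a requenching experiment in the mixed regime and classify it, then
fit the unified model to a graded-regime simulation:

```sh
$ transleak simulate --what requench --scenario mixed --seed 7 --out mixed.csv
$ transleak classify mixed.csv
mixed

$ transleak simulate --what requench --scenario graded --seed 3 --out graded.csv
$ transleak fit-requench graded.csv --out fit.json
{
  "model": "unified",
  "pleak": { "c1": 2.990631413638162, "c2": 0.39521089348841165 },
  "foutv": { "c1": 9.974944407256729, "c2": 0.7010418753926296 },
  "chi2": 1.263747221334576,
  "dof": 20,
  "converged": true,
  ...
}
```

The fit recovers the generating parameters (`Pleak`: C1 = 3, C2 = 0.4;
`fout`: C1 = 10, C2 = 0.7) from noisy data with a reduced χ² near 1, i.e. the
scatter is consistent with the declared measurement error.

Pore landscape post-processing works the same way from Python:

```python
>>> from transleak import SynthSpec, gen_pmf, find_features, xi_to_radius
>>> profile, truth = gen_pmf(SynthSpec(seed=0))
>>> feats = find_features(profile)
>>> feats.metastable_window
(1.11, 1.83)
>>> round(xi_to_radius(feats.metastable_window[1]), 1)
7.7
```

A metastable pore plateau spanning ξ = 1.11–1.83 corresponds to pore radii of
about 4.7–7.7 Å — large enough at the upper end to pass dye, and the
structural basis of transient leakage.

## Data formats

- Requenching tables: headered CSV with `cp` (or `lp`), `fout`, `qin`,
  `qin_sd` columns; L/P ratios are mapped to the normalized dose via
  `cp = lp_min / lp`.
- Plate-reader traces: CSV with `time_min` plus one column per well; buffer
  and Triton X-100 wells provide the 0% and 100% leakage levels.
- Free-energy profiles: 2–3 column text (`xi  F  [err]`), kcal/mol.

See `docs/methods.md` for the model details, parameter defaults, and the
assumptions behind the synthetic-data generators.
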