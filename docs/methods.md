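# Methods

## The requenching observables

A vesicle population entraps the fluorophore ANTS together with the quencher
DPX. Quenching combines a dynamic (collisional) and a static (association)
term:

    Q([DPX]) = 1 / ((1 + K_D [DPX]) (1 + K_S [DPX]))

Defaults `K_D = 50 M⁻¹`, `K_S = 490 M⁻¹` are standard ANTS/DPX literature
values; both are configurable, as is the initially entrapped concentration
`[DPX]₀` (default 0.004 M). All concentrations are handled internally in
molar; readers accept mM with an explicit unit tag.

A vesicle that releases the dye fraction `f` also releases quencher, at the
relative rate `α` (default 1.43, a slight preference for releasing the
smaller quencher):

    Qin_v(f) = Q([DPX]₀ (1 − f)^α)

`Qin_v` rises from `Q([DPX]₀)` at `f = 0` to exactly 1 at `f = 1`. The
ideal graded limit applies this with every vesicle leaking; the ideal
all-or-none limit leaves surviving vesicles untouched, so `Qin` is constant
at `Q([DPX]₀)`.

## The unified model

Both ideal behaviors are special cases of a two-step per-vesicle process at
normalized peptide dose `cp ∈ [0, 1]`:

1. the vesicle leaks with probability `Pleak(cp)`;
2. if it leaks, it releases the fraction `fout(cp)` of its contents.

Each response is a sigmoid with steepness `C1` and midpoint `C2`, or a
constant in [0, 1]. Bulk observables average over the population:

    fout_bulk = Pleak · fout_v
    Qin_bulk  = [P(1−f)·Qin_v(f) + (1−P)·Qin_v(0)] / [P(1−f) + (1−P)]

The `Qin` average is weighted by the dye each subpopulation retains, which is
what the requenching analysis actually measures (a nearly empty vesicle
contributes almost nothing to the internal fluorescence). The degenerate
point `P = 1, f = 1` retains no dye at all; its `Qin` is reported as 1 and
flagged `degenerate`, and classification ignores flagged points.

### Why the sigmoid saturates

The default sigmoid is a smoothstep `3t² − 2t³` on
`t = (cp − C2)·C1/6 + ½` (clipped to [0, 1]): it reaches exactly 0 and 1 at
`C2 ∓ 3/C1` and has midpoint slope `C1/4`, matching a logistic of the same
steepness through the middle of its range. The bounded support is a modeling
requirement, not a convenience. With strictly interior sigmoids (e.g. the
plain logistic) of equal steepness, the remnant-dye share of the leaking
subpopulation,

    w/(w+i) = P(1−f) / (P(1−f) + (1−P)),

tends to a *constant* at high dose (the ratio `(1−f)/(1−P)` approaches
`e^{−C1(C2_P − C2_f)}`), so `Qin_bulk` is monotone in `cp` for any quench
parameters — the model could never produce the observed mixed behavior in
which `Qin` falls back to its all-or-none level at high dose. With a
saturating `fout`, the leaking subpopulation retains exactly zero dye beyond
`fout`'s saturation point while `Pleak < 1` still leaves intact vesicles, and
`Qin_bulk` drops to `Q([DPX]₀)`: a rise-then-fall "mixed" curve from
steep responses with staggered midpoints (e.g. `Pleak`: C1 = 10, C2 = 0.7;
`fout`: C1 = 10, C2 = 0.6). The logistic remains available as
`kind="logistic"`; the form is isolated behind `SigmoidResponse`, so further
alternatives are one-line swaps.

Per-vesicle `fout_v` is deterministic at each dose (a delta distribution);
heterogeneity enters only through the Bernoulli leak/no-leak split. This is
the minimal model consistent with the two-step description; broadening
`fout_v` into a distribution would add a dispersion parameter the requenching
observables cannot separately constrain.

### Fitting and classification

`fit_unified` estimates the four sigmoid parameters by bounded least squares
from five deterministic starting points (plus the user's init), minimizing
sd-weighted `Qin` residuals jointly with `fout` residuals (`fout` is measured
essentially exactly relative to `Qin`; its residual weight defaults to
0.005). The reported statistic is the reduced χ² of the `Qin` residuals,
`Σ((obs−pred)/sd)² / (N − 4)`; the ideal-graded fit (`[DPX]₀`, `α`; `[DPX]₀`
optimized on a log scale) uses `N − 2`. Non-convergence and bound-pinned
solutions are reported in the result object, never silently.

`classify_behavior` orders `Qin` by increasing `fout` and applies two
tolerances (defaults: `flat_tol = 0.02`, `rise_tol = 0.05` quenching units):
total variation within `flat_tol` → all-or-none; nondecreasing with at least
`rise_tol` total rise → graded; a rise of `rise_tol` followed by a drop
exceeding `flat_tol` → mixed.

Experimental dose axes in L/P are mapped to `cp = (L/P)_min / (L/P)`, clipped
to [0, 1] (more peptide → lower L/P → higher `cp`); the reference ratio is
configurable.

## Surface occupancy

The geometry chain is deterministic arithmetic: leaflet area (sphere `πd²`,
or an explicit override — the conventional worked value 32,500 nm² for a
100 nm vesicle is slightly larger than the geometric 31,416 nm² and makes
the lipid count a round 100,000 at 65 Å²/lipid; the override exists to
reproduce that chain exactly), lipid count over both leaflets, whole
10 × 10 nm patches per leaflet, and peptides at a given L/P. Placement of
noninteracting peptides is uniform-multinomial: per-patch counts are
Binomial(n, 1/N) with variance ≈ mean, and the Poisson tail gives the
probability of near-empty patches. Both the 325-patch analytic count and the
18 × 18 = 324-bin display grid are supported. Attractive peptide-peptide
interactions, which would sharpen the heterogeneity, are out of scope.

## Leakage kinetics

Fractional leakage is `(F − F₀)/(F_max − F₀)` with buffer and Triton X-100
controls; out-of-range values are clipped with a warning. Burst rates are
ordinary least-squares slopes of fractional leakage versus time over a
configurable window (default the first 10 s of readings) after each peptide
addition — OLS rather than finite differences for noise robustness, and
fractional-leakage units so rates are in min⁻¹. Replicate rates are averaged
with SEM. The dose-response fit uses `y = 1 − 1/(1 + (x/EC₅₀)^p)` with
cooperativity `p`; `y(EC₅₀) = ½` for any `p`. The assay convention for which
axis holds the dose is ambiguous in places; the fit is applied literally to
user-designated (x, y) columns with dose as `x` by default.

## Pore landscapes

`F(ξ)` along the extended pore reaction coordinate: `ξ < 1` indexes pore
nucleation, `ξ ≥ 1` pore expansion with radius `≈ 4.22 Å × ξ` (4.22 Å is the
reference radius at `ξ ≈ 1`; nucleation-regime coordinates map to a NaN
radius sentinel). Feature extraction operates on user-supplied or synthetic
profiles — the simulation-derived energies themselves (which require
cluster-scale free-energy calculations) are outside what this package can
reproduce:

- energies are referenced to the global minimum; detection is invariant to
  constant shifts;
- smoothing: centered moving average, default window 5 samples;
- the water-wire shoulder is the interior minimum of the smoothed slope in a
  window (default ξ = 0.87 ± 0.15) — a derivative criterion chosen because a
  shoulder is a slope dip on a rising flank; a landscape with no interior
  slope dip reports the feature as absent;
- the CPP-like pore energy is read at ξ = 1.18 (configurable);
- the metastable plateau is the longest contiguous run beyond ξ = 1 with
  |dF/dξ| ≤ 1.5 kcal/mol per unit ξ (default), and an interior minimum at
  least 0.1 kcal/mol (default) below both flanks is flagged as a metastable
  local minimum;
- absent features are `None` plus an explanatory flag, never fabricated.

`compare_profiles` differences two profiles at a common radius, with
quadrature error propagation; `reference="raw"` (default) differences the
curves as supplied, `reference="min"` references each to its own minimum
first (the convention for stressed-vs-relaxed comparisons).

## Synthetic data

Generators define the study conditions for testing and calibration:

- **Requenching tables**: true bulk observables plus Gaussian `Qin` noise
  with `sd = base·(1 + inflation·fout_bulk)` (default base 0.02, inflation
  1.0, triplicate replicates averaged; the inflation emulates the growth of
  `Qin` error bars at high dose when few vesicles still hold dye). The
  emitted `sd` is the nominal standard deviation of the replicate mean, so
  χ² against the generating model is calibrated (ensemble mean ≈ 1, verified
  over 100–200 replicates in the suite). `fout` is noise-free by default.
- **Vesicle populations**: explicit Bernoulli leak indicators and pooled
  observables computed by brute force; at `n = 10⁵` they agree with the
  analytic averages within 3 delta-method standard errors at every dose
  tested.
- **Leakage traces**: sums of saturating exponentials
  `A_j(1 − e^{−k_j(t−t_j)})`, one per addition (defaults: rates 0.27 and
  0.14 min⁻¹, amplitudes 0.5 and 0.25, additions at 0 and 60 min, 1 s
  sampling over 2 h), plus flat buffer/Triton control traces. The OLS
  window slope of `A(1 − e^{−kt})` underestimates `Ak` by roughly `kT/2`
  over a window `T` (≈2% for 10 s at 0.27 min⁻¹), which sets the 5%
  recovery tolerance used in tests.
- **Free-energy profiles**: the slope dF/dξ is constructed analytically —
  saturating rise out of the minimum (exact zero crossing at the requested
  minimum), Gaussian slope dip centered at the shoulder, piecewise-linear
  descent/ascent around the plateau arranged so |slope| crosses the
  detection tolerance exactly at the requested window edges (linearity near
  the crossing makes the edge location survive moving-average smoothing),
  and the derivative of a negative Gaussian for the local dip — then
  integrated by the trapezoid rule. Defaults give a landscape with minimum
  at ξ = 0.25, shoulder at 0.87 (≈8 kcal/mol), plateau 1.11–1.83 at
  ≈9.4 kcal/mol with a 0.2 kcal/mol dip at 1.51, matching the qualitative
  shape of stressed-membrane landscapes; disabling the plateau yields a
  convex relaxed-membrane profile. Ground-truth feature locations are
  returned alongside the profile.

Every generator derives all randomness from a single recorded seed and is
bit-reproducible under it.

### What the generators do not emulate

Synthetic requenching noise is Gaussian and independent across doses; real
titration-derived `Qin` estimates share systematic components (pipetting,
`Q_out` calibration) across a plate. Traces have no photobleaching or drift.
Synthetic landscapes are noise-free by default and have exactly one plateau;
umbrella-sampling profiles carry correlated, ξ-dependent errors. Passing
tests therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to every instrumental artifact.

## Problem sizes

The test suite uses 24-point dose grids, 200-replicate recovery ensembles,
10⁵-vesicle populations, and 145-sample landscapes — sizes chosen so that
sampling error is far below the assertion tolerances while the whole suite
runs in seconds.

## Known limitations

- The model is a static dose-response construction; it contains no rate
  equations for pore opening/closing and cannot predict the time course of
  `Qin`.
- `cp` is an arbitrary normalized dose; the L/P mapping is monotone but not
  mechanistic.
- χ² conventions differ across published fits (raw vs reduced, co-fit quench
  constants); reported χ² values are reduced with the stated degrees of
  freedom and may not match other conventions numerically.
- Raw titration decomposition (deriving `fout`/`Qin` from fluorescence
  series) is out of scope; the pipeline consumes derived pairs.
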