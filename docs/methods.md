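# Methods

`evcompare` models the two measurement pillars of tetraspanin-based
extracellular-vesicle (EV) quantification — a digital single-molecule
immunoassay and size-exclusion chromatography (SEC) — and the summary
statistics used to compare EV isolation methods between biofluids. This
note documents the models, their parameters and defaults, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Digital immunoassay model

A bead-based digital ELISA captures single protein molecules on antibody
beads, isolates beads in femtoliter wells (at most one bead per well) and
counts wells with a fluorescent immunocomplex ("on" wells). Because target
molecules are scarce relative to beads, the number of labels per bead is
Poisson distributed, and the observed on-fraction is converted to the mean
label count per bead (AEB) by the occupancy correction

    AEB = -ln(1 - f_on).

This is implemented with `log1p` for accuracy at small `f_on`; its inverse
round-trips to better than 1e-12 relative over AEB in [1e-4, 5]. Readings
with `f_on >= 0.7` are outside the single-label counting regime and are
flagged `saturated` rather than modelled with a multi-label ("analog")
extension; readings with `f_on = 1` carry no information and raise.

The forward simulation draws, for a sample at true concentration `c` (pM),

    lambda_eff = capture_efficiency * (c / dilution_factor) + background_aeb
    n_on ~ Binomial(n_wells_loaded, 1 - exp(-lambda_eff)).

Background enters as additive mean labels per bead (where nonspecific
binding physically acts), not as an additive concentration. Default array
size is 50,000 counted beads; capture efficiencies and backgrounds are
per-marker configuration, not constants of the model.

Calibration uses a four-parameter logistic (Hill form) response

    AEB(c) = lower + (upper - lower) * c^h / (mid^h + c^h),

fitted by bounded least squares with an analytic Jacobian. The 4PL is the
standard monotone, saturating immunoassay curve; with noise-free standards
spanning both asymptotes the generating parameters are recovered to ~1e-12
relative. When the standards do not reach saturation the (upper, mid) pair
is unidentifiable — only their ratio (the low-end slope) is determined —
so the optimiser is capped at 300 function evaluations per start; this
leaves back-calculation accuracy unchanged while keeping fits fast.
Inversion never extrapolates: AEB at or below the lower asymptote reports
0 pM with a `blank_level` flag, AEB outside the standards' concentration
range is clamped to the range boundary and flagged `below_curve` /
`above_curve`. Reported concentrations are dilution-corrected to the neat
sample (the tetraspanin assays use 4x dilution, albumin 20x); technical
replicates are averaged arithmetically with CV = sample sd / mean.

## SEC elution model

Separation is hard-sphere partitioning into cylindrical pores: a solute of
hydrodynamic radius `r` on a resin of pore radius `r_p` has accessible
pore-volume fraction

    K = (1 - r/r_p)^2   for r < r_p, else 0,

and elutes at `V_e = V0 + K * Vi`, with `V0 = void_fraction * bed_volume`
and `Vi = porosity * bed_volume`. This is the simplest monotone model with
the correct limits (full exclusion at the pore size, free diffusion for
point solutes). Resin pore sizes use literature values for cross-linked
agarose — pore *diameters* 75 / 42 / 24 nm for Sepharose CL-2B / CL-4B /
CL-6B, halved to radii; whether such figures denote radii or diameters is
not standardised, so only ordering properties are asserted in tests and
the values are configurable. The Izon qEVoriginal 35 nm and 70 nm columns
are approximated as 10-ml columns whose pore diameter equals the series
label (a synthetic stand-in for proprietary media).

Band shape: each radius contributes a Gaussian centred at `V_e` with
sd = `dispersion * sqrt(V_e)` (default 0.35 sqrt-ml), convolved with the
rectangular load pulse; 2% of each species' mass (`fronting_fraction`) is
spread uniformly from the void volume to the band centre. The fronting
term represents the non-ideal early leakage seen on overloaded biofluid
columns; without it a pure Gaussian model predicts essentially zero
albumin in the EV window (numerically underflowing), making purity
degenerate. A wider band plus fronting reproduces the finite free-protein
contamination of EV fractions that motivates purity scoring in the first
place.

Geometry defaults: `void_fraction = 0.40` (interstitial porosity of a
packed bed of soft spheres, and the value that centres the fully-excluded
peak inside the conventional EV window), `porosity = 0.55`, so void +
internal volume stay strictly below the bed volume. Collection follows the
standard convention: 0.5-ml fractions numbered from sample loading,
fraction `k` covering `((k-1)*0.5, k*0.5]` ml; 10-ml (and Izon) columns
collect fractions 6–21, 20-ml columns 12–27; the default EV pool is
fractions 7–10 (10 ml) or 14–17 (20 ml).

EV sizes are log-normal over hydrodynamic radius, default median 35 nm
with geometric sd 1.6 (the usual 30–150 nm small-EV diameter range);
albumin is a fixed 3.5 nm sphere. The size distribution is discretised on
101 equal-weight mid-quantile nodes; profiles live on a 0.0125-ml grid
whose points include every fraction boundary, so binning conserves the
profile's own trapezoidal mass to machine precision (asserted at 1e-9).
Amounts are carried in fmol so that amount / volume(ml) is directly pM.
Column recovery (losses to the matrix) defaults to 1.0.

Under these defaults the model reproduces the qualitative findings that
motivate custom-column screening: smaller-pore resins put more EV mass in
the EV window (CL-6B > CL-4B > CL-2B on 10-ml columns), doubling the bed
to 20 ml trades EV recovery for a higher EV:albumin ratio, and larger load
volumes monotonically lower purity. It deliberately does not reproduce
two measured magnitudes: the >2-fold EV yield advantage of CL-6B over
CL-2B (pore exclusion alone yields ~1.2-fold; real large-pore columns
presumably also lose EVs to in-pore retention and adsorption, which this
model omits) and the CSF-specific preference for 10-ml over 20-ml columns
on purity (in the model the purity ordering between bed heights is
independent of the absolute albumin level; in practice near-LOD albumin
measurements in CSF pools change that calculus).

## Comparison statistics

Relative EV recovery divides each tetraspanin's concentration (pM) by the
same tetraspanin's concentration in an explicitly named reference
condition and averages the three ratios — the captioned mean-of-ratios
definition, not the ratio of sums (the two coincide only when a method
preserves the reference's marker profile). The reference is a required
argument because different experiment layouts normalise to different
conditions. Purity is the sum of the three tetraspanin concentrations
divided by albumin; it is scale-invariant and undefined (an error) at zero
albumin. Day replicates are averaged marker-wise *before* ratios are
formed; conditions run from reduced sample volume (e.g. a 0.25-ml
precipitation protocol) are rescaled to the 0.5-ml standard input before
averaging. Concentrations are compared as measured in each condition's
final eluate or pool without renormalising for pool-volume differences —
the convention of the comparison design this package supports — and every
report carries a note saying so. Ranking takes the argmax by combined
recovery ("high yield") and by purity ("high purity"), breaking ties
lexicographically and reporting them.

## Synthetic experiment generator

The generator is the package's testing surface: it produces complete
experiments whose every observable traces to configured ground truth and
a seed. One-pot methods (ultracentrifugation, precipitation) are
phenomenological — a per-marker recovery in [0,1] and an albumin
carryover in [0,1] — because such methods are characterised by their
outputs, not by a separation mechanism. SEC methods run the mechanistic
elution model and pool the configured window. Replicate scatter is
multiplicative log-normal noise with unit mean (default CV 15%), drawn
independently per method, replicate and marker, representing the combined
isolation-plus-assay day-to-day variability. Measured values then pass
through the digital-assay simulation (two technical replicates by
default), calibration fitting and inversion; an `ideal_assay` mode skips
the measurement layer to isolate separation physics from assay noise.

The plasma preset uses synthetic true concentrations (CD9 20, CD63 8,
CD81 12 pM; albumin 6e8 pM ~ 0.6 µM-scale free protein); the CSF preset
scales tetraspanins ~10x down and albumin 200x down. These are plausible
magnitudes, not measurements. The default layout is the 12-condition
panel (UC ± wash, ExoQuick, ExoQuick ULTRA at 0.25 ml input, two Izon
columns, and CL-2B/4B/6B at 10 and 20 ml) for each biofluid; a focused
three-column configuration with four column replicates mirrors a
confirmatory head-to-head design.

What passing tests show: that the statistics recover configured ground
truth exactly in the noise-free limit, rank methods correctly under
realistic noise when true recoveries differ by >= 30%, and that the SEC
model's orderings are robust. What they do not show: agreement with any
wet-lab measurement — real biofluids add lipoprotein interference, matrix
effects, antibody lot variability and column-to-column packing variation
that the generator does not emulate (a contaminant-species hook exists in
the SEC layer via extra `Species`, but no lipoprotein preset is shipped).

## Numerical and design choices

- Poisson correction via `-log1p(-f_on)`; domain errors below 0 and at 1.
- 4PL fit: two midpoint starts (data median and 10x top standard), bounds
  `lower >= 0`, `slope in [0.05, 20]`, tolerances 1e-12, 300-evaluation
  cap per start with early exit on exact fits; monotonicity enforced
  (`upper > lower`, `slope > 0`), degenerate flat standards rejected.
- CV uses the sample standard deviation (ddof = 1).
- Elution grid step 0.0125 ml (40 points per fraction); delta-band limits
  handled explicitly when both dispersion and load width vanish.
- Fraction binning integrates the shared grid, so mass conservation holds
  by construction rather than by quadrature agreement.
- Ties in rankings are broken lexicographically and reported, making
  `rank_methods` invariant to input order.
- All randomness flows through `numpy.random.Generator` seeded from a
  single integer; generated CSVs are byte-identical across reruns.
- Problem sizes in the validation suite (50,000–100,000 wells, 100-seed
  ranking runs, 20-seed calibration round-trips) were chosen as the
  smallest sizes at which binomial counting error is negligible relative
  to the modelled biological variability.

## Known limitations

- Partitioning ignores pore-size heterogeneity within a resin and any
  solute–matrix interaction; `K` depends only on the radius ratio.
- Band widths follow a square-root law with a single dispersion constant;
  no flow-rate or packing-quality dependence.
- The digital assay model has no analog (multi-label) extension, so
  concentrations driving `f_on` above 0.7 are clamp-and-flag only.
- Purity magnitudes depend strongly on the fronting fraction, which is a
  stylised stand-in for several non-ideal transport effects; only
  orderings and fold-change directions should be read from it.
- One-pot methods have no mechanistic content; their recoveries are
  configuration, so cross-method fold changes involving them describe the
  configuration, not chemistry.
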