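# Methods

This note documents the models, the numerical choices behind them, what
the synthetic generators do and do not emulate, and the design decisions
taken where more than one defensible option existed.

## Equilibrium binding

Titrations are fit with the single-site isotherm in its ligand-depletion
(quadratic) form, because the fixed DNA concentration (default 25 nM) is
of the same order as the dissociation constants of interest; the dilute
hyperbolic form would bias Kd low in this regime. The discriminant of
the quadratic is analytically non-negative; floating-point excursions
below zero are clamped at a relative tolerance of 1e-9 and anything more
negative raises, since it indicates corrupt inputs rather than rounding.

The fit is bounded nonlinear least squares (`scipy.optimize.least_squares`)
with Kd ≥ 0, initialised at Kd = D0 and ΔF0 = max(ΔF) — robust across
Kd from 0.1× to 100× D0, which the tests exercise. Standard errors come
from the Jacobian at the optimum scaled by the residual variance; the
95% confidence intervals they imply cover the generator truth in 90–99
of 100 seeded replicates at 1% noise, which the suite checks as a
calibration study. A series with no signal (all ΔF ≈ 0) is reported as
`converged=False` rather than raising: it is a data property, not a
programming error.

## Dissociation kinetics and barrier differences

Stopped-flow chase traces are fit as `baseline + A exp(−koff t)`; a
two-exponential model is available behind an explicit flag, with AIC
reported for both, and the dominant (larger-amplitude) phase defines the
quoted lifetime. Model order is never auto-selected, because the data
alone rarely distinguish a minor second phase from baseline drift; the
choice belongs to the analyst. Dead-time handling is likewise left to
the caller (traces are fit from their first sample); the first-sample
origin is subtracted so that fits are invariant to the time origin.

Temperatures are accepted in °C at the CLI and converted internally
(T_K = T_C + 273.15); all thermodynamics use kelvin and
R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹. Barrier differences from rate ratios are
ΔΔG‡ = R T ln(fold); the identity is exactly log-additive, which the
property tests assert, and kon = koff/Kd expresses the kinetic
compensation bookkeeping.

## Time-resolved FRET distance distributions

The end-to-end distance distribution (EEDD) is a skew-normal density —
location r0 (Å), width σ (Å), shape a — truncated to (0, r_max] with
r_max = 150 Å by default and renormalised. A single-population model is
used throughout; multi-population and asymmetric-tail variants are out
of scope. The donor decay is the Förster kernel averaged over the EEDD,
and the transfer efficiency is defined from time-integrated intensities,
which for this kernel reduces to the closed form
E = 1 − ⟨1/(1 + (R0/r)⁶)⟩; the suite cross-checks this against direct
numerical time integration.

Numerics: all r-integrals use a fixed 512-point Gauss-Legendre rule over
the truncated support (the integrand is smooth, so a fixed rule keeps
results deterministic); the skew-normal density and CDF are evaluated
directly via the normal CDF and Owen's T function. Degenerate
point-mass distributions are a separate container so the closed-form
identities (E = 0.5 at r = R0, decay rate (1 + 2⁻⁶)/τ_D at 2R0) are
evaluated without quadrature error.

Fitting proceeds in two stages: the donor-only curve fixes τ_D by
one-dimensional Poisson maximum likelihood, then (r0, σ, a) — or (r0, σ)
with the skew fixed at zero — are fit by Poisson MLE on the
donor-acceptor counts with Nelder-Mead under box bounds
(5 ≤ r0 ≤ r_max, 0.5 ≤ σ ≤ 60, |a| ≤ 10). Poisson likelihood is the
natural noise model for photon counting; a Gaussian fallback is not
needed for count data and is not provided. Instrument-response
convolution is omitted: decays are treated as ideal, which is adequate
when τ_D is long against the IRF width, and is the regime the
generators emulate. Curves totalling fewer than 10³ photons are flagged
`converged=False` (non-identifiable). When the fitted r0 approaches the
truncation bound or E < 1%, the result carries a warning message: with
negligible transfer the distance scale is unconstrained. The default
R0 = 55 Å is typical of a fluorescein/TAMRA pair and is configurable.

## Permutation-gel bend angles

The two-arm bent-rod model maps a bend of angle α at fractional position
x along a fragment of length L to the end-to-end distance
R² = (xL)² + ((1−x)L)² + 2x(1−x)L² cos α, and relative mobility is
taken as affine in R/L: m = c0 + c1 R/L. This is a transparent proxy
for the empirical mobility-curvature calibrations used with such
assays; inferred angles are comparable within the model rather than
absolute.

A point that shaped the interface: with (c0, c1) both free, the angle is
nearly unidentifiable. Over realistic probe grids, R(x)/L varies so
little in shape across α that the affine calibration absorbs almost all
of the angle dependence — a local Fisher analysis at 0.5% mobility noise
on the six default probe positions gives SE(α) in the range 150–1800°.
`fit_bend_angle` therefore accepts a known calibration intercept, as
when the mobility relation has been calibrated externally; with the
intercept supplied, SE(α) drops to 2–5° and recovery is essentially
unbiased (the suite verifies |mean(α̂) − α| < 2° over 50 replicates at
α ∈ {40°, 60°, 80°}). The fully joint three-parameter fit remains the
default — it is exact on noiseless data and affine-rescaling invariant —
but its reported SE makes the degeneracy visible. In either mode the
angle is profiled on a 1° grid (the calibration enters linearly, so each
grid point is an exact linear solve) before joint polishing, with ties
broken toward α = 0 so a flat profile reports no bend. Technical
replicates are fit independently and summarised as mean ± SD.

The persistence-length helper converts a persistence length to the
number of base pairs it spans at the canonical B-DNA rise of
0.34 nm/bp; 45 nm corresponds to ≈132 bp, which is why a 15-bp duplex
is effectively rigid and its free-DNA end-to-end width is dominated by
probe-linker flexibility.

## Bridging-water analysis

A bridge site is declared by atom selectors for protein side-chain,
protein backbone and DNA backbone partner oxygens, plus hydrogen-bond
criteria. Defaults are heavy-atom donor-acceptor distance ≤ 3.5 Å and
D-H···A angle ≥ 130° when hydrogens are present, falling back to the
distance criterion alone otherwise; both bounds are inclusive (with a
1e-9 float cushion) and config-exposed, and all derived residency
numbers are criterion-dependent. A single water hydrogen-bonded to at
least `min_partners` partners (default 2) spanning both macromolecules
is a 1-water bridge; a mutually bonded pair whose union spans both
sides, each member bonded to at least one partner, is a 2-water bridge.
The 1-water motif takes precedence when both match, and the occupant
recorded for a 2-water frame is the protein-proximal member, giving a
site-centred residency record.

Barcodes merge same-occupant segments across unoccupied gaps of at most
`gap_tolerance` frames (default 2) to suppress single-frame criterion
flicker without hiding genuine exchanges; occupancy fractions are
computed from the raw per-frame record, not the merged segments.
Coordinates are Å throughout, frames are 0-based, residue numbering
follows the input file, and the consensus-box ↔ full-length offset
(box 72 ↔ residue 127) is an explicit helper rather than silent
renumbering. Water residues are recognised by name (HOH/WAT/H2O/SOL,
extensible).

Distance traces are segmented into plateaus by optimal partitioning
(exact dynamic programming over within-segment squared error plus a
per-segment penalty) up to 10⁴ points, with greedy binary segmentation
beyond. The default penalty is 3σ̂² ln n with σ̂ estimated from the
median absolute first difference, which is insensitive to the level
shifts being sought; the constant was set by null calibration (zero
false splits in 200 pure-noise traces at the lengths and noise scales
the package targets) rather than detection tuning.

Crystal solvent summaries count water residues and report mean
B-factors per component (protein, DNA, water), per-chain atom counts,
and both the total water count and the subset within 5 Å of any
non-water atom, since "waters associated with the complex" is
ambiguous between the two. An explicit flag records whether the DNA
mean B exceeds the protein's.

## Synthetic data

Every generator is a pure function of its parameters and a seed and
emits ground truth sufficient for exact scoring. Defaults are the study
conditions the analyses target: 25 nM DNA, a 15-bp duplex
(5'-TCGGTGATTGTTCAG-3'), chase temperatures 10/15/25/37 °C, probe
distances 120/95/79/51/47/27 bp in a 150-bp fragment with calibration
(c0, c1) = (0.2, 0.8), and a toy trajectory standing in for a 200-ns
run sampled every 100 ps (scaled to 200 frames by default so test and
acceptance runs stay fast; the frame spacing, not the wall-clock extent,
is what the residency arithmetic consumes).

The toy trajectory is a kinetic caricature, deliberately not physics:
waters take Gaussian random-walk steps (σ = 1 Å/frame) in a reflecting
30 Å box; a triad of static partner oxygens (hydroxyl, carbonyl,
phosphate) sits 2.8 Å from the site centre; any water entering the
capture sphere (radius 6.5 Å) snaps to the centre if the site is free
and is otherwise kept outside; the occupant escapes each frame with a
fixed probability and cannot be recaptured within the frame it leaves.
Because the capture radius exceeds the partner offset plus the
hydrogen-bond cutoff (2.8 + 3.5 = 6.3 Å), no non-occupant water can
ever satisfy the bond criterion to any partner, so the emitted
occupancy record is *exact* ground truth for barcode construction
whenever the analysis cutoff matches the capture geometry — the
acceptance suite verifies bit-exact agreement over randomized
configurations. A mobile "tail" atom walks through a configurable
plateau schedule (default 3/5/8 Å with jitter σ = 0.15 Å) relative to a
static anchor, exercising the change-point path end to end.

What passing these tests shows is that the analysis stages recover known
truth under their own noise models; it does not validate force-field
realism, hydrogen placement, periodic-boundary effects beyond
minimum-image distances, instrument response functions, or gel physics,
none of which the generators attempt to emulate.

## Pipeline and provenance

The CLI is a thin layer over the library: one subcommand per stage plus
`run` for a YAML-configured multi-stage pipeline. Configs are validated
strictly (unknown keys rejected) before any stage runs; missing inputs
fail a stage before computation; a stage failure is recorded in the
report and later independent stages still run. Reports are
schema-versioned JSON carrying the config hash, seed and tool version
and no timestamps, so identical config + seed reproduces byte-identical
output. Exit codes: 0 success, 2 configuration error, 3 stage failure.

## Known limitations

- Bend angles are model-relative; absolute comparison with calibrations
  based on other mobility laws is only qualitative, and without an
  external intercept the angle is weakly identified (see above).
- The EEDD fit assumes an ideal (IRF-free) decay and a single
  population; probe-linker flexibility is folded into the fitted width
  rather than modelled separately.
- Stopped-flow fits expose single/double model order but no dead-time
  correction; unmeasurably fast decays surface as non-converged fits
  rather than censored estimates.
- Bridge classification uses heavy-atom geometry when hydrogens are
  absent; angle criteria only apply when the input provides hydrogens.
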