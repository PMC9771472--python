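# hmgclamp

Quantitative analysis of HMG-box/DNA complexes: equilibrium binding,
dissociation kinetics and barrier thermodynamics, time-resolved FRET
end-to-end distance distributions, permutation-gel DNA bend angles, and
bridging-water residency analysis of MD trajectories.

SRY and its SOX relatives bind the DNA minor groove through an ~80-residue
HMG box and bend it sharply; a C-terminal basic tail docks in the widened
groove, and interfacial water molecules can bridge the tail-DNA junction.
Clinically subtle variants at this junction leave equilibrium affinity and
bending nearly intact while markedly accelerating dissociation, which calls
for exactly the kinds of measurements this package models: titrations,
stopped-flow chase traces, donor fluorescence decays, circular-permutation
gels and per-frame hydration of a defined bridge site.

The package is written for biophysicists who have these data in plain
tabular or PDB form (or want matched synthetic data with known ground
truth) and want one tested pipeline from raw curves to fitted parameters.

## The models

**Binding isotherm (ligand depletion).** With total protein `S`, total DNA
`D0`, dissociation constant `Kd` and saturation amplitude `ΔF0`:

```
ΔF(S) = ΔF0 { 0.5 (1 + S/D0 + Kd/D0) − [0.25 (1 + S/D0 + Kd/D0)² − S/D0]^0.5 }
```

`fit_kd` recovers `(Kd, ΔF0)` by bounded nonlinear least squares.

**Dissociation kinetics.** `fit_koff` fits `F(t) = baseline + A e^(−koff t)`
(or a two-exponential sum, chosen explicitly, with AIC reported); the
complex lifetime is `1/koff`, and an off-rate fold change maps to a barrier
change `ΔΔG‡ = R T ln(fold)` with `R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹`.

**Time-resolved FRET.** The donor decay of a doubly-labelled duplex is a
Förster kernel over an end-to-end distance distribution `p(r)` (truncated
skew-normal):

```
I_DA(t) = ∫ p(r) exp[ −(t/τ_D)(1 + (R0/r)⁶) ] dr,
E = 1 − ∫I_DA dt / ∫I_D dt
```

`fit_eedd` recovers `(r0, σ, a)` by Poisson maximum likelihood from a
donor-only / donor-acceptor decay pair and reports mean, peak, FWHM and E.

**Bend geometry.** Circular-permutation mobilities are modelled with a
two-arm bent rod, `R²(x, α) = (xL)² + ((1−x)L)² + 2x(1−x)L² cos α`, and an
affine mobility calibration `m = c0 + c1 R/L`.

**Bridging-water barcodes.** A bridge site is a set of protein and DNA
partner oxygens plus hydrogen-bond criteria (heavy-atom D–A ≤ 3.5 Å,
D–H···A ≥ 130° when hydrogens exist). Per frame, the site is classified as
unoccupied, a 1-water bridge, or a 2-water bridge; the occupant identity
over time is the residency "barcode", from which dwell times, occupancy
and exchange counts follow. Stepwise contact displacement is segmented
into plateaus by exact change-point dynamic programming.

## Worked example

```python
import numpy as np
from hmgclamp.binding import fit_kd, fit_koff, ddg_from_fold
from hmgclamp.synth import gen_titration, gen_kinetic_trace

series, truth = gen_titration(Kd=20e-9, dF0=1.0, noise_sigma=0.01, seed=1)
fit = fit_kd(series)
print(f"Kd = {fit.kd/1e-9:.1f} +/- {fit.se_kd/1e-9:.1f} nM")

trace, _ = gen_kinetic_trace(koff=1.0, noise_sigma=0.02, seed=1)
kin = fit_koff(trace)
print(f"koff = {kin.koff:.3f} /s   lifetime = {kin.lifetime:.3f} s")
print(f"ddG for a 4-fold faster off-rate at 37 C: "
      f"{ddg_from_fold(4.0, 310.15):.2f} kcal/mol")
```

prints

```
Kd = 20.0 +/- 0.7 nM
koff = 1.014 /s   lifetime = 0.986 s
ddG for a 4-fold faster off-rate at 37 C: 0.85 kcal/mol
```

The fitted `Kd` agrees with the generator truth (20 nM) within its standard
error, the off-rate recovers the true 1 s⁻¹ within 1.5%, and a fourfold
off-rate acceleration at physiological temperature corresponds to a
0.85 kcal/mol reduction of the dissociation barrier.

The same analyses are available from the shell, e.g.

```
hmgclamp simulate --kind titration --seed 1 --out-dir run/
hmgclamp fit-kd --input run/titration.csv --dna-conc-nm 25
hmgclamp ddg --fold 4 --temperature-c 37
```

or as a multi-stage pipeline via `hmgclamp run --config pipeline.yaml`,
which writes a schema-versioned JSON report with provenance (config hash,
seed, version) so identical inputs give byte-identical reports.

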