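# Methods

`htdkit` models the quantitative chain by which ligand effects on a
nuclear-receptor LBD heterodimer are measured: coupled mass-action
equilibria, two flavours of ITC experiment, slow-exchange NMR observables,
and a cross-assay profiling layer, validated end to end on a synthetic
ligand panel.

## Binding model

The scheme is a homodimer-competition model. RXRα LBD monomer (A)
self-associates into a homodimer (A₂) and is shared with the Nurr1 LBD
monomer (B), which does not self-associate:

    A + A ⇌ A₂      K_D,homo = [A]²/[A₂]
    A + B ⇌ AB      K_D,het  = [A][B]/[AB]

Both constants are dissociation constants in M. The homodimer parameters are
anchored at K_D = 16.3 µM and ΔH = −13.10 kcal/mol (dilution-ITC values for
the apo RXRα LBD); the heterodimer parameters are what the competition
experiments measure, reported as log₁₀ K_D (log M) and ΔH (kcal/mol), with
TΔS = ΔH − RT ln(10)·log₁₀K_D at 298.15 K (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹).

RXRα homotetramers are known to exist but are deliberately not modelled, for
the same reason the fitted competition model omits them: the dilution
experiment constrains only the dimer step, and adding an unconstrained
tetramer equilibrium would make the fits unidentifiable. Likewise the model
assumes the homodimer affinity is ligand-independent; the sensitivity test
`test_wrong_fixed_homodimer_biases_heterodimer_affinity` quantifies what a
mis-specified fixed homodimer K_D does to the recovered heterodimer
affinity.

### Numerics

Both solvers reduce to one scalar equation in free A, strictly increasing
and bracketed on [0, total_A]; `solve_homodimer` uses the numerically stable
closed-form quadratic root, `solve_competition` uses Brent's method on the
bracket (xtol 1e−30 M, rtol ≈ 4 machine epsilons, cap 200 iterations), which
converges unconditionally — the property suite exercises totals and
constants over seven orders of magnitude (1e−9–1e−2 M) and checks mass
balance to 1e−9 relative and agreement with an independent nested-bisection
oracle to 1e−8 relative. Degenerate inputs (zero totals, zero titrant)
short-circuit to exact closed forms.

## ITC simulation and fitting

Two experiments are modelled with the standard discrete displacement model
for a perfusion cell (working volume V₀ = 200 µL, the instrument's nominal
cell volume, configurable): injecting dV scales pre-existing cell contents
by (1 − dV/V₀), adds syringe material at c_syr·dV/V₀, and the displaced
volume leaves at pre-injection composition. At dV/V₀ = 0.01 the difference
from the exact continuous-perfusion model is far below fit resolution. The
heat of injection *i* is the enthalpy of re-equilibration,

    q_i = 10⁹ · Σ_s ΔH_s · V₀ · (c_s,after − c_s,mixed)   [µcal],

summing over complexes (A₂, AB), where “mixed” counts complexes surviving
displacement plus those delivered by the syringe. Signs follow the
instrument frame (positive = endothermic); ΔH values are association
enthalpies, so dilution of a homodimer with ΔH = −13.10 kcal/mol produces
positive (endothermic dissociation) heats. A telescoping identity —
cumulative heat equals ΔH × (dimer delivered − dimer surviving in cell and
displaced aliquots) — is verified to 1e−6 relative. All injections are
retained (no first-injection discard) and all analysis is at 298.15 K.

Defaults mirror the published protocol: 20 × 2 µL injections; dilution runs
titrate 1 mM protein into buffer; competition runs titrate 1 mM Nurr1 LBD
into 100 µM RXRα LBD (10:1).

Fitting follows the model/results idiom (`DilutionITC`, `CompetitionITC` →
`.fit()` → results object with estimates, standard errors from the
least-squares covariance, residuals and `summary()`). Levenberg–Marquardt
(lmfit) on (log₁₀ K_D, ΔH) with K_D log-parameterized for positivity, ftol
1e−12, and a three-point decade grid of K_D starts; because ΔH enters the
heats linearly at fixed K_D, each start's ΔH guess is its conditional
linear-least-squares optimum, which makes the multi-start cheap and robust.
In the competition fit the homodimer pair is supplied and held fixed. Flat
isotherms (max |q| < 1e−3 µcal) are flagged unidentifiable rather than
fitted. Noiseless round trips recover all fifteen reference parameter sets
to |Δlog K_D| < 0.01; at 0.2 µcal Gaussian heat noise the median of 100
repeated fits sits within 0.05 of the generator.

## NMR exchange lineshape

The observed spin is the amide proton of a reporter residue (Thr411) on
Nurr1, exchanging between free monomer and heterodimer. The partner's
self-dimerization enters only through the equilibrium populations
(p_free, p_bound), computed by `solve_competition` with the observed protein
as B. The absorption spectrum is the steady-state solution of the two-site
Bloch–McConnell system,

    S(ω) = Re{ 1ᵀ [ i(ωI − Ω) + R + K ]⁻¹ p },

with offsets Ω = 2π·(−150, 0) Hz, decay R = 2π·(r2_free, r2_bound). The
quoted linewidth pairs (FWHH = 2 × R2) force reading R2 as a half-width at
half-height in Hz; the internal decay rate is 2π·R2 s⁻¹. Exchange satisfies
detailed balance exactly: k_bound→free = koff, k_free→bound =
koff·p_bound/p_free.

koff is not experimentally pinned; the default 5 s⁻¹ puts the system deep in
slow exchange (2π·|Δν| ≈ 942 s⁻¹), consistent with the two resolved peaks
seen experimentally, and is exposed as a parameter. Concentrations default
to 200 µM observed protein with the partner at `lr_ratio` molar equivalents
(1e−3 for the receptor-only limit, 2.0 for the titrated state) and partner
homodimer K_D 16 µM. The default grid (±400 Hz, 16384 points) gives ≥5×FWHH
margin and ~0.05 Hz resolution.

Peak metrics: maxima above 1% of the global maximum, positions/heights by
parabolic interpolation, FWHH by linear interpolation at half height, area
fractions by trapezoidal integration over watershed segments. Verified
limits: a lone site reproduces its Lorentzian width to 0.1 Hz; slow-exchange
area fractions match populations to 2% when tails are narrow enough not to
overlap (with the default 20/40 Hz widths and 150 Hz separation, watershed
partitioning of overlapping Lorentzian tails mixes a few percent of area
between peaks — an intrinsic property of the lineshapes, not of the
integrator); fast exchange collapses to a single peak at the
population-weighted offset within 1 Hz; total integrated intensity is
koff-independent to 1%.

## Peak-intensity populations

The monomer fraction is p = I_m/(I_m + I_hd) with first-order quadrature
error propagation, E = √[(I_hd·E_m)² + (I_m·E_hd)²]/(I_m+I_hd)². The
published form of this propagation equation lost its error terms in
typesetting (as printed it is signed and not a dispersion); the quadrature
form implemented here uses the partial derivatives the printed fragments
imply and is the only reading that yields a non-negative uncertainty. It
agrees with Monte-Carlo resampling to 5% relative for relative intensity
errors up to 10%. “Intensity” means peak height. Replicates aggregate as
mean / sample s.d. (n−1), with s.d. 0 and a flag for single-replicate
ligands.

Because the monomer and heterodimer resonances have different widths
(molecular-size effect), raw height ratios systematically overestimate the
monomer fraction — the same caveat that applies to the real measurement. The
end-to-end tracking test therefore runs at matched linewidths, where
height-derived populations follow the ground-truth free fraction within
0.05 across the studied affinity range.

## Panel profiling

Correlations: Pearson with the two-tailed t-test on n−2 degrees of freedom;
Spearman as Pearson on average ranks, with an exact full-enumeration
permutation p-value for n < 10 and the t-approximation for n ≥ 10 (panels
here have n = 12–14, so the approximation is the operative path; the split
is documented because software differs). Pairwise-complete observations for
correlations, listwise-complete for PCA.

PCA standardizes columns (n−1 s.d.) and eigendecomposes the correlation
matrix; per-PC sign is fixed by forcing the largest-magnitude loading
positive so outputs are byte-reproducible. Component retention uses parallel
analysis: eigenvalues of standardized standard-normal matrices of the same
shape, 95th percentile per rank, 1000 simulations by default, seeded.

## Synthetic panel

The generator encodes the study's structure as a generative model: 14
ligands in three classes (2 heterodimer-selective, 6 classical agonist, 6
antagonist); per-class log K_D,het of −4.4 ± 0.2, −4.9 ± 0.2 and −5.5 ± 0.4
(spanning the reported −6.13 … −4.38 range); endothermic ΔH tracking
affinity (20.0 + 3.0·logK_D ± 1.2 kcal/mol, floored at +0.5 — a straight-line
summary of the reported affinity–enthalpy trend); heterodimer-reporter
transcription affine in log K_D (slope 2.0 fold/log-unit, noise s.d. 0.8,
calibrated so the planted Pearson r ≈ 0.8 at n = 14); TR-FRET and
homodimer-reporter readouts class-driven and independent of log K_D given
class. Observation noise: 0.2 µcal per-injection heat noise and 2% relative
NMR intensity noise, two replicates each. Randomness derives from one master
seed through per-(ligand, stage) `SeedSequence` spawn keys, so panels extend
without reshuffling.

What the generator does **not** emulate: raw power traces and baseline
integration, 2D spectra, cell-to-cell reporter variance, ligand-dependent
homodimer affinity changes, or tetramer formation. Passing tests therefore
show the analysis chain is correct and well-calibrated under the stated
model, not that the model captures every feature of real data.

Problem sizes in the heavier validation runs are chosen to keep the suite
fast while leaving conclusions unchanged: the 100-seed sign-recovery check
fits one noisy replicate per ligand and reads NMR intensities from
4096-point spectra; single-panel analyses use the full defaults.

## Known limitations

* The homodimer K_D/ΔH are treated as ligand-independent and noise-free
  constants when fixed in competition fits; their uncertainty is not
  propagated into heterodimer estimates.
* The exchange model is two-site; intermediate-exchange artefacts (small
  negative excursions, coalescence shapes) are simulated faithfully but peak
  metrics are only meaningful away from coalescence.
* The entropy column of the bundled reference table contains one internally
  inconsistent row (9cRA), flagged `tds_inconsistent` and excluded from
  consistency checks rather than corrected.
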