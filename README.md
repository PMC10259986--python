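# htdkit

**Heterodimer thermodynamics & dynamics toolkit** — quantitative modelling of
ligand-induced dissociation of the Nurr1–RXRα ligand-binding-domain (LBD)
heterodimer.

Nurr1 (NR4A2) is an orphan nuclear receptor that is transcriptionally active
as a monomer on NBRE DNA elements and is repressed when RXRα (NR2B1)
heterodimerizes with it through an LBD–LBD interface. Certain RXRα-pocket
ligands activate Nurr1-RXRα–driven transcription not by the classical
coactivator-recruitment route but by *weakening the heterodimer* — acting as
allosteric protein–protein-interaction inhibitors that release
transcriptionally active Nurr1 monomer. `htdkit` implements the analysis
chain that quantifies this mechanism, for biophysicists and chemical
biologists working on nuclear-receptor dimer modulation:

* **`htdkit.equilibria`** — coupled mass-action solvers for the
  homodimer-competition scheme A + A ⇌ A₂, A + B ⇌ AB
  (K_D's defined as [A]²/[A₂] and [A][B]/[AB]).
* **`htdkit.itc`** — simulation and fitting of dissociation-by-dilution and
  competition ITC experiments, plus the ΔG/ΔH/TΔS decomposition
  (TΔS = ΔH − RT ln10·log₁₀K_D) and replicate statistics. Fitting follows
  the model/results idiom: `CompetitionITC(isotherm).fit()` returns a
  results object with estimates, standard errors and `summary()`.
* **`htdkit.nmr_lineshape`** — two-site Bloch–McConnell lineshape simulation
  of the observed Nurr1 reporter resonance (free monomer ⇌ heterodimer)
  coupled to RXRα self-dimerization, with peak metrics.
* **`htdkit.nmr_populations`** — the slow-exchange peak-intensity statistic
  I_m/(I_m+I_hd) with quadrature error propagation and replicate
  aggregation.
* **`htdkit.panel_stats`** — Pearson/Spearman correlations with two-tailed
  p-values and standardized PCA with parallel-analysis retention.
* **`htdkit.synthetic_data`** — a generative ligand-panel model (three
  pharmacological classes, affinity-linked transcription, class-driven
  coactivator readouts) so the whole chain runs and validates with no
  external data.

See `docs/methods.md` for the model details, conventions and numerical
choices.

## Worked example

Simulate a competition titration (1 mM Nurr1 syringe into a 100 µM RXRα
cell, 20 × 2 µL injections) from the vehicle-condition heterodimer
parameters, add realistic heat noise, and fit it with the homodimer
parameters (K_D 16.3 µM, ΔH −13.10 kcal/mol) held fixed:

```python
import numpy as np
from htdkit import (BindingParameters, CompetitionITC, TitrationProtocol,
                    simulate_competition_heats)

protocol = TitrationProtocol(syringe_conc=1e-3, cell_conc=1e-4)
truth = BindingParameters(log_kd_het=-5.335, dh_het=2.900)
isotherm = simulate_competition_heats(protocol, truth)
noisy = isotherm.with_noise(0.2, np.random.default_rng(42))
print(CompetitionITC(noisy).fit().summary())
```

```
CompetitionITCResults
=====================
n injections      20
identifiable      True
converged         True
residual SS       0.517205 µcal²
log_kd_het        -5.31896 ± 0.01267
dh_het            2.92153 ± 0.05164
```

The fit recovers the generating log K_D (−5.335) and ΔH (+2.900 kcal/mol)
within the noise-limited uncertainty. The same ligand state seen by NMR —
200 µM Nurr1 with two equivalents of RXRα, slow exchange:

```python
from htdkit import LineshapeParams, measure_peaks, simulate_spectrum

spec = simulate_spectrum(LineshapeParams(lr_ratio=2.0))
for pk in measure_peaks(spec):
    print(f"peak at {pk.position:8.2f} Hz  FWHH {pk.fwhh:5.2f} Hz  area {pk.area_fraction:.3f}")
print("populations (free, bound):", tuple(round(x, 4) for x in spec.populations))
```

```
peak at  -149.00 Hz  FWHH 39.44 Hz  area 0.138
peak at    -0.15 Hz  FWHH 41.74 Hz  area 0.862
populations (free, bound): (0.1077, 0.8923)
```

Two resolved peaks ~150 Hz apart whose areas track the monomer/heterodimer
populations: weakening K_D,het shifts area from the bound peak at 0 Hz to
the free-monomer peak at −150 Hz.

The full analysis graph — synthetic panel → ITC fits → NMR populations →
correlations → PCA — runs from the CLI:

```bash
htd run-all --seed 1 --out results/panel
htd itc simulate-competition --log-kd-het -4.376 --dh-het 5.365 --out brf.csv
htd nmr simulate --kd-het 4.2e-5 --lr-ratio 2.0 --out spectrum.csv
```

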