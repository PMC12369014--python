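# bacadhere

Mechanics-gated stochastic modelling and SEM morphometry of bacterial
adhesion on soft polymer films.

Softening a polymer film — for example a chitosan coating whose modulus
drops from ~85 MPa to ~1.8 MPa when interfacial water is entrapped —
changes how readily bacteria attach to it. `bacadhere` is a Python
library for researchers studying that coupling between substrate
mechanics and early (phase-one) bacterial adhesion. It implements:

- **JKR–Griffith adhesion thresholds.** A bacterium of effective contact
  radius *R* on a film with effective modulus *E*\* and work of adhesion
  Δγ has a critical contact radius
  *a*<sub>c</sub> = (9πΔγR² / 2E\*)<sup>1/3</sup> and an energetic
  barrier *U*<sub>th</sub> = −π*a*<sub>c</sub>²Δγ, which scales as
  *E*\*<sup>−2/3</sup> and Δγ<sup>5/3</sup>.
- **xDLVO interaction energies** (Lifshitz–van der Waals, electrostatic
  double layer, Lewis acid–base, sphere–plate forms) and a calibrated
  Gaussian sampler of per-contact interaction energy.
- **A stochastic lattice simulation**: contact attempts scheduled by
  logistic population growth; each attempt adheres iff its sampled
  energy is at or below the substrate threshold; adhered bacteria
  occupy cells of a binary 1024×1024 grid, reported at 6/12/18/24 h
  over replicate ensembles.
- **An SEM image quantification pipeline**: CLAHE, denoising,
  background correction, adaptive thresholding, watershed splitting,
  connected-component morphometrics (area, circularity, solidity),
  single/aggregate classification, and coverage-scaled counts.
- **A ground-truthed synthetic micrograph generator** and the study's
  statistics (pooled t-test, balanced two-way ANOVA) so every stage is
  testable without any external data.

## Worked example

```python
from bacadhere import (
    HYDRO_SOFTENED, UNSOFTENED, adhesion_threshold_energy,
    SimulationConfig, simulate_ensemble, fold_change,
)

for sub in (HYDRO_SOFTENED, UNSOFTENED):
    print(sub.label, adhesion_threshold_energy(sub))
# hydro-softened -1.1932726256113024e-12
# unsoftened     -1.5967471125581296e-12

soft = simulate_ensemble(SimulationConfig(substrate=HYDRO_SOFTENED, seed=1))
unsoft = simulate_ensemble(SimulationConfig(substrate=UNSOFTENED, seed=2))
print(soft.final_mean(), unsoft.final_mean(), fold_change(soft, unsoft))
# 1012.375 183.75 5.509...
```

The two thresholds (J) say the hydro-softened film presents a smaller
(less negative) energetic barrier; the ensemble means say that over a
24 h incubation the simulation seeds ~1000 bacteria on the softened film
versus ~180 on the unsoftened one — a >5-fold difference driven entirely
by the threshold shift, since both conditions share the same energy
sampler and growth schedule.

More narrative walk-throughs live in `examples/` (threshold model,
interaction profiles, simulation ensembles, synthetic-micrograph
quantification, morphology statistics); each prints its results with a
line on what they mean. A thin CLI mirrors the batch stages:
`bacadhere landscape | profile | simulate | quantify | synth-image |
synth-counts | stats` (see `bacadhere --help`).

## Documentation

`docs/methods.md` describes the model chain, every default and its
rationale, what the synthetic generator does and does not emulate, and
known limitations.
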