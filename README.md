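# syconpump

Hydrodynamics of pumping and particle capture in **gasket-less (syconoid)
sponge flagellated chambers**, for biological fluid dynamicists and
functional morphologists studying filter feeding.

Leucon-type sponges seal each collar filter with a physical gasket so that
their high-pressure canal systems cannot drive backflow around the filter.
Calcareous sponges with ascon/sycon architecture lack such seals, yet pump
and filter effectively.  This package implements the full modeling chain
behind that result:

* a quasi-steady **Stokes solver** for the repeating unit of a flagellated
  chamber — one ostium (inlet pore) surrounded by 24 choanocytes whose
  vaned flagella beat as prescribed traveling-wave sheets
  `d(s,t) = a (1 − e^{−(s/δ)²}) sin(2π(s/λ − f t))`, with the microvillar
  collars homogenized as Brinkman layers (resistance from the classical
  cylinder-row grating solution);
* the **pump/system characteristic framework**: the linear pump curve
  `P̂ = 1 − Q̂` against the canal (ostium) resistance
  `R_ost = 128 μ L_ost / (π D_ost⁴)`, whose intersection
  `Q̂ = 1/(1 + R_ost/C_pump)` is the operating point;
* **passive tracer transport** quantifying how the stagnation zone above
  the ostium (the "hydrodynamic gasket") forces inhaled water through the
  collars;
* the **In-Ex retention-efficiency statistics** (bead-calibrated cytometry
  counts, `100 (C_in − C_ex)/C_in`, box summaries) together with a
  synthetic-data generator that emulates the paired experiment.

## Worked example

Period-averaged base-case simulation on the coarse grid (h = 1 µm, a
couple of minutes on one CPU):

```python
from syconpump import (
    BeatKinematics, SolverConfig, reference_geometry,
    run_period, time_average, stagnation_height,
)

geom = reference_geometry()          # 7 µm ostium, 24 collars, no gasket
kin = BeatKinematics()               # λ=5, a=1, δ=1 µm, 30 Hz, W=0.7 µm
cfg = SolverConfig(h=1.0, phases_per_period=8, rtol=1e-6)

fields, probs, masks = run_period(geom, kin, cfg)
mean, rates = time_average(fields, probs, masks)
print(f"Q_ost = {rates.Q_ost:.0f} um^3/s")
print(f"Q_col = {rates.Q_col:.0f} um^3/s  (re-filtration ratio "
      f"{rates.Q_col / rates.Q_ost:.1f})")
print(f"stagnation height = {stagnation_height(mean, masks):.1f} um "
      f"(collar length {masks.collar_length} um)")
```

```
Q_ost = 530 um^3/s
Q_col = 980 um^3/s  (re-filtration ratio 1.8)
stagnation height = 3.5 um (collar length 4.8 um)
```

The chamber pumps ~530 µm³/s through the one ostium of this unit while
even more water passes the collar filters (water inside the chamber is
re-filtered), and the mean vertical flow above the ostium reverses just
below collar-tip height: the backflow zone that acts as a hydrodynamic
gasket and steers inhaled water into the filters.

The same pipeline is scriptable from the shell:

```
syconpump simulate --out runs/base --tracers
syconpump characterize-pump --out runs/pump
syconpump generate-synthetic --out runs/synth --seed 1
syconpump analyze-experiment --inex runs/synth/inex.tsv \
    --flux runs/synth/flux.tsv --out runs/analysis
```

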