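# felig

Iron-binding organic ligands and humic substances in seawater: a Python
toolkit for competitive-exchange titration modelling and for asking which
organic substances could plausibly supply the ligand pool that keeps
dissolved iron in solution.

Dissolved iron (DFe) in the ocean is almost entirely bound to organic
ligands (Fe-L). Electrochemical titrations (CLE-AdCSV: competitive ligand
exchange — adsorptive cathodic stripping voltammetry) measure the total
ligand concentration `L_T` and the conditional stability constant
`log K_Fe'L`, while a separate voltammetric signal quantifies electroactive
humic substances (eHS, in Suwannee River fulvic acid mass equivalents).
`felig` links the two: it fits titrations, and it converts an eHS
measurement into the ligand pool each candidate substance — exopolymeric
substances (EPS) from phytoplankton and bacteria, carbohydrates, terrestrial
humic and fulvic standards — would supply if it made up the humic signal.

## The model

**Titrations.** With added competing ligand salicylaldoxime (SA,
side-reaction coefficient α_SA = K₁[SA] (+ β₂[SA]²)), total iron partitions
as

```
Fe_T = [Fe'](1 + α_SA) + K·[Fe']·L_T / (1 + K·[Fe'])
```

which is a quadratic in inorganic iron [Fe'], solved in closed form. The
voltammetric peak is proportional to [FeSA] = α_SA·[Fe']. A titration
(0–9 nmol/L Fe additions) is inverted either by the van den Berg / Ruzic
linearisation `[Fe']/[FeL] = [Fe']/L_T + 1/(K·L_T)` or by nonlinear least
squares on the forward model over (L_T, log K, sensitivity).

**Humic equivalence.** For a substance X with eHS content `c_eHS`
(mg eHS/mg) and Fe-binding capacity `q_Fe` (nmol Fe/mg),

```
[X]      = eHS(mg/L) / c_eHS            (equivalent concentration, mg/L)
L_X      = [X] × q_Fe                   (ligand equivalent, nmol/L)
contrib  = 100 × L_X / Fe-L             (% of the in-situ ligand pool)
```

and the complexing-capacity criterion compares `eL × K` (excess ligand
eL = Fe-L − DFe times the conditional constant) between each substance and
the in-situ pool: only substances whose capacity matches or exceeds the
in-situ value can plausibly control iron chemistry.

## Worked example

```python
from felig import speciation as sp

curve = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3,
                              sensitivity=1e9, noise_sd=0.02, seed=42)
fit = sp.fit_nonlinear(curve)
print(fit.L_T, fit.logK)
```

prints `L_T = 2.004 ± 0.089 nmol/L, logK = 11.271 ± 0.210` — the fit
recovers the simulated ligand concentration and stability constant from a
10-point titration with 2% peak-current noise; the standard errors are
asymptotic. Running `python examples/humic_equivalence.py` for a surface
sample (eHS 75.7 µg/L, Fe-L 2.0 nmol/L, DFe 0.5 nmol/L) prints, per
substance, the ligand equivalent, its % contribution and the Fe saturation
the substance would need to account for the whole in-situ pool — e.g.
phytoplankton EPS supplies 45.6 nmol/L of potential ligand (2279% of
Fe-L), so ~4.4% Fe saturation of the EPS pool would already explain all
in-situ ligands, while fulvic acid reaches only 62%.

The other `examples/` scripts cover the dust-borne eHS flux budget
(0.74–69.6 µg m⁻² d⁻¹, a negligible ~7×10⁻⁵ of a summer mixed-layer
inventory per day) and a full synthetic survey analysed with the Pearson /
PCA / regression tools.

## Command line

A thin CLI wraps the library for file-based runs:

```
felig simulate-stations --n-stations 10 --seed 1 --out stations.csv
felig fit-titration --input titration.csv --method both
felig equivalence --stations stations.csv --out equivalence.csv
felig dust-flux --content 3.7 5.8 --deposition 0.2 12
felig run-all --seed 7 --out-dir results/
```

`run-all` executes generate → fit → equivalence → stats end to end and is
byte-reproducible from its seed.

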