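# nitriso

Nitrate isotope systematics for groundwater in serpentinizing (ophiolite)
aquifers: triple-oxygen-isotope source apportionment, Rayleigh
fractionation analysis of nitrate reduction, and the mass-balance
corrections those measurements need.

## The scientific problem

In arid, rock-hosted aquifers, dissolved nitrate comes from two sources:
atmospheric deposition and in-situ nitrification. Atmospheric NO₃⁻
carries a mass-independent ¹⁷O excess inherited from ozone photochemistry,

Δ¹⁷O = δ¹⁷O − 0.52 · δ¹⁸O   (linear frame; a logarithmic frame is also provided),

while biologically produced nitrate is mass-dependent (Δ¹⁷O = 0). Because
biology cannot create or destroy the anomaly, a two-endmember mass
balance gives the atmospheric fraction of any mixed sample:

f_atm = Δ¹⁷O_mixed / Δ¹⁷O_atm,

with Δ¹⁷O_atm = 16.8 ‰ (measured rainwater) by default and an inflated
31.8 ‰ endmember for a conservative lower bound. Inverting the δ¹⁸O mass
balance then recovers the composition of the biogeochemical endmember.

Nitrate consumption (denitrification or dissimilatory reduction to
ammonium) follows closed-system Rayleigh dynamics: regressing δ on
ln(C/C₀) estimates the enrichment factor ε (negative for normal kinetic
discrimination), and the slope of δ¹⁸O vs δ¹⁵N — the ¹⁸ε/¹⁵ε
proportionality — is diagnostic of the reductase (≈0.91 for
membrane-bound Nar, ≈0.55 for periplasmic Nap).

The package also provides: fluid reaction-history classification
(Mg²⁺-HCO₃⁻ vs hyperalkaline Ca²⁺-OH⁻ fluids, from pH and lithology),
conservative ∑Si tracer mixing, nitrite isotope inference by mass
balance from paired treated/untreated analyses, persulfate blank
correction, a reduced-N/∑NH₃ pool-equivalence check, an ammonia
degassing enrichment model, and a synthetic aquifer generator with a
hidden-truth table for end-to-end parameter-recovery testing.

It is written for isotope biogeochemists and hydrogeochemists working
with per-sample delta tables (CSV in, CSV out).

## Worked example

The in-study data tables ship with the package. Export them and run the
full pipeline:

```sh
nitriso fixtures --output fix
nitriso pipeline fix/samples.csv --output out
```

which prints (abridged):

```
nitriso pipeline report
samples: 34  flagged: 1
anomaly method: linear; atmospheric endmember 16.8 permil (conservative 31.8 permil)
f_atm range: 0.18 to 1.0 over 9 samples
...
caveat: Rayleigh fits assume a closed system; resupply of nitrate by
nitrification or diffusive mixing biases fitted epsilon toward zero.
```

`out/results.csv` holds the per-sample apportionment. The first row,
the deep packed interval of borehole BA1A, reads
`cap_delta17o_used = 4.3`, `f_atm = 0.256`, `f_atm_conservative = 0.135`,
`d18o_biogeo = 25.6`: about a quarter of that nitrate is relict
atmospheric deposition, and the biogeochemical remainder is strongly
¹⁸O-enriched — the signature of extensive nitrate reduction. Shallow
Mg²⁺-HCO₃⁻ fluids span f_atm 0.18–0.41.

The same machinery inverts its own forward model. Simulating 40 samples
with ε¹⁵ = −17.5 ‰ and a Nar-type proportionality of 0.91 at the stated
analytical precisions, then fitting:

```python
from nitriso import SimulationParams, generate_aquifer_dataset, fit_rayleigh

params = SimulationParams(n_samples=40, seed=42, epsilon15=-17.5, proportionality=0.91)
obs, truth = generate_aquifer_dataset(params)
fit = fit_rayleigh(obs["no3_um"], obs["d15n_no3_permil"], obs["d18o_no3_permil"])
print(fit.epsilon15, fit.proportionality, fit.reductase_label)
```

prints `eps15=-17.97  eps18=-16.61  prop=0.924  label=Nar-consistent  r2=0.998`
— the generating parameters recovered within the noise.

CLI subcommands: `simulate`, `classify`, `delta17o`, `fatm`, `rayleigh`,
`pipeline`, `fixtures`; see `nitriso --help`.

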