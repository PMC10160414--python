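# Methods

## Delta arithmetic and the ¹⁷O anomaly

Deltas are per-mil deviations of isotope ratios from air (N) or VSMOW
(O). All values are carried at full precision internally; rounding to
printed precision (one decimal for deltas and anomalies, two for
fractions, ties away from zero) happens only at report time. Absent
values are first-class (`None`/empty cells), never sentinel numbers.

The mass-independent anomaly is computed in one of two reference frames
with λ = 0.52 (a single configurable constant):

* linear: Δ¹⁷O = δ¹⁷O − λ·δ¹⁸O
* logarithmic: Δ¹⁷O = [ln(1+δ¹⁷O/1000) − λ·ln(1+δ¹⁸O/1000)]·1000

**Default: linear.** Published per-sample tables in this problem domain
are only self-consistent in the linear frame at large deltas (a
rainwater composition of δ¹⁸O 53.7, δ¹⁷O 44.7 gives 16.8 ‰ linear but
16.53 ‰ logarithmic), so the linear frame is the default and the method
in use is recorded next to every derived value. The frames differ by a
curvature term ≈(δ¹⁷O² − λ·δ¹⁸O²)/2000, under 0.35 ‰ for deltas within
±25 ‰ but up to ~0.25 ‰ already for atmospheric-endmember compositions.
Mixed-provenance tables (some rows matching one frame, some the other,
some neither because they were computed from unrounded raw deltas) are
reproduced row by row where they recompute, and not forced where they
do not.

## Fluid classification and tracer mixing

Gabbro-hosted fluids are reported as their own class regardless of
chemistry. For peridotite/alluvium wells, pH < 9.6 → Mg²⁺-HCO₃⁻
(shallow, open-system), pH ≥ 10 → Ca²⁺-OH⁻ (deep, extensively reacted),
with a `transitional` label for the 9.6–10 band so classification is
total — sampled fluids in the source system never fall in that band.
Classification is per sample, never per well: wells can change type
between sampling years. A cation-dominance cross-check (Ca vs Mg) warns
on disagreement but pH controls.

∑Si conservative-tracer mixing fractions are affine between endmember
concentrations, clipped to [0, 1] with a logged warning. Endmember ∑Si
values are configuration with **no defaults**: they derive from a
thermodynamic reaction-path model that is out of scope here, so
mixing-percentage output requires user-supplied endmember values.

## Source apportionment

f_atm = Δ¹⁷O_mixed/Δ¹⁷O_atm, clipped to [0, 1] (analytical noise can
push near-zero anomalies slightly negative; every clip is logged).
Defaults: Δ¹⁷O_atm = 16.8 ‰ (measured rainwater) for the central
estimate; 31.8 ‰ (+15 ‰, the seasonal fluctuation scale of atmospheric
NOₓ) for a conservative lower bound. The bound is a bound, not an
uncertainty interval. The biogeochemical endmember δ¹⁸O follows from
(δ¹⁸O_mixed − f_atm·δ¹⁸O_atm)/(1 − f_atm); it is undefined at
f_atm = 1 and such rows are flagged, not fatal.

Mixing arithmetic is in delta space, consistent with the f_atm
equations; relative to ratio-space mixing this introduces ≤0.05 ‰ at
these magnitudes. Mixing curves are mole-weighted when endmember
nitrate concentrations differ.

When a reproduced table carries its own published anomaly column, that
value feeds the apportionment by default (`prefer_reported_anomaly`):
published anomalies are computed from unrounded raw deltas, so the
printed anomaly is closer to the measurement than an anomaly recomputed
from printed (rounded) deltas. The recomputed anomaly is always emitted
alongside for comparison.

## Rayleigh analysis

Forward model, residual pool: exact δ = (1000+δ₀)·f^(ε/1000) − 1000 or
approximate δ = δ₀ + ε·ln f. Sign convention: ε < 0 is a normal kinetic
isotope effect everywhere; nothing flips signs silently. The two forms
differ by (ε·ln f)²/2000 plus a δ₀ cross-term — under 0.15 ‰ for
enrichments below ~17 ‰ but several tenths of a per-mil at strong
consumption, which matters when asserting anomaly invariance: the
linear-frame anomaly is exactly invariant under approximate-form
mass-dependent fractionation (¹⁷ε = λ·¹⁸ε) and the log-frame anomaly
exactly invariant under the exact form; cross-frame drift reaches
~0.3 ‰ at 95 % consumption.

ε is estimated by OLS of δ on ln(C/C₀) (the slope is ε, the intercept
δ₀). C₀ defaults to the maximum observed concentration — the choice
shifts only the intercept, never the slope — and is configurable and
logged. The ¹⁸ε/¹⁵ε proportionality reported in a joint fit is the
ratio of the two single-isotope slopes; the direct δ¹⁸O-on-δ¹⁵N
regression (OLS by default, major-axis optionally, since both variables
carry error) provides the diagnostic r². Fits require n ≥ 3 and
non-degenerate regressor variance.

Reductase consistency: |slope − 0.91| ≤ 0.15 → Nar-consistent,
|slope − 0.55| ≤ 0.15 → Nap-consistent, otherwise ambiguous (tolerance
configurable). Literature ¹⁵ε ranges (inclusive): Nar −31.6 to −6.6 ‰,
Nap −39.8 to −11.4 ‰.

Every report carries the mandatory caveat that aquifers resupplied by
nitrification or diffusive mixing violate the closed-system assumption,
biasing fitted ε toward zero; open-system models are out of scope.

## Ancillary pool models

* **Nitrite inference**: c and δ of the removed pool by mole-weighted
  mass balance from paired untreated/treated analyses; removed pools
  under 1 % of total warn (poorly constrained).
* **Persulfate blank correction**: standard isotope-dilution form;
  blank-dominated analyses error out.
* **Pool equivalence**: N_red ≈ ∑NH₃ iff |difference| ≤ k·combined σ
  (k = 2 default, configurable). The per-borehole verdict
  (`mixed_reduced_n_boreholes`) flags a borehole only when **every**
  evaluable sample fails: one discordant year amid concordant ones is
  treated as measurement scatter, while consistent discordance across
  samples indicates a genuine non-ammonia reduced-N component. On the
  packaged reduced-N table this flags exactly the two boreholes whose
  δ¹⁵N_red must be read as a mixed pool.
* **Ammonia degassing**: Rayleigh residual enrichment driven by the
  −42.5 ‰ equilibrium effect of ∑NH₃ speciation/volatilization, applied
  as if kinetic — adequate for residual-pool reasoning, not an
  air-water exchange model. NH₃/NH₄⁺ acid-base speciation is not
  modelled.

## Synthetic data generator

Per sample: draw f_atm (uniform on [0.18, 0.41] by default, the
observed groundwater range); mix endmembers in delta space — atmospheric
δ¹⁸O 53.7 ‰, Δ¹⁷O 16.8 ‰, δ¹⁵N −2.2 ‰ at 252.2 μM; nitrification δ¹⁸O
−0.4 ‰ (ambient-water value), Δ¹⁷O 0, δ¹⁵N configurable (default 5 ‰,
midrange of observed nitrified nitrate; the true value tracks the
ammonia substrate and has no field-constrained default) — with δ¹⁷O
built mass-dependently on the nitrification side so the pre-noise
linear anomaly is exactly f_atm·16.8 ‰. Draw f_remaining (log-uniform
on [0.05, 1]); apply Rayleigh reduction (exact form by default,
switchable) with ε¹⁵, ε¹⁸ = proportionality·ε¹⁵, ¹⁷ε = λ·¹⁸ε; route
consumed N to ∑NH₃ (total fixed N conserved to 1e−9 μM pre-noise) with
its δ¹⁵N from isotope mass balance. Add Gaussian noise: σ = 0.1 ‰
(δ¹⁵N), 0.3 ‰ (δ¹⁸O), 0.84/0.64 ‰ (triple-oxygen δ¹⁸O/δ¹⁷O), 3 %
concentration CV. Initial nitrate is 140 μM (the observed shallow-fluid
range is 66–146 μM). Output is byte-identical under a fixed seed; the
hidden-truth table always accompanies the observables.

What the generator does **not** emulate: hydrologic transport and time
dynamics, nitrate resupply during consumption (the very violation the
Rayleigh caveat warns about), nitrification isotope effects, seasonal
variation of the atmospheric endmember, inter-well heterogeneity of the
source mixture. Passing recovery tests therefore demonstrate that the
estimators invert the assumed process model at realistic noise — not
that a real aquifer satisfies that model. The emitted pH is a monotone
map of consumption (8.3 → 11.4) so the classifier has an input; it is
not a speciation calculation.

## Pipeline and numerical choices

Stages: classify → anomaly → f_atm (+bound) → biogeochemical δ¹⁸O →
per-stratum Rayleigh fits (fluid type by default, ≥3 usable samples).
Row failures flag the row and never abort the run; all clips and skips
are logged with their rule. The anomaly pairs δ¹⁷O with the
triple-oxygen δ¹⁸O column when present (same analytical aliquot),
falling back to the denitrifier-method δ¹⁸O. Runs are deterministic and
idempotent; CSV round trips are lossless at declared precision.

Problem sizes in the test suite are small by design — the method's
statistics stabilize at tens of samples, so recovery checks use n = 20
per replicate with 200 seeded replicates per condition and complete in
seconds.

## Known limitations

* Two endmembers only; no Bayesian multi-source apportionment.
* Closed-system Rayleigh only; fitted ε from resupplied systems are
  apparent values.
* The ∑Si mixing model needs user-supplied endmember concentrations.
* The published per-sample pH/major-ion supplement is not packaged, so
  classification on the packaged tables rests on the published
  per-sample labels rather than raw pH.
* N₂O systematics, rock-N, and metagenomic gene inventories are carried
  as data tables only; no computation is offered on them.
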