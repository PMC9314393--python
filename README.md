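# ntrace

A coupled soil–atmosphere nitrogen isotope model of terrestrial N₂O
emissions, for biogeochemists who want to constrain how nitrogen losses from
soils — leaching, ammonia volatilization, and microbial gas production — are
partitioned, using the natural-abundance ¹⁵N record instead of sparse flux
chambers.

## The model

Soil δ¹⁵N integrates the history of N losses: leaching removes nitrogen with
almost no isotopic fractionation, while NH₃ volatilization and microbial gas
production (NO, N₂O, N₂ from nitrification and denitrification) strongly
prefer ¹⁴N and enrich the remaining soil pool. At steady state,

    f_L + f_NH3 + f_G = 1
    δ¹⁵N_soil = δ¹⁵N_i − ε_G·f_G − ε_L·f_L − ε_NH3·f_NH3

where the `f` are the fractions of total N loss through each pathway and the
ε are *effective* fractionation factors, ε·frac_ex, with `frac_ex ∈ [0,1]`
the degree to which laboratory fractionation factors are expressed in
structured soils. The solver traces ¹⁴N and ¹⁵N (and, for N₂O, the α and β
positions separately, so site preference SP = δ¹⁵Nᵅ − δ¹⁵Nᵝ is carried)
through discrete addition/removal cycles and solves for f_G per grid cell by
a fixed-point update, to within 0.01 ‰.

Gas losses are split into N₂O/NO/N₂, and N₂O production into nitrification
vs denitrification, by logistic functions of water-filled pore space; N₂
production consumes N₂O (complete denitrification), Rayleigh-enriching the
residual flux. Per-cell fractions times annual N inputs (fertilisation ×
a harvest-reduction factor `fert_EF_red`, deposition, fixation), with a
temperature sensitivity `temp_sens` on microbial gas production, give
gridded fluxes; these feed a two-box troposphere–stratosphere model of N₂O
mixing ratio, δ¹⁵N and SP. A Metropolis MCMC (stepsizes 0.75/0.5/0.25 in
blocks, observations perturbed within their uncertainties each iteration)
calibrates the key parameters against binned atmospheric series and
climate-zone emission factors.

All inputs can be generated synthetically (`ntrace.synth`), so the entire
pipeline — including full parameter-recovery experiments — runs with no
external data.

## Worked example

```python
from ntrace import CoupledIsotopeModel, SynthConfig
from ntrace.synth import gen_pseudo_observations

config = SynthConfig(seed=7, resolution=8.0)
model = CoupledIsotopeModel.from_synthetic(config)
truth = {"frac_ex": 0.55, "temp_sens": 1.1, "fert_ef_red": 0.3, "tau_pi": 120.0}
obs = gen_pseudo_observations(truth, config, model=model)

result = model.fit(obs, schedule=(0.75, 0.5, 0.25), block=2000, seed=3)
print(result.summary())
```

prints

```
Coupled N isotope model - MCMC calibration
==============================================
iterations: 6000   accepted: 84 (1.4%)

posterior (mean +/- sd over accepted sets):
  frac_ex            0.5416 +/- 0.0164
  temp_sens          1.0750 +/- 0.0232
  fert_ef_red        0.3396 +/- 0.0525
  tau_pi           120.8721 +/- 2.1546
diagnosed (steady-state closure):
  f_ocean            1.7910 +/- 0.4280
  t_to_s             0.2595 +/- 0.0026
```

Each posterior mean recovers the value used to generate the
pseudo-observations to well within two posterior standard deviations:
the fractionation expression factor (`frac_ex`, truth 0.55), the warming
response of microbial gas production (`temp_sens`, truth 1.1 = +10 % per
°C), the fraction of fertiliser N escaping harvest (`fert_ef_red`, truth
0.30) and the N₂O lifetime (`tau_pi`, truth 120 a). `f_ocean` (Tg N₂O-N a⁻¹)
and `t_to_s` (the troposphere→stratosphere exchange coefficient) are not
sampled: they are diagnosed per accepted iteration from the preindustrial
steady-state closure. Continuing,

```python
sim = result.simulate()
ef = result.emission_factor_summary(sim)
```

gives a total N₂O flux of 10.81 Tg N₂O-N a⁻¹ in 1850 rising to 25.31 in
2020, tropospheric N₂O rising from 270.0 to 375.9 nmol mol⁻¹, and a mean
N₂O emission factor of 3.15 % area-weighted versus 6.2 % weighted by N
inputs — higher, because (synthetic, like real) N inputs concentrate in
warm, moist, high-emission regions.

A CLI mirrors the library: `ntrace synth|isoscape|simulate|calibrate|analyze
--config cfg.yaml --seed N --outdir out/`, each run writing a manifest with
the config hash and seed.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
rebuilds the synthetic world at 4° resolution from the seed, runs the soil
steady-state solver with its standard iteration counts (4 outer fixed-point
iterations, 10 inner add/remove cycles) over every solvable cell, and writes
the maximum absolute mismatch (‰) between target and modelled steady-state
soil δ¹⁵N, with the number of cells used.
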