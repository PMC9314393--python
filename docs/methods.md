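# Methods

## Soil steady-state isotope balance

Each grid cell holds a well-mixed available-N pool of unitless size 1
(δ¹⁵N = 0 initially) receiving inputs at unit rate with composition
δ¹⁵N_i (default −1.5 ‰ for natural inputs; fertiliser N carries +3 ‰, so
fertiliser-derived N₂O is shifted by +4.5 ‰ relative to the cell value).
One literature reading supports δ¹⁵N_i = +0.5 ‰ instead; the choice is the
`d15n_input` config switch and shifts mean f_G by a few percent per ‰.

Losses leave through leaching (ε_L = +1 ‰), NH₃ volatilization
(ε_NH3 = −17.9 ‰) and gas production, whose overall ε_G is the
nitrification/denitrification-weighted mean of ε_nit = −56.6 ‰ and
ε_denit = −46.2 ‰ (= −31.3 + −14.9, the NO₃⁻→NO₂⁻ and NO₂⁻→N₂O steps).
Every fractionation is multiplied by a single scalar `frac_ex` (prior
uniform 0.3–1.0, initial 0.7): soils are not well-mixed gas reservoirs, and
reactions completing inside closed pores express none of their intrinsic
fractionation. One scalar for all processes is an acknowledged
simplification; process-specific expression cannot be separated by the
available constraints.

**Bookkeeping convention.** A loss through pathway *p* leaves with
δ = δ_pool + ε_p,eff (permil-additive). The ratio-multiplicative alternative
(rate¹⁵ = rate¹⁴ × (ε/1000 + 1) applied to the pool ratio) differs at
second order — below 0.2 ‰ in steady-state δ for field-scale values, up to
6×10⁻³ in f_G — but only the additive convention satisfies the linear
steady-state balance exactly, which is the form the fixed-point update and
the 0.01 ‰ convergence criterion are written in. This is the standard
convention of permil-space box models.

**Iteration scheme.** f_G starts at 0.1 (f_L = 1 − f_G − f_NH3; f_NH3 is a
prescribed input field, nearly always < 0.05). Each of 4 outer iterations
runs 10 add/remove cycles; the pool composition relaxes toward steady state
with a contraction factor of about ½ per cycle, and the pool state carries
across outer iterations, so 40 cycles leave the relaxation error far below
the update error. The outer update
f_G ← f_G − (δ¹⁵N_soil − δ¹⁵N_ss)/ε_G is Newton's method with an
approximate slope (exact slope ε_G − ε_L), giving a contraction of
ε_L/(ε_G − ε_L) ≈ 1/30 per iteration; unflagged cells reach residuals of
~10⁻³ ‰ ≤ 0.01 ‰ after 4 iterations. Pool size affects only the number of
cycles to converge, not the result.

**Feasibility.** δ¹⁵N_ss(f_G) is monotone in f_G, so a target outside
[δ_ss(0), δ_ss(1 − f_NH3)] — e.g. soil lighter than the zero-gas-loss
composition, as in net-immobilizing systems that violate the steady-state
premise — has no solution; such cells are masked and counted, not forced.

**Gas partitioning.** Logistic curves of water-filled pore space (WFPS)
give the raw N₂O/NO/N₂ shares, renormalized to sum to 1, and the
denitrification share of N₂O production. The fitted coefficients behind the
published curves are not available; the defaults here (NO: 0.85→0.10
falling around WFPS 0.35; N₂O: 0.05→0.15 rising around 0.45; N₂: 0.10→0.95
rising around 0.75; denit share rising around 0.55) reproduce the
qualitative structure — NO dominates dry soils, N₂ wet soils, N₂O peaks at
intermediate moisture, denitrification grows with moisture — and are config
entries, asserted only qualitatively in tests.

**Emitted N₂O isotopes.** At the converged pool, nitrification and
denitrification produce N₂O at δ_pool + ε_path,eff with product site
preferences of +29.9 ‰ and −1.6 ‰ respectively. SP endmembers are product
compositions, not fractionations against a substrate (NO₃⁻ has no site
preference), so they are *not* scaled by frac_ex; the reduction effects
are. N₂ production is complete reduction of N₂O, so with
r = f_N2/(f_N2 + f_N2O) the surviving flux is the Rayleigh residue: bulk δ
shifted by ε_red,eff·ln(1−r) (ε_red = −6.6 ‰) and SP by −5·frac_ex·ln(1−r),
implemented on the α/β positions as bulk ± SP/2. Evaluating production at
the converged steady state is equivalent to accumulating it cycle by cycle,
and cheaper. Gridded runs first perturb the δ¹⁵N field by 5 % of its 1σ
uncertainty times a standard-normal draw, propagating isoscape uncertainty
into every forward run.

## Flux assembly

Annual per-cell gas flux = effective N input × f_G × gas share. Fertiliser
inputs are first multiplied by `fert_EF_red` (harvest/storage removal);
emission-factor denominators use inputs *before* this reduction, so
fertiliser EFs are depressed the way field measurements at harvested sites
are. Microbial gas production scales with warming as
1 + (temp_sens − 1)·ΔT relative to the 1800 climate (linear reading of
"+10 % per degree"; an exponential form is a config flag), with leaching
reduced to conserve total N loss and gas capped at 1 − f_NH3. ΔT is a
single global annual anomaly series. EF is independent of fertilisation
rate. Non-soil industrial categories (power, road transport, chemical
industry, wastewater) enter as prescribed N₂O maps with fixed isotope
signatures (δ¹⁵N/SP: 3.9/17.6, −7.2/10.0, −8.3/3.3, −11.6/10.0 ‰); a
constant ocean flux, diagnosed rather than prescribed, completes the
source.

## Two-box atmosphere

Moles of air: 1.5×10²⁰ (troposphere), 0.27×10²⁰ (stratosphere);
MW(N₂O-N) = 28 g mol⁻¹, so 1 nmol mol⁻¹ ≙ 4.2 Tg N (troposphere). All N₂O
destruction occurs in the stratosphere at rate (total burden)/τ_PI with the
whole-atmosphere lifetime τ_PI (prior 120 ± 10 a). Exchange is gross
two-way, T_to_S·MR each direction, so the net transfer is
T_to_S·(MR_trop − MR_strat) and stratospherically enriched N₂O returns to
the troposphere — without the return flux the sink fractionation could
never reach tropospheric δ¹⁵N. Destruction removes N₂O at
δ_strat − ε_app with apparent enrichment factors ε_app (+13 ‰ bulk, +6 ‰
SP by default; positive enriches the residual stratosphere; estimates of
these factors vary across the two-box N₂O literature, so they are config
entries and asserted nowhere).

The preindustrial closure takes F_terr from the soil side at the first
model year and shifts F_ocean (prior 4 ± 1 Tg N₂O-N a⁻¹) and T_to_S
(prior 0.25 ± 0.05 Tg N₂O-N a⁻¹ per nmol mol⁻¹) along the prior-weighted
Gauss–Newton direction, each single step capped at 1 prior σ, at most 20
iterations, until the tropospheric balance holds to 10⁻⁶·F_terr; the
T_to_S search is kept on the physical branch (MR_strat > 0). Isotopic
steady state has the closed form δ_trop = δ_source + (F_up/F_down)·ε_app,
δ_strat = δ_trop + (D/F_down)·ε_app, which the annual stepper preserves as
an exact fixed point. Forward integration is explicit with annual steps
(the emission data's resolution); against a fine-step ODE integration of
the same budget the terminal mixing ratio after a 220-year ramp agrees to
~0.05 %, and mass (burdens + cumulative destruction vs cumulative
emissions) closes to 10⁻⁶ relative by construction.

## Observations and calibration

Atmospheric records are offset-corrected to an anchor dataset by chaining
mean differences over overlap windows, then averaged in left-closed blocks:
25-year blocks to 1940, 2-year blocks after (the source record is
internally inconsistent about the final edge; the edge list is config).
Emission-factor records aggregate into 16 climate zones from a 4×4
MAT×MAP quantile grid (the published zone definitions are unavailable; the
zone map is replaceable). Likelihood: independent Gaussians with variance =
within-block SD² + model-error floor² (floors 0.5 nmol mol⁻¹, 0.1 ‰
isotopes, 0.5 EF percentage points).

The Metropolis sampler proposes all parameters jointly: Gaussian-prior
parameters move by σ·stepsize·r, uniform-prior ones by (range/4)·stepsize·r,
r ~ U(−1,1) independently per parameter; stepsizes cycle 0.75/0.5/0.25 in
equal blocks (5000 iterations each at full scale; the scaled-down test
schedule is 3×2000). Observations are perturbed each iteration by their SD
× stepsize × one shared draw per group (mixing ratio, δ¹⁵N, SP, zone EF).
A prior screen accepts/rejects the proposed parameters and observation
draws before the forward run; the second Metropolis stage compares the
proposal's model-observation log-probability against the current state
*re-scored under the same perturbed observations* — freezing the previous
value instead makes the chain stick on lucky draws (the pseudo-marginal
pathology) and was rejected. Posterior mean/σ are statistics of accepted
parameter sets; F_ocean and T_to_S are recorded per iteration from the
closure, giving posteriors for them without sampling. Acceptance rates are
low (1–5 %) because prior-scaled joint proposals are much wider than the
posterior; this matches the prescribed proposal rule, and recovery
experiments show calibrated posteriors nonetheless.

## Synthetic world

The generator is a pure function of (config, seed) with one independent
stream per component. Covariates are superposed low-order lat/lon
harmonics plus Gaussian noise, clipped to physical ranges (WFPS never
leaves [0,1]). The δ¹⁵N isoscape applies a normal-score transform to its
harmonic surface — raw sinusoid fields have bimodal (arcsine) marginals,
which would put half the world below the solvable range — spanning
−5…15 ‰ with a 1 ‰ uncertainty field. N inputs: global totals of ~120 Tg N
a⁻¹ preindustrial fixation (rising to 160 by 2020), 15→90 Tg deposition,
fertilisation 0 before 1900 reaching 110 Tg in 2020 with its fastest growth
after 1945; all categories exactly constant before 1850; interannual
multiplicative noise is largest for fixation (CV 6 % vs 2 % for
deposition, matching the "2–10× more variable" character of real fixation
forcing). Spatial patterns of fixation and fertilisation correlate with a
"productive tropics" index (warm, moderately moist, ¹⁵N-enriched), and the
fertilisation pattern migrates from a temperate-biased 1940 distribution
toward that index by 2020 — this is what makes input-weighted EF exceed
area-weighted EF and the redistribution counterfactual positive, as in the
real system. Non-soil emissions grow from 0 (1900) to 1.7 Tg N₂O-N a⁻¹
(2020). Warming reaches +1.2 °C by 2020.

Pseudo-observations are forward-model output plus independent Gaussian
noise at the within-block scatter of the real record: 5.4 nmol mol⁻¹,
0.5 ‰ (δ¹⁵N) and 1.2 ‰ (SP) for pre-1940 blocks, 0.8/0.2/0.6 after; zone
EFs get 1.5 percentage points (no published value; field EF compilations
scatter by several points). What a green recovery test establishes: the
sampler and forward model are internally consistent and the three N-cycle
parameters are identifiable from this observation geometry. What it does
not establish: that real-data posteriors would match the published ones —
the synthetic world has no land-use history, no spatially correlated input
errors, no calibration-scale drift between instruments, and its EF-input
correlation is constructed.

## Isoscape regressor

Point δ¹⁵N samples (0–50 cm pooled; depth shows no systematic signal in
that range) are gap-filled from the gridded covariates at their location
and fed to a pluggable regressor — a small feed-forward network
(default, hidden layers 16/8, standardized inputs) or gradient-boosted
trees. Uncertainty is the SD of a bootstrap ensemble (default 50
resampled refits; the published count is unstated). Hold-out R² is
recorded at fit time; a constructed linear rule is recovered with R² > 0.9
and shuffled labels score ~0.

## Numerical choices and limitations

- Regular lat-lon grid, cell-centre registration, half-open cells, rows
  south→north, cos(latitude) area weights; default full grid 0.5°,
  −60…85° latitude (290×720). Test worlds use 4–12° so everything runs in
  seconds.
- Masked cells are explicit booleans; NaNs never enter arithmetic.
- Bilinear regridding via scipy's RegularGridInterpolator; any stencil
  touching a masked source cell is masked.
- The EF-bin histogram uses 19 even bins from the minimum to mean + 3 SD
  plus an open top bin; zero-variance input degenerates to a single bin,
  flagged by length.
- Growth rates are centred means of first differences: the 10-year rate
  for 2000 spans 1995–2005.
- Not modelled (out of scope by design): fungal/chemo/co-denitrification,
  soil organic N turnover fractionation, harvest-N isotope effects,
  EF dependence on fertilisation rate, interhemispheric gradients,
  estuarine/coastal N₂O.
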