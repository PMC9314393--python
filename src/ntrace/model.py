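"""Coupled soil-atmosphere model object and its calibration results.

:class:`CoupledIsotopeModel` bundles the gridded inputs (soil d15N isoscape,
WFPS, NH3 loss fraction, annual N inputs, temperature anomalies, non-soil
emission maps) and exposes

* ``simulate(params)`` — one deterministic forward run: per-cell loss
  fractions, annual global fluxes by category, the two-box atmospheric
  history, and the emission-factor field;
* ``fit(obs)`` — Metropolis MCMC calibration against binned atmospheric
  observations and climate-zone emission factors, returning a
  :class:`CalibrationResults` with posterior means, uncertainties and a
  ``summary()`` table, in the spirit of statsmodels model/results pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis as _analysis
from .atmosphere import AtmosConstants, preindustrial_balance, run_forward
from .fluxes import EmissionParams, SourceSignature, SOIL_CATEGORIES
from .grid import GridField
from .mcmc import ParameterSpec, run_mcmc
from .observations import (MODEL_ERROR_FLOORS, ObservationSet, bin_series,
                           default_bin_edges, make_zone_map, zone_mean_field)
from .soil import DEFAULT_PARTITION, FractionationSet, solve_grid
from .synth import NONSOIL_SIGNATURES, SynthConfig

__all__ = ["CoupledIsotopeModel", "SimulationResult", "CalibrationResults",
           "DEFAULT_PARAMETER_SPECS"]

DEFAULT_PARAMETER_SPECS = (
    ParameterSpec("frac_ex", "uniform", 0.3, 1.0, init=0.7),
    ParameterSpec("temp_sens", "gaussian", 1.1, 0.04),
    ParameterSpec("fert_ef_red", "gaussian", 0.4, 0.15),
    ParameterSpec("tau_pi", "gaussian", 120.0, 10.0),
)

OCEAN_SIGNATURE = SourceSignature("ocean", d15n=5.5, sp=15.8)


@dataclass
class SimulationResult:
    """Output of one forward run of the coupled model."""

    params: dict
    totals: pd.DataFrame          # per-year global fluxes and source isotopes
    atmos: pd.DataFrame           # two-box history (mr/d15n/sp per box)
    terms: object                 # diagnosed preindustrial exchange terms
    solution: object              # per-cell GridSolution
    ef: np.ndarray                # EF field (%) for the reference year
    ef_year: int

    @property
    def n2o_total(self) -> pd.Series:
        cats = [c for c in self.totals.columns if c.startswith("n2o_")]
        return self.totals[cats].sum(axis=1).rename("n2o_total")


class CoupledIsotopeModel:
    """Coupled steady-state soil isotope / two-box atmosphere model."""

    def __init__(self, d15n_field: GridField, covariates: dict,
                 f_nh3_field: GridField, n_inputs: dict, temperature: pd.Series,
                 nonsoil: dict | None = None, obs: ObservationSet | None = None,
                 fractionation: FractionationSet = FractionationSet(),
                 partition=DEFAULT_PARTITION,
                 constants: AtmosConstants = AtmosConstants(),
                 d15n_input: float = -1.5, fert_d15n: float = 3.0,
                 ocean_signature: SourceSignature = OCEAN_SIGNATURE,
                 f_ocean_prior=(4.0, 1.0), t_to_s_prior=(0.25, 0.05),
                 bin_edges=None, ef_year: int = 2010,
                 temp_response: str = "linear", perturb: float = 0.05):
        self.grid = d15n_field.grid
        self.d15n_field = d15n_field
        self.covariates = covariates
        self.f_nh3_field = f_nh3_field
        self.n_inputs = n_inputs
        self.temperature = temperature
        self.nonsoil = nonsoil or {}
        self.obs = obs
        self.fractionation = fractionation
        self.partition = partition
        self.constants = constants
        self.d15n_input = d15n_input
        self.fert_d15n = fert_d15n
        self.ocean_signature = ocean_signature
        self.f_ocean_prior = f_ocean_prior
        self.t_to_s_prior = t_to_s_prior
        self.ef_year = ef_year
        self.temp_response = temp_response
        self.perturb = perturb

        self.years = np.asarray(next(iter(n_inputs.values())).years)
        if bin_edges is None:
            bin_edges = default_bin_edges(int(self.years[0]), int(self.years[-1]))
        self.bin_edges = np.asarray(bin_edges)

        self.mask = (d15n_field.mask & covariates["WFPS"].mask
                     & f_nh3_field.mask)
        self._flat = np.flatnonzero(self.mask.ravel())
        # precompute (n_years, n_valid) input stacks per soil category
        self._inputs = {
            cat: np.stack([np.where(s.field(y).mask, s.field(y).values, 0.0)
                           .ravel()[self._flat] for y in self.years])
            for cat, s in n_inputs.items()
        }
        # non-soil categories only enter as global totals with fixed signatures
        self._nonsoil_totals = {
            cat: np.array([np.where(s.field(y).mask, s.field(y).values, 0.0).sum()
                           for y in self.years])
            for cat, s in self.nonsoil.items()
        }
        self._nonsoil_sigs = {
            cat: SourceSignature(cat, d15n=sig[1], sp=sig[2])
            for cat, sig in NONSOIL_SIGNATURES.items()
        }
        self._dt = temperature.reindex(self.years).to_numpy(dtype=float)
        self.zone_map = make_zone_map(covariates["MAT"], covariates["MAP"])
        self._forward_counter = 0

    # ------------------------------------------------------------------
    @classmethod
    def from_synthetic(cls, config: SynthConfig, **kwargs) -> "CoupledIsotopeModel":
        """Build the model from the synthetic world defined by ``config``."""
        from .synth import (gen_covariates, gen_d15n_soil, gen_f_nh3,
                            gen_n_inputs, gen_nonsoil_emissions,
                            gen_temperature_anomalies)
        cov = gen_covariates(config)
        kwargs.setdefault("bin_edges",
                          default_bin_edges(config.year_start, config.year_end))
        return cls(
            d15n_field=gen_d15n_soil(config),
            covariates=cov,
            f_nh3_field=gen_f_nh3(config),
            n_inputs=gen_n_inputs(config),
            temperature=gen_temperature_anomalies(config),
            nonsoil=gen_nonsoil_emissions(config),
            **kwargs,
        )

    # ------------------------------------------------------------------
    def _params(self, params: dict | None) -> dict:
        p = {"frac_ex": self.fractionation.frac_ex,
             "temp_sens": 1.1, "fert_ef_red": 0.3,
             "tau_pi": self.constants.tau_pi,
             "d15n_input": self.d15n_input}
        if params:
            p.update(params)
        return p

    def simulate(self, params: dict | None = None, seed: int | None = 0,
                 rng=None) -> SimulationResult:
        """One forward run at the given parameter values."""
        p = self._params(params)
        fr = replace(self.fractionation, frac_ex=float(np.clip(p["frac_ex"], 0.0, 1.0)))
        eparams = EmissionParams(fert_ef_red=p["fert_ef_red"],
                                 temp_sens=p["temp_sens"],
                                 temp_response=self.temp_response)
        constants = replace(self.constants, tau_pi=p["tau_pi"])

        sol = solve_grid(self.d15n_field, self.covariates["WFPS"],
                         self.f_nh3_field, fr, seed=seed, rng=rng,
                         d15n_i=p["d15n_input"], partition=self.partition,
                         perturb=self.perturb)
        flat = self._flat
        ok = sol.mask.ravel()[flat]  # solver failures drop out of the budget

        def take(a):
            v = a.ravel()[flat]
            return np.where(ok, v, 0.0)

        f_g = take(sol.f_G)
        f_nh3 = take(sol.f_NH3)
        f_n2o = take(sol.f_N2O)
        f_no = take(sol.f_NO)
        f_n2 = take(sol.f_N2)
        d15n_cell = take(sol.d15n_n2o)
        sp_cell = take(sol.sp_n2o)

        m = eparams.temp_multiplier(self._dt)                    # (Y,)
        f_g_scaled = np.minimum(f_g[None, :] * m[:, None], 1.0 - f_nh3[None, :])

        shift = self.fert_d15n - p["d15n_input"]
        n2o_tot, no_tot, n2_tot = {}, 0.0, 0.0
        w_d15n = np.zeros(len(self.years))
        w_sp = np.zeros(len(self.years))
        n2o_cell_ref = np.zeros(len(flat))
        input_cell_ref = np.zeros(len(flat))
        iy_ref = int(self.ef_year - self.years[0])
        for cat in SOIL_CATEGORIES:
            if cat not in self._inputs:
                continue
            red = eparams.fert_ef_red if cat == "fertilisation" else 1.0
            inp = self._inputs[cat]
            gas = inp * red * f_g_scaled                          # (Y, C)
            fn2o = gas * f_n2o[None, :]
            n2o_tot[cat] = fn2o.sum(axis=1)
            no_tot = no_tot + (gas * f_no[None, :]).sum(axis=1)
            n2_tot = n2_tot + (gas * f_n2[None, :]).sum(axis=1)
            dshift = shift if cat == "fertilisation" else 0.0
            w_d15n += fn2o @ (d15n_cell + dshift)
            w_sp += fn2o @ sp_cell
            n2o_cell_ref += fn2o[iy_ref]
            input_cell_ref += inp[iy_ref]

        ns_total = np.zeros(len(self.years))
        for cat, tot in self._nonsoil_totals.items():
            sig = self._nonsoil_sigs[cat]
            ns_total += tot
            w_d15n += tot * sig.d15n
            w_sp += tot * sig.sp

        soil_total = sum(n2o_tot.values())
        terr_total = soil_total + ns_total

        f_terr_pi = float(terr_total[0])
        terms = preindustrial_balance(f_terr_pi, constants,
                                      f_ocean_prior=self.f_ocean_prior,
                                      t_to_s_prior=self.t_to_s_prior)
        total = terr_total + terms.f_ocean
        d15n_src = (w_d15n + terms.f_ocean * self.ocean_signature.d15n) / total
        sp_src = (w_sp + terms.f_ocean * self.ocean_signature.sp) / total

        atmos = run_forward(self.years, total, d15n_src, sp_src, terms, constants)

        totals = pd.DataFrame({"year": self.years}).set_index("year")
        for cat, v in n2o_tot.items():
            totals[f"n2o_{cat}"] = v
        totals["n2o_nonsoil"] = ns_total
        totals["n2o_ocean"] = terms.f_ocean
        totals["no_total"] = no_tot
        totals["n2_total"] = n2_tot
        totals["d15n_source"] = d15n_src
        totals["sp_source"] = sp_src

        ef = np.full(self.grid.shape, np.nan).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            ef[flat] = np.where(ok & (input_cell_ref > 0),
                                n2o_cell_ref / input_cell_ref * 100.0, np.nan)
        return SimulationResult(params=p, totals=totals, atmos=atmos,
                                terms=terms, solution=sol,
                                ef=ef.reshape(self.grid.shape),
                                ef_year=self.ef_year)

    # ------------------------------------------------------------------
    def observations_from_simulation(self, sim: SimulationResult) -> ObservationSet:
        """Bin a simulation into the observation structure used for fitting."""
        at = sim.atmos.reset_index()
        frames = []
        for group, col in (("mr", "mr_trop"), ("d15n", "d15n_trop"),
                           ("sp", "sp_trop")):
            b = bin_series(at.rename(columns={"year": "time", col: "value"}),
                           self.bin_edges)
            b.insert(0, "group", group)
            frames.append(b)
        series = pd.concat(frames, ignore_index=True)
        zone = zone_mean_field(sim.ef, self.zone_map)
        zone = zone[["zone", "mean", "sd", "n"]]
        return ObservationSet(series, zone, dict(MODEL_ERROR_FLOORS))

    def _model_values(self, sim: SimulationResult, obs: ObservationSet) -> dict:
        mine = self.observations_from_simulation(sim)
        out = {}
        for g in ("mr", "d15n", "sp"):
            ours = mine.group(g).set_index("bin_left")["mean"]
            theirs = obs.group(g)["bin_left"]
            out[g] = ours.reindex(theirs).to_numpy()
        ours = mine.zone_ef.set_index("zone")["mean"]
        out["ef"] = ours.reindex(obs.zone_ef["zone"]).to_numpy()
        return out

    def loglike(self, params: dict | None, obs: ObservationSet,
                seed: int | None = 0) -> float:
        from .mcmc import log_probability
        sim = self.simulate(params, seed=seed)
        return log_probability(self._model_values(sim, obs), obs)

    # ------------------------------------------------------------------
    def _cell_arrays(self, sol):
        """Flat per-valid-cell solution arrays with failures zeroed."""
        flat = self._flat
        ok = sol.mask.ravel()[flat]
        def take(a):
            v = a.ravel()[flat]
            return np.where(ok, v, 0.0)
        return ok, take(sol.f_G), take(sol.f_NH3), take(sol.f_N2O)

    def redistribution_counterfactual(self, params: dict | None = None,
                                      ref_year: int = 1940,
                                      target_year: int = 2020,
                                      seed: int | None = 0):
        """Emission change from the shifting spatial pattern of fertiliser N.

        Compares target-year fertiliser-driven N2O against a baseline using
        the ref-year spatial pattern rescaled to the target-year total.
        Returns (delta flux field, global delta in Tg N2O-N a-1).
        """
        p = self._params(params)
        sim = self.simulate(p, seed=seed)
        _, f_g, f_nh3, f_n2o = self._cell_arrays(sim.solution)
        eparams = EmissionParams(fert_ef_red=p["fert_ef_red"],
                                 temp_sens=p["temp_sens"],
                                 temp_response=self.temp_response)
        dt = self.temperature.loc[target_year]
        f_g_scaled = np.minimum(f_g * eparams.temp_multiplier(dt), 1.0 - f_nh3)

        def flux_fn(input_values):
            inp = np.asarray(input_values, dtype=float).ravel()[self._flat]
            flux = np.zeros(self.grid.n_rows * self.grid.n_cols)
            flux[self._flat] = inp * p["fert_ef_red"] * f_g_scaled * f_n2o
            return flux.reshape(self.grid.shape)

        return _analysis.counterfactual_redistribution(
            self.n_inputs["fertilisation"], flux_fn, ref_year, target_year)

    def warming_counterfactual(self, params: dict | None = None,
                               ref_year: int = 1940, target_year: int = 2020,
                               seed: int | None = 0):
        """Emission change from warming-driven EF increases since ref_year."""
        p = self._params(params)
        sim = self.simulate(p, seed=seed)
        _, f_g, f_nh3, f_n2o = self._cell_arrays(sim.solution)
        eparams = EmissionParams(fert_ef_red=p["fert_ef_red"],
                                 temp_sens=p["temp_sens"],
                                 temp_response=self.temp_response)

        def flux_with_dt(year, dt_ref_year):
            dt = self.temperature.loc[year if dt_ref_year is None else dt_ref_year]
            f_g_s = np.minimum(f_g * eparams.temp_multiplier(dt), 1.0 - f_nh3)
            iy = int(year - self.years[0])
            flux = np.zeros(self.grid.n_rows * self.grid.n_cols)
            for cat, inp in self._inputs.items():
                red = p["fert_ef_red"] if cat == "fertilisation" else 1.0
                flux[self._flat] += inp[iy] * red * f_g_s * f_n2o
            return flux.reshape(self.grid.shape)

        return _analysis.counterfactual_no_warming(flux_with_dt, ref_year,
                                                   target_year)

    # ------------------------------------------------------------------
    def fit(self, obs: ObservationSet | None = None,
            specs=DEFAULT_PARAMETER_SPECS, schedule=(0.75, 0.5, 0.25),
            block: int = 5000, total: int | None = None,
            seed: int = 0) -> "CalibrationResults":
        """Calibrate the model by Metropolis MCMC against ``obs``."""
        if obs is None:
            obs = self.obs
        if obs is None:
            raise ValueError("no observations supplied or attached to the model")
        specs = list(specs)
        self._forward_counter = 0
        base_seed = int(seed) % (2**20)

        def forward(params):
            self._forward_counter += 1
            rng = np.random.default_rng(
                np.random.SeedSequence([base_seed, self._forward_counter]))
            sim = self.simulate(params, rng=rng)
            vals = self._model_values(sim, obs)
            vals["diagnostics"] = {"f_ocean": sim.terms.f_ocean,
                                   "t_to_s": sim.terms.t_to_s}
            return vals

        res = run_mcmc(forward, specs, obs, schedule=schedule, block=block,
                       total=total, seed=seed)
        return CalibrationResults(self, res, obs)


class CalibrationResults:
    """Posterior estimates, uncertainties and diagnostics from a fit."""

    def __init__(self, model: CoupledIsotopeModel, mcmc_result, obs):
        self.model = model
        self.mcmc = mcmc_result
        self.obs = obs
        names = [s.name for s in mcmc_result.specs]
        self.params = mcmc_result.posterior["mean"].loc[names]
        self.bse = mcmc_result.posterior["sd"].loc[names]
        self.diagnostics = mcmc_result.posterior.drop(index=names)

    @property
    def chain(self) -> pd.DataFrame:
        return self.mcmc.chain

    @property
    def acceptance_rate(self) -> float:
        return self.mcmc.acceptance_rate

    def simulate(self, seed: int | None = 0) -> SimulationResult:
        """Forward run at the posterior mean parameters."""
        return self.model.simulate(dict(self.params), seed=seed)

    def summary(self) -> str:
        lines = ["Coupled N isotope model - MCMC calibration",
                 "=" * 46,
                 f"iterations: {len(self.chain)}   "
                 f"accepted: {int(self.chain['accepted'].sum())} "
                 f"({self.acceptance_rate:.1%})",
                 "",
                 "posterior (mean +/- sd over accepted sets):"]
        for name in self.params.index:
            lines.append(f"  {name:<14s} {self.params[name]:10.4f} "
                         f"+/- {self.bse[name]:.4f}")
        if len(self.diagnostics):
            lines.append("diagnosed (steady-state closure):")
            for name, row in self.diagnostics.iterrows():
                lines.append(f"  {name:<14s} {row['mean']:10.4f} "
                             f"+/- {row['sd']:.4f}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def emission_factor_summary(self, sim: SimulationResult | None = None) -> dict:
        """Area- and N-input-weighted global mean EF (%) at the EF year."""
        if sim is None:
            sim = self.simulate()
        area = self.model.grid.cell_area
        iy = int(self.model.ef_year - self.model.years[0])
        inputs = np.zeros(self.model.grid.shape).ravel()
        for cat in self.model._inputs:
            inputs[self.model._flat] += self.model._inputs[cat][iy]
        inputs = inputs.reshape(self.model.grid.shape)
        return {
            "ef_area_weighted": _analysis.weighted_mean_ef(sim.ef, area),
            "ef_input_weighted": _analysis.weighted_mean_ef(sim.ef, inputs),
        }

    def plot_timeseries(self, sim: SimulationResult | None = None, ax=None):
        """Tropospheric mixing ratio and d15N history at the posterior mean."""
        import matplotlib.pyplot as plt
        if sim is None:
            sim = self.simulate()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(sim.atmos.index, sim.atmos["mr_trop"], label="N2O mixing ratio")
        ax.set_xlabel("year")
        ax.set_ylabel("nmol mol$^{-1}$")
        ax2 = ax.twinx()
        ax2.plot(sim.atmos.index, sim.atmos["d15n_trop"], color="C1",
                 label=r"$\delta^{15}$N")
        ax2.set_ylabel("permil")
        return ax
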