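"""Synthetic inputs and pseudo-observations for the coupled model.

Every generator is a pure function of (config, seed): smooth covariate fields
are superpositions of low-order lat/lon harmonics with seeded coefficients,
N-input histories are flat before 1850 (no significant anthropogenic inputs
before then), fertilisation grows fastest after 1945, and biological fixation
carries the largest interannual variability (a few times that of deposition,
mirroring the 2-10x range seen in real input datasets).  Pseudo-observations
are forward-model output plus independent Gaussian noise, which makes full
parameter-recovery experiments possible without any external dataset.

Global magnitudes are chosen to resemble the real nitrogen budget: ~120 Tg N
a-1 of preindustrial fixation, ~15 Tg N a-1 of preindustrial deposition
growing to ~90 by 2020, fertilisation reaching ~110 Tg N a-1 in 2020, and
non-soil (industrial/wastewater) N2O emissions reaching ~1.7 Tg N2O-N a-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import AnnualGridSeries, GridField, ModelGrid, build_grid

__all__ = [
    "SynthConfig", "gen_covariates", "gen_d15n_soil", "gen_f_nh3",
    "gen_n_inputs", "gen_nonsoil_emissions", "gen_temperature_anomalies",
    "gen_soil_samples", "gen_pseudo_observations",
]

# covariate name -> (mean, harmonic amplitude, default noise sigma, lo, hi, units)
_COVARIATES = {
    "MAT": (8.0, 14.0, 1.0, -20.0, 30.0, "degC"),
    "MAP": (900.0, 600.0, 80.0, 50.0, 4000.0, "mm a-1"),
    "WFPS": (0.5, 0.22, 0.03, 0.02, 0.98, "1"),
    "bulk_density": (1.3, 0.25, 0.05, 0.7, 1.9, "g cm-3"),
    "soil_N": (0.25, 0.15, 0.03, 0.01, 1.2, "percent"),
    "pH": (6.3, 1.2, 0.2, 3.5, 9.0, "1"),
    "aridity": (0.8, 0.5, 0.08, 0.05, 3.0, "1"),
}

_FIELD_KEYS = {name: i for i, name in enumerate(
    list(_COVARIATES) + ["d15n", "mask", "f_nh3", "inputs", "temperature",
                         "samples", "obsnoise"])}


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic world (all randomness from ``seed``)."""

    seed: int = 0
    resolution: float = 4.0
    lat_range: tuple = (-60.0, 84.0)
    lon_range: tuple = (-180.0, 180.0)
    year_start: int = 1800
    year_end: int = 2020
    n_harmonics: int = 4
    land_fraction: float = 0.85
    noise_sigma: dict = field(default_factory=dict)  # overrides per covariate
    d15n_range: tuple = (-5.0, 15.0)
    d15n_sigma: float = 1.0          # 1-sigma uncertainty of the d15N isoscape
    # global N input totals, Tg N a-1
    fixation_pi: float = 120.0
    fixation_2020: float = 160.0
    deposition_pi: float = 15.0
    deposition_2020: float = 90.0
    fertilisation_2020: float = 110.0
    nonsoil_2020: float = 1.7        # Tg N2O-N a-1, direct non-soil emissions
    cv_fixation: float = 0.06        # interannual variability (multiplicative)
    cv_deposition: float = 0.02
    cv_fertilisation: float = 0.0
    warming_2020: float = 1.2        # degC anomaly vs 1800
    # pseudo-observation noise: within-block scatter of the atmospheric
    # record, (pre-1940 blocks, post-1940 blocks); a scalar applies to all
    # blocks.  The real composite record shows ~5.4 nmol/mol, 0.5 permil and
    # 1.2 permil scatter in the coarse early blocks against 0.8, 0.2 and
    # 0.6 in recent decades.
    sigma_mr: float | tuple = (5.4, 0.8)     # nmol mol-1
    sigma_delta: float | tuple = (0.5, 0.2)  # permil, d15N
    sigma_sp: float | tuple = (1.2, 0.6)     # permil, site preference
    sigma_ef: float = 1.5                    # percentage points, zone EF
    era_split_year: int = 1940

    def __post_init__(self):
        for v in self.noise_sigma.values():
            if v < 0:
                raise ValueError("noise sigma must be >= 0")
        for v in (self.sigma_mr, self.sigma_delta, self.sigma_sp, self.sigma_ef):
            if np.any(np.asarray(v, dtype=float) < 0):
                raise ValueError("observation noise sigma must be >= 0")

    def grid(self) -> ModelGrid:
        return build_grid(self.resolution, self.lat_range, self.lon_range)

    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def rng(self, key: str) -> np.random.Generator:
        """Independent, reproducible stream per generator component."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _FIELD_KEYS[key]]))


def _smooth_surface(grid: ModelGrid, rng: np.random.Generator, n_harmonics: int):
    """Standardised smooth surface from low-order spherical harmonics-like terms."""
    lat = np.deg2rad(grid.lats)[:, None]
    lon = np.deg2rad(grid.lons)[None, :]
    z = np.zeros(grid.shape)
    for k in range(1, n_harmonics + 1):
        a, b, c, d = rng.normal(size=4) / k
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        z += a * np.sin(k * lat + p1) + b * np.cos(k * lat + p2)
        z += (c * np.sin(k * lon + p1) + d * np.cos(k * lon + p2)) * np.cos(lat)
    s = z.std()
    return z / s if s > 0 else z


def gen_land_mask(config: SynthConfig) -> np.ndarray:
    """Smooth pseudo-continents covering ~land_fraction of the grid."""
    grid = config.grid()
    rng = config.rng("mask")
    z = _smooth_surface(grid, rng, config.n_harmonics + 2)
    thresh = np.quantile(z, 1.0 - config.land_fraction)
    return z >= thresh


def gen_covariates(config: SynthConfig) -> dict:
    """Smooth, noisy covariate fields within physically plausible ranges."""
    grid = config.grid()
    mask = gen_land_mask(config)
    out = {}
    for name, (mean, amp, sigma0, lo, hi, units) in _COVARIATES.items():
        sigma = config.noise_sigma.get(name, sigma0)
        rng = config.rng(name)
        smooth = mean + amp * _smooth_surface(grid, rng, config.n_harmonics)
        noise = rng.standard_normal(grid.shape)  # same draws for any sigma
        vals = np.clip(smooth + sigma * noise, lo, hi)
        out[name] = GridField(grid, vals, units, mask=mask)
    return out


def gen_d15n_soil(config: SynthConfig) -> GridField:
    """Synthetic soil d15N isoscape spanning (about) the configured range."""
    grid = config.grid()
    mask = gen_land_mask(config)
    rng = config.rng("d15n")
    z = _smooth_surface(grid, rng, config.n_harmonics)
    # harmonic surfaces have arcsine-like (bimodal) marginals; a normal-score
    # transform (monotone, so still spatially smooth) gives the gaussian-ish
    # distribution real soil d15N compilations show
    from scipy.stats import norm
    ranks = z.ravel().argsort().argsort()
    z = norm.ppf((ranks + 0.5) / ranks.size).reshape(grid.shape)
    lo, hi = config.d15n_range
    vals = (lo + hi) / 2.0 + z * (hi - lo) / 4.0
    vals = np.clip(vals, lo, hi)
    sigma = np.full(grid.shape, config.d15n_sigma)
    return GridField(grid, vals, "permil", sigma=sigma, mask=mask)


def gen_f_nh3(config: SynthConfig) -> GridField:
    """Fractional NH3 volatilization loss, nearly always below 0.05."""
    grid = config.grid()
    mask = gen_land_mask(config)
    rng = config.rng("f_nh3")
    z = _smooth_surface(grid, rng, config.n_harmonics)
    vals = np.clip(0.02 + 0.012 * z, 0.0, 0.05)
    return GridField(grid, vals, "1", mask=mask)


def _category_totals(config: SynthConfig) -> pd.DataFrame:
    """Deterministic global input trajectories (Tg N a-1) per category."""
    years = config.years().astype(float)
    t = np.maximum(years, 1850.0)
    span = config.year_end - 1850.0

    fix = config.fixation_pi + (config.fixation_2020 - config.fixation_pi) * \
        ((t - 1850.0) / span) ** 2
    dep = config.deposition_pi + (config.deposition_2020 - config.deposition_pi) * \
        ((t - 1850.0) / span) ** 1.7
    fert = np.zeros_like(years)
    pre = (years > 1900) & (years <= 1945)
    fert[pre] = 3.0 * ((years[pre] - 1900.0) / 45.0) ** 2
    post = years > 1945
    fert[post] = 3.0 + (config.fertilisation_2020 - 3.0) * \
        ((years[post] - 1945.0) / (config.year_end - 1945.0)) ** 1.5
    nonsoil = np.zeros_like(years)
    ns = years > 1900
    nonsoil[ns] = config.nonsoil_2020 * ((years[ns] - 1900.0) /
                                         (config.year_end - 1900.0)) ** 2
    return pd.DataFrame({"year": years.astype(int), "fertilisation": fert,
                         "deposition": dep, "fixation": fix,
                         "nonsoil": nonsoil}).set_index("year")


def _pattern(grid, mask, rng, n_harmonics, concentrated=False, climate=None):
    """Non-negative spatial input pattern summing to 1.

    ``climate`` is an optional standardised warm/wet surface; positive
    weight on it concentrates inputs where soils are moist and warm, the way
    real fixation and fertilisation cluster in productive (high-EF) regions.
    """
    z = _smooth_surface(grid, rng, n_harmonics)
    expo = (2.0 if concentrated else 1.5) * z
    if climate is not None:
        expo = expo + 2.0 * climate
    p = np.exp(expo)
    p = np.where(mask, p, 0.0)
    return p / p.sum()


def _climate_surface(config: SynthConfig, mask) -> np.ndarray:
    """Standardised productive-tropics index.

    High where soils are warm, moderately moist (neither arid nor
    waterlogged) and 15N-enriched — the regions where both biological N
    fixation and fertilised agriculture concentrate, and where N2O emission
    factors are highest.
    """
    cov = gen_covariates(config)
    d15n = gen_d15n_soil(config)

    def z(v):
        return (v - v[mask].mean()) / v[mask].std()

    wfps = cov["WFPS"].values
    moist = np.exp(-((wfps - 0.55) / 0.18) ** 2)  # penalise arid & waterlogged
    out = 1.2 * z(moist) + 0.5 * z(cov["MAT"].values) + 0.6 * z(d15n.values)
    return out / np.abs(out[mask]).max() * 2.0


def gen_n_inputs(config: SynthConfig) -> dict:
    """Annual gridded N inputs per category, flat before 1850.

    Interannual multiplicative noise (largest for fixation) is applied only
    after 1850 so the preindustrial slices are exactly constant.
    """
    grid = config.grid()
    mask = gen_land_mask(config)
    rng = config.rng("inputs")
    totals = _category_totals(config)
    years = config.years()
    cvs = {"fertilisation": config.cv_fertilisation,
           "deposition": config.cv_deposition,
           "fixation": config.cv_fixation}
    climate = _climate_surface(config, mask)
    # fertilisation migrates from its early temperate pattern (biased away
    # from the productive tropics) toward warm high-emission regions over
    # 1940-2020, emulating the real redistribution toward emerging economies
    fert_early = _pattern(grid, mask, rng, config.n_harmonics,
                          concentrated=True, climate=-0.8 * climate)
    fert_late = _pattern(grid, mask, rng, config.n_harmonics,
                         concentrated=True, climate=climate)
    alpha = np.clip((years - 1940.0) / (config.year_end - 1940.0), 0.0, 1.0)
    patterns = {
        "fertilisation": [(1.0 - a) * fert_early + a * fert_late for a in alpha],
        "deposition": _pattern(grid, mask, rng, config.n_harmonics),
        "fixation": _pattern(grid, mask, rng, config.n_harmonics, climate=climate),
    }
    out = {}
    for cat, pattern in patterns.items():
        noise = rng.standard_normal(len(years))
        factors = 1.0 + cvs[cat] * noise
        factors[years <= 1850] = 1.0
        factors = np.clip(factors, 0.05, None)
        fields = []
        for k, (y, f) in enumerate(zip(years, factors)):
            pat = pattern[k] if isinstance(pattern, list) else pattern
            tot = totals.loc[y, cat] * f
            fields.append(GridField(grid, pat * tot, "Tg N a-1", mask=mask))
        out[cat] = AnnualGridSeries(years, fields, category=cat)
    return out


# non-soil emission category shares and isotope signatures (d15N, SP, permil)
NONSOIL_SIGNATURES = {
    "power": (0.5, 3.9, 17.6),
    "road": (0.3, -7.2, 10.0),
    "chemical": (0.1, -8.3, 3.3),
    "wastewater": (0.1, -11.6, 10.0),
}


def gen_nonsoil_emissions(config: SynthConfig) -> dict:
    """Direct non-soil N2O emissions (Tg N2O-N a-1) per industry category."""
    grid = config.grid()
    mask = gen_land_mask(config)
    rng = config.rng("inputs")
    # consume the same draws as gen_n_inputs so patterns differ deterministically
    for _ in range(3):
        _pattern(grid, mask, rng, config.n_harmonics)
    totals = _category_totals(config)["nonsoil"]
    years = config.years()
    out = {}
    for cat, (share, _d15n, _sp) in NONSOIL_SIGNATURES.items():
        pattern = _pattern(grid, mask, rng, config.n_harmonics, concentrated=True)
        fields = [GridField(grid, pattern * totals.loc[y] * share,
                            "Tg N2O-N a-1", mask=mask) for y in years]
        out[cat] = AnnualGridSeries(years, fields, category="nonsoil")
    return out


def gen_temperature_anomalies(config: SynthConfig) -> pd.Series:
    """Global annual temperature anomaly (degC) relative to 1800."""
    years = config.years().astype(float)
    anom = np.zeros_like(years)
    w = years > 1900
    anom[w] = config.warming_2020 * ((years[w] - 1900.0) /
                                     (config.year_end - 1900.0)) ** 1.8
    rng = config.rng("temperature")
    jitter = 0.03 * rng.standard_normal(len(years))
    jitter[years <= 1850] = 0.0
    return pd.Series(anom + jitter, index=years.astype(int), name="dT")


def gen_soil_samples(config: SynthConfig, n_samples: int = 500,
                     noise: float = 0.5, missing_fraction: float = 0.0) -> pd.DataFrame:
    """Point soil d15N samples drawn from the synthetic isoscape.

    Samples sit at random valid cell centres; ancillary covariates are read
    from the gridded fields, with a ``missing_fraction`` of entries blanked
    to exercise gap-filling.
    """
    d15n = gen_d15n_soil(config)
    cov = gen_covariates(config)
    grid = config.grid()
    rng = config.rng("samples")
    valid = np.argwhere(d15n.mask)
    idx = valid[rng.integers(0, len(valid), size=n_samples)]
    rows = {
        "lat": grid.lats[idx[:, 0]],
        "lon": grid.lons[idx[:, 1]],
        "d15n": d15n.values[idx[:, 0], idx[:, 1]] + noise * rng.standard_normal(n_samples),
    }
    for name, f in cov.items():
        vals = f.values[idx[:, 0], idx[:, 1]].astype(float)
        if missing_fraction > 0:
            gone = rng.random(n_samples) < missing_fraction
            vals[gone] = np.nan
        rows[name] = vals
    return pd.DataFrame(rows)


def gen_pseudo_observations(true_params: dict, config: SynthConfig,
                            model=None):
    """Forward-model output at ``true_params`` plus independent Gaussian noise.

    Runs the coupled model built from this synthetic world (or a caller-built
    model sharing its config), then perturbs binned mixing ratio, d15N, SP
    and zone emission factors with the configured noise.  With all noise
    sigmas zero the observations equal the forward output exactly.
    """
    from .model import CoupledIsotopeModel  # local import: avoids cycle

    if model is None:
        model = CoupledIsotopeModel.from_synthetic(config)
    sim = model.simulate(true_params, seed=config.seed)
    obs = model.observations_from_simulation(sim)
    rng = config.rng("obsnoise")

    def era(sig, group):
        sig = np.asarray(sig, dtype=float)
        if sig.ndim == 0:
            return float(sig)
        left = obs.group(group)["bin_left"].to_numpy()
        return np.where(left < config.era_split_year, sig[0], sig[1])

    obs = obs.perturbed(
        rng,
        sigma_mr=era(config.sigma_mr, "mr"),
        sigma_delta=era(config.sigma_delta, "d15n"),
        sigma_sp=era(config.sigma_sp, "sp"),
        sigma_ef=config.sigma_ef,
    )
    return obs
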