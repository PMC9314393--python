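"""Metropolis MCMC over model parameters and observation perturbations.

Proposals follow the published step rules: Gaussian-prior parameters move by
sigma * stepsize * r and uniform-prior parameters by (range/4) * stepsize * r
with r ~ U(-1, 1) drawn independently per parameter.  Observations are also
perturbed each iteration by sd * stepsize * r with one shared draw per
observation group (mixing ratio, d15N, site preference, zone EF).  A
two-stage Metropolis rule is applied: a prior screen on the proposed
parameters and observation draws, then (after the forward run) the usual
accept/reject on the Gaussian model-observation log-probability.  The chain
cycles through stepsizes 0.75, 0.5, 0.25 in fixed-length blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ParameterSpec", "propose", "perturb_observations", "log_prior",
           "log_probability", "metropolis_accept", "run_mcmc", "MCMCResult"]

OBS_GROUPS = ("mr", "d15n", "sp", "ef")


@dataclass(frozen=True)
class ParameterSpec:
    """Prior and proposal rule for one calibrated parameter.

    ``prior`` is "gaussian" (a = mean, b = 1-sigma) or "uniform"
    (a = lower, b = upper).  ``init`` defaults to the mean/midpoint.
    """

    name: str
    prior: str
    a: float
    b: float
    init: float | None = None

    def __post_init__(self):
        if self.prior not in ("gaussian", "uniform"):
            raise ValueError(f"unknown prior family {self.prior!r}")
        if self.prior == "uniform" and not self.b > self.a:
            raise ValueError(f"{self.name}: uniform prior needs b > a")
        if self.prior == "gaussian" and not self.b > 0:
            raise ValueError(f"{self.name}: Gaussian prior needs sigma > 0")

    @property
    def start(self) -> float:
        if self.init is not None:
            return self.init
        return self.a if self.prior == "gaussian" else 0.5 * (self.a + self.b)

    def step_scale(self) -> float:
        return self.b if self.prior == "gaussian" else (self.b - self.a) / 4.0

    def log_prior(self, x: float) -> float:
        if self.prior == "gaussian":
            return -0.5 * ((x - self.a) / self.b) ** 2
        return 0.0 if self.a <= x <= self.b else -np.inf


def propose(values: dict, specs: list[ParameterSpec], stepsize: float,
            rng: np.random.Generator) -> dict:
    """One proposal: each parameter moves by its step scale * stepsize * r."""
    if stepsize < 0:
        raise ValueError("stepsize must be >= 0")
    out = dict(values)
    for spec in specs:
        r = rng.uniform(-1.0, 1.0)
        out[spec.name] = values[spec.name] + spec.step_scale() * stepsize * r
    return out


def log_prior(values: dict, specs: list[ParameterSpec]) -> float:
    return float(sum(spec.log_prior(values[spec.name]) for spec in specs))


def perturb_observations(obs, stepsize: float, rng: np.random.Generator):
    """Shift observations by sd * stepsize * r, one shared r per group.

    Returns (perturbed ObservationSet, draws dict, log-prior of the draws):
    the standardised group shifts u = stepsize * r are scored against a
    standard normal so large joint perturbations are rare.
    """
    draws = {g: rng.uniform(-1.0, 1.0) for g in OBS_GROUPS}
    shifted = obs.shifted(draws, stepsize=stepsize)
    logp = -0.5 * sum((stepsize * r) ** 2 for r in draws.values())
    return shifted, draws, logp


def log_probability(model_values: dict, obs) -> float:
    """Gaussian misfit: -0.5 sum((model - obs)^2 / (sd^2 + floor^2))."""
    ov = obs.values_vector()
    sig = obs.total_sigma()
    total = 0.0
    for g in OBS_GROUPS:
        m = np.asarray(model_values[g], dtype=float)
        o = ov[g]
        if m.shape != o.shape:
            raise ValueError(f"group {g}: model/obs length mismatch "
                             f"{m.shape} vs {o.shape}")
        if not np.all(np.isfinite(m)):
            return -np.inf
        total += -0.5 * float(np.sum(((m - o) / sig[g]) ** 2))
    return total


def metropolis_accept(logp_new: float, logp_old: float,
                      rng: np.random.Generator) -> bool:
    """Accept an improvement always, a worsening with prob exp(dlogp)."""
    if not np.isfinite(logp_old):
        raise ValueError("logp_old must be finite")
    if logp_new >= logp_old:
        return True
    if not np.isfinite(logp_new):
        return False
    return bool(rng.random() < np.exp(logp_new - logp_old))


class _VectorObs:
    """Array view of an ObservationSet for the per-iteration hot path.

    Equivalent to ``obs.shifted(draws, stepsize)`` but without rebuilding
    pandas frames every iteration.
    """

    def __init__(self, obs):
        self._base = obs.values_vector()
        self._sd = {g: obs.group(g)["sd"].fillna(0.0).to_numpy()
                    for g in ("mr", "d15n", "sp")}
        self._sd["ef"] = obs.zone_ef["sd"].fillna(0.0).to_numpy()
        self._sigma = obs.total_sigma()
        self._values = dict(self._base)

    def apply(self, draws: dict, stepsize: float) -> "_VectorObs":
        self._values = {g: self._base[g] + self._sd[g] * stepsize * draws[g]
                        for g in OBS_GROUPS}
        return self

    def values_vector(self) -> dict:
        return self._values

    def total_sigma(self) -> dict:
        return self._sigma


@dataclass
class MCMCResult:
    chain: pd.DataFrame            # one row per iteration (tested sets)
    posterior: pd.DataFrame        # mean/sd per parameter over accepted sets
    acceptance_rate: float
    specs: list

    def accepted(self) -> pd.DataFrame:
        return self.chain[self.chain["accepted"]]


def run_mcmc(forward, specs: list[ParameterSpec], obs,
             schedule=(0.75, 0.5, 0.25), block: int = 5000,
             total: int | None = None, seed: int = 0,
             extra_callback=None) -> MCMCResult:
    """Metropolis chain with the cyclic three-stepsize schedule.

    ``forward(params) -> dict`` must return model values for the observation
    groups (keys mr, d15n, sp, ef) and may include scalar diagnostics under
    a ``diagnostics`` key (e.g. the diagnosed ocean flux and
    troposphere-stratosphere exchange), which are recorded per iteration.
    """
    if total is None:
        total = block * len(schedule)
    if total % block != 0:
        raise ValueError("total iterations must be divisible by the block size")
    rng = np.random.default_rng(seed)

    params = {s.name: s.start for s in specs}
    cur_vals = forward(params)
    logprior = log_prior(params, specs)
    vec = _VectorObs(obs)
    _ = {g: rng.uniform(-1.0, 1.0) for g in OBS_GROUPS}  # initial draw, unused
    obslogp = 0.0
    if not np.isfinite(log_probability(cur_vals, vec)):
        raise RuntimeError("forward model failed at the initial parameter set")

    rows = []
    n_accept = 0
    stepsizes = [schedule[(i // block) % len(schedule)] for i in range(total)]
    for i, stepsize in enumerate(stepsizes):
        prop = propose(params, specs, stepsize, rng)
        lp_new = log_prior(prop, specs)
        draws = {g: rng.uniform(-1.0, 1.0) for g in OBS_GROUPS}
        obslp_new = -0.5 * sum((stepsize * r) ** 2 for r in draws.values())
        obs_i = vec.apply(draws, stepsize)
        # stage 1: prior screen on parameters and observation draws
        screen_ok = np.isfinite(lp_new) and metropolis_accept(
            lp_new + obslp_new, logprior + obslogp, rng)
        accepted = False
        ll_new = np.nan
        diag = {}
        if screen_ok:
            try:
                out = forward(prop)
                ll_new = log_probability(out, obs_i)
                diag = out.get("diagnostics", {})
            except Exception:
                ll_new = -np.inf
            # stage 2: Metropolis on the model-observation probability, with
            # the current state re-scored under this iteration's perturbed
            # observations so both sides see the same targets
            ll_cur = log_probability(cur_vals, obs_i)
            if np.isfinite(ll_new) and metropolis_accept(ll_new, ll_cur, rng):
                accepted = True
                params, logprior, obslogp = prop, lp_new, obslp_new
                cur_vals = out
                n_accept += 1
        row = {"iteration": i, "stepsize": stepsize, "accepted": accepted,
               "logp": ll_new, "log_prior": lp_new}
        row.update({s.name: prop[s.name] for s in specs})
        row.update(diag)
        rows.append(row)
        if extra_callback is not None:
            extra_callback(i, row)
    chain = pd.DataFrame(rows)
    acc = chain[chain["accepted"]]
    if len(acc) == 0:
        raise RuntimeError(
            "no accepted iterations: increase model error floors or reduce steps")
    names = [s.name for s in specs]
    diag_cols = [c for c in chain.columns
                 if c not in names + ["iteration", "stepsize", "accepted",
                                      "logp", "log_prior"]]
    post = pd.DataFrame({
        "mean": acc[names + diag_cols].mean(),
        "sd": acc[names + diag_cols].std(ddof=1),
    })
    return MCMCResult(chain=chain, posterior=post,
                      acceptance_rate=len(acc) / len(chain), specs=specs)
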