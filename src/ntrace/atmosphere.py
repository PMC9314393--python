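"""Two-box (troposphere + stratosphere) model of N2O and its isotopes.

The troposphere receives all surface emissions (assumed immediately well
mixed) and exchanges air with the stratosphere through a bulk coefficient
T_to_S; photochemical destruction acts on the whole-atmosphere burden with
lifetime tau_PI and is located in the stratosphere, which enriches the
residual stratospheric N2O by apparent enrichment factors (positive values
enrich).  Gross two-way exchange (T_to_S*MR down, T_to_S*MR_strat up) returns
that enrichment to the troposphere; the net transfer equals
T_to_S*(MR_trop - MR_strat), the form used in the preindustrial closure:

    F_terr + F_ocean = T_to_S * (MR_PI - MR_PI,strat)
    MR_PI,strat = MR_PI * (T_to_S*tau - m_trop) / (T_to_S*tau + m_strat)

where m_trop/m_strat are the moles of air in each box (the molecular weight
of N2O-N cancels).  Integration is explicit with annual steps, matching the
time resolution of the emission series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AtmosConstants", "AtmosState", "ExchangeTerms",
           "preindustrial_balance", "strat_isotope_steady", "step_year",
           "run_forward"]


@dataclass(frozen=True)
class AtmosConstants:
    """Physical constants and prior settings of the atmospheric module."""

    moles_trop: float = 1.5e20       # mol air
    moles_strat: float = 0.27e20     # mol air
    mw_n2o_n: float = 28.0           # g N per mol N2O
    tau_pi: float = 120.0            # whole-atmosphere N2O lifetime, years
    mr_pi: float = 270.0             # preindustrial tropospheric MR, nmol/mol
    eps_app_d15n: float = 13.0       # apparent strat. enrichment, permil (+ enriches)
    eps_app_sp: float = 6.0

    def __post_init__(self):
        if min(self.moles_trop, self.moles_strat, self.mw_n2o_n,
               self.tau_pi, self.mr_pi) <= 0:
            raise ValueError("atmospheric constants must be positive")

    # --- central unit converters: Tg N2O-N <-> nmol mol-1 ----------------
    @property
    def tg_per_mr_trop(self) -> float:
        """Tg N2O-N in the troposphere per nmol/mol of mixing ratio."""
        return self.moles_trop * self.mw_n2o_n * 1e-9 / 1e12

    @property
    def tg_per_mr_strat(self) -> float:
        return self.moles_strat * self.mw_n2o_n * 1e-9 / 1e12

    def burden_trop(self, mr):
        return mr * self.tg_per_mr_trop

    def burden_strat(self, mr):
        return mr * self.tg_per_mr_strat


@dataclass
class AtmosState:
    year: int
    mr_trop: float                   # nmol mol-1
    mr_strat: float
    d15n_trop: float                 # permil
    d15n_strat: float
    sp_trop: float
    sp_strat: float

    def __post_init__(self):
        if self.mr_trop <= 0 or self.mr_strat <= 0:
            raise ValueError("mixing ratios must be positive")


@dataclass
class ExchangeTerms:
    f_terr: float                    # Tg N2O-N a-1
    f_ocean: float                   # Tg N2O-N a-1, diagnosed
    t_to_s: float                    # Tg N2O-N a-1 per nmol/mol, diagnosed
    mr_pi_strat: float               # nmol mol-1
    residual: float                  # Eq. balance residual, Tg N2O-N a-1
    converged: bool


def _mr_strat_steady(t_to_s: float, constants: AtmosConstants) -> float:
    """Stratospheric steady-state MR for a given exchange coefficient."""
    ct = constants.tg_per_mr_trop
    cs = constants.tg_per_mr_strat
    tt = t_to_s * constants.tau_pi
    return constants.mr_pi * (tt - ct) / (tt + cs)


def _balance_residual(f_total: float, t_to_s: float, constants: AtmosConstants) -> float:
    mr_s = _mr_strat_steady(t_to_s, constants)
    return f_total - t_to_s * (constants.mr_pi - mr_s)


def preindustrial_balance(f_terr: float, constants: AtmosConstants,
                          f_ocean_prior=(4.0, 1.0), t_to_s_prior=(0.25, 0.05),
                          max_iter: int = 20, tol: float = 1e-6) -> ExchangeTerms:
    """Close the preindustrial budget by adjusting F_ocean and T_to_S.

    Both terms are shifted stepwise from their prior means, weighted by the
    prior variances (the minimum-prior-distance direction), until the
    tropospheric balance holds to ``tol * f_terr``.
    """
    if f_terr <= 0:
        raise ValueError("F_terr must be positive")
    (mu_f, sig_f), (mu_t, sig_t) = f_ocean_prior, t_to_s_prior
    f_ocean, t_to_s = float(mu_f), float(mu_t)
    target = tol * f_terr
    converged = False
    res = _balance_residual(f_terr + f_ocean, t_to_s, constants)
    for _ in range(max_iter):
        if abs(res) <= target:
            converged = True
            break
        # Gauss-Newton step along the prior-weighted direction
        eps_t = 1e-7 * max(abs(t_to_s), 1.0)
        dr_df = 1.0
        dr_dt = (_balance_residual(f_terr + f_ocean, t_to_s + eps_t, constants)
                 - res) / eps_t
        denom = (dr_df * sig_f) ** 2 + (dr_dt * sig_t) ** 2
        step_f = -res * dr_df * sig_f ** 2 / denom
        step_t = -res * dr_dt * sig_t ** 2 / denom
        # stepwise within the prior: single-iteration moves capped at 1 sigma
        f_ocean += float(np.clip(step_f, -sig_f, sig_f))
        t_to_s += float(np.clip(step_t, -sig_t, sig_t))
        f_ocean = max(f_ocean, 0.0)
        # stay on the physical branch: strat MR must remain positive
        t_min = 1.02 * constants.tg_per_mr_trop / constants.tau_pi
        t_to_s = max(t_to_s, t_min)
        res = _balance_residual(f_terr + f_ocean, t_to_s, constants)
    converged = converged or abs(res) <= target
    return ExchangeTerms(f_terr=f_terr, f_ocean=f_ocean, t_to_s=t_to_s,
                         mr_pi_strat=_mr_strat_steady(t_to_s, constants),
                         residual=res, converged=converged)


def strat_isotope_steady(terms: ExchangeTerms, constants: AtmosConstants,
                         d15n_source: float, sp_source: float):
    """Preindustrial steady-state isotopes of both boxes.

    With gross exchange fluxes F_down = T_to_S*MR_trop and
    F_up = T_to_S*MR_strat and destruction D = F_down - F_up removing N2O at
    delta_strat - eps_app, the steady state is

        delta_trop  = delta_source + (F_up/F_down) * eps_app
        delta_strat = delta_trop + (D/F_down) * eps_app

    so a positive apparent enrichment leaves the stratosphere heavier than
    the troposphere.  Returns (d15n_trop, d15n_strat, sp_trop, sp_strat).
    """
    f_down = terms.t_to_s * constants.mr_pi
    f_up = terms.t_to_s * terms.mr_pi_strat
    frac_up = f_up / f_down
    frac_d = (f_down - f_up) / f_down
    d15n_t = d15n_source + frac_up * constants.eps_app_d15n
    d15n_s = d15n_t + frac_d * constants.eps_app_d15n
    sp_t = sp_source + frac_up * constants.eps_app_sp
    sp_s = sp_t + frac_d * constants.eps_app_sp
    return d15n_t, d15n_s, sp_t, sp_s


def steady_state(f_terr: float, d15n_source: float, sp_source: float,
                 constants: AtmosConstants, **balance_kwargs):
    """Solve the full preindustrial steady state (burdens + isotopes)."""
    terms = preindustrial_balance(f_terr, constants, **balance_kwargs)
    d15n_t, d15n_s, sp_t, sp_s = strat_isotope_steady(
        terms, constants, d15n_source, sp_source)
    state = AtmosState(year=0, mr_trop=constants.mr_pi, mr_strat=terms.mr_pi_strat,
                       d15n_trop=d15n_t, d15n_strat=d15n_s,
                       sp_trop=sp_t, sp_strat=sp_s)
    return terms, state


def step_year(state: AtmosState, emission: float, d15n_e: float, sp_e: float,
              terms: ExchangeTerms, constants: AtmosConstants) -> AtmosState:
    """Advance both boxes by one year (explicit step).

    ``emission`` is the total surface source in Tg N2O-N a-1 with
    flux-weighted isotopes (d15n_e, sp_e), mixed instantaneously into the
    troposphere.
    """
    c = constants
    b_t = c.burden_trop(state.mr_trop)
    b_s = c.burden_strat(state.mr_strat)
    f_down = terms.t_to_s * state.mr_trop
    f_up = terms.t_to_s * state.mr_strat
    dest = (b_t + b_s) / c.tau_pi
    b_t2 = b_t + emission - f_down + f_up
    b_s2 = b_s + f_down - f_up - dest
    if b_t2 <= 0 or b_s2 <= 0:
        raise ValueError("negative burden: emission/exchange terms inconsistent")

    def mix(delta_t, delta_s, delta_e, eps_app):
        num_t = b_t * delta_t + emission * delta_e + f_up * delta_s - f_down * delta_t
        num_s = b_s * delta_s + f_down * delta_t - f_up * delta_s \
            - dest * (delta_s - eps_app)
        return num_t / b_t2, num_s / b_s2

    d15n_t, d15n_s = mix(state.d15n_trop, state.d15n_strat, d15n_e, c.eps_app_d15n)
    sp_t, sp_s = mix(state.sp_trop, state.sp_strat, sp_e, c.eps_app_sp)
    return AtmosState(year=state.year + 1,
                      mr_trop=b_t2 / c.tg_per_mr_trop,
                      mr_strat=b_s2 / c.tg_per_mr_strat,
                      d15n_trop=d15n_t, d15n_strat=d15n_s,
                      sp_trop=sp_t, sp_strat=sp_s)


def run_forward(years, emissions, d15n_source, sp_source,
                terms: ExchangeTerms, constants: AtmosConstants,
                initial: AtmosState | None = None) -> pd.DataFrame:
    """Integrate the two-box model over an annual emission series.

    Starts from the solved preindustrial steady state (isotopes at the
    first-year source composition) unless ``initial`` is given.  Returns one
    row per year with both boxes' MR, d15N and SP; row ``year`` is the state
    after that year's emissions.
    """
    years = np.asarray(years, dtype=int)
    if len(years) == 0 or np.any(np.diff(years) != 1):
        raise ValueError("years must be contiguous")
    emissions = np.asarray(emissions, dtype=float)
    d15n_source = np.asarray(d15n_source, dtype=float)
    sp_source = np.asarray(sp_source, dtype=float)
    if not (len(emissions) == len(d15n_source) == len(sp_source) == len(years)):
        raise ValueError("emission series lengths must match years")
    if initial is None:
        d15n_t, d15n_s, sp_t, sp_s = strat_isotope_steady(
            terms, constants, d15n_source[0], sp_source[0])
        state = AtmosState(year=years[0] - 1, mr_trop=constants.mr_pi,
                           mr_strat=terms.mr_pi_strat,
                           d15n_trop=d15n_t, d15n_strat=d15n_s,
                           sp_trop=sp_t, sp_strat=sp_s)
    else:
        state = initial
    rows = []
    for y, e, de, spe in zip(years, emissions, d15n_source, sp_source):
        state = step_year(state, e, de, spe, terms, constants)
        state.year = int(y)
        rows.append((y, state.mr_trop, state.mr_strat, state.d15n_trop,
                     state.d15n_strat, state.sp_trop, state.sp_strat))
    return pd.DataFrame(rows, columns=["year", "mr_trop", "mr_strat",
                                       "d15n_trop", "d15n_strat",
                                       "sp_trop", "sp_strat"]).set_index("year")
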