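"""Emission-factor statistics, attribution and counterfactual experiments.

The emission factor (EF) of a cell is the annual N2O-N emission divided by
the annual total N input, in percent; denominators use inputs before the
fertiliser harvest reduction, so harvest removal depresses fertiliser EFs the
way field measurements at agricultural sites are depressed.  Anthropogenic
fluxes are defined as everything above the 1850 baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ef_field", "weighted_mean_ef", "ef_bins", "anthropogenic_split",
           "growth_rate", "counterfactual_redistribution",
           "counterfactual_no_warming"]


def ef_field(n2o_flux: np.ndarray, n_input: np.ndarray) -> np.ndarray:
    """Per-cell EF (%) = N2O-N emitted / N input * 100; NaN where input = 0."""
    flux = np.asarray(n2o_flux, dtype=float)
    inp = np.asarray(n_input, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = np.where(inp > 0, flux / inp * 100.0, np.nan)
    return ef


def weighted_mean_ef(ef, weights, mask=None) -> float:
    """Weighted mean EF over valid cells (area or N-input weights)."""
    ef = np.asarray(ef, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    valid = np.isfinite(ef) & (w >= 0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if not valid.any() or w[valid].sum() == 0:
        raise ValueError("no valid cells with positive total weight")
    return float(np.sum(w[valid] * ef[valid]) / np.sum(w[valid]))


def ef_bins(values, weights, n_bins: int = 20):
    """Weighted shares across EF bins.

    The first ``n_bins - 1`` bins are spaced evenly between the minimum and
    mean + 3 SD of the values; the last bin collects everything above
    mean + 3 SD.  Returns (edges, shares) where ``edges`` has n_bins entries
    (the last bin is open-ended) and the shares sum to 1.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = np.isfinite(v) & np.isfinite(w)
    v, w = v[ok], w[ok]
    if len(np.unique(v)) < 2:
        edges = np.array([v.min()]) if len(v) else np.array([np.nan])
        return edges, np.array([1.0])
    top = v.mean() + 3.0 * v.std(ddof=0)
    edges = np.linspace(v.min(), top, n_bins)  # n_bins-1 even bins + open top
    idx = np.clip(np.searchsorted(edges[1:], v, side="right"), 0, n_bins - 1)
    shares = np.bincount(idx, weights=w, minlength=n_bins)
    total = shares.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    return edges, shares / total


def anthropogenic_split(totals: pd.DataFrame, baseline_year: int = 1850) -> pd.DataFrame:
    """Per-category anthropogenic flux = total(year) - total(baseline_year)."""
    if baseline_year not in totals.index:
        raise ValueError(f"baseline year {baseline_year} not in series")
    return totals - totals.loc[baseline_year]


def growth_rate(series: pd.Series, window: int = 10) -> pd.Series:
    """Centred mean of first differences over ``window`` years.

    The 10-year rate for year 2000 is the mean annual change over 1995-2005.
    Edges where the window is incomplete are NaN.
    """
    if window > len(series) - 1:
        raise ValueError("window longer than the series of differences")
    # centred mean of the first differences d[y-k1] .. d[y+k2]
    # = (v[y+k2] - v[y-k1-1]) / window; for window 10 this spans y-5 .. y+5
    k1 = (window - 1) // 2
    k2 = window - 1 - k1
    out = (series.shift(-k2) - series.shift(k1 + 1)) / window
    return out.rename("growth_rate")


def counterfactual_redistribution(fert_inputs, flux_fn, ref_year: int = 1940,
                                  target_year: int = 2020):
    """Emission change due to the shifting spatial pattern of fertiliser N.

    Baseline = the ref-year spatial pattern rescaled so its global total
    equals the target year's total; returns (delta_field, global_delta) with
    delta = actual target-year flux - baseline flux.  ``flux_fn(field)``
    must map a per-cell fertiliser input field to the per-cell N2O flux.
    """
    ref = np.asarray(fert_inputs.field(ref_year).values, dtype=float)
    tgt = np.asarray(fert_inputs.field(target_year).values, dtype=float)
    mask = fert_inputs.field(ref_year).mask
    ref = np.where(mask, ref, 0.0)
    tgt = np.where(mask, tgt, 0.0)
    ref_total = ref.sum()
    if ref_total <= 0:
        raise ValueError(f"zero fertiliser total in reference year {ref_year}")
    baseline = ref * (tgt.sum() / ref_total)
    delta = flux_fn(tgt) - flux_fn(baseline)
    return delta, float(np.nansum(delta))


def counterfactual_no_warming(flux_with_dt, ref_year: int = 1940,
                              target_year: int = 2020):
    """Emission change from warming-driven EF increases since ``ref_year``.

    ``flux_with_dt(year, dt)`` returns the per-cell flux for a year computed
    at temperature anomaly ``dt`` (pass None for the actual anomaly).
    Delta = actual flux - flux with the anomaly frozen at the ref year.
    """
    actual = flux_with_dt(target_year, None)
    frozen = flux_with_dt(target_year, ref_year)
    delta = actual - frozen
    return delta, float(np.nansum(delta))
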