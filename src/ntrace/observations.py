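"""Calibration targets: binned atmospheric series and climate-zone EFs.

Atmospheric records from several instruments/archives are put on a common
scale by chaining mean offsets over overlap periods toward an anchor dataset,
then averaged into time blocks (coarse 25-year blocks for the sparse early
record, 2-year blocks for the instrumental era).  Emission-factor records are
aggregated into 16 climate zones defined by a 4x4 quantile grid of mean
annual temperature and precipitation.  Model error floors (0.5 nmol/mol for
mixing ratio, 0.1 permil for isotopes, 0.5 percentage points for EF) are
added in quadrature to the per-bin spread in the calibration likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import GridField

__all__ = ["ObservationSet", "correct_offsets", "bin_series", "zone_efs",
           "make_zone_map", "DEFAULT_BIN_EDGES", "MODEL_ERROR_FLOORS"]

MODEL_ERROR_FLOORS = {"mr": 0.5, "d15n": 0.1, "sp": 0.1, "ef": 0.5}

#: left-closed, right-open block edges: 25-year blocks to 1940, 2-year after
DEFAULT_BIN_EDGES = tuple(range(1800, 1941, 25)) + tuple(range(1940, 2021, 2))


def default_bin_edges(year_start=1800, year_end=2020, switch=1940,
                      coarse=25, fine=2):
    edges = list(range(year_start, switch + 1, coarse))
    if edges[-1] != switch:
        edges.append(switch)
    edges += list(range(switch + fine, year_end + 1, fine))
    return np.asarray(edges)


@dataclass
class ObservationSet:
    """Binned atmospheric series plus climate-zone EFs with uncertainties.

    ``series`` has columns (group, bin_left, bin_right, mean, sd, n) with
    group in {mr, d15n, sp}; ``zone_ef`` has (zone, mean, sd, n).
    """

    series: pd.DataFrame
    zone_ef: pd.DataFrame
    floors: dict = field(default_factory=lambda: dict(MODEL_ERROR_FLOORS))

    def __post_init__(self):
        if np.any(self.series["sd"].fillna(0) < 0) or np.any(self.zone_ef["sd"].fillna(0) < 0):
            raise ValueError("bin standard deviations must be >= 0")

    def group(self, name: str) -> pd.DataFrame:
        return self.series[self.series["group"] == name]

    def total_sigma(self) -> dict:
        """Per-group total sigma arrays: sqrt(sd^2 + floor^2)."""
        out = {}
        for g in ("mr", "d15n", "sp"):
            sd = self.group(g)["sd"].fillna(0.0).to_numpy()
            out[g] = np.sqrt(sd ** 2 + self.floors[g] ** 2)
        sd = self.zone_ef["sd"].fillna(0.0).to_numpy()
        out["ef"] = np.sqrt(sd ** 2 + self.floors["ef"] ** 2)
        return out

    def perturbed(self, rng, sigma_mr=0.0, sigma_delta=0.0, sigma_ef=0.0,
                  sigma_sp=None) -> "ObservationSet":
        """Independent Gaussian noise per point (pseudo-observation maker).

        Each sigma may be a scalar or a per-point array (e.g. larger scatter
        for the sparse early blocks).  The applied noise level also becomes
        the per-bin ``sd`` so the likelihood sees a consistent uncertainty.
        """
        series = self.series.copy()
        sig = {"mr": sigma_mr, "d15n": sigma_delta,
               "sp": sigma_delta if sigma_sp is None else sigma_sp}
        for g, s in sig.items():
            m = series["group"] == g
            s = np.broadcast_to(np.asarray(s, dtype=float), (int(m.sum()),))
            series.loc[m, "mean"] = (series.loc[m, "mean"]
                                     + s * rng.standard_normal(int(m.sum())))
            series.loc[m, "sd"] = s
        zone = self.zone_ef.copy()
        zone["mean"] = zone["mean"] + sigma_ef * rng.standard_normal(len(zone))
        zone["sd"] = sigma_ef
        return ObservationSet(series, zone, dict(self.floors))

    def shifted(self, group_draws: dict, stepsize: float = 1.0) -> "ObservationSet":
        """Shift each observation by sd * stepsize * r, one draw per group."""
        series = self.series.copy()
        sd = series["sd"].fillna(0.0).to_numpy()
        groups = series["group"].to_numpy()
        shift = np.zeros(len(series))
        for g in ("mr", "d15n", "sp"):
            m = groups == g
            shift[m] = sd[m] * stepsize * group_draws.get(g, 0.0)
        series["mean"] = series["mean"].to_numpy() + shift
        zone = self.zone_ef.copy()
        zone["mean"] = (zone["mean"].to_numpy()
                        + zone["sd"].fillna(0.0).to_numpy() * stepsize
                        * group_draws.get("ef", 0.0))
        return ObservationSet(series, zone, dict(self.floors))

    def values_vector(self) -> dict:
        return {
            "mr": self.group("mr")["mean"].to_numpy(),
            "d15n": self.group("d15n")["mean"].to_numpy(),
            "sp": self.group("sp")["mean"].to_numpy(),
            "ef": self.zone_ef["mean"].to_numpy(),
        }


def correct_offsets(series_list: list[pd.DataFrame], anchor_id: str) -> pd.DataFrame:
    """Put datasets on the anchor's scale by chaining mean overlap offsets.

    Each element needs columns (dataset, time, value).  A dataset overlapping
    the anchor (or any already-corrected dataset) in time is shifted by the
    mean difference of the two datasets over the overlap window; corrections
    chain toward the anchor.  Raises if some dataset never overlaps the
    corrected set.
    """
    frames = {str(df["dataset"].iloc[0]): df.sort_values("time").reset_index(drop=True)
              for df in series_list}
    if anchor_id not in frames:
        raise ValueError(f"anchor dataset {anchor_id!r} not present")
    corrected = {anchor_id: frames[anchor_id].copy()}
    pending = {k: v for k, v in frames.items() if k != anchor_id}
    while pending:
        progress = False
        for name in list(pending):
            df = pending[name]
            for ref in corrected.values():
                lo = max(df["time"].min(), ref["time"].min())
                hi = min(df["time"].max(), ref["time"].max())
                if lo > hi:
                    continue
                own = df[(df["time"] >= lo) & (df["time"] <= hi)]["value"]
                other = ref[(ref["time"] >= lo) & (ref["time"] <= hi)]["value"]
                if len(own) == 0 or len(other) == 0:
                    continue
                offset = own.mean() - other.mean()
                out = df.copy()
                out["value"] = out["value"] - offset
                corrected[name] = out
                del pending[name]
                progress = True
                break
            if progress:
                break
        if not progress:
            raise ValueError(
                f"datasets {sorted(pending)} have no overlap with the anchor chain")
    return pd.concat(corrected.values(), ignore_index=True)


def bin_series(df: pd.DataFrame, edges, value_col: str = "value",
               time_col: str = "time") -> pd.DataFrame:
    """Per-block mean/SD/count over left-closed, right-open time blocks.

    Empty blocks are dropped; single-member blocks get NaN SD (flagged by
    ``n == 1``).
    """
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be increasing")
    t = df[time_col].to_numpy(dtype=float)
    v = df[value_col].to_numpy(dtype=float)
    idx = np.searchsorted(edges, t, side="right") - 1
    ok = (idx >= 0) & (idx < len(edges) - 1) & (t < edges[-1])
    rows = []
    for b in np.unique(idx[ok]):
        vals = v[ok][idx[ok] == b]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        rows.append((edges[b], edges[b + 1], float(np.mean(vals)), sd, len(vals)))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "mean", "sd", "n"])


def make_zone_map(mat_field: GridField, map_field: GridField,
                  n_bins: int = 4) -> GridField:
    """16 climate zones from a quantile grid of MAT x MAP over valid cells."""
    mask = mat_field.mask & map_field.mask
    mat = mat_field.values[mask]
    mapv = map_field.values[mask]
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    mat_edges = np.quantile(mat, qs)
    map_edges = np.quantile(mapv, qs)
    zi = np.searchsorted(mat_edges, mat_field.values, side="right")
    zj = np.searchsorted(map_edges, map_field.values, side="right")
    zones = zi * n_bins + zj
    vals = np.where(mask, zones, -1).astype(float)
    return GridField(mat_field.grid, vals, "zone", mask=mask)


def zone_efs(records: pd.DataFrame, zone_map: GridField) -> pd.DataFrame:
    """Aggregate EF records (lat, lon, ef in %) into climate-zone statistics.

    Records falling outside the grid or on masked cells are excluded (their
    count is reported via the ``n_excluded`` attribute of the result).
    """
    grid = zone_map.grid
    i, j, inside = grid.cell_index(records["lat"].to_numpy(),
                                   records["lon"].to_numpy())
    valid = inside.copy()
    valid[inside] &= zone_map.mask[i[inside], j[inside]]
    zones = np.full(len(records), -1)
    zones[valid] = zone_map.values[i[valid], j[valid]].astype(int)
    df = pd.DataFrame({"zone": zones[valid],
                       "ef": records["ef"].to_numpy()[valid]})
    g = df.groupby("zone")["ef"]
    out = pd.DataFrame({"zone": g.mean().index.astype(int),
                        "mean": g.mean().to_numpy(),
                        "sd": g.std(ddof=1).to_numpy(),
                        "n": g.count().to_numpy()})
    out.attrs["n_excluded"] = int((~valid).sum())
    return out.reset_index(drop=True)


def zone_mean_field(values: np.ndarray, zone_map: GridField,
                    n_zones: int = 16) -> pd.DataFrame:
    """Zone means of a per-cell model field (the model-side EF aggregate)."""
    mask = zone_map.mask & np.isfinite(values)
    z = zone_map.values[mask].astype(int)
    v = values[mask]
    rows = []
    for zone in range(n_zones):
        sel = z == zone
        if sel.any():
            rows.append((zone, float(v[sel].mean()),
                         float(v[sel].std(ddof=1)) if sel.sum() > 1 else np.nan,
                         int(sel.sum())))
    return pd.DataFrame(rows, columns=["zone", "mean", "sd", "n"])
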