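"""Water-column metrics, chlorophyll enrichment indexing and tidal spectra.

Covers extraction of the deep chlorophyll maximum (DCM) and mixed-layer
depth (MLD) from CTD casts, the Chlorophyll Enrichment Index (CEI) — the
percent deviation of each 4-km ocean-colour cell from the mean of a 30-90 km
reference annulus — 1-km radial binning of raster fields, and detection of
tidal periodicity in moored temperature series by loess detrending and
smoothed-periodogram estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dispersal import haversine_vec

__all__ = [
    "DCMResult",
    "extract_dcm",
    "extract_mld",
    "compute_cei",
    "radial_bin_means",
    "tidal_spectrum",
]


@dataclass
class DCMResult:
    depth_m: float
    concentration: float
    surface_type: bool = False
    tie: bool = False


def extract_dcm(profile: pd.DataFrame, surface_cap_m: float = 5.0) -> DCMResult:
    """Depth and value of the deep chlorophyll maximum below a surface cap.

    Monotone-decreasing profiles peak at the cap and are flagged
    ``surface_type``; exact ties report the shallower depth with ``tie`` set.
    """
    if "chl" not in profile.columns or profile["chl"].isna().all():
        raise ValueError("profile has no chlorophyll channel")
    depth = profile["depth_m"].to_numpy(float)
    if np.any(np.diff(depth) <= 0):
        raise ValueError("depth must be strictly increasing")
    sub = profile[depth >= surface_cap_m]
    chl = sub["chl"].to_numpy(float)
    d = sub["depth_m"].to_numpy(float)
    imax = int(np.argmax(chl))           # argmax returns the shallowest of ties
    tie = bool(np.sum(chl == chl[imax]) > 1)
    surface = imax == 0
    return DCMResult(depth_m=float(d[imax]), concentration=float(chl[imax]),
                     surface_type=surface, tie=tie)


def extract_mld(profile: pd.DataFrame, delta_t: float = 0.2,
                ref_depth_m: float = 10.0) -> float:
    """Isothermal-layer depth: shallowest depth where temperature falls more
    than ``delta_t`` C below the 10-m reference; the maximum profile depth
    (with a warning) if the column is isothermal to the bottom."""
    depth = profile["depth_m"].to_numpy(float)
    temp = profile["temperature_c"].to_numpy(float)
    if depth.max() < ref_depth_m:
        raise ValueError("profile shallower than the reference depth")
    t_ref = float(np.interp(ref_depth_m, depth, temp))
    below = (depth >= ref_depth_m) & (temp < t_ref - delta_t)
    if not below.any():
        warnings.warn("isothermal to maximum depth; MLD censored")
        return float(depth.max())
    return float(depth[np.flatnonzero(below)[0]])


def compute_cei(scene: pd.DataFrame, annulus_km: tuple = (30.0, 90.0),
                cloud_max: float = 0.5) -> pd.DataFrame:
    """Chlorophyll Enrichment Index per cell of one daily scene.

    CEI(cell) = 100 * (chl - ref_mean) / ref_mean, with ``ref_mean`` the
    mean over unmasked cells 30-90 km from that cell.  Scenes with cloud
    fraction above ``cloud_max`` are rejected (raises ``ValueError``);
    cells with an entirely masked annulus come back as NaN.
    """
    cloud = scene["cloud"].to_numpy(bool)
    frac = float(cloud.mean())
    if frac > cloud_max:
        raise ValueError(
            f"scene rejected: cloud fraction {frac:.2f} > {cloud_max:.2f}"
        )
    lon = scene["lon"].to_numpy(float)
    lat = scene["lat"].to_numpy(float)
    chl = scene["chl"].to_numpy(float)
    clear = ~cloud
    lo, hi = annulus_km
    cei = np.full(lon.size, np.nan)
    # pairwise great-circle distances, chunked to bound memory
    chunk = 2000
    for s in range(0, lon.size, chunk):
        sl = slice(s, min(s + chunk, lon.size))
        D = haversine_vec(lon[sl, None], lat[sl, None],
                          lon[None, clear.nonzero()[0]],
                          lat[None, clear.nonzero()[0]])
        ann = (D >= lo) & (D <= hi)
        counts = ann.sum(axis=1)
        sums = (ann * chl[clear][None, :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ref = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            cei[sl] = 100.0 * (chl[sl] - ref) / ref
    out = scene.copy()
    out["cei"] = np.where(clear, cei, np.nan)
    return out


def radial_bin_means(field: pd.DataFrame, summit: tuple, value_col: str = "chl",
                     bin_km: float = 1.0, max_km: float | None = None
                     ) -> pd.DataFrame:
    """Mean of a cell field in 1-km distance increments from the summit.

    Bins are half-open ``[i, i+1)`` km; empty bins are omitted.  The result
    feeds the Gaussian-family distance-effect model directly.
    """
    lon = field["lon"].to_numpy(float)
    lat = field["lat"].to_numpy(float)
    d = haversine_vec(lon, lat, summit[0], summit[1])
    v = field[value_col].to_numpy(float)
    ok = np.isfinite(v)
    if max_km is not None:
        ok &= d <= max_km
    # half-open [i, i+1) bins; epsilon guards boundary cells against FP error
    idx = np.floor(d[ok] / bin_km + 1e-9).astype(int)
    df = pd.DataFrame({"bin": idx, "v": v[ok]})
    g = df.groupby("bin")["v"].agg(["mean", "count"])
    out = pd.DataFrame({
        "distance_km": (g.index.to_numpy(float) + 0.5) * bin_km,
        "response": g["mean"].to_numpy(),
        "n_cells": g["count"].to_numpy(),
        "family": "gaussian",
    })
    return out.reset_index(drop=True)


def tidal_spectrum(series: pd.DataFrame, value_col: str = "temperature_c",
                   period_range_h: tuple = (2.0, 26.0),
                   loess_span_days: float = 30.0,
                   decimate_to_s: float | None = 600.0,
                   smooth_bins: int = 3) -> dict:
    """Dominant tidal periodicity of a moored series by detrend + periodogram.

    The series is optionally block-averaged (10-minute means by default),
    de-trended with a loess smoother whose span covers ~30 days, and a
    Hann-tapered periodogram lightly smoothed over ``smooth_bins`` Fourier
    bins is scanned for its maximum within ``period_range_h``.

    Returns ``{'peak_period_h', 'period_h', 'density'}``.
    """
    ts = pd.to_datetime(series["timestamp"])
    t_s = (ts - ts.iloc[0]).dt.total_seconds().to_numpy(float)
    y = series[value_col].to_numpy(float)
    dt = np.diff(t_s)
    if dt.size == 0:
        raise ValueError("series too short")
    step = float(np.median(dt))
    if np.any(np.abs(dt - step) > 0.01 * step):
        raise ValueError("sampling interval irregular beyond tolerance")
    duration_h = t_s[-1] / 3600.0
    if duration_h < 10 * period_range_h[1]:
        raise ValueError("series shorter than 10x the longest period of interest")

    if decimate_to_s is not None and decimate_to_s > step:
        m = int(round(decimate_to_s / step))
        nblk = y.size // m
        y = y[: nblk * m].reshape(nblk, m).mean(axis=1)
        t_s = t_s[: nblk * m : m]
        step = step * m

    frac = min((loess_span_days * 86400.0) / (t_s[-1] - t_s[0]), 1.0)
    trend = lowess(y, t_s, frac=frac, it=0, delta=0.01 * (t_s[-1] - t_s[0]),
                   return_sorted=False)
    resid = y - trend

    f, pxx = signal.periodogram(resid, fs=1.0 / step, window="hann",
                                detrend="linear")
    if smooth_bins > 1:
        kern = np.ones(smooth_bins) / smooth_bins
        pxx = np.convolve(pxx, kern, mode="same")
    with np.errstate(divide="ignore"):
        period_h = np.where(f > 0, 1.0 / (3600.0 * np.where(f > 0, f, 1.0)),
                            np.inf)
    mask = (period_h >= period_range_h[0]) & (period_h <= period_range_h[1])
    if not mask.any():
        raise ValueError("no Fourier frequencies inside the period range")
    i = np.flatnonzero(mask)[np.argmax(pxx[mask])]
    return {
        "peak_period_h": float(period_h[i]),
        "period_h": period_h[mask],
        "density": pxx[mask],
    }
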