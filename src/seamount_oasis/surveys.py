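"""Reduction of raw survey observations to modelled response variables.

Baited-video (BRUV) frame records become MaxN, maximum combined biomass and
species richness per set; vessel-based visual sightings are pooled into
5-minute effort bins with a distance-from-summit assigned at the interval
midpoint.  These are the response variables the distance-effect models
consume.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dispersal import haversine

__all__ = [
    "compute_maxn",
    "compute_max_biomass",
    "species_richness",
    "bin_visual_counts",
    "read_frames_csv",
    "write_radial_samples",
    "RADIAL_SAMPLE_COLUMNS",
]

RADIAL_SAMPLE_COLUMNS = [
    "seamount_id", "distance_km", "response", "family", "season",
    "transect_id", "diel_phase", "species",
]


def _pool_bins(frames: pd.DataFrame, align_bin_s: float) -> pd.Series:
    return (frames["time_bin"] // align_bin_s).astype(int)


def compute_maxn(frames: pd.DataFrame, species: str,
                 align_bin_s: float = 1.0,
                 cross_rig: bool = True) -> int:
    """MaxN: maximum count of ``species`` in any single pooled frame.

    Counts within each alignment bin are summed across rigs of the set
    (``cross_rig=True``, the default) or taken per rig, and the maximum over
    bins is returned.  Cameras are not frame-synchronized, so pooling uses
    1-second alignment bins by default.
    """
    if len(frames) == 0:
        warnings.warn("empty frame table; MaxN = 0")
        return 0
    if frames["set_id"].nunique() > 1:
        raise ValueError("frames must come from a single set")
    sub = frames[frames["species"] == species]
    if len(sub) == 0:
        return 0
    bins = _pool_bins(sub, align_bin_s)
    if cross_rig:
        per_bin = sub.groupby(bins)["count"].sum()
    else:
        per_bin = sub.groupby([bins, sub["rig_id"]])["count"].sum()
    return int(per_bin.max())


def _lengths_of(row) -> list[float]:
    fl = row.get("fork_lengths")
    if fl is None or (np.isscalar(fl) and pd.isna(fl)):
        return []
    if isinstance(fl, str):
        return [float(v) for v in fl.split(";") if v]
    return list(fl)


def compute_max_biomass(frames: pd.DataFrame, coeffs: pd.DataFrame,
                        align_bin_s: float = 1.0) -> float:
    """Maximum combined mass (kg) over pooled frames, via W = a * FL^b.

    Individuals lacking a stereo length use the species mean length over the
    set (flagged with a warning).  ``coeffs`` holds columns
    (species, a, b) of published weight-length relationships.
    """
    if len(frames) == 0:
        return 0.0
    coeffs = coeffs.set_index("species") if "species" in coeffs.columns else coeffs
    if (coeffs["a"] <= 0).any():
        raise ValueError("length-weight 'a' must be > 0")
    odd_b = coeffs[(coeffs["b"] < 2.5) | (coeffs["b"] > 3.5)]
    if len(odd_b):
        warnings.warn(
            f"allometric exponent outside [2.5, 3.5] for {list(odd_b.index)}"
        )
    missing = set(frames["species"]) - set(coeffs.index)
    if missing:
        raise KeyError(f"no length-weight coefficients for {sorted(missing)}")

    # species mean length per set, for unmeasured individuals
    mean_len: dict[str, float] = {}
    for sp, grp in frames.groupby("species"):
        all_l = [v for _, r in grp.iterrows() for v in _lengths_of(r)]
        if all_l:
            mean_len[sp] = float(np.mean(all_l))

    bins = _pool_bins(frames, align_bin_s)
    mass_per_bin: dict[int, float] = {}
    flagged = False
    for (b, _), row in zip(bins.items(), frames.itertuples(index=False)):
        row = row._asdict()
        sp = row["species"]
        a, bexp = float(coeffs.loc[sp, "a"]), float(coeffs.loc[sp, "b"])
        lengths = _lengths_of(row)
        n_unmeasured = int(row["count"]) - len(lengths)
        if n_unmeasured > 0:
            if sp not in mean_len:
                raise ValueError(
                    f"no measured lengths for {sp!r}: cannot impute"
                )
            lengths = lengths + [mean_len[sp]] * n_unmeasured
            flagged = True
        if any(l <= 0 for l in lengths):
            raise ValueError("fork lengths must be > 0")
        mass = sum(a * l**bexp for l in lengths)
        mass_per_bin[b] = mass_per_bin.get(b, 0.0) + mass
    if flagged:
        warnings.warn("unmeasured individuals assigned species mean length")
    return float(max(mass_per_bin.values(), default=0.0))


def species_richness(frames: pd.DataFrame,
                     trophic_levels: dict | None = None,
                     min_trophic: float | None = None) -> int:
    """Number of distinct species with >= 1 individual observed.

    With ``min_trophic`` set, only species whose mapped trophic level is
    strictly above the threshold qualify (e.g. sharks and teleosts at
    trophic level > 4); unmapped species are excluded with a warning.
    """
    if len(frames) == 0:
        return 0
    seen = frames.loc[frames["count"] > 0, "species"].unique()
    if min_trophic is None:
        return int(len(seen))
    if trophic_levels is None:
        raise ValueError("min_trophic requires a species trophic-level map")
    unknown = [s for s in seen if s not in trophic_levels]
    if unknown:
        warnings.warn(f"species without trophic level excluded: {unknown}")
    return int(sum(1 for s in seen
                   if trophic_levels.get(s, -np.inf) > min_trophic))


def bin_visual_counts(sightings: pd.DataFrame, summit: tuple,
                      window_s: float = 300.0,
                      seamount_id: str = "SM1") -> pd.DataFrame:
    """Pool time-stamped transect sightings into fixed observation intervals.

    One record per species per interval (explicit zeros for species observed
    elsewhere on the transect), with ``distance_km`` measured from the
    interval's midpoint position to the summit coordinate and partial
    trailing intervals kept with their own duration.

    ``sightings`` columns: transect_id, t_s (seconds from transect start),
    species, count, lon, lat.
    """
    out = []
    for tid, grp in sightings.groupby("transect_id"):
        if (grp["t_s"].diff().dropna() < 0).any():
            raise ValueError(f"non-monotone timestamps in transect {tid!r}")
        t_end = float(grp["t_s"].max())
        n_int = int(np.floor(t_end / window_s)) + 1
        species = sorted(grp["species"].unique())
        for i in range(n_int):
            lo, hi = i * window_s, (i + 1) * window_s
            dur = min(hi, t_end) - lo if hi > t_end else window_s
            inwin = grp[(grp["t_s"] >= lo) & (grp["t_s"] < hi)]
            # interval midpoint position: interpolate along the logged fixes
            tm = lo + min(dur, window_s) / 2.0
            lon = float(np.interp(tm, grp["t_s"], grp["lon"]))
            lat = float(np.interp(tm, grp["t_s"], grp["lat"]))
            dist = haversine((lon, lat), summit)
            for sp in species:
                cnt = int(inwin.loc[inwin["species"] == sp, "count"].sum())
                out.append((seamount_id, dist, cnt, "negative-binomial",
                            "expedition", tid, "day", sp, i, max(dur, 0.0)))
    return pd.DataFrame(out, columns=RADIAL_SAMPLE_COLUMNS
                        + ["interval", "duration_s"])


def read_frames_csv(path) -> pd.DataFrame:
    """Read a BRUV frame-observation table (fork_lengths ';'-separated)."""
    df = pd.read_csv(path)
    return df


def write_radial_samples(df: pd.DataFrame, path) -> None:
    """Write a radial-sample table with the documented column order."""
    cols = [c for c in RADIAL_SAMPLE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)
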