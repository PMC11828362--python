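"""Acoustic-telemetry residency analytics.

Detection logs from fixed receiver arrays are summarised into: track starts
(first detection on two consecutive days), residency indices (RI, the
proportion of tracking days with at least one detection), attrition curves,
residency periods (>= 14 consecutive detection days), hourly diel profiles
with a cyclic spline fit, per-receiver use with bootstrap intervals,
k-medoids (PAM) clustering of RIs into residents vs transients,
inter-seamount movement counts, the average maximum detection radius (AMDR)
from range tests, and quasibinomial GLM comparisons of RI across species,
sex and size.

Day boundaries are taken in local time (configurable UTC offset) because
diel statistics are local-time phenomena.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .families import get_family
from .smoothing import CyclicSpline, PenalizedGLM, RandomIntercept, TPSpline

__all__ = [
    "track_start",
    "residency_index",
    "attrition_curve",
    "residency_periods",
    "diel_profile",
    "receiver_use",
    "cluster_ri",
    "inter_seamount_moves",
    "amdr",
    "compare_ri_glm",
]


def _local_days(events: pd.DataFrame, utc_offset_hours: float = 0.0) -> pd.Series:
    ts = pd.to_datetime(events["timestamp"])
    return (ts + pd.Timedelta(hours=utc_offset_hours)).dt.floor("D")


def track_start(events: pd.DataFrame, tag_id: str,
                utc_offset_hours: float = 0.0) -> pd.Timestamp | None:
    """First date with detections on that day and the next (track-start rule).

    Animals never satisfying the two-consecutive-day rule return ``None``
    and are excluded from residency analyses.
    """
    sub = events[events["tag_id"] == tag_id]
    if len(sub) == 0:
        return None
    days = np.sort(_local_days(sub, utc_offset_hours).unique())
    for i in range(len(days) - 1):
        if (days[i + 1] - days[i]) == np.timedelta64(1, "D"):
            return pd.Timestamp(days[i])
    return None


def residency_index(events: pd.DataFrame, tag_id: str,
                    window: tuple | None = None,
                    study_end=None, utc_offset_hours: float = 0.0) -> float:
    """RI = (# days with >= 1 detection) / (# days from track start to end)."""
    sub = events[events["tag_id"] == tag_id]
    days = _local_days(sub, utc_offset_hours)
    if window is None:
        start = track_start(events, tag_id, utc_offset_hours)
        if start is None:
            raise ValueError(f"{tag_id!r} has no track start")
        end = pd.Timestamp(study_end) if study_end is not None \
            else days.max()
    else:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    n_days = (end.normalize() - start.normalize()).days + 1
    if n_days <= 0:
        raise ValueError("empty tracking window")
    det = days[(days >= start.normalize()) & (days <= end.normalize())]
    return float(det.nunique() / n_days)


def attrition_curve(events: pd.DataFrame, study_days: int,
                    utc_offset_hours: float = 0.0,
                    rule: str = "on-or-after", smooth: bool = True,
                    k: int = 10) -> pd.DataFrame:
    """Daily proportion of tagged animals still present on the array.

    ``on-or-after`` (default): an animal counts as present on day d if it has
    any detection on or after d; ``that-day`` counts only same-day
    detections.  A quasibinomial penalized spline of day is attached as
    column ``smooth`` (independence working model).
    """
    tags = events["tag_id"].unique()
    if len(tags) < 2:
        warnings.warn("attrition curve from fewer than 2 animals")
    days = _local_days(events, utc_offset_hours)
    t0 = days.min()
    day_idx = (days - t0).dt.days
    grid = np.arange(study_days)
    present = np.zeros((len(tags), study_days), dtype=bool)
    for i, tg in enumerate(tags):
        d = np.unique(day_idx[events["tag_id"] == tg])
        d = d[d < study_days]
        if rule == "on-or-after":
            if d.size:
                present[i, : d.max() + 1] = True
        elif rule == "that-day":
            present[i, d] = True
        else:
            raise ValueError(f"unknown rule {rule!r}")
    prop = present.mean(axis=0)
    out = pd.DataFrame({"day": grid, "proportion": prop})
    if smooth and len(tags) >= 2 and study_days >= 20:
        sp = TPSpline.from_data(grid.astype(float), k=k)
        blocks = [("intercept", np.ones((study_days, 1)), None, 0),
                  ("s(global)", sp.design(grid.astype(float)), sp.S, sp.rank)]
        fam = get_family("quasibinomial")
        res = PenalizedGLM(prop, blocks, fam,
                           weights=np.full(study_days, float(len(tags)))).fit()
        out["smooth"] = res.fitted
    return out


def residency_periods(events: pd.DataFrame, tag_id: str,
                      min_days: int = 14,
                      utc_offset_hours: float = 0.0) -> list[tuple]:
    """Maximal runs of consecutive detection days of length >= ``min_days``."""
    sub = events[events["tag_id"] == tag_id]
    days = np.sort(_local_days(sub, utc_offset_hours).unique())
    if days.size == 0:
        return []
    periods = []
    run_start = days[0]
    prev = days[0]
    for d in days[1:]:
        if (d - prev) > np.timedelta64(1, "D"):
            if ((prev - run_start) / np.timedelta64(1, "D")) + 1 >= min_days:
                periods.append((pd.Timestamp(run_start), pd.Timestamp(prev)))
            run_start = d
        prev = d
    if ((prev - run_start) / np.timedelta64(1, "D")) + 1 >= min_days:
        periods.append((pd.Timestamp(run_start), pd.Timestamp(prev)))
    return periods


def diel_profile(events: pd.DataFrame, periods: dict,
                 utc_offset_hours: float = 0.0, k: int = 8,
                 fit: bool = True):
    """Hourly residency indices during residency periods, with a cyclic fit.

    ``periods`` maps tag_id -> list of (start, end) residency periods.  For
    each animal, the hourly RI is the proportion of hourly bins (over period
    days) holding >= 1 detection.  The population trend is fitted with a
    quasibinomial model: cyclic cubic spline of hour (value and slope
    continuous across midnight) plus animal random intercepts.

    Returns ``(hourly, fitted)``: a long table (tag_id, hour, ri, n_bins)
    and a 24-point population curve (None when ``fit=False``).
    """
    rows = []
    for tg, pers in periods.items():
        if not pers:
            continue
        sub = events[events["tag_id"] == tg]
        ts = pd.to_datetime(sub["timestamp"]) + pd.Timedelta(
            hours=utc_offset_hours)
        n_days = 0
        hit = np.zeros(24, dtype=int)
        bins = np.zeros(24, dtype=int)
        for start, end in pers:
            ndays = (end - start).days + 1
            n_days += ndays
            bins += ndays
            mask = (ts >= start) & (ts < end + pd.Timedelta(days=1))
            if mask.any():
                hh = ts[mask].dt.hour
                dd = ts[mask].dt.floor("D")
                seen = pd.DataFrame({"h": hh, "d": dd}).drop_duplicates()
                for h, c in seen["h"].value_counts().items():
                    hit[h] += c
        if n_days == 0:
            continue
        for h in range(24):
            rows.append((tg, h, hit[h] / bins[h] if bins[h] else np.nan,
                         bins[h]))
    hourly = pd.DataFrame(rows, columns=["tag_id", "hour", "ri", "n_bins"])
    if len(hourly) == 0:
        raise ValueError("no residency-period days to profile")
    if not fit:
        return hourly, None
    sp = CyclicSpline.from_period(24.0, k=k)
    hrs = hourly["hour"].to_numpy(float)
    blocks = [("intercept", np.ones((len(hourly), 1)), None, 0),
              ("s(hour)", sp.design(hrs), sp.S, sp.rank)]
    if hourly["tag_id"].nunique() > 1:
        ri = RandomIntercept.from_data(hourly["tag_id"].to_numpy())
        blocks.append(("animal_re", ri.design(hourly["tag_id"].to_numpy()),
                       ri.S, ri.rank))
    fam = get_family("quasibinomial")
    res = PenalizedGLM(hourly["ri"].to_numpy(float), blocks, fam,
                       weights=hourly["n_bins"].to_numpy(float)).fit()
    grid = np.arange(24, dtype=float)
    Xg = np.zeros((24, res.beta.size))
    Xg[:, res.col_slices["intercept"]] = 1.0
    Xg[:, res.col_slices["s(hour)"]] = sp.design(grid)
    fitted = pd.DataFrame({
        "hour": grid,
        "ri": fam.linkinv(Xg @ res.beta),
    })
    fitted.attrs["model"] = res
    fitted.attrs["spline"] = sp
    return hourly, fitted


def receiver_use(events: pd.DataFrame, periods: dict,
                 diel_phase: str | None = None,
                 utc_offset_hours: float = 0.0,
                 day_hours: tuple = (6, 18),
                 n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Mean per-receiver share of detections with a bootstrap 95% CI.

    Per animal, detections inside its residency periods (optionally split by
    diel phase) are normalized to proportions across receivers; the species
    mean and a percentile CI from resampling animals with replacement are
    reported.  Animals without detections in the phase are excluded from it.
    """
    receivers = np.sort(events["receiver_id"].unique())
    per_animal = []
    for tg, pers in periods.items():
        if not pers:
            continue
        sub = events[events["tag_id"] == tg]
        ts = pd.to_datetime(sub["timestamp"]) + pd.Timedelta(
            hours=utc_offset_hours)
        mask = np.zeros(len(sub), dtype=bool)
        for start, end in pers:
            mask |= ((ts >= start) & (ts < end + pd.Timedelta(days=1))).to_numpy()
        if diel_phase is not None:
            hrs = ts.dt.hour.to_numpy()
            is_day = (hrs >= day_hours[0]) & (hrs < day_hours[1])
            mask &= is_day if diel_phase == "day" else ~is_day
        picked = sub[mask]
        if len(picked) == 0:
            continue
        counts = picked["receiver_id"].value_counts().reindex(
            receivers, fill_value=0)
        per_animal.append(counts / counts.sum())
    if not per_animal:
        raise ValueError("no detections to summarize")
    P = np.vstack([p.to_numpy(float) for p in per_animal])
    mean = P.mean(axis=0)
    rng = np.random.default_rng(seed)
    if P.shape[0] >= 2:
        idx = rng.integers(0, P.shape[0], size=(n_boot, P.shape[0]))
        boots = P[idx].mean(axis=1)
        lo = np.percentile(boots, 2.5, axis=0)
        hi = np.percentile(boots, 97.5, axis=0)
    else:
        lo = hi = mean
    return pd.DataFrame({"receiver_id": receivers, "mean_proportion": mean,
                         "lo95": lo, "hi95": hi,
                         "n_animals": P.shape[0]})


# ---------------------------------------------------------------------------
# PAM clustering of residency indices


def _pam_cost(x: np.ndarray, medoids: tuple) -> float:
    d = np.abs(x[:, None] - x[list(medoids)][None, :])
    return float(d.min(axis=1).sum())


def cluster_ri(ris, k: int = 2, exhaustive_limit: int = 5000):
    """Partitioning around medoids on 1-D residency indices.

    Solves the k-medoid objective (sum of absolute deviations from the
    nearest medoid) exactly by enumeration when the number of medoid
    combinations is small, otherwise by BUILD + SWAP to convergence.  Labels
    are ordered so cluster 0 has the lowest medoid; ties break on the
    lowest index, deterministically.

    Returns ``(labels, medoid_values)``.
    """
    x = np.asarray(ris, dtype=float)
    n = x.size
    if k > n:
        raise ValueError("k exceeds the number of observations")
    from math import comb

    if comb(n, k) <= exhaustive_limit:
        best, best_cost = None, np.inf
        for combo in itertools.combinations(range(n), k):
            c = _pam_cost(x, combo)
            if c < best_cost - 1e-12:
                best, best_cost = combo, c
        medoids = list(best)
    else:
        # BUILD: greedy cost-minimizing additions
        medoids = []
        for _ in range(k):
            best_j, best_cost = None, np.inf
            for j in range(n):
                if j in medoids:
                    continue
                c = _pam_cost(x, tuple(medoids + [j]))
                if c < best_cost - 1e-12:
                    best_j, best_cost = j, c
            medoids.append(best_j)
        # SWAP to convergence
        improved = True
        while improved:
            improved = False
            cur = _pam_cost(x, tuple(medoids))
            for mi in range(k):
                for j in range(n):
                    if j in medoids:
                        continue
                    cand = medoids.copy()
                    cand[mi] = j
                    c = _pam_cost(x, tuple(cand))
                    if c < cur - 1e-12:
                        medoids, cur, improved = cand, c, True
    medoids = sorted(medoids, key=lambda i: (x[i], i))
    mvals = x[medoids]
    d = np.abs(x[:, None] - mvals[None, :])
    labels = d.argmin(axis=1)
    return labels, mvals


def inter_seamount_moves(events: pd.DataFrame,
                         receiver_map: dict | None = None) -> pd.DataFrame:
    """Per-animal count of moves between seamounts.

    A move is a pair of consecutive detections on different seamounts; a
    switcher is an animal with >= 1 move.  ``receiver_map`` supplies
    receiver -> seamount when the events table lacks a seamount column.
    """
    ev = events.sort_values("timestamp", kind="stable")
    if "seamount_id" not in ev.columns:
        if receiver_map is None:
            raise ValueError("need seamount_id column or a receiver map")
        unmapped = set(ev["receiver_id"]) - set(receiver_map)
        if unmapped:
            raise KeyError(f"receivers without a seamount: {sorted(unmapped)}")
        ev = ev.assign(seamount_id=ev["receiver_id"].map(receiver_map))
    rows = []
    for tg, grp in ev.groupby("tag_id"):
        sm = grp["seamount_id"].to_numpy()
        moves = int(np.sum(sm[1:] != sm[:-1]))
        rows.append((tg, moves, moves > 0))
    out = pd.DataFrame(rows, columns=["tag_id", "n_moves", "switcher"])
    out.attrs["percent_switchers"] = float(
        100.0 * out["switcher"].mean()) if len(out) else np.nan
    return out


# ---------------------------------------------------------------------------
# detection range


def amdr(series: pd.DataFrame, threshold: float = 0.05, k: int = 10,
         site_col: str | None = "site") -> dict:
    """Average maximum detection radius from range-test series.

    Fits a binomial penalized spline of detection probability
    (received / expected per 180-s bin) against distance per site, averages
    the predicted curves and reports the smallest distance at which the mean
    predicted probability first drops below ``threshold``.  If it never
    does, the result is censored at the maximum tested distance.
    """
    if site_col and site_col in series.columns:
        sites = [g for _, g in series.groupby(site_col)]
    else:
        sites = [series]
    dmax = float(series["distance_m"].max())
    grid = np.linspace(0.0, dmax, 400)
    preds = []
    fam = get_family("binomial")
    for s in sites:
        d = s["distance_m"].to_numpy(float)
        p = s["received"].to_numpy(float) / s["expected"].to_numpy(float)
        if np.any(p > 1):
            raise ValueError("received exceeds expected")
        sp = TPSpline.from_data(d, k=k)
        blocks = [("intercept", np.ones((len(s), 1)), None, 0),
                  ("s(dist)", sp.design(d), sp.S, sp.rank)]
        res = PenalizedGLM(p, blocks, fam,
                           weights=s["expected"].to_numpy(float)).fit()
        Xg = np.zeros((grid.size, res.beta.size))
        Xg[:, res.col_slices["intercept"]] = 1.0
        Xg[:, res.col_slices["s(dist)"]] = sp.design(np.clip(grid, d.min(),
                                                             d.max()))
        preds.append(fam.linkinv(Xg @ res.beta))
    mean_pred = np.mean(preds, axis=0)
    below = mean_pred < threshold
    if not below.any():
        return {"amdr_m": dmax, "censored": True, "grid_m": grid,
                "mean_probability": mean_pred}
    return {"amdr_m": float(grid[np.flatnonzero(below)[0]]),
            "censored": False, "grid_m": grid, "mean_probability": mean_pred}


# ---------------------------------------------------------------------------
# RI comparisons


def compare_ri_glm(records: pd.DataFrame,
                   covariates: list[str] = ("species",)) -> pd.DataFrame:
    """Quasibinomial GLM of RI on categorical covariates, with F-tests.

    Each term's F statistic is the dispersion-scaled deviance drop between
    the full model and the model without that term.
    """
    records = records.reset_index(drop=True)
    y = records["RI"].to_numpy(float)
    covariates = list(covariates)
    for c in covariates:
        if records[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} has a single level")
        within = records.groupby(c)["RI"].nunique()
        if (within == 1).all() and records.groupby(c)["RI"].std().fillna(0).eq(0).all():
            warnings.warn(f"separation: RI constant within levels of {c!r}")

    def design(terms):
        mats = [np.ones((len(records), 1))]
        for c in terms:
            levels = sorted(records[c].astype(str).unique())
            mats.append(np.column_stack(
                [(records[c].astype(str) == lev).to_numpy(float)
                 for lev in levels[1:]]))
        return np.hstack(mats)

    Xf = design(covariates)
    full = sm.GLM(y, Xf, family=sm.families.Binomial()).fit(scale="X2")
    phi = float(full.scale)
    df_resid = full.df_resid
    rows = []
    for c in covariates:
        Xr = design([t for t in covariates if t != c])
        red = sm.GLM(y, Xr, family=sm.families.Binomial()).fit(scale="X2")
        df_diff = Xf.shape[1] - Xr.shape[1]
        F = float((red.deviance - full.deviance) / (df_diff * phi))
        p = float(stats.f.sf(max(F, 0.0), df_diff, df_resid))
        rows.append((c, F, df_diff, df_resid, p))
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"])
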