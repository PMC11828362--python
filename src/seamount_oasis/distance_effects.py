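"""Distance-effect inference: penalized-spline fits, derivative confidence
bands, the seamount radius of influence and the enrichment magnitude.

The model for a response :math:`y_i` observed at distance :math:`d_i` from
the nearest summit is

.. math:: g(E(y_i)) = \\beta_0 + f_s(d_i) + \\beta_1 x_i,

with :math:`f_s` a penalized thin-plate-type regression spline, optional
parametric covariates :math:`x` (season, vessel), an optional ridge-penalized
transect random intercept and, for depth-stratified acoustic fields, a
tensor-product smooth :math:`f(d, z)`.  Families: Gaussian (identity link),
negative binomial, Tweedie, quasi-Poisson and quasi-binomial (log/logit
links).

The radius of influence ``R`` is the furthest distance at which the slope of
the fitted smooth differs significantly from zero (95% pointwise interval on
finite-difference first derivatives).  Where a near-zero baseline makes the
derivative scan uninformative (non-Gaussian fits whose far-field prediction
falls below 0.05), ``R`` falls back to the furthest distance at which the
predicted response exceeds an oceanic reference mean (floored at 0.05).  The
enrichment magnitude is the ratio of the predicted response at the summit to
the mean predicted response beyond ``R``, with a credible interval from
posterior simulation of the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .families import get_family
from .smoothing import (
    GLMResults,
    PenalizedGLM,
    RandomIntercept,
    TensorSpline,
    TPSpline,
    fit_nb_profile,
)

__all__ = [
    "SmoothModel",
    "DerivativeBand",
    "DifferenceBand",
    "RadiusEstimate",
    "fit_distance_gam",
    "select_structure",
    "smooth_difference",
    "posterior_simulate",
    "derivative_band",
    "radius_of_influence",
    "enrichment_magnitude",
    "two_proportion_test",
]

GRID_SIZE = 100


@dataclass
class SmoothModel:
    """A fitted distance-effect model."""

    results: GLMResults
    family_tag: str
    structure: str                      # 'global' | 'per-seamount' | 'depth-group'
    smooths: dict                       # level -> TPSpline (or TensorSpline)
    level_col: str | None
    levels: list
    season_levels: list
    distance_range: tuple
    tensor: bool = False
    rho: float | None = None            # AR(1) coefficient, if estimated
    theta: float | None = None

    @property
    def edf(self) -> float:
        return self.results.edf

    @property
    def phi(self) -> float:
        return self.results.phi

    def _full_row(self, block_name: str, Xb: np.ndarray) -> np.ndarray:
        """Embed a block design into the full coefficient space."""
        p = self.results.beta.size
        out = np.zeros((Xb.shape[0], p))
        out[:, self.results.col_slices[block_name]] = Xb
        return out

    def _design(self, distance, level=None, depth=None,
                smooth_only: bool = False) -> np.ndarray:
        """Population-level design matrix at new distances.

        Season is held at its reference level and random intercepts at zero,
        so predictions describe a typical transect in the reference season.
        """
        distance = np.atleast_1d(np.asarray(distance, dtype=float))
        p = self.results.beta.size
        X = np.zeros((distance.size, p))
        if level is None:
            level = self.levels[0]
        if self.tensor:
            sm = self.smooths[level]
            if depth is None:
                raise ValueError("tensor-product model requires depth")
            depth = np.broadcast_to(np.asarray(depth, float), distance.shape)
            Xb = sm.design(distance, depth)
        else:
            Xb = self.smooths[level].design(distance)
        X[:, self.results.col_slices[f"s({level})"]] = Xb
        if not smooth_only:
            X[:, self.results.col_slices["intercept"]] = 1.0
            if self.structure != "global" and len(self.levels) > 1:
                sl = self.results.col_slices["level_main"]
                idx = self.levels.index(level)
                if idx > 0:
                    X[:, sl.start + idx - 1] = 1.0
        return X

    def predict(self, distance, level=None, depth=None,
                response_scale: bool = True) -> np.ndarray:
        X = self._design(distance, level=level, depth=depth)
        eta = X @ self.results.beta
        fam = self.results.family
        return fam.linkinv(eta) if response_scale else eta

    def predict_se(self, distance, level=None, depth=None) -> np.ndarray:
        X = self._design(distance, level=level, depth=depth)
        v = np.einsum("ij,jk,ik->i", X, self.results.cov, X)
        return np.sqrt(np.clip(v, 0, None))

    def smooth_p_value(self, level=None) -> float:
        """Wald-type p-value for the smooth term from the Bayesian covariance."""
        if level is None:
            level = self.levels[0]
        sl = self.results.col_slices[f"s({level})"]
        b = self.results.beta[sl]
        V = self.results.cov[sl, sl]
        Vp = np.linalg.pinv(V, rcond=1e-10)
        stat = float(b @ Vp @ b)
        df = max(self.results.block_edf(f"s({level})"), 1.0)
        return float(stats.chi2.sf(stat, df))


@dataclass
class DerivativeBand:
    """Finite-difference first derivative of the smooth with 95% bounds."""

    grid: np.ndarray
    derivative: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: object = None

    @property
    def significant(self) -> np.ndarray:
        return (self.lower > 0) | (self.upper < 0)


@dataclass
class DifferenceBand:
    grid: np.ndarray
    difference: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @property
    def distinct(self) -> bool:
        """True if the 95% CI excludes zero anywhere along the grid."""
        return bool(np.any((self.lower > 0) | (self.upper < 0)))


@dataclass
class RadiusEstimate:
    """Radius of influence and enrichment magnitude of a seamount effect."""

    R_km: float | None
    method: str                         # 'derivative-scan' | 'baseline-crossing' | 'none'
    magnitude: float | None = None
    magnitude_ci: tuple | None = None
    summit_prediction: float | None = None
    baseline_mean: float | None = None
    level: object = None

    @property
    def effect_detected(self) -> bool:
        return self.method != "none" and self.R_km is not None


# ---------------------------------------------------------------------------
# fitting


def _season_design(samples: pd.DataFrame):
    if "season" not in samples.columns or samples["season"].nunique() < 2:
        return None, []
    levels = sorted(samples["season"].astype(str).unique())
    X = np.column_stack(
        [(samples["season"].astype(str) == lev).to_numpy(float)
         for lev in levels[1:]]
    )
    return X, levels


def _ar1_order(groups, distance):
    """Within-group row sequences ordered along the survey track (distance)."""
    seqs = []
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        seqs.append(idx[np.argsort(distance[idx], kind="stable")])
    return seqs


def _ar1_whiten(y, blocks, seqs, rho):
    """Prais-Winsten whitening of response and design along each sequence."""
    y = y.copy()
    mats = [np.asarray(b[1], dtype=float).copy() for b in blocks]
    for idx in seqs:
        if idx.size < 2:
            continue
        head, rest, prev = idx[0], idx[1:], idx[:-1]
        c = np.sqrt(1.0 - rho**2)
        y[rest] = y[rest] - rho * y[prev]
        y[head] *= c
        for M in mats:
            M[rest] = M[rest] - rho * M[prev]
            M[head] *= c
    new_blocks = [(b[0], M, b[2], b[3]) for b, M in zip(blocks, mats)]
    return y, new_blocks


def fit_distance_gam(
    samples: pd.DataFrame,
    family: str = "gaussian",
    structure: str = "global",
    k: int = 10,
    theta: float | None = None,
    tweedie_power: float = 1.5,
    transect_re: bool | None = None,
    ar1: bool = False,
    depth: bool = False,
    k_depth: int = 5,
    weights_col: str | None = None,
) -> SmoothModel:
    """Fit the distance-effect model to a table of radial samples.

    Parameters
    ----------
    samples : DataFrame
        Columns ``distance_km`` and ``response`` are required; ``seamount_id``
        (for non-global structures), ``season``, ``transect_id`` and ``depth``
        are used when present.
    family : str
        ``gaussian``, ``negative-binomial``/``nb``, ``tweedie``,
        ``quasipoisson`` or ``quasibinomial``.
    structure : str
        ``global`` (one smooth), ``per-seamount`` (a smooth per
        ``seamount_id``) or ``depth-group`` (a smooth per ``depth_group``).
    k : int
        Basis dimension of each 1-D smooth.
    transect_re : bool, optional
        Ridge-penalized transect random intercepts; defaults to on when a
        ``transect_id`` column is present.
    ar1 : bool
        Iterated Prais-Winsten whitening of within-transect AR(1) residuals
        (Gaussian family only; for count families an independence working
        model is used and the request is recorded with a warning).
    depth : bool
        Fit a tensor-product smooth of distance and ``depth`` instead of a
        1-D smooth of distance.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 observations")
    samples = samples.reset_index(drop=True)
    d = samples["distance_km"].to_numpy(float)
    if np.any(d < 0):
        raise ValueError("distance_km must be >= 0")
    y = samples["response"].to_numpy(float)
    if family in ("negative-binomial", "nb", "tweedie", "quasipoisson") and np.any(y < 0):
        raise ValueError(f"negative responses are invalid for family {family!r}")
    if structure == "global":
        level_col, levels = None, ["global"]
        lev_of = np.array(["global"] * len(samples))
    elif structure == "per-seamount":
        level_col = "seamount_id"
        lev_of = samples[level_col].to_numpy()
        levels = sorted(pd.unique(lev_of).tolist())
    elif structure == "depth-group":
        level_col = "depth_group"
        lev_of = samples[level_col].to_numpy()
        levels = sorted(pd.unique(lev_of).tolist())
    else:
        raise ValueError(f"unknown structure {structure!r}")

    blocks = [("intercept", np.ones((len(samples), 1)), None, 0)]
    if len(levels) > 1:
        Xlev = np.column_stack(
            [(lev_of == lev).astype(float) for lev in levels[1:]]
        )
        blocks.append(("level_main", Xlev, None, 0))
    Xse, season_levels = _season_design(samples)
    if Xse is not None:
        blocks.append(("season", Xse, None, 0))

    smooths: dict = {}
    for lev in levels:
        mask = lev_of == lev
        if depth:
            sm = TensorSpline.from_data(
                d[mask], samples.loc[mask, "depth"].to_numpy(float),
                kx=k, ky=k_depth,
            )
            Xb = np.zeros((len(samples), sm.ncol))
            Xb[mask] = sm.design(d[mask], samples.loc[mask, "depth"].to_numpy(float))
            pen = sm.penalties()
            ranks = [sm.mx.rank * sm.my.ncol, sm.mx.ncol * sm.my.rank]
            blocks.append((f"s({lev})", Xb, pen, ranks))
        else:
            sm = TPSpline.from_data(d[mask], k=k)
            Xb = np.zeros((len(samples), sm.ncol))
            Xb[mask] = sm.design(d[mask])
            blocks.append((f"s({lev})", Xb, sm.S, sm.rank))
        smooths[lev] = sm

    if transect_re is None:
        transect_re = "transect_id" in samples.columns
    ri = None
    if transect_re and "transect_id" in samples.columns:
        ri = RandomIntercept.from_data(samples["transect_id"].to_numpy())
        blocks.append(("transect_re", ri.design(samples["transect_id"].to_numpy()),
                       ri.S, ri.rank))

    wts = samples[weights_col].to_numpy(float) if weights_col else None
    rho_hat = None

    def _fit(yv, blk):
        if family in ("nb", "negbin", "negative-binomial") and theta is None:
            return fit_nb_profile(yv, blk, weights=wts)
        fam = get_family(family, theta=theta, power=tweedie_power)
        return PenalizedGLM(yv, blk, fam, weights=wts).fit()

    res = _fit(y, blocks)
    if ar1:
        if family != "gaussian":
            warnings.warn(
                "AR(1) whitening supported for Gaussian responses only; "
                "count-family fit uses an independence working model"
            )
        elif "transect_id" in samples.columns:
            seqs = _ar1_order(samples["transect_id"].to_numpy(), d)
            resid = y - res.fitted
            num = den = 0.0
            for idx in seqs:
                r = resid[idx]
                if r.size >= 2:
                    num += float(np.sum(r[1:] * r[:-1]))
                    den += float(np.sum(r[:-1] ** 2))
            rho_hat = float(np.clip(num / den if den > 0 else 0.0,
                                    -0.95, 0.95))
            yw, blkw = _ar1_whiten(y.astype(float), blocks, seqs, rho_hat)
            res = _fit(yw, blkw)
    if not res.converged:
        warnings.warn("penalized IRLS did not fully converge")

    return SmoothModel(
        results=res,
        family_tag=family,
        structure=structure,
        smooths=smooths,
        level_col=level_col,
        levels=levels,
        season_levels=season_levels,
        distance_range=(float(d.min()), float(d.max())),
        tensor=depth,
        rho=rho_hat,
        theta=getattr(res.family, "theta", None),
    )


# ---------------------------------------------------------------------------
# structure selection


def select_structure(samples: pd.DataFrame, family: str = "gaussian",
                     **fit_kw) -> str:
    """Choose the smooth structure: per-seamount, depth-group or global.

    Likelihood families (Gaussian, negative binomial) are compared by AICc of
    the candidate fits.  Quasi-likelihood families have no AIC, so candidate
    smooths are merged whenever their pairwise difference bands cover zero
    along the whole grid.
    """
    has_sm = "seamount_id" in samples.columns and samples["seamount_id"].nunique() > 1
    has_dg = "depth_group" in samples.columns and samples["depth_group"].nunique() > 1
    if not has_sm and not has_dg:
        return "global"
    candidates = ["global"]
    if has_sm:
        candidates.append("per-seamount")
    if has_dg:
        candidates.append("depth-group")

    fits = {}
    for st in candidates:
        try:
            fits[st] = fit_distance_gam(samples, family=family, structure=st,
                                        **fit_kw)
        except Exception as e:  # candidate excluded, per selection contract
            warnings.warn(f"structure {st!r} failed to fit: {e}")
    if not fits:
        raise RuntimeError("no candidate structure converged")

    if family in ("gaussian", "nb", "negbin", "negative-binomial"):
        scores = {st: m.results.aicc() for st, m in fits.items()}
        return min(scores, key=scores.get)

    # quasi families: merge structures whose smooths are indistinguishable
    for st in ("per-seamount", "depth-group"):
        m = fits.get(st)
        if m is None:
            continue
        distinct = False
        for i in range(len(m.levels)):
            for j in range(i + 1, len(m.levels)):
                band = smooth_difference(m, level_a=m.levels[i],
                                         level_b=m.levels[j])
                if band.distinct:
                    distinct = True
        if distinct:
            return st
    return "global"


# ---------------------------------------------------------------------------
# inference on the fitted smooth


def _grid(model: SmoothModel, n: int = GRID_SIZE) -> np.ndarray:
    lo, hi = model.distance_range
    return np.linspace(lo, hi, n)


def smooth_difference(model_a: SmoothModel, model_b: SmoothModel | None = None,
                      level_a=None, level_b=None, grid_size: int = GRID_SIZE,
                      depth: float | None = None) -> DifferenceBand:
    """95% band for the pointwise difference between two fitted smooths.

    Either two levels of one factor-smooth model (joint covariance) or two
    independently fitted models over a shared distance domain.
    """
    if model_b is None:
        if level_a is None or level_b is None:
            raise ValueError("two levels of one model, or two models, required")
        g = _grid(model_a, grid_size)
        Xa = model_a._design(g, level=level_a, depth=depth)
        Xb = model_a._design(g, level=level_b, depth=depth)
        C = Xa - Xb
        diff = C @ model_a.results.beta
        var = np.einsum("ij,jk,ik->i", C, model_a.results.cov, C)
    else:
        lo = max(model_a.distance_range[0], model_b.distance_range[0])
        hi = min(model_a.distance_range[1], model_b.distance_range[1])
        if hi <= lo:
            raise ValueError("models have disjoint distance domains")
        g = np.linspace(lo, hi, grid_size)
        ea = model_a.predict(g, level=level_a, depth=depth, response_scale=False)
        eb = model_b.predict(g, level=level_b, depth=depth, response_scale=False)
        diff = ea - eb
        var = model_a.predict_se(g, level=level_a, depth=depth) ** 2 \
            + model_b.predict_se(g, level=level_b, depth=depth) ** 2
    se = np.sqrt(np.clip(var, 0, None))
    z = stats.norm.ppf(0.975)
    return DifferenceBand(grid=g, difference=diff, lower=diff - z * se,
                          upper=diff + z * se)


def posterior_simulate(model: SmoothModel, n_draws: int = 1000,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw coefficient vectors from the Gaussian posterior of the fit."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta, V = model.results.beta, model.results.cov
    if np.allclose(V, 0):
        return np.tile(beta, (n_draws, 1))
    ev = np.linalg.eigvalsh(V)
    jitter = 0.0
    if ev.min() < 0:
        if ev.min() < -1e-6 * max(ev.max(), 1.0):
            raise np.linalg.LinAlgError(
                "posterior covariance not PSD after regularization"
            )
        jitter = -ev.min() + 1e-12
    return rng.multivariate_normal(beta, V + jitter * np.eye(beta.size),
                                   size=n_draws, method="eigh")


def derivative_band(model: SmoothModel, grid_size: int = GRID_SIZE,
                    eps: float | None = None, level=None,
                    depth: float | None = None) -> DerivativeBand:
    """Finite-difference first derivative of the smooth term with 95% CI.

    Central differences of the smooth contribution to the linear predictor,
    with the pointwise interval propagated through the difference operator
    from the coefficient posterior covariance.
    """
    g = _grid(model, grid_size)
    lo, hi = model.distance_range
    if eps is None:
        eps = (hi - lo) / 1000.0
    gp = np.clip(g + eps, lo, hi)
    gm = np.clip(g - eps, lo, hi)
    Xp = model._design(gp, level=level, depth=depth, smooth_only=True)
    Xm = model._design(gm, level=level, depth=depth, smooth_only=True)
    C = (Xp - Xm) / (gp - gm)[:, None]
    der = C @ model.results.beta
    var = np.einsum("ij,jk,ik->i", C, model.results.cov, C)
    se = np.sqrt(np.clip(var, 0, None))
    z = stats.norm.ppf(0.975)
    return DerivativeBand(grid=g, derivative=der, lower=der - z * se,
                          upper=der + z * se, level=level)


def radius_of_influence(
    model: SmoothModel,
    band: DerivativeBand | None = None,
    oceanic_baseline: float | None = None,
    baseline_floor: float = 0.05,
    level=None,
    depth: float | None = None,
) -> RadiusEstimate:
    """Estimate the seamount radius of influence ``R``.

    Scanning from the far field toward the summit, ``R`` is the furthest
    grid distance at which the derivative CI excludes zero.  When the family
    is non-Gaussian and the far-field predicted response falls below
    ``baseline_floor``, the derivative scan cannot separate an enrichment
    from a monotone trend on the link scale, and ``R`` is instead the
    furthest distance at which the predicted response exceeds
    ``max(oceanic_baseline, baseline_floor)`` (magnitude not estimated).
    """
    if band is None:
        band = derivative_band(model, level=level, depth=depth)
    g = band.grid
    pred = model.predict(g, level=level, depth=depth)
    far = g >= (g[0] + 0.75 * (g[-1] - g[0]))
    baseline_pred = float(np.mean(pred[far]))

    if model.family_tag != "gaussian" and baseline_pred < baseline_floor:
        if model.smooth_p_value(level=level) > 0.05:
            return RadiusEstimate(R_km=None, method="none", level=level)
        thresh = max(oceanic_baseline or 0.0, baseline_floor)
        above = pred > thresh
        if not above.any() or not above[0]:
            return RadiusEstimate(R_km=None, method="none", level=level)
        R = float(g[np.max(np.flatnonzero(above))])
        return RadiusEstimate(
            R_km=R, method="baseline-crossing",
            summit_prediction=float(pred[0]), baseline_mean=baseline_pred,
            level=level,
        )

    sig = band.significant
    if not sig.any():
        return RadiusEstimate(R_km=None, method="none", level=level)
    R = float(g[np.max(np.flatnonzero(sig))])
    beyond = g > R
    base = float(np.mean(pred[beyond])) if beyond.any() else baseline_pred
    return RadiusEstimate(
        R_km=R, method="derivative-scan",
        summit_prediction=float(pred[0]), baseline_mean=base, level=level,
    )


def enrichment_magnitude(model: SmoothModel, R: float, n_draws: int = 1000,
                         seed: int | np.random.Generator = 0, level=None,
                         grid_size: int = GRID_SIZE,
                         depth: float | None = None):
    """Summit-to-baseline enrichment ratio with a 95% credible interval.

    The point estimate is E(y | d = 0) divided by the mean predicted response
    at distances beyond ``R``; the interval comes from recomputing the ratio
    for each posterior coefficient draw.
    """
    g = _grid(model, grid_size)
    beyond = g > R
    if not beyond.any():
        raise ValueError("R at or beyond the sampled range; no baseline region")
    X0 = model._design(np.array([0.0 if model.distance_range[0] == 0
                                 else model.distance_range[0]]),
                       level=level, depth=depth)
    Xb = model._design(g[beyond], level=level, depth=depth)
    fam = model.results.family
    mu0 = float(fam.linkinv(X0 @ model.results.beta)[0])
    base = float(np.mean(fam.linkinv(Xb @ model.results.beta)))
    if model.family_tag == "gaussian" and base <= 0:
        raise ValueError("non-positive Gaussian baseline: ratio undefined")
    point = mu0 / base
    draws = posterior_simulate(model, n_draws=n_draws, seed=seed)
    mu0_d = fam.linkinv(draws @ X0.T).ravel()
    base_d = np.mean(fam.linkinv(draws @ Xb.T), axis=1)
    ok = base_d > 0
    ratios = mu0_d[ok] / base_d[ok]
    ci = (float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5)))
    return point, ci


# ---------------------------------------------------------------------------


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        correction: bool = True) -> dict:
    """Two-sample proportion test as a 1-df chi-square (continuity-corrected).

    Returns ``{'chi_square': ..., 'p': ..., 'p1': ..., 'p2': ...}``.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("trial counts must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    res = stats.chi2_contingency(table, correction=correction)
    return {
        "chi_square": float(res.statistic),
        "p": float(res.pvalue),
        "p1": x1 / n1,
        "p2": x2 / n2,
    }
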