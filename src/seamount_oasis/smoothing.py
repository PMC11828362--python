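"""Penalized regression spline engine.

This module implements the quantitative core shared by the distance-effect,
diel and detection-range analyses: low-rank thin-plate regression splines in
one dimension (the 1-D thin-plate spline is the cubic smoothing spline),
cyclic cubic P-splines for diel effects, tensor-product smooths for
distance x depth fields, i.i.d. Gaussian random intercepts expressed as a
ridge-penalized block, and a penalized IRLS fitter whose smoothing
parameters are chosen by a working-model REML criterion.

The fitter returns the Bayesian posterior covariance of all coefficients,
(X'WX + S_lambda)^-1 * phi, which downstream code propagates through
finite-difference operators (derivative confidence bands), smooth-difference
contrasts and posterior simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .families import Family

__all__ = [
    "TPSpline",
    "CyclicSpline",
    "RandomIntercept",
    "TensorSpline",
    "PenalizedGLM",
    "GLMResults",
]


def _eta(r: np.ndarray) -> np.ndarray:
    # 1-D thin-plate (m=2) radial basis, Green's function |r|^3 / 12
    return np.abs(r) ** 3 / 12.0


@dataclass
class TPSpline:
    """Low-rank 1-D thin-plate regression spline term.

    The smooth carries its own linear null-space column (centred), so the
    slope of the fitted relationship belongs to the smooth term, as it must
    for derivative-based range-of-effect estimation.  The model intercept is
    supplied separately by the caller.
    """

    knots: np.ndarray      # on the standardized [0, 1] scale
    Z: np.ndarray          # null-space constraint basis, (k, k-2)
    S: np.ndarray          # penalty on [linear, radial...] columns, (k-1, k-1)
    x0: float              # covariate standardization: u = (x - x0) / xscale
    xscale: float
    center: float
    rank: int

    @classmethod
    def from_data(cls, x: np.ndarray, k: int = 10) -> "TPSpline":
        x = np.asarray(x, dtype=float)
        ux = np.unique(x)
        if ux.size < 4:
            raise ValueError("need at least 4 distinct covariate values")
        k = int(min(k, ux.size))
        x0 = float(ux.min())
        xscale = float(ux.max() - ux.min())
        u = (ux - x0) / xscale
        # knots at quantiles of the standardized observed distances
        knots = np.quantile(u, np.linspace(0, 1, k))
        knots = np.unique(knots)
        k = knots.size
        E = _eta(knots[:, None] - knots[None, :])
        T = np.column_stack([np.ones(k), knots])
        Q, _ = np.linalg.qr(T, mode="complete")
        Z = Q[:, 2:]                      # (k, k-2)
        Sz = Z.T @ E @ Z
        Sz = (Sz + Sz.T) / 2.0
        S = np.zeros((k - 1, k - 1))
        S[1:, 1:] = Sz
        # scale penalty so lambda is dimensionless-ish
        nrm = np.linalg.norm(Sz, "fro")
        if nrm > 0:
            S /= nrm
        return cls(knots=knots, Z=Z, S=S, x0=x0, xscale=xscale,
                   center=float(np.mean((x - x0) / xscale)), rank=k - 2)

    @property
    def ncol(self) -> int:
        return self.knots.size - 1

    def design(self, x: np.ndarray) -> np.ndarray:
        u = (np.asarray(x, dtype=float) - self.x0) / self.xscale
        Ex = _eta(u[:, None] - self.knots[None, :])
        return np.column_stack([u - self.center, Ex @ self.Z])


@dataclass
class CyclicSpline:
    """Cyclic cubic P-spline on [0, period); value and slope wrap around."""

    period: float
    k: int
    colmeans: np.ndarray
    S: np.ndarray
    rank: int

    @classmethod
    def from_period(cls, period: float = 24.0, k: int = 8) -> "CyclicSpline":
        # cyclic second-difference penalty
        D = np.zeros((k, k))
        for i in range(k):
            D[i, i] = 1.0
            D[i, (i + 1) % k] = -2.0
            D[i, (i + 2) % k] = 1.0
        S = D.T @ D
        nrm = np.linalg.norm(S, "fro")
        S = S / nrm
        # column means of the raw periodic basis over a fine grid, for centring
        dummy = cls(period=period, k=k, colmeans=np.zeros(k), S=S, rank=k - 1)
        grid = np.linspace(0, period, 512, endpoint=False)
        raw = dummy._raw(grid)
        dummy.colmeans = raw.mean(axis=0)
        return dummy

    @property
    def ncol(self) -> int:
        return self.k

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.mod(np.asarray(x, dtype=float), self.period)
        h = self.period / self.k
        t = np.arange(-3, self.k + 4) * h
        M = BSpline.design_matrix(x, t, 3).toarray()   # k+3 columns
        out = M[:, : self.k].copy()
        out[:, :3] += M[:, self.k : self.k + 3]
        return out

    def design(self, x: np.ndarray) -> np.ndarray:
        return self._raw(x) - self.colmeans


@dataclass
class RandomIntercept:
    """i.i.d. Gaussian random intercepts as a ridge-penalized factor block."""

    levels: np.ndarray

    @classmethod
    def from_data(cls, groups: np.ndarray) -> "RandomIntercept":
        return cls(levels=np.unique(np.asarray(groups)))

    @property
    def ncol(self) -> int:
        return self.levels.size

    @property
    def rank(self) -> int:
        return self.levels.size

    @property
    def S(self) -> np.ndarray:
        return np.eye(self.levels.size)

    def design(self, groups: np.ndarray) -> np.ndarray:
        groups = np.asarray(groups)
        out = np.zeros((groups.size, self.levels.size))
        for j, lev in enumerate(self.levels):
            out[groups == lev, j] = 1.0
        return out


@dataclass
class TensorSpline:
    """Tensor product of two marginal 1-D thin-plate smooths (e.g. distance x depth)."""

    mx: TPSpline
    my: TPSpline
    Sx: np.ndarray = field(init=False)
    Sy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        px, py = self.mx.ncol, self.my.ncol
        self.Sx = np.kron(self.mx.S, np.eye(py))
        self.Sy = np.kron(np.eye(px), self.my.S)

    @classmethod
    def from_data(cls, x, y, kx: int = 8, ky: int = 5) -> "TensorSpline":
        return cls(TPSpline.from_data(x, kx), TPSpline.from_data(y, ky))

    @property
    def ncol(self) -> int:
        return self.mx.ncol * self.my.ncol

    def design(self, x, y) -> np.ndarray:
        A = self.mx.design(x)
        B = self.my.design(y)
        return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)

    def penalties(self) -> list[np.ndarray]:
        return [self.Sx, self.Sy]


# ---------------------------------------------------------------------------


def _pseudo_logdet(S: np.ndarray, rank: int) -> float:
    ev = np.linalg.eigvalsh((S + S.T) / 2.0)
    ev = np.sort(ev)[::-1][:rank]
    ev = np.clip(ev, 1e-12, None)
    return float(np.sum(np.log(ev)))


@dataclass
class GLMResults:
    """Fitted penalized GLM: coefficients, Bayesian covariance and diagnostics."""

    beta: np.ndarray
    cov: np.ndarray              # Bayesian posterior covariance, phi*(X'WX+S)^-1
    phi: float                   # dispersion
    lambdas: np.ndarray
    edf: float
    edf_by_col: np.ndarray
    family: Family
    deviance: float
    fitted: np.ndarray
    eta: np.ndarray
    n: int
    reml: float
    converged: bool
    col_slices: dict = field(default_factory=dict)

    def block_edf(self, name: str) -> float:
        sl = self.col_slices[name]
        return float(np.sum(self.edf_by_col[sl]))

    def loglik(self) -> float:
        return self.family.loglik(self._y, self.fitted, self.phi)

    def aicc(self) -> float:
        """AICc with effective degrees of freedom as the parameter count."""
        k = self.edf + (1.0 if self.family.estimate_scale else 0.0)
        if self.family.name == "negative-binomial":
            k += 1.0
        ll = self.loglik()
        n = self.n
        denom = max(n - k - 1.0, 1e-6)
        return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1.0) / denom


class PenalizedGLM:
    """Penalized IRLS fitter over a block design.

    Parameters
    ----------
    y : array
        Response (for binomial-type families, the proportion).
    blocks : list of (name, X_block, S_block | None, rank)
        Columns are concatenated in order.  ``S_block`` of ``None`` marks an
        unpenalized parametric block.
    family : Family
    weights : array, optional
        Prior weights (binomial trial counts, bin durations).
    offset : array, optional
    """

    def __init__(self, y, blocks, family: Family, weights=None, offset=None):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        self.family = family
        self.w_prior = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        self.offset = np.zeros(n) if offset is None else np.asarray(offset, float)
        cols = []
        self.penalties: list[tuple[slice, np.ndarray, int, float]] = []
        self.col_slices: dict[str, slice] = {}
        start = 0
        for name, Xb, Sb, rank in blocks:
            Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
            if Xb.shape[0] != n:
                raise ValueError(f"block {name!r} has wrong number of rows")
            stop = start + Xb.shape[1]
            sl = slice(start, stop)
            self.col_slices[name] = sl
            cols.append(Xb)
            if Sb is not None:
                # a block may carry several penalties (tensor smooths)
                Sb_list = Sb if isinstance(Sb, (list, tuple)) else [Sb]
                rank_list = rank if isinstance(rank, (list, tuple)) else [rank]
                for Sbi, ri in zip(Sb_list, rank_list):
                    Sbi = np.asarray(Sbi, dtype=float)
                    self.penalties.append(
                        (sl, Sbi, int(ri), _pseudo_logdet(Sbi, ri))
                    )
            start = stop
        self.X = np.hstack(cols)
        self.p = self.X.shape[1]
        if n < self.p:
            warnings.warn("more coefficients than observations; fit is shrunk")

    # -- inner loop --------------------------------------------------------
    def _S_total(self, lambdas: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lam, (sl, Sb, _, _) in zip(lambdas, self.penalties):
            S[sl, sl] += lam * Sb
        return S

    def _pirls(self, lambdas: np.ndarray, beta0=None, max_iter: int = 60,
               tol: float = 1e-8):
        y, X, fam = self.y, self.X, self.family
        S = self._S_total(lambdas)
        if beta0 is None:
            mu = fam.initial_mu(y)
            eta = fam.linkfun(mu) - self.offset
            beta = None
        else:
            beta = beta0
            eta = X @ beta
            mu = fam.linkinv(eta + self.offset)
        dev = fam.deviance(y, mu, self.w_prior)
        for _ in range(max_iter):
            d = fam.dmu_deta(eta + self.offset)
            d = np.clip(d, 1e-10, None)
            V = fam.variance(mu)
            w = self.w_prior * d**2 / V
            z = eta + (y - mu) / d
            XtW = X.T * w
            A = XtW @ X + S
            try:
                c, low = cho_factor(A + 1e-10 * np.eye(self.p))
                beta_new = cho_solve((c, low), XtW @ z)
            except np.linalg.LinAlgError:
                beta_new = np.linalg.lstsq(A, XtW @ z, rcond=None)[0]
            eta_new = X @ beta_new
            mu_new = fam.linkinv(eta_new + self.offset)
            dev_new = fam.deviance(y, mu_new, self.w_prior)
            # step-halving on deviance increase / non-finite
            step = 1.0
            while (not np.isfinite(dev_new) or dev_new > dev + 1e-8) and step > 1e-3 \
                    and beta is not None:
                step /= 2.0
                beta_try = beta + step * (beta_new - beta)
                eta_new = X @ beta_try
                mu_new = fam.linkinv(eta_new + self.offset)
                dev_new = fam.deviance(y, mu_new, self.w_prior)
                beta_new = beta_try
            rel = abs(dev - dev_new) / (abs(dev_new) + 0.1)
            beta, eta, mu, dev = beta_new, eta_new, mu_new, dev_new
            if rel < tol:
                return beta, eta, mu, dev, w, z, True
        return beta, eta, mu, dev, w, z, False

    def _criterion(self, lambdas: np.ndarray, beta0=None):
        """Working-model REML score at the P-IRLS solution."""
        beta, eta, mu, dev, w, z, conv = self._pirls(lambdas, beta0)
        S = self._S_total(lambdas)
        XtW = self.X.T * w
        A = XtW @ self.X + S
        n = self.y.size
        # effective degrees of freedom
        try:
            Ainv = np.linalg.inv(A + 1e-10 * np.eye(self.p))
        except np.linalg.LinAlgError:
            Ainv = np.linalg.pinv(A)
        F = Ainv @ (XtW @ self.X)
        edf = float(np.trace(F))
        pearson = float(np.sum(self.w_prior * (self.y - mu) ** 2
                               / self.family.variance(mu)))
        if self.family.estimate_scale:
            phi = max(pearson / max(n - edf, 1.0), 1e-12)
        else:
            phi = 1.0
        rss = float(np.sum(w * (z - self.X @ beta) ** 2))
        pen = float(beta @ (S @ beta))
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            logdetA = np.sum(np.log(np.clip(np.diag(A), 1e-12, None)))
        logdetS = 0.0
        Mp = self.p
        for lam, (sl, Sb, rank, ld) in zip(lambdas, self.penalties):
            logdetS += rank * np.log(max(lam, 1e-300)) + ld
            Mp -= rank
        reml = (
            (rss + pen) / (2.0 * phi)
            + 0.5 * logdetA
            - 0.5 * logdetS
            + 0.5 * (n - Mp) * np.log(2.0 * np.pi * phi)
        )
        return reml, dict(beta=beta, eta=eta, mu=mu, dev=dev, w=w, z=z,
                          edf=edf, phi=phi, Ainv=Ainv, F=F, conv=conv)

    # -- outer loop --------------------------------------------------------
    def fit(self, lambdas=None, max_outer: int = 1) -> GLMResults:
        m = len(self.penalties)
        if m == 0:
            reml, st = self._criterion(np.zeros(0))
            lam_opt = np.zeros(0)
        elif lambdas is not None:
            lam_opt = np.asarray(lambdas, dtype=float)
            reml, st = self._criterion(lam_opt)
        elif m == 1:
            warm = {}

            def f(loglam):
                r, s = self._criterion(np.array([np.exp(loglam)]),
                                       warm.get("beta"))
                warm["beta"] = s["beta"]
                return r

            res = optimize.minimize_scalar(f, bounds=(-12.0, 18.0),
                                           method="bounded",
                                           options={"xatol": 1e-2})
            lam_opt = np.array([np.exp(res.x)])
            reml, st = self._criterion(lam_opt)
        else:
            warm = {}

            def f(loglam):
                r, s = self._criterion(np.exp(np.clip(loglam, -12, 18)),
                                       warm.get("beta"))
                warm["beta"] = s["beta"]
                return r

            x0 = np.zeros(m)
            res = optimize.minimize(f, x0, method="Nelder-Mead",
                                    options={"xatol": 5e-2, "fatol": 1e-3,
                                             "maxiter": 200 * m})
            lam_opt = np.exp(np.clip(res.x, -12, 18))
            reml, st = self._criterion(lam_opt)

        cov = st["phi"] * st["Ainv"]
        cov = (cov + cov.T) / 2.0
        out = GLMResults(
            beta=st["beta"],
            cov=cov,
            phi=st["phi"],
            lambdas=lam_opt,
            edf=st["edf"],
            edf_by_col=np.diag(st["F"]).copy(),
            family=self.family,
            deviance=st["dev"],
            fitted=st["mu"],
            eta=st["eta"],
            n=self.y.size,
            reml=reml,
            converged=bool(st["conv"]),
            col_slices=dict(self.col_slices),
        )
        out._y = self.y  # for loglik/AICc
        return out


def fit_nb_profile(y, blocks, weights=None, offset=None,
                   theta0: float = 1.0, max_outer: int = 4):
    """Fit a negative-binomial penalized GLM, profiling theta by moments.

    The shape parameter is updated so the Pearson statistic matches the
    residual degrees of freedom, alternating with REML smoothing selection.
    """
    from .families import get_family

    y = np.asarray(y, dtype=float)
    theta = float(theta0)
    res = None
    for _ in range(max_outer):
        fam = get_family("negative-binomial", theta=theta)
        res = PenalizedGLM(y, blocks, fam, weights=weights, offset=offset).fit()
        mu = res.fitted
        dof = max(res.n - res.edf, 1.0)

        def pearson_gap(log_th):
            th = np.exp(log_th)
            return float(np.sum((y - mu) ** 2 / (mu + mu**2 / th))) - dof

        lo, hi = np.log(1e-3), np.log(1e6)
        try:
            if pearson_gap(lo) * pearson_gap(hi) < 0:
                new_theta = float(np.exp(optimize.brentq(pearson_gap, lo, hi,
                                                         xtol=1e-4)))
            else:
                # under/over-dispersion off the bracket: pin to boundary
                new_theta = float(np.exp(hi if pearson_gap(hi) < 0 else lo))
        except ValueError:
            new_theta = theta
        if abs(np.log(new_theta) - np.log(theta)) < 1e-3:
            theta = new_theta
            break
        theta = new_theta
    fam = get_family("negative-binomial", theta=theta)
    res = PenalizedGLM(y, blocks, fam, weights=weights, offset=offset).fit()
    return res
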