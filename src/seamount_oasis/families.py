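"""Exponential-family / quasi-likelihood definitions for penalized GLM fitting.

Each family bundles a link, a variance function and a deviance, which is all
the penalized IRLS engine in :mod:`.smoothing` needs.  Families with a free
dispersion (Gaussian, Tweedie, quasi families) estimate it from the Pearson
statistic; the negative binomial profiles its shape parameter ``theta`` in an
outer moment iteration instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

_EPS = 1e-10


@dataclass
class Family:
    """A GLM family: link, variance function and deviance."""

    name: str
    link: str  # identity | log | logit
    estimate_scale: bool = True
    theta: float | None = None      # NB shape
    power: float = 1.5              # Tweedie variance power
    extra: dict = field(default_factory=dict)

    # -- link -------------------------------------------------------------
    def linkfun(self, mu: np.ndarray) -> np.ndarray:
        if self.link == "identity":
            return np.asarray(mu, dtype=float)
        if self.link == "log":
            return np.log(np.clip(mu, _EPS, None))
        if self.link == "logit":
            m = np.clip(mu, _EPS, 1 - _EPS)
            return np.log(m / (1 - m))
        raise ValueError(f"unknown link {self.link!r}")

    def linkinv(self, eta: np.ndarray) -> np.ndarray:
        if self.link == "identity":
            return np.asarray(eta, dtype=float)
        if self.link == "log":
            return np.exp(np.clip(eta, -700, 700))
        if self.link == "logit":
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        raise ValueError(f"unknown link {self.link!r}")

    def dmu_deta(self, eta: np.ndarray) -> np.ndarray:
        if self.link == "identity":
            return np.ones_like(np.asarray(eta, dtype=float))
        if self.link == "log":
            return np.exp(np.clip(eta, -700, 700))
        if self.link == "logit":
            p = self.linkinv(eta)
            return p * (1 - p)
        raise ValueError(f"unknown link {self.link!r}")

    # -- variance ----------------------------------------------------------
    def variance(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        if self.name == "gaussian":
            return np.ones_like(mu)
        if self.name == "negative-binomial":
            return mu + mu**2 / self.theta
        if self.name == "tweedie":
            return np.clip(mu, _EPS, None) ** self.power
        if self.name == "quasipoisson":
            return np.clip(mu, _EPS, None)
        if self.name in ("binomial", "quasibinomial"):
            return np.clip(mu * (1 - mu), _EPS, None)
        raise ValueError(f"unknown family {self.name!r}")

    # -- deviance ----------------------------------------------------------
    def deviance(self, y, mu, weights=None) -> float:
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        w = np.ones_like(y) if weights is None else np.asarray(weights, float)
        if self.name == "gaussian":
            d = (y - mu) ** 2
        elif self.name == "negative-binomial":
            th = self.theta
            mu = np.clip(mu, _EPS, None)
            yl = np.where(y > 0, y * np.log(np.clip(y, _EPS, None) / mu), 0.0)
            d = 2 * (yl - (y + th) * np.log((y + th) / (mu + th)))
        elif self.name == "tweedie":
            p = self.power
            mu = np.clip(mu, _EPS, None)
            d = 2 * (
                np.clip(y, 0, None) ** (2 - p) / ((1 - p) * (2 - p))
                - y * mu ** (1 - p) / (1 - p)
                + mu ** (2 - p) / (2 - p)
            )
        elif self.name == "quasipoisson":
            mu = np.clip(mu, _EPS, None)
            yl = np.where(y > 0, y * np.log(np.clip(y, _EPS, None) / mu), 0.0)
            d = 2 * (yl - (y - mu))
        elif self.name in ("binomial", "quasibinomial"):
            mu = np.clip(mu, _EPS, 1 - _EPS)
            t1 = np.where(y > 0, y * np.log(np.clip(y, _EPS, None) / mu), 0.0)
            t2 = np.where(
                y < 1, (1 - y) * np.log(np.clip(1 - y, _EPS, None) / (1 - mu)), 0.0
            )
            d = 2 * (t1 + t2)
        else:
            raise ValueError(f"unknown family {self.name!r}")
        return float(np.sum(w * np.clip(d, 0, None)))

    def initial_mu(self, y, weights=None) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.link == "logit":
            return np.clip((y + 0.5) / 2.0, 0.05, 0.95)
        if self.link == "log":
            return np.clip(y, 0.1, None) + 0.1
        return y.copy()

    def loglik(self, y, mu, scale: float = 1.0, weights=None) -> float:
        """Exact log-likelihood where it exists (Gaussian, NB); used for AICc."""
        y = np.asarray(y, dtype=float)
        mu = np.asarray(mu, dtype=float)
        if self.name == "gaussian":
            n = y.size
            rss = float(np.sum((y - mu) ** 2))
            s2 = max(rss / n, _EPS)
            return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
        if self.name == "negative-binomial":
            th = self.theta
            mu = np.clip(mu, _EPS, None)
            ll = (
                gammaln(y + th)
                - gammaln(th)
                - gammaln(y + 1)
                + th * np.log(th / (th + mu))
                + y * np.log(mu / (th + mu))
            )
            return float(np.sum(ll))
        raise NotImplementedError(
            f"exact log-likelihood not available for {self.name!r}"
        )


def get_family(tag: str, theta: float | None = None, power: float = 1.5) -> Family:
    """Build a family from a string tag.

    Parameters
    ----------
    tag : str
        One of ``gaussian``, ``negative-binomial`` (alias ``nb``), ``tweedie``,
        ``quasipoisson``, ``quasibinomial``, ``binomial``.
    theta : float, optional
        Negative-binomial shape; if omitted it is profiled during fitting.
    power : float
        Tweedie variance power, in (1, 2).
    """
    tag = tag.lower()
    aliases = {"nb": "negative-binomial", "negbin": "negative-binomial"}
    tag = aliases.get(tag, tag)
    if tag == "gaussian":
        return Family("gaussian", "identity", estimate_scale=True)
    if tag == "negative-binomial":
        if theta is not None and theta <= 0:
            raise ValueError("negative-binomial theta must be > 0")
        return Family("negative-binomial", "log", estimate_scale=False, theta=theta)
    if tag == "tweedie":
        if not 1.0 < power < 2.0:
            raise ValueError("tweedie power must lie in (1, 2)")
        return Family("tweedie", "log", estimate_scale=True, power=power)
    if tag == "quasipoisson":
        return Family("quasipoisson", "log", estimate_scale=True)
    if tag == "quasibinomial":
        return Family("quasibinomial", "logit", estimate_scale=True)
    if tag == "binomial":
        return Family("binomial", "logit", estimate_scale=False)
    raise ValueError(f"unknown family tag {tag!r}")
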