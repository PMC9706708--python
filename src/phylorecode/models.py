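"""Profile-mixture substitution models with Gamma rate variation.

A :class:`SubstitutionMixtureModel` is the generative and inferential
model used throughout the package: a symmetric exchangeability matrix
``rho`` shared across categories, a set of stationary profiles ``pi_c``
with mixture weights ``w_c`` (the CAT-style across-site compositional
heterogeneity component), and a discrete-Gamma distribution of site
rates with shape ``alpha`` and ``G`` categories.  Each per-category rate
matrix is normalized to one expected substitution per unit branch length
at its own stationary profile, so branch lengths are expected
substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammaincc, gammainc
from scipy.stats import gamma as gamma_dist

__all__ = [
    "SubstitutionMixtureModel",
    "lg_model_data",
    "discrete_gamma_rates",
    "poisson_exchangeabilities",
]

_PROFILE_FLOOR = 1e-8


def lg_model_data() -> tuple[np.ndarray, np.ndarray, str]:
    """LG exchangeabilities (20x20 symmetric), frequencies and residue order."""
    text = resources.files("phylorecode.data").joinpath("lg_model.txt").read_text()
    order = None
    freqs = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        key, _, rest = line.partition(" ")
        if key == "order":
            order = rest.split()
        elif key == "freqs":
            freqs = np.array([float(x) for x in rest.split()])
        elif key == "rates":
            rows.append([float(x) for x in rest.split()])
    k = len(order)
    rho = np.zeros((k, k))
    for i, row in enumerate(rows, start=1):
        rho[i, :i] = row
    rho = rho + rho.T
    return rho, freqs / freqs.sum(), "".join(order)


def poisson_exchangeabilities(k: int) -> np.ndarray:
    """All-equal exchangeabilities (F81/Poisson-type process)."""
    rho = np.ones((k, k))
    np.fill_diagonal(rho, 0.0)
    return rho


def discrete_gamma_rates(alpha: float, n_cats: int) -> np.ndarray:
    """Category means of the mean-1 Gamma(alpha) discretization.

    Categories are the equal-probability quantile bands; each category
    rate is the conditional mean within its band, so the rates average
    exactly 1.
    """
    if alpha <= 0:
        raise ValueError("Gamma shape must be positive")
    if n_cats == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, n_cats + 1), a=alpha, scale=1.0 / alpha)
    # E[X; a<X<b] for Gamma(alpha, 1/alpha) uses the shape alpha+1 CDF
    upper = gammainc(alpha + 1, alpha * edges[1:])
    upper[-1] = 1.0
    lower = gammainc(alpha + 1, alpha * edges[:-1])
    return n_cats * (upper - lower)


@dataclass
class SubstitutionMixtureModel:
    """Exchangeabilities + profile mixture + discrete-Gamma rates."""

    rho: np.ndarray
    profiles: np.ndarray           # (n_categories, k) stationary profiles
    weights: np.ndarray            # (n_categories,) mixture weights
    alpha: float = 0.5
    n_rate_cats: int = 4

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        k = self.rho.shape[0]
        if self.rho.shape != (k, k) or not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be square and symmetric")
        off = self.rho[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if self.profiles.shape[1] != k:
            raise ValueError("profile dimension does not match state count")
        if np.any(self.profiles <= 0):
            raise ValueError("profile entries must be strictly positive")
        if not np.allclose(self.profiles.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profiles must sum to 1")
        if self.weights.shape != (self.profiles.shape[0],):
            raise ValueError("weights length must match the number of profiles")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9) or np.any(self.weights < 0):
            raise ValueError("weights must be a simplex vector")
        if self.alpha <= 0:
            raise ValueError("Gamma shape alpha must be positive")
        if self.n_rate_cats < 1:
            raise ValueError("need at least one rate category")
        self._decomp_cache: dict[int, tuple] = {}

    # -- basic properties ---------------------------------------------
    @property
    def k(self) -> int:
        return self.rho.shape[0]

    @property
    def n_categories(self) -> int:
        return self.profiles.shape[0]

    def gamma_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_rate_cats)

    def stationary_mixture(self) -> np.ndarray:
        """Pooled stationary state frequencies sum_c w_c pi_c."""
        return self.weights @ self.profiles

    # -- rate matrices -------------------------------------------------
    def rate_matrix(self, c: int) -> np.ndarray:
        """Category-c generator, normalized to rate 1 at stationarity."""
        pi = self.profiles[c]
        q = self.rho * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(pi @ np.diag(q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return q / mu

    def _decomposition(self, c: int):
        """Eigendecomposition of Q_c via the pi-symmetrized form."""
        if c not in self._decomp_cache:
            pi = self.profiles[c]
            q = self.rate_matrix(c)
            d = np.sqrt(pi)
            s = (q * d[:, None]) / d[None, :]
            lam, v = np.linalg.eigh((s + s.T) / 2.0)
            # S = D Q D^-1 with D = diag(sqrt(pi)), so Q = (D^-1 V) L (V^T D)
            right = v / d[:, None]
            leftT = (v * d[:, None]).T
            self._decomp_cache[c] = (right, lam, leftT)
        return self._decomp_cache[c]

    def transition_matrix(self, c: int, t: float) -> np.ndarray:
        """P(t) = exp(Q_c t); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        right, lam, leftT = self._decomposition(c)
        p = (right * np.exp(lam * t)) @ leftT
        return np.clip(p, 0.0, None)

    # -- constructors --------------------------------------------------
    @classmethod
    def poisson(cls, k: int, freqs: np.ndarray | None = None, alpha: float = 0.5,
                n_rate_cats: int = 4) -> "SubstitutionMixtureModel":
        """Single-category equal-exchangeability model (F81-type)."""
        pi = np.full(k, 1.0 / k) if freqs is None else np.asarray(freqs, float)
        return cls(poisson_exchangeabilities(k), pi[None, :], np.ones(1),
                   alpha=alpha, n_rate_cats=n_rate_cats)

    @classmethod
    def lg(cls, alpha: float = 0.5, n_rate_cats: int = 4) -> "SubstitutionMixtureModel":
        rho, freqs, _ = lg_model_data()
        return cls(rho, freqs[None, :], np.ones(1), alpha=alpha,
                   n_rate_cats=n_rate_cats)

    def with_params(self, **kwargs) -> "SubstitutionMixtureModel":
        data = {"rho": self.rho, "profiles": self.profiles, "weights": self.weights,
                "alpha": self.alpha, "n_rate_cats": self.n_rate_cats}
        data.update(kwargs)
        return SubstitutionMixtureModel(**data)
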