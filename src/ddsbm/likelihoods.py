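"""Observation models, parameter priors, and the joint log score.

Three link functions map pairwise distance and type-pair parameters to
an edge distribution:

* **logistic-distance Bernoulli** — connection probability is a
  decreasing logistic in distance, rescaled into ``(p_min, p_max)``;
  per-type-pair threshold ``mu_mn`` and length scale ``lam_mn`` carry
  exponential priors whose means are global gridded hyperparameters.
* **logistic-distance Poisson** — synapse count is Poisson with rate a
  decreasing logistic in distance scaled into ``(r_min, r_mn)``; the
  logistic length scale ``lam`` is a single per-graph parameter.
* **per-component-ceiling Bernoulli** — the logistic's maximum
  probability ``p_mn`` is itself a per-type-pair parameter with a
  Beta(a, b) prior, and ``lam`` is tied to the threshold hyperprior
  (``lam = mu_hp / 10``).

All likelihood products run over observed (mask=True) off-diagonal
pairs; undirected relations use unordered pairs.  Probabilities are
clamped to ``[1e-12, 1 - 1e-12]`` before taking logs so user-supplied
extremes never produce ``-inf``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import (
    Assignment,
    ComponentParams,
    EntityGeometry,
    GriddedHyper,
    ModelState,
    Relation,
    SomaDepthModel,
    SynapseProfileModel,
)
from .priors import crp_log_prior, grid_log_prior

_PCLAMP = 1e-12


def _clamp(p):
    return np.clip(p, _PCLAMP, 1.0 - _PCLAMP)


def _exp_logpdf(x, mean):
    """Log-density of an exponential with the given MEAN (scale)."""
    x = np.asarray(x, dtype=float)
    out = -np.log(mean) - x / mean
    return np.where(x < 0, -np.inf, out)


# ---------------------------------------------------------------------------
# logistic-distance Bernoulli
# ---------------------------------------------------------------------------

def _logistic_prob_core(d, mu, lam, p_max, p_min):
    z = (np.asarray(d, dtype=float) - mu) / lam
    pstar = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
    return pstar * (p_max - p_min) + p_min


def _bernoulli_loglik_core(obs, p):
    p = _clamp(p)
    return np.where(np.asarray(obs) == 1, np.log(p), np.log1p(-p))


def logistic_bernoulli_prob(d, mu, lam, p_max=1.0, p_min=0.0):
    """Connection probability p = p* (p_max - p_min) + p_min.

    ``p* = 1 / (1 + exp((d - mu) / lam))`` decreases from p_max toward
    p_min as distance grows past the threshold ``mu``.
    """
    lam = np.asarray(lam, dtype=float)
    if (lam <= 0).any() if lam.ndim else lam <= 0:
        raise ValueError("lam must be positive")
    return _logistic_prob_core(d, mu, lam, p_max, p_min)


def logistic_bernoulli_loglik(obs, d, mu, lam, p_max=1.0, p_min=0.0):
    """Bernoulli log-pmf of ``obs`` in {0,1} at the logistic-distance prob."""
    obs = np.asarray(obs)
    if not np.isin(obs, (0, 1)).all():
        raise ValueError("bernoulli observations must be 0 or 1")
    return _bernoulli_loglik_core(obs, logistic_bernoulli_prob(d, mu, lam, p_max, p_min))


def eta_log_prior_logistic(mu, lam, mu_hp, lam_hp):
    """Exponential log-priors on (mu_mn, lam_mn); hyperparameters are means."""
    if np.any(np.asarray(mu) < 0) or np.any(np.asarray(lam) < 0):
        raise ValueError("mu and lam must be nonnegative")
    return _exp_logpdf(mu, mu_hp) + _exp_logpdf(lam, lam_hp)


# ---------------------------------------------------------------------------
# logistic-distance Poisson
# ---------------------------------------------------------------------------

def logistic_poisson_rate(d, mu, r, lam, r_min=0.01):
    """Rate r = r* (r_mn - r_min) + r_min with r* a logistic in distance."""
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("lam must be positive")
    if np.any(np.asarray(r) <= r_min):
        raise ValueError("r_mn must exceed r_min")
    z = (np.asarray(d, dtype=float) - mu) / lam
    rstar = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
    return rstar * (r - r_min) + r_min


def logistic_poisson_loglik(count, d, mu, r, lam, r_min=0.01):
    """Poisson log-pmf of ``count`` at the logistic-distance rate."""
    count = np.asarray(count)
    if (count < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = logistic_poisson_rate(d, mu, r, lam, r_min)
    return count * np.log(rate) - rate - gammaln(count + 1.0)


# ---------------------------------------------------------------------------
# per-component-ceiling Bernoulli
# ---------------------------------------------------------------------------

def percomp_pmax_bernoulli_prob(d, p, mu, lam, p_min=0.001):
    """Logistic-distance probability with per-type-pair ceiling ``p_mn``."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("per-component ceiling p must lie in (0, 1)")
    z = (np.asarray(d, dtype=float) - mu) / lam
    pstar = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
    return pstar * (p - p_min) + p_min


def beta_log_prior(p, a_hp, b_hp):
    """Beta(a, b) log-density of the per-component ceiling on (0, 1)."""
    p = np.asarray(p, dtype=float)
    lbeta = gammaln(a_hp) + gammaln(b_hp) - gammaln(a_hp + b_hp)
    return (a_hp - 1) * np.log(p) + (b_hp - 1) * np.log1p(-p) - lbeta


def percomp_pmax_log_prior(p, mu, a_hp, b_hp, mu_hp):
    """Beta(a, b) log-prior on the ceiling + exponential prior on mu_mn."""
    return beta_log_prior(p, a_hp, b_hp) + _exp_logpdf(mu, mu_hp)


# ---------------------------------------------------------------------------
# feature models
# ---------------------------------------------------------------------------

def soma_depth_loglik(depths, mu_hp, kappa_hp, sigma2_hp, nu_hp):
    """Collapsed marginal likelihood of one type's soma depths.

    The per-type (mean, variance) carry a conjugate normal–scaled-
    inverse-chi-squared prior, NIX(mu_hp, kappa_hp, sigma2_hp, nu_hp),
    and are integrated out analytically.  An empty type has marginal 1
    (log 0).
    """
    x = np.asarray(depths, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n == 0:
        return 0.0
    xbar = x.mean()
    ss = ((x - xbar) ** 2).sum()
    kappa_n = kappa_hp + n
    nu_n = nu_hp + n
    nu_sig_n = nu_hp * sigma2_hp + ss + kappa_hp * n * (xbar - mu_hp) ** 2 / kappa_n
    return float(
        gammaln(nu_n / 2.0)
        - gammaln(nu_hp / 2.0)
        + 0.5 * (np.log(kappa_hp) - np.log(kappa_n))
        + (nu_hp / 2.0) * np.log(nu_hp * sigma2_hp)
        - (nu_n / 2.0) * np.log(nu_sig_n)
        - (n / 2.0) * np.log(np.pi)
    )


def synapse_profile_loglik(points, means, weights, sigma2):
    """Mixture-of-Gaussians log-likelihood of one entity's synapse depths."""
    points = np.asarray(points, dtype=float)
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if means.size > SynapseProfileModel.MAX_MODES:
        raise ValueError("synapse profile supports at most 3 modes")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if points.size == 0:
        return 0.0
    z = points[:, None] - means[None, :]
    comp = -0.5 * z * z / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
    lw = np.log(_clamp(weights))
    return float(logsumexp(comp + lw[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# observation-model plumbing shared with the samplers
# ---------------------------------------------------------------------------

LOGISTIC_BERNOULLI = "logistic_bernoulli"
LOGISTIC_POISSON = "logistic_poisson"
PERCOMP_PMAX = "percomp_pmax"


def _grid_width(grid) -> float:
    """Slice-width scale from a hyper grid; degenerate grids fall back to
    the grid's magnitude so single-point grids still mix."""
    w = float(grid.max() - grid.min())
    return w if w > 0 else float(grid.max())


class ObsModel:
    """Vectorized interface one link-function family exposes to the samplers."""

    name: str
    param_names: tuple[str, ...]
    #: hyper grid names entering the edge likelihood (Gibbs needs refits)
    theta_lik_names: tuple[str, ...]
    #: hyper grid names entering only the eta prior
    theta_prior_names: tuple[str, ...]

    def loglik(self, obs, d, params: dict, hyper: GriddedHyper):
        raise NotImplementedError

    def link_prob(self, d, params: dict, hyper: GriddedHyper):
        """P(edge present): Bernoulli prob, or 1 - exp(-rate) for counts."""
        raise NotImplementedError

    def param_log_prior(self, params: dict, hyper: GriddedHyper):
        raise NotImplementedError

    def sample_params(self, shape, hyper: GriddedHyper, rng):
        raise NotImplementedError

    def slice_bounds(self, pname: str, hyper: GriddedHyper):
        """(lo, hi, width) bracket for slice-sampling parameter ``pname``."""
        raise NotImplementedError

    def param_log_prior_scalar(self, params: dict, hyper: GriddedHyper) -> float:
        """Scalar fast path used inside the slice sampler's inner loop."""
        return float(np.sum(self.param_log_prior(
            {k: np.asarray(v) for k, v in params.items()}, hyper)))


class LogisticBernoulliModel(ObsModel):
    name = LOGISTIC_BERNOULLI
    param_names = ("mu", "lam")
    theta_lik_names = ("p_max", "p_min")
    theta_prior_names = ("mu_hp", "lam_hp")

    def loglik(self, obs, d, params, hyper):
        p = _logistic_prob_core(
            d, params["mu"], params["lam"],
            hyper.current("p_max"), hyper.current("p_min"),
        )
        return _bernoulli_loglik_core(obs, p)

    def link_prob(self, d, params, hyper):
        return logistic_bernoulli_prob(
            d, params["mu"], params["lam"],
            hyper.current("p_max"), hyper.current("p_min"),
        )

    def param_log_prior(self, params, hyper):
        return eta_log_prior_logistic(
            params["mu"], params["lam"],
            hyper.current("mu_hp"), hyper.current("lam_hp"),
        )

    def sample_params(self, shape, hyper, rng):
        return {
            "mu": rng.exponential(hyper.current("mu_hp"), size=shape),
            "lam": rng.exponential(hyper.current("lam_hp"), size=shape),
        }

    def slice_bounds(self, pname, hyper):
        grid = hyper.grids["mu_hp" if pname == "mu" else "lam_hp"]
        return 1e-6, np.inf, _grid_width(grid)

    def param_log_prior_scalar(self, params, hyper):
        mu_hp = hyper.current("mu_hp")
        lam_hp = hyper.current("lam_hp")
        mu, lam = params["mu"], params["lam"]
        if mu < 0 or lam < 0:
            return -np.inf
        return (-np.log(mu_hp) - mu / mu_hp) + (-np.log(lam_hp) - lam / lam_hp)


class LogisticPoissonModel(ObsModel):
    name = LOGISTIC_POISSON
    param_names = ("mu", "r")
    theta_lik_names = ("lam",)
    theta_prior_names = ("mu_hp", "ratescale_hp")

    def loglik(self, obs, d, params, hyper):
        return logistic_poisson_loglik(
            obs, d, params["mu"], params["r"],
            hyper.current("lam"), hyper.current("rate_min"),
        )

    def link_prob(self, d, params, hyper):
        rate = logistic_poisson_rate(
            d, params["mu"], params["r"],
            hyper.current("lam"), hyper.current("rate_min"),
        )
        return -np.expm1(-rate)

    def param_log_prior(self, params, hyper):
        return _exp_logpdf(params["mu"], hyper.current("mu_hp")) + _exp_logpdf(
            params["r"], hyper.current("ratescale_hp")
        )

    def sample_params(self, shape, hyper, rng):
        r_min = hyper.current("rate_min")
        r = rng.exponential(hyper.current("ratescale_hp"), size=shape)
        return {
            "mu": rng.exponential(hyper.current("mu_hp"), size=shape),
            "r": np.maximum(r, r_min + 1e-6),
        }

    def slice_bounds(self, pname, hyper):
        if pname == "mu":
            return 1e-6, np.inf, _grid_width(hyper.grids["mu_hp"])
        grid = hyper.grids["ratescale_hp"]
        return hyper.current("rate_min") + 1e-6, np.inf, _grid_width(grid)

    def param_log_prior_scalar(self, params, hyper):
        mu_hp = hyper.current("mu_hp")
        r_hp = hyper.current("ratescale_hp")
        mu, r = params["mu"], params["r"]
        if mu < 0 or r < 0:
            return -np.inf
        return (-np.log(mu_hp) - mu / mu_hp) + (-np.log(r_hp) - r / r_hp)


class PercompPmaxModel(ObsModel):
    name = PERCOMP_PMAX
    param_names = ("p", "mu")
    theta_lik_names = ("mu_hp", "p_min")  # lam = mu_hp / 10 enters the likelihood
    theta_prior_names = ("a_hp", "b_hp")

    @staticmethod
    def _lam(hyper):
        return hyper.current("mu_hp") / 10.0

    def loglik(self, obs, d, params, hyper):
        p = _clamp(
            percomp_pmax_bernoulli_prob(
                d, params["p"], params["mu"], self._lam(hyper), hyper.current("p_min")
            )
        )
        obs = np.asarray(obs)
        return np.where(obs == 1, np.log(p), np.log1p(-p))

    def link_prob(self, d, params, hyper):
        return percomp_pmax_bernoulli_prob(
            d, params["p"], params["mu"], self._lam(hyper), hyper.current("p_min")
        )

    def param_log_prior(self, params, hyper):
        return percomp_pmax_log_prior(
            params["p"], params["mu"],
            hyper.current("a_hp"), hyper.current("b_hp"), hyper.current("mu_hp"),
        )

    def sample_params(self, shape, hyper, rng):
        return {
            "p": np.clip(
                rng.beta(hyper.current("a_hp"), hyper.current("b_hp"), size=shape),
                1e-6, 1 - 1e-6,
            ),
            "mu": rng.exponential(hyper.current("mu_hp"), size=shape),
        }

    def slice_bounds(self, pname, hyper):
        if pname == "p":
            return 1e-9, 1 - 1e-9, 0.2
        return 1e-6, np.inf, _grid_width(hyper.grids["mu_hp"])


_MODELS = {
    m.name: m for m in (LogisticBernoulliModel(), LogisticPoissonModel(), PercompPmaxModel())
}


def get_obs_model(name: str) -> ObsModel:
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(f"unknown observation model {name!r}") from None


# ---------------------------------------------------------------------------
# dataset container and whole-relation likelihoods
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Everything the sampler conditions on: graphs, geometry, features."""

    relations: list[Relation]
    geometry: EntityGeometry
    models: Optional[list[str]] = None
    soma: Optional[SomaDepthModel] = None
    synapse_profiles: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.models is None:
            self.models = [
                LOGISTIC_POISSON if r.obs_kind == "poisson" else LOGISTIC_BERNOULLI
                for r in self.relations
            ]

    @property
    def n(self) -> int:
        return self.geometry.n


def _pair_selector(relation: Relation) -> np.ndarray:
    """Boolean N x N selector of pairs entering the likelihood product."""
    n = relation.n
    sel = relation.mask & ~np.eye(n, dtype=bool)
    if not relation.directed:
        sel = sel & np.triu(np.ones((n, n), dtype=bool), k=1)
    return sel


def relation_loglik(
    relation: Relation,
    geometry: EntityGeometry,
    assignment: Assignment,
    params: ComponentParams,
    hyper: GriddedHyper,
    model: Optional[str] = None,
) -> float:
    """Log-likelihood of one relation: sum over observed off-diagonal pairs."""
    if relation.n != geometry.n or relation.n != assignment.n:
        raise ValueError("relation, geometry and assignment dimensions differ")
    om = get_obs_model(
        model or (LOGISTIC_POISSON if relation.obs_kind == "poisson" else LOGISTIC_BERNOULLI)
    )
    sel = _pair_selector(relation)
    i, j = np.nonzero(sel)
    if i.size == 0:
        return 0.0
    c = assignment.labels
    pij = {name: tab[c[i], c[j]] for name, tab in params.tables.items()}
    ll = om.loglik(relation.matrix[i, j], geometry.distances[i, j], pij, hyper)
    return float(ll.sum())


def joint_log_score(data: Dataset, state: ModelState, temperature: Optional[float] = None) -> float:
    """Unnormalized log posterior of the joint state.

    The likelihood terms (edges and features) are divided by the
    temperature; the CRP prior, parameter priors and uniform grid
    hyperpriors are not tempered.
    """
    T = state.temperature if temperature is None else temperature
    lik = 0.0
    prior = 0.0
    c = state.assignment
    for q, rel in enumerate(data.relations):
        om = get_obs_model(data.models[q])
        lik += relation_loglik(
            rel, data.geometry, c, state.component_params[q], state.hyper[q], data.models[q]
        )
        tabs = state.component_params[q].tables
        lp = om.param_log_prior(tabs, state.hyper[q])
        if rel.directed:
            prior += float(np.sum(lp))
        else:
            prior += float(np.sum(np.triu(lp)))
        prior += grid_log_prior(state.hyper[q])
    if state.soma is not None:
        for k in range(c.k):
            lik += soma_depth_loglik(
                state.soma.depths[c.labels == k],
                state.soma.mu_hp, state.soma.kappa_hp,
                state.soma.sigma2_hp, state.soma.nu_hp,
            )
    if state.synapse is not None and data.synapse_profiles is not None:
        sp = state.synapse
        for i, pts in enumerate(data.synapse_profiles):
            k = c.labels[i]
            lik += synapse_profile_loglik(pts, sp.means[k], sp.weights[k], sp.sigma2)
    prior += crp_log_prior(c, state.alpha.current("alpha"))
    prior += grid_log_prior(state.alpha)
    return lik / T + prior


__all__ = [
    "logistic_bernoulli_prob",
    "logistic_bernoulli_loglik",
    "eta_log_prior_logistic",
    "logistic_poisson_rate",
    "logistic_poisson_loglik",
    "percomp_pmax_bernoulli_prob",
    "beta_log_prior",
    "percomp_pmax_log_prior",
    "soma_depth_loglik",
    "synapse_profile_loglik",
    "relation_loglik",
    "joint_log_score",
    "Dataset",
    "ObsModel",
    "get_obs_model",
    "LOGISTIC_BERNOULLI",
    "LOGISTIC_POISSON",
    "PERCOMP_PMAX",
]
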