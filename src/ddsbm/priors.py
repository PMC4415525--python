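"""Chinese-restaurant-process partition prior and gridded hyperpriors.

The number of types is not fixed: assignments carry a CRP prior with
concentration alpha, so the probability of joining an existing type is
proportional to its current size and the probability of opening a new
type is proportional to alpha.  Global hyperparameters take values on
finite log10-spaced grids with a uniform hyperprior, which keeps their
Gibbs updates exact.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .core import Assignment, GriddedHyper


def crp_log_prior(assignment: Assignment, alpha: float) -> float:
    """Log-probability of the partition under a CRP(alpha).

    ``alpha^K * prod_k (N_k - 1)! / prod_{n=0}^{N-1} (alpha + n)``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    counts = assignment.counts()
    n = assignment.n
    k = counts.size
    return float(
        k * np.log(alpha)
        + gammaln(counts).sum()
        - (gammaln(alpha + n) - gammaln(alpha))
    )


def crp_conditional(counts_minus_i: np.ndarray, alpha: float) -> np.ndarray:
    """Unnormalized Gibbs weights: m_k per existing class, alpha for a new one."""
    counts = np.asarray(counts_minus_i, dtype=float)
    return np.concatenate([counts, [alpha]])


def grid_log_prior(hyper: GriddedHyper) -> float:
    """Uniform hyperprior over the Cartesian product of all grids."""
    total = 0.0
    for name, g in hyper.grids.items():
        if g.size == 0:
            raise ValueError(f"empty grid {name!r}")
        total -= np.log(g.size)
    return float(total)


def make_grid(lo: float, hi: float, n: int, spacing: str = "log10") -> np.ndarray:
    """n log10-spaced points from lo to hi inclusive, ascending."""
    if lo <= 0:
        raise ValueError("grid endpoints must be positive")
    if hi <= lo or n < 2:
        raise ValueError("need hi > lo and n >= 2")
    if spacing != "log10":
        raise ValueError(f"unsupported spacing {spacing!r}")
    return np.logspace(np.log10(lo), np.log10(hi), n)


# Default alpha grid spans under- to over-partitioning regimes
# symmetrically in log space.
DEFAULT_ALPHA_GRID = (0.1, 0.3, 1.0, 3.0, 10.0)


def default_alpha_hyper(grid=DEFAULT_ALPHA_GRID, start: float = 1.0) -> GriddedHyper:
    g = np.asarray(grid, dtype=float)
    return GriddedHyper({"alpha": g}, idx={"alpha": int(np.argmin(np.abs(g - start)))})


def default_hyper(model: str, distance_scale: float = 80.0) -> GriddedHyper:
    """Reference hyperprior grids per link-function family.

    ``distance_scale`` sets the upper end of the threshold / length-scale
    grids (e.g. ~80 um for a retinal patch, 2.0 for a normalized body
    axis, 500 for microprocessor layout units); grids are 40-point
    log10-spaced for the Bernoulli model, 20-point for the Poisson
    model, 50-point for the per-component-ceiling model.
    """
    if model == "logistic_bernoulli":
        g = make_grid(distance_scale / 80.0, distance_scale, 40)
        return GriddedHyper(
            {
                "mu_hp": g,
                "lam_hp": g.copy(),
                "p_max": np.array([0.95, 0.9, 0.7]),
                "p_min": np.array([0.001, 0.01, 0.02]),
            },
            idx={"mu_hp": 20, "lam_hp": 20, "p_max": 0, "p_min": 1},
        )
    if model == "logistic_poisson":
        g = make_grid(distance_scale / 10.0, distance_scale, 20)
        return GriddedHyper(
            {
                "mu_hp": g,
                "lam": g.copy(),
                "ratescale_hp": make_grid(2.0, 20.0, 20),
            },
            idx={"mu_hp": 10, "lam": 10, "ratescale_hp": 10},
            fixed={"rate_min": 0.01},
        )
    if model == "percomp_pmax":
        return GriddedHyper(
            {
                "mu_hp": make_grid(distance_scale / 50.0, distance_scale, 50),
                "p_min": np.array([0.001, 0.01, 0.02]),
                "a_hp": np.array([0.1, 1.0, 2.0]),
                "b_hp": np.array([0.1, 1.0, 2.0]),
            },
            idx={"mu_hp": 25, "p_min": 1, "a_hp": 1, "b_hp": 1},
        )
    raise ValueError(f"unknown model {model!r}")


__all__ = [
    "crp_log_prior",
    "crp_conditional",
    "grid_log_prior",
    "make_grid",
    "default_alpha_hyper",
    "default_hyper",
    "DEFAULT_ALPHA_GRID",
]
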