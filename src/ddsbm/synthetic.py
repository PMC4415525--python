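"""Synthetic-data generators for validation experiments.

Four generator families cover the model-match and model-mismatch
studies: the distance-dependent block model itself, a plain (distance-
blind) stochastic block model, a mixed-membership block model, and a
latent-position cluster model.  A feature generator produces per-type
soma depths and synapse depth profiles, and a circular windowing
operator emulates the edge effects of reconstructing only part of a
tissue volume.

All generators are deterministic given their seed.  Default parameters
aim for moderate edge density (roughly 0.05-0.3) with well-separated,
identifiable types.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (
    Assignment,
    EntityGeometry,
    Relation,
    SomaDepthModel,
    SyntheticTruth,
)
from .likelihoods import (
    Dataset,
    logistic_bernoulli_prob,
    logistic_poisson_rate,
)

UNIFORM_SQUARE = "uniform_square"
UNIFORM_INTERVAL = "uniform_interval"


def _balanced_labels(n: int, k: int, rng) -> np.ndarray:
    labels = np.arange(n) % k
    return rng.permutation(labels)


def _layout_positions(n, layout, box, rng):
    if layout == UNIFORM_SQUARE:
        return rng.uniform(0, box, size=(n, 2))
    if layout == UNIFORM_INTERVAL:
        return rng.uniform(0, box, size=(n, 1))
    raise ValueError(f"unknown layout {layout!r}")


def default_dd_sbm_params(k: int, box: float = 100.0, rng=None) -> dict:
    """A random but identifiable block pattern of logistic link parameters.

    Each type pair is either "connected" (threshold ~0.4 box, so nearby
    members link with probability near p_max) or "background" (threshold
    near zero, probability near p_min).  Patterns are redrawn until all
    type rows differ, so every type is distinguishable from connectivity
    alone.
    """
    rng = np.random.default_rng(rng)
    while True:
        pattern = rng.random((k, k)) < 0.5
        pattern = np.triu(pattern) | np.triu(pattern, 1).T
        if k == 1:
            break
        # every pair of type rows must differ in >= 2 blocks
        dist = (pattern[:, None, :] != pattern[None, :, :]).sum(axis=2)
        dist[np.diag_indices(k)] = 2
        if dist.min() >= 2:
            break
    mu = np.where(pattern, 0.45 * box, 0.01 * box)
    lam = np.full((k, k), 0.02 * box)
    return {"mu": mu, "lam": lam, "p_max": 0.9, "p_min": 0.01}


def gen_dd_sbm(
    n: int,
    k: int,
    layout: str = UNIFORM_SQUARE,
    eta_truth: Optional[dict] = None,
    theta: Optional[dict] = None,
    seed: int = 0,
    box: float = 100.0,
    obs_kind: str = "bernoulli",
    directed: bool = False,
    balanced: bool = True,
    crp_alpha: float = 1.0,
):
    """Sample a distance-dependent block model instance.

    Positions are i.i.d. uniform over the layout; types are balanced
    round-robin (or CRP-sized with ``balanced=False``); each edge is
    Bernoulli at the logistic-distance probability (or Poisson at the
    logistic-distance rate) of its type pair.
    """
    if k > n:
        raise ValueError("more types than entities")
    rng = np.random.default_rng(seed)
    pos = _layout_positions(n, layout, box, rng)
    geometry = EntityGeometry(pos)
    if balanced:
        labels = _balanced_labels(n, k, rng)
    else:
        labels = _crp_sized_labels(n, k, crp_alpha, rng)
    if eta_truth is None:
        eta_truth = default_dd_sbm_params(k, box, rng=rng)
    theta = dict(theta or {})
    d = geometry.distances
    mu = np.broadcast_to(np.asarray(eta_truth["mu"], dtype=float), (k, k))
    lam = np.broadcast_to(np.asarray(eta_truth["lam"], dtype=float), (k, k))
    if obs_kind == "bernoulli":
        p_max = theta.get("p_max", eta_truth.get("p_max", 0.9))
        p_min = theta.get("p_min", eta_truth.get("p_min", 0.01))
        p = logistic_bernoulli_prob(d, mu[labels[:, None], labels[None, :]],
                                    lam[labels[:, None], labels[None, :]],
                                    p_max, p_min)
        matrix = (rng.random((n, n)) < p).astype(np.int64)
    elif obs_kind == "poisson":
        r = np.broadcast_to(np.asarray(eta_truth["r"], dtype=float), (k, k))
        r_min = theta.get("r_min", eta_truth.get("r_min", 0.01))
        rate = logistic_poisson_rate(d, mu[labels[:, None], labels[None, :]],
                                     r[labels[:, None], labels[None, :]],
                                     lam[labels[:, None], labels[None, :]].mean(),
                                     r_min)
        matrix = rng.poisson(rate)
    else:
        raise ValueError(f"unknown obs_kind {obs_kind!r}")
    if not directed:
        matrix = np.triu(matrix, 1)
        matrix = matrix + matrix.T
    np.fill_diagonal(matrix, 0)
    rel = Relation(matrix, obs_kind=obs_kind, directed=directed)
    truth = SyntheticTruth(labels, {"eta": eta_truth, "theta": theta},
                           family="dd_sbm",
                           settings={"n": n, "k": k, "layout": layout, "box": box},
                           seed=seed)
    return rel, geometry, truth


def _crp_sized_labels(n, k_hint, alpha, rng):
    # CRP-sized classes; k_hint only seeds the expectation via alpha
    labels = np.zeros(n, dtype=np.int64)
    counts = [1]
    for i in range(1, n):
        w = np.array(counts + [alpha], dtype=float)
        j = rng.choice(w.size, p=w / w.sum())
        if j == len(counts):
            counts.append(1)
        else:
            counts[j] += 1
        labels[i] = j
    return labels


def gen_sbm(n: int, k: int, p_table=None, seed: int = 0, box: float = 100.0):
    """Plain stochastic block model: distance plays no role in edges.

    Positions are still generated (uniform square) so the data can feed
    spatial diagnostics; they are independent of the graph.
    """
    rng = np.random.default_rng(seed)
    if p_table is None:
        while True:
            pattern = rng.random((k, k)) < 0.5
            pattern = np.triu(pattern) | np.triu(pattern, 1).T
            if k == 1 or len({tuple(r) for r in pattern}) == k:
                break
        p_table = np.where(pattern, 0.4, 0.02)
    p_table = np.broadcast_to(np.asarray(p_table, dtype=float), (k, k))
    if ((p_table < 0) | (p_table > 1)).any():
        raise ValueError("block probabilities must lie in [0, 1]")
    labels = _balanced_labels(n, k, rng)
    p = p_table[labels[:, None], labels[None, :]]
    matrix = (rng.random((n, n)) < p).astype(np.int64)
    matrix = np.triu(matrix, 1)
    matrix = matrix + matrix.T
    pos = rng.uniform(0, box, size=(n, 2))
    rel = Relation(matrix, obs_kind="bernoulli", directed=False)
    truth = SyntheticTruth(labels, {"p_table": np.array(p_table)}, family="sbm",
                           settings={"n": n, "k": k, "box": box}, seed=seed)
    return rel, EntityGeometry(pos), truth


def gen_mixed_membership(n: int, k: int, dirichlet_conc: float = 0.3,
                         p_table=None, seed: int = 0):
    """Mixed-membership block model: entities hold a distribution over roles.

    For each pair, each endpoint samples a role from its membership
    vector and the edge is Bernoulli at the role-pair probability.
    Truth stores the membership vectors; there is no single true K for
    partition comparison.
    """
    if k < 2:
        raise ValueError("mixed membership needs k >= 2")
    rng = np.random.default_rng(seed)
    if p_table is None:
        p_table = np.where(np.eye(k, dtype=bool), 0.4, 0.02)
    p_table = np.asarray(p_table, dtype=float)
    membership = rng.dirichlet(np.full(k, dirichlet_conc), size=n)
    matrix = np.zeros((n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, 1)
    ri = np.array([rng.choice(k, p=membership[i]) for i in iu])
    rj = np.array([rng.choice(k, p=membership[j]) for j in ju])
    e = rng.random(iu.size) < p_table[ri, rj]
    matrix[iu, ju] = e
    matrix += matrix.T
    hard = membership.argmax(axis=1)
    truth = SyntheticTruth(hard, {"membership": membership, "p_table": p_table},
                           family="mixed_membership",
                           settings={"n": n, "k": k, "conc": dirichlet_conc},
                           seed=seed)
    return Relation(matrix), truth


def gen_latent_position_cluster(n: int, k: int, dims: int = 2,
                                cluster_means=None, sigma: float = 0.5,
                                intercept: float = 1.0, seed: int = 0):
    """Latent position cluster model: type is clustered-but-continuous.

    Latent positions come from a Gaussian mixture; the probability of an
    edge is logistic(intercept - latent distance), decreasing in the
    latent (not physical) distance.
    """
    if dims < 1:
        raise ValueError("need at least one latent dimension")
    rng = np.random.default_rng(seed)
    if cluster_means is None:
        cluster_means = rng.normal(0, 2.0, size=(k, dims))
    cluster_means = np.asarray(cluster_means, dtype=float)
    labels = _balanced_labels(n, k, rng)
    z = cluster_means[labels] + rng.normal(0, sigma, size=(n, dims))
    dist = np.sqrt(((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=-1))
    p = 1.0 / (1.0 + np.exp(-(intercept - dist)))
    matrix = (rng.random((n, n)) < p).astype(np.int64)
    matrix = np.triu(matrix, 1)
    matrix = matrix + matrix.T
    truth = SyntheticTruth(labels, {"z": z, "means": cluster_means,
                                    "sigma": sigma, "intercept": intercept},
                           family="latent_position_cluster",
                           settings={"n": n, "k": k, "dims": dims}, seed=seed)
    return Relation(matrix), truth


def gen_features(truth: SyntheticTruth, depth_params=None, profile_params=None,
                 seed: int = 0):
    """Per-type soma depths and synapse depth profiles for generated data.

    ``depth_params``: per-type (mean, variance) of the soma-depth
    Gaussian (normalized depth).  ``profile_params``: per-type dict with
    ``means`` (up to 3 modes), ``weights``, ``sigma2``, and the expected
    synapse count ``n_mean``.
    """
    rng = np.random.default_rng(seed)
    labels = truth.labels
    k = int(labels.max()) + 1
    if depth_params is None:
        centers = np.linspace(0.1, 0.9, k)
        depth_params = [(c, 0.003) for c in centers]
    if profile_params is None:
        centers = np.linspace(0.1, 0.9, k)
        profile_params = [
            {"means": np.array([c, min(c + 0.3, 1.0)]),
             "weights": np.array([0.7, 0.3]),
             "sigma2": 0.005, "n_mean": 30}
            for c in centers
        ]
    depths = np.array([
        rng.normal(depth_params[c][0], np.sqrt(depth_params[c][1])) for c in labels
    ])
    profiles = []
    for c in labels:
        pp = profile_params[c]
        n_i = max(1, rng.poisson(pp["n_mean"]))
        comp = rng.choice(len(pp["weights"]), size=n_i, p=np.asarray(pp["weights"]))
        pts = rng.normal(np.asarray(pp["means"])[comp], np.sqrt(pp["sigma2"]))
        profiles.append(pts)
    return depths, profiles


def edge_effect_window(data: Dataset, center, radius: float,
                       truth: Optional[SyntheticTruth] = None):
    """Restrict a dataset to entities within ``radius`` of ``center``.

    Returns (windowed dataset, windowed truth or None, kept indices);
    relations, masks, geometry and features are all restricted to the
    induced subgraph.
    """
    center = np.asarray(center, dtype=float)
    pos = data.geometry.positions
    keep = np.flatnonzero(np.sqrt(((pos - center) ** 2).sum(axis=1)) <= radius)
    rels = []
    for rel in data.relations:
        rels.append(Relation(rel.matrix[np.ix_(keep, keep)], obs_kind=rel.obs_kind,
                             directed=rel.directed,
                             mask=rel.mask[np.ix_(keep, keep)]))
    geom = EntityGeometry(pos[keep],
                          distances=data.geometry.distances[np.ix_(keep, keep)])
    soma = None
    if data.soma is not None:
        soma = SomaDepthModel(data.soma.depths[keep], data.soma.mu_hp,
                              data.soma.kappa_hp, data.soma.sigma2_hp,
                              data.soma.nu_hp)
    profiles = None
    if data.synapse_profiles is not None:
        profiles = [data.synapse_profiles[i] for i in keep]
    sub = Dataset(rels, geom, models=list(data.models), soma=soma,
                  synapse_profiles=profiles)
    sub_truth = None
    if truth is not None:
        sub_truth = SyntheticTruth(truth.labels[keep], truth.params, truth.family,
                                   dict(truth.settings), truth.seed)
    return sub, sub_truth, keep


def connectivity_distance_variance(relation: Relation, geometry: EntityGeometry,
                                   labels, n_bins: int = 8,
                                   min_pairs_per_bin: int = 10) -> float:
    """Spatial-dependence statistic: variance of the connectivity-distance plot.

    For every type pair, off-diagonal pairs are binned by distance
    (equal-width over the observed range); bins with at least
    ``min_pairs_per_bin`` pairs contribute their empirical connection
    frequency.  The statistic is the mean, over type pairs with >= 2
    occupied bins, of the variance of those frequencies across bins.
    Distance-independent data drive it to the binomial noise floor;
    strongly logistic data push it far above.
    """
    labels = np.asarray(labels if not isinstance(labels, Assignment) else labels.labels)
    n = relation.n
    sel = relation.mask & ~np.eye(n, dtype=bool)
    if not relation.directed:
        sel &= np.triu(np.ones((n, n), dtype=bool), 1)
    i, j = np.nonzero(sel)
    d = geometry.distances[i, j]
    present = (relation.matrix[i, j] > 0).astype(float)
    edges = np.linspace(d.min(), d.max() + 1e-9, n_bins + 1)
    binid = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    variances = []
    k = int(labels.max()) + 1
    pair_type = labels[i] * k + labels[j] if relation.directed else (
        np.minimum(labels[i], labels[j]) * k + np.maximum(labels[i], labels[j])
    )
    for tp in np.unique(pair_type):
        m = pair_type == tp
        freqs = []
        for b in range(n_bins):
            mb = m & (binid == b)
            if mb.sum() >= min_pairs_per_bin:
                freqs.append(present[mb].mean())
        if len(freqs) >= 2:
            variances.append(np.var(freqs))
    if not variances:
        raise ValueError("fewer than 2 occupied distance bins for every type pair")
    return float(np.mean(variances))


__all__ = [
    "gen_dd_sbm",
    "gen_sbm",
    "gen_mixed_membership",
    "gen_latent_position_cluster",
    "gen_features",
    "edge_effect_window",
    "connectivity_distance_variance",
    "default_dd_sbm_params",
    "UNIFORM_SQUARE",
    "UNIFORM_INTERVAL",
]
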