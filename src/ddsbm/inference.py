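"""MCMC inference: composed transition kernels with likelihood annealing.

Three kernels are chained per iteration:

1. **assignments** — Gibbs sweep of the type-assignment vector using the
   auxiliary-class method for non-conjugate likelihoods (Neal's
   algorithm 8): each entity chooses among existing types (weight = the
   type's current size) and ``n_aux`` ephemeral types (weight alpha /
   n_aux each) whose link parameters are drawn fresh from the prior.
2. **eta** — univariate slice sampling of every per-type-pair link
   parameter; given the assignment the components are conditionally
   independent.
3. **hypers** — exact discrete Gibbs over the hyperparameter grids
   (concentration alpha, link-function globals, profile variance scale).

During burn-in the likelihood terms (never the priors) are divided by a
temperature that cools geometrically from ``T_start`` to 1; afterwards
the chain runs at T = 1 and its final state is one posterior sample.
Pooling many short annealed chains started from independent CRP draws
gives the sample set used for prediction; the highest-scoring sample is
the MAP estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    Assignment,
    ComponentParams,
    GriddedHyper,
    ModelState,
    SampleSet,
    SynapseProfileModel,
)
from .likelihoods import (
    Dataset,
    get_obs_model,
    joint_log_score,
    relation_loglik,
    soma_depth_loglik,
    synapse_profile_loglik,
)
from .priors import crp_log_prior, default_alpha_hyper, default_hyper


@dataclass
class InferenceConfig:
    """Sampler settings; defaults follow the reference annealed protocol."""

    n_iters_anneal: int = 900
    n_iters_post: int = 100
    t_start: float = 64.0
    t_end: float = 1.0
    n_chains: int = 20
    n_aux_classes: int = 3
    slice_width_fraction: float = 0.1
    seed: int = 0
    kernel_order: tuple[str, ...] = ("assignments", "eta", "hypers")

    def __post_init__(self) -> None:
        if not (self.t_start >= self.t_end >= 1.0):
            raise ValueError("need T_start >= T_end >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_aux_classes < 1:
            raise ValueError(
                "n_aux_classes must be >= 1: with no auxiliary classes new "
                "types would be unreachable"
            )

    @property
    def n_iters_total(self) -> int:
        return self.n_iters_anneal + self.n_iters_post


def temperature_at(iteration: int, config: InferenceConfig) -> float:
    """Geometric cooling: T_start at 0, T_end from n_iters_anneal onward."""
    if iteration < 0:
        raise ValueError("iteration must be nonnegative")
    if iteration >= config.n_iters_anneal or config.n_iters_anneal == 0:
        return config.t_end
    frac = iteration / config.n_iters_anneal
    return float(config.t_start * (config.t_end / config.t_start) ** frac)


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

def slice_sample(x0, logf, width, rng, lo=0.0, hi=np.inf, max_steps=64):
    """One univariate slice-sampling update with step-out and shrinkage."""
    y = logf(x0) + np.log(rng.random())
    u = rng.random()
    left = x0 - u * width
    right = left + width
    steps = max_steps
    while left > lo and logf(left) > y and steps > 0:
        left -= width
        steps -= 1
    steps = max_steps
    while right < hi and logf(right) > y and steps > 0:
        right += width
        steps -= 1
    left = max(left, lo)
    right = min(right, hi)
    for _ in range(max_steps):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


# ---------------------------------------------------------------------------
# state initialization and class bookkeeping
# ---------------------------------------------------------------------------

def _sample_crp_assignment(n, alpha, rng) -> np.ndarray:
    labels = np.zeros(n, dtype=np.int64)
    counts = [1]
    for i in range(1, n):
        w = np.array(counts + [alpha], dtype=float)
        k = rng.choice(w.size, p=w / w.sum())
        if k == len(counts):
            counts.append(1)
        else:
            counts[k] += 1
        labels[i] = k
    return labels


def _symmetrize(tab: np.ndarray) -> np.ndarray:
    return np.triu(tab) + np.triu(tab, 1).T


def init_state(data: Dataset, config: InferenceConfig, rng,
               hyper: list[GriddedHyper] | None = None,
               alpha: GriddedHyper | None = None) -> ModelState:
    """Random initial state: CRP assignment, parameters from their priors."""
    n = data.n
    if alpha is None:
        alpha = default_alpha_hyper()
    if hyper is None:
        off = ~np.eye(n, dtype=bool)
        dscale = float(np.percentile(data.geometry.distances[off], 95)) if n > 1 else 1.0
        hyper = [default_hyper(m, max(dscale, 1e-3)) for m in data.models]
    labels = _sample_crp_assignment(n, alpha.current("alpha"), rng)
    assignment = Assignment(labels)
    k = assignment.k
    comps = []
    for q, rel in enumerate(data.relations):
        om = get_obs_model(data.models[q])
        tabs = om.sample_params((k, k), hyper[q], rng)
        if not rel.directed:
            tabs = {name: _symmetrize(t) for name, t in tabs.items()}
        comps.append(ComponentParams(tabs))
    synapse = None
    if data.synapse_profiles is not None:
        m = 3
        sp = SynapseProfileModel(
            profiles=data.synapse_profiles,
            means=rng.uniform(0, 1, size=(k, m)),
            weights=rng.dirichlet(np.ones(m), size=k),
            sigma2=0.1,
        )
        synapse = sp
    return ModelState(
        assignment=assignment,
        component_params=comps,
        hyper=hyper,
        alpha=alpha,
        soma=data.soma,
        synapse=synapse,
        temperature=config.t_start,
    )


def _pad_classes(state: ModelState, data: Dataset, n_new: int, rng) -> None:
    """Append n_new fresh classes with parameters drawn from the priors."""
    if n_new <= 0:
        return
    k = state.component_params[0].k
    k2 = k + n_new
    for q, rel in enumerate(data.relations):
        om = get_obs_model(data.models[q])
        cp = state.component_params[q]
        fresh = om.sample_params((k2, k2), state.hyper[q], rng)
        for name, tab in cp.tables.items():
            big = fresh[name]
            big[:k, :k] = tab
            if not rel.directed:
                # upper-triangular draws are authoritative; mirror below
                big = np.triu(big) + np.triu(big, 1).T
            cp.tables[name] = big
    if state.synapse is not None:
        sp = state.synapse
        m = sp.m
        sp.means = np.vstack([sp.means, rng.uniform(0, 1, size=(n_new, m))])
        sp.weights = np.vstack([sp.weights, rng.dirichlet(np.ones(m), size=n_new)])


def _compress_classes(state: ModelState) -> None:
    """Drop empty classes and relabel contiguously, preserving order."""
    labels = state.assignment.labels
    k = state.component_params[0].k
    counts = np.bincount(labels, minlength=k)
    keep = np.flatnonzero(counts > 0)
    if keep.size == k:
        return
    remap = -np.ones(k, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    state.assignment = Assignment(remap[labels])
    for cp in state.component_params:
        cp.tables = {name: t[np.ix_(keep, keep)] for name, t in cp.tables.items()}
    if state.synapse is not None:
        state.synapse.means = state.synapse.means[keep]
        state.synapse.weights = state.synapse.weights[keep]


# ---------------------------------------------------------------------------
# kernel 1: assignment Gibbs with auxiliary classes
# ---------------------------------------------------------------------------

def _soma_stats(depths, labels, k):
    """Per-class lists of observed soma depths."""
    return [depths[(labels == m) & ~np.isnan(depths)] for m in range(k)]


def kernel_assignments(state: ModelState, data: Dataset, rng) -> ModelState:
    """One Gibbs sweep of the assignment vector (auxiliary-class method).

    For each entity the conditional mixes existing types (CRP weight =
    the type's current size) with ``n_aux`` ephemeral types (weight
    alpha / n_aux each) whose link parameters are drawn fresh from the
    prior; when removing the entity empties its type, that type's
    parameters are retained as one of the ephemeral candidates.  Tables
    are only resized when an ephemeral type is actually selected.
    """
    T = state.temperature
    n_aux = getattr(state, "_n_aux", 3)
    n = data.n
    alpha = state.alpha.current("alpha")
    soma = state.soma
    labels = state.assignment.labels
    for i in range(n):
        k = state.component_params[0].k
        counts = np.bincount(labels, minlength=k)
        counts[labels[i]] -= 1
        emptied = counts[labels[i]] == 0
        # the emptied class (params intact) serves as one auxiliary class
        n_fresh = n_aux - 1 if emptied else n_aux
        existing = np.flatnonzero(counts > 0)
        aux_in_table = [labels[i]] if emptied else []
        cand_table = np.concatenate([existing, aux_in_table]).astype(np.int64)
        n_cand = cand_table.size + n_fresh
        log_w = np.concatenate([
            np.log(counts[existing]),
            np.full(len(aux_in_table) + n_fresh, np.log(alpha / n_aux)),
        ])
        # tempered likelihood of entity i's incident observed pairs
        others = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        c_others = labels[others]
        lik = np.zeros(n_cand)
        fresh_draws = []
        for q, rel in enumerate(data.relations):
            om = get_obs_model(data.models[q])
            tabs = state.component_params[q].tables
            draws_out = om.sample_params((n_fresh, k), state.hyper[q], rng)
            draws_in = (om.sample_params((n_fresh, k), state.hyper[q], rng)
                        if rel.directed else draws_out)
            fresh_draws.append((draws_out, draws_in))
            d_row = data.geometry.distances[i, others]
            m_out = rel.mask[i, others]
            if m_out.any():
                pij = {
                    name: np.vstack([t[cand_table][:, c_others],
                                     draws_out[name][:, c_others]])
                    for name, t in tabs.items()
                }
                ll = om.loglik(rel.matrix[i, others][None, :], d_row[None, :], pij,
                               state.hyper[q])
                lik += ll[:, m_out].sum(axis=1)
            if rel.directed:
                m_in = rel.mask[others, i]
                if m_in.any():
                    pji = {
                        name: np.vstack([t[:, cand_table].T[:, c_others],
                                         draws_in[name][:, c_others]])
                        for name, t in tabs.items()
                    }
                    ll = om.loglik(rel.matrix[others, i][None, :], d_row[None, :],
                                   pji, state.hyper[q])
                    lik += ll[:, m_in].sum(axis=1)
        if soma is not None and not np.isnan(soma.depths[i]):
            si = soma.depths[i]
            hp = (soma.mu_hp, soma.kappa_hp, soma.sigma2_hp, soma.nu_hp)
            empty_delta = soma_depth_loglik([si], *hp)
            for ci in range(n_cand):
                if ci < cand_table.size:
                    m = cand_table[ci]
                    sel = labels == m
                    sel[i] = False
                    dm = soma.depths[sel]
                    dm = dm[~np.isnan(dm)]
                    lik[ci] += (soma_depth_loglik(np.append(dm, si), *hp)
                                - soma_depth_loglik(dm, *hp))
                else:
                    lik[ci] += empty_delta
        if state.synapse is not None and data.synapse_profiles is not None:
            sp = state.synapse
            pts = data.synapse_profiles[i]
            fresh_means = rng.uniform(0, 1, size=(n_fresh, sp.m))
            fresh_weights = rng.dirichlet(np.ones(sp.m), size=n_fresh)
            for ci in range(n_cand):
                if ci < cand_table.size:
                    m = cand_table[ci]
                    mm, ww = sp.means[m], sp.weights[m]
                else:
                    f = ci - cand_table.size
                    mm, ww = fresh_means[f], fresh_weights[f]
                lik[ci] += synapse_profile_loglik(pts, mm, ww, sp.sigma2)
        logp = log_w + lik / T
        w = np.exp(logp - logp.max())
        cw = np.cumsum(w)
        ci = int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))
        if ci < cand_table.size:
            labels[i] = cand_table[ci]
        else:
            # a fresh auxiliary class becomes real: grow every table by one
            f = ci - cand_table.size
            for q, rel in enumerate(data.relations):
                om = get_obs_model(data.models[q])
                cp = state.component_params[q]
                draws_out, draws_in = fresh_draws[q]
                self_draw = om.sample_params((1,), state.hyper[q], rng)
                for name, t in cp.tables.items():
                    big = np.empty((k + 1, k + 1))
                    big[:k, :k] = t
                    big[k, :k] = draws_out[name][f]
                    big[:k, k] = draws_in[name][f] if rel.directed else draws_out[name][f]
                    big[k, k] = self_draw[name][0]
                    cp.tables[name] = big
            if state.synapse is not None:
                sp = state.synapse
                sp.means = np.vstack([sp.means, fresh_means[f][None, :]])
                sp.weights = np.vstack([sp.weights, fresh_weights[f][None, :]])
            labels[i] = k
        _compress_classes(state)
        labels = state.assignment.labels
    return state


# ---------------------------------------------------------------------------
# kernel 2: slice sampling of per-component link parameters
# ---------------------------------------------------------------------------

def _component_pairs(rel, labels, m, n_):
    """Index arrays of the observed pairs in block (m, n)."""
    rows = np.flatnonzero(labels == m)
    cols = np.flatnonzero(labels == n_)
    sub_mask = rel.mask[np.ix_(rows, cols)].copy()
    if m == n_:
        if rel.directed:
            np.fill_diagonal(sub_mask, False)
        else:
            sub_mask &= np.triu(np.ones_like(sub_mask), k=1).astype(bool)
    ri, ci = np.nonzero(sub_mask)
    return rows[ri], cols[ci]


def kernel_eta(state: ModelState, data: Dataset, rng,
               slice_width_fraction: float = 0.1) -> ModelState:
    """Slice-sample every per-type-pair parameter of every relation."""
    T = state.temperature
    labels = state.assignment.labels
    k = state.component_params[0].k
    for q, rel in enumerate(data.relations):
        om = get_obs_model(data.models[q])
        hyper = state.hyper[q]
        tabs = state.component_params[q].tables
        for m in range(k):
            n_range = range(k) if rel.directed else range(m, k)
            for n_ in n_range:
                ii, jj = _component_pairs(rel, labels, m, n_)
                obs = rel.matrix[ii, jj]
                dd = data.geometry.distances[ii, jj]
                cur = {name: float(tabs[name][m, n_]) for name in om.param_names}
                for pname in om.param_names:
                    lo, hi, rng_width = om.slice_bounds(pname, hyper)
                    width = slice_width_fraction * rng_width

                    def logf(x, _pname=pname):
                        trial = dict(cur)
                        trial[_pname] = x
                        lp = om.param_log_prior_scalar(trial, hyper)
                        if not np.isfinite(lp):
                            return -np.inf
                        if obs.size:
                            lp += float(om.loglik(obs, dd, trial, hyper).sum()) / T
                        return lp

                    cur[pname] = slice_sample(cur[pname], logf, width, rng, lo, hi)
                for name in om.param_names:
                    tabs[name][m, n_] = cur[name]
                    if not rel.directed:
                        tabs[name][n_, m] = cur[name]
    if state.synapse is not None and data.synapse_profiles is not None:
        _update_synapse_profiles(state, data, rng)
    return state


def _class_profile_loglik(state, data, m, means, weights):
    sp = state.synapse
    total = 0.0
    for i in np.flatnonzero(state.assignment.labels == m):
        total += synapse_profile_loglik(data.synapse_profiles[i], means, weights,
                                        sp.sigma2)
    return total


def _update_synapse_profiles(state: ModelState, data: Dataset, rng) -> None:
    """Slice-sample mixture means; independence-MH the weights from the prior."""
    sp = state.synapse
    T = state.temperature
    k = sp.means.shape[0]
    for m in range(k):
        for j in range(sp.m):
            def logf(x, _m=m, _j=j):
                mm = sp.means[_m].copy()
                mm[_j] = x
                return _class_profile_loglik(state, data, _m, mm, sp.weights[_m]) / T

            sp.means[m, j] = slice_sample(sp.means[m, j], logf, 0.2, rng,
                                          lo=-0.5, hi=1.5)
        prop = rng.dirichlet(np.ones(sp.m))
        cur_ll = _class_profile_loglik(state, data, m, sp.means[m], sp.weights[m]) / T
        prop_ll = _class_profile_loglik(state, data, m, sp.means[m], prop) / T
        if np.log(rng.random()) < prop_ll - cur_ll:
            sp.weights[m] = prop


# ---------------------------------------------------------------------------
# kernel 3: exact Gibbs over hyperparameter grids
# ---------------------------------------------------------------------------

def _gibbs_pick(log_w, rng) -> int:
    log_w = np.asarray(log_w, dtype=float)
    cw = np.cumsum(np.exp(log_w - log_w.max()))
    return int(np.searchsorted(cw, rng.random() * cw[-1], side="right"))


def _param_prior_total(om, cp: ComponentParams, hyper, directed: bool) -> float:
    lp = om.param_log_prior(cp.tables, hyper)
    return float(np.sum(lp)) if directed else float(np.sum(np.triu(lp)))


def kernel_hypers(state: ModelState, data: Dataset, rng) -> ModelState:
    """Gibbs-sample alpha and each relation's gridded globals exactly."""
    T = state.temperature
    # concentration parameter: prior term only (never tempered)
    agrid = state.alpha.grids["alpha"]
    if agrid.size > 1:
        lw = [crp_log_prior(state.assignment, a) for a in agrid]
        state.alpha.idx["alpha"] = _gibbs_pick(lw, rng)
    for q, rel in enumerate(data.relations):
        om = get_obs_model(data.models[q])
        hyper = state.hyper[q]
        cp = state.component_params[q]
        for name in om.theta_prior_names:
            grid = hyper.grids[name]
            if grid.size <= 1:
                continue
            lw = []
            for gi in range(grid.size):
                hyper.idx[name] = gi
                lw.append(_param_prior_total(om, cp, hyper, rel.directed))
            hyper.idx[name] = _gibbs_pick(lw, rng)
        for name in om.theta_lik_names:
            grid = hyper.grids[name]
            if grid.size <= 1:
                continue
            lw = []
            for gi in range(grid.size):
                hyper.idx[name] = gi
                ll = relation_loglik(rel, data.geometry, state.assignment, cp, hyper,
                                     data.models[q]) / T
                lw.append(ll + _param_prior_total(om, cp, hyper, rel.directed))
            hyper.idx[name] = _gibbs_pick(lw, rng)
    if state.synapse is not None and data.synapse_profiles is not None:
        sp = state.synapse
        cands = sp.sigma2_candidates
        if len(cands) > 1:
            lw = []
            for s2 in cands:
                old = sp.sigma2
                sp.sigma2 = s2
                tot = sum(
                    _class_profile_loglik(state, data, m, sp.means[m], sp.weights[m])
                    for m in range(sp.means.shape[0])
                )
                sp.sigma2 = old
                lw.append(tot / T)
            sp.sigma2 = float(cands[_gibbs_pick(lw, rng)])
    return state


_KERNELS = {
    "assignments": lambda s, d, r, cfg: kernel_assignments(s, d, r),
    "eta": lambda s, d, r, cfg: kernel_eta(s, d, r, cfg.slice_width_fraction),
    "hypers": lambda s, d, r, cfg: kernel_hypers(s, d, r),
}


# ---------------------------------------------------------------------------
# chain drivers
# ---------------------------------------------------------------------------

def run_chain(data: Dataset, config: InferenceConfig, seed,
              hyper: list[GriddedHyper] | None = None,
              alpha: GriddedHyper | None = None,
              on_iteration=None):
    """Run one annealed chain; return (final state at T=1, log-score trace).

    The trace records the un-tempered (T = 1) joint log score after each
    iteration, so scores are comparable across the annealing schedule.
    """
    rng = np.random.default_rng(seed)
    state = init_state(data, config, rng, hyper=hyper, alpha=alpha)
    state._n_aux = config.n_aux_classes
    trace = np.empty(config.n_iters_total)
    for it in range(config.n_iters_total):
        state.temperature = max(temperature_at(it, config), 1.0)
        for kname in config.kernel_order:
            _KERNELS[kname](state, data, rng, config)
        trace[it] = joint_log_score(data, state, temperature=1.0)
        if on_iteration is not None:
            on_iteration(it, trace[it])
    state.temperature = 1.0
    return state, trace


def run_chains(data: Dataset, config: InferenceConfig) -> SampleSet:
    """Pool the final states of n_chains independently seeded chains."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    samples, scores, ids = [], [], []
    for cid, ss in enumerate(seeds):
        state, trace = run_chain(data, config, ss)
        samples.append(state)
        scores.append(float(trace[-1]))
        ids.append(cid)
    return SampleSet(samples=samples, log_scores=scores, chain_ids=ids)


def map_sample(samples: SampleSet) -> ModelState:
    """Highest-scoring pooled sample; ties go to the lowest chain id."""
    if not samples.samples:
        raise ValueError("empty sample set")
    order = np.lexsort((samples.chain_ids, [-s for s in samples.log_scores]))
    return samples.samples[order[0]]


__all__ = [
    "InferenceConfig",
    "temperature_at",
    "slice_sample",
    "init_state",
    "kernel_assignments",
    "kernel_eta",
    "kernel_hypers",
    "run_chain",
    "run_chains",
    "map_sample",
]
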