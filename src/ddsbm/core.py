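"""Core domain types for distance-dependent infinite stochastic block models.

The model treats a connectome as one or more square relations (binary
adjacency or synapse counts) over the same N entities, together with a
pairwise distance structure and optional per-entity laminar features
(soma depth, synapse depth profiles).  A model state couples a partition
of the entities into types with per-type-pair link-function parameters,
gridded global hyperparameters, and an annealing temperature.

Type labels are contiguous 0-based integers ``0..K-1``; kernels relabel
after every sweep so empty types never persist.  Self-pairs ``(i, i)``
are excluded from every likelihood product: the model describes
connections between distinct cells and the diagonal has no defined
semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

BERNOULLI = "bernoulli"
POISSON = "poisson"

#: supported observation models for a relation
OBS_KINDS = (BERNOULLI, POISSON)


@dataclass
class Relation:
    """One observed graph over N entities.

    Parameters
    ----------
    matrix
        N x N observations; binary {0, 1} for ``bernoulli``, nonnegative
        integer counts for ``poisson``.
    obs_kind
        ``"bernoulli"`` or ``"poisson"``.
    directed
        Whether ordered pairs carry distinct observations.  Undirected
        relations must have symmetric ``matrix`` and ``mask``.
    mask
        N x N boolean; True marks a pair as observed.  Held-out pairs
        (link prediction) are simply False here and contribute nothing
        to the likelihood.
    """

    matrix: np.ndarray
    obs_kind: str = BERNOULLI
    directed: bool = False
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.mask is None:
            self.mask = np.ones(self.matrix.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self) -> list[str]:
        v: list[str] = []
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            v.append(f"relation matrix is not square: shape {m.shape}")
            return v
        if self.mask.shape != m.shape:
            v.append(f"mask shape {self.mask.shape} != matrix shape {m.shape}")
        if self.obs_kind not in OBS_KINDS:
            v.append(f"unknown obs_kind {self.obs_kind!r}")
        elif self.obs_kind == BERNOULLI:
            if not np.isin(m[self.mask], (0, 1)).all():
                v.append("bernoulli relation has entries outside {0, 1}")
        else:
            vals = m[self.mask]
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                v.append("poisson relation has negative or non-integer counts")
        if not self.directed:
            if not np.array_equal(m, m.T):
                v.append("undirected relation matrix is not symmetric")
            if self.mask.shape == m.shape and not np.array_equal(self.mask, self.mask.T):
                v.append("undirected relation mask is not symmetric")
        return v


class EntityGeometry:
    """Spatial positions and the pairwise distance function.

    ``positions`` is N x D (D in {1, 2, 3}), in the units of the source
    data (micrometres, or normalized body-axis position).  Distances are
    Euclidean by default; a precomputed distance matrix may be supplied
    instead, which also supports the constant-distance ablation used to
    emulate the distance-blind block model.
    """

    def __init__(self, positions: np.ndarray, distances: Optional[np.ndarray] = None):
        positions = np.asarray(positions, dtype=float)
        if positions.ndim == 1:
            positions = positions[:, None]
        self.positions = positions
        self._distances = None if distances is None else np.asarray(distances, dtype=float)

    @property
    def distances(self) -> np.ndarray:
        # computed lazily: position-only uses never pay the N^2 cost
        if self._distances is None:
            self._distances = cdist(self.positions, self.positions)
        return self._distances

    @property
    def n(self) -> int:
        return self.positions.shape[0] if self._distances is None else self._distances.shape[0]

    def distance(self, i: int, j: int) -> float:
        return float(self.distances[i, j])

    def constant_distance(self) -> "EntityGeometry":
        """Geometry with every off-diagonal distance replaced by the mean.

        Used as the distance-blind ablation: at a single common distance
        the logistic link reduces to a free per-block connection
        probability, i.e. a plain infinite stochastic block model.
        """
        n = self.n
        off = ~np.eye(n, dtype=bool)
        d = np.full((n, n), self.distances[off].mean())
        np.fill_diagonal(d, 0.0)
        return EntityGeometry(self.positions, distances=d)

    def validate(self) -> list[str]:
        v = []
        d = self.distances
        if d.shape[0] != d.shape[1]:
            v.append("distance matrix not square")
            return v
        if not np.allclose(np.diag(d), 0.0):
            v.append("distance(i,i) != 0")
        if not np.allclose(d, d.T):
            v.append("distance matrix not symmetric")
        if (d < 0).any():
            v.append("negative distances")
        return v


@dataclass
class Assignment:
    """Partition of entities into types: contiguous labels 0..K-1."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)

    def validate(self) -> list[str]:
        v = []
        if self.labels.size == 0:
            return ["empty assignment"]
        if self.labels.min() < 0:
            v.append("negative type label")
            return v
        if (self.counts() == 0).any():
            empty = np.flatnonzero(self.counts() == 0)
            v.append(f"empty type(s): {empty.tolist()}")
        return v

    def relabeled(self) -> "Assignment":
        """Return an equivalent assignment with contiguous labels 0..K-1."""
        _, inv = np.unique(self.labels, return_inverse=True)
        return Assignment(inv)


@dataclass
class ComponentParams:
    """Per-type-pair link-function parameters for one relation.

    ``tables`` maps parameter name (e.g. ``"mu"``, ``"lam"``, ``"r"``,
    ``"p"``) to a K x K array indexed [type of source, type of target].
    For undirected relations the tables are kept symmetric and entries
    (m, n) and (n, m) are the same parameter.
    """

    tables: dict[str, np.ndarray]

    @property
    def k(self) -> int:
        return next(iter(self.tables.values())).shape[0]

    def validate(self, directed: bool = False) -> list[str]:
        v = []
        for name, t in self.tables.items():
            if t.shape != (self.k, self.k):
                v.append(f"param table {name!r} shape {t.shape} inconsistent")
            if name == "p":
                if ((t <= 0) | (t >= 1)).any():
                    v.append(f"param table {name!r} outside (0, 1)")
            elif (t <= 0).any():
                v.append(f"param table {name!r} has nonpositive entries")
            if not directed and not np.allclose(t, t.T):
                v.append(f"param table {name!r} not symmetric for undirected relation")
        return v


@dataclass
class GriddedHyper:
    """Gridded global hyperparameters for one relation (or the CRP α).

    Each named grid is a 1-D array of admissible values together with
    the index of the currently selected value; the hyperprior is uniform
    over the Cartesian product of all grids.
    """

    grids: dict[str, np.ndarray]
    idx: dict[str, int] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grids = {k: np.asarray(v, dtype=float) for k, v in self.grids.items()}
        for name in self.grids:
            self.idx.setdefault(name, 0)

    def current(self, name: str) -> float:
        if name in self.fixed:
            return self.fixed[name]
        return float(self.grids[name][self.idx[name]])

    def validate(self) -> list[str]:
        v = []
        for name, g in self.grids.items():
            if g.size == 0:
                v.append(f"empty grid {name!r}")
                continue
            if not (0 <= self.idx[name] < g.size):
                v.append(f"grid index for {name!r} out of range")
        return v


@dataclass
class SomaDepthModel:
    """Per-type Gaussian soma depth with a conjugate NIX hyperprior.

    Hyperparameters (mu_hp, kappa_hp, sigma2_hp, nu_hp) parameterize the
    normal–scaled-inverse-chi-squared prior on each type's (mean,
    variance); the per-type parameters themselves are collapsed out
    during inference.  Depths are on a normalized [0, 1] scale.
    """

    depths: np.ndarray  # per entity; NaN = unobserved
    mu_hp: float = 0.5
    kappa_hp: float = 1.0
    sigma2_hp: float = 0.04
    nu_hp: float = 1.0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)

    def validate(self) -> list[str]:
        v = []
        if self.kappa_hp <= 0 or self.sigma2_hp <= 0 or self.nu_hp <= 0:
            v.append("soma-depth hyperparameters must be positive")
        return v


@dataclass
class SynapseProfileModel:
    """Per-type mixture-of-Gaussians synapse depth profile (M ≤ 3 modes).

    ``profiles`` lists each entity's synapse depths (normalized units).
    ``means`` is K x M, ``weights`` K x M rows on the simplex; ``sigma2``
    is a global variance scale drawn from a gridded candidate set.
    """

    profiles: list[np.ndarray]
    means: np.ndarray
    weights: np.ndarray
    sigma2: float = 0.1
    sigma2_candidates: tuple[float, ...] = (0.01, 0.1, 1.0)

    MAX_MODES = 3

    def __post_init__(self) -> None:
        self.profiles = [np.asarray(p, dtype=float) for p in self.profiles]
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.means.shape[1] > self.MAX_MODES:
            raise ValueError(
                f"synapse profile supports at most {self.MAX_MODES} modes, "
                f"got {self.means.shape[1]}"
            )

    @property
    def m(self) -> int:
        return self.means.shape[1]

    def validate(self) -> list[str]:
        v = []
        if self.sigma2 <= 0:
            v.append("synapse-profile sigma2 must be positive")
        if not np.allclose(self.weights.sum(axis=1), 1.0):
            v.append("synapse-profile weights do not sum to 1")
        if (self.weights < 0).any():
            v.append("negative synapse-profile weights")
        return v


@dataclass
class ModelState:
    """Joint MCMC state: partition, link parameters, hypers, temperature."""

    assignment: Assignment
    component_params: list[ComponentParams]
    hyper: list[GriddedHyper]
    alpha: GriddedHyper
    soma: Optional[SomaDepthModel] = None
    synapse: Optional[SynapseProfileModel] = None
    temperature: float = 1.0
    rng_seed: int = 0

    def validate(self, relations: Optional[list[Relation]] = None) -> list[str]:
        v = self.assignment.validate()
        k = self.assignment.k
        directed = [r.directed for r in relations] if relations else [True] * len(
            self.component_params
        )
        for q, cp in enumerate(self.component_params):
            v += [f"relation {q}: {msg}" for msg in cp.validate(directed=directed[q])]
            if cp.k != k:
                v.append(f"relation {q}: param table K={cp.k} != assignment K={k}")
        for q, h in enumerate(self.hyper):
            v += [f"relation {q} hyper: {msg}" for msg in h.validate()]
        v += [f"alpha: {msg}" for msg in self.alpha.validate()]
        if self.temperature < 1.0:
            v.append(f"temperature {self.temperature} < 1")
        if self.soma is not None:
            v += self.soma.validate()
        if self.synapse is not None:
            v += self.synapse.validate()
            if self.synapse.means.shape[0] != k:
                v.append("synapse-profile table K inconsistent with assignment")
        return v


@dataclass
class SampleSet:
    """Pooled posterior samples (one final state per chain) with scores."""

    samples: list[ModelState]
    log_scores: list[float]
    chain_ids: list[int]

    def __post_init__(self) -> None:
        if not (len(self.samples) == len(self.log_scores) == len(self.chain_ids)):
            raise ValueError("samples, log_scores and chain_ids must have equal length")


@dataclass
class SyntheticTruth:
    """Ground truth for generated data: assignment, parameters, provenance."""

    labels: np.ndarray
    params: dict
    family: str  # dd_sbm | sbm | mixed_membership | latent_position_cluster
    settings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def assignment(self) -> Assignment:
        return Assignment(self.labels)


def validate_state(
    state: ModelState, relations: Optional[list[Relation]] = None
) -> list[str]:
    """Collect every invariant violation in ``state``; empty list = valid."""
    return state.validate(relations)


__all__ = [
    "Relation",
    "EntityGeometry",
    "Assignment",
    "ComponentParams",
    "GriddedHyper",
    "SomaDepthModel",
    "SynapseProfileModel",
    "ModelState",
    "SampleSet",
    "SyntheticTruth",
    "validate_state",
    "BERNOULLI",
    "POISSON",
]
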