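"""Preprocessing rules for the three supported connectome dataset styles.

These loaders implement the documented conventions for turning raw
measurements into relations: contact-area thresholding for dense EM
reconstructions (retina-style), count rescaling for paired chemical /
electrical synapse graphs (worm-style), and terminal-pairing expansion
for transistor netlists (microprocessor-style).  The raw files
themselves are supplied by the user; loaders are pure functions of
their inputs.
"""

from __future__ import annotations

import numpy as np

from .core import EntityGeometry, Relation


def load_contact_area(area_matrix, soma_positions, threshold: float = 0.1):
    """Threshold a synapse-like contact-area matrix into a binary relation.

    An edge exists iff the contact area strictly exceeds ``threshold``
    (default 0.1 um^2).  Distances are Euclidean between reconstructed
    soma centers.  Returns (undirected Bernoulli Relation, geometry).
    """
    area = np.asarray(area_matrix, dtype=float)
    if area.ndim != 2 or area.shape[0] != area.shape[1]:
        raise ValueError("contact-area matrix must be square")
    if (area < 0).any():
        raise ValueError("contact areas must be nonnegative")
    area = np.maximum(area, area.T)  # contact is mutual
    matrix = (area > threshold).astype(np.int64)
    np.fill_diagonal(matrix, 0)
    geometry = EntityGeometry(np.asarray(soma_positions, dtype=float))
    if geometry.n != area.shape[0]:
        raise ValueError("soma positions do not match matrix size")
    return Relation(matrix, obs_kind="bernoulli", directed=False), geometry


def load_two_graph_counts(chemical, electrical, positions, scale: float = 4.0):
    """Prepare paired chemical (directed) / electrical (undirected) graphs.

    Counts are divided by ``scale`` (default 4.0, compensating for
    overdispersion relative to a Poisson) and rounded half-up to
    integers.  Positions are normalized anterior-posterior coordinates
    in [0, 1].  Returns ([chemical Relation, electrical Relation],
    geometry).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 1)
    if (pos < 0).any() or (pos > 1).any():
        raise ValueError("positions must lie in [0, 1]")
    chem = np.asarray(chemical, dtype=float)
    elec = np.asarray(electrical, dtype=float)
    if (chem < 0).any() or (elec < 0).any():
        raise ValueError("synapse counts must be nonnegative")
    elec = np.maximum(elec, elec.T)  # gap junctions are mutual

    def rescale(m):
        out = np.floor(m / scale + 0.5).astype(np.int64)  # round half-up
        np.fill_diagonal(out, 0)
        return out

    rel_chem = Relation(rescale(chem), obs_kind="poisson", directed=True)
    rel_elec = Relation(rescale(elec), obs_kind="poisson", directed=False)
    return [rel_chem, rel_elec], EntityGeometry(pos)


TERMINALS = ("g", "c1", "c2")
TERMINAL_PAIRINGS = (("g", "g"), ("g", "c1"), ("g", "c2"),
                     ("c1", "c1"), ("c1", "c2"), ("c2", "c2"))


def load_transistor_netlist(terminals, coordinates):
    """Expand a transistor netlist into six terminal-pairing relations.

    ``terminals`` maps (or lists, per transistor) each of the pins
    ``g``, ``c1``, ``c2`` to a net identifier; two transistors are
    connected in relation (x, y) iff one's pin x and the other's pin y
    share a net.  All six relations are symmetric binary graphs over
    the transistors; geometry comes from the layout coordinates.
    """
    if isinstance(terminals, dict):
        raise TypeError("terminals must be a sequence of per-transistor mappings")
    nets = {t: [] for t in TERMINALS}
    for ti, term in enumerate(terminals):
        for t in TERMINALS:
            if t not in term:
                raise ValueError(f"transistor {ti} missing terminal {t!r}")
            nets[t].append(term[t])
    n = len(terminals)
    net_arr = {t: np.asarray(nets[t]) for t in TERMINALS}
    relations = {}
    for x, y in TERMINAL_PAIRINGS:
        same = net_arr[x][:, None] == net_arr[y][None, :]
        matrix = (same | same.T).astype(np.int64)
        np.fill_diagonal(matrix, 0)
        relations[f"{x}{y}"] = Relation(matrix, obs_kind="bernoulli", directed=False)
    geometry = EntityGeometry(np.asarray(coordinates, dtype=float))
    if geometry.n != n:
        raise ValueError("coordinates do not match transistor count")
    return relations, geometry


__all__ = [
    "load_contact_area",
    "load_two_graph_counts",
    "load_transistor_netlist",
    "TERMINAL_PAIRINGS",
]
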