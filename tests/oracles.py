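"""Independent reference implementations used to validate the fast paths.

These are deliberately naive: explicit path enumeration for the hidden
chain, dense kernels, hand pruning.  They share only the emission
definition with the package (emissions themselves are validated against
hand-computed pruning in test_likelihood).
"""

import itertools

import numpy as np

from wgdresolve.likelihood import emission_matrix, junction_transition
from wgdresolve.pillars import n_vectors


def dense_emissions(pillar_set, tree, edge_P):
    E, log_scale = emission_matrix(pillar_set, tree, edge_P)
    return E * np.exp(log_scale)[:, None]


def brute_force_loglik(pillar_set, tree, edge_P, junctions):
    """Total likelihood by summing over every assignment-vector path."""
    E = dense_emissions(pillar_set, tree, edge_P)
    m = pillar_set.m
    V = n_vectors(pillar_set.n_genomes)
    kernels = [junction_transition(junctions, j) for j in range(m - 1)]
    total = 0.0
    for path in itertools.product(range(V), repeat=m):
        p = E[0, path[0]] / V
        for j in range(1, m):
            p *= kernels[j - 1][path[j - 1], path[j]] * E[j, path[j]]
        total += p
    return np.log(total)


def brute_force_posteriors(pillar_set, tree, edge_P, junctions):
    """Per-pillar assignment-vector posteriors by path enumeration."""
    E = dense_emissions(pillar_set, tree, edge_P)
    m = pillar_set.m
    V = n_vectors(pillar_set.n_genomes)
    kernels = [junction_transition(junctions, j) for j in range(m - 1)]
    post = np.zeros((m, V))
    for path in itertools.product(range(V), repeat=m):
        p = E[0, path[0]] / V
        for j in range(1, m):
            p *= kernels[j - 1][path[j - 1], path[j]] * E[j, path[j]]
        for j in range(m):
            post[j, path[j]] += p
    return post / post.sum(axis=1, keepdims=True)
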