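"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's computational paths:
transition probabilities come from scipy.linalg.expm (not the engine's
symmetric eigendecomposition), likelihoods from explicit enumeration of
internal-state assignments (not pruning), gamma category rates from
adaptive quadrature plus root-finding (not incomplete-gamma formulas).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.optimize import brentq

from phylodissect.models import AA_INDEX, N_STATES
from phylodissect.treeops import PhyloTree


def expm_transition(model, t: float, rate: float = 1.0) -> np.ndarray:
    """P(t*rate) via scipy's Pade-based matrix exponential."""
    return expm(model.rate_matrix * (t * rate))


def brute_force_site_lnl(aln, tree: PhyloTree, model) -> np.ndarray:
    """Per-site lnL by summing over every internal-state assignment.

    Missing leaf states contribute a factor of 1 (their transition row
    sums to one).  Only feasible for <= 5 taxa and a handful of sites.
    """
    codes = {
        taxon: [AA_INDEX.get(ch, N_STATES) for ch in row]
        for taxon, row in zip(aln.taxa, aln.rows)
    }
    internal = [n for n in tree.adj if n not in tree.labels]
    root = internal[0]
    order = tree.postorder(root)
    edges = [(par, node) for node, par in order if par is not None]
    pi = model.frequencies
    rates = model.rates
    out = np.zeros(aln.length)
    for s in range(aln.length):
        site_like = 0.0
        for rate in rates:
            pmats = {
                e: expm_transition(model, tree.adj[e[0]][e[1]], rate) for e in edges
            }
            cat_like = 0.0
            for assignment in itertools.product(range(N_STATES), repeat=len(internal)):
                state = dict(zip(internal, assignment))
                prob = pi[state[root]]
                for par, node in edges:
                    if node in tree.labels:
                        obs = codes[tree.labels[node]][s]
                        if obs == N_STATES:  # missing: marginalizes to 1
                            continue
                        prob *= pmats[(par, node)][state[par], obs]
                    else:
                        prob *= pmats[(par, node)][state[par], state[node]]
                    if prob == 0.0:
                        break
                cat_like += prob
            site_like += cat_like / len(rates)
        out[s] = math.log(site_like)
    return out


def quadrature_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-equiprobable-bin gamma rates via quadrature + root-finding."""
    pdf = lambda x: x ** (alpha - 1) * math.exp(-alpha * x) * alpha**alpha / math.gamma(alpha)
    cdf = lambda x: quad(pdf, 0, x, limit=200)[0]
    edges = [0.0]
    for m in range(1, k):
        edges.append(brentq(lambda x: cdf(x) - m / k, 1e-12, 400.0, xtol=1e-12))
    edges.append(math.inf)
    rates = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        upper = 400.0 if math.isinf(hi) else hi
        mass, _ = quad(lambda x: x * pdf(x), lo, upper, limit=200)
        rates.append(mass * k)
    return np.asarray(rates)


def all_unrooted_topologies(labels) -> list[PhyloTree]:
    """Every unrooted binary topology on the given labels (3, 15, 105, ...),
    built by inserting each new leaf into every edge; unit branch lengths."""
    labels = list(labels)
    base = PhyloTree()
    hub = base.add_node()
    for lab in labels[:3]:
        leaf = base.add_node(lab)
        base.add_edge(hub, leaf, 1.0)
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for tree in trees:
            for u, v in tree.edges():
                t = tree.copy()
                length = t.adj[u][v]
                del t.adj[u][v], t.adj[v][u]
                mid = t.add_node()
                t.add_edge(u, mid, length / 2)
                t.add_edge(mid, v, length / 2)
                leaf = t.add_node(lab)
                t.add_edge(mid, leaf, 1.0)
                nxt.append(t)
        trees = nxt
    return trees
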