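"""Maximum-likelihood engine for reversible amino-acid models.

Felsenstein pruning over site patterns with per-node log-scaling, the
discrete-gamma mixture averaged with equal category weights, coordinate-wise
Brent optimization of branch lengths against cached inside/outside partials,
alternating gamma-shape optimization, empirical-Bayes site-rate estimation,
and NJ + NNI hill-climbing tree search.

The user-facing entry point is the `TreeLikelihood` model object
(`TreeLikelihood(alignment, "LG+G4+F").fit()` returns a
`TreeLikelihoodResults` carrying the fitted tree, shape parameter, and
diagnostics); the module-level functions expose the same machinery
piecewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .models import N_STATES, SubstitutionModel, parse_model_spec
from .supermatrix import MISSING_CODE, GeneAlignment
from .treeops import PhyloTree, TreeError

MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0

__all__ = [
    "TreeLikelihood",
    "TreeLikelihoodResults",
    "SearchSettings",
    "SiteRateVector",
    "site_log_likelihoods",
    "optimize_branch_lengths",
    "optimize_parameters",
    "estimate_site_rates",
    "ml_tree_search",
    "ml_distance_matrix",
    "nj_tree",
]


class LikelihoodError(ValueError):
    pass


def _as_alignment(aln) -> GeneAlignment:
    if isinstance(aln, GeneAlignment):
        return aln
    if hasattr(aln, "as_alignment"):
        return aln.as_alignment()
    raise LikelihoodError(f"cannot interpret {type(aln).__name__} as an alignment")


def _compress(codes: np.ndarray):
    """Collapse identical columns; returns (patterns, weights, site_index)."""
    patterns, site_index, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), site_index


@dataclass
class _Env:
    """Per-tree likelihood workspace: rooted structure, inside partials
    (`up`, with edge-transformed messages `msg`), per-edge outside products
    (`out`) and per-node outside partials (`a`, including the stationary
    prior), each with log scalers."""

    order: list
    children: dict
    parent: dict
    up: dict
    sc: dict
    msg: dict
    out: dict
    out_sc: dict
    a: dict
    a_sc: dict


class _Engine:
    """Pruning workspace bound to one (alignment, tree, model) triple.

    The tree is referenced (not copied) and mutated in place by the
    optimizers.  Partials have shape (k, n_patterns, 20) with per-(category,
    pattern) log scalers.
    """

    def __init__(self, aln, tree: PhyloTree, model: SubstitutionModel, basis=None):
        aln = _as_alignment(aln)
        self.tree = tree
        self.model = model
        missing = [lab for lab in tree.labels.values() if lab not in aln.taxa]
        if missing:
            raise LikelihoodError(
                f"tree leaf {missing[0]!r} has no row in the alignment"
            )
        labels = tuple(sorted(tree.labels.values()))
        cached = getattr(aln, "_pattern_cache", None)
        if basis is not None:
            # patterns compressed over a superset of this tree's leaves
            # (used when scoring subtree reinsertions against a pruned tree)
            basis_labels, self.patterns, self.weights, self.site_index = basis
            labels = basis_labels
        elif cached is not None and cached[0] == labels:
            _, self.patterns, self.weights, self.site_index = cached
        else:
            codes = aln.to_codes()
            row_of = {t: i for i, t in enumerate(aln.taxa)}
            stacked = np.stack([codes[row_of[lab]] for lab in labels])
            self.patterns, self.weights, self.site_index = _compress(stacked)
            try:
                aln._pattern_cache = (labels, self.patterns, self.weights, self.site_index)
            except AttributeError:
                pass
        self.n_sites = self.site_index.shape[0]
        # leaf indicator partials (n_patterns, 20)
        eye = np.vstack([np.eye(N_STATES), np.ones(N_STATES)])
        label_row = {lab: i for i, lab in enumerate(labels)}
        self.leaf_part = {
            node: eye[self.patterns[label_row[lab]]]
            for node, lab in tree.labels.items()
        }
        self._labels = labels
        self._label_row = label_row
        self._eye = eye

    def basis(self):
        """Pattern basis reusable by engines over leaf subsets."""
        return (self._labels, self.patterns, self.weights, self.site_index)

    def tip_partial(self, label: str) -> np.ndarray:
        """Indicator partial (n_patterns, 20) for any taxon in the basis."""
        return self._eye[self.patterns[self._label_row[label]]]

    # -- core passes -----------------------------------------------------

    def _root(self) -> int:
        return self.tree.leaves[0]

    def _structure(self, root: int):
        order = self.tree.postorder(root)
        children: dict[int, list[int]] = {n: [] for n, _ in order}
        parent: dict[int, Optional[int]] = {}
        for node, par in order:
            parent[node] = par
            if par is not None:
                children[par].append(node)
        return order, children, parent

    def _up_pass(self, root: int, order):
        """Inside (subtree) partials for every node, children before parents.

        Leaf partials are read-only broadcast views; internal partials are
        fresh arrays, rescaled per (category, pattern) with the log scaler
        accumulated in `sc`.
        """
        k = self.model.k
        npat = self.weights.shape[0]
        zero_sc = np.zeros((k, npat))
        up: dict[int, np.ndarray] = {}
        sc: dict[int, np.ndarray] = {}
        msg: dict[int, np.ndarray] = {}  # P(t_edge) applied to up[node]
        for node, par in order:
            kids = [n for n in self.tree.adj[node] if n != par]
            if not kids:
                up[node] = np.broadcast_to(
                    self.leaf_part[node], (k, npat, N_STATES)
                )
                sc[node] = zero_sc
            else:
                if len(kids) == 1:  # rooted at a leaf
                    f = msg[kids[0]] * self.leaf_part[node][None]
                    s = sc[kids[0]]
                else:
                    f = msg[kids[0]] * msg[kids[1]]
                    s = sc[kids[0]] + sc[kids[1]]
                    for c in kids[2:]:
                        f *= msg[c]
                        s = s + sc[c]
                mx = f.max(axis=2)
                np.maximum(mx, 1e-300, out=mx)
                f /= mx[..., None]
                up[node] = f
                sc[node] = s + np.log(mx)
            if par is not None:
                pmats = self.model.transition_matrices(self.tree.adj[par][node])
                msg[node] = np.matmul(up[node], pmats.transpose(0, 2, 1))
        return up, sc, msg

    def _site_pattern_logl(self, per_category: bool = False):
        """Log-likelihood per pattern (mixed over categories unless asked)."""
        root = self._root()
        order, children, _ = self._structure(root)
        up, sc, msg = self._up_pass(root, order)
        pi = self.model.frequencies
        (c0,) = children[root]
        f = msg[c0] * self.leaf_part[root][None]
        l = f @ pi  # (k, P)
        logl = np.log(np.maximum(l, 1e-300)) + sc[c0]
        if per_category:
            return logl
        m = logl.max(axis=0)
        mixed = m + np.log(np.mean(np.exp(logl - m[None]), axis=0))
        return mixed

    def site_log_likelihoods(self) -> np.ndarray:
        return self._site_pattern_logl()[self.site_index]

    def lnl(self) -> float:
        return float(self._site_pattern_logl() @ self.weights)

    # -- branch optimization --------------------------------------------

    def _edge_environment(self, root: int):
        """Inside partials plus outside partials A[node] (including the
        stationary prior), and per-edge outside products."""
        order, children, parent = self._structure(root)
        up, sc, msg = self._up_pass(root, order)
        pi = self.model.frequencies
        a: dict[int, np.ndarray] = {}
        a_sc: dict[int, np.ndarray] = {}
        k = self.model.k
        npat = self.weights.shape[0]
        a[root] = np.broadcast_to(
            self.leaf_part[root] * pi[None, :], (k, npat, N_STATES)
        )
        a_sc[root] = np.zeros((k, npat))
        out: dict[int, np.ndarray] = {}  # outside of subtree(u), state at parent(u)
        out_sc: dict[int, np.ndarray] = {}
        for node, _ in reversed(order):  # preorder
            kids = children[node]
            for u in kids:
                o, s = a[node], a_sc[node]
                fresh = False
                for sib in kids:
                    if sib is not u:
                        if fresh:
                            o *= msg[sib]
                            s += sc[sib]
                        else:
                            o = o * msg[sib]
                            s = s + sc[sib]
                            fresh = True
                out[u] = o
                out_sc[u] = s
                pmats = self.model.transition_matrices(self.tree.adj[node][u])
                au = np.matmul(o, pmats)  # sum_j o_j P_{j i}
                mx = au.max(axis=2)
                np.maximum(mx, 1e-300, out=mx)
                au /= mx[..., None]
                a[u] = au
                a_sc[u] = s + np.log(mx)
        return _Env(order, children, parent, up, sc, msg, out, out_sc, a, a_sc)

    def mixed_site_lnl(self, l: np.ndarray, scaler: np.ndarray) -> float:
        """Total lnL from per-(category, pattern) likelihoods + log scalers."""
        logl = np.log(np.maximum(l, 1e-300)) + scaler
        m = logl.max(axis=0)
        mixed = m + np.log(np.mean(np.exp(logl - m[None]), axis=0))
        return float(mixed @ self.weights)

    def _edge_lnl(self, o, o_sc, u_part, u_sc, t: float) -> float:
        pmats = self.model.transition_matrices(t)
        v = np.matmul(u_part, pmats.transpose(0, 2, 1))
        l = np.einsum("cpi,cpi->cp", o, v)
        logl = np.log(np.maximum(l, 1e-300)) + o_sc + u_sc
        m = logl.max(axis=0)
        mixed = m + np.log(np.mean(np.exp(logl - m[None]), axis=0))
        return float(mixed @ self.weights)

    def optimize_branches(
        self,
        tol: float = 1e-4,
        max_sweeps: int = 100,
        xatol: float = 1e-6,
        edges: Optional[Iterable[tuple[int, int]]] = None,
        exact: bool = True,
    ) -> float:
        """Cycle Brent over branches until the lnL gain per sweep < tol.

        Outside partials are refreshed once per sweep; a sweep that fails
        to improve the exact lnL is reverted and redone with per-edge
        refreshes before giving up.  `exact=False` skips that guard and
        returns the last 1-D optimum instead of a full re-evaluation
        (used to rank throwaway rearrangement candidates).
        """
        target = None if edges is None else {frozenset(e) for e in edges}
        if not exact:
            value = None
            for _ in range(max_sweeps):
                v, gain = self._sweep_once(target, xatol)
                if v is None:
                    break
                value = v
                if gain < tol:
                    break
            return value
        snapshot = {
            frozenset((u, v)): self.tree.adj[u][v] for u, v in self.tree.edges()
        }
        start = self.lnl()
        for _ in range(max_sweeps):
            v, gain = self._sweep_once(target, xatol)
            if v is None or gain < tol:
                break
        final = self.lnl()
        if final < start - 1e-9:
            # stale-partial sweep degraded the exact lnL: revert and redo
            # with partials refreshed before every edge
            for e, t in snapshot.items():
                u, v = tuple(e)
                self.tree.set_length(u, v, t)
            final = self._sweep_per_edge(target, xatol)
            if final < start:
                for e, t in snapshot.items():
                    u, v = tuple(e)
                    self.tree.set_length(u, v, t)
                final = start
        return final

    def _sweep_once(self, target, xatol):
        """One pass over all (or targeted) edges against partials computed
        at sweep start.  Returns (last edge's 1-D optimum, summed per-edge
        1-D gains); the summed gain is the sweep's convergence measure —
        each edge's conditional improvement is exact at sweep start, so a
        sweep whose edges all stall has genuinely converged."""
        root = self._root()
        env = self._edge_environment(root)
        value = None
        total_gain = 0.0
        for node, _ in reversed(env.order):
            for u in env.children[node]:
                if target is not None and frozenset((node, u)) not in target:
                    continue
                value, gain = self._optimize_one_edge(
                    node, u, env.out[u], env.out_sc[u], env.up[u], env.sc[u], xatol
                )
                total_gain += gain
        return value, total_gain

    def _sweep_per_edge(self, target, xatol) -> float:
        root = self._root()
        order, children, _ = self._structure(root)
        for node, _ in reversed(order):
            for u in children[node]:
                if target is not None and frozenset((node, u)) not in target:
                    continue
                env = self._edge_environment(root)
                self._optimize_one_edge(
                    node, u, env.out[u], env.out_sc[u], env.up[u], env.sc[u], xatol
                )
        return self.lnl()

    def _optimize_one_edge(self, p, u, o, o_sc, u_part, u_sc, xatol) -> float:
        cur_t = self.tree.adj[p][u]
        cur_val = self._edge_lnl(o, o_sc, u_part, u_sc, cur_t)
        neg = lambda t: -self._edge_lnl(o, o_sc, u_part, u_sc, t)
        # bracket around the current length first; widen only if the
        # optimum presses against the trial upper bound
        upper = min(MAX_BRANCH, max(0.5, 4.0 * cur_t))
        res = minimize_scalar(
            neg, bounds=(MIN_BRANCH, upper), method="bounded",
            options={"xatol": xatol},
        )
        if upper < MAX_BRANCH and res.x > 0.9 * upper:
            res = minimize_scalar(
                neg, bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
                options={"xatol": xatol},
            )
        if -res.fun > cur_val:
            self.tree.set_length(p, u, float(res.x))
            return float(-res.fun), float(-res.fun - cur_val)
        return cur_val, 0.0

    # -- shape optimization ---------------------------------------------

    def optimize_alpha(self, xatol: float = 1e-3) -> float:
        if self.model.k < 2:
            raise LikelihoodError("alpha is undefined for k = 1")

        def neg(log_a: float) -> float:
            self.model = self.model.with_alpha(math.exp(log_a))
            return -self.lnl()

        res = minimize_scalar(
            neg,
            bounds=(math.log(0.02), math.log(50.0)),
            method="bounded",
            options={"xatol": xatol},
        )
        self.model = self.model.with_alpha(math.exp(float(res.x)))
        return -float(res.fun)


# ---------------------------------------------------------------------------
# public operations


def site_log_likelihoods(aln, tree: PhyloTree, model: SubstitutionModel):
    """Per-site log-likelihood vector and its total.

    Missing states are marginalized; the gamma mixture is averaged with
    equal weights 1/k.  The total is the plain numpy sum of the site
    vector, so the two are consistent by construction.
    """
    engine = _Engine(aln, tree, model)
    sites = engine.site_log_likelihoods()
    return sites, float(sites.sum())


def optimize_branch_lengths(
    aln, tree: PhyloTree, model: SubstitutionModel,
    tol: float = 1e-4, max_iter: int = 100,
):
    """ML branch lengths by per-branch Brent sweeps; returns (tree, lnL)."""
    tree = tree.copy()
    engine = _Engine(aln, tree, model)
    lnl = engine.optimize_branches(tol=tol, max_sweeps=max_iter)
    return tree, lnl


def optimize_parameters(
    aln, tree: PhyloTree, model: SubstitutionModel,
    optimize_alpha: bool = True, tol: float = 1e-4, max_rounds: int = 20,
):
    """Alternate branch-length sweeps with gamma-shape optimization.

    Returns (model, tree, lnL).  With k = 1 the shape is not applicable and
    only branch lengths are fitted.
    """
    tree = tree.copy()
    engine = _Engine(aln, tree, model)
    lnl = engine.optimize_branches(tol=tol)
    if not optimize_alpha or model.k < 2:
        return engine.model, tree, lnl
    for _ in range(max_rounds):
        lnl_a = engine.optimize_alpha()
        lnl_b = engine.optimize_branches(tol=tol)
        if lnl_b - lnl < tol:
            lnl = max(lnl_b, lnl)
            break
        lnl = lnl_b
    return engine.model, tree, lnl


@dataclass
class SiteRateVector:
    """Posterior-mean relative rates per column and the fastest-first ranking."""

    rates: np.ndarray

    @property
    def ranking(self) -> np.ndarray:
        """Column indices from fastest to slowest; ties keep the lower
        column index first."""
        return np.argsort(-self.rates, kind="stable")

    def removal_indices(self, fraction: float) -> np.ndarray:
        """0-based indices of the round(f*L) fastest columns."""
        if not (0 <= fraction < 1):
            raise LikelihoodError(f"removal fraction must be in [0, 1), got {fraction}")
        n = int(round(fraction * len(self.rates)))
        return self.ranking[:n]

    def kept_indices(self, fraction: float) -> np.ndarray:
        """Surviving column indices, in original order."""
        drop = set(self.removal_indices(fraction).tolist())
        return np.array(
            [i for i in range(len(self.rates)) if i not in drop], dtype=int
        )


def estimate_site_rates(aln, tree: PhyloTree, model: SubstitutionModel) -> SiteRateVector:
    """Empirical-Bayes posterior-mean relative rate of every column.

    r_hat_s = sum_m r_m P(m | x_s) with P(m | x_s) proportional to the
    category likelihood (equal priors 1/k); the analog of IQ-TREE's
    site-rate output.
    """
    if model.k < 2:
        raise LikelihoodError("site rates undefined without rate heterogeneity (k >= 2)")
    engine = _Engine(aln, tree, model)
    logl = engine._site_pattern_logl(per_category=True)  # (k, P)
    post = np.exp(logl - logl.max(axis=0, keepdims=True))
    post /= post.sum(axis=0, keepdims=True)
    rates = model.rates @ post
    return SiteRateVector(rates=rates[engine.site_index])


# ---------------------------------------------------------------------------
# distances, NJ and tree search


def ml_distance_matrix(aln, model: SubstitutionModel) -> tuple[np.ndarray, list[str]]:
    """Pairwise ML distances under the given model (Brent per pair)."""
    aln = _as_alignment(aln)
    codes = aln.to_codes()
    n = codes.shape[0]
    pi = model.frequencies
    k = model.k
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] != MISSING_CODE) & (codes[j] != MISSING_CODE)
            if not ok.any():
                dist[i, j] = dist[j, i] = 5.0
                continue
            counts = np.bincount(
                codes[i][ok].astype(int) * N_STATES + codes[j][ok].astype(int),
                minlength=N_STATES * N_STATES,
            ).reshape(N_STATES, N_STATES)

            def neg(t: float) -> float:
                p = model.transition_matrices(t).mean(axis=0)
                joint = pi[:, None] * p
                return -float((counts * np.log(np.maximum(joint, 1e-300))).sum())

            res = minimize_scalar(
                neg, bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
                options={"xatol": 1e-5},
            )
            dist[i, j] = dist[j, i] = float(res.x)
    return dist, list(aln.taxa)


def nj_tree(dist: np.ndarray, taxa: Sequence[str]) -> PhyloTree:
    """Neighbour-joining tree (scikit-bio), negative branch lengths clamped."""
    import dendropy
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    sk = skbio_nj(SkbioDM(dist, ids=list(taxa)))
    newick = str(sk).strip()
    dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    for edge in dt.preorder_edge_iter():
        if edge.length is None or edge.length < MIN_BRANCH:
            edge.length = MIN_BRANCH
    return PhyloTree.from_newick(dt.as_string(schema="newick"))


@dataclass
class SearchSettings:
    """Knobs for branch optimization and NNI search."""

    brlen_tol: float = 1e-4
    brlen_xatol: float = 1e-6
    max_sweeps: int = 100
    nni_tol: float = 1e-3
    max_nni_rounds: int = 25
    local_sweeps: int = 2
    #: rank NNI candidates by swap-only lnL and locally optimize only the
    #: best few, instead of optimizing every candidate
    prescreen: bool = False
    prescreen_keep: int = 2
    #: alternate leaf-SPR rounds (prune one leaf, reinsert on every edge)
    #: with the NNI loop; rescues placements more than one NNI move away,
    #: e.g. a lineage that must cross an unresolved region of the tree
    spr: bool = False
    #: SPR candidates fully re-optimized; swap-only scores rank insertions
    #: poorly (the gain of a better placement only appears once branch
    #: lengths adjust globally), so several candidates are carried forward
    spr_keep: int = 6

    @classmethod
    def fast(cls) -> "SearchSettings":
        """Coarse settings for bootstrap replicates and gene screening."""
        return cls(
            brlen_tol=5e-3, brlen_xatol=1e-4, max_sweeps=3,
            nni_tol=1e-2, max_nni_rounds=8, local_sweeps=1,
            prescreen=True,
        )


def _detach_leaf(tree: PhyloTree, leaf: int):
    """Copy of the tree without `leaf`; the attachment node is healed.
    Returns (pruned tree, old pendant length, nodes near the original
    position — reinsertions touching them are no-ops or NNI-reachable)."""
    t = tree.copy()
    (p,) = t.adj[leaf]
    pendant = t.adj[leaf][p]
    del t.adj[leaf]
    del t.adj[p][leaf]
    t.labels.pop(leaf)
    nbrs = list(t.adj[p].items())
    if len(nbrs) == 2:
        (a, ta), (b, tb) = nbrs
        del t.adj[a][p], t.adj[b][p], t.adj[p]
        t.node_labels.pop(p, None)
        t.adj[a][b] = ta + tb
        t.adj[b][a] = ta + tb
        origin = {a, b}
    else:
        origin = {p}
    return t, pendant, origin


def _insert_leaf(
    tree: PhyloTree, u: int, v: int, label: str, pendant: float
) -> PhyloTree:
    """Copy of the tree with a new leaf attached to the midpoint of (u, v)."""
    t = tree.copy()
    length = t.adj[u][v]
    del t.adj[u][v], t.adj[v][u]
    mid = t.add_node()
    t.add_edge(u, mid, length / 2)
    t.add_edge(mid, v, length / 2)
    leaf = t.add_node(label)
    t.add_edge(mid, leaf, max(pendant, MIN_BRANCH))
    return t


def _spr_round(aln, tree: PhyloTree, model, cur_lnl: float, s: "SearchSettings"):
    """One leaf-SPR pass: every leaf is pruned and scored for reinsertion
    at every edge not adjacent to its original position; scoring combines
    the pruned tree's inside/outside partials with the tip's message at
    the insertion midpoint, so no per-candidate engine is built.  The
    shortlist is then fully branch-re-optimized.  Returns
    (tree, lnl, improved)."""
    base = _Engine(aln, tree, model)
    basis = base.basis()
    candidates = []  # (score, order, pruned, (parent, child), label, pendant)
    for leaf in sorted(tree.leaves, key=lambda n: tree.labels[n]):
        label = tree.labels[leaf]
        pruned, pendant, origin = _detach_leaf(tree, leaf)
        ep = _Engine(aln, pruned, model, basis=basis)
        env = ep._edge_environment(ep._root())
        pmat_pend = model.transition_matrices(pendant)
        tip_msg = np.matmul(
            ep.tip_partial(label)[None], pmat_pend.transpose(0, 2, 1)
        )  # (k, P, 20)
        for node, _ in env.order:
            par = env.parent[node]
            if par is None or node in origin or par in origin:
                continue
            half = model.transition_matrices(pruned.adj[par][node] / 2)
            half_t = half.transpose(0, 2, 1)
            mid = np.matmul(env.up[node], half_t) * tip_msg
            v = np.matmul(mid, half_t)
            l = np.einsum("cpi,cpi->cp", env.out[node], v)
            score = ep.mixed_site_lnl(l, env.out_sc[node] + env.sc[node])
            candidates.append(
                (score, len(candidates), pruned, (par, node), label, pendant)
            )
    candidates.sort(key=lambda c: (-c[0], c[1]))
    best = None
    for score, _, pruned, (par, node), label, pendant in candidates[: s.spr_keep]:
        cand = _insert_leaf(pruned, par, node, label, pendant)
        engine_c = _Engine(aln, cand, model)
        exact = engine_c.optimize_branches(
            tol=s.brlen_tol, max_sweeps=max(s.max_sweeps, 3),
            xatol=s.brlen_xatol,
        )
        if best is None or exact > best[0]:
            best = (exact, cand)
    if best is not None and best[0] > cur_lnl + s.nni_tol:
        return best[1], best[0], True
    return tree, cur_lnl, False


def _canonical_internal_edges(tree: PhyloTree) -> list[tuple[int, int]]:
    keyed = []
    for u, v in tree.internal_edges():
        side = tree.side_leaves(u, v)
        keyed.append((tuple(sorted(side)), (u, v)))
    keyed.sort()
    return [e for _, e in keyed]


def ml_tree_search(
    aln,
    model: SubstitutionModel,
    start: Optional[PhyloTree] = None,
    seed: int = 0,
    settings: Optional[SearchSettings] = None,
    optimize_alpha: bool = False,
):
    """NJ start then NNI hill-climbing; returns (tree, lnL).

    Per round, both NNI neighbors of every internal edge are scored after
    re-optimizing the five branches around the focal edge; the best
    improving move is accepted and branch lengths re-swept.  Deterministic
    given the inputs.
    """
    aln = _as_alignment(aln)
    if aln.n_taxa < 4:
        raise LikelihoodError("tree search requires >= 4 taxa")
    s = settings or SearchSettings()
    if start is None:
        dist, taxa = ml_distance_matrix(aln, model)
        tree = nj_tree(dist, taxa)
    else:
        tree = start.copy()
    engine = _Engine(aln, tree, model)
    lnl = engine.optimize_branches(
        tol=s.brlen_tol, max_sweeps=s.max_sweeps, xatol=s.brlen_xatol
    )
    if optimize_alpha and model.k >= 2:
        lnl = engine.optimize_alpha()
        lnl = engine.optimize_branches(
            tol=s.brlen_tol, max_sweeps=s.max_sweeps, xatol=s.brlen_xatol
        )
        model = engine.model
    tree, lnl, model = _nni_loop(aln, tree, model, lnl, s, optimize_alpha)
    if s.spr:
        for _ in range(s.max_nni_rounds):
            tree2, lnl2, improved = _spr_round(aln, tree, model, lnl, s)
            if not improved:
                break
            engine = _Engine(aln, tree2, model)
            lnl2 = engine.optimize_branches(
                tol=s.brlen_tol, max_sweeps=s.max_sweeps, xatol=s.brlen_xatol
            )
            tree, lnl, model = _nni_loop(
                aln, tree2, model, lnl2, s, optimize_alpha
            )
    return tree, lnl


def _prescreen_nni_candidates(aln, tree, model):
    """Score every NNI rearrangement from one inside/outside pass.

    For the internal edge (v, u) with u-children x, y and v-sibling w, the
    swap y <-> w keeps every subtree's own edge length, so the candidate's
    swap-only likelihood combines the cached messages directly:
    L = a[v] * msg[y'] * P(t_uv) @ (msg[x'] * msg[w]).  Returns
    (score, order, u, v, y, w) tuples describing the swaps.
    """
    engine = _Engine(aln, tree, model)
    env = engine._edge_environment(engine._root())
    scored = []
    for u, _ in env.order:
        v = env.parent[u]
        if v is None or u in tree.labels:
            continue
        kids_u = env.children[u]
        sibs = [n for n in env.children[v] if n != u]
        if len(kids_u) != 2 or len(sibs) != 1:
            continue  # multifurcation: the NNI move is undefined here
        w = sibs[0]
        tr = model.transition_matrices(tree.adj[v][u]).transpose(0, 2, 1)
        for x, y in (kids_u, kids_u[::-1]):
            inner = np.matmul(env.msg[x] * env.msg[w], tr)
            l = np.einsum("cpi,cpi->cp", env.a[v] * env.msg[y], inner)
            score = engine.mixed_site_lnl(
                l, env.a_sc[v] + env.sc[x] + env.sc[w] + env.sc[y]
            )
            scored.append((score, len(scored), u, v, y, w))
    return scored


def _apply_swap(tree, u, v, y, w):
    """Candidate tree exchanging subtree y (child of u) with w (child of v)."""
    cand = tree.copy()
    ty, tw = cand.adj[u][y], cand.adj[v][w]
    del cand.adj[u][y], cand.adj[y][u], cand.adj[v][w], cand.adj[w][v]
    cand.add_edge(v, y, ty)
    cand.add_edge(u, w, tw)
    return cand


def _nni_loop(aln, tree, model, lnl, s: SearchSettings, optimize_alpha: bool):
    """NNI hill-climbing until no move improves lnL by more than nni_tol."""
    for _ in range(s.max_nni_rounds):
        if s.prescreen:
            scored = _prescreen_nni_candidates(aln, tree, model)
            if not scored:
                break
            scored.sort(key=lambda c: (-c[0], c[1]))
            rescored = []
            for score, _, u, v, y, w in scored[: s.prescreen_keep]:
                cand = _apply_swap(tree, u, v, y, w)
                local = [(a, b) for a in (u, v) for b in cand.adj[a]]
                engine_c = _Engine(aln, cand, model)
                engine_c.optimize_branches(
                    tol=s.brlen_tol, max_sweeps=s.local_sweeps,
                    xatol=s.brlen_xatol, edges=local, exact=False,
                )
                rescored.append((engine_c.lnl(), len(rescored), cand))
            rescored.sort(key=lambda c: (-c[0], c[1]))
            best_exact, _, best_tree = rescored[0]
        else:
            candidates = []
            for u, v in _canonical_internal_edges(tree):
                for cand in tree.nni_neighbors(u, v):
                    local = [(a, b) for a in (u, v) for b in cand.adj[a]]
                    engine_c = _Engine(aln, cand, model)
                    score = engine_c.optimize_branches(
                        tol=s.brlen_tol, max_sweeps=s.local_sweeps,
                        xatol=s.brlen_xatol, edges=local, exact=False,
                    )
                    candidates.append((score, len(candidates), cand, engine_c))
            if not candidates:
                break
            candidates.sort(key=lambda c: (-c[0], c[1]))
            best_tree = candidates[0][2]
            best_exact = candidates[0][3].lnl()  # verify the top candidate
        if best_exact <= lnl + s.nni_tol:
            break
        tree = best_tree
        engine = _Engine(aln, tree, model)
        lnl = engine.optimize_branches(
            tol=s.brlen_tol, max_sweeps=s.max_sweeps, xatol=s.brlen_xatol
        )
        if optimize_alpha and model.k >= 2:
            lnl = engine.optimize_alpha()
            model = engine.model
    return tree, lnl, model


# ---------------------------------------------------------------------------
# model-object interface


class TreeLikelihood:
    """Phylogenetic likelihood model bound to an alignment.

    Parameters
    ----------
    alignment : GeneAlignment or Supermatrix
    model : SubstitutionModel or spec string such as "LG+G4+F"
        "+F" frequencies are taken from this alignment.
    tree : optional starting tree; otherwise NJ from ML distances.
    """

    def __init__(self, alignment, model="LG+G4+F", tree: Optional[PhyloTree] = None):
        self.alignment = _as_alignment(alignment)
        if isinstance(model, str):
            model = parse_model_spec(model, alignment=self.alignment)
        self.model = model
        self.tree = tree

    def loglike(self, tree: Optional[PhyloTree] = None, model=None) -> float:
        tree = tree if tree is not None else self.tree
        if tree is None:
            raise LikelihoodError("no tree given and none attached to the model")
        return site_log_likelihoods(self.alignment, tree, model or self.model)[1]

    def site_loglikes(self, tree: Optional[PhyloTree] = None, model=None) -> np.ndarray:
        tree = tree if tree is not None else self.tree
        if tree is None:
            raise LikelihoodError("no tree given and none attached to the model")
        return site_log_likelihoods(self.alignment, tree, model or self.model)[0]

    def fit(
        self,
        start_tree: Optional[PhyloTree] = None,
        search: str = "nni",
        optimize_alpha: bool = True,
        settings: Optional[SearchSettings] = None,
        seed: int = 0,
    ) -> "TreeLikelihoodResults":
        """Fit tree and model.

        search="nni" runs the full NJ+NNI topology search; "brlens" keeps
        the given (or NJ) topology and fits branch lengths and alpha only.
        """
        start = start_tree if start_tree is not None else self.tree
        opt_a = optimize_alpha and self.model.k >= 2
        if search == "nni":
            tree, lnl = ml_tree_search(
                self.alignment, self.model, start=start, seed=seed,
                settings=settings, optimize_alpha=opt_a,
            )
            if opt_a:  # recover fitted alpha
                model, tree, lnl = optimize_parameters(
                    self.alignment, tree, self.model, optimize_alpha=True
                )
            else:
                model = self.model
        elif search == "brlens":
            if start is None:
                dist, taxa = ml_distance_matrix(self.alignment, self.model)
                start = nj_tree(dist, taxa)
            model, tree, lnl = optimize_parameters(
                self.alignment, start, self.model, optimize_alpha=opt_a
            )
        else:
            raise LikelihoodError(f"unknown search mode {search!r}")
        return TreeLikelihoodResults(model=self, fitted_model=model, tree=tree, llf=lnl)


@dataclass
class TreeLikelihoodResults:
    """Fit results: tree, substitution model with fitted alpha, lnL."""

    model: TreeLikelihood
    fitted_model: SubstitutionModel
    tree: PhyloTree
    llf: float

    @property
    def alpha(self) -> Optional[float]:
        return self.fitted_model.alpha if self.fitted_model.k >= 2 else None

    def site_loglikes(self) -> np.ndarray:
        return self.model.site_loglikes(self.tree, self.fitted_model)

    def site_rates(self) -> SiteRateVector:
        return estimate_site_rates(self.model.alignment, self.tree, self.fitted_model)

    def summary(self) -> str:
        aln = self.model.alignment
        lines = [
            "Tree likelihood results",
            "=" * 40,
            f"model:        {self.fitted_model.spec_string()}",
            f"taxa:         {aln.n_taxa}",
            f"sites:        {aln.length}",
            f"log-likelihood: {self.llf:.4f}",
        ]
        if self.alpha is not None:
            lines.append(f"gamma shape alpha: {self.alpha:.4f}")
        lines.append(f"tree length:  {self.tree.total_length():.4f}")
        lines.append(f"tree: {self.tree.to_newick()}")
        return "\n".join(lines)
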