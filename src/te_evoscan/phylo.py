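"""Distance-based phylogenetics and fixed-tree likelihood evaluation.

Topologies are estimated with neighbor-joining (deterministic Q-criterion
tie-breaking on the smallest index pair, negative branch estimates clamped
to zero), support with a seeded column bootstrap, and rooting by the
midpoint of the longest leaf-to-leaf path. Likelihoods of a fixed tree are
computed by Felsenstein pruning under GTR with optional discrete-Gamma rate
variation (equal-probability bins, mean-of-bin rates) and an optional
invariant-sites class.

Trees are held as dendropy ``Tree`` objects inside a :class:`Phylogeny`
wrapper that also carries bootstrap support per (canonical) bipartition, so
support survives rerooting unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .records import CodonAlignment
from .evometrics import DistanceMatrix, distance_matrix

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def canonical_bipartition(side, all_labels) -> frozenset:
    """Canonical key for an unrooted bipartition: the lexicographically smaller side."""
    side = frozenset(side)
    other = frozenset(all_labels) - side
    a, b = sorted(side), sorted(other)
    return side if (len(a), a) <= (len(b), b) else other


@dataclass
class Phylogeny:
    """A tree with branch lengths plus bootstrap support per bipartition."""

    tree: dendropy.Tree
    support: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def rooted(self) -> bool:
        return self.tree.is_rooted

    def node_leafset(self, node) -> frozenset:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def support_for(self, side) -> float | None:
        return self.support.get(canonical_bipartition(side, self.leaf_labels))

    def bipartitions(self) -> set[frozenset]:
        """Canonical nontrivial bipartitions induced by internal edges."""
        labels = self.leaf_labels
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = self.node_leafset(node)
            if 1 < len(side) < len(labels) - 1:
                out.add(canonical_bipartition(side, labels))
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """All leaf-to-leaf path lengths (unordered pairs, sorted key)."""
        pdm = self.tree.phylogenetic_distance_matrix()
        out = {}
        taxa = list(self.tree.taxon_namespace)
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                key = tuple(sorted((t1.label, t2.label)))
                out[key] = pdm.patristic_distance(t1, t2)
        return out

    def as_newick(self) -> str:
        """Newick string with integer-percent support as internal node labels."""
        labels = self.leaf_labels
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            sup = self.support.get(canonical_bipartition(self.node_leafset(node), labels))
            node.label = str(int(round(sup))) if sup is not None else None
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            rooting="force-rooted" if rooted else "force-unrooted",
        )
        phy = cls(tree=tree)
        labels = phy.leaf_labels
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            try:
                sup = float(node.label)
            except ValueError:
                continue
            phy.support[canonical_bipartition(phy.node_leafset(node), labels)] = sup
        return phy


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(D: DistanceMatrix) -> Phylogeny:
    """Neighbor-joining tree from a distance matrix (unrooted).

    Ties in the Q criterion are broken by the smallest (i, j) pair in the
    current working-matrix order (derived deterministically from input
    order); negative branch-length estimates are clamped to zero.
    """
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(D.ids)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    nodes = []
    for label in D.ids:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
    d = D.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best[0], best[1]] - 1e-12:
                    best = (i, j)
        i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(vi, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(vj, 0.0)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d2[m - 2, : m - 2] = d2[: m - 2, m - 2] = dnew[keep]
        d2[m - 2, m - 2] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2

    a, b, c = nodes
    va = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    vb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    vc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    center = tree.seed_node
    for node, v in ((a, va), (b, vb), (c, vc)):
        center.add_child(node)
        node.edge.length = max(v, 0.0)
    tree.update_bipartitions(suppress_unifurcations=False)
    return Phylogeny(tree=tree)


# ---------------------------------------------------------------------------
# Bootstrap


def _resample_columns(aln: CodonAlignment, rng: np.random.Generator) -> CodonAlignment:
    n = aln.n_sites
    cols = rng.integers(0, n, size=n)
    mat = np.array([list(s) for _, s in aln.records])
    res = mat[:, cols]
    # pad to a codon multiple so CodonAlignment accepts it (identity/distance
    # computations are column-wise and unaffected by within-row order)
    pad = (-res.shape[1]) % 3
    records = [
        (rec_id, "".join(row) + "-" * pad)
        for (rec_id, _), row in zip(aln.records, res)
    ]
    return CodonAlignment(records, codon_table=aln.codon_table)


def bootstrap_support(
    aln: CodonAlignment,
    n_reps: int = 100,
    seed: int = 0,
    dist_fn=None,
    model: str = "jc",
) -> Phylogeny:
    """NJ point-estimate tree with bootstrap support percentages.

    Alignment columns are resampled with replacement per replicate (seeded);
    the frequency of each bipartition across replicate NJ trees is attached
    to the point tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if dist_fn is None:
        dist_fn = lambda a: distance_matrix(a, model=model)  # noqa: E731
    point = nj_tree(dist_fn(aln))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = nj_tree(dist_fn(_resample_columns(aln, rng)))
        for bp in rep.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    point.support = {
        bp: 100.0 * counts.get(bp, 0) / n_reps for bp in point.bipartitions()
    }
    return point


# ---------------------------------------------------------------------------
# Midpoint rooting


def midpoint_root(phy: Phylogeny) -> Phylogeny:
    """Root the tree at the midpoint of the longest leaf-to-leaf path.

    Leaf-to-leaf path lengths are preserved; support (keyed by unrooted
    bipartition) carries over unchanged.
    """
    tree = phy.tree.clone(depth=1)
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")

    # distances from every node to its farthest descendant leaf, then find
    # the longest leaf-to-leaf path by brute accumulation from each leaf
    def dist_from(leaf):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            nd = stack.pop()
            nbrs = list(nd.child_nodes())
            if nd.parent_node is not None:
                nbrs.append(nd.parent_node)
            for nb in nbrs:
                if nb in dist:
                    continue
                edge = nd.edge if nb is nd.parent_node else nb.edge
                dist[nb] = dist[nd] + (edge.length or 0.0)
                stack.append(nb)
        return dist

    best = None
    for lf in leaves:
        dist = dist_from(lf)
        for other in leaves:
            if other is lf:
                continue
            key = (dist[other], sorted((lf.taxon.label, other.taxon.label)))
            if best is None or key > best[0:2]:
                best = (dist[other], key[1], lf, other, dist)
    total, _, start, end, dist = best
    if total <= 0:
        # zero-length tree: arbitrary root at the existing seed node
        tree.is_rooted = True
        return Phylogeny(tree=tree, support=dict(phy.support))

    # walk from `end` back toward `start` along parent pointers in the
    # distance map, find the edge containing the midpoint
    path = [end]
    node = end
    while node is not start:
        nbrs = list(node.child_nodes())
        if node.parent_node is not None:
            nbrs.append(node.parent_node)
        for nb in nbrs:
            edge = node.edge if nb is node.parent_node else nb.edge
            if abs(dist[nb] + (edge.length or 0.0) - dist[node]) < 1e-12 and nb not in path:
                path.append(nb)
                node = nb
                break
        else:  # pragma: no cover - defensive
            raise RuntimeError("failed to trace longest path")
    # path goes end -> ... -> start; midpoint measured from start
    half = total / 2.0
    acc = 0.0
    for k in range(len(path) - 1, 0, -1):
        a, b = path[k], path[k - 1]  # a closer to start
        edge = b.edge if b.parent_node is a else a.edge
        elen = edge.length or 0.0
        if acc + elen >= half - 1e-12:
            child = b if b.parent_node is a else a
            offset = half - acc  # measured from `a` along the edge
            if child is b:
                l_child = elen - offset
            else:
                l_child = offset
            tree.is_rooted = True
            tree.reroot_at_edge(
                child.edge,
                length1=elen - l_child,
                length2=l_child,
                update_bipartitions=False,
            )
            tree.is_rooted = True
            return Phylogeny(tree=tree, support=dict(phy.support))
        acc += elen
    raise RuntimeError("midpoint not found on longest path")  # pragma: no cover


# ---------------------------------------------------------------------------
# Supported clades


@dataclass
class CladeGroup:
    """A maximal clade whose bootstrap support exceeds the reporting threshold."""

    label: str
    member_ids: frozenset
    support: float
    nested_supports: list[float] = field(default_factory=list)

    @property
    def note(self) -> str:
        if not self.nested_supports:
            return ""
        return f"contains {len(self.nested_supports)} nested supported clade(s)"


def extract_supported_clades(phy: Phylogeny, threshold: float = 80.0) -> list[CladeGroup]:
    """Maximal clades with support strictly above ``threshold``.

    Requires a rooted tree (root it first, e.g. at the midpoint). Nested
    supported clades are reported under their maximal parent via
    ``nested_supports``.
    """
    if not phy.rooted:
        phy = midpoint_root(phy)
    labels = phy.leaf_labels
    groups: list[CladeGroup] = []

    def descend(node, inside_group):
        nonlocal groups
        if node.is_leaf():
            return
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sup = None
        if 1 < len(side) < len(labels):
            sup = phy.support.get(canonical_bipartition(side, labels))
        qualifies = sup is not None and sup > threshold
        if qualifies and inside_group is None:
            grp = CladeGroup(
                label=f"group_{len(groups) + 1}", member_ids=side, support=sup
            )
            groups.append(grp)
            inside_group = grp
        elif qualifies and inside_group is not None:
            inside_group.nested_supports.append(sup)
        for child in node.child_nodes():
            descend(child, inside_group)

    descend(phy.tree.seed_node, None)
    return groups


# ---------------------------------------------------------------------------
# GTR + Gamma (+I) likelihood


@dataclass
class SubstitutionModel:
    """GTR exchangeabilities/frequencies with optional +Gamma and +I.

    ``exchangeabilities`` order: AC, AG, AT, CG, CT, GT. The rate matrix is
    scaled to one expected substitution per site at equilibrium (including
    the invariant-class correction, so branch lengths keep their usual
    substitutions-per-site meaning).
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    p_invariant: float | None = None

    def __post_init__(self) -> None:
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or (ex < 0).any():
            raise ValueError("need 6 nonnegative exchangeabilities (AC,AG,AT,CG,CT,GT)")
        if pi.shape != (4,) or (pi <= 0).any():
            raise ValueError("need 4 positive base frequencies")
        self.base_freqs = tuple(pi / pi.sum())
        self.exchangeabilities = tuple(ex)
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.p_invariant is not None and not (0 <= self.p_invariant < 1):
            raise ValueError("p_invariant must be in [0, 1)")

    def rate_matrix(self) -> np.ndarray:
        """GTR Q scaled to 1 expected substitution/site at equilibrium."""
        ac, ag, at, cg, ct, gt = self.exchangeabilities
        pi = np.asarray(self.base_freqs)
        s = np.array(
            [[0, ac, ag, at], [ac, 0, cg, ct], [ag, cg, 0, gt], [at, ct, gt, 0]],
            dtype=float,
        )
        q = s * pi[None, :]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete mixture, overall mean rate 1."""
        rates, weights = [], []
        pinv = self.p_invariant or 0.0
        if pinv > 0:
            rates.append(0.0)
            weights.append(pinv)
        if self.gamma_shape is None:
            var_rates = np.array([1.0])
        else:
            k = self.n_rate_categories
            a = self.gamma_shape
            bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=a, scale=1.0 / a)
            # mean rate within each equal-probability bin
            var_rates = k * (gammainc(a + 1, a * bounds[1:]) - gammainc(a + 1, a * bounds[:-1]))
            var_rates = var_rates / var_rates.mean() * 1.0
        scale = 1.0 / (1.0 - pinv) if pinv > 0 else 1.0
        for r in var_rates:
            rates.append(float(r) * scale)
            weights.append((1.0 - pinv) / len(var_rates))
        return np.asarray(rates), np.asarray(weights)


def _transition_matrix(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (GTR is reversible)."""
    sq = np.sqrt(pi)
    b = (q * sq[:, None]) / sq[None, :]
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    p = (v * np.exp(w * t)) @ v.T
    p = p / sq[:, None] * sq[None, :]
    return np.clip(p, 0.0, None)


def _encode_alignment(aln: CodonAlignment) -> tuple[list[str], np.ndarray]:
    ids = aln.ids
    mat = np.full((len(ids), aln.n_sites), 4, dtype=np.int8)
    for r, (_, seq) in enumerate(aln.records):
        for c, ch in enumerate(seq.upper()):
            mat[r, c] = _NUC_INDEX.get(ch, 4)
    return ids, mat


def gtr_gamma_loglik(
    aln: CodonAlignment, phy: Phylogeny, model: SubstitutionModel | None = None
) -> float:
    """Log-likelihood of a fixed tree under GTR(+Gamma)(+I), by pruning.

    Gap and N characters are treated as missing data. The tree may be
    rooted or unrooted; for a reversible model the value is root-invariant.
    """
    model = model or SubstitutionModel()
    tree = phy.tree
    leaf_labels = set(phy.leaf_labels)
    if leaf_labels != set(aln.ids):
        missing = leaf_labels ^ set(aln.ids)
        raise ValueError(f"tree/alignment taxon mismatch: {sorted(missing)}")

    ids, mat = _encode_alignment(aln)
    row_of = {label: i for i, label in enumerate(ids)}
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    npat = patterns.shape[1]

    pi = np.asarray(model.base_freqs)
    q = model.rate_matrix()
    rates, weights = model.rate_categories()

    cat_loglikes = []  # per category: log site likelihood array
    for rate, weight in zip(rates, weights):
        pmats = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            t = (node.edge.length or 0.0) * rate
            pmats[node] = (
                np.eye(4) if t == 0 else _transition_matrix(q, pi, t)
            )
        logscale = np.zeros(npat)
        partial = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                states = patterns[row_of[node.taxon.label]]
                part = np.zeros((npat, 4))
                obs = states < 4
                part[obs, states[obs]] = 1.0
                part[~obs, :] = 1.0
            else:
                part = np.ones((npat, 4))
                for child in node.child_nodes():
                    part = part * (partial[child] @ pmats[child].T)
                mx = part.max(axis=1)
                mx[mx == 0] = 1.0
                part = part / mx[:, None]
                logscale += np.log(mx)
            partial[node] = part
        root_like = partial[tree.seed_node] @ pi
        with np.errstate(divide="ignore"):
            cat_loglikes.append(np.log(weight) + np.log(root_like) + logscale)
    logs = logsumexp(np.stack(cat_loglikes), axis=0)
    if np.isneginf(logs).any():
        return float("-inf")
    return float((logs * counts).sum())
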