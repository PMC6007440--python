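"""Population-structure layer: IBS distances, neighbor-joining, GRM-PCA and
distance correlation.

The identity-by-state distance between two individuals is one minus their
average allele-sharing proportion over jointly called sites.  Trees are
built with the Saitou–Nei neighbor-joining agglomeration (deterministic
tie-breaks) and serialized as Newick.  The genetic relationship matrix
follows VanRaden's first, frequency-standardized form G = ZZᵀ/m; its top
eigenpairs give genotype-PCA coordinates.  Geographic-vs-genetic distance
association uses Pearson correlation over matrix upper triangles with a
Mantel-style permutation p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import PopulationMap, ValidationError, VariantTable

logger = logging.getLogger("popsweep")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with ordered labels."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValidationError("distances must be non-negative")
        self.matrix = m

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = "\t".join(repr(float(x)) for x in self.matrix[i])
                fh.write(f"{lab}\t{row}\n")


def ibs_distance(vt: VariantTable) -> DistanceMatrix:
    """1 − mean allele-sharing proportion over jointly called sites.

    Per-site sharing between genotypes g_a, g_b is 1 − |g_a − g_b| / 2.
    A sample pair with no jointly called site is an error.
    """
    if vt.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    g = vt.genotypes.astype(np.float64)
    called = vt.genotypes >= 0
    n = vt.n_samples
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = int(both.sum())
            if m == 0:
                raise ValidationError(
                    f"samples {vt.samples[i]!r} and {vt.samples[j]!r} share no called site"
                )
            d = np.abs(g[i, both] - g[j, both]).sum() / (2.0 * m)
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(vt.samples, dist)


def population_distance(dm: DistanceMatrix, pm: PopulationMap) -> DistanceMatrix:
    """Population-level distances as means of cross-population individual
    distances (zero diagonal by convention)."""
    pm.validate_samples(dm.labels)
    pops = pm.populations
    out = np.zeros((len(pops), len(pops)))
    idx = {p: [i for i, s in enumerate(dm.labels) if pm.assignment[s] == p] for p in pops}
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            block = dm.matrix[np.ix_(idx[pops[a]], idx[pops[b]])]
            out[a, b] = out[b, a] = float(block.mean())
    return DistanceMatrix(tuple(pops), out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Tree node; an unrooted NJ tree is returned with a trifurcating root."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label] if self.label else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out

    def to_newick(self, clamp_negative: bool = True) -> str:
        """Serialize as Newick.  Small negative NJ branch lengths are
        clamped to 0 (raw value logged) unless ``clamp_negative=False``."""

        def fmt(node: "TreeNode", length: float | None) -> str:
            if node.children:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                s = f"({inner})" + (node.label or "")
            else:
                s = node.label or ""
            if length is not None:
                if clamp_negative and length < 0:
                    logger.info("clamping negative branch length %.6g to 0", length)
                    length = 0.0
                s += f":{length:.10g}"
            return s

        return fmt(self, None) + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (as the smaller-side leaf sets),
        a rooting-invariant topology fingerprint."""
        all_leaves = frozenset(self.leaf_labels())
        parts: set[frozenset[str]] = set()

        def walk(node: "TreeNode") -> frozenset[str]:
            if not node.children:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                # canonical side: smaller set, lexicographic on equal size
                key = (len(below), tuple(sorted(below)))
                okey = (len(other), tuple(sorted(other)))
                parts.add(below if key <= okey else other)
            return below

        walk(self)
        return parts


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Q-matrix minimization with ties broken on the lexicographically
    smallest pair of node sort keys (a node's key is its smallest leaf
    label), iterated down to three nodes which join at a trifurcating
    root.  Branch lengths use the standard formulas and may be negative;
    clamping happens only at serialization.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    keys: list[str] = list(dm.labels)
    D = dm.matrix.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best: tuple[float, str, str, int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                lo, hi = sorted((keys[i], keys[j]))
                cand = (q, lo, hi, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_key = min(keys[i], keys[j])
        d_new = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[: len(keep), : len(keep)] = D[np.ix_(keep, keep)]
        D2[-1, : len(keep)] = D2[: len(keep), -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]
    # three remaining nodes: closed-form branch lengths to a trifurcating root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    order = sorted(range(3), key=lambda k: keys[k])
    lens = [l0, l1, l2]
    return TreeNode(children=[(nodes[k], lens[k]) for k in order])


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length distances between all leaf pairs of a tree."""
    labels = sorted(tree.leaf_labels())
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    dist = np.zeros((n, n))

    def combine(node: TreeNode) -> dict[str, float]:
        if not node.children:
            return {node.label: 0.0}
        subs = []
        for child, length in node.children:
            depths = {l: d + length for l, d in combine(child).items()}
            subs.append(depths)
        for a in range(len(subs)):
            for b in range(a + 1, len(subs)):
                for la, da in subs[a].items():
                    for lb, db in subs[b].items():
                        dist[index[la], index[lb]] = dist[index[lb], index[la]] = da + db
        merged: dict[str, float] = {}
        for s in subs:
            merged.update(s)
        return merged

    combine(tree)
    return DistanceMatrix(tuple(labels), dist)


# ---------------------------------------------------------------------------
# GRM and PCA
# ---------------------------------------------------------------------------


def grm(vt: VariantTable) -> np.ndarray:
    """VanRaden (method 1) genetic relationship matrix G = ZZᵀ/m.

    Z holds frequency-standardized genotypes z = (g − 2p)/√(2p(1−p)) with p
    the overall sample allele frequency; monomorphic sites (p ∈ {0, 1}) and
    sites with any missing genotype contribute nothing and are excluded.
    """
    g = vt.genotypes
    complete = np.all(g >= 0, axis=0)
    gc = g[:, complete].astype(np.float64)
    p = gc.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValidationError("no polymorphic fully-called site for GRM")
    gc = gc[:, poly]
    p = p[poly]
    z = (gc - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = z.shape[1]
    return z @ z.T / m


def pca(G: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k eigenpairs of a relationship/covariance matrix.

    Returns (coordinates, eigenvalues, explained variance fraction) with
    coordinates = eigenvector · √eigenvalue and eigenvalues non-increasing.
    """
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValidationError("relationship matrix contains non-finite entries")
    n = G.shape[0]
    if k >= n:
        raise ValidationError(f"k ({k}) must be below the sample count ({n})")
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1][:k]
    eigvals = w[order]
    vecs = v[:, order]
    coords = vecs * np.sqrt(np.maximum(eigvals, 0.0))
    total = float(np.sum(np.maximum(w, 0.0)))
    explained = np.maximum(eigvals, 0.0) / total if total > 0 else np.zeros(k)
    return coords, eigvals, explained


# ---------------------------------------------------------------------------
# Distance correlation (Mantel)
# ---------------------------------------------------------------------------


def distance_correlation(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
    method: str = "mantel",
) -> tuple[float, float]:
    """Pearson correlation of two distance matrices' upper triangles.

    ``method="mantel"`` (default) permutes the labels of one matrix to get
    a two-sided p-value, p = (#{|r_perm| ≥ |r_obs|} + 1)/(permutations + 1).
    ``method="ttest"`` uses the naive parametric t-test on the flattened
    triangles, which ignores the non-independence of pairs and is provided
    for comparison only.
    """
    if genetic.labels != geographic.labels:
        raise ValidationError("distance matrices have different labels")
    x = genetic.upper_triangle()
    y = geographic.upper_triangle()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("constant distance vector; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if method == "ttest":
        from scipy import stats

        _, p = stats.pearsonr(x, y)
        return r, float(p)
    if method != "mantel":
        raise ValidationError(f"unknown method {method!r}")
    if permutations < 99:
        raise ValidationError("need at least 99 permutations for a p-value")
    rng = np.random.default_rng(seed)
    n = len(genetic.labels)
    count = 0
    m = geographic.matrix
    for _ in range(permutations):
        perm = rng.permutation(n)
        yp = m[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        rp = float(np.corrcoef(x, yp)[0, 1])
        if abs(rp) >= abs(r):
            count += 1
    p = (count + 1) / (permutations + 1)
    return r, float(p)
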