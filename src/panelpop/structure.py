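"""Population-structure stack: PCA, Nei distance, Ward clustering, Newick.

PCA is an eigendecomposition of the covariance (optionally correlation) of
the column-centered individuals x sites call matrix.  Pairwise Nei (1972)
standard genetic distance ``D = -ln(J_XY / sqrt(J_X J_Y))`` is computed with
per-locus allele "frequencies" in {0, 1}, the appropriate form for single
fully-inbred individuals.  Ward agglomeration is implemented through the
Lance-Williams recurrence applied directly to the supplied dissimilarities
(R's historical ``ward.D`` dialect; the squared-input ``ward.D2`` dialect is
available by flag), and trees can be cut into k groups or exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MAJOR, MINOR, GenotypeMatrix


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray  # (n_individuals, n_components)
    eigenvalues: np.ndarray  # non-increasing
    pct_variance: np.ndarray  # sums to 100 when total variance > 0
    individuals: list[str]
    #: False when the input had zero total variance (identical rows)
    variance_defined: bool = True

    def elbow(self) -> int:
        """Advisory elbow: component with the largest second difference of
        the eigenvalue scree (1-based).  k stays a user decision."""
        ev = self.eigenvalues
        if len(ev) < 3:
            return 1
        second = ev[:-2] - 2 * ev[1:-1] + ev[2:]
        return int(np.argmax(second)) + 2

    def to_frame(self, n: int | None = None) -> pd.DataFrame:
        n = n or self.scores.shape[1]
        df = pd.DataFrame(
            self.scores[:, :n],
            columns=[f"PC{i + 1}" for i in range(n)],
            index=self.individuals,
        )
        df.index.name = "individual"
        return df


def pca(gm: GenotypeMatrix, center: bool = True, scale: bool = False) -> PCAResult:
    """Principal components of the call matrix via SVD."""
    if gm.n_individuals < 2:
        raise StructureError("PCA requires at least 2 individuals")
    x = gm.calls.astype(np.float64)
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    n = gm.n_individuals
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    defined = bool(total > 0)
    pct = 100.0 * eig / total if defined else np.full_like(eig, np.nan)
    scores = u * s
    return PCAResult(
        scores=scores,
        eigenvalues=eig,
        pct_variance=pct,
        individuals=list(gm.individuals),
        variance_defined=defined,
    )


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    values: np.ndarray  # symmetric, zero diagonal; np.inf flags no shared allele
    names: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise StructureError("distance matrix must be square")
        if len(self.names) != v.shape[0]:
            raise StructureError("name count does not match matrix size")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def has_infinite(self) -> bool:
        return bool(np.isinf(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def submatrix(self, names) -> "DistanceMatrix":
        idx = [self.names.index(n) for n in names]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], list(names))


def nei_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Nei's standard genetic distance between every pair of inbred lines.

    With single fully-homozygous individuals the per-locus allele frequencies
    are 0/1 indicators, so the normalised identity ``J_XY / sqrt(J_X J_Y)``
    reduces to the fraction of loci at which the two lines carry the same
    allele, and ``D = -ln(identity)``.  A pair sharing no allele at any locus
    gets infinite distance (flagged via ``has_infinite``).
    """
    bad = ~np.isin(gm.calls, (MAJOR, MINOR))
    if bad.any():
        raise StructureError("nei_distance requires a fully imputed {0, 2} matrix")
    x = (gm.calls == MINOR).astype(np.float64)  # minor-allele indicator
    m = gm.n_sites
    same_minor = x @ x.T
    same_major = (1.0 - x) @ (1.0 - x).T
    identity = (same_minor + same_major) / m  # J_XY / sqrt(J_X J_Y); J_X = J_Y = 1
    with np.errstate(divide="ignore"):
        d = -np.log(identity)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(gm.individuals))


# ---------------------------------------------------------------------------
# Ward agglomeration (Lance-Williams)
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Agglomeration history.  Node ids follow the usual convention: leaves
    are 0..n-1; the i-th merge creates node n+i.  ``merges[i] = (a, b)`` and
    ``heights[i]`` is the dissimilarity at which a and b merged."""

    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,)
    leaf_names: list[str]
    dialect: str = "ward.D"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def inversions(self) -> int:
        """Number of height decreases along the merge sequence (possible for
        Ward on non-Euclidean input; logged, not an error)."""
        h = self.heights
        return int((np.diff(h) < -1e-12).sum())


def ward_cluster(dm: DistanceMatrix, dialect: str = "ward.D") -> Tree:
    """Agglomerate with Ward's minimum-variance criterion.

    The Lance-Williams recurrence with Ward coefficients
    ``alpha_i = (n_i + n_k) / (n_i + n_j + n_k)``,
    ``beta = -n_k / (n_i + n_j + n_k)``, ``gamma = 0``
    is applied to the supplied dissimilarities as-is (``ward.D``) or to their
    squares with square-rooted output heights (``ward.D2``).
    """
    if dialect not in ("ward.D", "ward.D2"):
        raise StructureError(f"unknown Ward dialect {dialect!r}")
    n = dm.n
    if n < 2:
        raise StructureError("clustering requires at least 2 leaves")
    if dm.has_infinite():
        raise StructureError("distance matrix contains infinite entries")
    d = dm.values.astype(np.float64).copy()
    if dialect == "ward.D2":
        d = d**2
    big = np.inf
    np.fill_diagonal(d, big)
    active = np.arange(n)  # current cluster node id per matrix row
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 2), dtype=np.int64)
    heights = np.empty(n - 1)
    for step in range(n - 1):
        sub = np.where(alive[:, None] & alive[None, :], d, big)
        flat = np.argmin(sub)
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = d[i, j]
        merges[step] = (active[i], active[j])
        heights[step] = h
        ni, nj = sizes[i], sizes[j]
        k = alive.copy()
        k[i] = k[j] = False
        nk = sizes[k]
        tot = ni + nj + nk
        d_new = ((ni + nk) * d[i, k] + (nj + nk) * d[j, k] - nk * h) / tot
        d[i, k] = d_new
        d[k, i] = d_new
        alive[j] = False
        sizes[i] = ni + nj
        active[i] = n + step
    if dialect == "ward.D2":
        heights = np.sqrt(heights)
    return Tree(merges=merges, heights=heights, leaf_names=list(dm.names),
                dialect=dialect)


def cut_tree(tree: Tree, k: int) -> pd.Series:
    """Group labels obtained by removing the k-1 highest merges.

    Ties in merge height are broken by merge order (later merges count as
    higher).  Groups are numbered 1..k in leaf order (the group containing
    the first leaf is 1, and so on), so labelling is deterministic.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise StructureError(f"k must lie in [1, {n}], got {k}")
    order = np.lexsort((np.arange(n - 1), tree.heights))  # height, then merge idx
    kept = set(order[: n - k].tolist())  # merges that survive the cut

    parent = list(range(2 * n - 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for idx in range(n - 1):
        if idx in kept:
            a, b = tree.merges[idx]
            node = n + idx
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=np.int64)
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[leaf] = roots[r]
    return pd.Series(labels, index=tree.leaf_names, name="group")


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _quote(name: str) -> str:
    if any(c in name for c in " ()[]{}:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Tree) -> str:
    """Newick string with branch lengths from merge heights.

    Each node sits at its merge height (leaves at 0); a branch length is the
    parent height minus the child height.  Names needing it are quoted.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    label: dict[int, str] = {i: _quote(tree.leaf_names[i]) for i in range(n)}
    for idx in range(n - 1):
        a, b = (int(v) for v in tree.merges[idx])
        h = float(tree.heights[idx])
        node = n + idx
        la = f"{label[a]}:{h - height[a]:.10g}"
        lb = f"{label[b]}:{h - height[b]:.10g}"
        label[node] = f"({la},{lb})"
        height[node] = h
    return label[2 * n - 2] + ";"
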