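"""Population-structure summaries: distance matrix, NJ tree, bootstrap, PCA.

The pairwise distance is allele sharing: the mean over co-non-missing
sites of |dosage_i - dosage_j| / 2, bounded in [0, 1].  Trees are built
with the Saitou-Nei neighbor-joining agglomeration (Q criterion), with
negative branch lengths clamped to zero.  Internal-edge supports come
from a phylogenetic bootstrap over SNP columns.  PCA standardizes each
site by its binomial standard deviation (Patterson normalization, as in
EIGENSOFT) and eigendecomposes the sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import MISSING, GenotypeMatrix
from .errors import ConfigError, DegenerateInputError, ValidationError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray
    n_sites_used: np.ndarray

    def validate(self) -> None:
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("nonzero diagonal")


def _pairwise_from_dosage(dosage: np.ndarray,
                          sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Allele-sharing distances from a raw dosage array (rows = samples)."""
    d = dosage.astype(float)
    d[dosage == MISSING] = np.nan
    n = d.shape[0]
    out = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    present = ~np.isnan(d)
    for i in range(n):
        for j in range(i + 1, n):
            co = present[i] & present[j]
            m = int(co.sum())
            if m == 0:
                raise ValidationError(
                    f"samples {sample_ids[i]!r} and {sample_ids[j]!r} share no sites")
            val = float(np.abs(d[i, co] - d[j, co]).mean() / 2.0)
            out[i, j] = out[j, i] = val
            used[i, j] = used[j, i] = m
    return out, used


def allele_sharing_distance(gm: GenotypeMatrix, metric: str = "allele_sharing"
                            ) -> DistanceMatrix:
    """Pairwise genetic distance between individuals.

    ``allele_sharing``: mean |dosage difference| / 2 over co-non-missing
    sites, bounded in [0, 1].  ``ibs`` selects 1 - identity-by-state,
    which under dosage coding reduces to the same normalized Manhattan
    value; the switch is kept explicit for configuration symmetry.
    """
    if gm.n_samples < 2:
        raise ValidationError("need at least two samples")
    if metric not in {"allele_sharing", "ibs"}:
        raise ConfigError(f"unknown distance metric {metric!r}")
    out, used = _pairwise_from_dosage(gm.dosage, gm.sample_ids)
    return DistanceMatrix(list(gm.sample_ids), out, used)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(f"{c._newick_node()}:{bl:.6g}" for c, bl in self.children)
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"


@dataclass
class PhyloTree:
    """Unrooted tree, represented rooted at the final trifurcating node."""

    root: TreeNode
    leaf_names: list[str]
    clamped_deficit: float = 0.0   # total negative branch length clamped to 0

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge bipartitions, each canonicalized as the side NOT
        containing the reference (alphabetically first) leaf."""
        ref = min(self.leaf_names)
        full = set(self.leaf_names)
        parts: set[frozenset[str]] = set()

        def visit(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                below |= visit(child)
            if node is not self.root and 1 < len(below) < len(full) - 1:
                side = below if ref not in below else full - below
                parts.add(frozenset(side))
            return below

        visit(self.root)
        return parts

    def annotate_supports(self, support: dict[frozenset[str], float]) -> None:
        ref = min(self.leaf_names)
        full = set(self.leaf_names)

        def visit(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                below |= visit(child)
            if node is not self.root and 1 < len(below) < len(full) - 1:
                side = frozenset(below if ref not in below else full - below)
                node.support = support.get(side, 0.0)
            return below

        visit(self.root)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Joins the pair minimizing Q = (n-2) d_ij - r_i - r_j; ties break on
    the smallest (i, j) index pair.  Negative branch lengths are clamped
    to zero and the total deficit recorded.
    """
    dm.validate()
    names = dm.sample_ids
    if len(names) < 3:
        raise ValidationError("need at least three taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in names]
    active = list(range(len(names)))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), n)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (n - 2)))
        lj = clamp(dij - (0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (n - 2))))
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row[None, :]])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        k = d.shape[0] - 1
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return PhyloTree(root=root, leaf_names=list(names), clamped_deficit=deficit)


def bootstrap_support(gm: GenotypeMatrix, n_boot: int = 1000,
                      seed: int = 0, metric: str = "allele_sharing") -> PhyloTree:
    """NJ tree with internal-edge bootstrap supports in [0, 100].

    SNP columns are resampled with replacement (same count) per replicate;
    each internal bipartition of the full-data tree is scored by the
    percentage of replicate trees containing it.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    tree = nj_tree(allele_sharing_distance(gm, metric))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, gm.n_variants, size=gm.n_variants)
        try:
            d, used = _pairwise_from_dosage(gm.dosage[:, cols], gm.sample_ids)
            reps = nj_tree(DistanceMatrix(list(gm.sample_ids), d, used)).bipartitions()
        except ValidationError:
            continue   # a pair may share no sites in a replicate
        for bp in target:
            if bp in reps:
                counts[bp] += 1
    tree.annotate_supports({bp: 100.0 * c / n_boot for bp, c in counts.items()})
    return tree


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    scores: np.ndarray              # (n_samples, k)
    variance_explained: np.ndarray
    sample_ids: list[str]
    n_sites_used: int


def pca(gm: GenotypeMatrix, k: int = 10) -> PCAResult:
    """Patterson-normalized genotype PCA.

    Each polymorphic site is centered by twice its sample allele
    frequency and scaled by sqrt(p(1-p)); missing entries are set to the
    site mean (zero after centering).  Scores are eigenvectors of the
    sample covariance scaled by the square root of their eigenvalues,
    with a deterministic sign (largest-magnitude loading positive).
    """
    if gm.n_samples < 2:
        raise ValidationError("need at least two samples")
    x = gm.dosage.astype(float)
    x[gm.dosage == MISSING] = np.nan
    p_hat = np.nanmean(x, axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1) & ~np.isnan(p_hat)
    if not poly.any():
        raise DegenerateInputError("all sites monomorphic")
    x = x[:, poly]
    p = p_hat[poly]
    x = (x - 2.0 * p) / np.sqrt(p * (1.0 - p))
    x[np.isnan(x)] = 0.0
    m = x.shape[1]
    cov = x @ x.T / (m - 1 if m > 1 else 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    k = min(k, gm.n_samples)
    evals_k = evals[:k]
    vecs = evecs[:, :k]
    for c in range(k):
        imax = int(np.argmax(np.abs(vecs[:, c])))
        if vecs[imax, c] < 0:
            vecs[:, c] = -vecs[:, c]
    scores = vecs * np.sqrt(evals_k)[None, :]
    total = evals.sum()
    return PCAResult(
        eigenvalues=evals_k,
        scores=scores,
        variance_explained=evals_k / total if total > 0 else np.zeros(k),
        sample_ids=list(gm.sample_ids),
        n_sites_used=int(poly.sum()),
    )
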