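"""Principal-tree pseudotime for the PSC trajectory across compartments.

A simplified reversed-graph-embedding fit: tree vertices live in the
reduced expression space and are optimised by alternating (i) soft
assignment of cells to vertices, (ii) vertex repositioning toward their
assigned cells under a spanning-tree smoothness penalty, and (iii)
minimum-spanning-tree re-linkage.  The root is the leaf whose assigned
cells have the highest primary-tumour fraction, pseudotime is geodesic
distance along tree edges from the root (plus the cell-to-vertex projection
offset), and vertices of degree >= 3 are branch points.

Differential expression along the tree uses count-family (quasi-Poisson)
spline regression: a natural cubic spline of pseudotime (df = 3 by
default), with a likelihood-ratio test against the intercept-only model for
pseudotime dependence, or against the shared-curve model for
branch-dependent (fate x pseudotime) expression.  Dispersion is
moment-estimated per gene from the Pearson chi-square of the richer model,
and p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import dijkstra, minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests


@dataclass
class PrincipalTree:
    """Embedded principal tree with per-cell assignments.

    ``edges`` always form a spanning tree (|E| = |V| - 1); pseudotime is
    populated by :func:`assign_pseudotime`.
    """

    vertices: np.ndarray                 # V x d positions
    edges: list[tuple[int, int]]
    cell_vertex: np.ndarray              # assigned vertex per cell
    cell_coords: np.ndarray              # n x d input coordinates
    converged: bool
    root: int | None = None
    pseudotime: np.ndarray | None = None
    branch_id: np.ndarray | None = None  # per cell
    notes: list[str] = field(default_factory=list)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def branch_vertices(self) -> list[int]:
        return [int(v) for v in np.flatnonzero(self.degrees() >= 3)]

    def adjacency(self) -> sp.csr_matrix:
        n = self.n_vertices
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols, w = [], [], []
        for i, j in self.edges:
            d = float(np.linalg.norm(self.vertices[i] - self.vertices[j]))
            rows += [i, j]
            cols += [j, i]
            w += [d, d]
        return sp.csr_matrix((w, (rows, cols)), shape=(n, n))


def _mst_edges(vertices: np.ndarray) -> list[tuple[int, int]]:
    d = cdist(vertices, vertices)
    mst = minimum_spanning_tree(d).tocoo()
    return [(int(i), int(j)) for i, j in zip(mst.row, mst.col)]


def fit_principal_tree(
    coords: np.ndarray,
    n_vertices: int | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    smoothness: float = 1.0,
) -> PrincipalTree:
    """Fit a principal tree to cells in reduced space (cells x dims).

    Vertices are initialised by seeded k-means, then alternately re-linked
    by a minimum spanning tree and repositioned toward their softly assigned
    cells with a Laplacian smoothness pull toward tree neighbours, until the
    maximum vertex movement falls below ``tol``.  Non-convergence returns
    the best tree with a warning note.
    """
    coords = np.asarray(coords, dtype=float)
    n_cells = coords.shape[0]
    if n_vertices is None:
        n_vertices = max(1, int(np.ceil(n_cells / 10)))
    if n_cells < n_vertices:
        raise ValueError(f"{n_cells} cells < {n_vertices} vertices")

    if n_vertices == 1:
        v = coords.mean(axis=0, keepdims=True)
        return PrincipalTree(vertices=v, edges=[],
                             cell_vertex=np.zeros(n_cells, dtype=int),
                             cell_coords=coords, converged=True)

    km = KMeans(n_clusters=n_vertices, random_state=seed, n_init=10)
    km.fit(coords)
    vertices = km.cluster_centers_.copy()

    converged = False
    notes: list[str] = []
    for _ in range(max_iter):
        d2 = cdist(coords, vertices) ** 2
        sigma2 = np.mean(d2.min(axis=1)) + 1e-12
        logw = -d2 / (2 * sigma2)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)

        edges = _mst_edges(vertices)
        adj = np.zeros((n_vertices, n_vertices))
        for i, j in edges:
            adj[i, j] = adj[j, i] = 1.0
        deg = adj.sum(axis=1)

        mass = w.sum(axis=0)                       # per-vertex cell mass
        pull = w.T @ coords                        # mass-weighted cell centroid
        smooth = adj @ vertices
        new_vertices = (pull + smoothness * smooth) / (
            (mass + smoothness * deg)[:, None] + 1e-12)
        move = float(np.max(np.linalg.norm(new_vertices - vertices, axis=1)))
        vertices = new_vertices
        if move < tol:
            converged = True
            break
    if not converged:
        warnings.warn("principal tree did not converge; returning best tree")
        notes.append("non-convergence")

    edges = _mst_edges(vertices)
    cell_vertex = np.argmin(cdist(coords, vertices), axis=1)
    return PrincipalTree(vertices=vertices, edges=edges,
                         cell_vertex=cell_vertex, cell_coords=coords,
                         converged=converged, notes=notes)


def _vertex_parents(tree: PrincipalTree, root: int) -> np.ndarray:
    """Parent of each vertex on the path from root (-1 for root)."""
    n = tree.n_vertices
    adj = [[] for _ in range(n)]
    for i, j in tree.edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = np.full(n, -1, dtype=int)
    seen = {root}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                stack.append(v)
    return parent


def assign_pseudotime(
    tree: PrincipalTree,
    sample_of_cell: np.ndarray,
    root_sample: str = "MsPrim",
    root: int | None = None,
) -> PrincipalTree:
    """Root the tree and assign per-cell pseudotime and branch ids (in place).

    The root is the leaf vertex whose assigned cells have the highest
    fraction of ``root_sample`` cells (ties broken by larger cell count),
    matching a trajectory that originates in the primary tumour.  Pseudotime
    is geodesic distance from the root along tree edges plus the projection
    of the cell onto its vertex's incoming edge direction, floored at zero.
    Branch ids partition vertices into maximal unbranched segments.
    """
    sample_of_cell = np.asarray(sample_of_cell)
    if sample_of_cell.shape[0] != tree.cell_coords.shape[0]:
        raise ValueError("sample_of_cell must align with cells")

    if tree.n_vertices == 1:
        tree.root = 0
        tree.pseudotime = np.zeros(tree.cell_coords.shape[0])
        tree.branch_id = np.zeros(tree.cell_coords.shape[0], dtype=int)
        return tree

    if root is None:
        deg = tree.degrees()
        leaves = np.flatnonzero(deg <= 1)
        best = None
        for leaf in leaves:
            cells = tree.cell_vertex == leaf
            n = int(cells.sum())
            frac = float((sample_of_cell[cells] == root_sample).mean()) if n else 0.0
            key = (frac, n)
            if best is None or key > best[0]:
                best = (key, int(leaf))
        root = best[1]
    tree.root = int(root)

    geo = dijkstra(tree.adjacency(), indices=tree.root)
    parent = _vertex_parents(tree, tree.root)

    # incoming edge direction per vertex (root uses its single child)
    directions = np.zeros_like(tree.vertices)
    for v in range(tree.n_vertices):
        if parent[v] >= 0:
            d = tree.vertices[v] - tree.vertices[parent[v]]
        else:
            children = [c for c in range(tree.n_vertices) if parent[c] == v]
            d = tree.vertices[children[0]] - tree.vertices[v] if children else \
                np.zeros(tree.vertices.shape[1])
        norm = np.linalg.norm(d)
        directions[v] = d / norm if norm > 0 else d

    offset = np.einsum(
        "ij,ij->i",
        tree.cell_coords - tree.vertices[tree.cell_vertex],
        directions[tree.cell_vertex])
    tree.pseudotime = np.maximum(geo[tree.cell_vertex] + offset, 0.0)

    # branch ids: segments between root/branch vertices
    deg = tree.degrees()
    vertex_branch = np.full(tree.n_vertices, -1, dtype=int)
    next_id = 0
    order = np.argsort(geo)  # process vertices root-outward
    for v in order:
        p = parent[v]
        if p < 0:
            vertex_branch[v] = next_id
            next_id += 1
        elif deg[p] >= 3 and p != tree.root:
            vertex_branch[v] = next_id
            next_id += 1
        else:
            vertex_branch[v] = vertex_branch[p]
    tree.branch_id = vertex_branch[tree.cell_vertex]
    return tree


# ---------------------------------------------------------------------------
# Spline regression along pseudotime


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis of ``x`` with ``df`` columns (no intercept).

    Knots at evenly spaced quantiles (df + 1 knots including boundaries);
    beyond the boundary knots the fit is linear.  ``x`` is rescaled to
    [0, 1] and the basis columns are centred and unit-scaled, so the design
    stays well conditioned whatever the pseudotime units.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    basis = _spline_eval_like(x, x, df)
    return basis


def _fit_poisson(y: np.ndarray, design: np.ndarray, offset: np.ndarray):
    """Poisson GLM via statsmodels; returns (deviance, pearson_chi2, dof, fitted)."""
    import statsmodels.api as sm

    model = sm.GLM(y, design, family=sm.families.Poisson(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    return res.deviance, res.pearson_chi2, res.df_resid, res


def _quasi_lrt(y, x_null, x_full, offset) -> tuple[float, float, int]:
    """Quasi-Poisson likelihood-ratio test of nested count models."""
    dev0, _, _, _ = _fit_poisson(y, x_null, offset)
    dev1, chi2, dof, _ = _fit_poisson(y, x_full, offset)
    phi = max(1.0, chi2 / dof) if dof > 0 else 1.0
    df_diff = x_full.shape[1] - x_null.shape[1]
    stat = max(0.0, (dev0 - dev1) / phi)
    p = float(scipy.stats.chi2.sf(stat, df_diff))
    return stat, p, df_diff


def pseudotime_dependent_genes(
    counts: np.ndarray | sp.spmatrix,
    gene_ids: list[str],
    pseudotime: np.ndarray,
    df: int = 3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test each gene for expression change over pseudotime.

    ``counts`` is genes x cells raw UMI counts; per-cell log depth enters
    as an offset.  Each gene's spline model (natural cubic basis, ``df``
    degrees of freedom) is compared with the intercept-only model by a
    dispersion-scaled likelihood-ratio test; q-values are BH-adjusted.
    All-zero genes are excluded with a note in the ``status`` column.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    if np.ptp(pseudotime) == 0:
        raise ValueError("pseudotime is constant")
    counts = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    depth = counts.sum(axis=0)
    offset = np.log(np.maximum(depth, 1.0) / np.median(np.maximum(depth, 1.0)))

    basis = natural_spline_basis(pseudotime, df=df)
    ones = np.ones((counts.shape[1], 1))
    x_null = ones
    x_full = np.hstack([ones, basis])

    rows = []
    for g in range(counts.shape[0]):
        y = counts[g]
        if y.sum() == 0:
            rows.append({"gene_id": gene_ids[g], "stat": np.nan, "p": np.nan,
                         "status": "all_zero"})
            continue
        try:
            stat, p, _ = _quasi_lrt(y, x_null, x_full, offset)
        except (ValueError, np.linalg.LinAlgError):
            rows.append({"gene_id": gene_ids[g], "stat": np.nan, "p": np.nan,
                         "status": "fit_failed"})
            continue
        rows.append({"gene_id": gene_ids[g], "stat": stat, "p": p,
                     "status": "tested"})
    out = pd.DataFrame(rows)
    tested = out["status"] == "tested"
    q = np.full(len(out), np.nan)
    if tested.any():
        _, q_t, _, _ = multipletests(out.loc[tested, "p"], method="fdr_bh")
        q[tested.to_numpy()] = q_t
    out["q"] = q
    out["significant"] = out["q"] < fdr
    return out.sort_values(["q", "p"], na_position="last").reset_index(drop=True)


def _limb_cells(tree: PrincipalTree, branch_vertex: int) -> list[np.ndarray]:
    """Cell masks of the subtrees hanging off ``branch_vertex`` away from root."""
    parent = _vertex_parents(tree, tree.root)
    children = [v for v in range(tree.n_vertices) if parent[v] == branch_vertex]
    masks = []
    for child in children:
        sub = {child}
        stack = [child]
        while stack:
            u = stack.pop()
            for v in range(tree.n_vertices):
                if parent[v] == u and v not in sub:
                    sub.add(v)
                    stack.append(v)
        masks.append(np.isin(tree.cell_vertex, sorted(sub)))
    return masks


def branch_expression_analysis(
    counts: np.ndarray | sp.spmatrix,
    gene_ids: list[str],
    tree: PrincipalTree,
    branch_vertex: int | None = None,
    df: int = 3,
    fdr: float = 0.05,
    k_clusters: int = 4,
    min_limb_cells: int = 10,
    n_grid: int = 50,
    seed: int = 0,
) -> dict:
    """Test genes for fate-dependent expression at a branch point.

    Cells on the two descendant limbs of the branch vertex are modelled
    with a spline of pseudotime; the full model adds fate main and fate x
    spline interaction terms and is compared with the shared-curve null by
    a dispersion-scaled LRT.  The fate direction of each significant gene
    is the limb with the higher fitted terminal mean.  Significant genes
    are arranged into a mirrored pre-branch -> fate heatmap (fate 1 columns
    reversed, then fate 2) and clustered by seeded k-means.

    Returns ``{"results": DataFrame, "heatmap": DataFrame, "branch_vertex",
    "skipped": bool}``.
    """
    if tree.root is None or tree.pseudotime is None:
        raise ValueError("assign_pseudotime must run before branch analysis")
    branches = tree.branch_vertices()
    if branch_vertex is None:
        if not branches:
            raise ValueError("tree has no branch vertex")
        # default: the branch point closest to the root
        geo = dijkstra(tree.adjacency(), indices=tree.root)
        branch_vertex = int(min(branches, key=lambda v: geo[v]))

    limbs = _limb_cells(tree, branch_vertex)
    limbs = sorted(limbs, key=lambda m: -int(m.sum()))[:2]
    if len(limbs) < 2 or min(int(m.sum()) for m in limbs) < min_limb_cells:
        warnings.warn(
            f"branch vertex {branch_vertex}: a limb has fewer than "
            f"{min_limb_cells} cells; skipping")
        return {"results": pd.DataFrame(), "heatmap": pd.DataFrame(),
                "branch_vertex": branch_vertex, "limb_masks": limbs,
                "skipped": True}

    counts = counts.toarray() if sp.issparse(counts) else np.asarray(counts)
    mask = limbs[0] | limbs[1]
    fate = np.where(limbs[0][mask], 0.0, 1.0)
    pt = tree.pseudotime[mask]
    sub = counts[:, mask]
    depth = sub.sum(axis=0)
    offset = np.log(np.maximum(depth, 1.0) / np.median(np.maximum(depth, 1.0)))

    basis = natural_spline_basis(pt, df=df)
    ones = np.ones((sub.shape[1], 1))
    x_null = np.hstack([ones, basis])
    x_full = np.hstack([ones, basis, fate[:, None], basis * fate[:, None]])

    rows = []
    fitted_curves = {}
    grid = np.linspace(pt.min(), pt.max(), n_grid)
    basis_grid = _spline_eval_like(pt, grid, df)
    for g in range(sub.shape[0]):
        y = sub[g]
        if y.sum() == 0:
            continue
        try:
            stat, p, _ = _quasi_lrt(y, x_null, x_full, offset)
            _, _, _, res = _fit_poisson(y, x_full, offset)
        except (ValueError, np.linalg.LinAlgError):
            continue
        beta = res.params
        eta0 = beta[0] + basis_grid @ beta[1:1 + basis.shape[1]]
        eta1 = (eta0 + beta[1 + basis.shape[1]]
                + basis_grid @ beta[2 + basis.shape[1]:])
        mu0, mu1 = np.exp(eta0), np.exp(eta1)
        fate_dir = 1 if mu0[-1] >= mu1[-1] else 2
        rows.append({"gene_id": gene_ids[g], "stat": stat, "p": p,
                     "fate": fate_dir})
        fitted_curves[gene_ids[g]] = (mu0, mu1)

    results = pd.DataFrame(rows)
    if results.empty:
        return {"results": results, "heatmap": pd.DataFrame(),
                "branch_vertex": branch_vertex, "limb_masks": limbs,
                "skipped": False}
    _, q, _, _ = multipletests(results["p"], method="fdr_bh")
    results["q"] = q
    results["significant"] = results["q"] < fdr

    sig_all = results[results["significant"]]["gene_id"].tolist()
    heatmap = pd.DataFrame()
    sig, mat = [], []
    for gid in sig_all:
        mu0, mu1 = fitted_curves[gid]
        row = np.concatenate([mu0[::-1], mu1])   # mirrored: fate1 <- pre | -> fate2
        if not np.isfinite(row).all():           # diverged extrapolation
            continue
        s = row.std()
        sig.append(gid)
        mat.append((row - row.mean()) / (s if s > 0 else 1.0))
    if sig:
        mat = np.asarray(mat)
        k = min(k_clusters, len(sig))
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        clusters = km.fit_predict(mat)
        heatmap = pd.DataFrame(mat, index=pd.Index(sig, name="gene_id"))
        heatmap.insert(0, "kmeans_cluster", clusters)
        results = results.merge(
            heatmap[["kmeans_cluster"]].reset_index(), on="gene_id", how="left")

    return {"results": results.sort_values(["q", "p"]).reset_index(drop=True),
            "heatmap": heatmap, "branch_vertex": branch_vertex,
            "limb_masks": limbs, "skipped": False}


def _spline_eval_like(x_train: np.ndarray, x_new: np.ndarray, df: int) -> np.ndarray:
    """Evaluate the training-knot spline basis (centred, unit-scaled) at new points.

    Both inputs are mapped through the affine rescaling of ``x_train`` onto
    [0, 1] before the truncated-power construction, and columns are
    standardised by the training moments, keeping the design well
    conditioned for IRLS regardless of the covariate's units.
    """
    x_train = np.asarray(x_train, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    lo, span = x_train.min(), np.ptp(x_train)
    xt = (x_train - lo) / span
    xn = (x_new - lo) / span
    knots = np.unique(np.quantile(xt, np.linspace(0, 1, df + 1)))

    if len(knots) < 3 or df == 1:
        build = lambda x: x[:, None]  # noqa: E731
    else:
        k_last = knots[-1]

        def d(j, x):
            return (np.clip(x - knots[j], 0, None) ** 3
                    - np.clip(x - k_last, 0, None) ** 3) / (k_last - knots[j])

        def build(x):
            cols = [x] + [d(j, x) - d(len(knots) - 2, x)
                          for j in range(len(knots) - 2)]
            return np.column_stack(cols)

    train = build(xt)
    center = train.mean(axis=0, keepdims=True)
    scale = train.std(axis=0, keepdims=True)
    scale[scale == 0] = 1.0
    return (build(xn) - center) / scale
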