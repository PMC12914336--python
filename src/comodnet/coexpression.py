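"""Weighted coexpression network construction and module detection.

The network is unsigned: adjacency a_ij = |pearson(x_i, x_j)|^beta with
the soft power beta chosen by the scale-free topology criterion. The
topological overlap measure

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj   (u != i, j)

drives average-linkage hierarchical clustering on 1 - TOM; a static
branch cut followed by iterative eigengene merging yields the module
assignment. Module eigengenes are the first principal component of the
standardized module submatrix, oriented so that the mean gene-eigengene
correlation is non-negative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, GeneSet, SampleGroups

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdScan",
    "CoexpressionNetwork",
    "ModuleAssignment",
    "ModuleTraitResult",
    "pick_soft_threshold",
    "build_network",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "drop_constant_genes",
]


@dataclass(frozen=True)
class SoftThresholdScan:
    candidates: tuple[int, ...]
    r_squared: tuple[float, ...]  # signed negative when the fit slope is positive
    mean_connectivity: tuple[float, ...]
    r2_target: float
    chosen: int


@dataclass(frozen=True, eq=False)
class CoexpressionNetwork:
    gene_ids: tuple[str, ...]
    beta: int
    adjacency: np.ndarray  # diag 1
    tom: np.ndarray  # diag 1
    connectivity: np.ndarray  # k_i = sum_{j != i} a_ij

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModuleAssignment:
    """gene -> module id map; module 0 collects unassigned genes."""

    labels: dict[str, int]
    min_module_size: int
    cut_height: float
    merge_cut: float

    def module_ids(self) -> list[int]:
        return sorted({m for m in self.labels.values() if m != 0})

    def module_genes(self, module: int) -> tuple[str, ...]:
        return tuple(g for g, m in self.labels.items() if m == module)

    def to_gene_sets(self, prefix: str = "module") -> list[GeneSet]:
        return [
            GeneSet(f"{prefix}_{m}", self.module_genes(m))
            for m in self.module_ids()
        ]


@dataclass
class ModuleTraitResult:
    eigengenes: dict[int, np.ndarray]
    trait_r: dict[int, float]
    trait_p: dict[int, float]
    gene_significance: dict[str, float]  # |cor(gene, trait)|
    module_membership: dict[tuple[str, int], float]  # cor(gene, eigengene)
    method: str = "spearman"


def drop_constant_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero variance (undefined correlation)."""
    sd = expr.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant gene rows before network build", int((~keep).sum()))
        genes = tuple(g for g, k in zip(expr.gene_ids, keep) if k)
        return ExpressionMatrix(genes, expr.sample_ids, expr.values[keep])
    return expr


def _abs_cor(values: np.ndarray) -> np.ndarray:
    c = np.corrcoef(values)
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite correlations; drop constant genes first")
    return np.abs(np.clip(c, -1.0, 1.0))


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log10 p(k) ~ log10 k regression.

    Connectivities are binned on log10(k); the fraction of nodes per bin
    is regressed on the bin mean log10(k). The R^2 is returned negative
    when the slope is positive (the scale-free law requires decay).
    """
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(logk[mask].mean())
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0
    fit = stats.linregress(xs, ys)
    r2 = fit.rvalue**2
    return -r2 if fit.slope > 0 else r2


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidates: tuple[int, ...] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate soft powers for scale-free topology fit.

    The chosen beta is the smallest candidate whose signed R^2 reaches
    ``r2_target``; if none does, the candidate with the largest R^2.
    """
    expr = drop_constant_genes(expr)
    if expr.n_samples < 3 or expr.n_genes < 30:
        raise ValueError("soft-threshold scan needs >= 3 samples and >= 30 genes")
    abscor = _abs_cor(expr.values)
    np.fill_diagonal(abscor, 0.0)
    r2s, mean_k = [], []
    for beta in candidates:
        k = (abscor**beta).sum(axis=1)
        r2s.append(scale_free_fit(k, n_bins=n_bins))
        mean_k.append(float(k.mean()))
    chosen = choose_beta(candidates, r2s, r2_target)
    return SoftThresholdScan(
        tuple(candidates), tuple(r2s), tuple(mean_k), r2_target, int(chosen)
    )


def choose_beta(candidates, r2s, r2_target: float) -> int:
    """Smallest candidate reaching the fit target, else the argmax."""
    for beta, r2 in zip(candidates, r2s):
        if r2 >= r2_target:
            return int(beta)
    return int(candidates[int(np.argmax(r2s))])


def build_network(expr: ExpressionMatrix, beta: int) -> CoexpressionNetwork:
    """Soft-powered adjacency and topological overlap matrix."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    adj = _abs_cor(expr.values) ** beta
    np.fill_diagonal(adj, 1.0)

    a0 = adj.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    num = a0 @ a0 + a0  # l_ij (u != i, j since diag(a0)=0) plus a_ij
    den = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    n_clip = int(((tom < -1e-9) | (tom > 1 + 1e-9)).sum())
    if n_clip:
        logger.info("TOM: clipped %d entries outside [0,1] beyond 1e-9", n_clip)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return CoexpressionNetwork(expr.gene_ids, int(beta), adj, tom, k)


def _first_pc(sub: np.ndarray) -> np.ndarray:
    """Sample scores of the first PC of a genes x samples submatrix."""
    sd = sub.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("module contains only zero-variance genes")
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    # orient: mean gene-eigengene correlation >= 0
    cors = (z @ eig) / (np.linalg.norm(z, axis=1) * np.linalg.norm(eig))
    if cors.mean() < 0:
        eig = -eig
    return eig


def module_eigengenes(
    expr: ExpressionMatrix, assignment: ModuleAssignment | dict[str, int]
) -> dict[int, np.ndarray]:
    """First principal component (sample scores) per module."""
    labels = assignment.labels if isinstance(assignment, ModuleAssignment) else assignment
    index = expr.gene_index()
    eigs: dict[int, np.ndarray] = {}
    for m in sorted({v for v in labels.values() if v != 0}):
        rows = [index[g] for g, mm in labels.items() if mm == m and g in index]
        if not rows:
            raise ValueError(f"module {m} has no genes in the matrix")
        eigs[m] = _first_pc(expr.values[rows])
    return eigs


def _merge_step(
    expr: ExpressionMatrix, labels: dict[str, int], merge_cut: float
) -> bool:
    """Merge the closest eigengene pair below merge_cut; True if merged."""
    ids = sorted({v for v in labels.values() if v != 0})
    if len(ids) < 2:
        return False
    eigs = module_eigengenes(expr, labels)
    best = None
    for i, mi in enumerate(ids):
        for mj in ids[i + 1 :]:
            diss = 1.0 - float(np.corrcoef(eigs[mi], eigs[mj])[0, 1])
            if diss < merge_cut and (best is None or diss < best[0]):
                best = (diss, mi, mj)
    if best is None:
        return False
    _, mi, mj = best
    for g, m in labels.items():
        if m == mj:
            labels[g] = mi
    return True


def _kme_refine(
    expr: ExpressionMatrix,
    labels: dict[str, int],
    min_module_size: int,
    kme_min: float,
    n_refine: int,
) -> dict[str, int]:
    """Reassign genes to their best-correlated module eigengene.

    Standard membership cleanup: each gene moves to the module whose
    eigengene it correlates with most strongly (absolute correlation,
    i.e. its kME), or to unassigned if even the best |kME| falls below
    ``kme_min``; modules dropping below ``min_module_size`` dissolve.
    """
    index = expr.gene_index()
    x = expr.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.divide(x - mean, sd, out=np.zeros_like(x), where=sd > 0)
    for _ in range(n_refine):
        ids = sorted({m for m in labels.values() if m != 0})
        if not ids:
            break
        eigs = module_eigengenes(expr, labels)
        emat = np.array([eigs[m] - eigs[m].mean() for m in ids])
        emat /= np.linalg.norm(emat, axis=1, keepdims=True)
        new: dict[str, int] = {}
        for g in labels:
            zi = z[index[g]]
            nz = np.linalg.norm(zi)
            if nz == 0:
                new[g] = 0
                continue
            kme = np.abs(emat @ (zi / nz))
            best = int(np.argmax(kme))
            new[g] = ids[best] if kme[best] >= kme_min else 0
        counts: dict[int, int] = {}
        for m in new.values():
            counts[m] = counts.get(m, 0) + 1
        labels = {g: (m if m != 0 and counts[m] >= min_module_size else 0) for g, m in new.items()}
    return labels


def detect_modules(
    network: CoexpressionNetwork,
    expr: ExpressionMatrix,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_cut: float = 0.25,
    branch_floor: int = 10,
    kme_min: float = 0.4,
    n_refine: int = 2,
) -> ModuleAssignment:
    """Cluster 1 - TOM, cut into branches, merge, and refine modules.

    Branches from a static cut of the average-linkage dendrogram at
    ``cut_height`` become candidate modules (branches smaller than
    ``branch_floor`` start unassigned). Modules whose eigengene
    dissimilarity (1 - cor) falls below ``merge_cut`` are merged
    iteratively until stable; membership is then refined by kME
    reassignment (fragments of one underlying module rejoin it, chained
    background genes drop out), modules below ``min_module_size``
    dissolve, and survivors are relabeled 1..M by decreasing size (ties
    by smallest member gene id).
    """
    genes = list(network.gene_ids)
    branch_floor = min(branch_floor, min_module_size)
    diss = 1.0 - network.tom
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    if condensed.size and np.allclose(condensed, condensed[0]):
        logger.warning("degenerate dendrogram (all distances equal); single module")
        labels = {g: (1 if len(genes) >= min_module_size else 0) for g in genes}
        return ModuleAssignment(labels, min_module_size, cut_height, merge_cut)
    z = linkage(condensed, method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")

    sizes: dict[int, int] = {}
    for c in flat:
        sizes[c] = sizes.get(c, 0) + 1
    labels = {
        g: (int(c) if sizes[c] >= branch_floor else 0)
        for g, c in zip(genes, flat)
    }

    expr = expr.subset_genes(genes)
    while _merge_step(expr, labels, merge_cut):
        pass
    labels = _kme_refine(expr, labels, min_module_size, kme_min, n_refine)

    # final size filter (also covers n_refine=0) and relabeling
    members: dict[int, list[str]] = {}
    for g, m in labels.items():
        if m != 0:
            members.setdefault(m, []).append(g)
    members = {m: gs for m, gs in members.items() if len(gs) >= min_module_size}
    order = sorted(members, key=lambda m: (-len(members[m]), min(members[m])))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = {g: (remap.get(m, 0) if m in members else 0) for g, m in labels.items()}
    return ModuleAssignment(labels, min_module_size, cut_height, merge_cut)


def module_trait_correlation(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment | dict[str, int],
    groups: SampleGroups,
    method: str = "spearman",
) -> ModuleTraitResult:
    """Module-trait correlation plus per-gene GS and MM.

    The trait is the binary case indicator; module eigengenes are
    correlated against it with Spearman's coefficient by default
    (Pearson optional). GS_g = |cor(gene, trait)|; MM_{g,m} =
    pearson(gene, eigengene m).
    """
    groups.validate_against(expr)
    trait = groups.trait_vector(expr.sample_ids)
    if method == "spearman":
        corfun = lambda a, b: stats.spearmanr(a, b)
    elif method == "pearson":
        corfun = lambda a, b: stats.pearsonr(a, b)
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    eigs = module_eigengenes(expr, assignment)
    trait_r, trait_p = {}, {}
    for m, eig in eigs.items():
        if np.std(eig) == 0:
            raise ValueError(f"module {m}: constant eigengene")
        r, p = corfun(eig, trait)
        trait_r[m], trait_p[m] = float(r), float(p)

    labels = assignment.labels if isinstance(assignment, ModuleAssignment) else assignment
    index = expr.gene_index()
    gs: dict[str, float] = {}
    mm: dict[tuple[str, int], float] = {}
    for g, m in labels.items():
        if g not in index:
            continue
        x = expr.values[index[g]]
        if np.std(x) == 0:
            gs[g] = 0.0
        else:
            r, _ = corfun(x, trait)
            gs[g] = abs(float(r))
        if m != 0:
            mm[(g, m)] = float(np.corrcoef(x, eigs[m])[0, 1]) if np.std(x) > 0 else 0.0
    return ModuleTraitResult(eigs, trait_r, trait_p, gs, mm, method)
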