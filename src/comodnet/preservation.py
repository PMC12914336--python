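"""Permutation Z_summary statistic for cross-disease module preservation.

For a module defined in a reference disease, two observed statistics are
computed in the test disease's coexpression network restricted to the
module's genes: the mean off-diagonal adjacency (density) and the
Pearson correlation of intramodular connectivity vectors between the
reference and test networks (connectivity preservation). Each statistic
is standardized against its null distribution over random gene sets of
the same size drawn from the shared gene universe, and

    Z_summary = (Z_density + Z_connectivity) / 2.

Modules with Z_summary >= z_cut (default 2) are called common between
the two diseases.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coexpression import ModuleAssignment
from .datatypes import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "PreservationResult",
    "CommonModuleCall",
    "module_preservation",
    "common_modules",
    "module_level_shared_genes",
]


@dataclass(frozen=True)
class PreservationResult:
    module: int
    size: int
    mean_adjacency: float
    cor_kim: float
    null_density_mean: float
    null_density_sd: float
    null_connectivity_mean: float
    null_connectivity_sd: float
    z_density: float
    z_connectivity: float
    z_summary: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class CommonModuleCall:
    reference: str
    test: str
    module: int
    z_summary: float
    is_common: bool


def _sub_adjacency(values: np.ndarray, rows: Sequence[int], beta: int) -> np.ndarray:
    sub = values[list(rows)]
    c = np.corrcoef(sub)
    c = np.nan_to_num(c, nan=0.0)  # zero-variance rows contribute no adjacency
    a = np.abs(np.clip(c, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _stats_for(rows_ref, rows_test, ref_values, test_values, beta_ref, beta_test):
    a_test = _sub_adjacency(test_values, rows_test, beta_test)
    m = a_test.shape[0]
    density = float(a_test.sum() / (m * (m - 1))) if m > 1 else 0.0
    a_ref = _sub_adjacency(ref_values, rows_ref, beta_ref)
    k_ref = a_ref.sum(axis=1)
    k_test = a_test.sum(axis=1)
    if k_ref.std() == 0 or k_test.std() == 0:
        cor_kim = 0.0
    else:
        cor_kim = float(np.corrcoef(k_ref, k_test)[0, 1])
    return density, cor_kim


def _zscore(obs: float, null: np.ndarray) -> tuple[float, float, float]:
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0:
        logger.warning("degenerate permutation null (sd=0); Z reported as +inf")
        return mu, sd, math.inf if obs > mu else (-math.inf if obs < mu else 0.0)
    return mu, sd, (obs - mu) / sd


def module_preservation(
    ref_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    assignment: ModuleAssignment | Mapping[str, int],
    beta_test: int,
    beta_ref: int | None = None,
    n_perm: int = 200,
    seed: int = 17,
    min_module_genes: int = 3,
) -> list[PreservationResult]:
    """Z_summary preservation of reference modules in a test dataset.

    Gene universes are intersected first; modules dropping below
    ``min_module_genes`` shared genes are skipped with a warning. The
    null draws ``n_perm`` random gene sets of the module's size from the
    shared universe excluding the module's own genes.
    """
    if beta_ref is None:
        beta_ref = beta_test
    labels = assignment.labels if isinstance(assignment, ModuleAssignment) else dict(assignment)

    shared = [g for g in ref_expr.gene_ids if g in set(test_expr.gene_ids)]
    shared_set = set(shared)
    ref_idx = ref_expr.gene_index()
    test_idx = test_expr.gene_index()

    modules: dict[int, list[str]] = {}
    for g, m in labels.items():
        if m != 0 and g in shared_set:
            modules.setdefault(m, []).append(g)
    dropped = {m for m in set(labels.values()) if m != 0} - set(modules)
    small = {m for m, gs in modules.items() if len(gs) < min_module_genes}
    for m in sorted(dropped | small):
        logger.warning("module %s: < %d shared genes, skipped", m, min_module_genes)
    modules = {m: gs for m, gs in modules.items() if m not in small}
    if not modules:
        return []

    max_size = max(len(gs) for gs in modules.values())
    if len(shared) < 2 * max_size:
        raise ValueError(
            f"shared gene universe ({len(shared)}) smaller than twice the "
            f"largest module ({max_size}); null draws would be degenerate"
        )

    rng = np.random.default_rng([seed, 211])
    results: list[PreservationResult] = []
    for m in sorted(modules):
        genes = modules[m]
        rows_ref = [ref_idx[g] for g in genes]
        rows_test = [test_idx[g] for g in genes]
        obs_density, obs_cor = _stats_for(
            rows_ref, rows_test, ref_expr.values, test_expr.values, beta_ref, beta_test
        )
        pool = [g for g in shared if g not in set(genes)]
        null_density = np.empty(n_perm)
        null_cor = np.empty(n_perm)
        for i in range(n_perm):
            pick = rng.choice(len(pool), size=len(genes), replace=False)
            sample = [pool[j] for j in pick]
            sr = [ref_idx[g] for g in sample]
            st = [test_idx[g] for g in sample]
            null_density[i], null_cor[i] = _stats_for(
                sr, st, ref_expr.values, test_expr.values, beta_ref, beta_test
            )
        dmu, dsd, z_d = _zscore(obs_density, null_density)
        cmu, csd, z_c = _zscore(obs_cor, null_cor)
        z_summary = (z_d + z_c) / 2.0
        results.append(
            PreservationResult(
                module=int(m),
                size=len(genes),
                mean_adjacency=obs_density,
                cor_kim=obs_cor,
                null_density_mean=dmu,
                null_density_sd=dsd,
                null_connectivity_mean=cmu,
                null_connectivity_sd=csd,
                z_density=z_d,
                z_connectivity=z_c,
                z_summary=z_summary,
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def common_modules(
    results: Sequence[PreservationResult],
    reference: str = "reference",
    test: str = "test",
    z_cut: float = 2.0,
) -> list[CommonModuleCall]:
    """Call modules common when Z_summary >= z_cut (inclusive bound)."""
    return [
        CommonModuleCall(
            reference=reference,
            test=test,
            module=r.module,
            z_summary=r.z_summary,
            is_common=bool(r.z_summary >= z_cut),
        )
        for r in results
    ]


def module_level_shared_genes(
    calls_by_pair: Mapping[tuple[str, str], Sequence[CommonModuleCall]],
    module_sets: Mapping[tuple[str, int], GeneSet],
) -> GeneSet:
    """Union of member genes of modules called common in any pairing.

    ``module_sets`` maps (reference disease, module id) to the module's
    gene set; every module flagged common in at least one pairwise
    comparison contributes its genes.
    """
    genes: set[str] = set()
    for (ref, _test), calls in calls_by_pair.items():
        for call in calls:
            if call.is_common:
                genes |= set(module_sets[(ref, call.module)].genes)
    return GeneSet.from_iterable("module_shared", sorted(genes))


def results_to_frame(results: Sequence[PreservationResult]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
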