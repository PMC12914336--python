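"""Synthetic three-disease expression data and interactome with ground truth.

The generator emulates the statistical structure the pipeline assumes:
each disease dataset carries planted coexpression modules built from a
one-factor Gaussian model, some modules shared across diseases (same
member genes), a subset of module genes carrying a case/control mean
shift with alternating sign, and an interaction network in which planted
"bridge" nodes are the only route between module node-sets — giving
analytic ground truth for driver-gene scoring.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np

from .datatypes import ExpressionMatrix, GeneSet, SampleGroups

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "GroundTruth", "simulate_disease_datasets", "simulate_interactome"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    ``disease_modules`` lists, per disease, which planted modules that
    disease carries; modules appearing under more than one disease use
    the same member gene ids (shared modules). ``within_module_cor`` is
    the factor-model loading rho: a member gene is
    sqrt(rho)*factor + sqrt(1-rho)*noise, so with unit noise_sd the
    expected pairwise within-module correlation equals rho.
    ``de_effect`` is the case-group mean shift (log2 units) applied to a
    ``de_fraction`` of each module's genes with alternating sign.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 10
    module_sizes: tuple[int, ...] = (50, 50, 50, 50, 50)
    disease_modules: tuple[tuple[int, ...], ...] = ((0, 1, 2), (0, 1, 3), (0, 1, 4))
    disease_names: tuple[str, ...] = ("disease_a", "disease_b", "disease_c")
    within_module_cor: float = 0.64
    de_effect: float = 2.0
    de_fraction: float = 0.3
    noise_sd: float = 1.0
    baseline: float = 8.0
    # interactome
    n_background_nodes: int = 40
    n_bridge_nodes: int = 4
    edge_prob: float = 0.5
    max_rewire_attempts: int = 25
    seed: int = 17

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if len(self.disease_modules) != len(self.disease_names):
            raise ValueError("disease_modules and disease_names length mismatch")
        for mods in self.disease_modules:
            for m in mods:
                if not 0 <= m < len(self.module_sizes):
                    raise ValueError(f"module index {m} out of range")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic run."""

    module_genes: dict[int, tuple[str, ...]]
    disease_modules: dict[str, tuple[int, ...]]
    shared_modules: tuple[int, ...]  # module indices in >= 2 diseases
    true_de: dict[str, dict[str, int]] = field(default_factory=dict)  # gene -> +-1
    bridge_nodes: tuple[str, ...] = ()

    def module_gene_set(self, module: int) -> GeneSet:
        return GeneSet(f"M{module}", self.module_genes[module])

    def true_de_set(self, disease: str) -> GeneSet:
        return GeneSet.from_iterable(f"{disease}_true_de", self.true_de[disease])

    def to_dict(self) -> dict:
        return {
            "module_genes": {str(k): list(v) for k, v in self.module_genes.items()},
            "disease_modules": {k: list(v) for k, v in self.disease_modules.items()},
            "shared_modules": list(self.shared_modules),
            "true_de": {d: dict(sorted(g.items())) for d, g in self.true_de.items()},
            "bridge_nodes": list(self.bridge_nodes),
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _module_blocks(spec: SyntheticSpec) -> dict[int, tuple[str, ...]]:
    genes = _gene_ids(spec.n_genes)
    blocks: dict[int, tuple[str, ...]] = {}
    start = 0
    for m, size in enumerate(spec.module_sizes):
        blocks[m] = tuple(genes[start : start + size])
        start += size
    return blocks


def _de_flags(block: Sequence[str], de_fraction: float) -> dict[str, int]:
    """Deterministic DE flags: first round(f*size) genes, signs alternating."""
    n_de = int(round(de_fraction * len(block)))
    return {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(block[:n_de])}


def simulate_disease_datasets(
    spec: SyntheticSpec,
) -> tuple[list[tuple[ExpressionMatrix, SampleGroups]], GroundTruth]:
    """Generate the per-disease expression datasets and their ground truth.

    Each disease gets independent samples (controls first, then cases);
    modules the disease carries are generated from the one-factor model,
    all other genes are pure noise around the baseline.
    """
    rho = spec.within_module_cor
    n_per = spec.n_samples_per_group
    n_samples = 2 * n_per
    genes = _gene_ids(spec.n_genes)
    blocks = _module_blocks(spec)
    gene_pos = {g: i for i, g in enumerate(genes)}

    counts = np.zeros(len(spec.module_sizes), dtype=int)
    for mods in spec.disease_modules:
        counts[list(mods)] += 1
    shared = tuple(int(m) for m in np.flatnonzero(counts >= 2))

    truth = GroundTruth(
        module_genes=blocks,
        disease_modules={
            name: tuple(mods)
            for name, mods in zip(spec.disease_names, spec.disease_modules)
        },
        shared_modules=shared,
    )

    datasets: list[tuple[ExpressionMatrix, SampleGroups]] = []
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.disease_names))
    for name, mods, child in zip(spec.disease_names, spec.disease_modules, children):
        rng = np.random.default_rng(child)
        case_mask = np.zeros(n_samples)
        case_mask[n_per:] = 1.0

        x = spec.baseline + spec.noise_sd * rng.standard_normal(
            (spec.n_genes, n_samples)
        )
        de_map: dict[str, int] = {}
        for m in mods:
            block = blocks[m]
            rows = [gene_pos[g] for g in block]
            factor = rng.standard_normal(n_samples)
            eps = spec.noise_sd * rng.standard_normal((len(block), n_samples))
            x[rows] = (
                spec.baseline
                + np.sqrt(rho) * factor
                + np.sqrt(1.0 - rho) * eps
            )
            for g, sign in _de_flags(block, spec.de_fraction).items():
                if spec.de_effect != 0:
                    de_map[g] = sign
                    x[gene_pos[g]] += sign * spec.de_effect * case_mask

        sample_ids = [f"{name}_ctrl_{i + 1:02d}" for i in range(n_per)] + [
            f"{name}_case_{i + 1:02d}" for i in range(n_per)
        ]
        labels = {s: ("control" if i < n_per else "case") for i, s in enumerate(sample_ids)}
        expr = ExpressionMatrix(tuple(genes), tuple(sample_ids), x)
        groups = SampleGroups(name, labels)
        datasets.append((expr, groups))
        truth.true_de[name] = de_map

    return datasets, truth


def simulate_interactome(
    spec: SyntheticSpec,
    modules: Sequence[GeneSet],
    seed: int | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Wire an interactome with planted bridge nodes between module sets.

    Each module's nodes form a dense G(n, p) subgraph; bridge nodes
    connect to at least one node in *every* module; the only edges
    between different modules run through bridges; background nodes
    attach inside a single randomly chosen module. Regenerates up to
    ``max_rewire_attempts`` times until the graph is connected.
    """
    if len(modules) < 2:
        raise ValueError("need at least two module node-sets")
    node_sets = [list(gs.genes) for gs in modules]
    flat = [g for ns in node_sets for g in ns]
    if len(set(flat)) != len(flat):
        raise ValueError("module node-sets must be disjoint")
    if spec.n_bridge_nodes < 1:
        raise ValueError(
            "at least one bridge node is required: direct inter-module edges "
            "are forbidden, so a bridgeless graph cannot be connected"
        )

    rng = np.random.default_rng([0 if seed is None else seed, spec.seed, 911])
    p = spec.edge_prob
    bridges = tuple(f"BR{i:03d}" for i in range(1, spec.n_bridge_nodes + 1))

    for attempt in range(spec.max_rewire_attempts):
        graph = nx.Graph()
        for ns in node_sets:
            graph.add_nodes_from(ns)
            for i in range(len(ns)):
                for j in range(i + 1, len(ns)):
                    if rng.random() < p:
                        graph.add_edge(ns[i], ns[j])
        for b in bridges:
            graph.add_node(b)
            for ns in node_sets:
                hits = [g for g in ns if rng.random() < p]
                if not hits:  # bridge must touch every module
                    hits = [ns[int(rng.integers(len(ns)))]]
                for g in hits:
                    graph.add_edge(b, g)
        for k in range(1, spec.n_background_nodes + 1):
            bg = f"BG{k:03d}"
            ns = node_sets[int(rng.integers(len(node_sets)))]
            n_attach = 1 + int(rng.binomial(2, 0.5))
            targets = rng.choice(len(ns), size=min(n_attach, len(ns)), replace=False)
            for t in targets:
                graph.add_edge(bg, ns[int(t)])
        if nx.is_connected(graph):
            if attempt:
                logger.info("interactome connected after %d rewires", attempt)
            truth = GroundTruth(
                module_genes={i: tuple(ns) for i, ns in enumerate(node_sets)},
                disease_modules={},
                shared_modules=(),
                bridge_nodes=bridges,
            )
            return graph, truth
    raise RuntimeError(
        f"could not generate a connected interactome in "
        f"{spec.max_rewire_attempts} attempts"
    )
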