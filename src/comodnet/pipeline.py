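"""End-to-end orchestration of the comorbid-module pipeline.

Stages: differential expression per disease -> coexpression modules per
disease -> pairwise Z_summary preservation (both directions) -> driver
scoring on the interactome for each disease pair -> key-gene
integration. Works either from three expression/group files plus an
interactome edge list (RunConfig paths) or from a SyntheticSpec, in
which case datasets, interactome, and ground truth are generated.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

from . import io
from .coexpression import (
    ModuleAssignment,
    build_network,
    detect_modules,
    drop_constant_genes,
    module_trait_correlation,
    pick_soft_threshold,
)
from .datatypes import ExpressionMatrix, GeneSet, RunConfig, SampleGroups
from .diffexpr import moderated_t, overlap_degs, records_to_frame, screen_degs
from .drivers import DriverScoreTable, flow_centrality, screen_drivers
from .integrate import KeyGeneReport, integrate_key_genes
from .preservation import (
    CommonModuleCall,
    common_modules,
    module_level_shared_genes,
    module_preservation,
    results_to_frame,
)
from .synthetic import GroundTruth, SyntheticSpec, simulate_disease_datasets, simulate_interactome

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "write_outputs"]


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: RunConfig
    disease_names: list[str]
    deg_records: dict = field(default_factory=dict)  # disease -> list[DEGRecord]
    deg_sets: dict = field(default_factory=dict)  # disease -> (up, down)
    deg_shared: GeneSet | None = None
    betas: dict = field(default_factory=dict)  # disease -> int
    assignments: dict = field(default_factory=dict)  # disease -> ModuleAssignment
    trait_results: dict = field(default_factory=dict)
    preservation: dict = field(default_factory=dict)  # (ref, test) -> results
    common_calls: dict = field(default_factory=dict)  # (ref, test) -> calls
    module_shared: GeneSet | None = None
    driver_tables: dict = field(default_factory=dict)  # (d1, d2) -> DriverScoreTable
    driver_call: object = None
    key_report: KeyGeneReport | None = None
    truth: GroundTruth | None = None

    def report_dict(self) -> dict:
        cfg = self.config.to_dict()
        report = {
            "config": cfg,
            "diseases": list(self.disease_names),
            "deg_counts": {
                d: {"up": len(up), "down": len(down)}
                for d, (up, down) in self.deg_sets.items()
            },
            "deg_shared": sorted(self.deg_shared.genes) if self.deg_shared else [],
            "betas": {d: int(b) for d, b in self.betas.items()},
            "module_counts": {
                d: len(a.module_ids()) for d, a in self.assignments.items()
            },
            "common_module_calls": {
                f"{ref}->{test}": [
                    {"module": c.module, "z_summary": round(c.z_summary, 6), "is_common": c.is_common}
                    for c in calls
                ]
                for (ref, test), calls in sorted(self.common_calls.items())
            },
            "module_shared": sorted(self.module_shared.genes) if self.module_shared else [],
            "drivers": sorted(self.driver_call.drivers.genes) if self.driver_call else [],
            "key_genes": self.key_report.to_dict() if self.key_report else {},
        }
        return report


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named re-raise
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


@_stage("load")
def _load_datasets(config: RunConfig) -> list[tuple[ExpressionMatrix, SampleGroups]]:
    if len(config.datasets) != 3:
        raise ValueError("need exactly three (name, expr, groups) dataset entries")
    out = []
    for name, expr_path, groups_path in config.datasets:
        expr = io.read_expression(expr_path)
        groups = io.read_sample_groups(groups_path, disease_name=name)
        groups.validate_against(expr)
        out.append((expr, groups))
    return out


@_stage("deg")
def _deg_stage(result: PipelineResult, datasets, config: RunConfig) -> None:
    pairs = []
    for expr, groups in datasets:
        records, _ = moderated_t(
            expr, groups, lfc_cut=config.lfc_cut, p_cut=config.p_cut,
            p_adjust=config.p_adjust,
        )
        up, down = screen_degs(records, config.lfc_cut, config.p_cut)
        result.deg_records[groups.disease_name] = records
        result.deg_sets[groups.disease_name] = (up, down)
        pairs.append((up, down))
    common_up, common_down, common_union = overlap_degs(pairs)
    if config.deg_shared_rule == "direction_matched":
        result.deg_shared = GeneSet.from_iterable("deg_shared", common_union.genes)
    else:  # direction-agnostic intersection of per-disease DEG unions
        unions = [set(up.genes) | set(down.genes) for up, down in pairs]
        result.deg_shared = GeneSet.from_iterable(
            "deg_shared", sorted(set.intersection(*unions))
        )


@_stage("wgcna")
def _wgcna_stage(result: PipelineResult, datasets, config: RunConfig) -> None:
    for expr, groups in datasets:
        expr_nc = drop_constant_genes(expr)
        if config.beta is not None:
            beta = config.beta
        else:
            scan = pick_soft_threshold(
                expr_nc, candidates=config.beta_candidates, r2_target=config.r2_target
            )
            beta = scan.chosen
        network = build_network(expr_nc, beta)
        assignment = detect_modules(
            network,
            expr_nc,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_cut=config.merge_cut,
        )
        result.betas[groups.disease_name] = beta
        result.assignments[groups.disease_name] = assignment
        if assignment.module_ids():
            result.trait_results[groups.disease_name] = module_trait_correlation(
                expr_nc, assignment, groups
            )


@_stage("preserve")
def _preserve_stage(result: PipelineResult, datasets, config: RunConfig) -> None:
    by_name = {groups.disease_name: expr for expr, groups in datasets}
    names = result.disease_names
    for ref, test in [(a, b) for a, b in combinations(names, 2)] + [
        (b, a) for a, b in combinations(names, 2)
    ]:
        res = module_preservation(
            by_name[ref],
            by_name[test],
            result.assignments[ref],
            beta_test=result.betas[test],
            beta_ref=result.betas[ref],
            n_perm=config.n_perm,
            seed=config.seed,
        )
        result.preservation[(ref, test)] = res
        result.common_calls[(ref, test)] = common_modules(
            res, reference=ref, test=test, z_cut=config.z_cut
        )
    module_sets = {}
    for d in names:
        for gs in result.assignments[d].to_gene_sets(prefix=d):
            module_sets[(d, int(gs.name.rsplit("_", 1)[1]))] = gs
    result.module_shared = module_level_shared_genes(result.common_calls, module_sets)


@_stage("drivers")
def _drivers_stage(result: PipelineResult, graph: nx.Graph, config: RunConfig) -> None:
    names = result.disease_names

    def common_genes(ref: str, other: str) -> list[str]:
        genes: set[str] = set()
        for call in result.common_calls[(ref, other)]:
            if call.is_common:
                genes |= set(result.assignments[ref].module_genes(call.module))
        return sorted(genes)

    tables: dict[tuple[str, str], DriverScoreTable] = {}
    for d1, d2 in combinations(names, 2):
        a_genes = common_genes(d1, d2)
        b_genes = common_genes(d2, d1)
        if not a_genes or not b_genes:
            raise ValueError(
                f"pair ({d1}, {d2}): no common-module genes to score drivers on"
            )
        a = GeneSet(f"{d1}_common", tuple(a_genes))
        b = GeneSet(f"{d2}_common", tuple(b_genes))
        tables[(d1, d2)] = flow_centrality(graph, a, b, pair_name=(d1, d2))
    result.driver_tables = tables
    result.driver_call = screen_drivers(tables, k=config.top_k)


@_stage("integrate")
def _integrate_stage(result: PipelineResult) -> None:
    result.key_report = integrate_key_genes(
        result.deg_shared, result.module_shared, result.driver_call.drivers
    )


def run_pipeline(
    config: RunConfig,
    spec: SyntheticSpec | None = None,
    interactome: nx.Graph | None = None,
) -> PipelineResult:
    """Run every stage and return the assembled result.

    With ``spec`` given, datasets (and, unless supplied, an interactome
    planted on the shared modules) are simulated; otherwise the three
    datasets and the interactome are loaded from the paths in
    ``config``.
    """
    truth = None
    if spec is not None:
        datasets, truth = simulate_disease_datasets(spec)
        if interactome is None:
            shared_sets = [truth.module_gene_set(m) for m in truth.shared_modules]
            if len(shared_sets) < 2:
                raise PipelineError("simulate", "need >= 2 planted shared modules for the interactome")
            interactome, net_truth = simulate_interactome(spec, shared_sets)
            truth.bridge_nodes = net_truth.bridge_nodes
    else:
        if interactome is None:
            # validate the drivers-stage input up front
            if not config.interactome_path:
                raise PipelineError("drivers", "no interactome file configured")
            if not Path(config.interactome_path).exists():
                raise PipelineError(
                    "drivers", f"interactome file not found: {config.interactome_path}"
                )
            interactome = io.read_edge_list(config.interactome_path)
        datasets = _load_datasets(config)

    result = PipelineResult(
        config=config,
        disease_names=[groups.disease_name for _, groups in datasets],
        truth=truth,
    )
    _deg_stage(result, datasets, config)
    _wgcna_stage(result, datasets, config)
    _preserve_stage(result, datasets, config)
    _drivers_stage(result, interactome, config)
    _integrate_stage(result)
    return result


def write_outputs(result: PipelineResult, outdir) -> Path:
    """Write stage tables, gene sets, and the JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for d, records in result.deg_records.items():
        io.write_table(records_to_frame(records), outdir / f"deg_{d}.tsv")
    sets = []
    for d, (up, down) in result.deg_sets.items():
        if len(up.genes):
            sets.append(GeneSet(f"{d}_up", up.genes))
        if len(down.genes):
            sets.append(GeneSet(f"{d}_down", down.genes))
    if sets:
        io.write_gene_sets(sets, outdir / "deg_sets.gmt")
    module_sets = []
    for d, assignment in result.assignments.items():
        module_sets.extend(assignment.to_gene_sets(prefix=d))
    if module_sets:
        io.write_gene_sets(module_sets, outdir / "modules.gmt")
    for (ref, test), res in result.preservation.items():
        if res:
            io.write_table(results_to_frame(res), outdir / f"preservation_{ref}_vs_{test}.tsv")
    for (d1, d2), table in result.driver_tables.items():
        io.write_table(table.scores, outdir / f"drivers_{d1}_vs_{d2}.tsv")
    report = result.report_dict()
    report["outputs"] = sorted(p.name for p in outdir.iterdir() if p.suffix in (".tsv", ".gmt"))
    io.write_report(report, outdir / "report.json")
    return outdir / "report.json"
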