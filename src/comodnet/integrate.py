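"""Key-gene integration across evidence tiers.

Key genes combine two lines of evidence: genes shared at both the DEG
level and the common-module level (their intersection), plus the
network driver genes. Each key gene carries provenance tags naming the
tiers that support it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import GeneSet

__all__ = ["KeyGeneReport", "integrate_key_genes"]


@dataclass
class KeyGeneReport:
    deg_shared: GeneSet
    module_shared: GeneSet
    deg_module_intersection: GeneSet
    drivers: GeneSet
    key_genes: GeneSet
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "deg_shared": sorted(self.deg_shared.genes),
            "module_shared": sorted(self.module_shared.genes),
            "deg_module_intersection": sorted(self.deg_module_intersection.genes),
            "drivers": sorted(self.drivers.genes),
            "key_genes": sorted(self.key_genes.genes),
            "provenance": {g: list(t) for g, t in sorted(self.provenance.items())},
        }


def integrate_key_genes(
    deg_shared: GeneSet, module_shared: GeneSet, drivers: GeneSet
) -> KeyGeneReport:
    """key_genes = (deg_shared intersect module_shared) union drivers."""
    inter = sorted(set(deg_shared.genes) & set(module_shared.genes))
    key = sorted(set(inter) | set(drivers.genes))
    provenance: dict[str, tuple[str, ...]] = {}
    for g in key:
        tiers = []
        if g in set(inter):
            tiers.append("deg_module_intersection")
        if g in set(drivers.genes):
            tiers.append("driver")
        provenance[g] = tuple(tiers)
    return KeyGeneReport(
        deg_shared=deg_shared,
        module_shared=module_shared,
        deg_module_intersection=GeneSet.from_iterable("deg_module_intersection", inter),
        drivers=drivers,
        key_genes=GeneSet.from_iterable("key_genes", key),
        provenance=provenance,
    )
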