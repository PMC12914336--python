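"""Core containers shared by every pipeline stage.

All stages exchange three small immutable containers — an expression
matrix on log2 scale, case/control sample labels, and named gene sets —
plus a run configuration holding every threshold and the global seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np

__all__ = ["ExpressionMatrix", "SampleGroups", "GeneSet", "RunConfig"]


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Gene and sample identifiers are unique and ordered; the value matrix
    is dense float64 with every entry finite (missing values must be
    resolved — collapsed or dropped — before construction).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids after collapse")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        index = self.gene_index()
        keep = [g for g in genes if g in index]
        rows = [index[g] for g in keep]
        return ExpressionMatrix(tuple(keep), self.sample_ids, self.values[rows])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df) -> "ExpressionMatrix":
        return cls(
            tuple(str(g) for g in df.index),
            tuple(str(s) for s in df.columns),
            df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SampleGroups:
    """Case/control labels for one disease dataset."""

    disease_name: str
    labels: Mapping[str, str]  # sample_id -> "case" | "control"

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"labels must be 'case'/'control', got {sorted(bad)}")
        if len(self.case_ids) < 2 or len(self.control_ids) < 2:
            raise ValueError(
                f"{self.disease_name}: need >= 2 case and >= 2 control samples"
            )

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.labels.items() if g == "case")

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.labels.items() if g == "control")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in expr.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(
                f"{self.disease_name}: samples without group label: {missing[:5]}"
            )

    def trait_vector(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Binary trait (control=0, case=1) in the given sample order."""
        return np.array(
            [1.0 if self.labels[s] == "case" else 0.0 for s in sample_ids]
        )


@dataclass(frozen=True)
class GeneSet:
    """Named, ordered collection of unique gene identifiers."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str], description: str = "") -> "GeneSet":
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g, None)
        return cls(name, tuple(seen), description)


@dataclass
class RunConfig:
    """Thresholds, permutation counts, and the global seed for one run.

    Defaults follow the screening rules the pipeline is built around:
    |log2FC| > 1 with p < 0.05 for differential expression, Z_summary >= 2
    for cross-disease module preservation, and top-10 screening for
    network driver genes.
    """

    lfc_cut: float = 1.0
    p_cut: float = 0.05
    z_cut: float = 2.0
    top_k: int = 10
    n_perm: int = 200
    seed: int = 17
    # coexpression network options
    beta: int | None = 6  # None = choose by scale-free fit per dataset
    beta_candidates: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_cut: float = 0.25
    # DEG-level shared genes: "direction_matched" (common-up union
    # common-down) or "direction_agnostic" (intersection of per-disease
    # DEG unions)
    deg_shared_rule: str = "direction_matched"
    p_adjust: str = "none"  # or "bh"
    # file inputs for a non-synthetic run: [(name, expr_path, groups_path)]
    datasets: list[tuple[str, str, str]] = field(default_factory=list)
    interactome_path: str | None = None

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0:
            raise ValueError("lfc_cut must be > 0")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_perm < 50:
            raise ValueError("n_perm must be >= 50")
        if self.deg_shared_rule not in ("direction_matched", "direction_agnostic"):
            raise ValueError(f"unknown deg_shared_rule {self.deg_shared_rule!r}")
        if self.p_adjust not in ("none", "bh"):
            raise ValueError(f"unknown p_adjust {self.p_adjust!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["datasets"] = [list(t) for t in self.datasets]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "datasets" in raw:
            raw["datasets"] = [tuple(t) for t in raw["datasets"]]
        if "beta_candidates" in raw:
            raw["beta_candidates"] = tuple(raw["beta_candidates"])
        return cls(**raw)
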