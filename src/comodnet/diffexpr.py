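"""Empirical-Bayes moderated t-testing and DEG screening.

Per gene, the pooled two-sample variance is shrunk toward a common prior
variance s0^2 with prior degrees of freedom d0 (both estimated from the
data by moment matching on log sample variances), and the moderated
t-statistic is referred to a t distribution with d0 + d degrees of
freedom. Genes pass the screen when |log2FC| > lfc_cut and p < p_cut
(strict inequalities); up/down screened sets are intersected across the
three diseases to obtain the direction-matched common DEGs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .datatypes import ExpressionMatrix, GeneSet, SampleGroups

logger = logging.getLogger(__name__)

__all__ = [
    "DEGRecord",
    "ModerationParams",
    "moderated_t",
    "screen_degs",
    "overlap_degs",
]

_D0_CAP = 1e6


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    t_stat: float
    p_value: float
    direction: str  # "up" | "down" | "none"
    passes: bool


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom d0 and prior variance s0^2."""

    d0: float
    s0_sq: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) / y < 1e-10:
            break
    return y


def estimate_moderation(s2: np.ndarray, d: int) -> ModerationParams:
    """Moment-match (d0, s0^2) from per-gene sample variances.

    Under the scaled-F model, log s_g^2 has variance
    trigamma(d/2) + trigamma(d0/2) and a mean offset by digamma terms;
    matching the observed moments gives both hyperparameters. d0 is
    capped at 1e6 (effectively complete pooling).
    """
    z = np.log(s2[s2 > 0])
    if z.size < 2:
        raise ValueError("need >= 2 genes with positive variance to moderate")
    evar = float(np.var(z, ddof=1))
    excess = evar - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        d0 = _D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(excess), _D0_CAP)
    log_s0_sq = (
        float(np.mean(z))
        - float(special.digamma(d / 2.0))
        + math.log(d / 2.0)
        + float(special.digamma(d0 / 2.0))
        - math.log(d0 / 2.0)
    )
    return ModerationParams(d0=d0, s0_sq=math.exp(log_s0_sq))


def moderated_t(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
    params: ModerationParams | None = None,
    p_adjust: str = "none",
) -> tuple[list[DEGRecord], ModerationParams]:
    """Per-gene moderated two-sample t-test (case vs control).

    log2FC is the difference of group means of the (already log2)
    values. Passing ``params`` overrides the moment-matched prior;
    ``ModerationParams(0, 1)`` reduces to the ordinary pooled t-test.
    """
    groups.validate_against(expr)
    sample_index = {s: j for j, s in enumerate(expr.sample_ids)}
    case = [sample_index[s] for s in groups.case_ids if s in sample_index]
    ctrl = [sample_index[s] for s in groups.control_ids if s in sample_index]
    n1, n2 = len(case), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples present in the matrix")

    xc = expr.values[:, case]
    x0 = expr.values[:, ctrl]
    lfc = xc.mean(axis=1) - x0.mean(axis=1)
    d = n1 + n2 - 2
    ss = xc.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    if params is None:
        if np.all(s2 == 0):
            logger.warning(
                "%s: all genes have zero pooled variance; falling back to "
                "ordinary t", groups.disease_name,
            )
            params = ModerationParams(0.0, 1.0)
        else:
            params = estimate_moderation(s2, d)

    s2_tilde = (params.d0 * params.s0_sq + d * s2) / (params.d0 + d)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
    # total df bounded by the pooled information across all genes
    df = min(params.d0 + d, expr.n_genes * d, _D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if p_adjust == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif p_adjust != "none":
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    records = []
    for g, fc, tg, pg in zip(expr.gene_ids, lfc, t, p):
        passes = bool(abs(fc) > lfc_cut and pg < p_cut)
        direction = "none" if not passes else ("up" if fc > 0 else "down")
        records.append(DEGRecord(g, float(fc), float(tg), float(pg), direction, passes))
    return records, params


def screen_degs(
    records: Sequence[DEGRecord], lfc_cut: float = 1.0, p_cut: float = 0.05
) -> tuple[GeneSet, GeneSet]:
    """Split records into up/down DEG sets at strict thresholds."""
    up = [r.gene_id for r in records if r.log2fc > lfc_cut and r.p_value < p_cut]
    down = [r.gene_id for r in records if r.log2fc < -lfc_cut and r.p_value < p_cut]
    return (
        GeneSet.from_iterable("up", up),
        GeneSet.from_iterable("down", down),
    )


def overlap_degs(
    deg_pairs: Sequence[tuple[GeneSet, GeneSet]],
) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Direction-matched DEG overlap across diseases.

    Returns (common_up, common_down, common_union) where common_up is
    the intersection of all up-sets, common_down of all down-sets, and
    the union combines both.
    """
    if not deg_pairs:
        raise ValueError("need at least one (up, down) pair")
    common_up = set.intersection(*(set(up.genes) for up, _ in deg_pairs))
    common_down = set.intersection(*(set(down.genes) for _, down in deg_pairs))
    return (
        GeneSet.from_iterable("common_up", sorted(common_up)),
        GeneSet.from_iterable("common_down", sorted(common_down)),
        GeneSet.from_iterable("common_union", sorted(common_up | common_down)),
    )


def records_to_frame(records: Sequence[DEGRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "t_stat": [r.t_stat for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
            "passes": [r.passes for r in records],
        }
    )
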