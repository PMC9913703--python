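"""Cross-cohort signature refinement with directional rank tests.

Each signature gene is tested for a disease-versus-control location shift
(Hodges-Lehmann estimate + two-sided Wilcoxon rank-sum p) in two independent
cohorts.  A gene survives refinement only if its shift has the same non-zero
sign in both cohorts and passes the p threshold in both; its refined
direction label comes from the patient-data sign, not the in vitro label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from osap.association_stats import mann_whitney
from osap.expression_io import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class GeneCohortStat:
    """Location shift (case - control) and rank-test p for one gene in one cohort."""

    gene_id: str
    cohort_id: str
    estimate: float  # Hodges-Lehmann: median of all pairwise case-control differences
    p_value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.estimate):
            raise ValueError(f"{self.gene_id}: non-finite estimate")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.gene_id}: p-value out of (0, 1]: {self.p_value}")


def hodges_lehmann(case: np.ndarray, control: np.ndarray) -> float:
    """Median of all pairwise differences case[i] - control[j]."""
    diffs = np.subtract.outer(np.asarray(case, float), np.asarray(control, float))
    return float(np.median(diffs))


def per_gene_rank_test(
    matrix: ExpressionMatrix,
    case_ids: list[str],
    control_ids: list[str],
    genes: list[str],
    cohort_id: str = "cohort",
) -> list[GeneCohortStat]:
    """Hodges-Lehmann shift and two-sided Wilcoxon rank-sum p per gene.

    Genes absent from the matrix are reported via a warning and skipped.
    """
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("each group needs >=2 samples")
    case = matrix.subset_samples(case_ids)
    control = matrix.subset_samples(control_ids)
    row = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in genes if g not in row]
    if missing:
        logger.warning("cohort %s: %d gene(s) absent, skipped: %s",
                       cohort_id, len(missing), ", ".join(missing))
    stats: list[GeneCohortStat] = []
    for g in genes:
        if g not in row:
            continue
        cv = case.values[row[g]]
        kv = control.values[row[g]]
        mw = mann_whitney(cv, kv)
        stats.append(GeneCohortStat(
            gene_id=g,
            cohort_id=cohort_id,
            estimate=hodges_lehmann(cv, kv),
            p_value=mw.p_value,
        ))
    return stats


def refine_signature(
    sig: GeneSignature,
    stats_a: list[GeneCohortStat],
    stats_b: list[GeneCohortStat],
    p_threshold: float = 0.05,
    require_significance: bool = True,
    bh_correct: bool = False,
) -> GeneSignature:
    """Keep genes with sign-consistent non-zero shifts in both cohorts.

    With ``require_significance`` (default) the gene must also reach
    ``p_threshold`` in both cohorts; with ``bh_correct`` the per-cohort
    p-values are Benjamini-Hochberg adjusted first.  Retained genes are
    relabeled by the shared patient-data sign and ordered by descending mean
    absolute shift.
    """
    by_gene_a = {s.gene_id: s for s in stats_a}
    by_gene_b = {s.gene_id: s for s in stats_b}
    universe = [g for g in sig.genes]
    missing = [g for g in universe if g not in by_gene_a or g not in by_gene_b]
    if missing:
        logger.warning("refinement: %d gene(s) missing from a cohort, skipped: %s",
                       len(missing), ", ".join(missing))
    testable = [g for g in universe if g not in set(missing)]

    if bh_correct:
        adj_a = _bh_adjust({g: by_gene_a[g].p_value for g in testable})
        adj_b = _bh_adjust({g: by_gene_b[g].p_value for g in testable})
    else:
        adj_a = {g: by_gene_a[g].p_value for g in testable}
        adj_b = {g: by_gene_b[g].p_value for g in testable}

    kept_up: list[tuple[str, float]] = []
    kept_down: list[tuple[str, float]] = []
    for g in testable:
        ea, eb = by_gene_a[g].estimate, by_gene_b[g].estimate
        if np.sign(ea) != np.sign(eb) or ea == 0 or eb == 0:
            continue
        if require_significance and not (adj_a[g] < p_threshold and adj_b[g] < p_threshold):
            continue
        strength = (abs(ea) + abs(eb)) / 2.0
        if ea > 0:
            kept_up.append((g, strength))
        else:
            kept_down.append((g, strength))

    if not kept_up and not kept_down:
        raise ValueError(
            "refined signature is empty; consider relaxing p_threshold or "
            "disabling the significance requirement"
        )
    kept_up.sort(key=lambda t: (-t[1], t[0]))
    kept_down.sort(key=lambda t: (-t[1], t[0]))
    return GeneSignature(
        name=sig.name + "_refined",
        up=[g for g, _ in kept_up],
        down=[g for g, _ in kept_down],
    )


def _bh_adjust(pvals: dict[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg adjusted p-values."""
    items = sorted(pvals.items(), key=lambda t: t[1])
    m = len(items)
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        g, p = items[rank - 1]
        running_min = min(running_min, p * m / rank)
        adjusted[rank - 1] = running_min
    return {items[i][0]: adjusted[i] for i in range(m)}


def stats_to_rows(stats: list[GeneCohortStat]) -> list[dict[str, object]]:
    return [
        {"gene_id": s.gene_id, "cohort_id": s.cohort_id,
         "estimate": s.estimate, "p_value": s.p_value}
        for s in stats
    ]
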