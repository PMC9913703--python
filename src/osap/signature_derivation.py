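"""Core-signature derivation by intersecting fold-change calls across contrasts.

A gene enters the signature only if its log2 fold change clears the cutoff,
in the same direction, in every case-versus-reference comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from osap.expression_io import ExpressionMatrix, GeneSignature


@dataclass
class ComparisonSpec:
    """One case-vs-reference contrast defined by sample IDs."""

    name: str
    case_sample_ids: list[str]
    reference_sample_ids: list[str]

    def __post_init__(self) -> None:
        if not self.case_sample_ids or not self.reference_sample_ids:
            raise ValueError(f"comparison {self.name!r}: case and reference must be non-empty")
        overlap = set(self.case_sample_ids) & set(self.reference_sample_ids)
        if overlap:
            raise ValueError(
                f"comparison {self.name!r}: samples in both case and reference: {sorted(overlap)}"
            )


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold changes (case mean - reference mean) per comparison."""

    gene_ids: list[str]
    comparison_names: list[str]
    lfc: np.ndarray

    def __post_init__(self) -> None:
        self.lfc = np.asarray(self.lfc, dtype=float)
        if self.lfc.shape != (len(self.gene_ids), len(self.comparison_names)):
            raise ValueError("lfc shape inconsistent with gene/comparison counts")
        if not np.all(np.isfinite(self.lfc)):
            raise ValueError("fold changes must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.lfc, index=self.gene_ids, columns=self.comparison_names)


def compute_fold_changes(
    matrix: ExpressionMatrix, specs: list[ComparisonSpec]
) -> FoldChangeTable:
    """log2 fold change per gene and comparison, as difference of group means.

    The matrix must already be on the log2 scale with unique gene IDs.
    """
    if len(set(matrix.gene_ids)) != len(matrix.gene_ids):
        raise ValueError("gene IDs must be unique (collapse probes first)")
    if not specs:
        raise ValueError("no comparisons supplied")
    col_index = {s: j for j, s in enumerate(matrix.sample_ids)}
    lfc = np.empty((matrix.n_genes, len(specs)), dtype=float)
    for c, spec in enumerate(specs):
        for sid in spec.case_sample_ids + spec.reference_sample_ids:
            if sid not in col_index:
                raise KeyError(f"comparison {spec.name!r}: unknown sample ID {sid!r}")
        case = matrix.values[:, [col_index[s] for s in spec.case_sample_ids]]
        ref = matrix.values[:, [col_index[s] for s in spec.reference_sample_ids]]
        lfc[:, c] = case.mean(axis=1) - ref.mean(axis=1)
    return FoldChangeTable(list(matrix.gene_ids), [s.name for s in specs], lfc)


def derive_core_signature(
    fc: FoldChangeTable,
    cutoff: float = 1.5,
    name: str = "CORE",
    inclusive: bool = True,
) -> GeneSignature:
    """Intersect per-contrast calls: up needs lfc >= log2(cutoff) in ALL
    comparisons, down needs lfc <= -log2(cutoff) in ALL.

    ``cutoff`` is a linear ratio (> 1).  ``inclusive`` toggles >= versus >
    at the threshold.  Output genes are ordered by descending mean |lfc|, so
    the strongest hits head each list.
    """
    if not cutoff > 1:
        raise ValueError(f"cutoff must exceed 1 (linear ratio), got {cutoff}")
    thr = np.log2(cutoff)
    if inclusive:
        # small absolute tolerance so means that are exactly at the threshold
        # up to float rounding still count as >=
        tol = 1e-9
        up_mask = np.all(fc.lfc >= thr - tol, axis=1)
        down_mask = np.all(fc.lfc <= -thr + tol, axis=1)
    else:
        up_mask = np.all(fc.lfc > thr, axis=1)
        down_mask = np.all(fc.lfc < -thr, axis=1)
    mean_abs = np.abs(fc.lfc).mean(axis=1)

    def ordered(mask: np.ndarray) -> list[str]:
        idx = np.flatnonzero(mask)
        # descending mean |lfc|, ties by gene ID for determinism
        keyed = sorted(idx, key=lambda i: (-mean_abs[i], fc.gene_ids[i]))
        return [fc.gene_ids[i] for i in keyed]

    up = ordered(up_mask)
    down = ordered(down_mask)
    if not up and not down:
        raise ValueError(f"no gene passes cutoff {cutoff} in all comparisons")
    return GeneSignature(name=name, up=up, down=down)
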