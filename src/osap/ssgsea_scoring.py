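"""Single-sample gene-set enrichment (ssGSEA) running-sum engine.

For one sample, genes are ranked by descending expression and assigned
integer ranks N..1.  The enrichment score of a gene set is

    ES = sum_{i=1..N} [ P_in^w(i) - P_out(i) ]

where ``P_in^w(i)`` is the rank-weighted (weight = rank^alpha) cumulative
fraction of set genes at or above position i, and ``P_out(i)`` the
unweighted cumulative fraction of non-set genes.  Ties in expression are
broken by gene ID, so scores are bit-reproducible and invariant under
strictly monotone transforms of a sample's values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osap.expression_io import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class SsgseaParams:
    """Engine parameters.

    alpha        rank-weight exponent (standard ssGSEA uses 0.25)
    normalize    divide all raw scores by the global score range
    min_overlap  minimum signature genes that must be present in the matrix
    stat         'sum' (ssGSEA convention) or 'max' (classic GSEA deviation)
    """

    alpha: float = 0.25
    normalize: bool = False
    min_overlap: int = 3
    stat: str = "sum"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.stat not in ("sum", "max"):
            raise ValueError("stat must be 'sum' or 'max'")


@dataclass
class RankProfile:
    """Descending-expression gene order for one sample with ranks N..1."""

    sample_id: str
    gene_order: list[str]
    ranks: np.ndarray  # ranks[i] is the rank of gene_order[i]; N at i=0 down to 1
    tie_policy: str = "gene-id-ascending"

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        n = len(self.gene_order)
        if self.ranks.shape != (n,):
            raise ValueError("ranks length must match gene order")
        if n and not np.array_equal(np.sort(self.ranks), np.arange(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..N")

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)


@dataclass
class ScoreMatrix:
    """Signatures x samples enrichment scores, raw and optionally normalized."""

    signature_names: list[str]
    sample_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray | None = None
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.signature_names), len(self.sample_ids)):
            raise ValueError("raw score shape inconsistent with names")

    @property
    def scores(self) -> np.ndarray:
        return self.normalized if self.normalized is not None else self.raw

    def to_frame(self, normalized: bool | None = None) -> pd.DataFrame:
        if normalized is None:
            data = self.scores
        else:
            if normalized and self.normalized is None:
                raise ValueError("no normalized scores present")
            data = self.normalized if normalized else self.raw
        return pd.DataFrame(data, index=self.signature_names, columns=self.sample_ids)

    def signature_scores(self, name: str) -> np.ndarray:
        try:
            i = self.signature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown signature {name!r}") from None
        return self.scores[i]


def rank_profile(matrix: ExpressionMatrix, sample_id: str) -> RankProfile:
    """Rank one sample's genes by descending expression (ties: gene ID ascending)."""
    if matrix.n_genes < 2:
        raise ValueError("ranking needs >=2 genes")
    values = matrix.sample_values(sample_id)
    # sort by (-value, gene_id): lexsort keys are applied last-key-primary
    gene_arr = np.array(matrix.gene_ids)
    order = np.lexsort((gene_arr, -values))
    n = matrix.n_genes
    return RankProfile(
        sample_id=sample_id,
        gene_order=[matrix.gene_ids[i] for i in order],
        ranks=np.arange(n, 0, -1, dtype=float),
    )


def enrichment_score(
    profile: RankProfile, gene_set: set[str] | list[str], alpha: float = 0.25,
    stat: str = "sum",
) -> float:
    """Running-sum enrichment score of ``gene_set`` in one ranked profile.

    Positive when set genes concentrate at the top of the profile, negative
    at the bottom.  ``stat='sum'`` sums the running difference over all
    positions (ssGSEA); ``stat='max'`` takes the maximum deviation (GSEA).
    """
    members = set(gene_set)
    in_set = np.fromiter((g in members for g in profile.gene_order), dtype=bool)
    n = profile.n_genes
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("signature gene overlap below min_overlap: no set gene in profile")
    if k == n:
        raise ValueError("gene set covers every profiled gene; out-of-set ECDF undefined")
    weights = np.where(in_set, profile.ranks ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_set) / (n - k)
    diff = p_in - p_out
    if stat == "sum":
        return float(diff.sum())
    if stat == "max":
        return float(diff[np.argmax(np.abs(diff))])
    raise ValueError("stat must be 'sum' or 'max'")


def score_samples(
    matrix: ExpressionMatrix,
    signatures: list[GeneSignature],
    params: SsgseaParams | None = None,
) -> ScoreMatrix:
    """Score every signature in every sample.

    Two-sided signatures score as ES(up) - ES(down); up-only signatures as
    ES(up).  Signature genes absent from the matrix are dropped with a
    warning; a signature whose present genes (up and down combined) fall
    below ``min_overlap`` is an error.
    """
    if params is None:
        params = SsgseaParams()
    present = set(matrix.gene_ids)
    dropped: dict[str, list[str]] = {}
    effective: list[tuple[str, list[str], list[str]]] = []
    for sig in signatures:
        missing = [g for g in sig.genes if g not in present]
        if missing:
            dropped[sig.name] = missing
            logger.warning(
                "signature %r: %d gene(s) absent from matrix, dropped: %s",
                sig.name, len(missing), ", ".join(missing),
            )
        up = [g for g in sig.up if g in present]
        down = [g for g in sig.down if g in present]
        if len(up) + len(down) < params.min_overlap:
            raise ValueError(
                f"signature {sig.name!r}: only {len(up) + len(down)} gene(s) present, "
                f"below min_overlap={params.min_overlap}"
            )
        effective.append((sig.name, up, down))

    raw = np.empty((len(signatures), matrix.n_samples), dtype=float)
    for j, sid in enumerate(matrix.sample_ids):
        profile = rank_profile(matrix, sid)
        for i, (_, up, down) in enumerate(effective):
            score = 0.0
            if up:
                score += enrichment_score(profile, up, params.alpha, params.stat)
            if down:
                score -= enrichment_score(profile, down, params.alpha, params.stat)
            raw[i, j] = score

    result = ScoreMatrix([s.name for s in signatures], list(matrix.sample_ids), raw,
                         dropped_genes=dropped)
    if params.normalize:
        result = normalize_scores(result)
    return result


def normalize_scores(scores: ScoreMatrix) -> ScoreMatrix:
    """Divide all raw scores by the global (max - min) over the whole matrix."""
    span = float(scores.raw.max() - scores.raw.min())
    if span == 0.0:
        raise ValueError("cannot range-normalize a constant score matrix")
    return ScoreMatrix(
        list(scores.signature_names),
        list(scores.sample_ids),
        scores.raw,
        normalized=scores.raw / span,
        dropped_genes=dict(scores.dropped_genes),
    )


def write_scores(scores: ScoreMatrix, path: str, normalized: bool | None = None) -> None:
    frame = scores.to_frame(normalized=normalized)
    frame.to_csv(path, sep="\t", index_label="signature", float_format="%.17g")


def read_scores(path: str) -> ScoreMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
        frame.to_numpy(dtype=float),
    )
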