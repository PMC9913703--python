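"""Expression-matrix, annotation and gene-set I/O plus array-level preprocessing.

Supported formats: GCT 1.2, plain TSV matrices, GMT gene sets (with an
``_UP``/``_DN`` merging convention for two-sided signatures), and TSV sample
annotation tables with mandatory ``sample_id``/``group``/``cohort`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    ``gene_ids`` may contain duplicates at the probe level; after
    :func:`collapse_probes` they are unique.  All values must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def sample_values(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample ID: {sample_id!r}") from None
        return self.values[:, j]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def log2_transform(self) -> "ExpressionMatrix":
        """Explicit log2(x+1) transform for linear-intensity inputs."""
        if np.any(self.values < 0):
            raise ValueError("log2 transform requires non-negative values")
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), np.log2(self.values + 1.0)
        )


@dataclass
class SampleTable:
    """Per-sample annotations: group and cohort labels plus optional covariates."""

    frame: pd.DataFrame  # index = sample_id; columns include group, cohort

    def __post_init__(self) -> None:
        for col in ("group", "cohort"):
            if col not in self.frame.columns:
                raise ValueError(f"sample table missing mandatory column {col!r}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_ids: {dups}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def samples_in_group(self, group: str) -> list[str]:
        return [str(s) for s in self.frame.index[self.frame["group"] == group]]

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.frame["group"]:
            seen.setdefault(str(g), None)
        return list(seen)

    def covariate(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"unknown covariate {name!r}")
        return self.frame[name]


@dataclass
class GeneSignature:
    """Named two-sided gene set: ordered up- and down-regulated gene IDs."""

    name: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both up and down: {sorted(overlap)}"
            )
        if not self.up and not self.down:
            raise ValueError(f"signature {self.name!r} is empty")
        for side, genes in (("up", self.up), ("down", self.down)):
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {self.name!r}: duplicate genes in {side} list")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)


# ---------------------------------------------------------------------------
# Matrix readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str, format: str = "gct") -> ExpressionMatrix:
    """Read a GCT 1.2 or TSV expression matrix.

    Duplicate gene IDs are allowed (probe-level data); file order is kept.
    """
    if format == "gct":
        return _read_gct(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r} (expected 'gct' or 'tsv')")


def _parse_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric cell {token!r}") from None


def _read_gct(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise ParseError(f"{path}:1: GCT file must start with '#1.2'")
    if len(lines) < 3:
        raise ParseError(f"{path}:2: truncated GCT file")
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise ParseError(f"{path}:2: expected '<n_genes>\\t<n_samples>'")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except ValueError:
        raise ParseError(f"{path}:2: non-integer dimensions {dims[:2]}") from None
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name":
        raise ParseError(f"{path}:3: GCT header must begin 'Name\\tDescription\\t...'")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise ParseError(
            f"{path}:3: header lists {len(sample_ids)} samples but dims line declares {n_samples}"
        )
    body = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(body) != n_genes:
        raise ParseError(
            f"{path}:2: dims line declares {n_genes} rows but file contains {len(body)}"
        )
    gene_ids: list[str] = []
    values = np.empty((n_genes, n_samples), dtype=float)
    for i, line in enumerate(body):
        lineno = i + 4
        fields = line.split("\t")
        if len(fields) != n_samples + 2:
            raise ParseError(
                f"{path}:{lineno}: expected {n_samples + 2} fields, found {len(fields)}"
            )
        gene_ids.append(fields[0])
        values[i] = [_parse_float(tok, path, lineno) for tok in fields[2:]]
    return ExpressionMatrix(gene_ids, sample_ids, values)


def _read_tsv(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}:1: header must contain an ID column plus sample IDs")
    sample_ids = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[1:]):
        if line.strip() == "":
            continue
        lineno = i + 2
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        gene_ids.append(fields[0])
        rows.append([_parse_float(tok, path, lineno) for tok in fields[1:]])
    if not gene_ids:
        raise ParseError(f"{path}:2: matrix has no data rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression(matrix: ExpressionMatrix, path: str, format: str = "gct") -> None:
    """Write a matrix at full precision (17 significant digits)."""
    if matrix.n_samples == 0:
        raise ValueError("refusing to write a matrix with no samples")
    if matrix.n_genes == 0:
        raise ValueError("refusing to write a matrix with no genes")
    fmt = "%.17g"
    with open(path, "w") as fh:
        if format == "gct":
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for gid, row in zip(matrix.gene_ids, matrix.values):
                fh.write(gid + "\tna\t" + "\t".join(fmt % v for v in row) + "\n")
        elif format == "tsv":
            fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
            for gid, row in zip(matrix.gene_ids, matrix.values):
                fh.write(gid + "\t" + "\t".join(fmt % v for v in row) + "\n")
        else:
            raise ValueError(f"unknown format {format!r} (expected 'gct' or 'tsv')")


def read_sample_table(path: str) -> SampleTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}:1: missing mandatory column 'sample_id'")
    frame = frame.set_index("sample_id")
    # numeric covariates come back as strings; convert what converts cleanly
    for col in frame.columns:
        if col in ("group", "cohort"):
            continue
        converted = pd.to_numeric(frame[col], errors="coerce")
        if not converted.isna().any():
            frame[col] = converted
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path: str) -> None:
    table.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> list[GeneSignature]:
    """Read GMT gene sets, merging ``<stem>_UP``/``<stem>_DN`` pairs.

    Sets whose names end in ``_UP`` or ``_DN`` and share a stem (case
    sensitive) become a single two-sided :class:`GeneSignature`; all other
    sets become up-only signatures.
    """
    raw: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, found {len(fields)}"
                )
            name = fields[0]
            if name in raw:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g != ""]
            if len(set(genes)) != len(genes):
                raise ParseError(f"{path}:{lineno}: duplicate genes within set {name!r}")
            raw[name] = genes

    signatures: list[GeneSignature] = []
    consumed: set[str] = set()
    for name in raw:
        if name in consumed:
            continue
        if name.endswith("_UP") or name.endswith("_DN"):
            stem = name[:-3]
            up_name, dn_name = stem + "_UP", stem + "_DN"
            up = raw.get(up_name, [])
            down = raw.get(dn_name, [])
            consumed.update(n for n in (up_name, dn_name) if n in raw)
            signatures.append(GeneSignature(name=stem, up=up, down=down))
        else:
            consumed.add(name)
            signatures.append(GeneSignature(name=name, up=raw[name], down=[]))
    return signatures


def write_gmt(signatures: list[GeneSignature], path: str) -> None:
    """Write signatures as GMT; two-sided signatures emit ``_UP`` and ``_DN`` lines."""
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.down:
                if sig.up:
                    fh.write("\t".join([sig.name + "_UP", "na"] + list(sig.up)) + "\n")
                fh.write("\t".join([sig.name + "_DN", "na"] + list(sig.down)) + "\n")
            else:
                fh.write("\t".join([sig.name, "na"] + list(sig.up)) + "\n")


# ---------------------------------------------------------------------------
# Normalization and probe collapse
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples to the mean of their sorted value vectors.

    After normalization, every sample's sorted values equal the across-sample
    mean of sorted values.  Tied input values within a sample receive the
    mean of their target quantiles, which makes the result independent of
    input row order.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    values = matrix.values
    reference = np.mean(np.sort(values, axis=0), axis=1)  # target quantiles
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # average target quantiles across runs of equal input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(col)]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                mapped[order[s:e]] = reference[s:e].mean()
        out[:, j] = mapped
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out)


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene_map: dict[str, str]
) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol.

    Keeps, for each gene, the probe with the highest mean across samples;
    exact ties go to the lexicographically smallest probe ID.  Probes absent
    from the mapping are dropped.
    """
    if not probe_to_gene_map:
        raise ValueError("probe_to_gene_map is empty")
    means = matrix.values.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}  # gene -> (mean, probe_id, row)
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_to_gene_map.get(probe)
        if gene is None:
            continue
        candidate = (means[i], probe, i)
        incumbent = best.get(gene)
        if incumbent is None:
            best[gene] = candidate
            continue
        # higher mean wins; on an exact tie the smaller probe ID wins
        if candidate[0] > incumbent[0] or (
            candidate[0] == incumbent[0] and candidate[1] < incumbent[1]
        ):
            best[gene] = candidate
    if not best:
        raise ValueError("no probes matched the mapping")
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionMatrix(genes, list(matrix.sample_ids), matrix.values[rows])
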