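"""Planted-signal expression simulators for end-to-end pipeline validation.

Three generators mirror the study designs the pipeline serves:

* ``simulate_cell_lines`` — a parental line plus derived conditions sharing a
  planted core of up/down genes, each condition adding private noise DE.
* ``simulate_cohort`` — patient groups where the epithelial signal is diluted
  by a per-sample reprogrammed-cell fraction ``f`` and an inflammation module
  pushes a subset of the in vitro DOWN genes UP in disease (the confounder
  that motivates cross-cohort refinement).
* ``simulate_sorted_populations`` — flow-sorted pure populations with
  group-specific ``f`` and driver genes coupled to ``f``.

All generators are fully deterministic given their config and seed and emit
a :class:`SimTruth` record of the planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from osap.expression_io import ExpressionMatrix, SampleTable


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    up_genes: list[str]
    down_genes: list[str]
    line_specific: dict[str, list[str]] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)  # sample_id -> f
    inflammation_genes: list[str] = field(default_factory=list)
    stemness: dict[str, float] = field(default_factory=dict)
    driver_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _baseline(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    # per-gene baseline log2 intensity, microarray-like dynamic range
    return rng.uniform(6.0, 12.0, size=n_genes)


# ---------------------------------------------------------------------------
# Cell lines
# ---------------------------------------------------------------------------

@dataclass
class CellLineSimConfig:
    n_genes: int = 2000
    n_core_up: int = 27
    n_core_down: int = 32
    n_line_specific: int = 50
    core_effect: float = 1.5  # log2 shift shared by all derived conditions
    line_effect: float = 1.5  # log2 shift of each condition's private genes
    noise_sd: float = 0.15
    n_replicates: int = 3
    n_conditions: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        needed = self.n_core_up + self.n_core_down + self.n_conditions * self.n_line_specific
        if needed >= self.n_genes:
            raise ValueError(
                f"planted genes ({needed}) must be fewer than n_genes ({self.n_genes})"
            )
        if self.n_replicates < 1 or self.n_conditions < 1:
            raise ValueError("n_replicates and n_conditions must be >=1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >=0")


def simulate_cell_lines(
    config: CellLineSimConfig,
) -> tuple[ExpressionMatrix, SampleTable, SimTruth]:
    """Parental + derived conditions sharing a planted core program.

    Core up genes shift +core_effect and core down genes -core_effect in every
    derived condition; each condition additionally shifts its own private
    gene block by +/-line_effect (random signs).  Replicate noise is Gaussian
    on the log2 scale.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baseline = _baseline(rng, config.n_genes)

    cursor = 0
    up_idx = np.arange(cursor, cursor + config.n_core_up); cursor += config.n_core_up
    down_idx = np.arange(cursor, cursor + config.n_core_down); cursor += config.n_core_down
    line_idx: dict[str, np.ndarray] = {}
    condition_names = [f"derived{i + 1}" for i in range(config.n_conditions)]
    for cond in condition_names:
        line_idx[cond] = np.arange(cursor, cursor + config.n_line_specific)
        cursor += config.n_line_specific
    line_signs = {
        cond: rng.choice([-1.0, 1.0], size=config.n_line_specific)
        for cond in condition_names
    }

    all_conditions = ["parental"] + condition_names
    sample_ids: list[str] = []
    groups: list[str] = []
    columns: list[np.ndarray] = []
    for cond in all_conditions:
        mean = baseline.copy()
        if cond != "parental":
            mean[up_idx] += config.core_effect
            mean[down_idx] -= config.core_effect
            mean[line_idx[cond]] += line_signs[cond] * config.line_effect
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{cond}_r{r}")
            groups.append(cond)
            columns.append(mean + rng.normal(0.0, config.noise_sd, size=config.n_genes))

    matrix = ExpressionMatrix(genes, sample_ids, np.column_stack(columns))
    anno = SampleTable(pd.DataFrame(
        {"group": groups, "cohort": "cell_lines"}, index=pd.Index(sample_ids, name="sample_id"),
    ))
    truth = SimTruth(
        up_genes=[genes[i] for i in up_idx],
        down_genes=[genes[i] for i in down_idx],
        line_specific={cond: [genes[i] for i in idx] for cond, idx in line_idx.items()},
    )
    return matrix, anno, truth


# ---------------------------------------------------------------------------
# Patient cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    n_genes: int = 2000
    n_core_up: int = 27
    n_core_down: int = 32
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"healthy": 15, "disease": 15, "disease_neoplasia": 15}
    )
    f_means: dict[str, float] = field(
        default_factory=lambda: {"healthy": 0.0, "disease": 0.2, "disease_neoplasia": 0.4}
    )
    f_jitter_sd: float = 0.05
    core_effect: float = 1.5
    inflammation_fraction: float = 0.6  # fraction of core-down genes confounded
    inflammation_shift: float = 1.0  # +log2 shift in disease groups, overrides dilution
    disease_groups: tuple[str, ...] = ("disease", "disease_neoplasia")
    stem_coupling: float = 0.8
    noise_sd: float = 0.3
    cohort_id: str = "cohort"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core_up + self.n_core_down >= self.n_genes:
            raise ValueError("planted genes must be fewer than n_genes")
        if not (0.0 <= self.inflammation_fraction <= 1.0):
            raise ValueError("inflammation_fraction must lie in [0, 1]")
        for g, n in self.group_sizes.items():
            if n < 3:
                raise ValueError(f"group {g!r} needs >=3 samples")
        for g, f in self.f_means.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"f mean for group {g!r} out of [0, 1]: {f}")
        if not (-1.0 <= self.stem_coupling <= 1.0):
            raise ValueError("stem_coupling must lie in [-1, 1]")


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[ExpressionMatrix, SampleTable, SimTruth]:
    """Heterogeneous-tissue cohorts with diluted planted signal.

    Per sample: core up genes shift by ``f * core_effect`` and core down by
    ``-f * core_effect`` where ``f`` is the sample's reprogrammed-cell
    fraction — except inflammation-module genes (a subset of the core down
    genes), which get ``+inflammation_shift`` in every disease-group sample
    regardless of ``f``.  A stemness covariate correlates with ``f`` at
    ``stem_coupling``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baseline = _baseline(rng, config.n_genes)

    up_idx = np.arange(config.n_core_up)
    down_idx = np.arange(config.n_core_up, config.n_core_up + config.n_core_down)
    n_inflamed = int(round(config.inflammation_fraction * config.n_core_down))
    inflamed_idx = down_idx[:n_inflamed]
    inflamed_set = set(inflamed_idx.tolist())

    sample_ids: list[str] = []
    groups: list[str] = []
    fractions: list[float] = []
    columns: list[np.ndarray] = []
    for group, size in config.group_sizes.items():
        f_mean = config.f_means.get(group, 0.0)
        diseased = group in config.disease_groups
        for s in range(1, size + 1):
            f = float(np.clip(rng.normal(f_mean, config.f_jitter_sd), 0.0, 1.0))
            mean = baseline.copy()
            mean[up_idx] += f * config.core_effect
            mean[down_idx] -= f * config.core_effect
            if diseased and n_inflamed:
                mean[inflamed_idx] = baseline[inflamed_idx] + config.inflammation_shift
            sample_ids.append(f"{group}_{s:02d}")
            groups.append(group)
            fractions.append(f)
            columns.append(mean + rng.normal(0.0, config.noise_sd, size=config.n_genes))

    f_arr = np.array(fractions)
    f_std = f_arr.std()
    z = (f_arr - f_arr.mean()) / f_std if f_std > 0 else np.zeros_like(f_arr)
    rho = config.stem_coupling
    stemness = rho * z + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.normal(size=len(f_arr))

    matrix = ExpressionMatrix(genes, sample_ids, np.column_stack(columns))
    anno = SampleTable(pd.DataFrame(
        {"group": groups, "cohort": config.cohort_id, "stemness": stemness},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    truth = SimTruth(
        up_genes=[genes[i] for i in up_idx],
        down_genes=[genes[i] for i in down_idx],
        fractions=dict(zip(sample_ids, (float(f) for f in f_arr))),
        inflammation_genes=[genes[i] for i in sorted(inflamed_set)],
        stemness=dict(zip(sample_ids, (float(s) for s in stemness))),
    )
    return matrix, anno, truth


# ---------------------------------------------------------------------------
# Sorted populations
# ---------------------------------------------------------------------------

@dataclass
class SortedPopulationSimConfig:
    n_genes: int = 2000
    n_core_up: int = 27
    n_core_down: int = 32
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "normal_high": 12, "normal_low": 12, "adenoma_high": 12, "adenoma_low": 12,
        }
    )
    f_by_group: dict[str, float] = field(
        default_factory=lambda: {
            "normal_high": 0.0, "normal_low": 0.1, "adenoma_high": 0.5, "adenoma_low": 0.7,
        }
    )
    core_effect: float = 1.5
    n_drivers: int = 2
    driver_coupling: float = 1.0  # driver expression = baseline + coupling * f + noise
    noise_sd: float = 0.3
    cohort_id: str = "sorted"
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_core_up + self.n_core_down + self.n_drivers
        if planted >= self.n_genes:
            raise ValueError("planted genes must be fewer than n_genes")
        for g, n in self.group_sizes.items():
            if n < 3:
                raise ValueError(f"group {g!r} needs >=3 samples")
        for g, f in self.f_by_group.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"f for group {g!r} out of [0, 1]: {f}")


def simulate_sorted_populations(
    config: SortedPopulationSimConfig,
) -> tuple[ExpressionMatrix, SampleTable, SimTruth]:
    """Pure sorted populations: undiluted group-level ``f`` plus driver genes.

    Driver genes sit outside the planted signature; their expression tracks
    ``f`` linearly, standing in for the upstream transcription factors.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    baseline = _baseline(rng, config.n_genes)

    up_idx = np.arange(config.n_core_up)
    down_idx = np.arange(config.n_core_up, config.n_core_up + config.n_core_down)
    driver_idx = np.arange(
        config.n_core_up + config.n_core_down,
        config.n_core_up + config.n_core_down + config.n_drivers,
    )
    driver_names = [f"DRIVER{i + 1}" for i in range(config.n_drivers)]
    for i, name in zip(driver_idx, driver_names):
        genes[i] = name

    sample_ids: list[str] = []
    groups: list[str] = []
    fractions: list[float] = []
    columns: list[np.ndarray] = []
    for group, size in config.group_sizes.items():
        f = config.f_by_group.get(group, 0.0)
        for s in range(1, size + 1):
            mean = baseline.copy()
            mean[up_idx] += f * config.core_effect
            mean[down_idx] -= f * config.core_effect
            mean[driver_idx] += config.driver_coupling * f
            sample_ids.append(f"{group}_{s:02d}")
            groups.append(group)
            fractions.append(f)
            columns.append(mean + rng.normal(0.0, config.noise_sd, size=config.n_genes))

    matrix = ExpressionMatrix(genes, sample_ids, np.column_stack(columns))
    anno = SampleTable(pd.DataFrame(
        {"group": groups, "cohort": config.cohort_id},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    truth = SimTruth(
        up_genes=[genes[i] for i in up_idx],
        down_genes=[genes[i] for i in down_idx],
        fractions=dict(zip(sample_ids, (float(f) for f in fractions))),
        driver_genes=driver_names,
    )
    return matrix, anno, truth
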