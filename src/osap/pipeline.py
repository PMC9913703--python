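"""End-to-end pipeline: derive -> refine -> score -> associate.

The pipeline is configured by a single YAML/JSON-style mapping, validates it
up front, writes plain-text artifacts per stage plus a machine-readable
manifest (effective config, input/output checksums, package version), and is
deterministic given fixed inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from osap import __version__ as _version
from osap.association_stats import kruskal_wallis, mann_whitney, spearman
from osap.expression_io import (
    read_expression,
    read_gmt,
    read_sample_table,
    write_gmt,
)
from osap.signature_derivation import (
    ComparisonSpec,
    compute_fold_changes,
    derive_core_signature,
)
from osap.signature_refinement import per_gene_rank_test, refine_signature, stats_to_rows
from osap.ssgsea_scoring import SsgseaParams, score_samples, write_scores

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, Any] = {
    "cutoff": 1.5,
    "inclusive_cutoff": True,
    "alpha": 0.25,
    "normalize": True,
    "min_overlap": 3,
    "stat": "sum",
    "p_threshold": 0.05,
    "require_significance": True,
    "test": "kw",
    "signature_name": "CORE",
}

STAGES = ("derive", "refine", "score", "associate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :func:`load_config`)."""

    expression: str
    contrasts: str
    cohort_a: dict[str, str]
    cohort_b: dict[str, str]
    out_dir: str
    score_expression: str | None = None
    score_annotation: str | None = None
    expression_format: str = "gct"
    params: dict[str, Any] = field(default_factory=dict)

    def effective_params(self) -> dict[str, Any]:
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        return merged

    def to_dict(self) -> dict[str, Any]:
        return {
            "expression": self.expression,
            "contrasts": self.contrasts,
            "cohort_a": self.cohort_a,
            "cohort_b": self.cohort_b,
            "out_dir": self.out_dir,
            "score_expression": self.score_expression,
            "score_annotation": self.score_annotation,
            "expression_format": self.expression_format,
            "params": self.effective_params(),
        }


def load_config(mapping: dict[str, Any]) -> PipelineConfig:
    known = {
        "expression", "contrasts", "cohort_a", "cohort_b", "out_dir",
        "score_expression", "score_annotation", "expression_format", "params",
    }
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(**mapping)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from None


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the pipeline can run."""
    problems: list[str] = []
    for label, path in (("expression", config.expression), ("contrasts", config.contrasts)):
        if not path:
            problems.append(f"missing input path: {label}")
        elif not os.path.exists(path):
            problems.append(f"input file not found: {label} = {path}")
    for label, cohort in (("cohort_a", config.cohort_a), ("cohort_b", config.cohort_b)):
        for key in ("expression", "annotation", "case", "control"):
            if key not in cohort:
                problems.append(f"{label}: missing key {key!r}")
        for key in ("expression", "annotation"):
            path = cohort.get(key)
            if path and not os.path.exists(path):
                problems.append(f"{label}: file not found: {path}")
    params = config.effective_params()
    if not params["cutoff"] > 1:
        problems.append("cutoff must exceed 1 (linear fold-change ratio)")
    if params["alpha"] < 0:
        problems.append("alpha must be >= 0")
    if not (0 < params["p_threshold"] <= 1):
        problems.append("p_threshold must lie in (0, 1]")
    if params["test"] not in ("mw", "kw"):
        problems.append("test must be 'mw' or 'kw'")
    if params["stat"] not in ("sum", "max"):
        problems.append("stat must be 'sum' or 'max'")
    if params["min_overlap"] < 1:
        problems.append("min_overlap must be >= 1")
    return problems


def read_contrasts(path: str) -> list[ComparisonSpec]:
    """Contrast table: columns name, case_ids, ref_ids (comma-joined IDs)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "case_ids", "ref_ids"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: contrasts table missing columns {sorted(missing)}")
    specs = []
    for _, row in frame.iterrows():
        specs.append(ComparisonSpec(
            name=row["name"],
            case_sample_ids=[s.strip() for s in row["case_ids"].split(",") if s.strip()],
            reference_sample_ids=[s.strip() for s in row["ref_ids"].split(",") if s.strip()],
        ))
    return specs


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> str:
    """Run all stages; return the run directory.

    On stage failure the run halts, partial outputs stay in place, and a
    ``FAILED`` marker names the failing stage.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(problems))
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    params = config.effective_params()
    fmt = config.expression_format

    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("osap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict[str, Any] = {
        "version": _version,
        "config": config.to_dict(),
        "inputs": {},
        "outputs": {},
        "stages": {},
    }
    input_paths = [config.expression, config.contrasts,
                   config.cohort_a["expression"], config.cohort_a["annotation"],
                   config.cohort_b["expression"], config.cohort_b["annotation"]]
    if config.score_expression:
        input_paths.append(config.score_expression)
    if config.score_annotation:
        input_paths.append(config.score_annotation)
    for path in input_paths:
        manifest["inputs"][path] = _sha256(path)

    current_stage = "derive"
    try:
        # ---- derive -------------------------------------------------------
        logger.info("stage derive: %s", config.expression)
        matrix = read_expression(config.expression, format=fmt)
        specs = read_contrasts(config.contrasts)
        fc = compute_fold_changes(matrix, specs)
        signature = derive_core_signature(
            fc, cutoff=params["cutoff"], name=params["signature_name"],
            inclusive=params["inclusive_cutoff"],
        )
        sig_path = os.path.join(out_dir, "signature.gmt")
        write_gmt([signature], sig_path)
        fc_path = os.path.join(out_dir, "fold_changes.tsv")
        fc.to_frame().to_csv(fc_path, sep="\t", index_label="gene_id", float_format="%.17g")
        manifest["stages"]["derive"] = {
            "status": "completed", "n_up": len(signature.up), "n_down": len(signature.down),
        }

        # ---- refine -------------------------------------------------------
        current_stage = "refine"
        cohort_stats = {}
        for label, cohort in (("A", config.cohort_a), ("B", config.cohort_b)):
            expr = read_expression(cohort["expression"], format=fmt)
            anno = read_sample_table(cohort["annotation"])
            stats = per_gene_rank_test(
                expr,
                case_ids=anno.samples_in_group(cohort["case"]),
                control_ids=anno.samples_in_group(cohort["control"]),
                genes=signature.genes,
                cohort_id=label,
            )
            cohort_stats[label] = stats
            stats_path = os.path.join(out_dir, f"cohort_{label}_stats.tsv")
            pd.DataFrame(stats_to_rows(stats)).to_csv(
                stats_path, sep="\t", index=False, float_format="%.17g")
        refined = refine_signature(
            signature, cohort_stats["A"], cohort_stats["B"],
            p_threshold=params["p_threshold"],
            require_significance=params["require_significance"],
        )
        refined_path = os.path.join(out_dir, "signature_refined.gmt")
        write_gmt([refined], refined_path)
        manifest["stages"]["refine"] = {
            "status": "completed", "n_up": len(refined.up), "n_down": len(refined.down),
        }

        # ---- score --------------------------------------------------------
        current_stage = "score"
        score_expr_path = config.score_expression or config.cohort_a["expression"]
        score_anno_path = config.score_annotation or config.cohort_a["annotation"]
        score_expr = read_expression(score_expr_path, format=fmt)
        score_anno = read_sample_table(score_anno_path)
        ssgsea = SsgseaParams(
            alpha=params["alpha"], normalize=params["normalize"],
            min_overlap=params["min_overlap"], stat=params["stat"],
        )
        scores = score_samples(score_expr, [signature, refined], ssgsea)
        scores_path = os.path.join(out_dir, "scores.tsv")
        write_scores(scores, scores_path)
        manifest["stages"]["score"] = {
            "status": "completed",
            "n_signatures": len(scores.signature_names),
            "n_samples": len(scores.sample_ids),
        }

        # ---- associate ----------------------------------------------------
        current_stage = "associate"
        rows = []
        groups = score_anno.groups()
        for sig_name in scores.signature_names:
            vec = scores.signature_scores(sig_name)
            by_group = {
                g: vec[[scores.sample_ids.index(s) for s in score_anno.samples_in_group(g)
                        if s in scores.sample_ids]]
                for g in groups
            }
            by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
            if len(by_group) >= 2:
                if params["test"] == "kw" and len(by_group) > 2:
                    res = kruskal_wallis(list(by_group.values()), list(by_group))
                    rows.append({"signature": sig_name, "test": "kruskal_wallis",
                                 "groups": ",".join(by_group), "statistic": res.statistic,
                                 "p_value": res.p_value})
                else:
                    names = list(by_group)
                    for i in range(len(names)):
                        for j in range(i + 1, len(names)):
                            res = mann_whitney(by_group[names[i]], by_group[names[j]])
                            rows.append({"signature": sig_name, "test": "mann_whitney",
                                         "groups": f"{names[i]},{names[j]}",
                                         "statistic": res.statistic, "p_value": res.p_value})
            for covariate in score_anno.frame.columns:
                if covariate in ("group", "cohort"):
                    continue
                cov = pd.to_numeric(score_anno.frame[covariate], errors="coerce")
                if cov.isna().any():
                    continue
                aligned = cov.reindex(scores.sample_ids)
                try:
                    corr = spearman(aligned.to_numpy(dtype=float), vec)
                except ValueError:
                    continue  # constant covariate: correlation undefined
                rows.append({"signature": sig_name, "test": f"spearman:{covariate}",
                             "groups": "all", "statistic": corr.rho, "p_value": corr.p_value})
        assoc_path = os.path.join(out_dir, "associations.tsv")
        pd.DataFrame(rows).to_csv(assoc_path, sep="\t", index=False, float_format="%.17g")
        manifest["stages"]["associate"] = {"status": "completed", "n_results": len(rows)}

    except Exception as exc:
        with open(os.path.join(out_dir, "FAILED"), "w") as fh:
            fh.write(f"stage {current_stage} failed: {exc}\n")
        manifest["stages"].setdefault(current_stage, {})["status"] = "failed"
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc

    for fname in sorted(os.listdir(out_dir)):
        if fname in ("manifest.json", "run.log", "FAILED"):
            continue
        manifest["outputs"][fname] = _sha256(os.path.join(out_dir, fname))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    failed_marker = os.path.join(out_dir, "FAILED")
    if os.path.exists(failed_marker):
        os.remove(failed_marker)
    root.removeHandler(handler)
    handler.close()
    return out_dir
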