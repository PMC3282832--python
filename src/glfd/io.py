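"""Tab-delimited readers/writers, run configuration, and the run pipeline."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .mlsa import SearchConfig
from .preprocessing import (
    ClinicalFactorSet,
    ExpressionMatrix,
    standardize_genes,
    whiten_clinical,
)
from .selection import GLFDResult, direct_mlsa_pipeline, fit_glfd
from .simulate import SimulationConfig, SimulationTruth, simulate_dataset

logger = logging.getLogger("glfd")


@dataclass
class RunConfig:
    """Parameters of a pipeline run; defaults reproduce the standard regime."""

    alpha: float = 0.001
    phi: float = 100.0
    lambda_fdr: float = 0.1
    overlap_p: float = 0.01
    max_dim: int = 10
    min_module_genes: int = 10
    search_mode: str = "exhaustive"
    pipeline: str = "glfd"  # or "direct_mlsa"
    seed: int = 0
    em_max_iter: int = 500
    em_tol: float = 1e-6
    expression_path: Optional[str] = None
    clinical_path: Optional[str] = None
    output_dir: Optional[str] = None

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            max_dim=self.max_dim,
            min_module_genes=self.min_module_genes,
            alpha_module=self.alpha,
            phi=self.phi,
            max_iter=self.em_max_iter,
            tol=self.em_tol,
            search_mode=self.search_mode,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples tab-delimited expression table.

    First column holds gene identifiers, the header row sample identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no sample columns found")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated gene identifiers: {dup}")
    dup_cols = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_cols:
        raise ValueError(f"{path}: duplicated sample identifiers: {dup_cols}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = df.columns[~df.apply(pd.api.types.is_numeric_dtype)].tolist()
        raise ValueError(f"{path}: non-numeric values in columns {bad}") from exc
    if not np.all(np.isfinite(values)):
        rows = [df.index[i] for i in np.unique(np.nonzero(~np.isfinite(values))[0])]
        raise ValueError(f"{path}: non-finite values in genes {rows}")
    return ExpressionMatrix(
        values, [str(g) for g in df.index], [str(s) for s in df.columns]
    )


def read_clinical(path) -> pd.DataFrame:
    """Read a samples x factors tab-delimited clinical table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicated sample identifiers: {dup}")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite clinical values")
    df.index = df.index.map(str)
    return df


def align_clinical(expr: ExpressionMatrix, clinical: pd.DataFrame) -> ClinicalFactorSet:
    """Reconcile clinical rows to the expression sample order by identifier."""
    missing = [s for s in expr.sample_ids if s not in clinical.index]
    extra = [s for s in clinical.index if s not in expr.sample_ids]
    if missing or extra:
        raise ValueError(
            f"sample identifiers disagree between expression and clinical data; "
            f"missing from clinical: {missing}; unmatched in clinical: {extra}"
        )
    ordered = clinical.loc[list(expr.sample_ids)]
    return whiten_clinical(
        ordered.to_numpy(dtype=float),
        sample_ids=list(expr.sample_ids),
        factor_names=[str(c) for c in ordered.columns],
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(
        expr.values, index=list(expr.gene_ids), columns=list(expr.sample_ids)
    ).to_csv(path, sep="\t", index_label="gene_id")


def write_clinical(clin_raw: np.ndarray, sample_ids, factor_names, path) -> None:
    pd.DataFrame(clin_raw, index=list(sample_ids), columns=list(factor_names)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def write_factor_scores(result: GLFDResult, path) -> None:
    """Retained factor scores, samples in rows, one column per factor."""
    labels = [rf.label for rf in result.retained]
    pd.DataFrame(
        result.retained_factors,
        index=list(result.clinical.sample_ids),
        columns=labels,
    ).to_csv(path, sep="\t", index_label="sample_id")


def write_module_summary(result: GLFDResult, path) -> None:
    rows = []
    for j, (mod, ov) in enumerate(zip(result.modules, result.set_overlaps)):
        rows.append(
            {
                "module": f"M{j + 1}",
                "dimensionality": mod.dimensionality,
                "member_count": mod.member_count,
                "converged": mod.converged,
                "iterations": mod.n_iterations,
                "set_overlap_p": ov.p_value,
                "set_significant": ov.significant,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "module", "dimensionality", "member_count", "converged",
            "iterations", "set_overlap_p", "set_significant",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_association_table(result: GLFDResult, path) -> None:
    """Per-gene association with the clinical basis and each module subspace."""
    assoc = result.clinical_association
    df = pd.DataFrame(
        {
            "gene_id": list(assoc.gene_ids),
            "clinical_l": assoc.projection_lengths,
            "clinical_F": assoc.f_statistics,
            "clinical_p": assoc.p_values,
            "clinical_fdr": assoc.fdr,
            "clinical_significant": assoc.significant,
        }
    )
    for j, am in enumerate(result.module_associations):
        df[f"M{j + 1}_l"] = am.projection_lengths
        df[f"M{j + 1}_fdr"] = am.fdr
        df[f"M{j + 1}_significant"] = am.significant
    df.to_csv(path, sep="\t", index=False)


def write_overlap_report(result: GLFDResult, path) -> None:
    rows = []
    for j, ov in enumerate(result.set_overlaps):
        rows.append({"test": f"M{j + 1}.set", **_overlap_row(ov)})
        for c, ovf in enumerate(result.factor_overlaps[j]):
            if ovf is not None:
                rows.append({"test": f"M{j + 1}.F{c + 1}", **_overlap_row(ovf)})
    pd.DataFrame(
        rows,
        columns=[
            "test", "p_total", "m1", "m2", "r_overlap",
            "m1_adj", "m2_adj", "r_adj", "p_value", "significant",
        ],
    ).to_csv(path, sep="\t", index=False)


def _overlap_row(ov) -> Dict[str, object]:
    return {
        "p_total": ov.p_total,
        "m1": ov.m1,
        "m2": ov.m2,
        "r_overlap": ov.r_overlap,
        "m1_adj": ov.m1_adj,
        "m2_adj": ov.m2_adj,
        "r_adj": ov.r_adj,
        "p_value": ov.p_value,
        "significant": ov.significant,
    }


def write_run_summary(result: GLFDResult, path) -> None:
    summary = {
        "params": {k: _plain(v) for k, v in result.params.items()},
        "n_modules": len(result.modules),
        "module_dimensionalities": [m.dimensionality for m in result.modules],
        "module_member_counts": [m.member_count for m in result.modules],
        "n_clinical_associated": int(result.clinical_association.n_significant),
        "set_overlap_p_values": [float(ov.p_value) for ov in result.set_overlaps],
        "n_retained_factors": result.n_retained,
        "retained": [
            {"factor": rf.label, "overlap_p": float(rf.overlap.p_value)}
            for rf in result.retained
        ],
    }
    Path(path).write_text(yaml.safe_dump(summary, sort_keys=False))


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


# ---------------------------------------------------------------------------
# pipeline entry point
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> GLFDResult:
    """Read inputs, execute the configured pipeline, write all outputs.

    A run that finds no latent factor is a successful run: the retained
    factor table is simply empty.
    """
    if config.expression_path is None or config.clinical_path is None:
        raise ValueError("expression_path and clinical_path are required")
    expr = read_expression(config.expression_path)
    clinical_df = read_clinical(config.clinical_path)
    clin = align_clinical(expr, clinical_df)
    expr_std = standardize_genes(expr)
    logger.info(
        "loaded %d genes x %d samples, %d clinical factor(s)",
        expr.n_genes, expr.n_samples, clin.n_factors,
    )
    search = config.search_config()
    if config.pipeline == "glfd":
        result = fit_glfd(
            expr_std,
            clin,
            config=search,
            alpha=config.alpha,
            phi=config.phi,
            fdr_cutoff=config.lambda_fdr,
            overlap_p_cutoff=config.overlap_p,
        )
    elif config.pipeline == "direct_mlsa":
        result = direct_mlsa_pipeline(
            expr_std,
            clin,
            config=search,
            fdr_cutoff=config.lambda_fdr,
            overlap_p_cutoff=config.overlap_p,
        )
    else:
        raise ValueError(f"unknown pipeline {config.pipeline!r}")

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_factor_scores(result, outdir / "retained_factors.tsv")
        write_module_summary(result, outdir / "module_summary.tsv")
        write_association_table(result, outdir / "gene_association.tsv")
        write_overlap_report(result, outdir / "overlap_tests.tsv")
        write_run_summary(result, outdir / "run_summary.yaml")
        config.to_yaml(outdir / "run_config.yaml")
        logger.info("wrote outputs to %s", outdir)
    return result


def write_simulation(
    config: SimulationConfig, outdir, write_truth: bool = True
) -> None:
    """Simulate one dataset and write it as tab-delimited tables."""
    expr, clin_raw, truth = simulate_dataset(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(expr, outdir / "expression.tsv")
    write_clinical(clin_raw, expr.sample_ids, ["clinical"], outdir / "clinical.tsv")
    if write_truth:
        labels = [
            f"M{m}_L{i + 1}"
            for i, m in enumerate(truth.latent_module)
        ]
        pd.DataFrame(
            truth.latent_scores, index=list(expr.sample_ids), columns=labels
        ).to_csv(outdir / "truth_latent_scores.tsv", sep="\t", index_label="sample_id")
        pd.Series(truth.module_membership, name="module").to_csv(
            outdir / "truth_membership.tsv", sep="\t", index_label="gene_id"
        )
    cfg_dict = asdict(config)
    cfg_dict["background_module_dims"] = list(cfg_dict["background_module_dims"])
    (outdir / "sim_config.yaml").write_text(
        yaml.safe_dump(cfg_dict, sort_keys=False)
    )
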