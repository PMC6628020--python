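"""End-to-end biomarker screening pipeline.

For each candidate gene: normalize every study, fit the per-study logistic
classifier, form the 2x2 tables, pool the diagnostic indices and fit the
summary ROC — yielding one report row per gene, comparable across genes
because every row uses the same study set.  Also provides boxplot-style
group summaries and Pearson-correlation similar-gene ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import expression as eio
from .classify import confusion_table
from .meta import pool_log_ratio, pool_proportion, study_indices
from .simulate import Study, StudySet
from .sroc import fit_moses

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "BiomarkerReport",
    "normalize_study",
    "tables_for_gene",
    "run_pipeline",
    "group_summaries",
    "similar_genes",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the screening pipeline.

    ``min_samples`` enforces the cohort-inclusion rule (default 30 samples);
    ``threshold`` is the classification probability cutoff; ``model`` picks
    fixed vs random-effects pooling for the ratio indices; ``sroc_weighted``
    selects inverse-variance weighting of the Moses regression;
    ``missing_gene`` is "drop" (skip that study for that gene, warn) or
    "error".
    """

    min_samples: int = 30
    threshold: float = 0.5
    model: str = "random"
    sroc_weighted: bool = False
    normalize: bool = True
    missing_gene: str = "drop"


@dataclass(frozen=True)
class BiomarkerReport:
    """One gene's pooled diagnostic profile across the study set."""

    gene: str
    sens: float
    spec: float
    plr: float
    nlr: float
    dor: float
    auc: float
    q_star: float
    i2: float
    n_studies: int

    def as_dict(self) -> dict:
        return asdict(self)


def normalize_study(study: Study) -> Study:
    """Log-standardize then quantile-normalize one study's matrix."""
    mat = eio.log_standardize(study.expression)
    mat = eio.quantile_normalize(mat)
    return Study(study.study_id, mat, study.phenotype)


def _included_studies(studyset: StudySet, config: PipelineConfig) -> list[Study]:
    kept = []
    for st in studyset:
        n = st.expression.shape[1]
        if n < config.min_samples:
            logger.warning(
                "study %s excluded: %d samples < min_samples=%d",
                st.study_id, n, config.min_samples,
            )
            continue
        kept.append(normalize_study(st) if config.normalize else st)
    return kept


def tables_for_gene(studies, gene: str, config: PipelineConfig):
    """Per-study 2x2 tables for one gene (logistic classification)."""
    tables = []
    for st in studies:
        if gene not in st.expression.index:
            if config.missing_gene == "error":
                raise KeyError(f"gene {gene!r} missing from study {st.study_id!r}")
            logger.warning("gene %s missing from study %s: dropped", gene, st.study_id)
            continue
        x = st.expression.loc[gene].to_numpy(dtype=float)
        tables.append(
            confusion_table(x, st.labels.to_numpy(), config.threshold, st.study_id)
        )
    return tables


def report_from_tables(gene: str, tables, config: PipelineConfig) -> BiomarkerReport:
    """Meta-analysis + SROC summary of a set of 2x2 tables."""
    indices = [study_indices(t) for t in tables]
    sens = pool_proportion(tables, "sens")
    spec = pool_proportion(tables, "spec")
    plr = pool_log_ratio(indices, "plr", config.model)
    nlr = pool_log_ratio(indices, "nlr", config.model)
    dor = pool_log_ratio(indices, "dor", config.model)
    model = fit_moses(indices, weighted=config.sroc_weighted)
    return BiomarkerReport(
        gene=gene,
        sens=sens.estimate,
        spec=spec.estimate,
        plr=plr.estimate,
        nlr=nlr.estimate,
        dor=dor.estimate,
        auc=model.auc,
        q_star=model.q_star,
        i2=sens.i2,
        n_studies=len(tables),
    )


def run_pipeline(studyset: StudySet, genes, config: PipelineConfig | None = None):
    """One BiomarkerReport per gene over the (filtered, normalized) studies."""
    config = config or PipelineConfig()
    studies = _included_studies(studyset, config)
    if len(studies) < 2:
        raise ValueError(
            f"only {len(studies)} study(ies) pass min_samples="
            f"{config.min_samples}; need >= 2 for a meta-analysis"
        )
    reports = []
    for gene in genes:
        tables = tables_for_gene(studies, gene, config)
        if len(tables) < 2:
            logger.warning("gene %s present in <2 studies: skipped", gene)
            continue
        reports.append(report_from_tables(gene, tables, config))
    return reports


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


def group_summaries(studyset: StudySet, gene: str) -> pd.DataFrame:
    """Boxplot-ready five-number summaries per study and group."""
    rows = []
    for st in studyset:
        if gene not in st.expression.index:
            continue
        x = st.expression.loc[gene]
        for group in ("case", "control"):
            vals = x[st.labels == group].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({
                "study_id": st.study_id, "group": group, "n": vals.size,
                "min": vals.min(), "q1": q1, "median": med, "q3": q3,
                "max": vals.max(),
            })
    return pd.DataFrame(rows)


def _pearson_vs_target(mat: pd.DataFrame, target: str) -> pd.Series:
    """Pearson r of every gene against the target across samples; genes with
    zero variance are excluded (r undefined)."""
    x = mat.loc[target].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"target gene {target!r} has zero variance")
    vals = mat.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    keep = sds > 0
    dropped = mat.index[~keep]
    if len(dropped):
        logger.warning("excluding %d zero-variance gene(s): %s",
                       len(dropped), ", ".join(map(str, dropped[:5])))
    xc = x - x.mean()
    vc = vals[keep] - vals[keep].mean(axis=1, keepdims=True)
    r = (vc @ xc) / (np.linalg.norm(vc, axis=1) * np.linalg.norm(xc))
    return pd.Series(r, index=mat.index[keep])


def similar_genes(data, target_gene: str, k: int = 10) -> pd.DataFrame:
    """Top-k genes most correlated with the target (Pearson r, descending).

    ``data`` is a single genes x samples DataFrame or a StudySet; for a
    StudySet the per-study correlations are averaged across the studies in
    which both genes vary (an unweighted mean — a multi-cohort extension of
    the usual single-cohort ranking).  Ties break by gene id.
    """
    if isinstance(data, StudySet):
        per_study = []
        for st in data:
            if target_gene not in st.expression.index:
                continue
            if st.expression.shape[1] < 3:
                logger.warning("study %s has <3 samples: skipped", st.study_id)
                continue
            per_study.append(_pearson_vs_target(st.expression, target_gene))
        if not per_study:
            raise ValueError(f"target gene {target_gene!r} found in no usable study")
        r = pd.concat(per_study, axis=1).mean(axis=1)
    else:
        if data.shape[1] < 3:
            raise ValueError("need >= 3 samples for a meaningful correlation")
        r = _pearson_vs_target(data, target_gene)
    r = r.drop(index=target_gene, errors="ignore").dropna()
    out = r.reset_index()
    out.columns = ["gene", "r"]
    out = out.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")
    return out.head(k).reset_index(drop=True)
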