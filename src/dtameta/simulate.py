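"""Synthetic multi-study case/control expression cohorts.

The generator produces the statistical structure the downstream analysis
assumes: per-study genes x samples matrices of Gaussian log2 intensities in
which one marker gene is mean-shifted in cases (negative shift = reduced
expression in disease) while noise genes share one distribution across
groups.  Each study draws its own baseline offset so that classification
must happen per study, never on pooled samples.

A single global seed fans out deterministically to per-study child seeds
(seed * 1000 + study index), so adding a study never perturbs the draws of
earlier ones and identical specs reproduce bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as eio

__all__ = ["StudySpec", "Study", "StudySet", "generate_study", "generate_paperlike_set"]

DEFAULT_MARKER = "MARKER"

#: (study_id, n_case, n_control) for the five-cohort colon-cancer layout:
#: four microarray series, the first contributing two control arms (healthy
#: donors and patients' normal adjacent mucosa), giving five analysis rows.
PAPERLIKE_LAYOUT = (
    ("GSE44076_healthy", 98, 50),
    ("GSE44076_mucosa", 97, 98),
    ("GSE74602", 31, 29),
    ("GSE10972", 24, 24),
    ("GSE23878", 35, 24),
)


@dataclass(frozen=True)
class StudySpec:
    """Parameters of one simulated case/control cohort.

    ``marker_shift`` is the case-minus-control mean difference of the marker
    gene in log2 units (negative = down-regulated in cases); noise genes are
    identically distributed in both groups.
    """

    study_id: str
    n_case: int
    n_control: int
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    marker_shift: float = -1.5
    n_noise_genes: int = 50
    study_offset_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_case < 0 or self.n_control < 0 or self.n_case + self.n_control < 1:
            raise ValueError("need at least one sample across both groups")
        if self.baseline_sd <= 0:
            raise ValueError(f"baseline_sd must be positive, got {self.baseline_sd}")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be non-negative")
        if self.study_offset_sd < 0:
            raise ValueError("study_offset_sd must be non-negative")


@dataclass(frozen=True)
class Study:
    """One simulated (or loaded) cohort: expression + phenotype."""

    study_id: str
    expression: pd.DataFrame  # genes x samples, log2 scale
    phenotype: pd.DataFrame  # index sample, columns group, stage

    def __post_init__(self):
        if set(self.expression.columns) != set(self.phenotype.index):
            raise ValueError(
                f"study {self.study_id!r}: expression samples and phenotype "
                "rows disagree"
            )
        if self.expression.index.duplicated().any():
            raise ValueError(f"study {self.study_id!r}: duplicate gene ids")

    @property
    def labels(self) -> pd.Series:
        return self.phenotype["group"].reindex(self.expression.columns)


@dataclass(frozen=True)
class StudySet:
    """An ordered collection of cohorts sharing a marker gene of interest."""

    studies: tuple[Study, ...]
    marker_gene: str = DEFAULT_MARKER

    def __iter__(self):
        return iter(self.studies)

    def __len__(self):
        return len(self.studies)

    def write(self, directory) -> None:
        """Write each study as <id>.expr.tsv / <id>.pheno.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for st in self.studies:
            eio.write_expression(st.expression, directory / f"{st.study_id}.expr.tsv")
            eio.write_phenotype(st.phenotype, directory / f"{st.study_id}.pheno.tsv")


def generate_study(spec: StudySpec, marker_gene: str = DEFAULT_MARKER,
                   stage: str = "early") -> Study:
    """Draw one cohort according to ``spec`` (deterministic given the seed).

    The marker gene is N(baseline + shift, sd) in cases and N(baseline, sd)
    in controls; each noise gene draws a shared random mean around the study
    baseline, then N(mean, sd) in every sample.  A study-level baseline
    offset ~ N(0, study_offset_sd) emulates between-cohort location
    differences (platform and lab effects) without touching within-study
    contrasts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    study_offset = rng.normal(0.0, spec.study_offset_sd) if spec.study_offset_sd else 0.0
    base = spec.baseline_mean + study_offset
    rows = {}
    case_marker = rng.normal(base + spec.marker_shift, spec.baseline_sd, spec.n_case)
    ctrl_marker = rng.normal(base, spec.baseline_sd, spec.n_control)
    rows[marker_gene] = np.concatenate([case_marker, ctrl_marker])
    gene_means = rng.normal(base, 1.0, spec.n_noise_genes)
    for g, mu in enumerate(gene_means):
        rows[f"NOISE{g:04d}"] = rng.normal(mu, spec.baseline_sd, n)
    samples = [f"{spec.study_id}_case{i:03d}" for i in range(spec.n_case)] + [
        f"{spec.study_id}_ctrl{i:03d}" for i in range(spec.n_control)
    ]
    expr = pd.DataFrame(rows, index=samples).T
    pheno = pd.DataFrame(
        {
            "group": ["case"] * spec.n_case + ["control"] * spec.n_control,
            "stage": [stage] * n,
        },
        index=pd.Index(samples, name="sample"),
    )
    return Study(spec.study_id, expr, pheno)


def generate_paperlike_set(
    seed: int = 0,
    marker_shift: float = -1.5,
    n_noise_genes: int = 50,
    marker_gene: str = "CHGA",
) -> StudySet:
    """Five cohorts with the case/control counts of the colon-cancer
    meta-analysis layout (98/50, 97/98, 31/29, 24/24, 35/24).

    The marker gene is down-shifted in cases by ``marker_shift`` log2 units
    — large enough to separate groups well, small enough that per-study
    classification error rates are nonzero.
    """
    studies = []
    for i, (sid, n_case, n_control) in enumerate(PAPERLIKE_LAYOUT):
        spec = StudySpec(
            study_id=sid,
            n_case=n_case,
            n_control=n_control,
            marker_shift=marker_shift,
            n_noise_genes=n_noise_genes,
            seed=seed * 1000 + i,
        )
        studies.append(generate_study(spec, marker_gene=marker_gene))
    return StudySet(tuple(studies), marker_gene=marker_gene)
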