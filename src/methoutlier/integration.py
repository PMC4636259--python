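"""Methylation-expression integration filtering and HPV-stratified group tests.

Outlier candidates are retained when promoter methylation anti-correlates with
expression (Spearman rho < 0). Group differences use Welch's t-test; an
outlier-presence Fisher exact test covers genes whose tumor signal is carried
by a heterogeneous subset rather than a mean shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    ExpressionMatrix,
    HPV_POSITIVE_COPY_THRESHOLD,
    MethylationMatrix,
    SampleAnnotation,
    ValidationError,
)
from .diagnostics import fisher_exact_2x2

logger = logging.getLogger(__name__)


class ConstantVectorError(ValueError):
    """Correlation is undefined on a constant vector; flagged, not silently 0."""


@dataclass
class CandidateRecord:
    gene_id: str
    outlier_score: float
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    ttest_p_all: Optional[float] = None
    ttest_p_hpvneg: Optional[float] = None
    fisher_outlier_p: Optional[float] = None
    passed_correlation_filter: bool = False


@dataclass
class GroupComparison:
    gene_id: str
    contrast: str
    n_a: int
    n_b: int
    statistic: float
    p: float
    direction: int  # sign of mean(group_a) - mean(group_b)


def spearman_meth_expr(
    meth_vector: Sequence[float], expr_vector: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of paired beta / expression values.

    rho is the Pearson correlation of midranks; p from the t approximation.
    Pairs with a missing value on either side are dropped.
    """
    m = np.asarray(meth_vector, dtype=float)
    e = np.asarray(expr_vector, dtype=float)
    if m.shape != e.shape:
        raise ValidationError("methylation and expression vectors differ in length")
    keep = ~(np.isnan(m) | np.isnan(e))
    m, e = m[keep], e[keep]
    if m.size < 4:
        raise ValidationError("need >= 4 paired non-missing samples")
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        raise ConstantVectorError("correlation undefined on a constant vector")
    rho, p = stats.spearmanr(m, e)
    return float(rho), float(p)


def correlation_filter(
    candidates: Sequence[CandidateRecord], max_p: Optional[float] = None
) -> list[CandidateRecord]:
    """Retain genes with rho strictly negative (optionally also p <= max_p);
    sets the pass flag on every record."""
    retained = []
    for rec in candidates:
        ok = rec.spearman_rho is not None and rec.spearman_rho < 0
        if ok and max_p is not None:
            ok = rec.spearman_p is not None and rec.spearman_p <= max_p
        rec.passed_correlation_filter = bool(ok)
        if ok:
            retained.append(rec)
    return retained


def group_ttest(
    values_a: Sequence[float], values_b: Sequence[float],
    gene_id: str = "", contrast: str = "",
) -> GroupComparison:
    """Welch two-sided t-test between two sample groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 non-missing values per group")
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        stat, p = 0.0, 1.0  # identical degenerate groups
    direction = int(np.sign(a.mean() - b.mean()))
    return GroupComparison(gene_id, contrast, a.size, b.size, float(stat), float(p), direction)


def fisher_outlier_presence(
    n_tumor_outliers: int, n_tumor: int, n_normal_outliers: int, n_normal: int
) -> float:
    """Two-sided Fisher exact p for presence of outliers in tumor vs normal."""
    if min(n_tumor_outliers, n_tumor, n_normal_outliers, n_normal) < 0:
        raise ValueError("counts must be nonnegative")
    if n_tumor_outliers > n_tumor or n_normal_outliers > n_normal:
        raise ValueError("outlier counts cannot exceed group sizes")
    return fisher_exact_2x2(
        n_tumor_outliers,
        n_tumor - n_tumor_outliers,
        n_normal_outliers,
        n_normal - n_normal_outliers,
    )


def hpv_call(copy_number: float) -> str:
    """'positive' iff copy number >= 1 per genome/cell."""
    if copy_number < 0:
        raise ValueError("copy number must be nonnegative")
    return "positive" if copy_number >= HPV_POSITIVE_COPY_THRESHOLD else "negative"


_CONTRASTS = (
    ("tumor_vs_normal", "tumor", "normal"),
    ("hpvneg_vs_normal", "tumor_hpvneg", "normal"),
    ("hpvpos_vs_normal", "tumor_hpvpos", "normal"),
    ("hpvneg_vs_hpvpos", "tumor_hpvneg", "tumor_hpvpos"),
)


def _stratum_ids(annotation: SampleAnnotation, name: str) -> list[str]:
    df = annotation.table
    if name == "tumor":
        sel = df["group"] == "tumor"
    elif name == "normal":
        sel = df["group"] == "normal"
    elif name == "tumor_hpvneg":
        sel = (df["group"] == "tumor") & (df["hpv_status"] == "negative")
    elif name == "tumor_hpvpos":
        sel = (df["group"] == "tumor") & (df["hpv_status"] == "positive")
    else:  # pragma: no cover
        raise ValueError(name)
    return df.loc[sel, "sample_id"].tolist()


def stratified_comparisons(
    matrix: MethylationMatrix | ExpressionMatrix,
    annotation: SampleAnnotation,
    genes: Optional[Sequence[str]] = None,
) -> list[GroupComparison]:
    """Per-gene Welch t-tests for tumor/normal and HPV-stratified contrasts.

    Contrasts whose strata have fewer than two usable samples are skipped with
    a logged reason.
    """
    gene_ids = list(genes) if genes is not None else matrix.row_ids
    cols = set(matrix.col_ids)
    out: list[GroupComparison] = []
    for contrast, name_a, name_b in _CONTRASTS:
        ids_a = [s for s in _stratum_ids(annotation, name_a) if s in cols]
        ids_b = [s for s in _stratum_ids(annotation, name_b) if s in cols]
        if len(ids_a) < 2 or len(ids_b) < 2:
            logger.info(
                "skipping contrast %s: stratum too small (%d vs %d)",
                contrast, len(ids_a), len(ids_b),
            )
            continue
        for gene in gene_ids:
            row = matrix.values.loc[gene]
            out.append(
                group_ttest(row.loc[ids_a], row.loc[ids_b], gene_id=gene, contrast=contrast)
            )
    return out


def build_candidate_records(
    screen_results,
    meth: MethylationMatrix,
    expr: ExpressionMatrix,
    annotation: SampleAnnotation,
) -> list[CandidateRecord]:
    """Assemble per-gene records: Spearman rho over tumor+normal samples with
    both assays, Welch t-tests (all tumors, HPV- tumors) vs normals, and the
    outlier-presence Fisher p."""
    shared = [s for s in annotation.sample_ids
              if s in meth.values.columns and s in expr.values.columns]
    tumor_ids = [s for s in annotation.samples_in_group("tumor") if s in meth.values.columns]
    normal_ids = [s for s in annotation.samples_in_group("normal") if s in meth.values.columns]
    hpvneg_ids = [s for s in _stratum_ids(annotation, "tumor_hpvneg") if s in meth.values.columns]
    records = []
    for res in screen_results:
        gene = res.gene_id
        rec = CandidateRecord(gene_id=gene, outlier_score=res.score)
        if gene in expr.values.index:
            try:
                rec.spearman_rho, rec.spearman_p = spearman_meth_expr(
                    meth.values.loc[gene, shared], expr.values.loc[gene, shared]
                )
            except (ConstantVectorError, ValidationError) as exc:
                logger.warning("gene %s: %s", gene, exc)
        mrow = meth.values.loc[gene]
        try:
            rec.ttest_p_all = group_ttest(mrow.loc[tumor_ids], mrow.loc[normal_ids]).p
        except ValidationError:
            pass
        if len(hpvneg_ids) >= 2:
            rec.ttest_p_hpvneg = group_ttest(mrow.loc[hpvneg_ids], mrow.loc[normal_ids]).p
        # normals are judged against the same gene-level cutoff; the screening
        # outlier set itself is tumor-only
        normals = mrow.loc[normal_ids]
        if res.tail == "right":
            n_norm_out = int((normals > res.baseline_cutoff).sum())
        else:
            n_norm_out = int((normals < res.baseline_cutoff).sum())
        rec.fisher_outlier_p = fisher_outlier_presence(
            len(res.outlier_samples), len(tumor_ids), n_norm_out, len(normal_ids)
        )
        records.append(rec)
    return records


def candidates_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "score": [r.outlier_score for r in records],
            "rho": [r.spearman_rho for r in records],
            "rho_p": [r.spearman_p for r in records],
            "ttest_p": [r.ttest_p_all for r in records],
            "ttest_p_hpvneg": [r.ttest_p_hpvneg for r in records],
            "fisher_outlier_p": [r.fisher_outlier_p for r in records],
            "passed_correlation_filter": [r.passed_correlation_filter for r in records],
        }
    )
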